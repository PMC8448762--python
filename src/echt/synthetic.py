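"""Synthetic structures with known hierarchical disorder.

Peptides are built from ideal internal coordinates (NeRF chain extension)
so backbone hydrogen-bond geometry is realistic enough for secondary-
structure detection.  Ground-truth ADPs are composed additively from TLS
groups assigned to scheme levels, optionally with isotropic noise, and the
composition is recorded for parameter-recovery tests.

``sample_rigid_ensemble`` is the Monte-Carlo oracle for the closed-form
TLS contribution: it draws rigid-body (rotation, translation) pairs from
the Gaussian implied by the T/L/S matrices and accumulates linearized
per-atom displacement covariances.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from . import adp
from .adp import B_SCALE
from .hierarchy import LevelScheme
from .structure_io import AtomRecord
from .tls import TLSMatrices, mean_trace_third, tls_uij

__all__ = ["make_peptide", "make_ground_truth", "sample_rigid_ensemble"]

# heavy-atom templates beyond the backbone (N, CA, C, O); entries are
# (name, element, bond, angle, torsion) placed from (N, CA, CB) -- CB itself
# is placed from (N, C, CA).
_SIDECHAINS = {
    "GLY": [],
    "ALA": [("CB", "C")],
    "PRO": [("CB", "C"), ("CG", "C", 1.50, 104.0, -30.0)],
    "SER": [("CB", "C"), ("OG", "O", 1.42, 110.5, -60.0)],
    "VAL": [("CB", "C"), ("CG1", "C", 1.52, 110.5, -60.0)],
    "THR": [("CB", "C"), ("OG1", "O", 1.43, 109.6, -60.0)],
    "LEU": [("CB", "C"), ("CG", "C", 1.53, 116.3, -60.0)],
    "ASP": [("CB", "C"), ("CG", "C", 1.52, 112.6, -60.0)],
    "PHE": [("CB", "C"), ("CG", "C", 1.50, 113.8, -60.0)],
}

_DEFAULT_POOL = ["SER", "VAL", "THR", "LEU", "ASP", "PHE", "GLY", "ALA", "PRO"]

_CONFORMATIONS = {"extended": (-140.0, 135.0), "helix": (-57.0, -47.0)}


def residue_template(res_name: str) -> list[str]:
    """Heavy-atom names of one residue in the synthetic peptide."""
    return ["N", "CA", "C", "O"] + [s[0] for s in _SIDECHAINS[res_name]]


def _place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position with given bond to c, angle at c, torsion a-b-c-*."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_peptide(
    n_residues: int,
    n_chains: int = 1,
    seed: int = 0,
    conformation: str = "extended",
    sequence: list[str] | None = None,
    phi_psi: tuple[float, float] | list[tuple[float, float]] | None = None,
) -> list[AtomRecord]:
    """Build an idealized peptide with standard bond geometry.

    Deterministic for a fixed seed; residue names are drawn from a pool
    covering both Gly/Ala/Pro and regular residues unless ``sequence``
    (cycled) is given.  ``phi_psi`` overrides the named conformation, either
    as one (phi, psi) pair or one pair per residue.  Chains are labelled
    A, B, ... and translated apart.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if phi_psi is None:
        torsions = [_CONFORMATIONS[conformation]] * n_residues
    elif isinstance(phi_psi, tuple):
        torsions = [phi_psi] * n_residues
    else:
        torsions = [phi_psi[i % len(phi_psi)] for i in range(n_residues)]
    rng = np.random.default_rng(seed)
    if sequence is None:
        names = [str(rng.choice(_DEFAULT_POOL)) for _ in range(n_residues)]
    else:
        names = [sequence[i % len(sequence)] for i in range(n_residues)]

    atoms: list[AtomRecord] = []
    serial = 1
    for ci in range(n_chains):
        chain_id = chr(ord("A") + ci)
        offset = np.array([0.0, 0.0, 30.0 * ci])
        n_prev = ca_prev = c_prev = None
        for ri in range(n_residues):
            res = names[ri]
            phi, psi = torsions[ri]
            if ri == 0:
                n_pos = np.array([0.0, 0.0, 0.0]) + offset
                ca_pos = n_pos + np.array([1.458, 0.0, 0.0])
                ang = math.radians(111.2)
                c_pos = ca_pos + 1.525 * np.array(
                    [-math.cos(ang), math.sin(ang), 0.0]
                )
            else:
                psi_prev = torsions[ri - 1][1]
                n_pos = _place(n_prev, ca_prev, c_prev, 1.329, 116.2, psi_prev)
                ca_pos = _place(ca_prev, c_prev, n_pos, 1.458, 121.7, 180.0)
                c_pos = _place(c_prev, n_pos, ca_pos, 1.525, 111.2, phi)
            o_pos = _place(n_pos, ca_pos, c_pos, 1.231, 120.5, psi + 180.0)
            coords = {"N": n_pos, "CA": ca_pos, "C": c_pos, "O": o_pos}
            for entry in _SIDECHAINS[res]:
                if entry[0] == "CB":
                    coords["CB"] = _place(n_pos, c_pos, ca_pos, 1.53, 110.4, 122.6)
                else:
                    name, _, bond, angle, tor = entry
                    coords[name] = _place(n_pos, ca_pos, coords["CB"], bond, angle, tor)
            for name in residue_template(res):
                element = {"N": "N", "O": "O"}.get(name[0], "C")
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        atom_name=name,
                        alt_loc="",
                        res_name=res,
                        chain_id=chain_id,
                        res_seq=ri + 1,
                        icode="",
                        position=coords[name],
                        occupancy=1.0,
                        b_iso=0.0,
                        u_aniso=None,
                        element=element,
                        is_polymer=True,
                    )
                )
                serial += 1
            n_prev, ca_prev, c_prev = n_pos, ca_pos, c_pos
    return atoms


def make_ground_truth(
    atoms: list[AtomRecord],
    scheme: LevelScheme,
    amplitudes_spec: list[dict],
    noise_b: float = 0.0,
    seed: int = 0,
    isotropic_output: bool = False,
) -> tuple[list[AtomRecord], dict]:
    """Compose per-atom ADPs additively from TLS groups at scheme levels.

    Each ``amplitudes_spec`` entry selects groups on one level and assigns a
    mean equivalent-B contribution::

        {"level": "chain", "group": "all" | int, "b": 10.0,
         "T": [...6], "L": [...6], "S": [...8]}   # matrices optional

    Matrices default to an isotropic unit T; given matrices are normalized
    over the group so ``b`` is the group's mean B contribution exactly.
    Gaussian isotropic noise (sd ``noise_b``, in B units) is clipped from
    below so every output tensor stays PSD.

    Returns the new atom list (ADPs set) and a machine-readable ground-truth
    record.  Raises if a spec entry references an unknown level/group or if
    a covered atom ends up with zero disorder (the fit cannot weight it).
    """
    level_by_name = {lv.name: (k, lv) for k, lv in enumerate(scheme.levels)}
    positions = np.array([a.position for a in atoms])
    n_full = len(atoms)
    total = np.zeros((n_full, 6))
    truth: dict = {"levels": {}, "noise_b": noise_b, "seed": seed}

    covered = sorted(
        {int(i) for lv in scheme.tls_levels for g in lv.groups for i in g.selection}
    )

    for entry in amplitudes_spec:
        name = entry["level"]
        if name not in level_by_name:
            raise ValueError(f"ground-truth spec references unknown level {name!r}")
        k, level = level_by_name[name]
        if level.kind == "atomic":
            raise ValueError("ground-truth spec assigns TLS to the atomic level")
        which = entry.get("group", "all")
        group_ids = range(len(level.groups)) if which == "all" else [int(which)]
        rec = truth["levels"].setdefault(name, {"groups": []})
        for gi in group_ids:
            if gi >= len(level.groups):
                raise ValueError(f"level {name!r} has no group {gi}")
            g = level.groups[gi]
            origin = positions[g.selection].mean(axis=0)
            m = TLSMatrices(
                T=np.asarray(entry.get("T", [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]), float),
                L=np.asarray(entry.get("L", np.zeros(6)), float),
                S=np.asarray(entry.get("S", np.zeros(8)), float),
                origin=origin,
            )
            scale = mean_trace_third(m, positions[g.selection])
            if scale <= 0:
                raise ValueError("ground-truth matrices give zero mean trace")
            m = m.scaled(1.0 / scale)
            amplitude = float(entry["b"]) / B_SCALE
            g.matrices = m
            g.amplitude = amplitude
            contrib = amplitude * tls_uij(m, positions[g.selection])
            total[g.selection] += contrib
            rec["groups"].append(
                {"index": gi, "label": g.label, "amplitude": amplitude,
                 "b": float(entry["b"])}
            )

    if noise_b > 0.0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_b, size=len(covered))
        lam_min = np.linalg.eigvalsh(adp.to_matrix(total[covered]))[:, 0]
        # clip from below at 95% of the smallest eigenvalue so the tensor
        # stays PSD and keeps a strictly positive trace
        noise = np.maximum(noise, -0.95 * lam_min * B_SCALE)
        total[covered, 0] += noise / B_SCALE
        total[covered, 1] += noise / B_SCALE
        total[covered, 2] += noise / B_SCALE

    out = list(atoms)
    for i in covered:
        tr3 = total[i, :3].sum() / 3.0
        if tr3 <= 0.0:
            raise ValueError(
                f"atom {atoms[i].serial} covered by the scheme has zero disorder; "
                "assign a base level contribution"
            )
        out[i] = replace(
            atoms[i],
            b_iso=float(B_SCALE * tr3),
            u_aniso=None if isotropic_output else total[i].copy(),
        )

    # per-level mean contribution over covered atoms, for recovery checks
    for name, (k, level) in level_by_name.items():
        if level.kind == "atomic":
            continue
        contrib = np.zeros((n_full, 6))
        for g in level.groups:
            if g.amplitude > 0:
                contrib[g.selection] += g.amplitude * tls_uij(
                    g.matrices, positions[g.selection]
                )
        if name in truth["levels"]:
            truth["levels"][name]["mean_b_contribution"] = float(
                np.mean(adp.u_to_b_equivalent(contrib[covered]))
            )
    truth["mean_b_total"] = float(
        np.mean([B_SCALE * total[i, :3].sum() / 3.0 for i in covered])
    )
    return out, truth


def sample_rigid_ensemble(
    m: TLSMatrices, positions: np.ndarray, n_samples: int, seed: int = 0
) -> np.ndarray:
    """Empirical per-atom displacement covariances from sampled rigid motions.

    Draws (rotation, translation) pairs from the joint Gaussian with
    covariance ``[[L, S], [S^T, T]]`` (pseudo-square-root via symmetric
    eigendecomposition, so singular L/T are handled) and applies the
    linearized displacement ``delta = t + theta x (r - origin)``.  Valid in
    the small-angle regime; converges to the closed form at rate ~1/sqrt(n).

    Returns
    -------
    ndarray, shape (n_atoms, 6)
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    rng = np.random.default_rng(seed)
    cov = m.joint_covariance()
    if np.linalg.eigvalsh(cov)[0] < 0 and np.abs(m.S).max() > 0:
        s_trace, _ = m.best_s_trace()
        cov = m.joint_covariance(s_trace)
    w, v = np.linalg.eigh(cov)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_samples, 6)) @ root.T
    theta, t = z[:, :3], z[:, 3:]
    d = pos - m.origin
    disp = t[:, None, :] + np.cross(theta[:, None, :], d[None, :, :])
    disp = disp - disp.mean(axis=0, keepdims=True)
    cov_atoms = np.einsum("nai,naj->aij", disp, disp) / max(n_samples, 1)
    return adp.from_matrix(cov_atoms)
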