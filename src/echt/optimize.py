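"""Hierarchical disorder fitting by alternating elastic-net optimization.

The fit alternates, within each macrocycle, between (micro-)cycles of
per-group TLS-matrix simplex optimization against inter-level difference
targets, PSD-constrained atomic-ADP optimization, and a joint bounded
gradient-based optimization of all component amplitudes under combined
lasso + ridge penalties.  Between macrocycles the penalty weights decay
geometrically, so disorder is first forced into the largest-scale groups
and progressively released to smaller scales only where required.

Definitions used throughout:

* residual:  sum_a  w_a * ||U_target - U_model||_a^2, where the tensor norm
  is the squared Frobenius norm of the symmetric 3x3 (off-diagonal elements
  counted twice); for isotropically-fitted atoms the norm is replaced by
  (Tr(dU)/3)^2 so only equivalent-B magnitudes are compared.
* penalty:   Omega_alpha * sum(A) + Omega_beta * sum(A^2), with
  Omega_alpha = gamma * Omega_total and Omega_beta = (1-gamma) * Omega_total.
* amplitudes: every TLS group and every atomic ADP carries a non-negative
  scalar amplitude multiplying a normalized (unit mean-trace/3) tensor basis.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

from . import adp
from .adp import B_SCALE, SYM_WEIGHTS
from .hierarchy import LevelScheme
from .tls import TLSMatrices, TLSGroup, normalize_group, tls_uij, validate_tls

__all__ = [
    "OptimizerConfig",
    "OptimizationTrace",
    "EchtModel",
    "compute_weights",
    "level_target",
    "residual",
    "elastic_net_penalty",
    "decay_weights",
    "optimize_tls_matrices",
    "optimize_atomic_adps",
    "optimize_amplitudes",
    "fit_echt",
    "fit_isotropic_mode",
    "model_complexity",
]

_REJECTED = 1e8  # objective value returned for invalid TLS parameter sets


@dataclass
class OptimizerConfig:
    """Tunables for the hierarchical fit.

    ``omega0=None`` auto-scales the initial total elastic-net weight to
    ``omega0_scale`` times the weight-averaged input Tr(U)/3, which makes
    the first macrocycle suppress all but the largest-scale level
    independently of the input's absolute B scale.
    """

    gamma: float = 0.9  # lasso/ridge mixing
    delta: float = 0.8  # per-macrocycle penalty decay
    omega0: float | None = None  # total initial penalty weight (None = auto)
    omega0_scale: float = 5.0  # kappa for the auto scaling
    db_cutoff: float = 0.1  # amplitude-stability cutoff, A^2 (B units)
    stable_fraction: float = 0.25  # fraction of cycles amplitudes must be stable
    rmsd_cutoff: float | None = None  # optional early stop on model-vs-input RMSD
    max_macrocycles: int = 60
    min_macrocycles: int = 5
    max_microcycles: int = 8
    eps_psd: float = 1e-6  # PSD tolerance (A^2)
    simplex_step: float = 0.01  # initial simplex increment per matrix element
    simplex_maxiter: int = 120
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must be in (0, 1)")
        for name in ("db_cutoff", "eps_psd", "simplex_step", "omega0_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.omega0 is not None and self.omega0 < 0:
            raise ValueError("omega0 must be non-negative")
        if self.rmsd_cutoff is not None and self.rmsd_cutoff < 0:
            raise ValueError("rmsd_cutoff must be non-negative")


@dataclass
class MacrocycleRecord:
    cycle: int
    omega_alpha: float
    omega_beta: float
    level_mean_b: dict[str, float]
    level_sum_sq_amp: dict[str, float]
    objective: float  # unpenalized residual at end of macrocycle
    penalized_objective: float
    micro_objectives: list[float]  # penalized, one per completed microcycle
    n_simplex_unconverged: int = 0


@dataclass
class OptimizationTrace:
    """Per-macrocycle diagnostics of a fit."""

    records: list[MacrocycleRecord] = field(default_factory=list)
    converged: bool = False
    final_rmsd: float | None = None

    def as_rows(self) -> list[dict]:
        rows = []
        for r in self.records:
            for name in r.level_mean_b:
                rows.append(
                    {
                        "cycle": r.cycle,
                        "level": name,
                        "mean_b": r.level_mean_b[name],
                        "sum_sq_amplitudes": r.level_sum_sq_amp[name],
                        "omega_alpha": r.omega_alpha,
                        "omega_beta": r.omega_beta,
                        "objective": r.penalized_objective,
                    }
                )
        return rows

    def level_series(self, name: str) -> np.ndarray:
        return np.array([r.level_mean_b[name] for r in self.records])


@dataclass
class EchtModel:
    """A fitted hierarchical disorder model over the fit atoms.

    All arrays are in "fit atom" space (``fit_indices`` maps back to the
    original atom list).  The per-atom model total is, exactly by
    construction, the sum of the level contributions.
    """

    scheme: LevelScheme
    atomic_uhat: np.ndarray  # (n, 6), unit mean-trace/3 (or identity at A=0)
    atomic_amp: np.ndarray  # (n,), >= 0
    positions: np.ndarray  # (n, 3)
    fit_indices: list[int]
    isotropic_atoms: np.ndarray  # (n,) bool
    config: OptimizerConfig = field(default_factory=OptimizerConfig)
    provenance: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def flat_groups(self) -> list[TLSGroup]:
        return [g for lv in self.scheme.tls_levels for g in lv.groups]

    def level_contributions(self) -> np.ndarray:
        """(n_levels, n_atoms, 6) per-level ADP contributions (atomic last)."""
        n = self.n_atoms
        out = np.zeros((len(self.scheme.levels), n, 6))
        for k, lv in enumerate(self.scheme.tls_levels):
            for g in lv.groups:
                if g.amplitude > 0.0:
                    out[k][g.selection] += g.amplitude * tls_uij(
                        g.matrices, self.positions[g.selection]
                    )
        out[-1] = self.atomic_amp[:, None] * self.atomic_uhat
        return out

    def total_uijs(self) -> np.ndarray:
        return self.level_contributions().sum(axis=0)

    def level_mean_b(self) -> dict[str, float]:
        contribs = self.level_contributions()
        return {
            lv.name: float(np.mean(adp.u_to_b_equivalent(contribs[k])))
            for k, lv in enumerate(self.scheme.levels)
        }

    def all_amplitudes(self) -> np.ndarray:
        return np.concatenate(
            [[g.amplitude for g in self.flat_groups()], self.atomic_amp]
        )

    def complexity(self) -> tuple[float, float]:
        """Sum of all component amplitudes (A^2) and its per-atom normalization."""
        total = float(self.all_amplitudes().sum())
        return total, total / self.n_atoms

    def tls_groups_dict(self) -> dict:
        return {
            lv.name: [g.to_dict() for g in lv.groups] for lv in self.scheme.tls_levels
        }


# ---------------------------------------------------------------------------
# target function pieces


def compute_weights(input_adps: np.ndarray) -> np.ndarray:
    """Per-atom weights, inversely proportional to Tr(U)/3, normalized to sum 1."""
    u = np.asarray(input_adps, dtype=float)
    t = u[:, :3].sum(axis=1) / 3.0
    bad = np.nonzero(t <= 0.0)[0]
    if bad.size:
        raise ValueError(
            f"atom(s) {bad[:5].tolist()} have non-positive Tr(U): weights undefined"
        )
    w = 1.0 / t
    return w / w.sum()


def level_target(
    input_adps: np.ndarray, contributions: np.ndarray, k: int
) -> np.ndarray:
    """Difference target for level ``k``: input minus all other levels' model."""
    others = contributions.sum(axis=0) - contributions[k]
    return np.asarray(input_adps) - others


def _pair_scores(diff: np.ndarray, iso: np.ndarray | None) -> np.ndarray:
    """Per-atom squared tensor distances (Frobenius; trace-only for iso atoms)."""
    s = (diff**2 * SYM_WEIGHTS).sum(axis=-1)
    if iso is not None and iso.any():
        tr3 = diff[..., :3].sum(axis=-1) / 3.0
        s = np.where(iso, tr3**2, s)
    return s


def residual(
    target: np.ndarray,
    candidate: np.ndarray,
    weights: np.ndarray,
    iso: np.ndarray | None = None,
) -> float:
    """Weighted least-squares disagreement between two sets of ADPs."""
    return float((weights * _pair_scores(target - candidate, iso)).sum())


def _metric_dot(x: np.ndarray, y: np.ndarray, iso: np.ndarray | None) -> np.ndarray:
    d = (x * y * SYM_WEIGHTS).sum(axis=-1)
    if iso is not None and iso.any():
        tx = x[..., :3].sum(axis=-1) / 3.0
        ty = y[..., :3].sum(axis=-1) / 3.0
        d = np.where(iso, tx * ty, d)
    return d


def elastic_net_penalty(
    amplitudes: np.ndarray, omega_alpha: float, omega_beta: float
) -> float:
    """Lasso + ridge penalty on component amplitudes."""
    a = np.asarray(amplitudes, dtype=float)
    return float(omega_alpha * a.sum() + omega_beta * (a**2).sum())


def decay_weights(omega: float, delta: float, n_cycles: int) -> float:
    """Penalty weight after ``n_cycles`` geometric decays."""
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    return omega * delta**n_cycles


# ---------------------------------------------------------------------------
# TLS-matrix optimization (simplex)


def _s8_to_full(s8: np.ndarray) -> np.ndarray:
    return np.array(
        [
            [s8[0], s8[1], s8[2]],
            [s8[3], s8[4], s8[5]],
            [s8[6], s8[7], -(s8[0] + s8[4])],
        ]
    )


def _rotate_params(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Conjugate a (T6, L6, S8) parameter vector by rotation matrix ``r``."""
    t = r.T @ adp.to_matrix(p[:6]) @ r
    l = r.T @ adp.to_matrix(p[6:12]) @ r
    s = r.T @ _s8_to_full(p[12:]) @ r
    return np.concatenate(
        [adp.from_matrix(t), adp.from_matrix(l), s.reshape(-1)[:8]]
    )


def optimize_tls_matrices(
    group: TLSGroup,
    target: np.ndarray,
    weights: np.ndarray,
    positions: np.ndarray,
    config: OptimizerConfig,
    iso: np.ndarray | None = None,
    omega_alpha: float = 0.0,
    omega_beta: float = 0.0,
) -> tuple[TLSMatrices, bool]:
    """Refine a group's TLS matrices by simplex search at fixed amplitude.

    The starting simplex increments each of the 20 free matrix elements by
    ``config.simplex_step`` in the eigenframe of the current L matrix (lab
    frame when L is zero).  Candidate parameter sets failing the validity
    screen are rejected.  The returned matrices never have a higher residual
    than the starting ones; the ``bool`` flags simplex convergence within
    the iteration cap.

    When penalty weights are given, the searched objective additionally
    carries the elastic-net cost of the post-normalization amplitude
    (``A * mean-trace/3`` of the candidate), so accepting the result can
    never increase the penalized objective.
    """
    sel = group.selection
    tgt, w, pos = target[sel], weights[sel], positions[sel]
    iso_sel = None if iso is None else iso[sel]
    amp = group.amplitude
    origin = group.matrices.origin
    p0 = group.matrices.as_vector()

    lmat = adp.to_matrix(group.matrices.L)
    if np.abs(lmat).max() > 1e-12:
        _, frame = np.linalg.eigh(lmat)
    else:
        frame = np.eye(3)

    def objective(q: np.ndarray) -> float:
        m = TLSMatrices.from_vector(_rotate_params(q, frame.T), origin)
        if not validate_tls(m, config.eps_psd):
            return _REJECTED
        u = tls_uij(m, pos)
        f = residual(tgt, amp * u, w, iso_sel)
        if omega_alpha or omega_beta:
            a_new = amp * np.mean(u[:, :3].sum(axis=1)) / 3.0
            f += omega_alpha * a_new + omega_beta * a_new**2
        return f

    q0 = _rotate_params(p0, frame)
    simplex = np.vstack([q0] + [q0 + config.simplex_step * e for e in np.eye(q0.size)])
    res = scipy.optimize.minimize(
        objective,
        q0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "maxiter": config.simplex_maxiter,
            "xatol": 1e-8,
            "fatol": 1e-14,
        },
    )
    best = res.x if res.fun <= objective(q0) else q0
    matrices = TLSMatrices.from_vector(_rotate_params(best, frame.T), origin)
    return matrices, bool(res.success)


# ---------------------------------------------------------------------------
# atomic-level optimization


def optimize_atomic_adps(
    target: np.ndarray,
    weights: np.ndarray,
    config: OptimizerConfig,
    iso: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom least-squares ADPs constrained to the PSD cone.

    For anisotropic atoms the minimizer is the PSD projection of the target
    (eigenvalue clipping); for isotropic atoms it is ``max(Tr/3, 0)``
    times the identity.  Results are returned in normalized form:
    amplitudes ``A_a = Tr(U_a)/3`` and unit-mean-trace tensors ``U_hat``
    (identity for zero amplitudes).
    """
    target = np.asarray(target, dtype=float)
    n = target.shape[0]
    u = adp.psd_project(target)
    if iso is not None and iso.any():
        tr3 = np.clip(target[:, :3].sum(axis=1) / 3.0, 0.0, None)
        u_iso = np.zeros_like(target)
        u_iso[:, :3] = tr3[:, None]
        u = np.where(iso[:, None], u_iso, u)
    amps = u[:, :3].sum(axis=1) / 3.0
    uhat = np.zeros((n, 6))
    uhat[:, :3] = 1.0
    nz = amps > 0.0
    uhat[nz] = u[nz] / amps[nz, None]
    return uhat, amps


# ---------------------------------------------------------------------------
# joint amplitude optimization


def optimize_amplitudes(
    model: EchtModel,
    input_adps: np.ndarray,
    weights: np.ndarray,
    omega_alpha: float,
    omega_beta: float,
) -> np.ndarray:
    """Jointly optimize all group and atomic amplitudes (non-negative).

    Minimizes the weighted residual to ``input_adps`` plus the elastic-net
    penalty over all amplitudes, with normalized tensor bases fixed, using
    L-BFGS-B with analytic gradients and ``A >= 0`` bounds.  Returns the
    amplitude vector (groups in level order, then atoms); the achieved
    objective never exceeds the starting one.
    """
    groups = model.flat_groups()
    iso = model.isotropic_atoms
    n = model.n_atoms
    bases = [tls_uij(g.matrices, model.positions[g.selection]) for g in groups]
    x0 = model.all_amplitudes()
    n_g = len(groups)

    def assemble(x: np.ndarray) -> np.ndarray:
        u = x[n_g:, None] * model.atomic_uhat
        for j, g in enumerate(groups):
            if x[j] != 0.0:
                u[g.selection] += x[j] * bases[j]
        return u

    def fun_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        r = input_adps - assemble(x)
        f = float((weights * _pair_scores(r, iso)).sum())
        f += omega_alpha * x.sum() + omega_beta * float((x**2).sum())
        grad = np.empty_like(x)
        for j, g in enumerate(groups):
            sel = g.selection
            grad[j] = -2.0 * float(
                (weights[sel] * _metric_dot(r[sel], bases[j], None if iso is None else iso[sel])).sum()
            )
        grad[n_g:] = -2.0 * weights * _metric_dot(r, model.atomic_uhat, iso)
        grad += omega_alpha + 2.0 * omega_beta * x
        return f, grad

    res = scipy.optimize.minimize(
        fun_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * x0.size,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
    )
    x = np.clip(res.x, 0.0, None)
    if fun_grad(x)[0] > fun_grad(x0)[0]:
        x = x0
    return x


# ---------------------------------------------------------------------------
# the full fit


def _remap_scheme(scheme: LevelScheme, positions_full: np.ndarray):
    """Deep-copy a scheme into fit-atom index space; reset groups to the
    initial state (isotropic unit T, zero L/S, zero amplitude)."""
    fit_idx = sorted(
        {int(i) for lv in scheme.tls_levels for g in lv.groups for i in g.selection}
    )
    local = {orig: k for k, orig in enumerate(fit_idx)}
    new_scheme = copy.deepcopy(scheme)
    for lv in new_scheme.tls_levels:
        for j, g in enumerate(lv.groups):
            sel = np.array([local[int(i)] for i in g.selection], dtype=int)
            origin = positions_full[[fit_idx[k] for k in sel]].mean(axis=0)
            t = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
            lv.groups[j] = TLSGroup(
                selection=sel,
                matrices=TLSMatrices(T=t, origin=origin),
                amplitude=0.0,
                label=g.label,
            )
    return new_scheme, fit_idx


def _auto_omega0(weights: np.ndarray, u_input: np.ndarray, scale: float) -> float:
    t = u_input[:, :3].sum(axis=1) / 3.0
    return float(scale * (weights * t).sum())


def _apply_amplitudes(model: EchtModel, x: np.ndarray) -> None:
    groups = model.flat_groups()
    for j, g in enumerate(groups):
        g.amplitude = float(x[j])
    model.atomic_amp = x[len(groups):].copy()


def _rmsd(u_input: np.ndarray, u_model: np.ndarray, iso: np.ndarray) -> float:
    d = u_input - u_model
    s = (d**2 * SYM_WEIGHTS).sum(axis=-1)
    tr3 = d[:, :3].sum(axis=-1) / 3.0
    s = np.where(iso, 3.0 * tr3**2, s)
    return float(math.sqrt(s.mean() / 3.0))


def fit_echt(
    atoms: list,
    scheme: LevelScheme,
    config: OptimizerConfig | None = None,
    force_isotropic: bool = False,
) -> tuple[EchtModel, OptimizationTrace]:
    """Fit the hierarchical disorder model to a structure's ADPs.

    Parameters
    ----------
    atoms : list of AtomRecord
        Structure with displacement parameters; ``scheme`` selections index
        into this list.
    scheme : LevelScheme
        Level partitioning (atomic level last).
    config : OptimizerConfig
    force_isotropic : bool
        Fit every atom isotropically regardless of deposited a-ADPs.

    Returns
    -------
    (EchtModel, OptimizationTrace)
    """
    config = config or OptimizerConfig()
    config.validate()

    positions_full = np.array([a.position for a in atoms])
    local_scheme, fit_idx = _remap_scheme(scheme, positions_full)
    n = len(fit_idx)
    positions = positions_full[fit_idx]
    u_input = np.array([atoms[i].u for i in fit_idx])
    iso = np.array(
        [force_isotropic or atoms[i].u_aniso is None for i in fit_idx], dtype=bool
    )
    weights = compute_weights(u_input)

    uhat0 = np.zeros((n, 6))
    uhat0[:, :3] = 1.0
    model = EchtModel(
        scheme=local_scheme,
        atomic_uhat=uhat0,
        atomic_amp=np.zeros(n),
        positions=positions,
        fit_indices=fit_idx,
        isotropic_atoms=iso,
        config=config,
        provenance={"n_atoms": n, "isotropic_mode": bool(iso.all())},
    )

    gamma0 = config.omega0 if config.omega0 is not None else _auto_omega0(
        weights, u_input, config.omega0_scale
    )
    trace = OptimizationTrace()
    amp_history: list[np.ndarray] = []
    db_u = config.db_cutoff / B_SCALE  # stability cutoff in U units
    n_levels = len(model.scheme.levels)

    for cycle in range(1, config.max_macrocycles + 1):
        oa = config.gamma * gamma0
        ob = (1.0 - config.gamma) * gamma0
        micro_objectives: list[float] = []
        n_bad_simplex = 0

        for _micro in range(config.max_microcycles):
            amps_before = model.all_amplitudes()
            contribs = model.level_contributions()

            # per-level TLS matrix refinement (largest scale first)
            for k, level in enumerate(model.scheme.tls_levels):
                target = level_target(u_input, contribs, k)
                changed = False
                for g in level.groups:
                    if g.amplitude <= 0.0:
                        continue
                    new_m, ok = optimize_tls_matrices(
                        g, target, weights, positions, config, iso, oa, ob
                    )
                    n_bad_simplex += not ok
                    g.matrices = new_m
                    gn = normalize_group(g, positions)
                    g.matrices, g.amplitude = gn.matrices, gn.amplitude
                    changed = True
                if changed:
                    contribs[k] = 0.0
                    for g in level.groups:
                        if g.amplitude > 0.0:
                            contribs[k][g.selection] += g.amplitude * tls_uij(
                                g.matrices, positions[g.selection]
                            )

            # atomic level (guarded so the penalized objective cannot rise)
            tls_sum = contribs[:-1].sum(axis=0)
            pen_before = residual(
                u_input, tls_sum + contribs[-1], weights, iso
            ) + elastic_net_penalty(model.all_amplitudes(), oa, ob)
            cand_uhat, cand_amp = optimize_atomic_adps(
                u_input - tls_sum, weights, config, iso
            )
            cand_total = tls_sum + cand_amp[:, None] * cand_uhat
            amps_cand = np.concatenate(
                [[g.amplitude for g in model.flat_groups()], cand_amp]
            )
            pen_after = residual(u_input, cand_total, weights, iso) + elastic_net_penalty(
                amps_cand, oa, ob
            )
            if pen_after <= pen_before + 1e-12:
                model.atomic_uhat, model.atomic_amp = cand_uhat, cand_amp

            # joint amplitude optimization
            x = optimize_amplitudes(model, u_input, weights, oa, ob)
            _apply_amplitudes(model, x)

            contribs = model.level_contributions()
            obj = residual(u_input, contribs.sum(axis=0), weights, iso)
            micro_objectives.append(obj + elastic_net_penalty(x, oa, ob))

            if np.abs(model.all_amplitudes() - amps_before).max() < db_u:
                break

        contribs = model.level_contributions()
        obj = residual(u_input, contribs.sum(axis=0), weights, iso)
        level_b = {
            lv.name: float(np.mean(adp.u_to_b_equivalent(contribs[k])))
            for k, lv in enumerate(model.scheme.levels)
        }
        level_ssq = {}
        for k, lv in enumerate(model.scheme.levels):
            if lv.kind == "atomic":
                level_ssq[lv.name] = float((model.atomic_amp**2).sum())
            else:
                level_ssq[lv.name] = float(
                    sum(g.amplitude**2 for g in lv.groups)
                )
        trace.records.append(
            MacrocycleRecord(
                cycle=cycle,
                omega_alpha=oa,
                omega_beta=ob,
                level_mean_b=level_b,
                level_sum_sq_amp=level_ssq,
                objective=obj,
                penalized_objective=micro_objectives[-1],
                micro_objectives=micro_objectives,
                n_simplex_unconverged=n_bad_simplex,
            )
        )

        amp_history.append(model.all_amplitudes())
        if _is_converged(amp_history, cycle, config, db_u):
            trace.converged = True
        rmsd = _rmsd(u_input, contribs.sum(axis=0), iso)
        if config.rmsd_cutoff is not None and rmsd <= config.rmsd_cutoff:
            trace.converged = True
        if trace.converged:
            break
        gamma0 = decay_weights(gamma0, config.delta, 1)

    trace.final_rmsd = _rmsd(u_input, model.total_uijs(), iso)
    return model, trace


def _is_converged(
    amp_history: list[np.ndarray],
    cycle: int,
    config: OptimizerConfig,
    db_u: float,
) -> bool:
    if cycle < config.min_macrocycles:
        return False
    window = max(2, math.ceil(config.stable_fraction * cycle))
    if len(amp_history) < window + 1:
        return False
    recent = amp_history[-(window + 1):]
    diffs = [np.abs(recent[i + 1] - recent[i]).max() for i in range(window)]
    return all(d < db_u for d in diffs)


def fit_isotropic_mode(
    atoms: list, scheme: LevelScheme, config: OptimizerConfig | None = None
) -> tuple[EchtModel, OptimizationTrace]:
    """Fit against isotropic equivalent B-factors only.

    Only the magnitudes of the anisotropic TLS components are constrained by
    the data; the atomic level is kept isotropic.  Used for structures
    refined with i-ADPs (or mixtures, by calling :func:`fit_echt` directly).
    """
    return fit_echt(atoms, scheme, config, force_isotropic=True)


def model_complexity(model: EchtModel) -> tuple[float, float]:
    """Sum of all component amplitudes (A^2), plus per-atom normalization."""
    return model.complexity()
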