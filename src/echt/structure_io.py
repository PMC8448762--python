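"""Structure input/output: atom records with ADPs, PDB/mmCIF round trips.

Reading is backed by Biopython (``Bio.PDB`` for PDB files, ``MMCIF2Dict``
for mmCIF); writing uses compact fixed-column / ``atom_site`` emitters so
that ANISOU records and REMARK 3 TLS blocks are fully under our control.

Author residue numbering (chain id, residue number, insertion code) is
preserved verbatim through read/write cycles so that selection strings
survive round trips.
"""

from __future__ import annotations

import json
import logging
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import adp
from .tls import TLSMatrices, tls_uij

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "read_structure",
    "write_pdb",
    "write_mmcif",
    "write_level_structures",
    "write_summary",
]

DEG2 = (math.pi / 180.0) ** 2  # deg^2 -> rad^2
DEG = math.pi / 180.0


@dataclass
class AtomRecord:
    """One atom with coordinates and displacement parameters.

    ``u_aniso``, when present, stores the 6 unique tensor elements in A^2
    (ANISOU order).  ``b_iso`` is the isotropic(-equivalent) B-factor in A^2.
    """

    serial: int
    atom_name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    icode: str
    position: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0
    u_aniso: np.ndarray | None = None
    element: str = ""
    is_polymer: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.u_aniso is not None:
            self.u_aniso = np.asarray(self.u_aniso, dtype=float)

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def u(self) -> np.ndarray:
        """Displacement tensor; isotropic embedding of b_iso when no a-ADP."""
        if self.u_aniso is not None:
            return self.u_aniso
        return adp.iso_to_u(self.b_iso)


# ---------------------------------------------------------------------------
# reading


def read_structure(path: str | Path, tls_handling: str = "include") -> list[AtomRecord]:
    """Read a PDB or mmCIF structure into a flat list of atom records.

    ANISOU integers are scaled by 1e-4 to A^2.  When REMARK 3 (or
    ``_pdbx_refine_tls``) TLS parameters are present and
    ``tls_handling="include"``, the TLS contribution is evaluated per atom
    and added to the atomic ADPs (producing a-ADPs); ``"exclude"`` leaves
    the residual ADPs as deposited.

    Raises
    ------
    ValueError
        If the structure carries no displacement parameters at all.
    """
    if tls_handling not in ("include", "exclude"):
        raise ValueError("tls_handling must be 'include' or 'exclude'")
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        atoms, tls_groups = _read_mmcif(path)
    else:
        atoms, tls_groups = _read_pdb(path)
    if not atoms:
        raise ValueError(f"no atoms read from {path}")
    if all(a.b_iso == 0.0 and a.u_aniso is None for a in atoms):
        raise ValueError(f"{path} carries no displacement parameters")
    for a in atoms:
        _check_b_consistency(a)
    if tls_handling == "include" and tls_groups:
        _apply_tls_contributions(atoms, tls_groups)
    return atoms


def _check_b_consistency(a: AtomRecord) -> None:
    if a.u_aniso is None:
        return
    b_from_u = adp.u_to_b_equivalent(a.u_aniso)
    # ANISOU quantization is 1e-4 A^2 in U -> ~0.008 A^2 in B; the B column
    # itself is quantized at 0.01 A^2.  Warn (don't fail) beyond that.
    if abs(b_from_u - a.b_iso) > 0.05:
        warnings.warn(
            f"atom {a.serial} {a.atom_name}: B column {a.b_iso:.2f} inconsistent "
            f"with ANISOU equivalent {b_from_u:.2f}",
            stacklevel=3,
        )


def _read_pdb(path: Path) -> tuple[list[AtomRecord], list[dict]]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    atoms: list[AtomRecord] = []
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            hetfield, resseq, icode = residue.id
            is_polymer = hetfield == " "
            for atom in residue.get_unpacked_list():
                anisou = atom.get_anisou()
                u = None if anisou is None else np.asarray(anisou, dtype=float)
                atoms.append(
                    AtomRecord(
                        serial=atom.serial_number,
                        atom_name=atom.get_name(),
                        alt_loc=atom.get_altloc().strip(),
                        res_name=residue.get_resname().strip(),
                        chain_id=chain.id,
                        res_seq=int(resseq),
                        icode=icode.strip(),
                        position=atom.get_coord().astype(float),
                        occupancy=float(atom.get_occupancy() or 0.0),
                        b_iso=float(atom.get_bfactor() or 0.0),
                        u_aniso=u,
                        element=(atom.element or "").strip(),
                        is_polymer=is_polymer,
                    )
                )
    tls_groups = _parse_remark3_tls(path.read_text().splitlines())
    return atoms, tls_groups


def _mmcif_value(v: str) -> str:
    return "" if v in ("?", ".") else v


def _read_mmcif(path: Path) -> tuple[list[AtomRecord], list[dict]]:
    from Bio.PDB.MMCIF2Dict import MMCIF2Dict

    d = MMCIF2Dict(str(path))

    def col(name: str, default=None):
        v = d.get(name, default)
        if v is None:
            return None
        return v if isinstance(v, list) else [v]

    n = len(col("_atom_site.id"))
    aniso: dict[str, np.ndarray] = {}
    if "_atom_site_anisotrop.id" in d:
        ids = col("_atom_site_anisotrop.id")
        keys = ["U[1][1]", "U[2][2]", "U[3][3]", "U[1][2]", "U[1][3]", "U[2][3]"]
        cols = [col(f"_atom_site_anisotrop.{k}") for k in keys]
        for i, aid in enumerate(ids):
            aniso[aid] = np.array([float(c[i]) for c in cols])

    atoms = []
    group = col("_atom_site.group_PDB", ["ATOM"] * n)
    alt = col("_atom_site.label_alt_id", ["."] * n)
    icode = col("_atom_site.pdbx_PDB_ins_code", ["?"] * n)
    occ = col("_atom_site.occupancy", ["1.0"] * n)
    b = col("_atom_site.B_iso_or_equiv", ["0.0"] * n)
    chain = col("_atom_site.auth_asym_id") or col("_atom_site.label_asym_id")
    resseq = col("_atom_site.auth_seq_id") or col("_atom_site.label_seq_id")
    for i in range(n):
        aid = col("_atom_site.id")[i]
        atoms.append(
            AtomRecord(
                serial=int(aid),
                atom_name=col("_atom_site.label_atom_id")[i],
                alt_loc=_mmcif_value(alt[i]),
                res_name=col("_atom_site.label_comp_id")[i],
                chain_id=chain[i],
                res_seq=int(resseq[i]),
                icode=_mmcif_value(icode[i]),
                position=np.array(
                    [
                        float(col("_atom_site.Cartn_x")[i]),
                        float(col("_atom_site.Cartn_y")[i]),
                        float(col("_atom_site.Cartn_z")[i]),
                    ]
                ),
                occupancy=float(occ[i]),
                b_iso=float(b[i]),
                u_aniso=aniso.get(aid),
                element=_mmcif_value(col("_atom_site.type_symbol", [""] * n)[i]),
                is_polymer=group[i] == "ATOM",
            )
        )
    return atoms, _parse_mmcif_tls(d)


# --- REMARK 3 TLS ----------------------------------------------------------

_TENSOR_RE = re.compile(r"([TLS]\d\d)\s*:\s*(-?[\d.]+(?:[eE][+-]?\d+)?)")
_FLOAT_RE = re.compile(r"-?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _parse_remark3_tls(lines: list[str]) -> list[dict]:
    """Parse REFMAC-style REMARK 3 TLS groups (T/L/S tensors + ranges).

    Returns raw dicts with T (A^2), L (deg^2), S (A deg), origin and residue
    ranges; unit conversion happens when the contribution is applied.
    Unparseable groups are skipped with a warning.
    """
    groups: list[dict] = []
    current: dict | None = None
    for line in lines:
        if not line.startswith("REMARK   3"):
            continue
        body = line[10:].strip()
        if body.startswith("TLS GROUP"):
            current = {"ranges": [], "tensors": {}, "origin": None}
            groups.append(current)
        elif current is None:
            continue
        elif body.startswith("RESIDUE RANGE"):
            toks = body.split(":", 1)[1].split()
            if len(toks) == 4:
                current["ranges"].append(
                    (toks[0], int(toks[1]), toks[2], int(toks[3]))
                )
        elif body.startswith("ORIGIN FOR THE GROUP"):
            vals = _FLOAT_RE.findall(body.split(":", 1)[1])
            if len(vals) >= 3:
                current["origin"] = np.array([float(v) for v in vals[:3]])
        else:
            for key, val in _TENSOR_RE.findall(body):
                current["tensors"][key] = float(val)
    out = []
    for g in groups:
        if g["origin"] is None or len(g["tensors"]) < 12 or not g["ranges"]:
            if g["tensors"] or g["ranges"]:
                warnings.warn("skipping incomplete REMARK 3 TLS group", stacklevel=3)
            continue
        out.append(g)
    return out


def _parse_mmcif_tls(d: dict) -> list[dict]:
    if "_pdbx_refine_tls.id" not in d:
        return []

    def col(name):
        v = d[name]
        return v if isinstance(v, list) else [v]

    ids = col("_pdbx_refine_tls.id")
    groups = []
    key_map = {
        "T11": "T[1][1]", "T22": "T[2][2]", "T33": "T[3][3]",
        "T12": "T[1][2]", "T13": "T[1][3]", "T23": "T[2][3]",
        "L11": "L[1][1]", "L22": "L[2][2]", "L33": "L[3][3]",
        "L12": "L[1][2]", "L13": "L[1][3]", "L23": "L[2][3]",
        "S11": "S[1][1]", "S12": "S[1][2]", "S13": "S[1][3]",
        "S21": "S[2][1]", "S22": "S[2][2]", "S23": "S[2][3]",
        "S31": "S[3][1]", "S32": "S[3][2]", "S33": "S[3][3]",
    }
    rng_ids = col("_pdbx_refine_tls_group.refine_tls_id") if (
        "_pdbx_refine_tls_group.refine_tls_id" in d
    ) else []
    for i, gid in enumerate(ids):
        tensors = {
            k: float(col(f"_pdbx_refine_tls.{v}")[i]) for k, v in key_map.items()
        }
        origin = np.array(
            [
                float(col("_pdbx_refine_tls.origin_x")[i]),
                float(col("_pdbx_refine_tls.origin_y")[i]),
                float(col("_pdbx_refine_tls.origin_z")[i]),
            ]
        )
        ranges = []
        for j, rid in enumerate(rng_ids):
            if rid != gid:
                continue
            c1 = col("_pdbx_refine_tls_group.beg_auth_asym_id")[j]
            r1 = int(col("_pdbx_refine_tls_group.beg_auth_seq_id")[j])
            c2 = col("_pdbx_refine_tls_group.end_auth_asym_id")[j]
            r2 = int(col("_pdbx_refine_tls_group.end_auth_seq_id")[j])
            ranges.append((c1, r1, c2, r2))
        if ranges:
            groups.append({"ranges": ranges, "tensors": tensors, "origin": origin})
    return groups


def _tls_group_matrices(g: dict) -> TLSMatrices:
    """Convert a parsed REMARK-3-convention group to internal units."""
    t = g["tensors"]
    T = np.array([t["T11"], t["T22"], t["T33"], t["T12"], t["T13"], t["T23"]])
    L = np.array([t["L11"], t["L22"], t["L33"], t["L12"], t["L13"], t["L23"]]) * DEG2
    # internal S stores 8 free elements, trace removed
    s_full = np.array(
        [t["S11"], t["S12"], t["S13"], t["S21"], t["S22"], t["S23"],
         t["S31"], t["S32"], t.get("S33", -(t["S11"] + t["S22"]))]
    ) * DEG
    trace = (s_full[0] + s_full[4] + s_full[8]) / 3.0
    s_full[0] -= trace
    s_full[4] -= trace
    s_full[8] -= trace
    return TLSMatrices(T=T, L=L, S=s_full[:8], origin=g["origin"])


def _apply_tls_contributions(atoms: list[AtomRecord], tls_groups: list[dict]) -> None:
    for g in tls_groups:
        m = _tls_group_matrices(g)
        sel = []
        for i, a in enumerate(atoms):
            for c1, r1, c2, r2 in g["ranges"]:
                if c1 != c2:
                    warnings.warn("multi-chain TLS range not supported", stacklevel=3)
                    continue
                if a.chain_id == c1 and r1 <= a.res_seq <= r2:
                    sel.append(i)
                    break
        if not sel:
            continue
        pos = np.array([atoms[i].position for i in sel])
        u_tls = tls_uij(m, pos)
        for k, i in enumerate(sel):
            a = atoms[i]
            a.u_aniso = a.u + u_tls[k]
            a.b_iso = adp.u_to_b_equivalent(a.u_aniso)


# ---------------------------------------------------------------------------
# writing


def _pdb_atom_name(a: AtomRecord) -> str:
    name = a.atom_name
    if len(name) >= 4:
        return name[:4]
    if len(a.element) == 1 or (not a.element and len(name) < 4):
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(
    atoms: list[AtomRecord],
    path: str | Path,
    write_aniso: bool = True,
    header_lines: list[str] | None = None,
) -> None:
    """Write atom records as a PDB file (ATOM/HETATM + optional ANISOU)."""
    lines: list[str] = list(header_lines or [])
    for a in atoms:
        rec = "ATOM  " if a.is_polymer else "HETATM"
        x, y, z = a.position
        lines.append(
            f"{rec}{a.serial % 100000:5d} {_pdb_atom_name(a)}{a.alt_loc or ' ':1s}"
            f"{a.res_name:>3s} {a.chain_id:1s}{a.res_seq:4d}{a.icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_iso:6.2f}"
            f"          {a.element:>2s}"
        )
        if write_aniso and a.u_aniso is not None:
            u = np.rint(a.u_aniso * 1e4).astype(int)
            lines.append(
                f"ANISOU{a.serial % 100000:5d} {_pdb_atom_name(a)}"
                f"{a.alt_loc or ' ':1s}{a.res_name:>3s} "
                f"{a.chain_id:1s}{a.res_seq:4d}{a.icode or ' ':1s} "
                f"{u[0]:7d}{u[1]:7d}{u[2]:7d}{u[3]:7d}{u[4]:7d}{u[5]:7d}"
                f"      {a.element:>2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mmcif(
    atoms: list[AtomRecord],
    path: str | Path,
    write_aniso: bool = True,
    data_name: str = "echt",
) -> None:
    """Write atom records as a minimal mmCIF (atom_site + anisotrop loops)."""
    out = [f"data_{data_name}", "#", "loop_"]
    out += [
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_seq_id",
        "_atom_site.pdbx_PDB_ins_code",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.occupancy",
        "_atom_site.B_iso_or_equiv",
        "_atom_site.auth_seq_id",
        "_atom_site.auth_asym_id",
    ]
    for a in atoms:
        x, y, z = a.position
        out.append(
            f"{'ATOM' if a.is_polymer else 'HETATM'} {a.serial} "
            f"{a.element or '?'} {a.atom_name} {a.alt_loc or '.'} {a.res_name} "
            f"{a.chain_id} {a.res_seq} {a.icode or '?'} "
            f"{x:.3f} {y:.3f} {z:.3f} {a.occupancy:.2f} {a.b_iso:.3f} "
            f"{a.res_seq} {a.chain_id}"
        )
    aniso_atoms = [a for a in atoms if a.u_aniso is not None] if write_aniso else []
    if aniso_atoms:
        out += ["#", "loop_"]
        out += [
            "_atom_site_anisotrop.id",
            "_atom_site_anisotrop.type_symbol",
            "_atom_site_anisotrop.U[1][1]",
            "_atom_site_anisotrop.U[2][2]",
            "_atom_site_anisotrop.U[3][3]",
            "_atom_site_anisotrop.U[1][2]",
            "_atom_site_anisotrop.U[1][3]",
            "_atom_site_anisotrop.U[2][3]",
        ]
        for a in aniso_atoms:
            u = a.u_aniso
            out.append(
                f"{a.serial} {a.element or '?'} "
                + " ".join(f"{v:.5f}" for v in u)
            )
    out.append("#")
    Path(path).write_text("\n".join(out) + "\n")


def tls_remark3_lines(groups, atoms: list[AtomRecord]) -> list[str]:
    """Serialize TLS groups to PDB REMARK 3 convention (L in deg^2, S in A deg)."""
    lines = ["REMARK   3  TLS DETAILS", f"REMARK   3   NUMBER OF TLS GROUPS  : {len(groups)}"]
    for n, g in enumerate(groups, start=1):
        sel_atoms = [atoms[i] for i in g.selection]
        lines.append(f"REMARK   3   TLS GROUP : {n}")
        # contiguous residue ranges per chain
        for c, r1, r2 in _residue_ranges(sel_atoms):
            lines.append(
                f"REMARK   3    RESIDUE RANGE :   {c}  {r1:>4d}        {c}  {r2:>4d}"
            )
        ox, oy, oz = g.matrices.origin
        lines.append(
            f"REMARK   3    ORIGIN FOR THE GROUP (A): {ox:9.4f} {oy:9.4f} {oz:9.4f}"
        )
        amp = g.amplitude
        T = g.matrices.T * amp
        L = g.matrices.L * amp / DEG2
        s_full = g.matrices.s_matrix.reshape(-1) * amp / DEG
        lines.append("REMARK   3    T TENSOR")
        lines.append(f"REMARK   3      T11: {T[0]:8.4f} T22: {T[1]:8.4f}")
        lines.append(f"REMARK   3      T33: {T[2]:8.4f} T12: {T[3]:8.4f}")
        lines.append(f"REMARK   3      T13: {T[4]:8.4f} T23: {T[5]:8.4f}")
        lines.append("REMARK   3    L TENSOR")
        lines.append(f"REMARK   3      L11: {L[0]:8.4f} L22: {L[1]:8.4f}")
        lines.append(f"REMARK   3      L33: {L[2]:8.4f} L12: {L[3]:8.4f}")
        lines.append(f"REMARK   3      L13: {L[4]:8.4f} L23: {L[5]:8.4f}")
        lines.append("REMARK   3    S TENSOR")
        lines.append(
            f"REMARK   3      S11: {s_full[0]:8.4f} S12: {s_full[1]:8.4f} S13: {s_full[2]:8.4f}"
        )
        lines.append(
            f"REMARK   3      S21: {s_full[3]:8.4f} S22: {s_full[4]:8.4f} S23: {s_full[5]:8.4f}"
        )
        lines.append(
            f"REMARK   3      S31: {s_full[6]:8.4f} S32: {s_full[7]:8.4f} S33: {s_full[8]:8.4f}"
        )
    return lines


def _residue_ranges(sel_atoms: list[AtomRecord]) -> list[tuple[str, int, int]]:
    by_chain: dict[str, list[int]] = {}
    for a in sel_atoms:
        by_chain.setdefault(a.chain_id, []).append(a.res_seq)
    out = []
    for c, seqs in by_chain.items():
        seqs = sorted(set(seqs))
        start = prev = seqs[0]
        for s in seqs[1:]:
            if s != prev + 1:
                out.append((c, start, prev))
                start = s
            prev = s
        out.append((c, start, prev))
    return out


# ---------------------------------------------------------------------------
# fitted-model output


def write_level_structures(model, atoms: list[AtomRecord], outdir: str | Path) -> list[Path]:
    """Write one structure per level (B = level contribution) plus the total.

    Each level file stores, per atom, the equivalent B of that level's
    contribution in the B column and the contribution tensor as ANISOU
    records (suppressed for atoms fitted isotropically).  Atoms without a
    group at a level get B = 0.  Returns the written paths.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {outdir}: {e}") from e
    contribs = model.level_contributions()
    iso = model.isotropic_atoms
    paths = []
    for k, level in enumerate(model.scheme.levels):
        paths += _write_contribution(
            atoms, contribs[k], iso, outdir, f"level_{k:02d}_{_slug(level.name)}"
        )
    total = np.sum(contribs, axis=0)
    paths += _write_contribution(atoms, total, iso, outdir, "total")
    sidecar = outdir / "tls_groups.json"
    sidecar.write_text(json.dumps(model.tls_groups_dict(), indent=1))
    paths.append(sidecar)
    return paths


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_").lower()


def _write_contribution(atoms, u6: np.ndarray, iso_flags, outdir: Path, stem: str):
    recs = []
    for i, a in enumerate(atoms):
        recs.append(
            replace(
                a,
                b_iso=float(adp.u_to_b_equivalent(u6[i])),
                u_aniso=None if iso_flags[i] else u6[i].copy(),
            )
        )
    p1 = outdir / f"{stem}.pdb"
    p2 = outdir / f"{stem}.cif"
    write_pdb(recs, p1)
    write_mmcif(recs, p2, data_name=stem)
    return [p1, p2]


def write_summary(model, trace, outdir: str | Path) -> dict:
    """Write summary.json (per-level mean B table, complexity, convergence)
    and trace.csv.  Returns the summary dict.

    Raises
    ------
    ValueError
        If the trace contains no completed macrocycles.
    """
    import pandas as pd

    if not trace.records:
        raise ValueError("empty optimization trace: no macrocycles completed")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    mean_b = model.level_mean_b()
    total_b = float(sum(mean_b.values()))
    table = {
        name: {
            "mean_b": round(float(b), 4),
            "percent_of_total": round(100.0 * float(b) / total_b, 2) if total_b else 0.0,
        }
        for name, b in mean_b.items()
    }
    sum_amp, per_atom = model.complexity()
    summary = {
        "levels": table,
        "total_mean_b": round(total_b, 4),
        "complexity": {"sum_amplitudes": sum_amp, "per_atom": per_atom},
        "n_atoms": int(model.n_atoms),
        "converged": bool(trace.converged),
        "n_macrocycles": len(trace.records),
        "rmsd_to_input": float(trace.final_rmsd) if trace.final_rmsd is not None else None,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    pd.DataFrame(trace.as_rows()).to_csv(outdir / "trace.csv", index=False)
    return summary
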