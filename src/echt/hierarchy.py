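"""Partitioning of a structure into hierarchical TLS levels.

The default hierarchy is: chain -> secondary-structure element -> residue ->
backbone/sidechain -> atomic.  Secondary structure is assigned with the
Kabsch-Sander hydrogen-bond energy rule (helix/strand only; everything else
is coil, represented as singleton per-residue groups so the level still
covers the chain).  C-beta atoms are grouped with the backbone; Gly/Ala/Pro
residues are omitted from the backbone/sidechain level.

Levels are ordered largest length scale first; the atomic level is always
last.  Within a level, group selections are pairwise disjoint.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .structure_io import AtomRecord
from .tls import TLSGroup, make_group

logger = logging.getLogger(__name__)

__all__ = [
    "Level",
    "LevelScheme",
    "select_fit_atoms",
    "assign_secondary_structure",
    "build_default_scheme",
    "parse_custom_levels",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "CB"}  # CB counts as backbone
BB_SC_EXCLUDED_RESIDUES = {"GLY", "ALA", "PRO"}
DEFAULT_LEVEL_NAMES = ("chain", "ss", "residue", "backbone_sidechain", "atomic")

# Kabsch-Sander electrostatic H-bond model
_KS_Q1Q2_F = 0.084 * 332.0  # kcal/mol * A
_KS_CUTOFF = -0.5  # kcal/mol


@dataclass
class Level:
    """An ordered, named set of disjoint TLS groups at one length scale."""

    name: str
    groups: list[TLSGroup] = field(default_factory=list)
    kind: str = "tls"  # "tls" | "atomic"

    def validate_disjoint(self) -> None:
        seen: dict[int, str] = {}
        for g in self.groups:
            for i in g.selection:
                if int(i) in seen:
                    raise ValueError(
                        f"level {self.name!r}: atom index {int(i)} appears in "
                        f"groups {seen[int(i)]!r} and {g.label!r}"
                    )
                seen[int(i)] = g.label


@dataclass
class LevelScheme:
    """Ordered list of levels; the atomic level is always last."""

    levels: list[Level]

    def __post_init__(self) -> None:
        if not self.levels or self.levels[-1].kind != "atomic":
            raise ValueError("a level scheme must end with the atomic level")
        for lv in self.levels[:-1]:
            lv.validate_disjoint()

    @property
    def tls_levels(self) -> list[Level]:
        return self.levels[:-1]

    def level_names(self) -> list[str]:
        return [lv.name for lv in self.levels]


def select_fit_atoms(atoms: list[AtomRecord]) -> list[int]:
    """Indices of atoms entering the disorder fit.

    Polymer heavy atoms only; for alternate conformers the highest-occupancy
    one is kept (ties by file order).
    """
    best: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        if not a.is_polymer:
            continue
        if a.element.upper() in ("H", "D"):
            continue
        key = (a.chain_id, a.res_seq, a.icode, a.atom_name)
        if key in best:
            if a.occupancy > atoms[best[key]].occupancy:
                logger.debug("altloc: keeping %s over %s", a.serial, atoms[best[key]].serial)
                best[key] = i
        else:
            best[key] = i
    return sorted(best.values())


def _group_by_residue(atoms, indices):
    """Ordered mapping (chain, res_seq, icode) -> atom indices."""
    residues: dict[tuple, list[int]] = {}
    for i in indices:
        residues.setdefault(atoms[i].residue_id, []).append(i)
    return residues


# ---------------------------------------------------------------------------
# secondary structure (Kabsch-Sander, H/E only)


def _backbone_index(atoms, indices):
    bb: dict[tuple, dict[str, np.ndarray]] = {}
    for i in indices:
        a = atoms[i]
        if a.atom_name in ("N", "CA", "C", "O"):
            bb.setdefault(a.residue_id, {})[a.atom_name] = a.position
    return bb


def _ks_energy(don: dict, acc: dict, h_pos: np.ndarray | None) -> float:
    """Kabsch-Sander electrostatic energy between NH(donor) and CO(acceptor)."""
    if h_pos is None:
        return 0.0
    n, c, o = don["N"], acc["C"], acc["O"]
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h_pos)
    r_oh = np.linalg.norm(o - h_pos)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing/bonded, not an H-bond
        return 0.0
    return _KS_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(
    atoms: list[AtomRecord], indices: list[int] | None = None
) -> list[tuple[str, tuple[tuple[int, str], tuple[int, str]], str]]:
    """Helix/strand segments from the Kabsch-Sander H-bond rule.

    The amide H is placed 1 A from N along the preceding residue's C=O
    direction; an H-bond exists when the electrostatic energy is below
    -0.5 kcal/mol.  Alpha-helix: two consecutive i -> i+4 turns; strand:
    parallel/antiparallel bridge patterns.  Residues missing backbone atoms
    are excluded from detection (logged).

    Returns
    -------
    list of (chain_id, ((res_seq, icode), (res_seq, icode)), ss_class)
        Contiguous segments, ss_class in {"H", "E"}.
    """
    if indices is None:
        indices = select_fit_atoms(atoms)
    bb = _backbone_index(atoms, indices)

    # chains in file order, residues in file order
    chain_res: dict[str, list[tuple]] = {}
    for i in indices:
        rid = atoms[i].residue_id
        lst = chain_res.setdefault(rid[0], [])
        if rid not in lst:
            lst.append(rid)

    segments = []
    all_res: list[tuple] = []
    complete: list[bool] = []
    chain_of: list[str] = []
    for ch, rids in chain_res.items():
        for rid in rids:
            all_res.append(rid)
            chain_of.append(ch)
            ok = rid in bb and all(k in bb[rid] for k in ("N", "CA", "C", "O"))
            if not ok:
                logger.info("residue %s missing backbone atoms; excluded from SS", rid)
            complete.append(ok)

    n = len(all_res)
    # amide H positions (None for chain starts / incomplete residues / PRO)
    h_pos: list[np.ndarray | None] = [None] * n
    for k in range(1, n):
        if chain_of[k] != chain_of[k - 1] or not (complete[k] and complete[k - 1]):
            continue
        rid, prev = all_res[k], all_res[k - 1]
        resname = next(
            atoms[i].res_name for i in indices if atoms[i].residue_id == rid
        )
        if resname == "PRO":
            continue
        co = bb[prev]["C"] - bb[prev]["O"]
        nrm = np.linalg.norm(co)
        if nrm > 0:
            h_pos[k] = bb[rid]["N"] + co / nrm

    def hbond(i: int, j: int) -> bool:
        """CO of residue i accepts the NH of residue j."""
        if not (0 <= i < n and 0 <= j < n):
            return False
        if not (complete[i] and complete[j]) or h_pos[j] is None:
            return False
        return _ks_energy(bb[all_res[j]], bb[all_res[i]], h_pos[j]) < _KS_CUTOFF

    same = lambda i, j: 0 <= i < n and 0 <= j < n and chain_of[i] == chain_of[j]

    turn4 = [same(i, i + 4) and hbond(i, i + 4) for i in range(n)]
    ss = [""] * n
    for i in range(1, n):
        if turn4[i - 1] and turn4[i]:
            for j in range(i, min(i + 4, n)):
                ss[j] = "H"

    for i in range(n):
        for j in range(i + 3, n):
            para = (hbond(i - 1, j) and hbond(j, i + 1)) or (
                hbond(j - 1, i) and hbond(i, j + 1)
            )
            anti = (hbond(i, j) and hbond(j, i)) or (
                hbond(i - 1, j + 1) and hbond(j - 1, i + 1)
            )
            if para or anti:
                for k in (i, j):
                    if ss[k] != "H":
                        ss[k] = "E"

    k = 0
    while k < n:
        if ss[k] in ("H", "E"):
            start = k
            while k + 1 < n and ss[k + 1] == ss[start] and chain_of[k + 1] == chain_of[start]:
                k += 1
            segments.append(
                (
                    chain_of[start],
                    (all_res[start][1:], all_res[k][1:]),
                    ss[start],
                )
            )
        k += 1
    return segments


# ---------------------------------------------------------------------------
# scheme construction


def _positions(atoms) -> np.ndarray:
    return np.array([a.position for a in atoms])


def build_default_scheme(
    atoms: list[AtomRecord], indices: list[int] | None = None
) -> LevelScheme:
    """Default five-level scheme: chain / SS / residue / backbone-sidechain / atomic.

    ``indices`` (defaulting to :func:`select_fit_atoms`) are the atoms the
    model covers; group selections index into the full ``atoms`` list.
    """
    if indices is None:
        indices = select_fit_atoms(atoms)
    if not indices:
        raise ValueError("structure contains no polymer atoms to partition")
    pos = _positions(atoms)

    chains: dict[str, list[int]] = {}
    for i in indices:
        chains.setdefault(atoms[i].chain_id, []).append(i)
    chain_level = Level(
        "chain",
        [make_group(np.array(sel), pos, label=f"chain {c}") for c, sel in chains.items()],
    )

    ss_level = Level("ss", _ss_groups(atoms, indices, pos))

    residues = _group_by_residue(atoms, indices)
    residue_level = Level(
        "residue",
        [
            make_group(np.array(sel), pos, label=f"residue {rid[0]} {rid[1]}{rid[2]}")
            for rid, sel in residues.items()
        ],
    )

    bbsc_groups = []
    for rid, sel in residues.items():
        resname = atoms[sel[0]].res_name
        if resname in BB_SC_EXCLUDED_RESIDUES:
            continue
        bb = [i for i in sel if atoms[i].atom_name in BACKBONE_ATOMS]
        sc = [i for i in sel if atoms[i].atom_name not in BACKBONE_ATOMS]
        tag = f"{rid[0]} {rid[1]}{rid[2]}"
        if bb:
            bbsc_groups.append(make_group(np.array(bb), pos, label=f"backbone {tag}"))
        if sc:
            bbsc_groups.append(make_group(np.array(sc), pos, label=f"sidechain {tag}"))
    bbsc_level = Level("backbone_sidechain", bbsc_groups)

    atomic = Level("atomic", [], kind="atomic")
    return LevelScheme([chain_level, ss_level, residue_level, bbsc_level, atomic])


def _ss_groups(atoms, indices, pos) -> list[TLSGroup]:
    segments = assign_secondary_structure(atoms, indices)
    residues = _group_by_residue(atoms, indices)
    rid_list = list(residues)
    in_segment: set[tuple] = set()
    groups = []
    for ch, ((r1, i1), (r2, i2)), cls in segments:
        sel: list[int] = []
        for rid in rid_list:
            if rid[0] != ch:
                continue
            if (r1, i1) <= (rid[1], rid[2]) <= (r2, i2):
                sel += residues[rid]
                in_segment.add(rid)
        if sel:
            groups.append(
                make_group(np.array(sel), pos, label=f"{cls} {ch} {r1}{i1}-{r2}{i2}")
            )
    for rid in rid_list:  # coil residues: singleton groups
        if rid not in in_segment:
            groups.append(
                make_group(
                    np.array(residues[rid]), pos, label=f"coil {rid[0]} {rid[1]}{rid[2]}"
                )
            )
    return groups


# ---------------------------------------------------------------------------
# custom levels

_SEL_RE = re.compile(
    r"^\s*(?P<chain>[A-Za-z0-9])\s*"
    r"(?::\s*(?P<r1>-?\d+)(?P<i1>[A-Za-z]?)\s*-\s*(?P<r2>-?\d+)(?P<i2>[A-Za-z]?))?\s*$"
)


def parse_selection(expr: str, atoms: list[AtomRecord], indices: list[int]) -> np.ndarray:
    """Atom indices matched by a selection string.

    Syntax: segments joined by ``+``; each segment is ``CHAIN`` (whole chain)
    or ``CHAIN:START-END`` (inclusive author residue numbers, optional
    insertion-code suffixes, e.g. ``A:52A-60``).
    """
    sel: list[int] = []
    for part in expr.split("+"):
        m = _SEL_RE.match(part)
        if not m:
            raise ValueError(f"cannot parse selection segment {part!r}")
        ch = m.group("chain")
        for i in indices:
            a = atoms[i]
            if a.chain_id != ch:
                continue
            if m.group("r1") is not None:
                lo = (int(m.group("r1")), m.group("i1") or "")
                hi = (int(m.group("r2")), m.group("i2") or "")
                if not (lo <= (a.res_seq, a.icode) <= hi):
                    continue
            sel.append(i)
    if not sel:
        raise ValueError(f"selection {expr!r} matches no atoms")
    return np.array(sorted(set(sel)), dtype=int)


def parse_custom_levels(
    config: dict | None, atoms: list[AtomRecord], indices: list[int] | None = None
) -> LevelScheme:
    """Build a scheme from a config dict (e.g. loaded from YAML/JSON).

    ``config["levels"]`` lists levels in order, largest scale first.  Each
    entry is either the name of a built-in level (``chain``, ``ss``,
    ``residue``, ``backbone_sidechain``, ``atomic``) or a mapping with
    ``name`` and ``groups`` (list of selection strings).  The atomic level
    is appended automatically if absent.  An empty/missing config yields the
    default scheme.
    """
    if indices is None:
        indices = select_fit_atoms(atoms)
    if not config or not config.get("levels"):
        return build_default_scheme(atoms, indices)
    default = {
        lv.name: lv for lv in build_default_scheme(atoms, indices).levels
    }
    pos = _positions(atoms)
    levels: list[Level] = []
    for entry in config["levels"]:
        if isinstance(entry, str):
            if entry not in default:
                raise ValueError(
                    f"unknown built-in level {entry!r}; choose from {DEFAULT_LEVEL_NAMES}"
                )
            levels.append(default[entry])
        else:
            name = entry["name"]
            groups = [
                TLSGroup(
                    selection=parse_selection(expr, atoms, indices),
                    matrices=make_group(
                        parse_selection(expr, atoms, indices), pos
                    ).matrices,
                    amplitude=0.0,
                    label=f"{name}: {expr}",
                )
                for expr in entry["groups"]
            ]
            levels.append(Level(name, groups))
    if levels[-1].kind != "atomic":
        levels.append(default["atomic"])
    return LevelScheme(levels)
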