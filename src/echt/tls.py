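"""Translation-Libration-Screw (TLS) rigid-body disorder models.

A TLS parameter set describes the Gaussian distribution of rigid-body
displacements of a group of atoms: T (A^2) is the translation covariance,
L (rad^2) the libration (rotation) covariance, and S (A rad) the
screw coupling between the two.  The per-atom anisotropic contribution is
the standard closed form

    U(r) = T + A L A^T + A S + S^T A^T,

with ``A`` the antisymmetric cross-product matrix of the lever arm
``d = r - origin`` (such that ``A theta = theta x d``).

Conventions
-----------
* L is stored in rad^2 internally; degree^2 I/O is converted at the boundary.
* S is stored as 8 free elements ``(s11, s12, s13, s21, s22, s23, s31, s32)``
  with the trace constraint ``s33 = -(s11 + s22)`` (the S trace is not
  determined by the ADPs).
* The group origin is the centroid of the selected atoms, fixed when the
  selection is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import adp

__all__ = [
    "TLSMatrices",
    "TLSGroup",
    "tls_uij",
    "validate_tls",
    "normalize_group",
    "group_uijs",
]

N_TLS_PARAMS = 20  # 6 T + 6 L + 8 S


@dataclass
class TLSMatrices:
    """TLS matrices plus origin.  All-zero matrices are valid (zero disorder)."""

    T: np.ndarray = field(default_factory=lambda: np.zeros(6))  # A^2, sym
    L: np.ndarray = field(default_factory=lambda: np.zeros(6))  # rad^2, sym
    S: np.ndarray = field(default_factory=lambda: np.zeros(8))  # A rad
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))  # A

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def s_matrix(self) -> np.ndarray:
        """Full 3x3 S matrix with the trace constraint applied."""
        s = self.S
        return np.array(
            [
                [s[0], s[1], s[2]],
                [s[3], s[4], s[5]],
                [s[6], s[7], -(s[0] + s[4])],
            ]
        )

    def as_vector(self) -> np.ndarray:
        """Free parameters as a flat length-20 vector (T6, L6, S8)."""
        return np.concatenate([self.T, self.L, self.S])

    @classmethod
    def from_vector(cls, p: np.ndarray, origin: np.ndarray) -> "TLSMatrices":
        p = np.asarray(p, dtype=float)
        if p.shape != (N_TLS_PARAMS,):
            raise ValueError(f"expected {N_TLS_PARAMS} parameters, got {p.shape}")
        return cls(T=p[:6].copy(), L=p[6:12].copy(), S=p[12:].copy(), origin=origin)

    def is_zero(self, tol: float = 0.0) -> bool:
        return bool(
            np.all(np.abs(self.T) <= tol)
            and np.all(np.abs(self.L) <= tol)
            and np.all(np.abs(self.S) <= tol)
        )

    def scaled(self, factor: float) -> "TLSMatrices":
        """All matrices multiplied by a common scalar (origin unchanged)."""
        return TLSMatrices(
            T=self.T * factor, L=self.L * factor, S=self.S * factor, origin=self.origin
        )

    def joint_covariance(self, s_trace: float = 0.0) -> np.ndarray:
        """6x6 covariance of the (libration, translation) Gaussian.

        Block form ``[[L, S + s_trace*I], [(S + s_trace*I)^T, T]]`` with
        S = <theta t^T>.  The S trace is not determined by the ADPs (adding
        c*I to S leaves every predicted U unchanged because the lever-arm
        matrix is antisymmetric), so ``s_trace`` parameterizes the free
        trace split.  A TLS set is physically decomposable iff this matrix
        is PSD for some choice of ``s_trace``.
        """
        c = np.zeros((6, 6))
        c[:3, :3] = adp.to_matrix(self.L)
        c[3:, 3:] = adp.to_matrix(self.T)
        s = self.s_matrix + s_trace * np.eye(3)
        c[:3, 3:] = s
        c[3:, :3] = s.T
        return c

    def best_s_trace(self) -> tuple[float, float]:
        """S-trace split maximizing the smallest joint-covariance eigenvalue.

        The smallest eigenvalue is concave in the trace parameter, so a
        golden-section search finds its maximum.  Returns ``(s_trace,
        smallest_eigenvalue)``.
        """

        def lam_min(c: float) -> float:
            return float(np.linalg.eigvalsh(self.joint_covariance(c))[0])

        lmax = float(np.abs(self.L).max())
        tmax = float(np.abs(self.T).max())
        bound = 1e-3 + 2.0 * (np.abs(self.S).max() + np.sqrt(lmax * tmax))
        lo, hi = -bound, bound
        inv_phi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c1 = b - inv_phi * (b - a)
        c2 = a + inv_phi * (b - a)
        f1, f2 = lam_min(c1), lam_min(c2)
        for _ in range(40):
            if f1 < f2:
                a, c1, f1 = c1, c2, f2
                c2 = a + inv_phi * (b - a)
                f2 = lam_min(c2)
            else:
                b, c2, f2 = c2, c1, f1
                c1 = b - inv_phi * (b - a)
                f1 = lam_min(c1)
        best = 0.5 * (a + b)
        return best, lam_min(best)

    def to_dict(self) -> dict:
        return {
            "T": self.T.tolist(),
            "L": self.L.tolist(),
            "S": self.S.tolist(),
            "origin": self.origin.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TLSMatrices":
        return cls(
            T=np.asarray(d["T"], dtype=float),
            L=np.asarray(d["L"], dtype=float),
            S=np.asarray(d["S"], dtype=float),
            origin=np.asarray(d["origin"], dtype=float),
        )


def _cross_matrices(d: np.ndarray) -> np.ndarray:
    """Antisymmetric matrices A with ``A theta = theta x d`` for lever arms d."""
    d = np.atleast_2d(np.asarray(d, dtype=float))
    n = d.shape[0]
    a = np.zeros((n, 3, 3))
    a[:, 0, 1] = d[:, 2]
    a[:, 0, 2] = -d[:, 1]
    a[:, 1, 0] = -d[:, 2]
    a[:, 1, 2] = d[:, 0]
    a[:, 2, 0] = d[:, 1]
    a[:, 2, 1] = -d[:, 0]
    return a


def tls_uij(m: TLSMatrices, positions: np.ndarray) -> np.ndarray:
    """Anisotropic displacement contribution of a TLS model at position(s).

    At ``position == origin`` the result is exactly T.

    Parameters
    ----------
    m : TLSMatrices
    positions : array-like, shape (3,) or (n, 3), in A.

    Returns
    -------
    ndarray, shape (6,) or (n, 6)
    """
    pos = np.asarray(positions, dtype=float)
    single = pos.ndim == 1
    a = _cross_matrices(np.atleast_2d(pos) - m.origin)
    lmat = adp.to_matrix(m.L)
    smat = m.s_matrix
    als = np.einsum("nij,jk,nlk->nil", a, lmat, a)  # A L A^T
    asym = np.einsum("nij,jk->nik", a, smat)  # A S
    u = adp.to_matrix(m.T) + als + asym + np.transpose(asym, (0, 2, 1))
    u6 = adp.from_matrix(u)
    return u6[0] if single else u6


def validate_tls(m: TLSMatrices, eps: float = 1e-6) -> bool:
    """Screen a TLS parameter set for physical decomposability.

    Simplified validity check: the joint 6x6 (libration, translation)
    covariance ``[[L, S + cI], [(S + cI)^T, T]]`` must be PSD within ``eps``
    (smallest eigenvalue >= -eps) for some S-trace split ``c``.  Joint PSD
    implies T and L individually PSD and the screw-reduced residual
    translation ``T - S^T L^+ S`` PSD -- i.e. the parameters are the second
    moments of an actual rigid-body displacement distribution.  All-zero
    matrices pass.  The trace-free split is tried first (cheap common
    path); the golden-section trace search only runs when it fails.
    """
    w = np.linalg.eigvalsh(m.joint_covariance())
    if w[0] >= -eps:
        return True
    if np.abs(m.S).max() == 0.0:
        return False  # no screw coupling: the trace split cannot help
    _, lam = m.best_s_trace()
    return bool(lam >= -eps)


@dataclass
class TLSGroup:
    """An atom selection with TLS matrices and a scalar amplitude.

    ``matrices`` are kept in normalized form (mean over group atoms of
    ``Tr(U_hat)/3`` equal to 1) whenever they are non-zero; ``amplitude``
    (A^2) then carries the magnitude, so per-atom contributions are
    ``amplitude * tls_uij(matrices, position)``.  Amplitudes are never
    negative.
    """

    selection: np.ndarray  # atom indices, non-empty
    matrices: TLSMatrices
    amplitude: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.selection = np.asarray(self.selection, dtype=int)
        if self.selection.size == 0:
            raise ValueError(f"TLS group {self.label!r} has an empty selection")
        if self.amplitude < 0:
            raise ValueError("TLS group amplitude must be non-negative")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "selection": self.selection.tolist(),
            "amplitude": float(self.amplitude),
            "matrices": self.matrices.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TLSGroup":
        return cls(
            selection=np.asarray(d["selection"], dtype=int),
            matrices=TLSMatrices.from_dict(d["matrices"]),
            amplitude=float(d["amplitude"]),
            label=d.get("label", ""),
        )


def make_group(
    selection: np.ndarray, positions: np.ndarray, label: str = ""
) -> TLSGroup:
    """Create a zero-amplitude group with an isotropic unit T matrix.

    The origin is the centroid of the selected atoms; T = diag(1, 1, 1) is
    already normalized (unit mean trace/3), so the group is ready for
    amplitude optimization.
    """
    selection = np.asarray(selection, dtype=int)
    origin = np.asarray(positions, dtype=float)[selection].mean(axis=0)
    t = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    return TLSGroup(
        selection=selection,
        matrices=TLSMatrices(T=t, origin=origin),
        amplitude=0.0,
        label=label,
    )


def mean_trace_third(m: TLSMatrices, positions: np.ndarray) -> float:
    """Mean over atoms of Tr(U)/3 for the raw matrix contribution."""
    u = tls_uij(m, np.atleast_2d(positions))
    return float(np.mean(u[:, :3].sum(axis=1)) / 3.0)


def normalize_group(g: TLSGroup, positions: np.ndarray) -> TLSGroup:
    """Rescale matrices to unit mean trace/3 over the group, amplitude inversely.

    The per-atom product ``amplitude * U_hat`` is unchanged.  A group whose
    matrices produce a zero mean trace cannot be normalized: its amplitude is
    set to 0 and the matrices zeroed.
    """
    pos = np.asarray(positions, dtype=float)[g.selection]
    scale = mean_trace_third(g.matrices, pos)
    if scale <= 0.0:
        return replace(g, matrices=TLSMatrices(origin=g.matrices.origin), amplitude=0.0)
    return replace(
        g,
        matrices=g.matrices.scaled(1.0 / scale),
        amplitude=g.amplitude * scale,
    )


def group_uijs(g: TLSGroup, positions: np.ndarray) -> np.ndarray:
    """Per-atom contributions ``A_g * U_hat(position)`` for the group's atoms.

    ``positions`` is the full coordinate array indexed by ``g.selection``.
    """
    pos = np.asarray(positions, dtype=float)
    if g.selection.max() >= pos.shape[0]:
        raise IndexError(
            f"group {g.label!r} selects atom {int(g.selection.max())} "
            f"but only {pos.shape[0]} coordinates are available"
        )
    if g.amplitude == 0.0:
        return np.zeros((g.selection.size, 6))
    return g.amplitude * tls_uij(g.matrices, pos[g.selection])
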