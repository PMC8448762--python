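"""Arithmetic for isotropic and anisotropic atomic displacement parameters.

Anisotropic displacement parameters (ADPs) are symmetric 3x3 tensors in
Angstrom^2.  Throughout this package they are stored in their 6 unique
elements, ordered ``(u11, u22, u33, u12, u13, u23)`` -- the same order used
by PDB ``ANISOU`` records.  Functions in this module accept arrays of shape
``(..., 6)`` and broadcast over leading dimensions.

The internal unit for displacement tensors is Angstrom^2 everywhere;
B-factors (``B = 8 pi^2 <u^2>``) are derived views, never stored alongside.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "B_SCALE",
    "u_to_b_equivalent",
    "iso_to_u",
    "to_matrix",
    "from_matrix",
    "is_psd",
    "psd_project",
]

#: Conversion factor between mean-square displacement and B-factor (8 pi^2).
B_SCALE: float = 8.0 * math.pi**2

# Duplication weights for the 6 unique elements when contracting a full
# symmetric 3x3 tensor (off-diagonals appear twice).
SYM_WEIGHTS = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


def u_to_b_equivalent(u: np.ndarray) -> np.ndarray | float:
    """Equivalent isotropic B-factor of a displacement tensor.

    ``B_eq = 8 pi^2 * Tr(U) / 3``; linear in ``u``.

    Parameters
    ----------
    u : array-like, shape (..., 6)
        Displacement tensor(s) in A^2.

    Returns
    -------
    float or ndarray
        B-factor(s) in A^2.
    """
    u = np.asarray(u, dtype=float)
    b = B_SCALE * (u[..., 0] + u[..., 1] + u[..., 2]) / 3.0
    return float(b) if b.ndim == 0 else b


def iso_to_u(b: np.ndarray | float) -> np.ndarray:
    """Embed isotropic B-factor(s) as isotropic displacement tensor(s).

    Inverse of :func:`u_to_b_equivalent` on isotropic tensors.

    Raises
    ------
    ValueError
        If any B-factor is negative (unphysical input).
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("unphysical input: negative B-factor(s)")
    u = np.zeros(b.shape + (6,))
    u[..., :3] = (b / B_SCALE)[..., np.newaxis]
    return u


def to_matrix(u: np.ndarray) -> np.ndarray:
    """Expand 6-element tensor(s) of shape (..., 6) to full (..., 3, 3)."""
    u = np.asarray(u, dtype=float)
    m = np.empty(u.shape[:-1] + (3, 3))
    m[..., 0, 0] = u[..., 0]
    m[..., 1, 1] = u[..., 1]
    m[..., 2, 2] = u[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = u[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = u[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = u[..., 5]
    return m


def from_matrix(m: np.ndarray) -> np.ndarray:
    """Collapse full symmetric (..., 3, 3) tensor(s) to unique elements."""
    m = np.asarray(m, dtype=float)
    return np.stack(
        [
            m[..., 0, 0],
            m[..., 1, 1],
            m[..., 2, 2],
            0.5 * (m[..., 0, 1] + m[..., 1, 0]),
            0.5 * (m[..., 0, 2] + m[..., 2, 0]),
            0.5 * (m[..., 1, 2] + m[..., 2, 1]),
        ],
        axis=-1,
    )


def is_psd(u: np.ndarray, eps: float = 0.0) -> bool | np.ndarray:
    """Whether tensor(s) are positive semi-definite within tolerance.

    True iff the smallest eigenvalue of the symmetric 3x3 tensor is
    ``>= -eps``.  The tolerance applies to eigenvalues directly (symmetric
    eigendecomposition, not Cholesky).
    """
    if eps < 0:
        raise ValueError("eps must be non-negative")
    w = np.linalg.eigvalsh(to_matrix(u))
    ok = w[..., 0] >= -eps
    return bool(ok) if ok.ndim == 0 else ok


def psd_project(u: np.ndarray) -> np.ndarray:
    """Nearest positive semi-definite tensor(s) in the Frobenius norm.

    Eigenvalues below zero are clipped to zero; this is the exact minimizer
    of the (symmetric-)Frobenius distance over the PSD cone.
    """
    w, v = np.linalg.eigh(to_matrix(u))
    w = np.clip(w, 0.0, None)
    m = np.einsum("...ik,...k,...jk->...ij", v, w, v)
    return from_matrix(m)
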