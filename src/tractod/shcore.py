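"""Real, even-order, antipodally symmetric spherical harmonic (SH) basis.

This is the mathematical core shared by track orientation distributions
(TODs), fibre orientation distributions (FODs) and tract atlases: all are
band-limited spherical functions stored as ordered vectors of real SH
coefficients, even orders only (antipodal symmetry), up to ``lmax``.

Basis convention
----------------
With :math:`Y_l^m` the complex spherical harmonics (Condon-Shortley phase,
``scipy.special.sph_harm_y``), the real basis used throughout is

.. math::

    Y_j = \\begin{cases}
        \\sqrt{2}\\,(-1)^m\\,\\mathrm{Im}\\,Y_l^{|m|} & m < 0 \\\\
        Y_l^0                                        & m = 0 \\\\
        \\sqrt{2}\\,(-1)^m\\,\\mathrm{Re}\\,Y_l^{m}  & m > 0
    \\end{cases}

with the flat index :math:`j = l(l+1)/2 + m` over even ``l`` only.  This
basis is orthonormal on the sphere (verified by quadrature in the test
suite).  Files produced by other toolchains may use a different sign or
``sqrt(2)`` placement for the ``m != 0`` terms; no silent conversion is
attempted.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "n_coeffs",
    "lmax_for",
    "sh_index",
    "sh_degree_order",
    "sh_basis",
    "eval_sh",
    "project_delta",
    "default_taper",
    "spherical_integral",
    "inner_product",
    "rotation_matrix_sh",
    "rotate_sh",
    "fibonacci_sphere",
]

#: Amplitude of Y_{0,0}; the first coefficient of any unit-integral function
#: equals 1 / SQRT_4PI.
SQRT_4PI = float(np.sqrt(4.0 * np.pi))

_DIR_TOL = 1e-10


def n_coeffs(lmax: int) -> int:
    """Number of real even-order coefficients up to ``lmax`` (45 at lmax=8)."""
    if lmax < 0 or lmax % 2:
        raise ValueError(f"lmax must be an even non-negative integer, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


def lmax_for(n: int) -> int:
    """Inverse of :func:`n_coeffs`; raises for invalid coefficient counts."""
    lmax = int(np.rint((np.sqrt(8 * n + 1) - 3) / 2))
    if lmax < 0 or lmax % 2 or n_coeffs(lmax) != n:
        valid = [n_coeffs(l) for l in range(0, 17, 2)]
        raise ValueError(
            f"{n} is not a valid even-order SH coefficient count; "
            f"valid counts are {valid}"
        )
    return lmax


def sh_index(l: int, m: int) -> int:
    """Flat storage index of the (l, m) basis function.

    Ordering is l ascending (even only), m ascending from -l to l:
    (0,0), (2,-2) ... (2,2), (4,-4) ... so ``j = l(l+1)/2 + m``.
    """
    if l < 0 or l % 2:
        raise ValueError(f"degree l must be even and non-negative, got (l={l}, m={m})")
    if abs(m) > l:
        raise ValueError(f"order m must satisfy |m| <= l, got (l={l}, m={m})")
    return l * (l + 1) // 2 + m


def sh_degree_order(j: int) -> tuple[int, int]:
    """Recover (l, m) from the flat index ``j``."""
    if j < 0:
        raise ValueError(f"index must be non-negative, got {j}")
    l = 0
    while l * (l + 1) // 2 + l < j:
        l += 2
    m = j - l * (l + 1) // 2
    return l, m


def _check_dirs(dirs: np.ndarray) -> np.ndarray:
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    if dirs.ndim != 2 or dirs.shape[1] != 3 or dirs.shape[0] == 0:
        raise ValueError("directions must be a non-empty (N, 3) array")
    norms = np.linalg.norm(dirs, axis=1)
    bad = np.abs(norms - 1.0) > 1e-6
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} direction(s) are not unit vectors "
            f"(max |norm-1| = {np.abs(norms - 1).max():.3g})"
        )
    return dirs


def sh_basis(dirs: np.ndarray, lmax: int) -> np.ndarray:
    """Evaluate every basis function at unit directions.

    Parameters
    ----------
    dirs : (N, 3) array of unit vectors.
    lmax : even maximum degree.

    Returns
    -------
    (N, J) matrix B with B[i, j] = Y_j(dirs[i]).
    """
    dirs = _check_dirs(dirs)
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))  # polar angle
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    out = np.empty((dirs.shape[0], n_coeffs(lmax)))
    for l in range(0, lmax + 1, 2):
        base = l * (l + 1) // 2
        out[:, base] = sph_harm_y(l, 0, theta, phi).real
        for m in range(1, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            sign = -1.0 if m % 2 else 1.0
            out[:, base + m] = np.sqrt(2.0) * sign * y.real
            out[:, base - m] = np.sqrt(2.0) * sign * y.imag
    return out


def eval_sh(coeffs: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Evaluate the function with the given coefficient vector at ``dirs``."""
    coeffs = np.asarray(coeffs, dtype=float)
    lmax = lmax_for(coeffs.shape[-1])
    return sh_basis(dirs, lmax) @ coeffs


def default_taper(lmax: int, sigma: float = 0.17) -> np.ndarray:
    """Per-degree apodization weights a_l = exp(-sigma^2 l(l+1)).

    The default ``sigma`` keeps the l=8 band weight at
    exp(-0.17^2 * 72) ~= 0.125, i.e. above 0.1, so high-frequency content
    is damped without being annihilated.
    """
    l = np.arange(0, lmax + 1, 2)
    return np.exp(-(sigma**2) * l * (l + 1))


def _per_coeff_taper(taper: np.ndarray, lmax: int) -> np.ndarray:
    """Expand per-degree weights a_l to per-coefficient weights."""
    taper = np.asarray(taper, dtype=float)
    n_bands = lmax // 2 + 1
    if taper.shape != (n_bands,):
        raise ValueError(
            f"taper must have one weight per even degree "
            f"({n_bands} values for lmax={lmax}), got shape {taper.shape}"
        )
    if taper[0] != 1.0:
        raise ValueError("taper weight a_0 must be exactly 1 (preserves mass)")
    if np.any(taper <= 0) or np.any(taper > 1) or np.any(np.diff(taper) > 0):
        raise ValueError("taper weights must lie in (0, 1] and be non-increasing")
    out = np.empty(n_coeffs(lmax))
    for l in range(0, lmax + 1, 2):
        base = l * (l + 1) // 2
        out[base - l : base + l + 1] = taper[l // 2]
    return out


def project_delta(
    u: np.ndarray, lmax: int = 8, taper: np.ndarray | None = None
) -> np.ndarray:
    """Apodized delta lobe: a smooth antipodally symmetric bump at +/-u.

    The raw SH projection of an orientation delta has coefficients
    ``Y_j(u)``; the per-degree taper ``a_l`` damps ringing.  The result has
    unit spherical integral (mass 1) since ``a_0 = 1``.
    """
    u = _check_dirs(u)
    if u.shape[0] != 1:
        raise ValueError("project_delta expects a single direction")
    if taper is None:
        taper = default_taper(lmax)
    return sh_basis(u, lmax)[0] * _per_coeff_taper(taper, lmax)


def spherical_integral(coeffs: np.ndarray) -> float | np.ndarray:
    """Integral of the function over the sphere: sqrt(4*pi) * c_0.

    All basis functions except Y_{0,0} integrate to zero, so only the first
    coefficient contributes.  Works on a single vector or an array whose
    last axis is the coefficient axis.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    return SQRT_4PI * coeffs[..., 0]


def inner_product(a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
    """Integral of the product of two band-limited spherical functions.

    By orthonormality this is the dot product of the coefficient vectors.
    Vectors with different ``lmax`` are truncated to the shorter one: the
    discarded cross terms pair a retained coefficient with one that is
    exactly zero in the shorter expansion, so truncation is exact for the
    common band.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[-1], b.shape[-1]
    lmax_for(na), lmax_for(nb)  # validate both
    n = min(na, nb)
    return np.einsum("...j,...j->...", a[..., :n], b[..., :n])


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions (spherical Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be a 3x3 matrix, got shape {R.shape}")
    if np.abs(R.T @ R - np.eye(3)).max() > 1e-8:
        raise ValueError("matrix is not orthogonal (R^T R != I within 1e-8)")
    if np.linalg.det(R) < 0:
        # Even-order functions are inversion-invariant, so fold the
        # reflection through -I (which acts as identity here).
        R = -R
    return R


def rotation_matrix_sh(R: np.ndarray, lmax: int = 8) -> np.ndarray:
    """(J, J) matrix M acting on coefficient vectors so that the rotated
    function g(u) = f(R^T u) has coefficients ``M @ f``.

    Computed by least-squares refit on a Fibonacci design: rotation
    preserves the band limit, so the refit is exact up to conditioning.
    The matrix is block-diagonal per degree and orthogonal.
    """
    R = _check_rotation(R)
    n = n_coeffs(lmax)
    dirs = fibonacci_sphere(max(4 * n, 180))
    B = sh_basis(dirs, lmax)
    # f evaluated at R^T u for each design point u
    A = sh_basis(dirs @ R, lmax)
    M, *_ = np.linalg.lstsq(B, A)
    return M


def rotate_sh(coeffs: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Rotate a spherical function by rotating its coefficient vector."""
    coeffs = np.asarray(coeffs, dtype=float)
    lmax = lmax_for(coeffs.shape[-1])
    return coeffs @ rotation_matrix_sh(R, lmax).T
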