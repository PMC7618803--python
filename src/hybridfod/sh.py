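"""Real even spherical-harmonic basis for antipodally symmetric FODs.

Convention (matching the common FOD-tool layout): coefficients are ordered by
even degree l = 0, 2, ..., lmax, and within each degree by order
m = -l, ..., l.  The basis is the orthonormal real basis

    Y_{l,0}  = Re Y_l^0
    Y_{l,m}  = sqrt(2) (-1)^m Re Y_l^m     (m > 0)
    Y_{l,-m} = sqrt(2) (-1)^m Im Y_l^m     (m > 0)

built from the Condon-Shortley complex harmonics, so the l=0 coefficient of a
unit-mass density is 1/sqrt(4 pi) times its integral.  Only even degrees are
used, which makes every represented function exactly antipodally symmetric.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y_all

__all__ = ["n_coeffs", "sh_basis", "eval_sh", "lm_table"]


def n_coeffs(lmax: int) -> int:
    """Number of real even-degree coefficients up to order lmax (45 for 8)."""
    if lmax < 0 or lmax % 2:
        raise ValueError("lmax must be even and non-negative")
    return (lmax + 1) * (lmax + 2) // 2


def lm_table(lmax: int) -> list[tuple[int, int]]:
    """(l, m) pairs in coefficient order."""
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def sh_basis(directions: np.ndarray, lmax: int = 8) -> np.ndarray:
    """Evaluate the real even basis at unit directions; returns (N, n_coeffs)."""
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(d[:, 1], d[:, 0])
    # all_ylm[l, m] with m indexed 0..l then aliased negative orders at the end
    all_ylm = sph_harm_y_all(lmax, lmax, theta, phi)  # (lmax+1, 2*lmax+1, N)
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            y = all_ylm[l, m]
            if m == 0:
                cols.append(y.real)
            elif m > 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
            else:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * all_ylm[l, -m].imag)
    return np.stack(cols, axis=-1)


def eval_sh(coeffs: np.ndarray, directions: np.ndarray, lmax: int | None = None) -> np.ndarray:
    """FOD amplitude(s) at unit directions.

    ``coeffs`` may be a single coefficient vector or a stack (..., K).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    K = coeffs.shape[-1]
    if lmax is None:
        lmax = _lmax_from_ncoef(K)
    B = sh_basis(directions, lmax)
    return coeffs @ B.T


def _lmax_from_ncoef(K: int) -> int:
    lmax = int(np.round((-3 + np.sqrt(1 + 8 * K)) / 2))
    if n_coeffs(lmax) != K:
        raise ValueError(f"{K} is not a valid even-basis coefficient count")
    return lmax
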