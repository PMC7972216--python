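"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (direct summation, closed forms) and
shares no code with the package's fast paths.
"""

import numpy as np


def ndft_forward(image: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Direct non-uniform DFT: sum_x img[x] exp(-i w.x), centred grid."""
    axes = [np.arange(n) - n // 2 for n in image.shape]
    grids = np.meshgrid(*axes, indexing="ij")
    out = np.empty(len(omega), dtype=complex)
    for j, w in enumerate(omega):
        ph = sum(wi * g for wi, g in zip(w, grids))
        out[j] = np.sum(image * np.exp(-1j * ph))
    return out


def ndft_adjoint(omega: np.ndarray, data: np.ndarray,
                 shape: tuple[int, ...]) -> np.ndarray:
    """Direct adjoint: sum_j d_j exp(+i w_j.x) on the centred grid."""
    axes = [np.arange(n) - n // 2 for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    out = np.zeros(shape, dtype=complex)
    for j, w in enumerate(omega):
        ph = sum(wi * g for wi, g in zip(w, grids))
        out += data[j] * np.exp(1j * ph)
    return out


def ball_ft(k: np.ndarray, radius: float) -> np.ndarray:
    """Continuous FT of the unit-amplitude ball: 4 pi a^3 (sin u - u cos u)/u^3."""
    k = np.asarray(k, float)
    u = 2.0 * np.pi * k * radius
    out = np.empty_like(u)
    small = np.abs(u) < 1e-6
    out[small] = 4.0 / 3.0 * np.pi * radius**3
    us = u[~small]
    out[~small] = 4.0 * np.pi * radius**3 * (
        np.sin(us) - us * np.cos(us)) / us**3
    return out


def ols_slope_stderr(x: np.ndarray, y: np.ndarray):
    """Textbook OLS slope, its standard error and R^2 (two-pass formulas)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xb, yb = x.mean(), y.mean()
    sxx = np.sum((x - xb) ** 2)
    sxy = np.sum((x - xb) * (y - yb))
    slope = sxy / sxx
    intercept = yb - slope * xb
    resid = y - intercept - slope * x
    s2 = np.sum(resid**2) / (n - 2)
    stderr = np.sqrt(s2 / sxx)
    syy = np.sum((y - yb) ** 2)
    r2 = 1.0 - np.sum(resid**2) / syy if syy > 0 else np.nan
    return slope, stderr, r2


def solve_velocity_bruteforce(phases: np.ndarray, h: np.ndarray,
                              venc: float) -> np.ndarray:
    """Solve phi = pi/(2 venc) h v for v by explicit least squares."""
    A = (np.pi / (2.0 * venc)) * h
    v, *_ = np.linalg.lstsq(A, np.asarray(phases, float), rcond=None)
    return v
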