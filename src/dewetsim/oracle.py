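"""Independent axisymmetric oracle for the contractile disk on a foundation.

For a uniform contraction γ on the full disk the 2D problem reduces to a
radial ODE. With D11 = λ + 2μ and D12 = λ (the same constitutive matrix as
the 2D model) the radial and hoop stresses are

    σrr = D11·u' + D12·u/r + (D11 + D12)·γ
    σθθ = D12·u' + D11·u/r + (D11 + D12)·γ

and radial force balance against the foundation reaction gives

    D11·(u'' + u'/r − u/r²) = k_eff · u,      u(0) = 0,  σrr(R) = 0,

with k_eff = α·k. This module discretizes the ODE with second-order central
finite differences on a uniform radial grid — a deliberately separate code
path from the 2D finite-element solver, used only for cross-validation. The
closed-form solution u(r) = C·I₁(r/ℓ) with ℓ = √(D11/k_eff) (modified Bessel
function) is also provided as a second, analytic check.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import iv

from dewetsim.fem import lame_constants


def _coeffs(E: float, nu: float) -> tuple[float, float]:
    lam, mu = lame_constants(E, nu)
    return lam + 2.0 * mu, lam


def axisym_oracle(
    E: float,
    nu: float,
    k_eff: float,
    gamma: float,
    R: float,
    n_r: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial displacement profile u(r) of the uniformly contracting disk.

    Parameters
    ----------
    E, nu : elastic constants (kPa, dimensionless).
    k_eff : effective foundation density α·k (kPa/μm), > 0.
    gamma : uniform contraction magnitude (≥ 0, contraction-positive).
    R : disk radius (μm).
    n_r : number of radial grid points (≥ 10).

    Returns
    -------
    (r, u) : radial grid and displacement; u ≤ 0 (inward) for gamma > 0.
    """
    if k_eff <= 0:
        raise ValueError("k_eff must be positive")
    if n_r < 10:
        raise ValueError("n_r must be at least 10 for a meaningful resolution")
    a, b = _coeffs(E, nu)
    r = np.linspace(0.0, R, n_r)
    dr = r[1] - r[0]

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_r)

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    add(0, 0, 1.0)  # u(0) = 0
    for i in range(1, n_r - 1):
        ri = r[i]
        add(i, i - 1, a * (1.0 / dr**2 - 1.0 / (2.0 * ri * dr)))
        add(i, i, a * (-2.0 / dr**2 - 1.0 / ri**2) - k_eff)
        add(i, i + 1, a * (1.0 / dr**2 + 1.0 / (2.0 * ri * dr)))
    # σrr(R) = 0, one-sided second-order derivative
    n = n_r - 1
    add(n, n, a * 3.0 / (2.0 * dr) + b / R)
    add(n, n - 1, a * (-4.0) / (2.0 * dr))
    add(n, n - 2, a * 1.0 / (2.0 * dr))
    rhs[n] = -(a + b) * gamma

    A = sp.coo_matrix((vals, (rows, cols)), shape=(n_r, n_r)).tocsc()
    u = spla.spsolve(A, rhs)
    return r, u


def axisym_closed_form(
    E: float, nu: float, k_eff: float, gamma: float, R: float, r: np.ndarray
) -> np.ndarray:
    """Analytic solution u(r) = C·I₁(r/ℓ), ℓ = √((λ+2μ)/k_eff).

    C is fixed by the traction-free rim condition σrr(R) = 0. Uses modified
    Bessel functions; valid for uniform contraction γ on the whole disk.
    """
    a, b = _coeffs(E, nu)
    ell = np.sqrt(a / k_eff)
    x = R / ell
    # I1'(x) = I0(x) - I1(x)/x
    dI1 = iv(0, x) - iv(1, x) / x
    C = -(a + b) * gamma / (a * dI1 / ell + b * iv(1, x) / R)
    return C * iv(1, np.asarray(r) / ell)
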