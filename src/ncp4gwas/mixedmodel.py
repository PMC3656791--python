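"""Single-random-effect REML machinery on the eigenbasis of a relationship matrix.

The model is y = Xb + u + e with var(u) = K sigma_a^2 and var(e) = I sigma_e^2,
one record per animal. Rotating by the eigenvectors of K makes the covariance
diagonal, after which the restricted likelihood is cheap for any variance
ratio. Two fitters are provided:

``profile``
    maximizes the restricted likelihood profiled over sigma_e^2 as a function
    of the variance ratio gamma = sigma_a^2/sigma_e^2 (grid + golden/Brent
    refinement, boundary gamma = 0 checked explicitly);
``em``
    classical EM-REML updates, which increase the restricted likelihood at
    every iteration (kept both as an alternative and because its monotone
    trace is a useful self-check).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["RotatedDesign", "RemlResult", "rotate", "reml_fit", "gls_fixed_effects"]


@dataclass
class RotatedDesign:
    """Response/design rotated by the eigenvectors of the relationship matrix."""

    eigvals: np.ndarray    # eigenvalues of K, ascending, clipped at 0
    eigvecs: np.ndarray    # corresponding eigenvectors (columns)
    x_rot: np.ndarray      # U' X
    y_rot: np.ndarray      # U' y

    @property
    def n(self) -> int:
        return len(self.y_rot)

    @property
    def p(self) -> int:
        return self.x_rot.shape[1]

    def replace_y(self, y: np.ndarray) -> "RotatedDesign":
        return RotatedDesign(self.eigvals, self.eigvecs, self.x_rot, self.eigvecs.T @ y)


@dataclass
class RemlResult:
    sigma_a2: float
    sigma_e2: float
    heritability: float
    beta: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    method: str
    loglik_trace: list[float] = field(default_factory=list)


def rotate(y: np.ndarray, x: np.ndarray, kinship: np.ndarray | None = None,
           eig: tuple[np.ndarray, np.ndarray] | None = None) -> RotatedDesign:
    """Eigendecompose K (or reuse a decomposition) and rotate y and X."""
    if eig is None:
        if kinship is None:
            raise ValueError("either kinship or its eigendecomposition is required")
        k = np.asarray(kinship, dtype=float)
        if not np.allclose(k, k.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")
        w, u = np.linalg.eigh(k)
        if w[0] < -1e-6 * max(1.0, w[-1]):
            raise ValueError(f"relationship matrix is not PSD (min eigenvalue {w[0]:.3e})")
        w = np.clip(w, 0.0, None)
    else:
        w, u = eig
    return RotatedDesign(w, u, u.T @ np.asarray(x, float), u.T @ np.asarray(y, float))


def _neg2_restricted_ll(gamma: float, d: RotatedDesign) -> tuple[float, float, np.ndarray]:
    """-2 profiled restricted log-likelihood at variance ratio gamma.

    Returns (-2 llR, profiled sigma_e^2, GLS beta)."""
    v0 = gamma * d.eigvals + 1.0
    w = 1.0 / v0
    xw = d.x_rot * w[:, None]
    xtwx = d.x_rot.T @ xw
    xtwy = xw.T @ d.y_rot
    beta = np.linalg.solve(xtwx, xtwy)
    r = d.y_rot - d.x_rot @ beta
    rss = float(np.sum(w * r * r))
    df = d.n - d.p
    sigma_e2 = rss / df
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite (rank-deficient design?)")
    neg2 = df * np.log(sigma_e2) + float(np.sum(np.log(v0))) + logdet_xtwx + df
    return neg2, sigma_e2, beta


def _fit_profile(d: RotatedDesign, tol: float) -> RemlResult:
    grid = np.concatenate(([0.0], np.exp(np.linspace(np.log(1e-4), np.log(1e4), 41))))
    vals = np.array([_neg2_restricted_ll(g, d)[0] for g in grid])
    j = int(np.argmin(vals))
    if j == 0:
        lo, hi = 0.0, grid[1]
    else:
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
    res = minimize_scalar(lambda g: _neg2_restricted_ll(g, d)[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": tol * max(1.0, grid[j])})
    gamma = float(res.x)
    neg2, sigma_e2, beta = _neg2_restricted_ll(gamma, d)
    if vals[0] <= neg2:  # boundary at least as good: no additive variance
        gamma = 0.0
        neg2, sigma_e2, beta = _neg2_restricted_ll(0.0, d)
    sigma_a2 = gamma * sigma_e2
    return RemlResult(sigma_a2, sigma_e2, sigma_a2 / (sigma_a2 + sigma_e2),
                      beta, -0.5 * neg2, int(res.nfev) + len(grid), True, "profile")


def _fit_em(d: RotatedDesign, tol: float, max_iter: int) -> RemlResult:
    n, p = d.n, d.p
    var_y = float(np.var(d.y_rot))
    sigma_a2 = sigma_e2 = max(var_y / 2.0, 1e-10)
    trace: list[float] = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        v = sigma_a2 * d.eigvals + sigma_e2
        w = 1.0 / v
        xw = d.x_rot * w[:, None]
        xtwx = d.x_rot.T @ xw
        beta = np.linalg.solve(xtwx, xw.T @ d.y_rot)
        r = d.y_rot - d.x_rot @ beta
        py = w * r
        c = np.linalg.inv(xtwx)
        # tr(P G) = tr(WG) - tr(C X'WGWX) for G diagonal
        def tr_pg(g: np.ndarray) -> float:
            m = d.x_rot.T @ (d.x_rot * (w * w * g)[:, None])
            return float(np.sum(w * g) - np.trace(c @ m))

        ypdpy = float(np.sum(d.eigvals * py * py))
        yppy = float(np.sum(py * py))
        sign, logdet = np.linalg.slogdet(xtwx)
        ll = -0.5 * (float(np.sum(np.log(v))) + logdet + float(np.sum(r * py)))
        trace.append(ll)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        sigma_a2 = max(sigma_a2 + sigma_a2 ** 2 * (ypdpy - tr_pg(d.eigvals)) / n, 1e-12)
        sigma_e2 = max(sigma_e2 + sigma_e2 ** 2 * (yppy - tr_pg(np.ones(n))) / n, 1e-12)
    h2 = sigma_a2 / (sigma_a2 + sigma_e2)
    return RemlResult(sigma_a2, sigma_e2, h2, beta, trace[-1], it, converged, "em", trace)


def reml_fit(design: RotatedDesign, method: str = "profile", tol: float = 1e-8,
             max_iter: int = 200) -> RemlResult:
    """Fit variance components by REML on a rotated design."""
    if design.n <= design.p:
        raise ValueError("more fixed-effect parameters than records")
    if method == "profile":
        return _fit_profile(design, tol)
    if method == "em":
        return _fit_em(design, tol, max_iter)
    raise ValueError(f"unknown REML method {method!r}")


def gls_fixed_effects(design: RotatedDesign, sigma_a2: float, sigma_e2: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """GLS estimates and covariance of the fixed effects at given components."""
    v = sigma_a2 * design.eigvals + sigma_e2
    w = 1.0 / v
    xw = design.x_rot * w[:, None]
    xtwx = design.x_rot.T @ xw
    cov = np.linalg.inv(xtwx)
    beta = cov @ (xw.T @ design.y_rot)
    return beta, cov
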