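"""The five-parameter Frequency Modulated Mobius (FMM) oscillation model.

The FMM wave is

    mu(t) = M + A * cos(beta + 2 * arctan(omega * tan((t - alpha) / 2)))

with midline M, amplitude A >= 0, translation alpha in [0, 2 pi), shape
angle beta in [0, 2 pi) controlling skewness, and sharpness omega in (0, 1].
At omega = 1 the Mobius time-warp is the identity and the wave reduces to a
pure sinusoid M + A cos(t + beta - alpha); small omega concentrates the wave
into a sharp asymmetric pulse.  The peak phase (acrophase) has the closed
form

    t_U = alpha + 2 * arctan((1 / omega) * tan(-beta / 2))   (mod 2 pi).

Fitting profiles out the linear parameters: for fixed (alpha, omega) the
model is linear in (M, A cos beta, -A sin beta), so a grid over
(alpha, omega) with an exact least-squares inner solve, followed by a
Nelder-Mead refinement of (alpha, omega), yields a deterministic fit.  The
cosinor (three-parameter sinusoid) is the omega = 1 submodel and is always
included as a candidate, so the FMM fit can never score below cosinor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

TWO_PI = 2.0 * np.pi

__all__ = [
    "FMMParameters",
    "FMMFit",
    "GridSpec",
    "fmm_evaluate",
    "peak_time",
    "fmm_fit",
    "fmm_fit_batch",
    "cosinor_fit",
]


@dataclass(frozen=True)
class FMMParameters:
    """FMM wave parameters; angles stored reduced modulo 2 pi."""

    m: float
    a: float
    alpha: float
    beta: float
    omega: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("amplitude A must be >= 0")
        if not (0.0 < self.omega <= 1.0):
            raise ValueError("omega must lie in (0, 1]")
        object.__setattr__(self, "alpha", float(np.mod(self.alpha, TWO_PI)))
        object.__setattr__(self, "beta", float(np.mod(self.beta, TWO_PI)))


@dataclass(frozen=True)
class FMMFit:
    """A fitted FMM wave: parameters, peak phase t_U and goodness of fit."""

    params: FMMParameters
    t_u: float
    r2: float
    residual_sse: float


@dataclass(frozen=True)
class GridSpec:
    """Search grid for the (alpha, omega) profile: 48 translations x 24
    log-spaced sharpness values, then derivative-free local refinement."""

    n_alpha: int = 48
    n_omega: int = 24
    omega_min: float = 0.01
    omega_max: float = 1.0
    refine: bool = True
    nm_maxiter: int = 200

    def alphas(self) -> np.ndarray:
        return np.linspace(0.0, TWO_PI, self.n_alpha, endpoint=False)

    def omegas(self) -> np.ndarray:
        return np.geomspace(self.omega_min, self.omega_max, self.n_omega)


DEFAULT_GRID = GridSpec()


def _phase_warp(t: np.ndarray, alpha: float, omega: float) -> np.ndarray:
    """psi(t) = 2 arctan(omega tan((t - alpha)/2)), computed with atan2 so the
    tangent singularity at t - alpha = pi is handled continuously."""
    half = (np.asarray(t, dtype=float) - alpha) / 2.0
    return 2.0 * np.arctan2(omega * np.sin(half), np.cos(half))


def fmm_evaluate(p: FMMParameters, t: Sequence[float] | np.ndarray) -> np.ndarray:
    """Evaluate mu(t) = M + A cos(beta + psi(t)) elementwise."""
    psi = _phase_warp(np.asarray(t, dtype=float), p.alpha, p.omega)
    return p.m + p.a * np.cos(p.beta + psi)


def peak_time(p: FMMParameters) -> float:
    """Closed-form peak phase t_U = alpha + 2 arctan(tan(-beta/2) / omega).

    The warp psi is a strictly increasing bijection of the circle, so the
    unique maximizer of the wave is where psi(t) = -beta (mod 2 pi).
    """
    if p.a == 0:
        raise ValueError("peak undefined for flat signal (A = 0)")
    inner = 2.0 * np.arctan2(np.sin(-p.beta / 2.0),
                             p.omega * np.cos(-p.beta / 2.0))
    t_u = float(np.mod(p.alpha + inner, TWO_PI))
    # collapse the 0 / 2 pi seam so boundary peaks classify as phase 0
    return 0.0 if TWO_PI - t_u < 1e-9 else t_u


# -- fitting -------------------------------------------------------------------


def _sse_to_r2(sse: float, sst: float) -> float:
    if sst <= 0:
        return 0.0
    return float(min(1.0, max(0.0, 1.0 - sse / sst)))


def cosinor_fit(y: Sequence[float], t: Sequence[float]) -> FMMFit:
    """Exact least-squares sinusoid M + A cos(t + phi), returned as the
    omega = 1 FMM submodel (alpha = t_U, beta = 0)."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("y and t must be 1-D of equal length")
    if len(y) < 4:
        raise ValueError("cosinor fit needs at least 4 points")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        params = FMMParameters(m=float(y[0]), a=0.0, alpha=0.0, beta=0.0, omega=1.0)
        return FMMFit(params=params, t_u=0.0, r2=0.0, residual_sse=0.0)
    design = np.column_stack([np.ones_like(t), np.cos(t), np.sin(t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sse = float(resid @ resid)
    m0, c, s = coef
    a = float(np.hypot(c, s))
    t_u = float(np.mod(np.arctan2(s, c), TWO_PI))
    params = FMMParameters(m=float(m0), a=a, alpha=t_u, beta=0.0, omega=1.0)
    return FMMFit(params=params, t_u=t_u if a > 0 else 0.0,
                  r2=_sse_to_r2(sse, sst), residual_sse=sse)


class _ProfileDesign:
    """Precomputed grid designs shared across genes measured at the same t.

    For every grid point (alpha_i, omega_j) the 3 x 3 normal matrix of the
    design [1, cos psi, sin psi] depends only on t, so its inverse is built
    once; per gene only the right-hand side changes.
    """

    def __init__(self, t: np.ndarray, grid: GridSpec):
        self.t = np.asarray(t, dtype=float)
        self.grid = grid
        alphas = grid.alphas()
        omegas = grid.omegas()
        aa, oo = np.meshgrid(alphas, omegas, indexing="ij")
        self.alpha_flat = aa.ravel()
        self.omega_flat = oo.ravel()
        m = len(self.t)
        half = (self.t[None, :] - self.alpha_flat[:, None]) / 2.0
        psi = 2.0 * np.arctan2(self.omega_flat[:, None] * np.sin(half),
                               np.cos(half))
        self.C = np.cos(psi)
        self.S = np.sin(psi)
        n = len(self.alpha_flat)
        G = np.empty((n, 3, 3))
        G[:, 0, 0] = m
        G[:, 0, 1] = G[:, 1, 0] = self.C.sum(axis=1)
        G[:, 0, 2] = G[:, 2, 0] = self.S.sum(axis=1)
        G[:, 1, 1] = (self.C * self.C).sum(axis=1)
        G[:, 1, 2] = G[:, 2, 1] = (self.C * self.S).sum(axis=1)
        G[:, 2, 2] = (self.S * self.S).sum(axis=1)
        try:
            self.Ginv = np.linalg.inv(G)
        except np.linalg.LinAlgError:
            self.Ginv = np.linalg.pinv(G)

    def solve_gene(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (coef, sse) over all grid points for one response vector."""
        b = np.empty((len(self.alpha_flat), 3))
        b[:, 0] = y.sum()
        b[:, 1] = self.C @ y
        b[:, 2] = self.S @ y
        coef = np.einsum("nij,nj->ni", self.Ginv, b)
        sse = float(y @ y) - np.einsum("ni,ni->n", coef, b)
        return coef, sse


def _profile_sse(y: np.ndarray, t: np.ndarray, alpha: float,
                 omega: float) -> tuple[float, np.ndarray]:
    psi = _phase_warp(t, alpha, omega)
    design = np.column_stack([np.ones_like(t), np.cos(psi), np.sin(psi)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def _coef_to_params(coef: np.ndarray, alpha: float, omega: float) -> FMMParameters:
    m0, c, s = coef
    a = float(np.hypot(c, s))
    # cos(beta + psi) = cos beta cos psi - sin beta sin psi:
    # c = A cos beta, s = -A sin beta
    beta = float(np.mod(np.arctan2(-s, c), TWO_PI))
    return FMMParameters(m=float(m0), a=a, alpha=alpha, beta=beta,
                         omega=float(omega))


def _fit_single(y: np.ndarray, t: np.ndarray, grid: GridSpec,
                design: _ProfileDesign | None = None) -> FMMFit:
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        params = FMMParameters(m=float(y[0]), a=0.0, alpha=0.0, beta=0.0, omega=1.0)
        return FMMFit(params=params, t_u=0.0, r2=0.0, residual_sse=0.0)

    if design is None:
        design = _ProfileDesign(t, grid)
    coef_grid, sse_grid = design.solve_gene(y)
    best = int(np.argmin(sse_grid))
    alpha0 = float(design.alpha_flat[best])
    omega0 = float(design.omega_flat[best])
    best_sse, best_coef = _profile_sse(y, t, alpha0, omega0)
    best_alpha, best_omega = alpha0, omega0

    if grid.refine:
        lo, hi = grid.omega_min, grid.omega_max

        def objective(x: np.ndarray) -> float:
            a_, w_ = x
            if not (lo <= w_ <= hi):
                return best_sse + 1e6 * (1.0 + abs(w_))
            return _profile_sse(y, t, a_, w_)[0]

        res = minimize(objective, x0=np.array([alpha0, omega0]),
                       method="Nelder-Mead",
                       options={"maxiter": grid.nm_maxiter,
                                "xatol": 1e-6, "fatol": 1e-12})
        a_, w_ = res.x
        if lo <= w_ <= hi:
            sse_ref, coef_ref = _profile_sse(y, t, float(a_), float(w_))
            if sse_ref < best_sse:
                best_sse, best_coef = sse_ref, coef_ref
                best_alpha, best_omega = float(np.mod(a_, TWO_PI)), float(w_)

    # cosinor is the omega = 1 submodel: keep it whenever it scores at least
    # as well, guaranteeing R2_FMM >= R2_cosinor exactly.
    cos_fit = cosinor_fit(y, t)
    if cos_fit.residual_sse <= best_sse:
        return cos_fit

    params = _coef_to_params(best_coef, best_alpha, best_omega)
    t_u = peak_time(params) if params.a > 0 else 0.0
    return FMMFit(params=params, t_u=t_u,
                  r2=_sse_to_r2(best_sse, sst), residual_sse=best_sse)


def fmm_fit(y: Sequence[float], t: Sequence[float],
            grid: GridSpec = DEFAULT_GRID) -> FMMFit:
    """Fit the FMM wave to (t, y) by profiled grid search plus refinement.

    Deterministic for a fixed GridSpec; t need not be equally spaced.
    Requires at least 7 observations (5 parameters + 2).
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("y and t must be 1-D of equal length")
    if len(y) < 7:
        raise ValueError("FMM fit needs at least 7 points")
    return _fit_single(y, t, grid)


def fmm_fit_batch(Y: np.ndarray, t: Sequence[float],
                  grid: GridSpec = DEFAULT_GRID,
                  skip_errors: bool = False) -> list[FMMFit | None]:
    """Fit many genes measured at the same angles, sharing the grid design.

    With ``skip_errors`` a gene whose fit raises is returned as None
    instead of aborting the batch.
    """
    Y = np.asarray(Y, dtype=float)
    t = np.asarray(t, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != len(t):
        raise ValueError("Y must be n_genes x len(t)")
    if len(t) < 7:
        raise ValueError("FMM fit needs at least 7 points")
    design = _ProfileDesign(t, grid)
    fits: list[FMMFit | None] = []
    for i in range(Y.shape[0]):
        try:
            fits.append(_fit_single(Y[i], t, grid, design=design))
        except Exception:
            if not skip_errors:
                raise
            fits.append(None)
    return fits
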