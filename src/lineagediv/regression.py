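"""Model competition for lineage diversity along the precipitation gradient.

Three mean structures are compared by AIC: a straight line, a quadratic
("hump-shaped") polynomial, and a piecewise model in which two independent,
possibly discontinuous lines meet at an estimated break point.  Spatial
autocorrelation in the residuals is handled by generalized least squares
with exponential, Gaussian, linear or spherical correlation decaying with
great-circle distance, the range estimated by profile maximum likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import linalg, optimize, stats

from .simulate import distance_matrix_km

__all__ = [
    "SpatialCorrelation",
    "SegmentLine",
    "ModelFit",
    "fit_polynomial",
    "fit_piecewise",
    "evaluate_piecewise",
    "gls_fit",
    "select_model",
    "mean_ci",
    "correlation_matrix",
]

STRUCTURES = ("none", "exponential", "gaussian", "linear", "spherical")


@dataclass(frozen=True)
class SpatialCorrelation:
    """Residual spatial correlation: kind, range (km) and nugget."""

    structure: str = "none"
    range_km: float | None = None
    nugget: float = 0.0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown spatial structure {self.structure!r}")
        if self.structure != "none" and (self.range_km is None or self.range_km <= 0):
            raise ValueError("range_km must be > 0 for a spatial structure")
        if not 0.0 <= self.nugget < 1.0:
            raise ValueError("nugget must be in [0, 1)")


def correlation_matrix(d_km: np.ndarray, spec: SpatialCorrelation) -> np.ndarray:
    """Correlation matrix for a distance matrix under a spatial structure.

    rho(0) = 1 exactly; for d > 0 the nugget discounts all structures by
    (1 - nugget).  All four kernels are nonincreasing in distance.
    """
    if spec.structure == "none":
        return np.eye(d_km.shape[0])
    r = float(spec.range_km)
    h = d_km / r
    if spec.structure == "exponential":
        rho = np.exp(-h)
    elif spec.structure == "gaussian":
        rho = np.exp(-(h ** 2))
    elif spec.structure == "linear":
        rho = np.where(h < 1.0, 1.0 - h, 0.0)
    elif spec.structure == "spherical":
        rho = np.where(h < 1.0, 1.0 - 1.5 * h + 0.5 * h ** 3, 0.0)
    else:  # pragma: no cover
        raise ValueError(spec.structure)
    if spec.nugget:
        rho = (1.0 - spec.nugget) * rho
    np.fill_diagonal(rho, 1.0)
    return rho


@dataclass(frozen=True)
class SegmentLine:
    """One straight-line segment of a piecewise fit, on its MAP domain."""

    slope: float
    intercept: float
    domain: tuple[float, float]
    cov: np.ndarray | None = None  # 2x2 covariance of (intercept, slope)
    df_resid: int = 0
    n: int = 0
    p_values: tuple[float, float] | None = None

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class ModelFit:
    """A fitted mean model with its likelihood bookkeeping.

    ``k`` counts every estimated parameter including the residual variance
    (and the break point / spatial range where present), so AIC values are
    comparable across kinds.
    """

    kind: str  # linear | quadratic | piecewise | gls
    coefficients: np.ndarray | tuple[SegmentLine, SegmentLine]
    k: int
    loglik: float
    aic: float
    r2: float
    adj_r2: float
    n: int
    p_values: np.ndarray | None = None
    break_point: float | None = None
    spatial: SpatialCorrelation | None = None
    delta_aic_vs_null_spatial: float | None = None
    cov_params: np.ndarray | None = None
    df_resid: int | None = None
    design_fn: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)
    fitted: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)

    def summary_row(self) -> dict:
        return {
            "kind": self.kind,
            "structure": self.spatial.structure if self.spatial else "none",
            "k": self.k,
            "loglik": self.loglik,
            "aic": self.aic,
            "delta_aic": self.delta_aic_vs_null_spatial,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "break_point": self.break_point,
        }


def _gaussian_loglik(rss: float, n: int) -> float:
    s2 = max(rss / n, np.finfo(float).tiny)
    return -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)


def _check_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    return x, y


def fit_polynomial(x: np.ndarray, y: np.ndarray, degree: int) -> ModelFit:
    """OLS polynomial of degree 1 (linear) or 2 (quadratic) with adjusted r²,
    two-sided t p-values, and Gaussian-likelihood AIC."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x, y = _check_xy(x, y)
    n = len(x)
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    X = np.vander(x, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant x?)")
    res = sm.OLS(y, X).fit()
    k = degree + 2  # coefficients + residual variance
    ll = float(res.llf)
    fit = ModelFit(
        kind="linear" if degree == 1 else "quadratic",
        coefficients=np.asarray(res.params),
        k=k,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n=n,
        p_values=np.asarray(res.pvalues),
        cov_params=np.asarray(res.cov_params()),
        df_resid=int(res.df_resid),
        design_fn=lambda g, d=degree: np.vander(np.asarray(g, dtype=float), d + 1,
                                                increasing=True),
        fitted=np.asarray(res.fittedvalues),
        _y=y,
    )
    return fit


def _segment_ols(x: np.ndarray, y: np.ndarray, domain: tuple[float, float]) -> tuple[SegmentLine, float]:
    X = np.column_stack([np.ones_like(x), x])
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    seg = SegmentLine(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        domain=domain,
        cov=np.asarray(res.cov_params()),
        df_resid=int(res.df_resid),
        n=len(x),
        p_values=(float(res.pvalues[0]), float(res.pvalues[1])),
    )
    return seg, rss


def fit_piecewise(x: np.ndarray, y: np.ndarray, min_segment: int = 5) -> ModelFit:
    """Break-point regression: two independent lines split at the x value
    minimizing pooled residual sum of squares.

    Candidates are the unique observed x leaving at least ``min_segment``
    points strictly below and at-or-above; the two segments are fit by
    separate OLS with no continuity constraint, so the mean function may
    jump at the break.  AIC counts 6 parameters (two slopes, two
    intercepts, the break point, the residual variance).
    """
    if min_segment < 3:
        raise ValueError("min_segment must be >= 3")
    x, y = _check_xy(x, y)
    n = len(x)
    if n < 2 * min_segment:
        raise ValueError("too few points for a piecewise fit")
    xs = np.unique(x)
    if len(xs) < 2:
        raise ValueError("all x values equal")
    candidates = [c for c in xs
                  if (x < c).sum() >= min_segment and (x >= c).sum() >= min_segment]
    if not candidates:
        raise ValueError("no candidate break point satisfies the segment minimum")
    # vectorized RSS scan over candidates via cumulative sums on sorted x
    best_rss, best_c = np.inf, None
    order = np.argsort(x, kind="stable")
    xo, yo = x[order], y[order]
    for c in candidates:
        left = xo < c
        rss = _ols_rss(xo[left], yo[left]) + _ols_rss(xo[~left], yo[~left])
        if rss < best_rss - 1e-15 or (best_c is None):
            best_rss, best_c = rss, c
    left = x < best_c
    seg_lo, rss_lo = _segment_ols(x[left], y[left], (float(x.min()), float(best_c)))
    seg_hi, rss_hi = _segment_ols(x[~left], y[~left], (float(best_c), float(x.max())))
    rss = rss_lo + rss_hi
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    p_mean = 5  # regression parameters: 2 slopes + 2 intercepts + break point
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / max(n - p_mean, 1)
    k = 6
    ll = _gaussian_loglik(rss, n)
    fitted = np.where(left, seg_lo.predict(x), seg_hi.predict(x))
    return ModelFit(
        kind="piecewise",
        coefficients=(seg_lo, seg_hi),
        k=k,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        r2=max(r2, 0.0),
        adj_r2=adj_r2,
        n=n,
        p_values=np.array([*seg_lo.p_values, *seg_hi.p_values]),
        break_point=float(best_c),
        fitted=fitted,
        _y=y,
    )


def _ols_rss(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx = (x * x).sum() - sx * sx / n
    sxy = (x * y).sum() - sx * sy / n
    syy = (y * y).sum() - sy * sy / n
    if sxx <= 0:
        return float(syy)
    return float(max(syy - sxy * sxy / sxx, 0.0))


def evaluate_piecewise(fit: ModelFit, x: np.ndarray | float) -> np.ndarray | float:
    """Predicted LD at x: the before-segment line below the break point, the
    after-segment line at or above it."""
    if fit.kind != "piecewise":
        raise ValueError("fit is not piecewise")
    seg_lo, seg_hi = fit.coefficients
    xa = np.asarray(x, dtype=float)
    out = np.where(xa < fit.break_point, seg_lo.predict(xa), seg_hi.predict(xa))
    return float(out) if np.isscalar(x) else out


# -- spatial GLS --------------------------------------------------------


def _gls_profile(X: np.ndarray, y: np.ndarray, sigma_corr: np.ndarray,
                 jitter: bool = True) -> dict:
    n, p = X.shape
    try:
        cho = linalg.cho_factor(sigma_corr, lower=True)
    except linalg.LinAlgError:
        if not jitter:
            raise
        try:
            cho = linalg.cho_factor(sigma_corr + 1e-10 * np.eye(n), lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("spatial correlation matrix is not positive definite") from exc
    si_X = linalg.cho_solve(cho, X)
    si_y = linalg.cho_solve(cho, y)
    xtsx = X.T @ si_X
    beta = np.linalg.solve(xtsx, X.T @ si_y)
    r = y - X @ beta
    si_r = linalg.cho_solve(cho, r)
    rss = float(r @ si_r)
    s2_ml = max(rss / n, np.finfo(float).tiny)
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    ll = -0.5 * (n * math.log(2 * math.pi * s2_ml) + logdet + n)
    s2_unb = rss / max(n - p, 1)
    cov_beta = s2_unb * np.linalg.inv(xtsx)
    return {"beta": beta, "loglik": ll, "rss": rss, "cov_beta": cov_beta,
            "sigma2_ml": s2_ml, "df_resid": n - p}


def gls_fit(design: np.ndarray, y: np.ndarray, coords: np.ndarray,
            structure: SpatialCorrelation | str,
            range_bounds: tuple[float, float] | None = None) -> ModelFit:
    """Generalized least squares with a spatial residual correlation.

    ``design`` is the full design matrix (intercept included); ``coords``
    are (lon, lat) pairs in decimal degrees, converted to great-circle
    distances in km.  For the four spatial structures the correlation
    range is estimated by profile maximum likelihood over
    [1 km, 2 x max distance] unless a fixed-range spec is given.  AIC
    counts the coefficients, the residual variance, and the range where
    estimated.  ``delta_aic_vs_null_spatial`` is AIC minus the AIC of the
    same design with no spatial structure; ``r2`` is the squared Pearson
    correlation of fitted versus observed.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("too few observations for the design")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    d = distance_matrix_km(coords[:, 0], coords[:, 1])
    dmax = float(d.max())
    if dmax <= 0:
        raise ValueError("all pairwise distances are zero")

    if isinstance(structure, str):
        spec_kind = structure
        fixed_range = None
        nugget = 0.0
    else:
        spec_kind = structure.structure
        fixed_range = structure.range_km
        nugget = structure.nugget

    def fit_at(spec: SpatialCorrelation) -> dict:
        return _gls_profile(X, y, correlation_matrix(d, spec))

    none_res = fit_at(SpatialCorrelation("none"))
    k_none = p + 1
    aic_none = -2.0 * none_res["loglik"] + 2.0 * k_none

    if spec_kind == "none":
        res, spec, k, aic = none_res, SpatialCorrelation("none"), k_none, aic_none
    elif fixed_range is not None:
        spec = SpatialCorrelation(spec_kind, fixed_range, nugget)
        res = fit_at(spec)
        k = p + 1  # range not estimated
        aic = -2.0 * res["loglik"] + 2.0 * k
    else:
        lo, hi = range_bounds if range_bounds else (1.0, 2.0 * dmax)

        def negll(r_km: float) -> float:
            try:
                return -fit_at(SpatialCorrelation(spec_kind, r_km, nugget))["loglik"]
            except ValueError:
                return 1e300  # finite sentinel keeps the bounded search stable

        grid = np.geomspace(lo, hi, 8)
        vals = [(negll(r), r) for r in grid]
        best_val, best_r = min(vals)
        gi = int(np.argmin([v for v, _ in vals]))
        blo = grid[max(gi - 1, 0)]
        bhi = grid[min(gi + 1, len(grid) - 1)]
        if blo < bhi:
            opt = optimize.minimize_scalar(negll, bounds=(blo, bhi), method="bounded")
            if np.isfinite(opt.fun) and opt.fun < best_val:
                best_val, best_r = float(opt.fun), float(opt.x)
        if not np.isfinite(best_val):
            raise ValueError(f"profile likelihood failed for structure {spec_kind!r}")
        spec = SpatialCorrelation(spec_kind, best_r, nugget)
        res = fit_at(spec)
        k = p + 2  # coefficients + sigma2 + range
        aic = -2.0 * res["loglik"] + 2.0 * k

    beta = res["beta"]
    fitted = X @ beta
    se = np.sqrt(np.diag(res["cov_beta"]))
    tvals = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=res["df_resid"])
    if np.std(fitted) > 0 and np.std(y) > 0:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    else:
        r2 = 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / max(n - p, 1)
    return ModelFit(
        kind="gls",
        coefficients=beta,
        k=k,
        loglik=float(res["loglik"]),
        aic=float(aic),
        r2=r2,
        adj_r2=adj_r2,
        n=n,
        p_values=pvals,
        spatial=spec,
        delta_aic_vs_null_spatial=float(aic - aic_none),
        cov_params=res["cov_beta"],
        df_resid=int(res["df_resid"]),
        fitted=fitted,
        _y=y,
    )


def select_model(fits: Sequence[ModelFit]) -> ModelFit:
    """Minimum-AIC fit; ties (ΔAIC < 1e-9) go to the fewest parameters."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to select among")
    y0 = fits[0]._y
    for f in fits[1:]:
        if f._y is None or y0 is None or len(f._y) != len(y0) or not np.allclose(f._y, y0):
            raise ValueError("fits were computed on different response vectors")
    best = fits[0]
    for f in fits[1:]:
        if f.aic < best.aic - 1e-9 or (abs(f.aic - best.aic) < 1e-9 and f.k < best.k):
            best = f
    return best


def mean_ci(fit: ModelFit, x_grid: np.ndarray, level: float = 0.99) -> dict[str, np.ndarray]:
    """Pointwise confidence band for the mean response along ``x_grid``.

    Delta method on the coefficient covariance; for piecewise fits the band
    is computed per segment and excludes break-point uncertainty.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    xg = np.asarray(x_grid, dtype=float).ravel()
    if fit.kind == "piecewise":
        seg_lo, seg_hi = fit.coefficients
        pred = evaluate_piecewise(fit, xg)
        half = np.empty_like(xg)
        for seg, mask in ((seg_lo, xg < fit.break_point), (seg_hi, xg >= fit.break_point)):
            if not mask.any():
                continue
            G = np.column_stack([np.ones(mask.sum()), xg[mask]])
            var = np.einsum("ij,jk,ik->i", G, seg.cov, G)
            tq = stats.t.ppf(0.5 + level / 2.0, df=max(seg.df_resid, 1))
            half[mask] = tq * np.sqrt(np.maximum(var, 0.0))
    else:
        if fit.design_fn is None or fit.cov_params is None:
            raise ValueError("fit carries no design/covariance for a mean band")
        G = fit.design_fn(xg)
        pred = G @ fit.coefficients
        var = np.einsum("ij,jk,ik->i", G, fit.cov_params, G)
        tq = stats.t.ppf(0.5 + level / 2.0, df=max(fit.df_resid or fit.n - G.shape[1], 1))
        half = tq * np.sqrt(np.maximum(var, 0.0))
    return {"x": xg, "fit": pred, "lower": pred - half, "upper": pred + half}
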