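"""Penalized-spline additive models for temporal and spatial contrasts.

A compact Gaussian GAM engine built on penalized B-splines (P-splines:
equally spaced B-spline bases with difference penalties), supporting

* univariate smooths ``s(x)`` with second-order difference penalties,
* cyclic smooths (wrapped basis and penalty) for hour-of-day and
  day-of-year,
* tensor-product smooths ``te(x1, x2)`` from marginal bases with one
  penalty (and one smoothing parameter) per margin,
* factor-``by`` smooths: a separate smooth, with its own penalty, per
  level of a grouping factor (used for the indoor/outdoor split),
* parametric factor terms (dummy-coded).

Smoothing parameters minimize the generalized cross-validation score
GCV = n * RSS / (n - edf)^2 over log-lambda.  Effective degrees of
freedom are tr(H) of the penalized hat matrix; AIC is the Gaussian
2*(edf+1) - 2*logLik with the variance profiled out, and adjusted R^2
uses n - edf residual degrees of freedom.  Model comparison between
nested fits uses an approximate F test on effective degrees of freedom —
approximate because penalized edf are not integer ranks; it is labelled
as such in outputs.

Identifiability: every smooth is centered (sum of fitted values
constrained to zero, absorbed by reparameterization), so intercept and
factor terms carry the level information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats
from scipy.interpolate import BSpline

logger = logging.getLogger("microheat.gam")

__all__ = [
    "Term",
    "smooth_1d",
    "tensor_cyclic",
    "parametric_factor",
    "fit_additive",
    "fit_temporal",
    "fit_spatial",
    "compare",
    "ModelFit",
    "ModelComparison",
]

_RIDGE = 1e-8  # relative diagonal jitter for numerical safety


# ---------------------------------------------------------------------------
# bases and penalties

def _bspline_design(x: np.ndarray, k: int, lo: float, hi: float) -> np.ndarray:
    """Cubic B-spline design with k equally spaced basis functions on [lo, hi]."""
    if k < 4:
        raise ValueError("need k >= 4 basis functions for cubic splines")
    if hi <= lo:
        raise ValueError("degenerate covariate range")
    dx = (hi - lo) / (k - 3)
    knots = lo + (np.arange(k + 4) - 3) * dx
    xc = np.clip(x, lo, hi - 1e-12 * (hi - lo))
    return BSpline.design_matrix(xc, knots, 3).toarray()


def _cyclic_design(x: np.ndarray, k: int, period: float) -> np.ndarray:
    """Cyclic cubic B-spline design: k wrapped basis functions of period P."""
    if k < 4:
        raise ValueError("need k >= 4 basis functions for cyclic splines")
    dx = period / k
    knots = (np.arange(k + 7) - 3) * dx
    B = BSpline.design_matrix(np.mod(x, period), knots, 3).toarray()  # n x (k+3)
    B[:, :3] += B[:, k: k + 3]
    return B[:, :k]


def _diff_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _cyclic_penalty(k: int, order: int = 2) -> np.ndarray:
    idx = np.arange(k)
    D = np.zeros((k, k))
    if order != 2:
        raise ValueError("only second-order cyclic penalties supported")
    for i in idx:
        D[i, i] += 1.0
        D[i, (i + 1) % k] += -2.0
        D[i, (i + 2) % k] += 1.0
    return D.T @ D


def _absorb_centering(
    X: np.ndarray, penalties: list[np.ndarray], active: np.ndarray | None = None
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Reparameterize so the smooth sums to zero over (active) rows."""
    rows = X if active is None else X[active]
    c = rows.sum(axis=0)
    nrm = np.linalg.norm(c)
    if nrm < 1e-12:
        return X, penalties
    Z = sla.null_space(c[None, :] / nrm)
    return X @ Z, [Z.T @ S @ Z for S in penalties]


# ---------------------------------------------------------------------------
# term construction

@dataclass
class Term:
    """One block of the design: columns plus zero or more penalties.

    Each penalty matrix gets its own smoothing parameter.  ``X`` rows for
    observations outside a ``by`` level are zero.
    """

    name: str
    X: np.ndarray
    penalties: list[np.ndarray] = field(default_factory=list)
    is_smooth: bool = True


def smooth_1d(
    x: np.ndarray,
    name: str,
    k: int = 10,
    by: np.ndarray | None = None,
    cyclic: bool = False,
    period: float | None = None,
    min_unique: int = 4,
) -> Term:
    """Penalized univariate smooth of x, optionally restricted to a level.

    A covariate with fewer than ``min_unique`` distinct values cannot
    support a smooth and is demoted to a centered linear term (no
    penalty), with a log note.
    """
    x = np.asarray(x, dtype=float)
    active = np.ones(len(x), dtype=bool) if by is None else np.asarray(by, bool)
    xa = x[active]
    n_unique = np.unique(xa[~np.isnan(xa)]).size
    if n_unique < min_unique:
        logger.info("term %s: %d unique values < %d, demoted to linear",
                    name, n_unique, min_unique)
        col = np.zeros(len(x))
        col[active] = xa - np.nanmean(xa)
        if np.ptp(col) == 0:
            col[:] = 0.0
        return Term(name=name, X=col[:, None], penalties=[], is_smooth=False)
    k = min(k, max(4, n_unique))
    if cyclic:
        B = _cyclic_design(x, k, float(period))
        S = _cyclic_penalty(k)
    else:
        lo, hi = np.nanmin(xa), np.nanmax(xa)
        B = _bspline_design(x, k, float(lo), float(hi))
        S = _diff_penalty(k)
    if by is not None:
        B = B * active[:, None]
    B, pens = _absorb_centering(B, [S], active if by is not None else None)
    return Term(name=name, X=B, penalties=pens)


def tensor_cyclic(
    x1: np.ndarray,
    x2: np.ndarray,
    name: str,
    k: int = 8,
    periods: tuple[float, float] = (24.0, 366.0),
    by: np.ndarray | None = None,
) -> Term:
    """Tensor-product smooth of two cyclic covariates (hour, day-of-year).

    The basis is the row-wise Kronecker product of the two cyclic marginal
    bases; each margin contributes one penalty (S1 x I and I x S2) with
    its own smoothing parameter, so anisotropy in the two directions is
    handled naturally.
    """
    B1 = _cyclic_design(np.asarray(x1, float), k, periods[0])
    B2 = _cyclic_design(np.asarray(x2, float), k, periods[1])
    B = (B1[:, :, None] * B2[:, None, :]).reshape(len(B1), k * k)
    S1 = np.kron(_cyclic_penalty(k), np.eye(k))
    S2 = np.kron(np.eye(k), _cyclic_penalty(k))
    active = None
    if by is not None:
        active = np.asarray(by, bool)
        B = B * active[:, None]
    B, pens = _absorb_centering(B, [S1, S2], active)
    return Term(name=name, X=B, penalties=pens)


def parametric_factor(values: pd.Series | np.ndarray, name: str,
                      by: np.ndarray | None = None) -> Term:
    """Dummy-coded factor term (first level dropped as reference)."""
    s = pd.Series(np.asarray(values))
    levels = sorted(s.unique())
    cols = []
    for lev in levels[1:]:
        col = (s == lev).to_numpy(float)
        if by is not None:
            col = col * np.asarray(by, float)
        cols.append(col)
    X = np.column_stack(cols) if cols else np.zeros((len(s), 0))
    return Term(name=name, X=X, penalties=[], is_smooth=False)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class ModelFit:
    """A fitted penalized additive model (Gaussian, identity link)."""

    variant: str
    response: str
    n: int
    edf: float
    edf_terms: dict[str, float]
    rss: float
    tss: float
    aic: float
    adj_r2: float
    log_lambdas: np.ndarray
    coef: np.ndarray
    term_slices: dict[str, slice]
    y_checksum: int
    converged: bool
    design: np.ndarray | None = field(default=None, repr=False)

    def partial_effect(self, term_name: str) -> np.ndarray:
        """Fitted contribution of one term at the training rows."""
        if self.design is None:
            raise ValueError("fit was run without keep_design=True")
        sl = self.term_slices[term_name]
        return self.design[:, sl] @ self.coef[sl]

    @property
    def fitted(self) -> np.ndarray:
        if self.design is None:
            raise ValueError("fit was run without keep_design=True")
        return self.design @ self.coef


def fit_additive(
    y: np.ndarray,
    terms: list[Term],
    variant: str = "",
    response: str = "y",
    keep_design: bool = False,
) -> ModelFit:
    """Fit y ~ intercept + sum(terms) with GCV-selected smoothing.

    Raises on rank-deficient designs (after the per-term centering
    constraints) and flags non-converged smoothing searches rather than
    silently accepting them.
    """
    y = np.asarray(y, dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("response contains NaN; drop incomplete rows first")
    n = len(y)
    blocks = [np.ones((n, 1))]
    slices: dict[str, slice] = {"intercept": slice(0, 1)}
    pen_entries: list[tuple[slice, np.ndarray]] = []
    p = 1
    for t in terms:
        q = t.X.shape[1]
        sl = slice(p, p + q)
        slices[t.name] = sl
        blocks.append(t.X)
        for S in t.penalties:
            pen_entries.append((sl, S))
        p += q
    X = np.hstack(blocks)
    if n <= p:
        raise ValueError(f"more coefficients ({p}) than rows ({n})")

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    tss = float(((y - y.mean()) ** 2).sum())
    ridge = _RIDGE * float(np.trace(XtX)) / p

    def assemble(log_lams: np.ndarray) -> np.ndarray:
        A = XtX.copy()
        A[np.diag_indices_from(A)] += ridge
        for (sl, S), ll in zip(pen_entries, log_lams):
            A[sl, sl] += np.exp(ll) * S
        return A

    def solve(log_lams: np.ndarray):
        A = assemble(log_lams)
        try:
            cf = sla.cho_factor(A, check_finite=False)
        except sla.LinAlgError as exc:
            raise ValueError("rank-deficient design") from exc
        b = sla.cho_solve(cf, Xty, check_finite=False)
        H = sla.cho_solve(cf, XtX, check_finite=False)
        edf = float(np.trace(H))
        rss = max(yty - 2 * b @ Xty + b @ XtX @ b, 1e-300)
        return b, edf, rss, H

    n_lam = len(pen_entries)
    converged = True
    if n_lam:
        def gcv(log_lams):
            _, edf, rss, _ = solve(np.asarray(log_lams))
            denom = max(n - edf, 1.0)
            return n * rss / denom ** 2

        res = optimize.minimize(
            gcv, x0=np.zeros(n_lam), method="Powell",
            bounds=[(-10.0, 18.0)] * n_lam,
            options={"maxiter": 4000, "xtol": 1e-3, "ftol": 1e-8},
        )
        converged = bool(res.success)
        if not converged:
            logger.warning("smoothing-parameter search did not converge: %s",
                           res.message)
        log_lams = np.asarray(res.x)
    else:
        log_lams = np.zeros(0)

    b, edf, rss, H = solve(log_lams)
    edf_terms = {
        name: float(np.trace(H[sl, sl])) for name, sl in slices.items()
    }
    sigma2 = rss / n
    aic = n * np.log(2 * np.pi * sigma2) + n + 2.0 * (edf + 1.0)
    adj_r2 = 1.0 - (rss / max(n - edf, 1.0)) / (tss / (n - 1)) if tss > 0 else np.nan
    return ModelFit(
        variant=variant, response=response, n=n, edf=edf, edf_terms=edf_terms,
        rss=rss, tss=tss, aic=float(aic), adj_r2=float(adj_r2),
        log_lambdas=log_lams, coef=b, term_slices=slices,
        y_checksum=_checksum(y), converged=converged,
        design=X if keep_design else None,
    )


def _checksum(y: np.ndarray) -> int:
    import zlib

    return zlib.crc32(np.ascontiguousarray(y).tobytes())


# ---------------------------------------------------------------------------
# the four model variants

def fit_temporal(
    data: pd.DataFrame,
    response: str = "T",
    variant: str = "1",
    k: int = 8,
    keep_design: bool = False,
) -> ModelFit:
    """Temporal trend model: response ~ te(hour, day-of-year)[ | location].

    Variant "1" pools locations into one tensor smooth; variant "2" adds a
    location intercept and fits a separate tensor smooth per location.
    ``data`` needs columns ``response``, hour, doy (and location for
    variant 2); rows with missing response are dropped.
    """
    df = data.dropna(subset=[response])
    hour = df["hour"].to_numpy(float)
    doy = df["doy"].to_numpy(float)
    if variant == "1":
        terms = [tensor_cyclic(hour, doy, "te(hour,doy)", k=k)]
    elif variant == "2":
        loc = df["location"].to_numpy()
        levels = sorted(pd.unique(loc))
        if len(levels) != 2:
            raise ValueError(f"variant 2 needs both locations, got {levels}")
        terms = [parametric_factor(loc, "location")]
        for lev in levels:
            terms.append(
                tensor_cyclic(hour, doy, f"te(hour,doy):{lev}", k=k,
                              by=(loc == lev))
            )
    else:
        raise ValueError(f"unknown temporal variant {variant!r}")
    return fit_additive(df[response].to_numpy(float), terms, variant=variant,
                        response=response, keep_design=keep_design)


_SPATIAL_VARS = ("albedo", "bvol", "ndvi", "water")


def fit_spatial(
    data: pd.DataFrame,
    response: str = "min_T",
    variant: str = "3",
    k: int = 10,
    keep_design: bool = False,
) -> ModelFit:
    """Spatial model: seasonal extremes ~ smooths of land cover + season.

    Variants: "3" pooled, "4" location-split smooths and season factor,
    "3A"/"4A" the same without the NDVI term (concurvity sensitivity).
    ``data`` rows are site x location x season with feature columns
    albedo, bvol, ndvi, water at their selected focal windows.
    """
    base = variant.rstrip("A")
    drop_ndvi = variant.endswith("A")
    if base not in ("3", "4"):
        raise ValueError(f"unknown spatial variant {variant!r}")
    df = data.dropna(subset=[response])
    if df["site_id"].nunique() < 10:
        raise ValueError("need >= 10 sites for the spatial models")
    feats = [v for v in _SPATIAL_VARS if not (drop_ndvi and v == "ndvi")]
    terms: list[Term] = []
    if base == "3":
        for v in feats:
            terms.append(smooth_1d(df[v].to_numpy(float), f"s({v})", k=k))
        terms.append(parametric_factor(df["season"], "season"))
    else:
        loc = df["location"].to_numpy()
        levels = sorted(pd.unique(loc))
        if len(levels) != 2:
            raise ValueError(f"variant 4 needs both locations, got {levels}")
        terms.append(parametric_factor(loc, "location"))
        for lev in levels:
            mask = loc == lev
            for v in feats:
                terms.append(
                    smooth_1d(df[v].to_numpy(float), f"s({v}):{lev}", k=k,
                              by=mask)
                )
            terms.append(
                parametric_factor(df["season"], f"season:{lev}", by=mask)
            )
    return fit_additive(df[response].to_numpy(float), terms, variant=variant,
                        response=response, keep_design=keep_design)


# ---------------------------------------------------------------------------
# comparison

@dataclass
class ModelComparison:
    """Nested comparison: AIC change, adj-R2 change, approximate F test."""

    variant_a: str
    variant_b: str
    delta_aic: float        # AIC_b - AIC_a (negative favors b)
    delta_adj_r2: float
    df_num: float
    f_stat: float
    p: float
    method: str = "approximate F test on effective degrees of freedom"


def compare(fit_a: ModelFit, fit_b: ModelFit) -> ModelComparison:
    """Compare a simpler fit (a) with a richer nested fit (b).

    Both fits must be on identical response rows.  The test statistic is
    F = [(RSS_a - RSS_b)/(edf_b - edf_a)] / [RSS_b/(n - edf_b)], referred
    to an F distribution on the effective-dof differences.  With
    penalized smooths this is approximate, not exact.
    """
    if fit_a.n != fit_b.n or fit_a.y_checksum != fit_b.y_checksum:
        raise ValueError("fits are not on identical response rows")
    delta_aic = fit_b.aic - fit_a.aic
    delta_r2 = fit_b.adj_r2 - fit_a.adj_r2
    df_num = fit_b.edf - fit_a.edf
    if df_num < 1e-6:
        return ModelComparison(fit_a.variant, fit_b.variant, delta_aic,
                               delta_r2, max(df_num, 0.0), 0.0, 1.0)
    df_den = max(fit_b.n - fit_b.edf, 1.0)
    f_stat = max((fit_a.rss - fit_b.rss) / df_num, 0.0) / (fit_b.rss / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return ModelComparison(fit_a.variant, fit_b.variant, delta_aic, delta_r2,
                           df_num, f_stat, p)
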