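"""Regression of dependence on specialization: OLS, phylogenetic GEE, bootstrap.

Three estimators are provided.

``fit_ols``
    Ordinary least squares of IPD on a (possibly log-transformed)
    specialization index, linear or with an added quadratic term.  Reported
    ``estimate`` is always the linear-term slope.

``fit_gee``
    Gaussian generalized estimating equations with a fixed working
    correlation taken from the phylogeny.  With an identity link and fixed
    correlation this coincides with generalized least squares,
    ``beta = (X' V^-1 X)^-1 X' V^-1 y`` with ``V = phi * corr`` and the
    scale ``phi`` estimated from the whitened residual sum of squares.
    Slope t-tests use phylogenetic degrees of freedom dfP (see
    :func:`pollindep.phylo.phylogenetic_df`) minus the parameter count, so
    closely related species do not inflate apparent sample size.

``bootstrap_significance``
    Resamples species rows (x, y pairs jointly) with replacement to a
    target sample size, refits the regression per replicate, and reports
    the fraction of replicates whose slope is significant at ``alpha``.
    This addresses whether a non-significant fit in a small community is a
    power artifact: if structure is present, enlarging the sample by
    resampling should make it significant in most replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

_N_PARAMS = {"linear": 2, "quadratic": 3}


@dataclass(frozen=True)
class RegressionSpec:
    """What to regress and how."""

    predictor: str = "L"
    response: str = "IPD"
    transform: str = "none"  # none | log (natural log of the predictor)
    form: str = "linear"  # linear | quadratic
    method: str = "LM"  # LM | GEE

    def __post_init__(self) -> None:
        if self.transform not in ("none", "log"):
            raise ValueError(f"transform must be 'none' or 'log', got {self.transform!r}")
        if self.form not in _N_PARAMS:
            raise ValueError(f"form must be 'linear' or 'quadratic', got {self.form!r}")
        if self.method not in ("LM", "GEE"):
            raise ValueError(f"method must be 'LM' or 'GEE', got {self.method!r}")

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.form]

    @property
    def label(self) -> str:
        name = f"log ({self.predictor})" if self.transform == "log" else self.predictor
        return name if self.form == "linear" else f"{name} + {name}^2"


@dataclass(frozen=True)
class RegressionResult:
    spec: RegressionSpec
    estimate: float
    se: float
    t: float
    p: float
    n: int
    r2: float | None = None  # LM only
    df: float | None = None  # residual df (LM) or dfP (GEE)
    intercept: float = 0.0
    coefficients: tuple = field(default=(), repr=False)


@dataclass(frozen=True)
class BootstrapSummary:
    predictor: str
    n_boot: int
    n_target: int
    alpha: float
    frac_significant: float
    seed: int


def _design(x: np.ndarray, spec: RegressionSpec) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if spec.transform == "log":
        if np.any(x <= 0):
            raise ValueError("log transform requires strictly positive predictor values")
        x = np.log(x)
    cols = [np.ones_like(x), x]
    if spec.form == "quadratic":
        cols.append(x**2)
    return np.column_stack(cols)


def _check_inputs(x: np.ndarray, y: np.ndarray, spec: RegressionSpec) -> None:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if len(x) < spec.n_params + 1:
        raise ValueError(f"need at least {spec.n_params + 1} observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")


def fit_ols(x, y, spec: RegressionSpec = RegressionSpec()) -> RegressionResult:
    """Ordinary least squares fit; estimate/t/p refer to the linear slope."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    _check_inputs(x, y, spec)
    if np.ptp(y) == 0:
        # constant response: the zero slope carries no evidence either way
        return RegressionResult(
            spec=spec, estimate=0.0, se=0.0, t=0.0, p=1.0, n=len(y), r2=0.0,
            df=float(len(y) - spec.n_params), intercept=float(y[0]),
            coefficients=(float(y[0]),) + (0.0,) * (spec.n_params - 1),
        )
    X = _design(x, spec)
    fit = sm.OLS(y, X).fit()
    est, se = float(fit.params[1]), float(fit.bse[1])
    if se == 0 or not np.isfinite(se):
        # degenerate exact fit (e.g. constant response): slope is known
        # without error, report t = 0 so it is never counted significant
        t_stat, p = 0.0, 1.0
    else:
        t_stat = est / se
        p = 2 * stats.t.sf(abs(t_stat), fit.df_resid)
    return RegressionResult(
        spec=spec,
        estimate=est,
        se=se,
        t=t_stat,
        p=float(p),
        n=len(y),
        r2=float(fit.rsquared),
        df=float(fit.df_resid),
        intercept=float(fit.params[0]),
        coefficients=tuple(fit.params),
    )


def fit_gee(
    x,
    y,
    spec: RegressionSpec,
    corr: np.ndarray,
    dfp: float | None = None,
) -> RegressionResult:
    """GEE/GLS fit with a fixed phylogenetic working correlation.

    ``dfp`` is the phylogenetic degrees of freedom used for the slope
    t-test (``df = dfp - n_params``); when omitted it defaults to ``n``,
    which reproduces the OLS test on a star phylogeny.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    _check_inputs(x, y, spec)
    corr = np.asarray(corr, dtype=float)
    n = len(y)
    if corr.shape != (n, n):
        raise ValueError("correlation matrix order must match species order of x, y")
    if np.linalg.matrix_rank(corr) < n:
        raise ValueError(
            "singular correlation matrix: check the tree is not degenerate "
            "(identical tips) or jitter zero-length terminal branches"
        )
    X = _design(x, spec)
    fit = sm.GLS(y, X, sigma=corr).fit()
    est, se = float(fit.params[1]), float(fit.bse[1])
    dfp = float(n) if dfp is None else float(dfp)
    df_test = dfp - spec.n_params
    if df_test <= 0:
        raise ValueError(f"non-positive test degrees of freedom: dfP={dfp}")
    if se == 0 or not np.isfinite(se):
        t_stat, p = 0.0, 1.0
    else:
        t_stat = est / se
        p = 2 * stats.t.sf(abs(t_stat), df_test)
    return RegressionResult(
        spec=spec,
        estimate=est,
        se=se,
        t=t_stat,
        p=float(p),
        n=n,
        r2=None,
        df=dfp,
        intercept=float(fit.params[0]),
        coefficients=tuple(fit.params),
    )


def select_model(candidates: list[RegressionResult]) -> RegressionResult:
    """Retain the candidate with the best fit (highest R²), ties by lowest p."""
    if not candidates:
        raise ValueError("no candidate models")
    def key(r: RegressionResult):
        return (-(r.r2 if r.r2 is not None else -np.inf), r.p)
    return min(candidates, key=key)


def bootstrap_significance(
    x,
    y,
    spec: RegressionSpec,
    n_target: int,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BootstrapSummary:
    """Fraction of bootstrap resamples with a significant slope.

    Species rows are drawn with replacement up to ``n_target``; each
    replicate is refit with the same spec (transform applied before
    resampling, so replicates share the transform decision) and the slope
    tested two-sided at ``alpha``.  Replicates with zero predictor variance
    cannot be fit and are counted as non-significant.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    _check_inputs(x, y, spec)
    if n_target < spec.n_params + 1:
        raise ValueError("n_target too small for the model")
    X_full = _design(x, spec)
    rng = np.random.default_rng(seed)
    df_resid = n_target - spec.n_params
    n_sig = 0
    n_degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), size=n_target)
        Xb, yb = X_full[idx], y[idx]
        if np.ptp(Xb[:, 1]) == 0:
            n_degenerate += 1
            continue
        beta, _, rank, _ = np.linalg.lstsq(Xb, yb, rcond=None)
        if rank < Xb.shape[1]:
            n_degenerate += 1
            continue
        resid = yb - Xb @ beta
        s2 = resid @ resid / df_resid
        if s2 <= 1e-20 * (1.0 + yb @ yb):
            # exact fit: a nonzero slope is significant at any level
            n_sig += abs(beta[1]) > 1e-10 * (1.0 + abs(beta[0]))
            continue
        xtx_inv = np.linalg.inv(Xb.T @ Xb)
        se = np.sqrt(s2 * xtx_inv[1, 1])
        p = 2 * stats.t.sf(abs(beta[1] / se), df_resid)
        if p < alpha:
            n_sig += 1
    if n_degenerate:
        logger.info(
            "%d of %d bootstrap replicates were degenerate (zero predictor "
            "variance) and counted as non-significant", n_degenerate, n_boot,
        )
    return BootstrapSummary(
        predictor=spec.label,
        n_boot=n_boot,
        n_target=n_target,
        alpha=alpha,
        frac_significant=n_sig / n_boot,
        seed=seed,
    )
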