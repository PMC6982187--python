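"""Global and local regression of sqrt-RAI on screened covariates.

Three estimators share one Model/Results surface:

- :class:`OLSModel` — ordinary least squares (statsmodels under the hood);
- :class:`SpatialLag` — maximum-likelihood spatial lag model
  y = rho W y + X beta (+ W X gamma) + eps, the Durbin lagged-X block
  behind a flag defaulting to off;
- :class:`GWR` — geographically weighted regression with a Gaussian
  adaptive kernel, the neighbor count chosen by golden-section search on
  the corrected AIC.

Each model's ``fit()`` returns a results object carrying coefficients,
standard errors, t/p values, R², adjusted R², AICc, log-likelihood and
residuals, plus ``summary()``. Model selection follows the Δ AICc >= 3
decisiveness rule.

Conventions (documented so cross-package comparisons are reproducible):
the Gaussian log-likelihood uses the ML variance RSS/n; AICc counts
k = n_coefficients + 1 (variance) parameters for OLS, plus one more (rho)
for the spatial lag model, with AICc = AIC + 2k(k+1)/(n-k-1); the GWR AICc
is 2n ln(sigma_hat) + n ln(2 pi) + n (n + tr S) / (n - 2 - tr S).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

from .spatial import SpatialWeights

__all__ = [
    "Design", "ModelFit", "SARFit", "GWRFit",
    "OLSModel", "SpatialLag", "GWR",
    "pearson_screen", "vif", "fit_ols", "fit_sar", "fit_gwr",
    "compare_models", "standardize_coefficients",
]

_STARS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


def _stars(p: float) -> str:
    for thr, s in _STARS:
        if p < thr:
            return s
    return ""


# ---------------------------------------------------------------------------
# Design


@dataclass
class Design:
    """An outcome vector and a covariate matrix with an intercept column."""

    ids: list
    y: np.ndarray
    X: np.ndarray
    names: list[str]
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if len(self.y) != n or len(self.names) != p or len(self.ids) != n:
            raise ValueError("design dimensions disagree")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise ValueError("design contains missing values")
        if n <= p + 2:
            raise ValueError(f"need n > p + 2 (n={n}, p={p})")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, covariates: list[str],
                       id_col: str | None = None,
                       coord_cols: tuple[str, str] | None = ("x", "y")) -> "Design":
        ids = list(df[id_col]) if id_col else list(df.index)
        y = df[outcome].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float)
                                                  for c in covariates])
        coords = None
        if coord_cols and all(c in df.columns for c in coord_cols):
            coords = df[list(coord_cols)].to_numpy(dtype=float)
        return cls(ids=ids, y=y, X=X, names=["intercept"] + list(covariates), coords=coords)


# ---------------------------------------------------------------------------
# Results containers


@dataclass
class ModelFit:
    method: str
    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    std_params: np.ndarray
    r2: float
    adj_r2: float
    aicc: float
    loglik: float
    residuals: np.ndarray
    fitted: np.ndarray
    nobs: int
    k_params: int

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params, "std_estimate": self.std_params,
            "se": self.bse, "t": self.tvalues, "p": self.pvalues,
            "sig": [_stars(p) for p in self.pvalues],
        }, index=self.names)

    def summary(self) -> str:
        lines = [f"{self.method.upper()} fit  (n = {self.nobs}, k = {self.k_params})",
                 self.coef_table().to_string(float_format=lambda v: f"{v:.4f}"),
                 f"R2 = {self.r2:.3f}   adj. R2 = {self.adj_r2:.3f}   "
                 f"AICc = {self.aicc:.3f}   logL = {self.loglik:.3f}"]
        return "\n".join(lines)


@dataclass
class SARFit(ModelFit):
    rho: float = 0.0
    rho_se: float = float("nan")
    rho_interval: tuple[float, float] = (float("nan"), float("nan"))
    gamma_names: list[str] = field(default_factory=list)

    def summary(self) -> str:
        base = super().summary()
        return base + f"\nrho = {self.rho:.4f} (SE {self.rho_se:.4f}), stable interval " \
                      f"({self.rho_interval[0]:.3f}, {self.rho_interval[1]:.3f})"


@dataclass
class GWRFit(ModelFit):
    local_params: np.ndarray = None
    bandwidth: int = 0
    trace_S: float = float("nan")
    coef_min: np.ndarray = None
    coef_max: np.ndarray = None

    def summary(self) -> str:
        tab = pd.DataFrame({"min": self.coef_min, "mean": self.local_params.mean(axis=0),
                            "max": self.coef_max}, index=self.names)
        return (f"GWR fit  (n = {self.nobs}, adaptive bandwidth = {self.bandwidth} neighbors, "
                f"tr(S) = {self.trace_S:.2f})\n"
                + tab.to_string(float_format=lambda v: f"{v:.4f}")
                + f"\nR2 = {self.r2:.3f}   adj. R2 = {self.adj_r2:.3f}   AICc = {self.aicc:.3f}")


# ---------------------------------------------------------------------------
# Screening


def pearson_screen(df: pd.DataFrame, outcome: str, covariates: list[str],
                   alpha: float = 0.05) -> list[str]:
    """Retain covariates whose Pearson correlation with the outcome is
    two-sided significant at ``alpha``. Zero-variance covariates are
    excluded with a warning; tiny samples are flagged for low power."""
    y = df[outcome].to_numpy(dtype=float)
    n = len(y)
    if n < 4:
        warnings.warn(f"n={n}: Pearson screening has essentially no power", stacklevel=2)
    retained = []
    for name in covariates:
        x = df[name].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.allclose(x, x[0], rtol=1e-12, atol=0):
            warnings.warn(f"covariate {name!r} has (near-)zero variance; excluded",
                          stacklevel=2)
            continue
        r, p = stats.pearsonr(x, y)
        if np.isfinite(p) and p < alpha:
            retained.append(name)
    return retained


def vif(df: pd.DataFrame, covariates: list[str]) -> dict[str, float]:
    """Variance inflation factors: VIF_j = 1/(1 - R²_j) of covariate j on
    the rest (with intercept). Exact collinearity reports +inf."""
    if len(covariates) < 2:
        raise ValueError("VIF needs at least 2 covariates")
    X = df[list(covariates)].to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(covariates):
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# Shared helpers


def _gaussian_loglik(rss: float, n: int) -> float:
    sigma2 = rss / n
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def _aicc(loglik: float, k: int, n: int) -> float:
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return float("inf")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def standardize_coefficients(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                             names: list[str]) -> np.ndarray:
    """beta_std_j = beta_j * sd(x_j) / sd(y); the intercept gets NaN."""
    sy = y.std(ddof=1)
    if sy == 0:
        raise ValueError("outcome has zero variance")
    out = np.empty_like(np.asarray(params, dtype=float))
    for j, name in enumerate(names):
        sx = X[:, j].std(ddof=1)
        out[j] = np.nan if sx == 0 else params[j] * sx / sy
    return out


# ---------------------------------------------------------------------------
# OLS


class OLSModel:
    """Ordinary least squares on a :class:`Design` (the global baseline)."""

    def __init__(self, design: Design):
        self.design = design

    def fit(self) -> ModelFit:
        d = self.design
        n, p = d.X.shape
        rank = np.linalg.matrix_rank(d.X)
        if rank < p:
            # name the collinear columns for the error message
            bad = [d.names[j] for j in range(p)
                   if np.linalg.matrix_rank(np.delete(d.X, j, axis=1)) == rank]
            raise ValueError(f"singular design: collinear columns {bad}")
        res = sm.OLS(d.y, d.X).fit()
        rss = float(res.ssr)
        ll = _gaussian_loglik(rss, n)
        k = p + 1  # + variance
        return ModelFit(
            method="ols", names=list(d.names),
            params=np.asarray(res.params), bse=np.asarray(res.bse),
            tvalues=np.asarray(res.tvalues), pvalues=np.asarray(res.pvalues),
            std_params=standardize_coefficients(res.params, d.X, d.y, d.names),
            r2=float(res.rsquared), adj_r2=float(res.rsquared_adj),
            aicc=_aicc(ll, k, n), loglik=ll,
            residuals=np.asarray(res.resid), fitted=np.asarray(res.fittedvalues),
            nobs=n, k_params=k)


def fit_ols(design: Design) -> ModelFit:
    return OLSModel(design).fit()


# ---------------------------------------------------------------------------
# Spatial lag (SAR) by maximum likelihood


class SpatialLag:
    """ML spatial lag model y = rho W y + X beta (+ W X gamma) + eps.

    The log-likelihood's Jacobian term ln|I - rho W| is evaluated through
    the eigenvalues of W (real, because the row-standardized matrix is
    similar to a symmetric one), and rho is found by bounded scalar
    minimization of the concentrated negative log-likelihood over the
    stable interval (1/lambda_min, 1/lambda_max).
    """

    def __init__(self, design: Design, weights: SpatialWeights, lagged_X: bool = False):
        self.design = design
        if weights.n != len(design.y):
            raise ValueError("weights not conformable with design")
        self.weights = weights.row_standardized()
        self.lagged_X = lagged_X

    @staticmethod
    def _eigenvalues(W: np.ndarray) -> np.ndarray:
        rs = W.sum(axis=1)
        if np.all(rs > 0):
            # W = D^-1 A with A symmetric: similar to D^-1/2 A D^-1/2
            A = W * rs[:, None]
            if np.allclose(A, A.T, atol=1e-10):
                s = np.sqrt(rs)
                return np.linalg.eigvalsh(A / np.outer(s, s))
        lam = np.linalg.eigvals(W)
        return np.sort(lam.real)

    def fit(self, rho: float | None = None) -> SARFit:
        """ML fit; passing ``rho`` fixes the lag parameter instead of
        profiling it (rho=0 reduces the estimator to OLS exactly)."""
        d = self.design
        n, p0 = d.X.shape
        W = self.weights.W
        X = d.X
        names = list(d.names)
        gamma_names: list[str] = []
        if self.lagged_X:
            lagged = W @ X[:, 1:]  # no lag of the intercept
            X = np.column_stack([X, lagged])
            gamma_names = [f"W.{nm}" for nm in d.names[1:]]
            names = names + gamma_names
        p = X.shape[1]
        if n < p + 3:
            raise ValueError("too few observations for the SAR parameter count")
        y = d.y
        Wy = W @ y
        lam = self._eigenvalues(W)
        lo = 1.0 / lam.min() if lam.min() < 0 else -0.999
        hi = 1.0 / lam.max() if lam.max() > 0 else 0.999
        eps = 1e-6
        XtX = X.T @ X
        b0 = np.linalg.solve(XtX, X.T @ y)
        b1 = np.linalg.solve(XtX, X.T @ Wy)
        e0 = y - X @ b0
        e1 = Wy - X @ b1

        def negll(rho: float) -> float:
            e = e0 - rho * e1
            rss = float(e @ e)
            logdet = float(np.log(np.abs(1.0 - rho * lam)).sum())
            return 0.5 * n * math.log(rss / n) - logdet

        if rho is None:
            res = optimize.minimize_scalar(negll, bounds=(lo + eps, hi - eps),
                                           method="bounded", options={"xatol": 1e-8})
            rho = float(res.x)
            if not lo + 10 * eps < rho < hi - 10 * eps:
                warnings.warn(f"rho estimate {rho:.4f} pinned near the stable-interval "
                              "boundary", stacklevel=2)
        elif not lo < rho < hi:
            raise ValueError(f"fixed rho={rho} outside the stable interval ({lo}, {hi})")
        beta = b0 - rho * b1
        e = e0 - rho * e1
        rss = float(e @ e)
        sigma2 = rss / n
        logdet = float(np.log(np.abs(1.0 - rho * lam)).sum())
        ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet

        se_beta, se_rho = self._asymptotic_se(X, beta, rho, sigma2, W)
        tvals = beta / se_beta
        pvals = 2.0 * stats.norm.sf(np.abs(tvals))
        fitted = np.linalg.solve(np.eye(n) - rho * W, X @ beta)
        r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2)  # pseudo-R2
        k = p + 2  # + rho + variance
        fit = SARFit(
            method="sar", names=names, params=beta, bse=se_beta, tvalues=tvals,
            pvalues=pvals,
            std_params=standardize_coefficients(beta, X, y, names),
            r2=r2, adj_r2=float("nan"), aicc=_aicc(ll, k, n), loglik=ll,
            residuals=e, fitted=fitted, nobs=n, k_params=k,
            rho=rho, rho_se=se_rho, rho_interval=(lo, hi), gamma_names=gamma_names)
        return fit

    @staticmethod
    def _asymptotic_se(X, beta, rho, sigma2, W) -> tuple[np.ndarray, float]:
        """Classical information-matrix standard errors of (beta, rho)."""
        n, p = X.shape
        A_inv = np.linalg.inv(np.eye(n) - rho * W)
        WA = W @ A_inv
        WAXb = WA @ (X @ beta)
        I = np.zeros((p + 2, p + 2))
        I[:p, :p] = X.T @ X / sigma2
        I[:p, p] = X.T @ WAXb / sigma2
        I[p, :p] = I[:p, p]
        I[p, p] = np.trace(WA @ WA) + np.trace(WA.T @ WA) + float(WAXb @ WAXb) / sigma2
        I[p, p + 1] = np.trace(WA) / sigma2
        I[p + 1, p] = I[p, p + 1]
        I[p + 1, p + 1] = n / (2.0 * sigma2 ** 2)
        cov = np.linalg.inv(I)
        return np.sqrt(np.diag(cov)[:p]), float(math.sqrt(max(cov[p, p], 0.0)))


def fit_sar(design: Design, weights: SpatialWeights, lagged_X: bool = False,
            rho: float | None = None) -> SARFit:
    return SpatialLag(design, weights, lagged_X=lagged_X).fit(rho=rho)


# ---------------------------------------------------------------------------
# GWR


class GWR:
    """Geographically weighted regression with a Gaussian adaptive kernel.

    The kernel scale at location i is the distance to its b-th nearest
    neighbor (self included), so dense neighborhoods get tight kernels and
    sparse ones wide kernels; b is chosen by golden-section search over the
    integer range [p+2, n] minimizing the GWR AICc, ties broken toward the
    larger (smoother) bandwidth.
    """

    def __init__(self, design: Design, coords: np.ndarray | None = None):
        self.design = design
        coords = coords if coords is not None else design.coords
        if coords is None:
            raise ValueError("GWR requires coordinates")
        self.coords = np.asarray(coords, dtype=float)
        if len(self.coords) != len(design.y):
            raise ValueError("coords not conformable with design")
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        self._dist = np.sqrt((diff ** 2).sum(axis=2))
        self._dist_sorted = np.sort(self._dist, axis=1)

    def _local_fit(self, bandwidth: int, kernel_scale: float = 1.0):
        d = self.design
        n, p = d.X.shape
        h = self._dist_sorted[:, bandwidth - 1].copy() * kernel_scale
        h[h <= 0] = max(self._dist_sorted.max() * 1e-6, 1e-9)
        local = np.empty((n, p))
        s_diag = np.empty(n)
        fitted = np.empty(n)
        X, y = d.X, d.y
        for i in range(n):
            w = np.exp(-0.5 * (self._dist[i] / h[i]) ** 2)
            Xw = X * w[:, None]
            XtWX = X.T @ Xw
            try:
                B = np.linalg.solve(XtWX, Xw.T)  # p x n
            except np.linalg.LinAlgError:
                return None
            bi = B @ y
            local[i] = bi
            fitted[i] = X[i] @ bi
            s_diag[i] = X[i] @ B[:, i]
        return local, fitted, s_diag

    def _aicc_for(self, bandwidth: int, kernel_scale: float = 1.0) -> tuple[float, tuple | None]:
        out = self._local_fit(bandwidth, kernel_scale)
        if out is None:
            return float("inf"), None
        local, fitted, s_diag = out
        n = len(fitted)
        tr_s = float(s_diag.sum())
        if n - 2.0 - tr_s <= 0:
            return float("inf"), None
        rss = float(((self.design.y - fitted) ** 2).sum())
        sigma = math.sqrt(rss / n)
        aicc = 2.0 * n * math.log(sigma) + n * math.log(2.0 * math.pi) \
            + n * (n + tr_s) / (n - 2.0 - tr_s)
        return aicc, (local, fitted, s_diag)

    def select_bandwidth(self) -> int:
        n, p = self.design.X.shape
        lo, hi = p + 2, n
        cache: dict[int, float] = {}

        def f(b: int) -> float:
            if b not in cache:
                cache[b] = self._aicc_for(b)[0]
            return cache[b]

        phi = (math.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c = int(round(b - phi * (b - a)))
        d_ = int(round(a + phi * (b - a)))
        while b - a > 2:
            if f(c) < f(d_):
                b, d_ = d_, c
                c = int(round(b - phi * (b - a)))
            else:
                a, c = c, d_
                d_ = int(round(a + phi * (b - a)))
            if c >= d_:
                break
        # final local scan; ties toward the larger bandwidth
        lo_s, hi_s = max(lo, a - 2), min(hi, b + 2)
        best_b, best_v = lo_s, float("inf")
        for bb in range(lo_s, hi_s + 1):
            v = f(bb)
            if v < best_v - 1e-12 or (abs(v - best_v) <= 1e-12 and bb > best_b):
                best_b, best_v = bb, v
        return best_b

    def fit(self, bandwidth: int | None = None, kernel_scale: float = 1.0) -> GWRFit:
        """Fit at a given adaptive bandwidth (neighbor count) or, by
        default, at the AICc-optimal one. ``kernel_scale`` inflates every
        local kernel width by a constant factor; a very large scale makes
        all weights ~1, the global (OLS) limit."""
        d = self.design
        n, p = d.X.shape
        bw = bandwidth if bandwidth is not None else self.select_bandwidth()
        aicc, payload = self._aicc_for(bw, kernel_scale)
        if payload is None:
            raise ValueError(f"GWR fit failed at bandwidth {bw}: singular local design; "
                             "increase the minimum bandwidth")
        local, fitted, s_diag = payload
        resid = d.y - fitted
        rss = float(resid @ resid)
        tss = float(((d.y - d.y.mean()) ** 2).sum())
        tr_s = float(s_diag.sum())
        r2 = 1.0 - rss / tss
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1.0) / (n - tr_s)
        ll = _gaussian_loglik(rss, n)
        mean_params = local.mean(axis=0)
        return GWRFit(
            method="gwr", names=list(d.names), params=mean_params,
            bse=np.full(p, np.nan), tvalues=np.full(p, np.nan),
            pvalues=np.full(p, np.nan),
            std_params=standardize_coefficients(mean_params, d.X, d.y, d.names),
            r2=r2, adj_r2=adj_r2, aicc=aicc, loglik=ll,
            residuals=resid, fitted=fitted, nobs=n, k_params=int(round(tr_s)) + 1,
            local_params=local, bandwidth=bw, trace_S=tr_s,
            coef_min=local.min(axis=0), coef_max=local.max(axis=0))


def fit_gwr(design: Design, coords: np.ndarray | None = None,
            bandwidth: int | None = None) -> GWRFit:
    return GWR(design, coords).fit(bandwidth=bandwidth)


# ---------------------------------------------------------------------------
# Model comparison


def compare_models(fits: dict[str, ModelFit]) -> dict:
    """Rank fits by AICc; the best is decisive only if >= 3 below all others.

    Also reports percent change in R² and AICc of each local model against
    the OLS baseline (when present): 100 * (local - ols) / |ols|.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    ns = {name: f.nobs for name, f in fits.items()}
    if len(set(ns.values())) != 1:
        raise ValueError(f"fits on different sample sizes are not comparable: {ns}")
    aiccs = {name: f.aicc for name, f in fits.items()}
    best = min(aiccs, key=aiccs.get)
    margin = min(v - aiccs[best] for k, v in aiccs.items() if k != best)
    result = {
        "ranking": sorted(aiccs, key=aiccs.get),
        "aicc": aiccs,
        "best": best,
        "decisive": bool(margin >= 3.0),
        "margin": float(margin),
    }
    if "ols" in fits:
        base = fits["ols"]
        changes = {}
        for name, f in fits.items():
            if name == "ols":
                continue
            changes[name] = {
                "r2_pct_change": 100.0 * (f.r2 - base.r2) / abs(base.r2) if base.r2 else float("nan"),
                "aicc_pct_change": 100.0 * (f.aicc - base.aicc) / abs(base.aicc),
            }
        result["vs_ols"] = changes
    return result
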