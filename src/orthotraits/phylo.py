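"""Phylogenetic comparative statistics for a continuous trait.

All methods share one engine: under Brownian motion (BM) with rate sigma^2
and root state z0, tip values are multivariate normal with mean ``z0 * 1``
and covariance ``sigma^2 * C``, where C is the shared-path matrix of the
tree (see :mod:`orthotraits.tree`).  Everything below is a transformation of
C plus generalized least squares:

* **Blomberg's K** — ratio of the observed mean-squared-error partition to
  its BM expectation; K = 1 under BM, K < 1 when relatives resemble each
  other less than BM predicts.  Significance by permuting tip values.
* **Pagel's lambda** — multiplies the off-diagonal of C by lambda in [0, 1]
  and maximises the BM likelihood over lambda; likelihood-ratio test against
  lambda = 0 (no signal).
* **BM1 / OU1 model fits** — maximum likelihood with analytic profiling of
  the mean and rate; the single-optimum Ornstein–Uhlenbeck model adds a pull
  strength alpha towards the optimum theta (root placed at the optimum,
  non-stationary variance).  Models compared by AIC.
* **PGLS** — generalized least squares regression with error covariance
  C(lambda), lambda estimated by ML.
* **Phylogenetic ANOVA** — the ordinary one-way F statistic referred to a
  null distribution of F values obtained by simulating BM on the tree.

A plain two-sample t-test (pooled or Welch) and the Wilcoxon rank-sum test
are included as the non-phylogenetic baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .errors import ValidationError
from .tree import Phylogeny

__all__ = [
    "ModelFit",
    "PGLSResult",
    "AnovaResult",
    "TTestResult",
    "BlombergResult",
    "PagelResult",
    "PhyloSigResult",
    "bm_loglik",
    "fit_bm",
    "fit_ou",
    "ou_loglik",
    "blomberg_k",
    "pagel_lambda",
    "phylosig",
    "pgls",
    "phylo_anova",
    "two_sample_test",
]

# ----------------------------------------------------------------- plumbing
def _as_vector(tree: Phylogeny, x: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """Trait values ordered like ``tree.tip_labels``."""
    if isinstance(x, Mapping):
        missing = [t for t in tree.tip_labels if t not in x]
        extra = [t for t in x if t not in tree.tip_labels]
        if missing or extra:
            raise ValidationError(
                f"trait tips do not match tree tips (missing {missing[:3]}, extra {extra[:3]})"
            )
        return np.array([float(x[t]) for t in tree.tip_labels])
    arr = np.asarray(x, dtype=float)
    if arr.shape != (tree.n_tips,):
        raise ValidationError(
            f"trait vector length {arr.shape} != number of tips {tree.n_tips}"
        )
    return arr


def _safe_vcv(tree: Phylogeny) -> np.ndarray:
    """VCV matrix; zero-length terminal branches are nudged to keep it PD."""
    lengths = tree.length
    tips = tree.tip_indices
    zero_tips = tips[lengths[tips] == 0.0]
    if len(zero_tips):
        warnings.warn(
            f"{len(zero_tips)} zero-length terminal branches nudged to keep "
            "the phylogenetic covariance invertible",
            stacklevel=2,
        )
        new = lengths.copy()
        height = tree.depths()[tips].max()
        new[zero_tips] = 1e-9 * (height if height > 0 else 1.0)
        tree = tree.with_lengths(new)
    C, _ = tree.vcv()
    return C


def _chol(C: np.ndarray, what: str = "phylogenetic covariance"):
    try:
        return cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        raise ValidationError(
            f"{what} is singular (identical tips or zero-length branches?)"
        ) from None


def _logdet(chol_factor) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(chol_factor[0]))))


def _gls_profile(C: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """GLS mean, ML variance scale and profiled log-likelihood under N(m*1, s2*C)."""
    n = len(x)
    if np.ptp(x) == 0:
        raise ValidationError("trait has no variance on this tree (sigma^2 = 0)")
    cf = _chol(C)
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    Cix = cho_solve(cf, x)
    mean = float(ones @ Cix) / float(ones @ Ci1)
    r = x - mean
    quad = float(r @ cho_solve(cf, r))
    sigma2 = quad / n
    if sigma2 <= 0 or not math.isfinite(sigma2):
        raise ValidationError("trait has no variance on this tree (sigma^2 = 0)")
    loglik = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2) + _logdet(cf) + n)
    return mean, sigma2, loglik


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = C * lam
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


# -------------------------------------------------------------- result types
@dataclass
class ModelFit:
    """Maximum-likelihood fit of a trait-evolution model."""

    model: str  # "BM1" or "OU1"
    params: dict[str, float]
    loglik: float
    k: int
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik


@dataclass
class PGLSResult:
    params: pd.DataFrame  # estimate, se, t, p per coefficient
    df_resid: int
    r_squared: float
    model_p: float
    lam: float
    loglik: float
    n: int


@dataclass
class AnovaResult:
    F: float
    p_sim: float
    n_sim: int


@dataclass
class TTestResult:
    statistic: float
    df: float
    p: float
    variant: str


class BlombergResult(NamedTuple):
    K: float
    p: float
    n_perm: int


class PagelResult(NamedTuple):
    lam: float
    loglik: float
    loglik0: float
    p: float


@dataclass
class PhyloSigResult:
    K: float
    p_K: float
    lam: float
    loglik_lam: float
    loglik0: float
    p_lambda: float


# ----------------------------------------------------------- Brownian motion
def bm_loglik(
    tree: Phylogeny, x: Mapping[str, float] | Sequence[float], sigma2: float, z0: float
) -> float:
    """Exact BM log-likelihood at given parameters."""
    if sigma2 <= 0:
        raise ValidationError("sigma2 must be positive")
    xv = _as_vector(tree, x)
    C = _safe_vcv(tree)
    n = len(xv)
    cf = _chol(C)
    r = xv - z0
    quad = float(r @ cho_solve(cf, r))
    return -0.5 * (
        n * math.log(2 * math.pi) + n * math.log(sigma2) + _logdet(cf) + quad / sigma2
    )


def fit_bm(tree: Phylogeny, x: Mapping[str, float] | Sequence[float]) -> ModelFit:
    """ML fit of single-rate Brownian motion (parameters z0 and sigma^2)."""
    xv = _as_vector(tree, x)
    C = _safe_vcv(tree)
    z0, sigma2, loglik = _gls_profile(C, xv)
    return ModelFit("BM1", {"z0": z0, "sigma2": sigma2}, loglik, k=2)


# -------------------------------------------------------- Ornstein–Uhlenbeck
def _ou_cov(C: np.ndarray, T: float, alpha: float, stationary_root: bool) -> np.ndarray:
    """OU1 covariance (up to sigma^2) with the root at the optimum theta."""
    if stationary_root:
        return np.exp(-2.0 * alpha * (T - C)) / (2.0 * alpha)
    return np.exp(-2.0 * alpha * (T - C)) * (1.0 - np.exp(-2.0 * alpha * C)) / (2.0 * alpha)


def ou_loglik(
    tree: Phylogeny,
    x: Mapping[str, float] | Sequence[float],
    alpha: float,
    stationary_root: bool = False,
) -> float:
    """Profiled OU1 log-likelihood at a fixed alpha (theta and sigma^2 at ML)."""
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    if not tree.is_ultrametric():
        raise ValidationError("OU1 fitting requires an ultrametric tree")
    xv = _as_vector(tree, x)
    C = _safe_vcv(tree)
    T = float(np.diag(C).max())
    V = _ou_cov(C, T, alpha, stationary_root)
    _, _, loglik = _gls_profile(V, xv)
    return loglik


def fit_ou(
    tree: Phylogeny,
    x: Mapping[str, float] | Sequence[float],
    stationary_root: bool = False,
    alpha_bounds: tuple[float, float] | None = None,
) -> ModelFit:
    """ML fit of the single-optimum OU model (theta, sigma^2, alpha).

    theta is profiled as the GLS mean and sigma^2 analytically; alpha is
    optimised on the log scale by bounded 1-D search.  The tree must be
    ultrametric (the covariance used assumes a common tip age).
    """
    if not tree.is_ultrametric():
        raise ValidationError("OU1 fitting requires an ultrametric tree")
    xv = _as_vector(tree, x)
    C = _safe_vcv(tree)
    T = float(np.diag(C).max())
    if alpha_bounds is None:
        alpha_bounds = (1e-8 / T, 100.0 / T)
    lo, hi = math.log(alpha_bounds[0]), math.log(alpha_bounds[1])

    def neg_loglik(u: float) -> float:
        V = _ou_cov(C, T, math.exp(u), stationary_root)
        try:
            _, _, ll = _gls_profile(V, xv)
        except ValidationError:
            return np.inf
        return -ll

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    # bounded Brent can miss boundary optima; compare against both ends
    candidates = [(res.x, res.fun), (lo, neg_loglik(lo)), (hi, neg_loglik(hi))]
    u_hat, neg_ll = min(candidates, key=lambda c: c[1])
    alpha = math.exp(u_hat)
    V = _ou_cov(C, T, alpha, stationary_root)
    theta, sigma2, loglik = _gls_profile(V, xv)
    flags = {"alpha_at_upper_bound": alpha >= 0.99 * alpha_bounds[1]}
    if flags["alpha_at_upper_bound"]:
        warnings.warn("OU pull strength alpha hit its upper bound", stacklevel=2)
    return ModelFit(
        "OU1", {"theta": theta, "sigma2": sigma2, "alpha": alpha}, loglik, k=3, flags=flags
    )


# --------------------------------------------------------- phylogenetic signal
def blomberg_k(
    tree: Phylogeny,
    x: Mapping[str, float] | Sequence[float],
    n_perm: int = 999,
    seed: int | None = None,
) -> BlombergResult:
    """Blomberg's K with a tip-permutation significance test.

    K compares the observed ratio of the raw to the phylogenetically
    corrected mean squared error with its expectation under BM; the p-value
    is the fraction of tip permutations whose corrected MSE is at most the
    observed one (small MSE = strong signal), with the +1 correction.
    """
    xv = _as_vector(tree, x)
    n = len(xv)
    if n < 4:
        raise ValidationError("Blomberg's K needs at least 4 tips")
    C = _safe_vcv(tree)
    cf = _chol(C)
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    denom_1C1 = float(ones @ Ci1)
    Cinv = cho_solve(cf, np.eye(n))

    def mse_pair(v: np.ndarray) -> tuple[float, float]:
        a_hat = float(Ci1 @ v) / denom_1C1
        r = v - a_hat
        return float(r @ r) / (n - 1), float(r @ Cinv @ r) / (n - 1)

    mse0, mse = mse_pair(xv)
    if mse <= 0:
        raise ValidationError("trait has no variance")
    expected = (float(np.trace(C)) - n / denom_1C1) / (n - 1)
    K = (mse0 / mse) / expected
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(xv)
        _, mse_p = mse_pair(perm)
        if mse_p <= mse:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return BlombergResult(K, p, n_perm)


def pagel_lambda(
    tree: Phylogeny,
    x: Mapping[str, float] | Sequence[float],
    lam_max: float = 1.0,
) -> PagelResult:
    """ML estimate of Pagel's lambda with a likelihood-ratio test vs lambda=0."""
    if not tree.is_ultrametric():
        raise ValidationError("Pagel's lambda requires an ultrametric tree")
    xv = _as_vector(tree, x)
    if len(xv) < 4:
        raise ValidationError("Pagel's lambda needs at least 4 tips")
    C = _safe_vcv(tree)

    def neg_loglik(lam: float) -> float:
        try:
            return -_gls_profile(_lambda_transform(C, lam), xv)[2]
        except ValidationError:
            return np.inf

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(0.0, lam_max), method="bounded", options={"xatol": 1e-8}
    )
    candidates = [(res.x, res.fun), (0.0, neg_loglik(0.0)), (lam_max, neg_loglik(lam_max))]
    lam_hat, neg_ll = min(candidates, key=lambda c: c[1])
    loglik = -neg_ll
    loglik0 = -neg_loglik(0.0)
    lr = max(0.0, 2.0 * (loglik - loglik0))
    p = float(stats.chi2.sf(lr, df=1))
    return PagelResult(float(lam_hat), loglik, loglik0, p)


def phylosig(
    tree: Phylogeny,
    x: Mapping[str, float] | Sequence[float],
    n_perm: int = 999,
    seed: int | None = None,
) -> PhyloSigResult:
    """Both phylogenetic-signal statistics in one call."""
    bk = blomberg_k(tree, x, n_perm=n_perm, seed=seed)
    pl = pagel_lambda(tree, x)
    return PhyloSigResult(bk.K, bk.p, pl.lam, pl.loglik, pl.loglik0, pl.p)


# ----------------------------------------------------------------------- PGLS
def _design_matrix(
    tree: Phylogeny, predictors: Mapping[str, object] | pd.DataFrame
) -> tuple[np.ndarray, list[str]]:
    """Intercept + predictors ordered like the tree tips; categorical columns
    are dummy-coded against their alphabetically first level."""
    if isinstance(predictors, pd.DataFrame):
        frame = predictors
    else:
        frame = pd.DataFrame({"x": pd.Series(dict(predictors))})
    missing = [t for t in tree.tip_labels if t not in frame.index]
    if missing:
        raise ValidationError(f"predictors missing for tips {missing[:3]}")
    frame = frame.loc[tree.tip_labels]
    cols: list[np.ndarray] = [np.ones(tree.n_tips)]
    names = ["(Intercept)"]
    for col in frame.columns:
        series = frame[col]
        if pd.api.types.is_numeric_dtype(series):
            cols.append(series.to_numpy(dtype=float))
            names.append(str(col))
        else:
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:
                cols.append((series.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{col}[{level}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank-deficient (constant predictor?)")
    return X, names


def _gls_fit(V: np.ndarray, X: np.ndarray, y: np.ndarray):
    """GLS estimates plus the quantities needed for inference."""
    cf = _chol(V)
    Vi_X = cho_solve(cf, X)
    Vi_y = cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    rss = float(resid @ cho_solve(cf, resid))
    return cf, beta, XtViX, rss


def pgls(
    tree: Phylogeny,
    trait: Mapping[str, float] | Sequence[float],
    predictors: Mapping[str, object] | pd.DataFrame,
    lam: float | str = "ml",
) -> PGLSResult:
    """Phylogenetic generalized least squares with lambda-scaled covariance.

    ``lam="ml"`` estimates lambda jointly by maximum likelihood; a numeric
    value fixes it.  R^2 is the GLS residual version relative to a GLS
    intercept-only fit under the same covariance; the model p-value is the
    corresponding F test.
    """
    y = _as_vector(tree, trait)
    X, names = _design_matrix(tree, predictors)
    n, p = X.shape
    if n <= p:
        raise ValidationError("more coefficients than observations")
    C = _safe_vcv(tree)

    def neg_profile(lam_val: float) -> float:
        V = _lambda_transform(C, lam_val)
        try:
            cf, beta, _, rss = _gls_fit(V, X, y)
        except ValidationError:
            return np.inf
        sigma2 = rss / n
        if sigma2 <= 0:
            return np.inf
        return 0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2) + _logdet(cf) + n)

    if lam == "ml":
        res = optimize.minimize_scalar(
            neg_profile, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-8}
        )
        candidates = [(res.x, res.fun), (0.0, neg_profile(0.0)), (1.0, neg_profile(1.0))]
        lam_hat = float(min(candidates, key=lambda c: c[1])[0])
    else:
        lam_hat = float(lam)
        if not (0.0 <= lam_hat <= 1.0):
            raise ValidationError("lambda must be in [0, 1]")
    V = _lambda_transform(C, lam_hat)
    cf, beta, XtViX, rss = _gls_fit(V, X, y)
    loglik = -neg_profile(lam_hat)
    df_resid = n - p
    sigma2_hat = rss / df_resid
    cov_beta = sigma2_hat * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df_resid)
    # intercept-only GLS fit under the same covariance for R^2 and the F test
    ones = np.ones((n, 1))
    _, _, _, tss = _gls_fit(V, ones, y)
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    if p > 1 and tss > rss:
        F = ((tss - rss) / (p - 1)) / (rss / df_resid)
        model_p = float(stats.f.sf(F, p - 1, df_resid))
    else:
        model_p = 1.0
    params = pd.DataFrame(
        {"estimate": beta, "se": se, "t": tvals, "p": pvals}, index=names
    )
    return PGLSResult(params, df_resid, float(r2), model_p, lam_hat, loglik, n)


# ------------------------------------------------------- phylogenetic ANOVA
def _anova_f(x: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA F statistic (vectorised for the simulation loop)."""
    n = len(x)
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_within = 0.0
    for g in range(n_groups):
        vals = x[codes == g]
        ss_within += float(((vals - vals.mean()) ** 2).sum())
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within <= 0:
        raise ValidationError("zero within-group variance; ANOVA is degenerate")
    return (ss_between / df_b) / (ss_within / df_w)


def phylo_anova(
    tree: Phylogeny,
    x: Mapping[str, float] | Sequence[float],
    groups: Mapping[str, str],
    n_sim: int = 1000,
    seed: int | None = None,
) -> AnovaResult:
    """Simulation-based phylogenetic ANOVA.

    The observed one-way F statistic is referred to the distribution of F
    values computed on traits simulated under BM on the tree (rate and root
    state estimated from the data), so the test accounts for the
    non-independence of related tips.
    """
    xv = _as_vector(tree, x)
    labels = [groups.get(t) for t in tree.tip_labels]
    if any(l is None for l in labels):
        missing = [t for t, l in zip(tree.tip_labels, labels) if l is None]
        raise ValidationError(f"group missing for tips {missing[:3]}")
    level_names = sorted(set(labels))
    if len(level_names) < 2:
        raise ValidationError("need at least two groups")
    codes = np.array([level_names.index(l) for l in labels])
    for g, name in enumerate(level_names):
        if (codes == g).sum() < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 tips")
    F_obs = _anova_f(xv, codes, len(level_names))
    fit = fit_bm(tree, xv)
    C = _safe_vcv(tree)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(xv)) * np.diag(C).max())
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(fit.params["sigma2"])
    count = 0
    for _ in range(n_sim):
        sim = fit.params["z0"] + sigma * (L @ rng.standard_normal(len(xv)))
        if _anova_f(sim, codes, len(level_names)) >= F_obs:
            count += 1
    p_sim = (1 + count) / (1 + n_sim)
    return AnovaResult(float(F_obs), p_sim, n_sim)


# ------------------------------------------------------------ plain baseline
def two_sample_test(
    a: Sequence[float], b: Sequence[float], variant: str = "pooled"
) -> TTestResult:
    """Two-sample comparison: pooled-variance t, Welch t, or Wilcoxon rank-sum."""
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    na, nb = len(av), len(bv)
    if na < 2 or nb < 2:
        raise ValidationError("each sample needs at least 2 values")
    if variant == "wilcoxon":
        stat, p = stats.ranksums(av, bv)
        return TTestResult(float(stat), float(na + nb - 2), float(p), variant)
    va, vb = av.var(ddof=1), bv.var(ddof=1)
    diff = av.mean() - bv.mean()
    if variant == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 <= 0:
            raise ValidationError("zero pooled variance; t-test is degenerate")
        t = diff / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = float(na + nb - 2)
    elif variant == "welch":
        se2 = va / na + vb / nb
        if se2 <= 0:
            raise ValidationError("zero variance; t-test is degenerate")
        t = diff / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        raise ValidationError(f"unknown variant {variant!r}")
    p = 2.0 * float(stats.t.sf(abs(t), df=df))
    return TTestResult(float(t), float(df), p, variant)
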