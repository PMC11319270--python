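"""Single-trait additive GBLUP: y = 1*mu + g + e,  g ~ N(0, G*sg2), e ~ N(0, I*se2).

The default fit estimates the variance components by restricted maximum
likelihood on the eigendecomposition of G (profiled over the variance ratio
``delta = se2 / sg2``), then returns BLUP breeding values E[g | y] for every
sample, including unphenotyped ones.  An optional Gibbs sampler fits the
same model with weakly informative scaled-inverse-chi-square priors and
yields posterior-mean GEBVs; point predictions from the two routes coincide
to Monte-Carlo error.

Model assessment follows standard genomic-prediction practice: repeated
random k-fold cross-validation with per-repeat Pearson correlation between
pooled out-of-fold GEBVs and observed phenotypes, the regression slope of
observed on predicted as a bias measure (1 = calibrated), and a paired
t-test on Fisher z-transformed per-repeat correlations to compare two
genotype encodings evaluated on identical fold assignments.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .grm import GRM

__all__ = [
    "ModelFit",
    "CVResult",
    "PairedComparison",
    "fit_gblup",
    "cross_validate",
    "prediction_bias",
    "compare_correlations",
]

_MIN_VAR_FACTOR = 1e-8  # lower bound on each component, relative to var(y)
_PSD_TOL = 1e-6


@dataclass
class ModelFit:
    """Fitted GBLUP model: mean, variance components, breeding values.

    ``mean_diag`` is the average diagonal of the relationship matrix over
    the phenotyped samples; the genetic variance per individual is
    ``sigma2_g * mean_diag``, so the heritability estimate scales
    ``sigma2_g`` by it.  (With a tetraploid-scaled G on mixed-ploidy
    continuous genotypes the diagonal exceeds 1, because lower-copy loci
    have more allele-fraction variance than the tetraploid scaling assumes.)
    """

    mu: float
    sigma2_g: float
    sigma2_e: float
    gebv: pd.Series
    method: str
    mean_diag: float = 1.0

    @property
    def h2(self) -> float:
        vg = self.sigma2_g * self.mean_diag
        tot = vg + self.sigma2_e
        return vg / tot if tot > 0 else 0.0


@dataclass
class CVResult:
    """Per-repeat cross-validated accuracy for one trait x encoding."""

    correlations: np.ndarray  # one Pearson r per repeat
    bias: np.ndarray          # one observed-on-GEBV slope per repeat
    n_folds: int
    n_repeats: int
    seed: int
    trait: str | None = None
    encoding: str | None = None
    fold_assignments: list[np.ndarray] = field(default_factory=list)

    @property
    def mean_correlation(self) -> float:
        return float(np.mean(self.correlations))

    @property
    def mean_bias(self) -> float:
        return float(np.mean(self.bias))


@dataclass
class PairedComparison:
    """Paired t-test of Fisher z-transformed per-repeat correlations."""

    mean_difference: float  # mean r_b - r_a
    t: float
    df: int
    p: float


def _align(y: pd.Series, G: GRM) -> np.ndarray:
    if not isinstance(y, pd.Series):
        y = pd.Series(np.asarray(y, dtype=float), index=G.sample_ids)
    missing = [s for s in G.sample_ids if s not in y.index]
    if missing:
        raise ValueError(f"phenotype vector lacks sample {missing[0]!r}")
    return y.reindex(G.sample_ids).to_numpy(dtype=float)


def _reml_delta(yr: np.ndarray, xr: np.ndarray, d: np.ndarray
                ) -> tuple[float, float, float]:
    """Profile REML over delta = se2/sg2 on rotated data; return (delta, sg2, mu-hat
    numerator pieces are recomputed by the caller)."""
    n = yr.size

    def neg_restricted_ll(log_delta: float) -> float:
        delta = math.exp(log_delta)
        w = 1.0 / (d + delta)
        xwx = float((xr * xr * w).sum())
        beta = float((xr * yr * w).sum()) / xwx
        r = yr - xr * beta
        ss = float((r * r * w).sum())
        sg2 = ss / (n - 1)
        return 0.5 * ((n - 1) * math.log(sg2) - np.log(w).sum()
                      + math.log(xwx) + (n - 1))

    grid = np.linspace(-12.0, 12.0, 49)
    vals = [neg_restricted_ll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    delta = float(math.exp(res.x))
    w = 1.0 / (d + delta)
    xwx = float((xr * xr * w).sum())
    beta = float((xr * yr * w).sum()) / xwx
    r = yr - xr * beta
    sg2 = float((r * r * w).sum()) / (n - 1)
    return delta, sg2, beta


def reml_components(y_obs: np.ndarray, G_obs: np.ndarray
                    ) -> tuple[float, float, float]:
    """REML estimates (mu, sg2, se2) of the null GBLUP model on observed samples."""
    n = y_obs.size
    d, U = np.linalg.eigh(G_obs)
    if d[0] < -_PSD_TOL * max(1.0, float(d[-1])):
        raise ValueError(
            f"relationship matrix is not positive semidefinite "
            f"(min eigenvalue {d[0]:.3g})")
    d = np.clip(d, 0.0, None)
    yr = U.T @ y_obs
    xr = U.T @ np.ones(n)
    delta, sg2, mu = _reml_delta(yr, xr, d)
    vy = float(np.var(y_obs))
    floor = _MIN_VAR_FACTOR * max(vy, 1e-12)
    sg2 = max(sg2, floor)
    se2 = max(delta * sg2, floor)
    return mu, sg2, se2


def _blup_gebv(y: np.ndarray, obs: np.ndarray, G: np.ndarray,
               mu: float, sg2: float, se2: float) -> np.ndarray:
    """E[g | y_obs] for all samples: sg2 * G[:, obs] @ V_obs^-1 (y_obs - mu)."""
    G_obs = G[np.ix_(obs, obs)]
    d, U = np.linalg.eigh(G_obs)
    d = np.clip(d, 0.0, None)
    resid = y[obs] - mu
    alpha = U @ ((U.T @ resid) / (sg2 * d + se2))
    return sg2 * (G[:, obs] @ alpha)


def _gibbs_fit(y_obs: np.ndarray, obs: np.ndarray, G: np.ndarray,
               n_iter: int, burn_in: int, seed: int
               ) -> tuple[float, float, float, np.ndarray]:
    """Gibbs sampler on the eigen-rotated model; returns posterior means."""
    rng = np.random.default_rng(seed)
    n = y_obs.size
    G_obs = G[np.ix_(obs, obs)]
    d, U = np.linalg.eigh(G_obs)
    d = np.clip(d, 0.0, None)
    pos = d > 1e-10
    vy = float(np.var(y_obs))
    # weakly informative scaled-inv-chi2 priors, mode at half the phenotypic
    # variance for each component (df 5)
    df0 = 5.0
    s0 = 0.5 * vy * (df0 + 2.0) / df0

    mu = float(np.mean(y_obs))
    sg2 = se2 = 0.5 * vy
    a = np.zeros(n)
    mu_sum = 0.0
    sg2_sum = se2_sum = 0.0
    a_sum = np.zeros(n)
    kept = 0
    ones_r = U.T @ np.ones(n)
    y_r = U.T @ y_obs
    for it in range(n_iter):
        # a | rest: independent components because U is orthonormal
        resid_r = y_r - ones_r * mu
        prec = 1.0 / se2 + np.where(pos, 1.0 / (sg2 * np.maximum(d, 1e-300)), np.inf)
        mean_a = (resid_r / se2) / prec
        sd_a = np.sqrt(1.0 / prec)
        a = np.where(pos, rng.normal(mean_a, sd_a), 0.0)
        # mu | rest
        r = y_obs - U @ a
        mu = rng.normal(float(np.mean(r)), math.sqrt(se2 / n))
        # sg2 | a
        ssa = float((a[pos] ** 2 / d[pos]).sum())
        df_g = df0 + pos.sum()
        sg2 = (ssa + df0 * s0) / rng.chisquare(df_g)
        # se2 | residuals
        e = y_obs - mu - U @ a
        df_e = df0 + n
        se2 = (float(e @ e) + df0 * s0) / rng.chisquare(df_e)
        if it >= burn_in:
            kept += 1
            mu_sum += mu
            sg2_sum += sg2
            se2_sum += se2
            a_sum += a
    a_mean = a_sum / kept
    return mu_sum / kept, sg2_sum / kept, se2_sum / kept, U @ a_mean


def fit_gblup(y: pd.Series, G: GRM, method: str = "reml",
              fixed_ratio: float | None = None,
              n_iter: int = 12_000, burn_in: int = 2_000,
              seed: int = 0) -> ModelFit:
    """Fit the GBLUP model and return breeding values for every sample.

    Parameters
    ----------
    y : phenotypes indexed by sample id; NaN marks unphenotyped samples,
        which still receive GEBVs.
    G : genomic relationship matrix.
    method : "reml" (deterministic, default) or "gibbs" (posterior means
        from ``n_iter`` sweeps with ``burn_in`` discarded).
    fixed_ratio : if given, the variance ratio se2/sg2 is held at this value
        instead of being estimated (sg2 is still profiled).
    """
    yv = _align(y, G)
    obs = np.flatnonzero(np.isfinite(yv))
    if obs.size < 10:
        raise ValueError(f"need at least 10 non-missing phenotypes, got {obs.size}")
    y_obs = yv[obs]
    G_obs = G.values[np.ix_(obs, obs)]

    if method == "gibbs":
        mu, sg2, se2, g_obs = _gibbs_fit(y_obs, obs, G.values, n_iter, burn_in, seed)
        gebv = _blup_gebv(yv, obs, G.values, mu, sg2, se2)
        # posterior-mean breeding values for the observed samples
        gebv[obs] = g_obs
    elif method == "reml":
        if fixed_ratio is not None:
            if fixed_ratio <= 0:
                raise ValueError("fixed_ratio must be positive")
            n = y_obs.size
            d, U = np.linalg.eigh(G_obs)
            if d[0] < -_PSD_TOL * max(1.0, float(d[-1])):
                raise ValueError("relationship matrix is not positive semidefinite")
            d = np.clip(d, 0.0, None)
            w = 1.0 / (d + fixed_ratio)
            yr, xr = U.T @ y_obs, U.T @ np.ones(n)
            xwx = float((xr * xr * w).sum())
            mu = float((xr * yr * w).sum()) / xwx
            r = yr - xr * mu
            sg2 = float((r * r * w).sum()) / (n - 1)
            se2 = fixed_ratio * sg2
        else:
            mu, sg2, se2 = reml_components(y_obs, G_obs)
        gebv = _blup_gebv(yv, obs, G.values, mu, sg2, se2)
    else:
        raise ValueError(f"unknown method {method!r}")

    return ModelFit(
        mu=float(mu), sigma2_g=float(sg2), sigma2_e=float(se2),
        gebv=pd.Series(gebv, index=pd.Index(G.sample_ids, name="sample_id")),
        method=method,
        mean_diag=float(np.mean(np.diag(G_obs))),
    )


def prediction_bias(observed: np.ndarray, gebv: np.ndarray) -> float:
    """OLS slope of observed phenotypes on GEBVs; 1 indicates no bias."""
    observed = np.asarray(observed, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    ok = np.isfinite(observed) & np.isfinite(gebv)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired non-missing values")
    o, g = observed[ok], gebv[ok]
    vg = g.var()
    if vg <= 0:
        raise ValueError("GEBV variance is zero; the bias slope is undefined")
    return float(np.cov(g, o, ddof=1)[0, 1] / g.var(ddof=1))


def cross_validate(y: pd.Series, G: GRM, n_folds: int = 8, n_repeats: int = 10,
                   seed: int = 0, method: str = "reml",
                   trait: str | None = None,
                   encoding: str | None = None) -> CVResult:
    """Repeated random k-fold cross-validation of GBLUP predictions.

    Per repeat, phenotyped samples are shuffled into ``n_folds`` folds; each
    fold's phenotypes are masked, the model refit, and the fold's GEBVs
    predicted.  The pooled out-of-fold GEBVs give one correlation and one
    bias slope per repeat.  Fold assignments depend only on ``seed``, so two
    encodings evaluated with the same seed share identical groupings.
    """
    yv = _align(y, G)
    phen = np.flatnonzero(np.isfinite(yv))
    if phen.size < n_folds:
        raise ValueError(
            f"{phen.size} phenotyped samples cannot fill {n_folds} folds")
    correlations = np.empty(n_repeats)
    bias = np.empty(n_repeats)
    assignments: list[np.ndarray] = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        perm = rng.permutation(phen.size)
        fold_of = np.empty(phen.size, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, n_folds)):
            fold_of[chunk] = f
        assignments.append(fold_of.copy())
        pred = np.full(phen.size, np.nan)
        for f in range(n_folds):
            test = phen[fold_of == f]
            y_masked = yv.copy()
            y_masked[test] = np.nan
            fit = fit_gblup(pd.Series(y_masked, index=G.sample_ids), G,
                            method=method, seed=seed)
            pred[fold_of == f] = fit.gebv.to_numpy()[test]
        obs = yv[phen]
        correlations[rep] = float(np.corrcoef(pred, obs)[0, 1])
        bias[rep] = prediction_bias(obs, pred)
    return CVResult(
        correlations=correlations, bias=bias, n_folds=n_folds,
        n_repeats=n_repeats, seed=seed, trait=trait, encoding=encoding,
        fold_assignments=assignments,
    )


def compare_correlations(cv_a: CVResult, cv_b: CVResult) -> PairedComparison:
    """Paired t-test of Fisher r-to-z transformed per-repeat correlations.

    Requires the two results to have the same number of repeats (and, for a
    meaningful pairing, identical fold assignments, i.e. the same seed).
    """
    ra, rb = cv_a.correlations, cv_b.correlations
    if ra.size != rb.size:
        raise ValueError("the two results must have equal repeat counts")
    if (np.abs(ra) >= 1).any() or (np.abs(rb) >= 1).any():
        raise ValueError("|r| = 1 overflows the Fisher z transform")
    dz = np.arctanh(rb) - np.arctanh(ra)
    n = dz.size
    mean = float(dz.mean())
    sd = float(dz.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        if mean == 0.0:
            return PairedComparison(0.0, 0.0, n - 1, 1.0)
        t = math.inf if mean > 0 else -math.inf
        return PairedComparison(mean, t, n - 1, 0.0)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedComparison(mean, float(t), n - 1, float(p))
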