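"""Single-marker mixed-model association scan with LOCO correction.

Model per marker: y = 1*mu + x_i * beta_i + g + e with g ~ N(0, G*sg2) where
G is the leave-one-chromosome-out (LOCO) relationship matrix of the tested
marker's chromosome, so the marker is never represented in the polygenic
term.  Variance components are estimated once per chromosome under the null
model and held fixed across that chromosome's markers; each marker's effect
and Wald chi-square then come from generalized least squares with
V = G*sg2 + I*se2.

Residual overdispersion is handled by genomic control: lambda_gc is the
median marker chi-square over the chi-square(1) median (0.4549...), and when
lambda_gc > 1 every chi-square is deflated by it before conversion back to
p-values.  Genome-wide significance uses the Bonferroni threshold
alpha / n_markers.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import reml_components
from .genotyping import GenotypeMatrix
from .grm import GRM

__all__ = [
    "GWASResult",
    "single_marker_scan",
    "genomic_control",
    "bonferroni_threshold",
    "scan_report",
]

CHI2_1_MEDIAN = 0.4549364231  # median of the chi-square distribution, 1 df


@dataclass
class GWASResult:
    """Per-marker association statistics plus scan-level summaries.

    ``table`` columns: locus, chrom, pos, beta, se, chi2, p, zero_variance
    and, after :func:`genomic_control`, p_corrected.
    """

    table: pd.DataFrame
    alpha: float = 0.05
    lambda_gc: float | None = None

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def bonferroni(self) -> float:
        return bonferroni_threshold(self.n_markers, self.alpha)

    def significant(self) -> pd.DataFrame:
        col = "p_corrected" if "p_corrected" in self.table.columns else "p"
        return self.table[self.table[col] < self.bonferroni]


def _impute_markers(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing marker genotypes; flag zero-variance markers."""
    X = X.copy()
    means = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=0)
    means = np.where(np.isfinite(means), means, 0.0)
    miss = ~np.isfinite(X)
    X[miss] = np.broadcast_to(means, X.shape)[miss]
    zero_var = X.std(axis=0) <= 1e-12
    return X, zero_var


def single_marker_scan(y: pd.Series, geno: GenotypeMatrix,
                       loco: dict[str, GRM],
                       alpha: float = 0.05,
                       fixed_components: tuple[float, float] | None = None
                       ) -> GWASResult:
    """Mixed-model single-marker regression across all markers.

    ``loco`` must contain a GRM for every chromosome present in ``geno``.
    ``fixed_components`` (sg2, se2), if given, bypasses the per-chromosome
    null REML fit; with sg2 = 0 the scan reduces exactly to ordinary least
    squares.  Markers with zero variance after mean imputation get p = 1 and
    a ``zero_variance`` flag.
    """
    if not isinstance(y, pd.Series):
        y = pd.Series(np.asarray(y, dtype=float), index=geno.sample_ids)
    yv = y.reindex(geno.sample_ids).to_numpy(dtype=float)
    obs = np.flatnonzero(np.isfinite(yv))
    if obs.size < 10:
        raise ValueError("need at least 10 phenotyped samples")
    y_obs = yv[obs]
    n = obs.size

    chroms = geno.locus_map["chrom"].to_numpy()
    rows = []
    for c in pd.unique(chroms):
        if c not in loco:
            raise ValueError(f"no LOCO relationship matrix for chromosome {c!r}")
        G = loco[c]
        if list(G.sample_ids) != list(geno.sample_ids):
            raise ValueError(
                f"sample ids of LOCO GRM for chromosome {c!r} do not match genotypes")
        G_obs = G.values[np.ix_(obs, obs)]
        if fixed_components is not None:
            sg2, se2 = fixed_components
        else:
            _, sg2, se2 = reml_components(y_obs, G_obs)
        d, U = np.linalg.eigh(G_obs)
        d = np.clip(d, 0.0, None)
        w = 1.0 / np.sqrt(sg2 * d + se2)
        yt = w * (U.T @ y_obs)
        ot = w * (U.T @ np.ones(n))

        idx = np.flatnonzero(chroms == c)
        X, zero_var = _impute_markers(geno.values[np.ix_(obs, idx)])
        Xt = w[:, None] * (U.T @ X)

        a11 = float(ot @ ot)
        a12 = ot @ Xt
        a22 = np.einsum("ij,ij->j", Xt, Xt)
        b1 = float(ot @ yt)
        b2 = Xt.T @ yt
        det = a11 * a22 - a12 ** 2
        safe = (det > 1e-12) & ~zero_var
        beta = np.where(safe, (a11 * b2 - a12 * b1) / np.where(safe, det, 1.0), 0.0)
        var_beta = np.where(safe, a11 / np.where(safe, det, 1.0), np.inf)
        se = np.sqrt(var_beta)
        chi2 = np.where(safe, (beta / se) ** 2, 0.0)
        p = np.where(safe, stats.chi2.sf(chi2, df=1), 1.0)
        rows.append(pd.DataFrame({
            "locus": geno.locus_map.index[idx],
            "chrom": geno.locus_map["chrom"].iloc[idx].to_numpy(),
            "pos": geno.locus_map["pos"].iloc[idx].to_numpy(),
            "beta": beta,
            "se": np.where(safe, se, np.nan),
            "chi2": chi2,
            "p": p,
            "zero_variance": ~safe,
        }))
    table = pd.concat(rows, ignore_index=True)
    return GWASResult(table=table, alpha=alpha)


def genomic_control(result: GWASResult) -> GWASResult:
    """Deflate test statistics by the genomic inflation factor.

    lambda_gc = median(chi2) / 0.4549..., with chi2 recovered from each raw
    p-value through the inverse chi-square(1) upper-tail function.  When
    lambda_gc > 1 every chi-square is divided by it and converted back to a
    corrected p-value; otherwise p-values pass through unchanged.
    lambda_gc is reported either way.
    """
    if result.n_markers < 10:
        raise ValueError("genomic control needs at least 10 markers")
    p = result.table["p"].to_numpy(dtype=float)
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    table = result.table.copy()
    if np.all(p >= 1.0):
        lam = 0.0
        table["p_corrected"] = p
    elif lam > 1.0 + 1e-8:  # tolerance for the truncated chi2(1)-median constant
        table["p_corrected"] = stats.chi2.sf(chi2 / lam, df=1)
    else:
        table["p_corrected"] = p
    return GWASResult(table=table, alpha=result.alpha, lambda_gc=lam)


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / n_markers."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return alpha / n_markers


def _chrom_sort_key(table: pd.DataFrame) -> pd.DataFrame:
    key = pd.to_numeric(table["chrom"], errors="coerce").fillna(np.inf)
    return table.assign(_ck=key).sort_values(["_ck", "pos"]).drop(columns="_ck")


def scan_report(result: GWASResult, out_prefix, make_plots: bool = True) -> dict:
    """Write per-marker and significant-marker TSVs plus optional plots.

    The per-marker table is sorted by chromosome (the unanchored bin "0"
    first) and position.  Significant markers are those with corrected (or,
    if uncorrected, raw) p below the Bonferroni threshold.  Returns a dict
    of written paths.
    """
    out_prefix = str(out_prefix)
    table = _chrom_sort_key(result.table)
    paths = {}
    markers_path = Path(f"{out_prefix}markers.tsv")
    markers_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(markers_path, sep="\t", index=False, float_format="%.6g")
    paths["markers"] = markers_path
    sig = _chrom_sort_key(result.significant())
    sig_path = Path(f"{out_prefix}significant.tsv")
    sig.to_csv(sig_path, sep="\t", index=False, float_format="%.6g")
    paths["significant"] = sig_path

    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        pcol = "p_corrected" if "p_corrected" in table.columns else "p"
        logp = -np.log10(np.clip(table[pcol].to_numpy(dtype=float), 1e-300, 1.0))
        chrom_order = list(dict.fromkeys(table["chrom"]))
        fig, ax = plt.subplots(figsize=(10, 3.2))
        offset = 0
        ticks, labels = [], []
        for i, c in enumerate(chrom_order):
            sel = table["chrom"] == c
            pos = table.loc[sel, "pos"].to_numpy(dtype=float)
            span = pos.max() - pos.min() + 1 if sel.any() else 1
            x = offset + (pos - pos.min())
            ax.scatter(x, logp[sel.to_numpy()], s=4,
                       color="#1f77b4" if i % 2 == 0 else "#ff7f0e")
            ticks.append(offset + span / 2)
            labels.append(str(c))
            offset += span * 1.05
        ax.axhline(-np.log10(result.bonferroni), color="red", lw=0.8)
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome (0 = unanchored bin)")
        ax.set_ylabel(r"$-\log_{10}(p)$")
        fig.tight_layout()
        man_path = Path(f"{out_prefix}manhattan.png")
        fig.savefig(man_path, dpi=120)
        plt.close(fig)
        paths["manhattan"] = man_path

        fig, ax = plt.subplots(figsize=(3.6, 3.6))
        exp = -np.log10((np.arange(1, logp.size + 1) - 0.5) / logp.size)
        ax.scatter(exp, np.sort(logp)[::-1], s=4)
        lim = max(exp.max(), logp.max()) * 1.05
        ax.plot([0, lim], [0, lim], color="gray", lw=0.8)
        ax.set_xlabel("expected $-\\log_{10}(p)$")
        ax.set_ylabel("observed $-\\log_{10}(p)$")
        fig.tight_layout()
        qq_path = Path(f"{out_prefix}qq.png")
        fig.savefig(qq_path, dpi=120)
        plt.close(fig)
        paths["qq"] = qq_path
    return paths
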