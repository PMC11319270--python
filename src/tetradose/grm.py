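"""Genomic relationship matrices with missing-data weighting.

The G-matrix is built identically from either genotype encoding (values on
the 0-1 scale):

1. per-sample missing-data weights
   ``w_i = sum_k p_k (1 - p_k)  /  sum_{k observed in i} p_k (1 - p_k)``,
   where ``p_k`` is the mean genotype at locus k over non-missing samples;
2. centering and scaling ``Z_ik = (X_ik - p_k) * w_i`` with missing entries
   mean-imputed to zero after centering;
3. global tetraploid scaling ``G = Z Z' / (0.25 * sum_k p_k (1 - p_k))``.

Under tetraploid random mating the scaling constant equals the expected
``Z Z'`` diagonal, so the mean diagonal of G is ~1.  Leave-one-chromosome-out
(LOCO) variants rebuild weights and centering on the retained loci.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotyping import GenotypeMatrix

__all__ = [
    "GRM",
    "missing_weights",
    "center_and_impute",
    "compute_grm",
    "build_grm",
    "loco_grms",
]


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with provenance fields."""

    sample_ids: list[str]
    values: np.ndarray
    excluded_chromosome: str | None = None
    locus_means: np.ndarray | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"GRM must be {n}x{n}, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def subset(self, idx: np.ndarray) -> "GRM":
        idx = np.asarray(idx)
        return GRM(
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            excluded_chromosome=self.excluded_chromosome,
            locus_means=self.locus_means,
            scale=self.scale,
        )


def _locus_means(values: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(values, axis=0)
    return p


def missing_weights(geno: GenotypeMatrix) -> np.ndarray:
    """Per-sample missing-data weights from locus heterozygosity mass.

    ``w_i`` rescales each sample's genotypes so that samples typed at fewer
    loci are not systematically closer to the origin: the numerator is the
    heterozygosity mass ``sum p_k (1 - p_k)`` over all loci, the denominator
    the same sum restricted to the loci observed in sample i.
    """
    values = geno.values
    p = _locus_means(values)
    if np.isnan(p).any():
        bad = geno.locus_map.index[np.isnan(p)][0]
        raise ValueError(f"locus {bad!r} has no non-missing genotypes")
    v = p * (1.0 - p)
    total = v.sum()
    if total <= 0:
        raise ValueError("all loci are monomorphic (every p_k in {0, 1}); "
                         "weights are undefined")
    observed = np.isfinite(values)
    if not observed.any(axis=1).all():
        bad = geno.sample_ids[int(np.flatnonzero(~observed.any(axis=1))[0])]
        raise ValueError(f"sample {bad!r} is missing every locus")
    denom = observed @ v
    if (denom <= 0).any():
        bad = geno.sample_ids[int(np.flatnonzero(denom <= 0)[0])]
        raise ValueError(f"sample {bad!r} observes only zero-variance loci")
    return total / denom


def center_and_impute(geno: GenotypeMatrix,
                      weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Center by locus means, scale rows by w_i, mean-impute missing to zero.

    Returns ``(Z, imputed_fraction)``.
    """
    values = geno.values
    if weights.shape != (geno.n_samples,):
        raise ValueError("weights must be one per sample")
    p = _locus_means(values)
    Z = (values - p[None, :]) * weights[:, None]
    missing = ~np.isfinite(Z)
    Z[missing] = 0.0
    return Z, float(missing.mean())


def compute_grm(Z: np.ndarray, p: np.ndarray) -> np.ndarray:
    """G = Z Z' / (0.25 * sum p_k (1 - p_k)).

    ``p`` are the locus mean genotypes the centering used.  Returns a bare
    symmetric matrix; use :func:`build_grm` for the labelled container.
    """
    scale = 0.25 * float((p * (1.0 - p)).sum())
    if scale <= 0:
        raise ValueError("zero scaling constant: all loci are monomorphic")
    return Z @ Z.T / scale


def build_grm(geno: GenotypeMatrix,
              exclude_chromosome: str | None = None) -> GRM:
    """Weights + centering + scaling in one step, optionally excluding a chromosome."""
    if exclude_chromosome is not None:
        chrom = geno.locus_map["chrom"].to_numpy()
        keep = np.flatnonzero(chrom != str(exclude_chromosome))
        if keep.size == geno.n_loci:
            warnings.warn(
                f"chromosome {exclude_chromosome!r} has no loci; "
                "the LOCO matrix equals the full GRM")
        if keep.size == 0:
            raise ValueError(
                f"excluding chromosome {exclude_chromosome!r} leaves no loci")
        geno = geno.subset(loci=keep)
    w = missing_weights(geno)
    Z, _ = center_and_impute(geno, w)
    p = _locus_means(geno.values)
    values = compute_grm(Z, p)
    return GRM(
        sample_ids=list(geno.sample_ids),
        values=values,
        excluded_chromosome=exclude_chromosome,
        locus_means=p,
        scale=0.25 * float((p * (1.0 - p)).sum()),
    )


def loco_grms(geno: GenotypeMatrix,
              chromosomes: list[str] | None = None) -> dict[str, GRM]:
    """One leave-one-chromosome-out GRM per chromosome.

    The unanchored bin (chromosome "0") is treated as its own exclusion
    group.  Raises on single-chromosome input, where LOCO is undefined.
    """
    present = list(pd.unique(geno.locus_map["chrom"]))
    if chromosomes is None:
        chromosomes = present
    if len(present) < 2:
        raise ValueError("LOCO requires at least two chromosomes with loci")
    return {str(c): build_grm(geno, exclude_chromosome=str(c))
            for c in chromosomes}
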