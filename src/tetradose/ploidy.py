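"""Read-depth requirements for discriminating heterozygous ploidy states.

In a mixed-ploidy genome the observed alternative-allele read fraction of a
heterozygous locus clusters at m / (copy number): 0.25/0.5/0.75 for
tetraploid, 1/3 and 2/3 for triploid loci, and composite fractions when two
loci co-map to a single reference position.  At GBS depth these clusters
overlap heavily; this module quantifies the depth needed to tell them apart:

* :func:`simulate_ratio_envelope` - Monte-Carlo percentile envelopes of the
  binomial allele-ratio distribution per depth.
* :func:`find_discrimination_depth` - smallest depth at which the envelopes
  of two heterozygous states stop overlapping (the "worst case" pair is the
  simplex tetraploid 0.25 vs heterozygous triploid 1/3, which requires depth
  in the hundreds).
* :func:`heterozygous_ratio_histogram` / :func:`expected_peak_positions` -
  the observed-ratio histogram of heterozygous genotypes and the theoretical
  peak positions for single or co-mapped loci.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .genotyping import GenotypeMatrix

__all__ = [
    "RatioHistogram",
    "simulate_ratio_envelope",
    "find_discrimination_depth",
    "discrimination_depth_normal_approx",
    "heterozygous_ratio_histogram",
    "expected_peak_positions",
]


def simulate_ratio_envelope(p: float, depths, n_loci: int = 2500,
                            seed: int = 0,
                            percentiles: tuple[float, float] = (5.0, 95.0)
                            ) -> pd.DataFrame:
    """Percentile envelope of the binomial allele ratio as a function of depth.

    For each depth N, draws ``n_loci`` counts from binomial(N, p), converts
    them to ratios and records the requested percentiles (empirical order
    statistics with linear interpolation) and the mean.

    Returns a DataFrame indexed by depth with columns ``lower``, ``upper``,
    ``mean``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    depths = np.asarray(list(depths), dtype=int)
    if depths.size == 0 or (depths < 1).any():
        raise ValueError("depths must be positive integers")
    rng = np.random.default_rng(seed)
    lower, upper, mean = np.empty(depths.size), np.empty(depths.size), np.empty(depths.size)
    for i, n in enumerate(depths):
        ratios = rng.binomial(n, p, size=n_loci) / n
        lower[i], upper[i] = np.percentile(ratios, percentiles)
        mean[i] = ratios.mean()
    return pd.DataFrame({"lower": lower, "upper": upper, "mean": mean},
                        index=pd.Index(depths, name="depth"))


def find_discrimination_depth(p_tetra: float, p_tri: float,
                              confidence: float = 0.95,
                              depths=range(3, 1001), n_loci: int = 2500,
                              seed: int = 0) -> int | None:
    """Smallest depth at which two heterozygous states separate.

    Simulates both states' allele-ratio distributions on the depth grid and
    returns the first depth at which the lower-mean state's upper
    ``confidence`` percentile falls below the higher-mean state's lower
    ``1 - confidence`` percentile (i.e. the one-sided envelopes no longer
    cross).  Returns ``None`` if the envelopes never separate on the grid.
    """
    if not 0.5 < confidence < 1.0:
        raise ValueError("confidence must be in (0.5, 1)")
    if p_tetra == p_tri:
        raise ValueError("the two states have equal allele fractions; no crossing")
    p_lo, p_hi = sorted((p_tetra, p_tri))
    depths = np.asarray(list(depths), dtype=int)
    if (depths < 1).any():
        raise ValueError("depths must be positive integers")
    rng = np.random.default_rng(seed)
    up_q = 100.0 * confidence
    lo_q = 100.0 * (1.0 - confidence)
    for n in depths:
        lo_state = rng.binomial(n, p_lo, size=n_loci) / n
        hi_state = rng.binomial(n, p_hi, size=n_loci) / n
        if np.percentile(lo_state, up_q) < np.percentile(hi_state, lo_q):
            return int(n)
    return None


def discrimination_depth_normal_approx(p_a: float, p_b: float,
                                       confidence: float = 0.95) -> float:
    """Closed-form normal approximation to the envelope-crossing depth.

    Solves z * (sqrt(pa qa) + sqrt(pb qb)) / sqrt(N) = |pa - pb| for N,
    with z the one-sided normal quantile at ``confidence``.
    """
    from scipy.stats import norm

    z = norm.ppf(confidence)
    num = z * (np.sqrt(p_a * (1 - p_a)) + np.sqrt(p_b * (1 - p_b)))
    return float((num / abs(p_a - p_b)) ** 2)


@dataclass
class RatioHistogram:
    """Histogram of heterozygous allele ratios with detected peak positions."""

    bin_edges: np.ndarray
    counts: np.ndarray
    peaks: np.ndarray  # bin centers of detected local maxima
    n_values: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers, "count": self.counts})


def heterozygous_ratio_histogram(geno: GenotypeMatrix,
                                 ratio_window: tuple[float, float] = (0.1, 0.9),
                                 bin_width: float = 0.01,
                                 peak_prominence_factor: float = 0.15
                                 ) -> RatioHistogram:
    """Histogram of observed allele ratios across heterozygous genotypes.

    Heterozygous is defined as strictly inside ``ratio_window``.  Local
    maxima are detected with a prominence threshold of
    ``peak_prominence_factor`` times the median bin count; dosage-class
    peaks ride on a dense binomial-sampling baseline, so their prominence
    is a modest fraction of the median rather than a multiple of it.
    """
    if geno.encoding != "continuous":
        raise ValueError("ratio histogram requires the continuous encoding")
    lo, hi = ratio_window
    if not lo < hi:
        return RatioHistogram(np.array([lo, hi]), np.array([0]), np.array([]), 0)
    v = geno.values[np.isfinite(geno.values)]
    v = v[(v > lo) & (v < hi)]
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    prominence = peak_prominence_factor * max(float(np.median(counts)), 1.0)
    idx, _ = find_peaks(counts, prominence=prominence)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RatioHistogram(edges, counts, centers[idx], int(v.size))


def expected_peak_positions(copy_numbers: list[int]) -> list[float]:
    """Theoretical heterozygous-ratio peaks for one locus or two co-mapped loci.

    Pooling loci with copy numbers c1 (+ c2) yields allele ratios
    m / (c1 + c2) for m = 1 .. total - 1.  Examples: [4] -> {.25, .5, .75};
    [4, 3] -> sevenths; [2, 3] -> fifths.
    """
    if not copy_numbers:
        raise ValueError("copy_numbers must not be empty")
    if len(copy_numbers) > 2:
        raise ValueError("at most two co-mapped loci are supported")
    if any(not 1 <= int(c) <= 8 for c in copy_numbers):
        raise ValueError("copy numbers must be integers in 1..8")
    total = int(sum(copy_numbers))
    return [m / total for m in range(1, total)]
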