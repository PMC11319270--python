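"""Genotype encodings from read counts and the shared filter cascade.

Two encodings of the same biallelic read-count data are produced:

* **continuous** - the observed alternative-allele read fraction
  ``alt / (ref + alt)``, used directly as a genotype value in [0, 1].  This
  encoding carries whatever allele dosage the locus truly has, including
  non-tetraploid states.
* **tetraploid** - a forced five-class dosage call (nulliplex..quadruplex)
  by maximum binomial likelihood over the class means
  ``{eps, 0.25, 0.5, 0.75, 1 - eps}``, recoded to ``{0, 0.25, 0.5, 0.75, 1}``.

Both encodings are filtered identically so that every downstream comparison
is on the same sample and locus sets.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReadCountMatrix",
    "GenotypeMatrix",
    "FilterConfig",
    "FilterReport",
    "EmptyFilterResult",
    "allele_frequency_genotypes",
    "call_tetraploid_dosages",
    "apply_filters",
]


@dataclass
class ReadCountMatrix:
    """Per sample x locus reference/alternative allele read counts."""

    sample_ids: list[str]
    locus_map: pd.DataFrame  # index: locus id; columns: chrom, pos[, ref, alt]
    ref_count: np.ndarray
    alt_count: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.sample_ids), len(self.locus_map))
        if self.ref_count.shape != shape or self.alt_count.shape != shape:
            raise ValueError(
                f"count layers must both have shape {shape}, got "
                f"{self.ref_count.shape} and {self.alt_count.shape}"
            )
        if (self.ref_count < 0).any() or (self.alt_count < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_map)

    def subset(self, samples: np.ndarray | None = None,
               loci: np.ndarray | None = None) -> "ReadCountMatrix":
        s = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        l = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return ReadCountMatrix(
            sample_ids=[self.sample_ids[i] for i in s],
            locus_map=self.locus_map.iloc[l].copy(),
            ref_count=self.ref_count[np.ix_(s, l)],
            alt_count=self.alt_count[np.ix_(s, l)],
        )


@dataclass
class GenotypeMatrix:
    """Sample x locus genotypes on the 0-1 scale; NaN marks missing."""

    sample_ids: list[str]
    locus_map: pd.DataFrame
    values: np.ndarray
    encoding: str  # "continuous" | "tetraploid"

    _TET_CLASSES = (0.0, 0.25, 0.5, 0.75, 1.0)

    def __post_init__(self) -> None:
        shape = (len(self.sample_ids), len(self.locus_map))
        if self.values.shape != shape:
            raise ValueError(f"values must have shape {shape}, got {self.values.shape}")
        if self.encoding not in ("continuous", "tetraploid"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("genotype values must lie in [0, 1]")
        if self.encoding == "tetraploid" and finite.size:
            if not np.isin(finite, self._TET_CLASSES).all():
                raise ValueError("tetraploid values must be in {0, .25, .5, .75, 1}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_map)

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())

    def subset(self, samples: np.ndarray | None = None,
               loci: np.ndarray | None = None) -> "GenotypeMatrix":
        s = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        l = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in s],
            locus_map=self.locus_map.iloc[l].copy(),
            values=self.values[np.ix_(s, l)],
            encoding=self.encoding,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.locus_map.index)


def allele_frequency_genotypes(counts: ReadCountMatrix,
                               min_depth: int = 5) -> GenotypeMatrix:
    """Continuous genotypes: alt / (ref + alt), missing where depth <= min_depth.

    The depth requirement is strict ("read coverage > min_depth"), so a
    genotype with depth exactly ``min_depth`` is set missing.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    depth = counts.depth
    if not (depth > 0).any():
        warnings.warn("all read depths are zero; returning an all-missing matrix")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(depth > min_depth, counts.alt_count / np.maximum(depth, 1),
                          np.nan)
    return GenotypeMatrix(
        sample_ids=list(counts.sample_ids),
        locus_map=counts.locus_map.copy(),
        values=values.astype(float),
        encoding="continuous",
    )


def call_tetraploid_dosages(counts: ReadCountMatrix, error_rate: float = 0.01,
                            min_depth: int = 5) -> GenotypeMatrix:
    """Forced tetraploid dosage calls by binomial maximum likelihood.

    Each genotype is assigned the dosage d in {0..4} whose class mean
    ``{eps, 0.25, 0.5, 0.75, 1 - eps}`` maximizes the binomial likelihood of
    the observed alt count at the observed depth, then recoded to d/4.
    Ties are broken toward the lower dosage.  Genotypes with depth <=
    ``min_depth`` are missing.
    """
    if not 0.0 < error_rate < 0.25:
        raise ValueError("error_rate must be in (0, 0.25)")
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    eps = error_rate
    class_means = np.array([eps, 0.25, 0.5, 0.75, 1.0 - eps])
    alt = counts.alt_count.astype(np.float64)
    ref = counts.ref_count.astype(np.float64)
    best_ll = np.full(alt.shape, -np.inf)
    best_d = np.zeros(alt.shape, dtype=np.int8)
    for d, q in enumerate(class_means):
        ll = alt * np.log(q) + ref * np.log1p(-q)
        better = ll > best_ll  # strict: ties keep the lower dosage
        best_ll[better] = ll[better]
        best_d[better] = d
    values = best_d / 4.0
    values[counts.depth <= min_depth] = np.nan
    return GenotypeMatrix(
        sample_ids=list(counts.sample_ids),
        locus_map=counts.locus_map.copy(),
        values=values,
        encoding="tetraploid",
    )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the marker/sample filter cascade.

    ``maf_bounds`` are strict bounds on the pooled-read allele frequency;
    ``locus_depth_window`` is inclusive; ``min_genotype_depth`` is strict
    (depth must exceed it); samples are kept while their missing fraction is
    strictly below ``max_sample_missing``.
    """

    maf_bounds: tuple[float, float] = (0.01, 0.99)
    max_locus_missing: float = 0.5
    min_genotype_depth: int = 5
    locus_depth_window: tuple[float, float] = (5.0, 60.0)
    max_sample_missing: float = 0.7
    drop_monomorphic_in_either: bool = True

    def validate(self) -> None:
        lo, hi = self.maf_bounds
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("maf_bounds must be ordered within [0, 1]")
        if not 0.0 <= self.max_locus_missing <= 1.0:
            raise ValueError("max_locus_missing must be in [0, 1]")
        if not 0.0 <= self.max_sample_missing <= 1.0:
            raise ValueError("max_sample_missing must be in [0, 1]")
        dlo, dhi = self.locus_depth_window
        if dlo > dhi:
            raise ValueError("locus_depth_window must be ordered")


@dataclass
class FilterReport:
    """Loci/samples surviving each cascade step, in application order."""

    initial_samples: int
    initial_loci: int
    steps: list[dict] = field(default_factory=list)

    def record(self, name: str, n_samples: int, n_loci: int) -> None:
        self.steps.append({"step": name, "n_samples": n_samples, "n_loci": n_loci})

    @property
    def final_samples(self) -> int:
        return self.steps[-1]["n_samples"] if self.steps else self.initial_samples

    @property
    def final_loci(self) -> int:
        return self.steps[-1]["n_loci"] if self.steps else self.initial_loci

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"initial_samples": self.initial_samples,
                 "initial_loci": self.initial_loci, "steps": self.steps},
                fh, indent=2)
            fh.write("\n")


class EmptyFilterResult(RuntimeError):
    """Raised when a filter step removes every locus or every sample."""

    def __init__(self, step: str, axis: str):
        self.step = step
        super().__init__(f"filter step {step!r} removed every {axis}")


def _is_monomorphic(values: np.ndarray) -> np.ndarray:
    """Per-locus flag: fewer than two distinct non-missing values."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanmin(values, axis=0)
        hi = np.nanmax(values, axis=0)
    all_nan = np.isnan(lo)
    return all_nan | (hi - lo <= 0)


def apply_filters(af: GenotypeMatrix, tet: GenotypeMatrix,
                  counts: ReadCountMatrix, cfg: FilterConfig | None = None
                  ) -> tuple[GenotypeMatrix, GenotypeMatrix, FilterReport]:
    """Apply the shared filter cascade to both genotype encodings.

    Order: per-genotype depth masking; locus mean-depth window; locus MAF
    bounds (from pooled read counts); locus missing-rate cap; sample
    missing-rate cap; removal of loci monomorphic in either encoding from
    both.  The two outputs always share identical sample and locus sets.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    if af.locus_map.shape[0] != tet.locus_map.shape[0] or af.n_samples != tet.n_samples:
        raise ValueError("the two genotype matrices must share dimensions")
    if af.n_loci != counts.n_loci or af.n_samples != counts.n_samples:
        raise ValueError("genotype matrices and counts must share dimensions")

    report = FilterReport(af.n_samples, af.n_loci)
    va = af.values.copy()
    vt = tet.values.copy()
    depth = counts.depth

    # 1. per-genotype depth masking (strict: depth must exceed the minimum)
    shallow = depth <= cfg.min_genotype_depth
    va[shallow] = np.nan
    vt[shallow] = np.nan
    s_keep = np.arange(af.n_samples)
    l_keep = np.arange(af.n_loci)
    report.record("genotype_depth_mask", s_keep.size, l_keep.size)

    def _check(step: str) -> None:
        if l_keep.size == 0:
            raise EmptyFilterResult(step, "locus")
        if s_keep.size == 0:
            raise EmptyFilterResult(step, "sample")

    # 2. locus mean-depth window (inclusive)
    mean_depth = depth[np.ix_(s_keep, l_keep)].mean(axis=0)
    lo, hi = cfg.locus_depth_window
    l_keep = l_keep[(mean_depth >= lo) & (mean_depth <= hi)]
    report.record("locus_depth_window", s_keep.size, l_keep.size)
    _check("locus_depth_window")

    # 3. MAF from pooled read counts (strict bounds)
    pooled_alt = counts.alt_count[np.ix_(s_keep, l_keep)].sum(axis=0)
    pooled_tot = depth[np.ix_(s_keep, l_keep)].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_af = np.where(pooled_tot > 0, pooled_alt / np.maximum(pooled_tot, 1),
                             np.nan)
    mlo, mhi = cfg.maf_bounds
    ok = np.isfinite(pooled_af) & (pooled_af > mlo) & (pooled_af < mhi)
    l_keep = l_keep[ok]
    report.record("locus_maf", s_keep.size, l_keep.size)
    _check("locus_maf")

    # 4. locus missing-rate cap
    miss = np.isnan(va[np.ix_(s_keep, l_keep)]).mean(axis=0)
    l_keep = l_keep[miss <= cfg.max_locus_missing]
    report.record("locus_missing", s_keep.size, l_keep.size)
    _check("locus_missing")

    # 5. sample missing-rate cap (keep strictly below the cap)
    smiss = np.isnan(va[np.ix_(s_keep, l_keep)]).mean(axis=1)
    s_keep = s_keep[smiss < cfg.max_sample_missing]
    report.record("sample_missing", s_keep.size, l_keep.size)
    _check("sample_missing")

    # 6. loci monomorphic in either encoding, removed from both
    if cfg.drop_monomorphic_in_either:
        mono = (_is_monomorphic(va[np.ix_(s_keep, l_keep)])
                | _is_monomorphic(vt[np.ix_(s_keep, l_keep)]))
        l_keep = l_keep[~mono]
        report.record("monomorphic_in_either", s_keep.size, l_keep.size)
        _check("monomorphic_in_either")

    out_af = GenotypeMatrix(
        sample_ids=[af.sample_ids[i] for i in s_keep],
        locus_map=af.locus_map.iloc[l_keep].copy(),
        values=va[np.ix_(s_keep, l_keep)],
        encoding=af.encoding,
    )
    out_tet = GenotypeMatrix(
        sample_ids=[tet.sample_ids[i] for i in s_keep],
        locus_map=tet.locus_map.iloc[l_keep].copy(),
        values=vt[np.ix_(s_keep, l_keep)],
        encoding=tet.encoding,
    )
    return out_af, out_tet, report
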