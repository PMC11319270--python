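"""Synthetic mixed-ploidy breeding populations with GBS-style read counts.

Emulates a diallel-cross panel of an autotetraploid crop in which gene copy
number varies locus by locus (1-4 copies, averaging ~3.2 with ~54% of loci
tetraploid, as reported for elite potato assemblies).  Three stages:

1. :func:`simulate_population` - parents and diallel offspring with per
   sample x locus copy number and alternative-allele copies.
2. :func:`simulate_read_counts` - binomial read sampling at GBS-like depth
   (negative-binomial depth truncated to a window, default 5-60 with mean
   ~19), optionally pooling duplicate-mapped loci into one observed locus.
3. :func:`simulate_phenotypes` - additive traits with a chosen heritability,
   a configurable number of major QTLs and a polygenic background.

All stages are deterministic functions of ``SimConfig.seed``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genotyping import ReadCountMatrix

__all__ = [
    "TraitSpec",
    "SimConfig",
    "PopulationTruth",
    "PhenotypeTable",
    "simulate_population",
    "simulate_read_counts",
    "simulate_phenotypes",
]


@dataclass(frozen=True)
class TraitSpec:
    """Additive trait architecture.

    ``polygenic_share`` is the fraction of genetic variance contributed by
    the polygenic background (small effects at every locus); the remainder
    is split over ``n_qtl`` major loci.  ``missing_rate`` masks phenotypes
    completely at random, emulating incomplete field scoring.
    """

    name: str
    h2: float = 0.5
    n_qtl: int = 0
    polygenic_share: float = 1.0
    missing_rate: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"trait {self.name!r}: h2 must be in [0, 1], got {self.h2}")
        if self.n_qtl < 0:
            raise ValueError(f"trait {self.name!r}: n_qtl must be >= 0")
        if not 0.0 <= self.polygenic_share <= 1.0:
            raise ValueError(f"trait {self.name!r}: polygenic_share must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"trait {self.name!r}: missing_rate must be in [0, 1)")


# Copy-number mixture chosen to give ~54% tetraploid loci and a mean of
# 3.2 copies (0.08*1 + 0.18*2 + 0.20*3 + 0.54*4 = 3.20), matching the
# published "Otava" summary while keeping most mass on 3 and 4 copies.
_DEFAULT_PLOIDY = {1: 0.08, 2: 0.18, 3: 0.20, 4: 0.54}

_DEFAULT_TRAITS = (
    TraitSpec("major_qtl", h2=0.5, n_qtl=3, polygenic_share=0.5),
    TraitSpec("polygenic", h2=0.5, n_qtl=0, polygenic_share=1.0),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic panel.

    Defaults emulate the MASPOT design: 762 offspring of a diallel cross of
    18 elite parents, ~31k biallelic SNPs on 12 chromosomes plus an
    unanchored bin ("chromosome 0"), read depth 5-60 with mean ~19.
    """

    n_parents: int = 18
    n_offspring: int = 762
    n_loci: int = 31_000
    n_chromosomes: int = 12
    unanchored_fraction: float = 0.03
    ploidy_fractions: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_PLOIDY)
    )
    ancestral_af_range: tuple[float, float] = (0.05, 0.95)
    depth_range: tuple[int, int] = (5, 60)
    mean_depth: float = 19.0
    depth_dispersion: float = 6.0
    error_rate: float = 0.01
    duplicate_fraction: float = 0.05
    traits: tuple[TraitSpec, ...] = _DEFAULT_TRAITS
    seed: int = 0

    def validate(self) -> None:
        if self.n_parents < 2:
            raise ValueError("n_parents must be >= 2 (a cross needs two parents)")
        if self.n_offspring < 1 or self.n_loci < 1 or self.n_chromosomes < 1:
            raise ValueError("n_offspring, n_loci and n_chromosomes must be positive")
        if not self.ploidy_fractions:
            raise ValueError("ploidy_fractions must be non-empty")
        if any(c not in (1, 2, 3, 4) for c in self.ploidy_fractions):
            raise ValueError("copy numbers must be in {1, 2, 3, 4}")
        if abs(sum(self.ploidy_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("ploidy_fractions must sum to 1")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("depth_range must satisfy 0 < low <= high")
        if not lo <= self.mean_depth <= hi:
            raise ValueError("mean_depth must lie inside depth_range")
        alo, ahi = self.ancestral_af_range
        if not (0.0 <= alo <= ahi <= 1.0):
            raise ValueError("ancestral_af_range must be ordered within [0, 1]")
        if not 0.0 <= self.duplicate_fraction <= 0.5:
            raise ValueError("duplicate_fraction must be in [0, 0.5]")
        for t in self.traits:
            t.validate()

    def with_(self, **kw) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


@dataclass
class PopulationTruth:
    """Ground-truth genotypes of a simulated panel.

    ``copy_number`` and ``alt_copies`` are samples x truth-loci integer
    arrays (parents first, then offspring).  ``duplicate_groups`` lists
    pairs of truth-locus indices that co-map to a single observed locus in
    the read data; ``observed_of_truth`` maps every truth locus to its
    observed-locus index.
    """

    sample_ids: list[str]
    locus_map: pd.DataFrame  # index: locus id; columns: chrom, pos
    copy_number: np.ndarray
    alt_copies: np.ndarray
    duplicate_groups: list[tuple[int, int]] = field(default_factory=list)
    causal_effects: dict[str, pd.Series] = field(default_factory=dict)
    n_parents: int = 0

    @property
    def true_af(self) -> np.ndarray:
        """Per sample x locus fraction of alternative allele copies."""
        return self.alt_copies / self.copy_number

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_map)

    @property
    def observed_of_truth(self) -> np.ndarray:
        """Map truth-locus index -> observed-locus index (pooled pairs share one)."""
        second = {j: i for i, j in self.duplicate_groups}
        obs = np.full(self.n_loci, -1, dtype=np.int64)
        nxt = 0
        for k in range(self.n_loci):
            if k in second:
                continue
            obs[k] = nxt
            nxt += 1
        for i, j in self.duplicate_groups:
            obs[j] = obs[i]
        return obs

    def observed_locus_map(self) -> pd.DataFrame:
        """Locus map of the observed (post-pooling) loci."""
        second = {j for _, j in self.duplicate_groups}
        keep = [k for k in range(self.n_loci) if k not in second]
        return self.locus_map.iloc[keep].copy()

    def validate(self) -> None:
        cn, ac = self.copy_number, self.alt_copies
        if cn.shape != ac.shape or cn.shape != (self.n_samples, self.n_loci):
            raise ValueError("copy_number/alt_copies shape mismatch")
        if cn.min() < 1 or cn.max() > 4:
            raise ValueError("copy_number must be in {1, 2, 3, 4}")
        if (ac < 0).any() or (ac > cn).any():
            raise ValueError("alt_copies must satisfy 0 <= alt_copies <= copy_number")
        for trait, eff in self.causal_effects.items():
            if not eff.index.isin(self.locus_map.index).all():
                raise ValueError(f"trait {trait!r}: causal locus not in locus_map")


@dataclass
class PhenotypeTable:
    """Observed phenotypes (NaN = missing) and the underlying genetic values."""

    values: pd.DataFrame
    genetic_values: pd.DataFrame


def _locus_layout(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign loci to chromosomes 0..n (0 = unanchored bin) with sorted positions."""
    n0 = int(round(config.unanchored_fraction * config.n_loci))
    rest = config.n_loci - n0
    per = np.full(config.n_chromosomes, rest // config.n_chromosomes)
    per[: rest % config.n_chromosomes] += 1
    chroms = np.concatenate(
        [np.zeros(n0, dtype=int)]
        + [np.full(per[c - 1], c) for c in range(1, config.n_chromosomes + 1)]
    )
    pos = np.empty(config.n_loci, dtype=np.int64)
    span = 60_000_000
    start = 0
    for c in range(0, config.n_chromosomes + 1):
        n_c = int((chroms == c).sum())
        p = np.sort(rng.choice(span, size=n_c, replace=False)) + 1
        pos[start : start + n_c] = p
        start += n_c
    ids = [f"{c}_{p}" for c, p in zip(chroms, pos)]
    return pd.DataFrame({"chrom": chroms.astype(str), "pos": pos}, index=ids)


def simulate_population(config: SimConfig) -> PopulationTruth:
    """Draw parents and diallel offspring with per-locus copy-number variation.

    Parents receive an independent copy number per locus from
    ``ploidy_fractions`` and alternative-allele copies from a binomial draw
    at the locus' ancestral allele frequency (uniform on
    ``ancestral_af_range``).  Gametes are phase-based: a parent's
    ``copy_number`` gene copies sit on that many of its four homologous
    phases (phase deletions account for the rest), and a gamete samples two
    phases without replacement, transmitting the copies - and the alleles -
    it finds there.  This keeps the copy-number distribution stable across
    generations (a gamete carries ``copy_number / 2`` copies in
    expectation) without modelling recombination or double reduction.
    Offspring are assigned round-robin over all unordered parent pairs of
    the diallel.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    locus_map = _locus_layout(config, rng)
    L = config.n_loci
    af = rng.uniform(*config.ancestral_af_range, size=L)

    cn_levels = np.array(sorted(config.ploidy_fractions), dtype=np.int8)
    cn_probs = np.array([config.ploidy_fractions[int(c)] for c in cn_levels])
    P = config.n_parents
    cn_par = rng.choice(cn_levels, p=cn_probs, size=(P, L))
    alt_par = rng.binomial(cn_par, af[None, :]).astype(np.int8)

    pairs = [(a, b) for a in range(P) for b in range(a + 1, P)]
    n_off = config.n_offspring
    cn_off = np.empty((n_off, L), dtype=np.int8)
    alt_off = np.empty((n_off, L), dtype=np.int8)
    def gamete(parent: int) -> tuple[np.ndarray, np.ndarray]:
        cn, alt = cn_par[parent], alt_par[parent]
        # copies transmitted: two of four phases, cn of which carry a copy
        t = rng.hypergeometric(cn, 4 - cn, 2)
        # alt copies among those transmitted
        g = rng.hypergeometric(alt, cn - alt, t)
        return t, g

    for o in range(n_off):
        a, b = pairs[o % len(pairs)]
        ta, ga = gamete(a)
        tb, gb = gamete(b)
        cn = ta + tb
        alt = ga + gb
        # both gametes may carry zero copies at a low-copy locus; restore one
        zero = cn == 0
        if zero.any():
            cn[zero] = 1
            alt[zero] = rng.binomial(1, af[zero])
        cn_off[o] = cn
        alt_off[o] = alt

    dup: list[tuple[int, int]] = []
    n_pairs = int(round(config.duplicate_fraction * L / 2))
    if n_pairs:
        chosen = rng.choice(L, size=2 * n_pairs, replace=False)
        dup = [(int(min(i, j)), int(max(i, j)))
               for i, j in zip(chosen[:n_pairs], chosen[n_pairs:])]

    sample_ids = [f"P{p + 1:02d}" for p in range(P)] + [
        f"O{o + 1:04d}" for o in range(n_off)
    ]
    truth = PopulationTruth(
        sample_ids=sample_ids,
        locus_map=locus_map,
        copy_number=np.vstack([cn_par, cn_off]),
        alt_copies=np.vstack([alt_par, alt_off]),
        duplicate_groups=dup,
        n_parents=P,
    )
    truth.validate()
    return truth


def _truncated_nb(mean_target: float, lo: int, hi: int, dispersion: float):
    """Support grid and probabilities of a negative binomial conditioned on
    [lo, hi], with the untruncated mean tuned so the conditional mean hits
    ``mean_target``."""
    grid = np.arange(lo, hi + 1)

    def cond_mean(mu: float) -> float:
        p = dispersion / (dispersion + mu)
        w = stats.nbinom.pmf(grid, dispersion, p)
        return float((grid * w).sum() / w.sum())

    lo_mu, hi_mu = 0.1, 4.0 * hi
    if not cond_mean(lo_mu) <= mean_target <= cond_mean(hi_mu):
        # degenerate window; fall back to uniform over the window
        return grid, np.full(grid.size, 1.0 / grid.size)
    for _ in range(80):
        mid = 0.5 * (lo_mu + hi_mu)
        if cond_mean(mid) < mean_target:
            lo_mu = mid
        else:
            hi_mu = mid
    p = dispersion / (dispersion + 0.5 * (lo_mu + hi_mu))
    w = stats.nbinom.pmf(grid, dispersion, p)
    return grid, w / w.sum()


def simulate_read_counts(truth: PopulationTruth, config: SimConfig) -> ReadCountMatrix:
    """Binomial read sampling of the true allele fractions.

    Depth is drawn per sample x truth locus from a negative binomial
    truncated to ``depth_range`` (conditional mean = ``mean_depth``).  The
    sampled alternative-read probability is the true allele fraction pushed
    toward the interior by the sequencing error rate:
    ``q = af * (1 - eps) + (1 - af) * eps``.  Counts of duplicate-mapped
    truth loci are summed into their shared observed locus.
    """
    config.validate()
    if truth.n_loci != config.n_loci:
        raise ValueError(
            f"truth has {truth.n_loci} loci but config expects {config.n_loci}"
        )
    rng = np.random.default_rng([config.seed, 1])
    grid, probs = _truncated_nb(
        config.mean_depth, config.depth_range[0], config.depth_range[1],
        config.depth_dispersion,
    )
    S, L = truth.n_samples, truth.n_loci
    depth = rng.choice(grid, p=probs, size=(S, L)).astype(np.int32)
    eps = config.error_rate
    q = truth.true_af * (1.0 - eps) + (1.0 - truth.true_af) * eps
    alt = rng.binomial(depth, q).astype(np.int32)
    ref = depth - alt

    obs_of = truth.observed_of_truth
    second = {j for _, j in truth.duplicate_groups}
    keep = [k for k in range(L) if k not in second]
    alt_obs = alt[:, keep].copy()
    ref_obs = ref[:, keep].copy()
    for i, j in truth.duplicate_groups:
        alt_obs[:, obs_of[i]] += alt[:, j]
        ref_obs[:, obs_of[i]] += ref[:, j]

    lm = truth.observed_locus_map()
    lm = lm.assign(ref="A", alt="B")
    return ReadCountMatrix(
        sample_ids=list(truth.sample_ids),
        locus_map=lm,
        ref_count=ref_obs,
        alt_count=alt_obs,
    )


def simulate_phenotypes(truth: PopulationTruth, config: SimConfig) -> PhenotypeTable:
    """Additive phenotypes on the true allele fractions.

    Genetic value = major-QTL part (``n_qtl`` loci, effects standardized to
    ``1 - polygenic_share`` of genetic variance) + polygenic part (small
    effects at every polymorphic locus).  Noise is residualized against the
    genetic value and rescaled so the realized variance ratio equals ``h2``
    exactly; traits are standardized to mean 0, variance 1.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    X = truth.true_af
    n = truth.n_samples
    Xc = X - X.mean(axis=0, keepdims=True)
    polymorphic = Xc.std(axis=0) > 1e-12

    values = {}
    genetic = {}
    for trait in config.traits:
        qtl_share = 0.0 if trait.n_qtl == 0 else 1.0 - trait.polygenic_share
        g = np.zeros(n)
        effects = pd.Series(dtype=float)
        if trait.n_qtl > 0 and qtl_share > 0:
            cand = np.flatnonzero(polymorphic)
            idx = rng.choice(cand, size=min(trait.n_qtl, cand.size), replace=False)
            b = rng.normal(size=idx.size)
            gq = Xc[:, idx] @ b
            sd = gq.std()
            if sd > 0:
                scale = np.sqrt(qtl_share) / sd
                gq *= scale
                b *= scale
            g += gq
            effects = pd.Series(b, index=truth.locus_map.index[idx])
        poly_share = 1.0 - qtl_share
        if poly_share > 0:
            bp = rng.normal(size=int(polymorphic.sum()))
            gp = Xc[:, polymorphic] @ bp
            sd = gp.std()
            if sd > 0:
                gp *= np.sqrt(poly_share) / sd
            g += gp
        gsd = g.std()
        if gsd > 0:
            g /= gsd

        e = rng.normal(size=n)
        if gsd > 0:
            # orthogonalize noise against g so the realized ratio is exact
            e -= g * (e @ g) / (g @ g)
        esd = e.std()
        if esd > 0:
            e /= esd
        h2 = trait.h2
        y = np.sqrt(h2) * g + np.sqrt(1.0 - h2) * e
        sd_y = y.std()
        if sd_y > 0:
            y = (y - y.mean()) / sd_y
        if trait.missing_rate > 0:
            mask = rng.random(n) < trait.missing_rate
            y = y.astype(float)
            y[mask] = np.nan
        values[trait.name] = y
        genetic[trait.name] = np.sqrt(h2) * g
        truth.causal_effects[trait.name] = effects

    idx = pd.Index(truth.sample_ids, name="sample_id")
    return PhenotypeTable(
        values=pd.DataFrame(values, index=idx),
        genetic_values=pd.DataFrame(genetic, index=idx),
    )
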