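"""Genotype encodings and the shared filter cascade."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import tetradose as td
from conftest import make_counts


class TestAlleleFrequencyGenotypes:
    def test_simple_ratios(self):
        counts = make_counts([[9, 0, 3]], [[3, 12, 2]])
        g = td.allele_frequency_genotypes(counts, min_depth=5)
        assert g.values[0, 0] == pytest.approx(0.25)   # 3 / 12
        assert g.values[0, 1] == pytest.approx(1.0)    # 12 / 12
        assert np.isnan(g.values[0, 2])                # depth 5 is not > 5
        assert g.encoding == "continuous"

    def test_all_zero_depth_warns_not_raises(self):
        counts = make_counts(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.warns(UserWarning, match="all-missing"):
            g = td.allele_frequency_genotypes(counts)
        assert np.isnan(g.values).all()


class TestTetraploidDosages:
    def test_extreme_and_exact_ratios(self):
        counts = make_counts([[0, 15, 5]], [[20, 5, 3]])
        g = td.call_tetraploid_dosages(counts, error_rate=0.01, min_depth=0)
        assert g.values[0, 0] == 1.0    # 20/20 alt -> quadruplex
        assert g.values[0, 1] == 0.25   # ratio exactly 0.25 -> simplex
        # ratio 0.375: binom(8,3;0.5)=0.21875 > binom(8,3;0.25)~0.2076
        assert g.values[0, 2] == 0.50
        assert g.encoding == "tetraploid"

    def test_depth_masking(self):
        counts = make_counts([[3]], [[2]])
        g = td.call_tetraploid_dosages(counts, min_depth=5)
        assert np.isnan(g.values[0, 0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(ref=st.integers(0, 200), alt=st.integers(0, 200),
           eps=st.floats(0.001, 0.2))
    def test_matches_brute_force_likelihood(self, ref, alt, eps):
        """The vectorized caller equals an explicit pmf argmax with low-dosage ties."""
        counts = make_counts([[ref]], [[alt]])
        g = td.call_tetraploid_dosages(counts, error_rate=eps, min_depth=0)
        n = ref + alt
        if n == 0:
            return
        means = [eps, 0.25, 0.5, 0.75, 1 - eps]
        lik = [stats.binom.pmf(alt, n, q) for q in means]
        best = int(np.argmax(lik))  # argmax takes the first = lowest dosage
        assert g.values[0, 0] == pytest.approx(best / 4)

    def test_invalid_error_rate(self):
        counts = make_counts([[1]], [[1]])
        with pytest.raises(ValueError, match="error_rate"):
            td.call_tetraploid_dosages(counts, error_rate=0.3)

    def test_encodings_agree_at_high_depth(self):
        """At depth -> infinity the dosage call rounds the continuous value
        to the nearest class, so they differ by at most 0.125 + eps."""
        rng = np.random.default_rng(0)
        af = rng.choice([0, 0.25, 1 / 3, 0.5, 2 / 3, 0.75, 1.0], size=(5, 200))
        depth = 2000
        alt = rng.binomial(depth, np.clip(af, 0.005, 0.995))
        counts = make_counts(depth - alt, alt)
        cont = td.allele_frequency_genotypes(counts, min_depth=0)
        tet = td.call_tetraploid_dosages(counts, error_rate=0.01, min_depth=0)
        diff = np.abs(cont.values - tet.values)
        assert np.nanmax(diff) <= 0.125 + 0.01 + 0.02  # small binomial slack


def _toy_filter_fixture():
    """4 samples x 6 loci; locus 5 is monomorphic in the tetraploid encoding
    only, locus 0 fails MAF, locus 2 exceeds the depth window."""
    depth = np.array([
        [20, 20, 90, 20, 20, 20],
        [20, 20, 90, 20, 20, 20],
        [20, 20, 90, 20, 20, 20],
        [20, 20, 90, 20,  4, 20],
    ])
    af_true = np.array([
        [0.0, 0.25, 0.5, 0.75, 0.5, 0.50],
        [0.0, 0.50, 0.5, 0.25, 0.5, 0.55],
        [0.0, 0.75, 0.5, 0.50, 0.5, 0.45],
        [0.0, 0.25, 0.5, 0.25, 0.5, 0.50],
    ])
    alt = np.rint(depth * af_true).astype(int)
    return make_counts(depth - alt, alt)


def brute_force_filter_counts(af, tet, counts, cfg):
    """Independent re-scan of the cascade with plain Python loops."""
    va = af.values.copy()
    vt = tet.values.copy()
    depth = counts.depth
    n_s, n_l = va.shape
    for i in range(n_s):
        for k in range(n_l):
            if depth[i, k] <= cfg.min_genotype_depth:
                va[i, k] = np.nan
                vt[i, k] = np.nan
    samples = list(range(n_s))
    loci = list(range(n_l))
    out = [("genotype_depth_mask", len(samples), len(loci))]
    loci = [k for k in loci
            if cfg.locus_depth_window[0]
            <= sum(depth[i, k] for i in samples) / len(samples)
            <= cfg.locus_depth_window[1]]
    out.append(("locus_depth_window", len(samples), len(loci)))
    kept = []
    for k in loci:
        tot = sum(depth[i, k] for i in samples)
        a = sum(counts.alt_count[i, k] for i in samples)
        if tot > 0 and cfg.maf_bounds[0] < a / tot < cfg.maf_bounds[1]:
            kept.append(k)
    loci = kept
    out.append(("locus_maf", len(samples), len(loci)))
    loci = [k for k in loci
            if np.mean([np.isnan(va[i, k]) for i in samples])
            <= cfg.max_locus_missing]
    out.append(("locus_missing", len(samples), len(loci)))
    samples = [i for i in samples
               if np.mean([np.isnan(va[i, k]) for k in loci])
               < cfg.max_sample_missing]
    out.append(("sample_missing", len(samples), len(loci)))

    def mono(vals, k):
        obs = [vals[i, k] for i in samples if not np.isnan(vals[i, k])]
        return len(set(obs)) <= 1

    loci = [k for k in loci if not (mono(va, k) or mono(vt, k))]
    out.append(("monomorphic_in_either", len(samples), len(loci)))
    return out


class TestFilterCascade:
    def test_toy_fixture_matches_brute_force(self):
        counts = _toy_filter_fixture()
        af = td.allele_frequency_genotypes(counts)
        tet = td.call_tetraploid_dosages(counts)
        cfg = td.FilterConfig()
        af_f, tet_f, report = td.apply_filters(af, tet, counts, cfg)
        expected = brute_force_filter_counts(af, tet, counts, cfg)
        got = [(s["step"], s["n_samples"], s["n_loci"]) for s in report.steps]
        assert got == expected
        # locus 5 is polymorphic continuously but monomorphic as dosages
        assert report.steps[-1]["step"] == "monomorphic_in_either"
        assert "1_105" not in af_f.locus_map.index
        assert list(af_f.locus_map.index) == list(tet_f.locus_map.index)

    def test_simulated_panel_matches_brute_force(self, small_panel):
        cfg_sim, truth, counts, _ = small_panel
        sub = counts.subset(samples=np.arange(30), loci=np.arange(120))
        af = td.allele_frequency_genotypes(sub)
        tet = td.call_tetraploid_dosages(sub)
        cfg = td.FilterConfig()
        _, _, report = td.apply_filters(af, tet, sub, cfg)
        expected = brute_force_filter_counts(af, tet, sub, cfg)
        got = [(s["step"], s["n_samples"], s["n_loci"]) for s in report.steps]
        assert got == expected

    def test_open_config_is_identity(self):
        counts = make_counts([[5, 8], [7, 2]], [[5, 2], [3, 8]])
        af = td.allele_frequency_genotypes(counts, min_depth=0)
        tet = td.call_tetraploid_dosages(counts, min_depth=0)
        cfg = td.FilterConfig(maf_bounds=(0.0, 1.0), max_locus_missing=1.0,
                              min_genotype_depth=0,
                              locus_depth_window=(0, np.inf),
                              max_sample_missing=1.0,
                              drop_monomorphic_in_either=False)
        af_f, tet_f, _ = td.apply_filters(af, tet, counts, cfg)
        assert np.array_equal(af_f.values, af.values, equal_nan=True)
        assert np.array_equal(tet_f.values, tet.values, equal_nan=True)

    def test_high_missing_sample_removed(self):
        depth = np.full((3, 10), 20)
        depth[0, :8] = 2  # sample 0 missing 80% after depth masking
        alt = (depth * 0.5).astype(int)
        alt[:, 0] = 0
        alt[:, 0] = [2, 8, 14]  # keep locus 0 polymorphic
        counts = make_counts(depth - alt, alt)
        af = td.allele_frequency_genotypes(counts)
        tet = td.call_tetraploid_dosages(counts)
        cfg = td.FilterConfig(locus_depth_window=(0, 100), maf_bounds=(0.0, 1.0),
                              max_locus_missing=1.0, max_sample_missing=0.7,
                              drop_monomorphic_in_either=False)
        af_f, _, _ = td.apply_filters(af, tet, counts, cfg)
        assert "S0" not in af_f.sample_ids
        assert len(af_f.sample_ids) == 2

    def test_exhausting_filter_raises_named_step(self):
        counts = make_counts([[10, 10]], [[10, 10]])
        af = td.allele_frequency_genotypes(counts, min_depth=0)
        tet = td.call_tetraploid_dosages(counts, min_depth=0)
        cfg = td.FilterConfig(locus_depth_window=(100, 200))
        with pytest.raises(td.EmptyFilterResult, match="locus_depth_window"):
            td.apply_filters(af, tet, counts, cfg)

    def test_outputs_share_sample_and_locus_sets(self, filtered_panel):
        *_, af_f, tet_f, report = filtered_panel
        assert af_f.sample_ids == tet_f.sample_ids
        assert list(af_f.locus_map.index) == list(tet_f.locus_map.index)
        assert af_f.n_loci == report.final_loci
        assert af_f.n_samples == report.final_samples
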