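import numpy as np
import pandas as pd
import pytest

import tetradose as td


def make_counts(ref, alt, chrom=None, pos=None, sample_prefix="S"):
    """Small ReadCountMatrix from explicit count arrays (samples x loci)."""
    ref = np.asarray(ref, dtype=np.int32)
    alt = np.asarray(alt, dtype=np.int32)
    n_s, n_l = ref.shape
    chrom = chrom or ["1"] * n_l
    pos = pos or list(range(100, 100 + n_l))
    lm = pd.DataFrame({"chrom": [str(c) for c in chrom], "pos": pos},
                      index=[f"{c}_{p}" for c, p in zip(chrom, pos)])
    return td.ReadCountMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(n_s)],
        locus_map=lm, ref_count=ref, alt_count=alt)


def make_genotypes(values, encoding="continuous", chrom=None, pos=None):
    values = np.asarray(values, dtype=float)
    n_s, n_l = values.shape
    chrom = chrom or ["1"] * n_l
    pos = pos or list(range(100, 100 + n_l))
    lm = pd.DataFrame({"chrom": [str(c) for c in chrom], "pos": pos},
                      index=[f"{c}_{p}" for c, p in zip(chrom, pos)])
    return td.GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n_s)],
        locus_map=lm, values=values, encoding=encoding)


@pytest.fixture(scope="session")
def small_panel():
    """A small mixed-ploidy panel shared by read-only tests."""
    cfg = td.SimConfig(n_parents=10, n_offspring=190, n_loci=800,
                       n_chromosomes=4, seed=42,
                       traits=(td.TraitSpec("poly", h2=0.5),
                               td.TraitSpec("qtl", h2=0.6, n_qtl=2,
                                            polygenic_share=0.5)))
    truth = td.simulate_population(cfg)
    counts = td.simulate_read_counts(truth, cfg)
    pheno = td.simulate_phenotypes(truth, cfg)
    return cfg, truth, counts, pheno


@pytest.fixture(scope="session")
def filtered_panel(small_panel):
    cfg, truth, counts, pheno = small_panel
    af = td.allele_frequency_genotypes(counts)
    tet = td.call_tetraploid_dosages(counts)
    af_f, tet_f, report = td.apply_filters(af, tet, counts)
    return cfg, truth, counts, pheno, af_f, tet_f, report
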