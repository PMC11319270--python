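"""GBLUP cross-validation: does forcing tetraploid dosages hurt prediction?

Fits single-trait GBLUP with the missing-data-weighted genomic relationship
matrix on both encodings of the same simulated panel and compares repeated
eightfold cross-validated accuracies with a paired t-test on Fisher
z-transformed correlations.
"""
import tetradose as td

cfg = td.SimConfig(n_offspring=400 - 18, n_loci=3000, seed=2,
                   traits=(td.TraitSpec("yield_like", h2=0.5),))
truth = td.simulate_population(cfg)
counts = td.simulate_read_counts(truth, cfg)
pheno = td.simulate_phenotypes(truth, cfg)
af = td.allele_frequency_genotypes(counts)
tet = td.call_tetraploid_dosages(counts)
af_f, tet_f, _ = td.apply_filters(af, tet, counts)
y = pheno.values.loc[af_f.sample_ids, "yield_like"]

cvs = {}
for geno in (af_f, tet_f):
    G = td.build_grm(geno)
    fit = td.fit_gblup(y, G)
    cv = td.cross_validate(y, G, n_folds=8, n_repeats=10, seed=3,
                           trait="yield_like", encoding=geno.encoding)
    cvs[geno.encoding] = cv
    print(f"{geno.encoding:<11} h2_hat={fit.h2:.3f}  "
          f"mean r={cv.mean_correlation:.3f}  mean bias={cv.mean_bias:.3f}")

test = td.compare_correlations(cvs["continuous"], cvs["tetraploid"])
diff = abs(cvs['continuous'].mean_correlation
           - cvs['tetraploid'].mean_correlation)
print(f"paired t-test (Fisher z): t={test.t:.2f}, df={test.df}, p={test.p:.3g}")
print(f"difference in mean r: {diff:.3f}")
print("\nr is the correlation between out-of-fold predicted breeding values")
print("and phenotypes; bias ~1 means calibrated predictions. Because the")
print("folds are paired, even a diminutive difference in r (here < 0.01)")
print("can be statistically significant - the practically relevant result")
print("is that the two encodings predict essentially equally well.")
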