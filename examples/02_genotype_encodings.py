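"""Two genotype encodings of one mixed-ploidy panel, plus the ratio histogram.

Simulates a small diallel panel whose gene copy number varies by locus
(1-4 copies), samples GBS-style read counts, and builds the two genotype
matrices the package compares: continuous allele fractions and forced
tetraploid dosage calls.  The heterozygous-ratio histogram shows the
dosage-class peaks - including the triploid 1/3 and 2/3 peaks a tetraploid
model cannot represent.
"""
import numpy as np

import tetradose as td

cfg = td.SimConfig(n_parents=18, n_offspring=300, n_loci=4000,
                   n_chromosomes=6, ploidy_fractions={3: 0.5, 4: 0.5},
                   depth_range=(20, 60), mean_depth=33.0,
                   duplicate_fraction=0.0, seed=11)
truth = td.simulate_population(cfg)
counts = td.simulate_read_counts(truth, cfg)
print(f"panel: {truth.n_samples} samples x {counts.n_loci} loci, "
      f"mean copy number {truth.copy_number.mean():.2f}, "
      f"mean depth {counts.depth.mean():.1f}")

af = td.allele_frequency_genotypes(counts)
tet = td.call_tetraploid_dosages(counts)
af_f, tet_f, report = td.apply_filters(af, tet, counts)
print("filter cascade (samples, loci):")
for s in report.steps:
    print(f"  {s['step']:<24} {s['n_samples']:>4} {s['n_loci']:>6}")

hist = td.heterozygous_ratio_histogram(af_f)
print(f"\nheterozygous genotypes in (0.1, 0.9): {hist.n_values}")
print("detected ratio peaks:", np.round(hist.peaks, 3))
print("expected for a 4x locus:", td.expected_peak_positions([4]))
print("expected for a 3x locus:",
      [round(p, 3) for p in td.expected_peak_positions([3])])
print("\nPeaks near 0.25/0.5/0.75 are tetraploid dosage classes; the peaks")
print("near 0.333 and 0.667 come from triploid loci that a forced")
print("tetraploid dosage call must shoehorn into the wrong class.")
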