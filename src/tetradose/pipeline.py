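"""End-to-end orchestration of the two parallel genotype-encoding pipelines.

One call to :func:`run_pipeline` takes read counts (simulated or from a VCF)
and phenotypes through genotyping (both encodings), the shared filter
cascade, full and LOCO relationship matrices, repeated cross-validated
GBLUP per trait and encoding with the paired encoding comparison, and a
LOCO mixed-model GWAS with genomic control - writing every artifact to a
run directory stamped with the configuration hash and seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .gblup import compare_correlations, cross_validate
from .genotyping import (FilterConfig, allele_frequency_genotypes,
                         apply_filters, call_tetraploid_dosages)
from .grm import build_grm, loco_grms
from .gwas import genomic_control, scan_report, single_marker_scan
from .simulate import (SimConfig, simulate_phenotypes, simulate_population,
                       simulate_read_counts)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("tetradose")


@dataclass
class RunConfig:
    """Configuration for a full two-encoding run.

    Either ``sim`` (synthetic inputs) or both ``vcf`` and ``phenotypes``
    (file inputs) must be provided.
    """

    out_dir: str | Path = "run"
    seed: int = 0
    sim: SimConfig | None = None
    vcf: str | Path | None = None
    phenotypes: str | Path | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    dosage_error_rate: float = 0.01
    min_genotype_depth: int = 5
    n_folds: int = 8
    n_repeats: int = 10
    alpha: float = 0.05
    run_gwas: bool = True
    make_plots: bool = False
    traits: list[str] | None = None  # default: every phenotype column

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "sim" in raw and raw["sim"] is not None:
            sim = raw["sim"]
            if "traits" in sim:
                from .simulate import TraitSpec
                sim["traits"] = tuple(TraitSpec(**t) for t in sim["traits"])
            if "ploidy_fractions" in sim:
                sim["ploidy_fractions"] = {int(k): float(v)
                                           for k, v in sim["ploidy_fractions"].items()}
            raw["sim"] = SimConfig(**sim)
        if "filters" in raw and raw["filters"] is not None:
            raw["filters"] = FilterConfig(**raw["filters"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output path is excluded
        so reruns into different directories stamp identically)."""
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)
                        if f.name != "out_dir"}
            if isinstance(obj, (tuple, list)):
                return [enc(x) for x in obj]
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, Path):
                return str(obj)
            return obj

        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def run_pipeline(config: RunConfig) -> Path:
    """Run both encoding pipelines and write all artifacts to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kw):
        log.info("stage %s", name)
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-labelled and re-raised
            raise PipelineError(name, exc) from exc

    # --- inputs ---------------------------------------------------------
    if config.sim is not None:
        sim = config.sim.with_(seed=config.seed)
        truth = stage("simulate_population", simulate_population, sim)
        counts = stage("simulate_read_counts", simulate_read_counts, truth, sim)
        pheno = stage("simulate_phenotypes", simulate_phenotypes, truth, sim).values
        stage("write_inputs", lambda: (
            tio.write_vcf(counts, out / "input" / "counts.vcf"),
            tio.write_truth_tsv(truth, out / "input" / "truth.tsv"),
            tio.write_phenotypes_tsv(pheno, out / "input" / "phenotypes.tsv"),
        ))
    elif config.vcf is not None and config.phenotypes is not None:
        counts, n_skipped = stage("read_vcf", tio.read_vcf_allele_depths, config.vcf)
        log.info("read %d samples x %d loci (%d records skipped)",
                 counts.n_samples, counts.n_loci, n_skipped)
        pheno = stage("read_phenotypes", tio.read_phenotypes_tsv, config.phenotypes)
        pheno = pheno.reindex(counts.sample_ids)
    else:
        raise ValueError("provide either sim or both vcf and phenotypes")

    # --- genotyping + filters ------------------------------------------
    af = stage("allele_frequency_genotypes", allele_frequency_genotypes,
               counts, config.min_genotype_depth)
    tet = stage("call_tetraploid_dosages", call_tetraploid_dosages,
                counts, config.dosage_error_rate, config.min_genotype_depth)
    af, tet, report = stage("apply_filters", apply_filters, af, tet, counts,
                            config.filters)
    geno_dir = out / "genotypes"
    tio.write_genotype_tsv(af, geno_dir / "continuous.tsv")
    tio.write_genotype_tsv(tet, geno_dir / "tetraploid.tsv")
    report.to_json(geno_dir / "filter_report.json")
    log.info("filters: %d samples x %d loci survive",
             report.final_samples, report.final_loci)

    pheno = pheno.loc[af.sample_ids]
    trait_names = config.traits or list(pheno.columns)
    encodings = {"continuous": af, "tetraploid": tet}

    # --- relationship matrices -----------------------------------------
    grms = {}
    locos = {}
    for name, geno in encodings.items():
        grms[name] = stage(f"grm_{name}", build_grm, geno)
        tio.write_grm_tsv(grms[name], out / "grm" / f"{name}_full.tsv")
        if config.run_gwas:
            locos[name] = stage(f"loco_{name}", loco_grms, geno)
            for c, g in locos[name].items():
                tio.write_grm_tsv(g, out / "grm" / f"{name}_loco_{c}.tsv")

    # --- genomic prediction --------------------------------------------
    cv_summary = {}
    for trait in trait_names:
        y = pheno[trait]
        cvs = {}
        for name, geno in encodings.items():
            cvs[name] = stage(
                f"cv_{trait}_{name}", cross_validate, y, grms[name],
                config.n_folds, config.n_repeats, config.seed,
                trait=trait, encoding=name)
        comp = compare_correlations(cvs["continuous"], cvs["tetraploid"])
        cv_summary[trait] = {
            name: {
                "correlations": [round(float(r), 10) for r in cv.correlations],
                "mean_correlation": round(cv.mean_correlation, 10),
                "bias": [round(float(b), 10) for b in cv.bias],
                "mean_bias": round(cv.mean_bias, 10),
            } for name, cv in cvs.items()
        }
        cv_summary[trait]["paired_test"] = {
            "mean_z_difference": round(comp.mean_difference, 10),
            "t": None if np.isinf(comp.t) else round(comp.t, 10),
            "df": comp.df,
            "p": round(comp.p, 12),
        }
    with open(out / "prediction.json", "w") as fh:
        json.dump(cv_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    # --- GWAS -----------------------------------------------------------
    if config.run_gwas:
        gwas_summary = {}
        for trait in trait_names:
            y = pheno[trait]
            for name, geno in encodings.items():
                res = stage(f"gwas_{trait}_{name}", single_marker_scan,
                            y, geno, locos[name], config.alpha)
                res = genomic_control(res)
                prefix = out / "gwas" / f"{trait}_{name}_"
                scan_report(res, prefix, make_plots=config.make_plots)
                gwas_summary[f"{trait}/{name}"] = {
                    "lambda_gc": round(float(res.lambda_gc), 10),
                    "bonferroni": res.bonferroni,
                    "n_markers": res.n_markers,
                    "n_significant": int(len(res.significant())),
                }
        with open(out / "gwas" / "summary.json", "w") as fh:
            json.dump(gwas_summary, fh, indent=2, sort_keys=True)
            fh.write("\n")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples": report.final_samples,
        "n_loci": report.final_loci,
        "traits": trait_names,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
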