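"""End-to-end orchestration: demo scenario generation and the full run.

``make_demo`` writes a self-contained synthetic study to disk — an
EHG-like and a European-farmer-like European source, a Nganasan-like
Siberian source, and an admixed target population created g generations
ago — as EIGENSTRAT triplets, per-individual pileups and a YAML scenario
descriptor.  ``run_pipeline`` then executes the analysis stages (calling,
QC, sex typing, damage profiling, f-statistics, qpAdm search, LD dating)
and emits a versioned JSON report.  The pipeline is a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fstats, qpadm
from .dating import AdmixtureLdDecay
from .formats import GenotypeMatrix, read_eigenstrat, read_pileup, write_eigenstrat, write_pileup
from .genotyping import CallerConfig, call_matrix, damage_profile, qc_min_snps
from .sexdet import sex_from_pileup
from .synthetic import (AdmixtureEvent, PopulationModel, ReadSimParams,
                        default_panel, diploids_from_haplotypes,
                        haplotypes_from_freqs, simulate_admixture_haplotypes,
                        simulate_freqs, simulate_genotypes, simulate_reads)

logger = logging.getLogger(__name__)

REPORT_SCHEMA = 1


@dataclass
class RunConfig:
    prefix: str                        # EIGENSTRAT prefix of called genotypes
    out_dir: str
    seed: int = 0
    min_base_quality: int = 30
    min_mapping_quality: int = 30
    trim_bases: int = 2
    min_snps: int = 15_000
    p_cutoff: float = 0.05
    min_fit_distance_cm: float = 1.0
    generation_time: float = 29.0
    stages: tuple[str, ...] = ("qc", "fstats", "qpadm", "dating")
    target: str | None = None
    sources: tuple[str, ...] = ()
    rights: tuple[str, ...] = ()
    dating_refs: tuple[str, str] | None = None
    sample_age_bp: float = 0.0
    sample_age_se: float = 0.0


def make_demo(out_dir: str | Path, seed: int = 0, n_sites: int = 3000,
              n_chrom: int = 3, alpha: float = 0.4, g: int = 17,
              n_target: int = 60, mean_depth: float = 5.0) -> dict:
    """Write a synthetic admixture study and return the scenario dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    panel = default_panel(n_chrom=n_chrom, sites_per_chrom=n_sites // n_chrom,
                          seed=seed)
    # two source clades, each carrying a related right population, so the
    # outgroup set can tell the ancestries apart (qpAdm identifiability)
    model = PopulationModel(
        populations=[("Outgroup", 0.25),
                     ("SibAnc", 0.06), ("EuroAnc", 0.06),
                     ("Siberian", 0.05, "SibAnc"), ("SibRight", 0.05, "SibAnc"),
                     ("EuroHG", 0.05, "EuroAnc"), ("EuroRight", 0.05, "EuroAnc"),
                     ("Farmer", 0.08, "EuroAnc"), ("ExtraRight", 0.12)])
    freqs = simulate_freqs(model, len(panel), seed=rng.integers(2**31))
    ref_pops = ["Outgroup", "Siberian", "SibRight", "EuroHG", "EuroRight",
                "Farmer", "ExtraRight"]
    refs = simulate_genotypes({k: freqs[k] for k in ref_pops},
                              n_per_pop=25, seed=rng.integers(2**31),
                              panel=panel)
    write_eigenstrat(refs, out / "references")

    pool_a = haplotypes_from_freqs(freqs["Siberian"], 200, panel,
                                   seed=rng.integers(2**31))
    pool_b = haplotypes_from_freqs(freqs["EuroHG"], 200, panel,
                                   seed=rng.integers(2**31))
    admixed = simulate_admixture_haplotypes(pool_a, pool_b, alpha, g,
                                            2 * n_target,
                                            seed=rng.integers(2**31))
    target = diploids_from_haplotypes(admixed, population="Target")
    write_eigenstrat(target, out / "target")
    combined = GenotypeMatrix(panel, refs.individuals + target.individuals,
                              np.concatenate([refs.calls, target.calls]))
    write_eigenstrat(combined, out / "combined")

    params = ReadSimParams(mean_depth=mean_depth, error_rate=0.001,
                           deamination_amplitude=0.3, deamination_decay=0.5,
                           seed=seed)
    pileup_dir = out / "pileups"
    pileup_dir.mkdir(exist_ok=True)
    for i in range(min(3, target.n_individuals)):
        sites = simulate_reads(target.calls[i], panel, params,
                               seed=rng.integers(2**31))
        write_pileup(sites, pileup_dir / f"{target.individuals[i].id}.pileup")

    scenario = {
        "seed": int(seed), "alpha": float(alpha), "generations": int(g),
        "n_sites": int(len(panel)), "panel_chromosomes": int(n_chrom),
        "target": "Target", "sources": ["Siberian", "EuroHG"],
        "rights": ["Outgroup", "SibRight", "EuroRight", "ExtraRight"],
        "populations": ref_pops,
        "files": {"references": "references", "target": "target",
                  "combined": "combined", "pileups": "pileups"},
    }
    with open(out / "scenario.yaml", "w") as fh:
        yaml.safe_dump(scenario, fh, sort_keys=False)
    return scenario


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages and write report.json to the out dir."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema": REPORT_SCHEMA, "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stages": {},
    }
    try:
        matrix = read_eigenstrat(config.prefix)
        report["n_individuals"] = matrix.n_individuals
        report["n_sites"] = len(matrix.panel)

        if "qc" in config.stages:
            qc = qc_min_snps(matrix, threshold=config.min_snps)
            report["stages"]["qc"] = {
                "threshold": config.min_snps,
                "pass": {k: bool(v) for k, v in qc.items()},
            }
        freqs = fstats.allele_freqs(matrix)
        if "fstats" in config.stages and config.target and len(config.sources) >= 2:
            r3 = fstats.f3(freqs, config.target, config.sources[0],
                           config.sources[1])
            report["stages"]["f3"] = {
                "populations": list(r3.populations), "estimate": r3.estimate,
                "se": r3.se, "z": r3.z, "n_snps": r3.n_snps}
        if "qpadm" in config.stages and config.target and config.sources \
                and config.rights:
            search = qpadm.model_search(
                freqs, config.target, list(config.sources),
                [("OG1", list(config.rights))], p_threshold=config.p_cutoff,
                seed=config.seed)
            sel = search.selected
            report["stages"]["qpadm"] = {
                "found": search.found,
                "ledger": search.ledger.to_dict(orient="records"),
                "selected": None if sel is None else {
                    "sources": sel.sources,
                    "weights": [float(w) for w in sel.weights],
                    "weight_se": [float(s) for s in sel.weight_se],
                    "p": sel.p_value, "dof": sel.dof},
            }
        if "dating" in config.stages and config.dating_refs and config.target:
            r1 = freqs.freq[freqs.row(config.dating_refs[0])]
            r2 = freqs.freq[freqs.row(config.dating_refs[1])]
            res = AdmixtureLdDecay(
                matrix, r1, r2, target_population=config.target,
                ref_labels=config.dating_refs,
                min_distance_cm=config.min_fit_distance_cm,
            ).fit(sample_age_bp=config.sample_age_bp,
                  sample_age_se=config.sample_age_se,
                  generation_time=config.generation_time)
            report["stages"]["dating"] = {
                "generations": res.fit.generations,
                "se_generations": res.fit.se_generations,
                "ok": res.fit.ok,
                "date_ybp": res.date_ybp, "date_se": res.date_se}
    except Exception as exc:
        report["error"] = f"{type(exc).__name__}: {exc}"
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        raise
    logger.info("pipeline finished in %.2f s", time.time() - t0)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
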