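"""Pseudohaploid genotype calling from pileups, damage profiling and QC.

The caller mimics random-read genotyping of low-coverage ancient samples:
after base/mapping-quality filtering and end-trimming, exactly one read is
drawn per site and the individual is treated as homozygous for the base on
that read.  Bases matching neither panel allele are conservatively recorded
as missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats import MISSING, GenotypeMatrix, Individual, PileupSite, SnpPanel

logger = logging.getLogger(__name__)

TRANSITIONS = (frozenset(("C", "T")), frozenset(("G", "A")))


@dataclass
class CallerConfig:
    min_base_quality: int = 30
    min_mapping_quality: int = 30
    transversions_only: bool = False
    trim_bases: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.min_mapping_quality < 0:
            raise ValueError("quality thresholds must be >= 0")
        if self.trim_bases < 0:
            raise ValueError("trim_bases must be >= 0")


def _passes(obs, config: CallerConfig) -> bool:
    if obs.base_quality < config.min_base_quality:
        return False
    if obs.mapping_quality < config.min_mapping_quality:
        return False
    if config.trim_bases and obs.read_position >= 0 and obs.read_length > 0:
        if obs.read_position < config.trim_bases:
            return False
        if obs.read_position >= obs.read_length - config.trim_bases:
            return False
    return True


def call_pseudohaploid(pileup: Iterable[PileupSite], panel: SnpPanel,
                       config: CallerConfig | None = None,
                       individual: str | int = 0) -> np.ndarray:
    """Random-read pseudohaploid calls for one individual.

    Observations failing the BQ/MQ thresholds, or lying within
    ``trim_bases`` of either read end, are discarded first; one surviving
    observation is then drawn uniformly.  The call is 2 if its base equals
    allele1, 0 if allele2, and missing otherwise (including N, or when
    nothing survives).  The draw RNG is keyed by (seed, individual, site
    index) so results do not depend on pileup iteration order.
    """
    config = config or CallerConfig()
    index = panel.site_index()
    calls = np.full(len(panel), MISSING, dtype=np.int8)
    ind_key = abs(hash(str(individual))) % (2**31)
    for site in pileup:
        key = (site.chrom, site.ppos)
        j = index.get(key)
        if j is None:
            logger.debug("pileup site %s:%d absent from panel; skipped",
                         site.chrom, site.ppos)
            continue
        surviving = [o for o in site.observations if _passes(o, config)]
        if not surviving:
            continue
        if len(surviving) == 1:
            pick = surviving[0]
        else:
            rng = np.random.default_rng([config.seed, ind_key, j])
            pick = surviving[int(rng.integers(len(surviving)))]
        if pick.base == panel.allele1[j]:
            calls[j] = 2
        elif pick.base == panel.allele2[j]:
            calls[j] = 0
    if config.transversions_only:
        calls[~apply_transversion_mask(panel)] = MISSING
    return calls


def call_matrix(pileups: dict[str, Iterable[PileupSite]], panel: SnpPanel,
                populations: dict[str, str] | None = None,
                config: CallerConfig | None = None) -> GenotypeMatrix:
    """Call several individuals' pileups into one pseudohaploid matrix."""
    populations = populations or {}
    individuals = []
    rows = []
    for ind_id, pileup in pileups.items():
        rows.append(call_pseudohaploid(pileup, panel, config, individual=ind_id))
        individuals.append(Individual(id=ind_id,
                                      population=populations.get(ind_id, ind_id),
                                      ploidy_mode="pseudohaploid"))
    calls = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(panel)), np.int8)
    return GenotypeMatrix(panel, individuals, calls)


def apply_transversion_mask(panel: SnpPanel) -> np.ndarray:
    """True where the site is a transversion (kept); C/T and G/A are masked.

    Restricting to transversions removes post-mortem C->T / G->A damage
    artefacts at the cost of ~2/3 of the panel.
    """
    mask = np.ones(len(panel), dtype=bool)
    for j in range(len(panel)):
        if frozenset((panel.allele1[j], panel.allele2[j])) in TRANSITIONS:
            mask[j] = False
    return mask


@dataclass
class DamageProfile:
    """Terminal substitution frequencies by distance from the read ends.

    ``ct5`` holds the C->T frequency at distance i from the 5' end (in the
    read's own orientation); ``ga3`` the G->A frequency from the 3' end.
    Positions never observed have frequency NaN, not 0.
    """

    ct5: np.ndarray
    ga3: np.ndarray
    n_ct5: np.ndarray
    n_ga3: np.ndarray

    @property
    def window(self) -> int:
        return len(self.ct5)


def damage_profile(pileup: Iterable[PileupSite], window: int = 25) -> DamageProfile:
    """Count reference-C positions read as T near the 5' end (and G->A, 3').

    On minus-strand reads the read's own orientation is the reverse
    complement of the reference, so a 5' C->T appears as reference-G read
    as A; the counting below folds both strands into read coordinates.
    """
    ct_num = np.zeros(window)
    ct_den = np.zeros(window)
    ga_num = np.zeros(window)
    ga_den = np.zeros(window)
    for site in pileup:
        ref = site.ref
        for o in site.observations:
            if o.read_position < 0 or o.read_length <= 0:
                continue
            d5 = o.read_position
            d3 = o.read_length - 1 - o.read_position
            if o.strand == "+":
                ref_read, base_read = ref, o.base
            else:
                ref_read = _complement(ref)
                base_read = _complement(o.base)
            if d5 < window and ref_read == "C":
                ct_den[d5] += 1
                if base_read == "T":
                    ct_num[d5] += 1
            if d3 < window and ref_read == "G":
                ga_den[d3] += 1
                if base_read == "A":
                    ga_num[d3] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ct5 = np.where(ct_den > 0, ct_num / np.maximum(ct_den, 1), np.nan)
        ga3 = np.where(ga_den > 0, ga_num / np.maximum(ga_den, 1), np.nan)
    return DamageProfile(ct5=ct5, ga3=ga3, n_ct5=ct_den, n_ga3=ga_den)


def _complement(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}.get(base, "N")


def phenotype_table(pileup: Iterable[PileupSite], panel: SnpPanel,
                    snp_ids: Sequence[str] | None = None,
                    config: CallerConfig | None = None) -> pd.DataFrame:
    """Raw allele read counts at phenotype-informative SNPs (no random draw).

    Returns one row per requested SNP with counts of reads supporting
    allele1, allele2 and any other base, after BQ/MQ filtering.
    """
    config = config or CallerConfig()
    index = panel.site_index()
    wanted = None
    if snp_ids is not None:
        id_to_j = {panel.ids[j]: j for j in range(len(panel))}
        missing_ids = [s for s in snp_ids if s not in id_to_j]
        if missing_ids:
            raise KeyError(f"SNPs not in panel: {missing_ids[:5]}")
        wanted = {id_to_j[s] for s in snp_ids}
    counts: dict[int, list[int]] = {}
    for site in pileup:
        j = index.get((site.chrom, site.ppos))
        if j is None or (wanted is not None and j not in wanted):
            continue
        row = counts.setdefault(j, [0, 0, 0])
        for o in site.observations:
            if o.base_quality < config.min_base_quality:
                continue
            if o.mapping_quality < config.min_mapping_quality:
                continue
            if o.base == panel.allele1[j]:
                row[0] += 1
            elif o.base == panel.allele2[j]:
                row[1] += 1
            else:
                row[2] += 1
    rows = []
    order = sorted(wanted) if wanted is not None else sorted(counts)
    for j in order:
        c = counts.get(j, [0, 0, 0])
        rows.append({"snp_id": panel.ids[j], "allele1": panel.allele1[j],
                     "allele2": panel.allele2[j], "n_allele1": c[0],
                     "n_allele2": c[1], "n_other": c[2]})
    return pd.DataFrame(rows, columns=["snp_id", "allele1", "allele2",
                                       "n_allele1", "n_allele2", "n_other"])


def qc_min_snps(matrix: GenotypeMatrix, threshold: int = 15_000) -> pd.Series:
    """Pass/fail per individual: >= threshold non-missing autosomal calls.

    Individuals under the threshold are the ones a downstream analysis
    should drop as too sparsely covered.
    """
    aut = matrix.panel.is_autosomal()
    n_called = (matrix.calls[:, aut] != MISSING).sum(axis=1)
    return pd.Series(n_called >= threshold,
                     index=[ind.id for ind in matrix.individuals], name="qc_pass")
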