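"""Synthetic population-genetic data with the structure the pipeline assumes.

Three layers of realism, each matched to the analysis that consumes it:

* **Unlinked allele frequencies** under the Balding-Nichols drift model —
  enough for f-statistics, qpAdm and supervised-ancestry tests, which treat
  sites as exchangeable.
* **Linked haplotypes** over a genetic map, produced by explicit generations
  of random mating with Poisson(1 per Morgan) recombination after a two-way
  admixture pulse — this is what gives admixture LD decaying as exp(-g d).
* **Sequencing reads** with uniform base error and 5' terminal C->T
  deamination decaying geometrically into the read, mirrored as G->A on the
  minus strand — the ancient-DNA damage signature.

All randomness flows through numpy Generators; helpers accept either a seed
or a Generator so callers can derive independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .formats import (MISSING, GenotypeMatrix, Individual, Observation,
                      PileupSite, SnpPanel, X_CHROM, Y_CHROM)

BASES = np.array(["A", "C", "G", "T"], dtype=object)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

def default_panel(n_chrom: int = 3, cm_per_chrom: float = 100.0,
                  sites_per_chrom: int = 5000, seed=0,
                  transversions_only: bool = False) -> SnpPanel:
    """Autosomal panel with a uniform genetic map.

    The default (3 chromosomes x 100 cM x 5000 sites) is the desk-scale
    stand-in for a capture panel: dense enough for LD decay fitting, small
    enough that every test runs in seconds.
    """
    rng = _rng(seed)
    ids, chrom, gpos, ppos, a1, a2 = [], [], [], [], [], []
    for c in range(1, n_chrom + 1):
        g = np.linspace(0.0, cm_per_chrom / 100.0, sites_per_chrom)
        p = np.arange(1, sites_per_chrom + 1) * 10_000
        for j in range(sites_per_chrom):
            ids.append(f"snp_{c}_{j + 1}")
        chrom.extend([c] * sites_per_chrom)
        gpos.extend(g)
        ppos.extend(p)
        pairs = _random_allele_pairs(rng, sites_per_chrom, transversions_only)
        a1.extend(pairs[:, 0])
        a2.extend(pairs[:, 1])
    return SnpPanel(np.array(ids, dtype=object), chrom, gpos, ppos,
                    np.array(a1, dtype=object), np.array(a2, dtype=object))


def _random_allele_pairs(rng: np.random.Generator, n: int,
                         transversions_only: bool) -> np.ndarray:
    pairs = []
    transitions = {frozenset("CT"), frozenset("GA")}
    while len(pairs) < n:
        i, j = rng.choice(4, size=2, replace=False)
        pair = (BASES[i], BASES[j])
        if transversions_only and frozenset(pair) in transitions:
            continue
        pairs.append(pair)
    return np.array(pairs, dtype=object)


def sex_panel(n_aut: int = 10_000, n_x: int = 600, n_y: int = 300, seed=0) -> SnpPanel:
    """Panel including X (chrom 23) and Y (chrom 24) sites for sex typing.

    Default class proportions mirror a 1240K-style capture panel scaled to
    desk size: ~6% X and ~3% Y targets relative to autosomes.
    """
    rng = _rng(seed)
    ids, chrom, gpos, ppos, a1, a2 = [], [], [], [], [], []
    blocks = [(1, n_aut), (X_CHROM, n_x), (Y_CHROM, n_y)]
    for c, n in blocks:
        for j in range(n):
            ids.append(f"s{c}_{j}")
        chrom.extend([c] * n)
        gpos.extend(np.linspace(0, 1, n) if n > 1 else [0.0])
        ppos.extend(np.arange(1, n + 1) * 1000)
        pairs = _random_allele_pairs(rng, n, False)
        a1.extend(pairs[:, 0])
        a2.extend(pairs[:, 1])
    return SnpPanel(np.array(ids, dtype=object), chrom, gpos, ppos,
                    np.array(a1, dtype=object), np.array(a2, dtype=object))


# ---------------------------------------------------------------------------
# Population model / allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureEvent:
    target: str
    source_a: str
    source_b: str
    alpha: float                      # proportion from source_a
    post_admixture_F: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 <= self.post_admixture_F < 1.0:
            raise ValueError("post_admixture_F must be in [0, 1)")


@dataclass
class PopulationModel:
    """Drift tree over a shared ancestral frequency, plus admixture pulses.

    Each population's frequency is a Balding-Nichols draw around its
    parent's frequency p: Beta(p(1-F)/F, (1-p)(1-F)/F), reducing to p at
    F = 0.  ``populations`` entries are (label, F) — drifted straight from
    the ancestral draw — or (label, F, parent_label), nesting under an
    earlier population so the two share the drift accumulated down to that
    parent (this is what gives outgroups differential relatedness to
    sources, which rank/admixture tests need).  Admixture targets mix two
    already-defined populations with proportion alpha from source A, then
    drift again.
    """

    populations: list[tuple]                      # (label, F[, parent])
    admixture_events: list[AdmixtureEvent] = field(default_factory=list)
    freq_low: float = 0.05
    freq_high: float = 0.95

    def __post_init__(self) -> None:
        self.populations = [tuple(p) for p in self.populations]
        labels = [p[0] for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        defined: set[str] = set()
        for entry in self.populations:
            if len(entry) not in (2, 3):
                raise ValueError(f"population entry {entry!r} must be "
                                 "(label, F) or (label, F, parent)")
            F = entry[1]
            if not 0.0 <= F < 1.0:
                raise ValueError("drift F must be in [0, 1)")
            if len(entry) == 3 and entry[2] not in defined:
                raise ValueError(f"parent of {entry[0]!r} must precede it")
            defined.add(entry[0])
        for ev in self.admixture_events:
            if ev.source_a not in defined or ev.source_b not in defined:
                raise ValueError(f"admixture sources of {ev.target!r} must precede it")
            if ev.target in defined:
                raise ValueError(f"admixture target {ev.target!r} already defined")
            defined.add(ev.target)

    @property
    def labels(self) -> list[str]:
        return [p[0] for p in self.populations] + [e.target for e in self.admixture_events]


def _bn_draw(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    if F == 0.0:
        return p.copy()
    scale = (1.0 - F) / F
    return rng.beta(np.clip(p * scale, 1e-12, None),
                    np.clip((1.0 - p) * scale, 1e-12, None))


def simulate_freqs(model: PopulationModel, n_sites: int, seed=0) -> dict[str, np.ndarray]:
    """Per-population allele-1 frequency vectors under the model.

    Returns a dict label -> array of length ``n_sites``; the key
    ``"__ancestral__"`` carries the shared ancestral draw.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _rng(seed)
    anc = rng.uniform(model.freq_low, model.freq_high, size=n_sites)
    freqs: dict[str, np.ndarray] = {"__ancestral__": anc}
    for entry in model.populations:
        label, F = entry[0], entry[1]
        parent = freqs[entry[2]] if len(entry) == 3 else anc
        freqs[label] = _bn_draw(rng, parent, F)
    for ev in model.admixture_events:
        mixed = ev.alpha * freqs[ev.source_a] + (1.0 - ev.alpha) * freqs[ev.source_b]
        freqs[ev.target] = _bn_draw(rng, mixed, ev.post_admixture_F)
    return freqs


def simulate_genotypes(freqs: dict[str, np.ndarray] | np.ndarray,
                       n_per_pop: int | dict[str, int],
                       ploidy_mode: str | dict[str, str] = "diploid",
                       seed=0, panel: SnpPanel | None = None) -> GenotypeMatrix:
    """Draw genotypes from per-population frequencies.

    Diploid calls are Binomial(2, p); pseudohaploid calls are 2*Bernoulli(p),
    where p is the allele-1 frequency.
    """
    rng = _rng(seed)
    if isinstance(freqs, np.ndarray):
        freqs = {"pop": freqs}
    pops = [k for k in freqs if k != "__ancestral__"]
    n_sites = len(next(iter(freqs.values())))
    if panel is None:
        panel = default_panel(1, 100.0, n_sites, seed=0)
    if len(panel) != n_sites:
        raise ValueError("panel size does not match frequency vectors")
    individuals: list[Individual] = []
    rows = []
    for pop in pops:
        p = np.asarray(freqs[pop])
        if np.any((p < 0) | (p > 1)):
            raise ValueError(f"frequencies of {pop!r} outside [0, 1]")
        n = n_per_pop[pop] if isinstance(n_per_pop, dict) else n_per_pop
        mode = ploidy_mode[pop] if isinstance(ploidy_mode, dict) else ploidy_mode
        if mode == "diploid":
            calls = rng.binomial(2, p, size=(n, n_sites))
        elif mode == "pseudohaploid":
            calls = 2 * rng.binomial(1, p, size=(n, n_sites))
        else:
            raise ValueError(f"unknown ploidy mode {mode!r}")
        rows.append(calls)
        for i in range(n):
            individuals.append(Individual(id=f"{pop}_{i}", population=pop,
                                          ploidy_mode=mode))
    calls = np.concatenate(rows, axis=0).astype(np.int8)
    return GenotypeMatrix(panel, individuals, calls)


# ---------------------------------------------------------------------------
# Linked haplotypes / admixture LD
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePool:
    """Binary haplotypes (allele-1 dosage per site) over a mapped panel."""

    panel: SnpPanel
    haplotypes: np.ndarray            # uint8, (n_hap, n_sites)
    population: str = "pool"
    ancestry: np.ndarray | None = None  # bool, True where ancestry is source A

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.panel):
            raise ValueError("haplotype matrix shape does not match panel")
        if np.any(self.haplotypes > 1):
            raise ValueError("haplotypes must be binary")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]


def haplotypes_from_freqs(freqs: np.ndarray, n_hap: int, panel: SnpPanel,
                          population: str = "pool", seed=0) -> HaplotypePool:
    """Unlinked founder haplotypes: Bernoulli(p) per site (no within-pop LD)."""
    rng = _rng(seed)
    hap = rng.binomial(1, freqs, size=(n_hap, len(panel))).astype(np.uint8)
    return HaplotypePool(panel, hap, population)


def _meiosis(rng: np.random.Generator, panel: SnpPanel,
             chrom_slices: list[tuple[int, int, float]],
             h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """One gamete from two parental haplotypes: Poisson(1/Morgan) crossovers."""
    out = np.empty_like(h1)
    for start, stop, length in chrom_slices:
        g = panel.gpos[start:stop]
        k = rng.poisson(length)
        current = rng.integers(2)
        if k == 0:
            sel = np.full(stop - start, current, dtype=bool)
        else:
            cuts = np.sort(rng.uniform(g[0], g[0] + length, size=k))
            # parity of crossovers passed so far decides the template
            sel = ((np.searchsorted(cuts, g, side="right") + current) % 2).astype(bool)
        seg = np.where(sel, h2[start:stop], h1[start:stop])
        out[start:stop] = seg
    return out


def _chrom_slices(panel: SnpPanel) -> list[tuple[int, int, float]]:
    slices = []
    for c in np.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == c)
        start, stop = idx[0], idx[-1] + 1
        g = panel.gpos[start:stop]
        slices.append((int(start), int(stop), float(g[-1] - g[0]) or 1e-9))
    return slices


def simulate_admixture_haplotypes(pool_a: HaplotypePool, pool_b: HaplotypePool,
                                  alpha: float, g: int, n_out: int,
                                  seed=0, pool_size: int | None = None,
                                  ) -> HaplotypePool:
    """Two-way admixture pulse followed by g generations of random mating.

    Founders are whole-genome copies from pool A with probability ``alpha``,
    else pool B.  Each subsequent generation replaces the whole breeding
    pool: every offspring haplotype is a gamete of two haplotypes sampled
    with replacement from the previous generation, with crossovers falling
    as a Poisson process of rate 1 per Morgan on the genetic map.  The
    breeding pool holds ``pool_size`` haplotypes (default: at least 1000),
    of which ``n_out`` are returned; a small pool would add coalescent
    background and slow the admixture-LD decay below the nominal
    exp(-g d).  Local ancestry (True = pool A) is tracked alongside the
    alleles so the decay rate can be verified directly.
    """
    if not np.array_equal(pool_a.panel.gpos, pool_b.panel.gpos):
        raise ValueError("pools must share a panel")
    if g < 0:
        raise ValueError("g must be >= 0")
    rng = _rng(seed)
    panel = pool_a.panel
    n_sites = len(panel)
    slices = _chrom_slices(panel)
    n_pool = pool_size if pool_size is not None else max(n_out, 1000)
    if n_pool < n_out:
        raise ValueError("pool_size must be >= n_out")

    origin = rng.random(n_pool) < alpha
    hap = np.empty((n_pool, n_sites), dtype=np.uint8)
    anc = np.empty((n_pool, n_sites), dtype=np.uint8)
    for i in range(n_pool):
        src = pool_a if origin[i] else pool_b
        hap[i] = src.haplotypes[rng.integers(src.n_hap)]
        anc[i] = 1 if origin[i] else 0

    for _ in range(g):
        new_hap = np.empty_like(hap)
        new_anc = np.empty_like(anc)
        for i in range(n_pool):
            p1, p2 = rng.integers(n_pool, size=2)
            # one crossover mask applied to alleles and ancestry jointly
            seed_state = rng.integers(2**31)
            r1 = np.random.default_rng(seed_state)
            new_hap[i] = _meiosis(r1, panel, slices, hap[p1], hap[p2])
            r2 = np.random.default_rng(seed_state)
            new_anc[i] = _meiosis(r2, panel, slices, anc[p1], anc[p2])
        hap, anc = new_hap, new_anc

    return HaplotypePool(panel, hap[:n_out], population="admixed",
                         ancestry=anc[:n_out].astype(bool))


def diploids_from_haplotypes(pool: HaplotypePool, population: str = "admixed",
                             ) -> GenotypeMatrix:
    """Pair consecutive haplotypes into diploid individuals (allele-1 dosage)."""
    if pool.n_hap % 2:
        raise ValueError("need an even number of haplotypes")
    n_ind = pool.n_hap // 2
    calls = (pool.haplotypes[0::2] + pool.haplotypes[1::2]).astype(np.int8)
    individuals = [Individual(id=f"{population}_{i}", population=population)
                   for i in range(n_ind)]
    return GenotypeMatrix(pool.panel, individuals, calls)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimParams:
    """Sequencing model: Poisson depth, uniform error, terminal deamination.

    ``deamination_amplitude`` is the 5'-terminal C->T probability; it decays
    geometrically with factor ``deamination_decay`` per base into the read.
    The minus strand mirrors this as G->A (in reference orientation).
    """

    mean_depth: float = 1.0
    error_rate: float = 0.001
    deamination_amplitude: float = 0.0
    deamination_decay: float = 0.5
    read_length: int = 60
    min_base_quality_phred: int = 37
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0.0 <= self.deamination_amplitude <= 1.0:
            raise ValueError("deamination_amplitude must be in [0, 1]")
        if not 0.0 < self.deamination_decay < 1.0:
            raise ValueError("deamination_decay must be in (0, 1)")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")


def simulate_reads(calls: np.ndarray, panel: SnpPanel, params: ReadSimParams,
                   seed=None, depth_scale: np.ndarray | None = None,
                   ) -> list[PileupSite]:
    """Simulate a pileup for one individual's genotype row.

    Per site, depth is Poisson(mean_depth), each read templates one of the
    individual's two alleles uniformly, deamination is applied to the
    templated base (C->T on +, G->A on -) with probability
    delta0 * k^position, and otherwise a uniform sequencing error fires with
    probability ``error_rate``.  The site's reference base is taken to be
    allele1.  ``depth_scale`` multiplies the per-site Poisson mean (used for
    sex-chromosome copy number).  Missing genotypes yield no reads.
    """
    rng = _rng(params.seed if seed is None else seed)
    n_sites = len(panel)
    lam = np.full(n_sites, params.mean_depth)
    if depth_scale is not None:
        lam = lam * depth_scale
    depths = rng.poisson(lam)
    sites: list[PileupSite] = []
    L = params.read_length
    bq = params.min_base_quality_phred + 3
    for j in range(n_sites):
        d = int(depths[j])
        if d == 0 or calls[j] == MISSING:
            continue
        a1, a2 = panel.allele1[j], panel.allele2[j]
        p1 = calls[j] / 2.0
        obs = []
        for _ in range(d):
            base = a1 if rng.random() < p1 else a2
            pos = int(rng.integers(L))
            strand = "+" if rng.random() < 0.5 else "-"
            pdam = params.deamination_amplitude * params.deamination_decay ** pos
            if strand == "+" and base == "C" and rng.random() < pdam:
                base = "T"
            elif strand == "-" and base == "G" and rng.random() < pdam:
                base = "A"
            elif params.error_rate and rng.random() < params.error_rate:
                base = str(rng.choice([b for b in BASES if b != base]))
            obs.append(Observation(base=base, base_quality=bq, mapping_quality=60,
                                   read_position=pos, read_length=L, strand=strand))
        sites.append(PileupSite(chrom=int(panel.chrom[j]), ppos=int(panel.ppos[j]),
                                ref=str(a1), observations=obs))
    return sites
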