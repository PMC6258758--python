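"""f3 and f4 statistics with bias correction and weighted block jackknife.

f3(C; A, B) averages (c-a)(c-b) over sites, minus the finite-sample
heterozygosity correction c(1-c)/(n_c - 1) for the target; a significantly
negative value indicates C is admixed between populations related to A and
B.  f4(A, B; C, D) averages (a-b)(c-d) and needs no correction.  Standard
errors come from a weighted delete-one-block jackknife over contiguous
genetic-map blocks, which is robust to LD between nearby sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .formats import MISSING, GenotypeMatrix, SnpPanel


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFreqTable:
    """Per-population allele-1 frequency and observed allele-copy count.

    Pseudohaploid individuals contribute one allele copy per non-missing
    call, diploid individuals two.  ``freq`` is NaN where ``count`` is 0.
    """

    populations: list[str]
    freq: np.ndarray                  # (n_pop, n_sites), NaN where count == 0
    count: np.ndarray                 # (n_pop, n_sites) int
    panel: SnpPanel | None = None
    all_pseudohaploid: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.float64)
        self.count = np.asarray(self.count, dtype=np.int64)
        if self.freq.shape != self.count.shape:
            raise ValueError("freq and count shapes differ")
        if self.freq.shape[0] != len(self.populations):
            raise ValueError("row count != number of populations")

    def row(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"population {population!r} not in table") from None

    @property
    def n_sites(self) -> int:
        return self.freq.shape[1]


def allele_freqs(matrix: GenotypeMatrix,
                 populations: list[str] | None = None) -> AlleleFreqTable:
    """Observed allele-1 frequencies per population.

    A diploid call g contributes g copies of allele1 out of 2; a
    pseudohaploid call contributes g/2 copies out of 1 (its two recorded
    copies are one sampled read).
    """
    pops = populations or matrix.populations()
    n_sites = len(matrix.panel)
    freq = np.full((len(pops), n_sites), np.nan)
    count = np.zeros((len(pops), n_sites), dtype=np.int64)
    pseudo_only = {}
    for r, pop in enumerate(pops):
        idx = matrix.pop_indices(pop)
        copies = np.zeros(n_sites)
        total = np.zeros(n_sites)
        modes = set()
        for i in idx:
            calls = matrix.calls[i].astype(np.float64)
            observed = calls != MISSING
            mode = matrix.individuals[i].ploidy_mode
            modes.add(mode)
            if mode == "pseudohaploid":
                copies[observed] += calls[observed] / 2.0
                total[observed] += 1
            else:
                copies[observed] += calls[observed]
                total[observed] += 2
        with np.errstate(invalid="ignore"):
            freq[r] = np.where(total > 0, copies / np.maximum(total, 1), np.nan)
        count[r] = total.astype(np.int64)
        pseudo_only[pop] = modes == {"pseudohaploid"}
    return AlleleFreqTable(list(pops), freq, count, panel=matrix.panel,
                           all_pseudohaploid=pseudo_only)


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

def assign_blocks(panel: SnpPanel, block_cm: float = 5.0,
                  fallback_blocks: int = 700) -> np.ndarray:
    """Contiguous jackknife block id per site.

    Blocks are ``block_cm`` centimorgan windows along the genetic map,
    never spanning a chromosome boundary.  If the panel carries no map
    (all genetic positions zero) sites are split into up to
    ``fallback_blocks`` equal-count blocks instead.
    """
    n = len(panel)
    blocks = np.zeros(n, dtype=np.int64)
    if n == 0:
        return blocks
    if np.all(panel.gpos == 0.0):
        n_blocks = min(fallback_blocks, n)
        return (np.arange(n) * n_blocks // n).astype(np.int64)
    width = block_cm / 100.0          # Morgans
    next_id = 0
    for c in np.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == c)
        g = panel.gpos[idx]
        local = np.floor((g - g[0]) / width).astype(np.int64)
        # renumber to consecutive ids within the chromosome
        _, local = np.unique(local, return_inverse=True)
        blocks[idx] = local + next_id
        next_id = blocks[idx].max() + 1
    return blocks


# ---------------------------------------------------------------------------
# Weighted block jackknife
# ---------------------------------------------------------------------------

def block_jackknife(values: np.ndarray, weights: np.ndarray,
                    ) -> tuple[float, float]:
    """Weighted delete-one-block jackknife of a weighted mean.

    ``values`` are per-block means and ``weights`` their SNP counts.  The
    estimate is the weighted mean; the variance uses the unequal-block-size
    jackknife (Busing's formula), which reduces to the textbook delete-one
    jackknife when all weights are equal.  With a single block the SE is
    undefined (NaN).
    """
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    keep = weights > 0
    values, weights = values[keep], weights[keep]
    g = len(values)
    if g == 0:
        return float("nan"), float("nan")
    n = weights.sum()
    theta = float(np.sum(weights * values) / n)
    if g == 1:
        return theta, float("nan")
    loo = (n * theta - weights * values) / (n - weights)
    h = n / weights
    theta_jack = g * theta - float(np.sum((1.0 - weights / n) * loo))
    tau = h * theta - (h - 1.0) * loo
    var = float(np.mean((tau - theta_jack) ** 2 / (h - 1.0)))
    return theta, np.sqrt(var)


def _jackknife_from_sums(block_sums: np.ndarray, block_counts: np.ndarray,
                         ) -> tuple[float, float, np.ndarray]:
    """Jackknife a ratio estimator sum/count given per-block partials."""
    keep = block_counts > 0
    s, m = block_sums[keep], block_counts[keep]
    values = s / m
    est, se = block_jackknife(values, m)
    return est, se, keep


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------

@dataclass
class FStatResult:
    statistic: str
    populations: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_snps: int
    block_values: np.ndarray
    block_weights: np.ndarray
    block_cm: float

    def __repr__(self) -> str:
        pops = ", ".join(self.populations)
        return (f"<{self.statistic}({pops}) = {self.estimate:.6g} "
                f"± {self.se:.3g}, Z = {self.z:.2f}, n = {self.n_snps}>")

    def summary(self) -> str:
        pops = ", ".join(self.populations)
        return "\n".join([
            f"{self.statistic}({pops})",
            f"  estimate      {self.estimate: .6e}",
            f"  jackknife SE  {self.se: .6e}",
            f"  Z             {self.z: .3f}",
            f"  SNPs used     {self.n_snps}",
            f"  blocks        {len(self.block_values)} x {self.block_cm} cM",
        ])


def _finish(name: str, pops: tuple[str, ...], contrib: np.ndarray,
            used: np.ndarray, blocks: np.ndarray, block_cm: float) -> FStatResult:
    n_blocks = int(blocks.max()) + 1 if len(blocks) else 0
    sums = np.bincount(blocks[used], weights=contrib[used], minlength=n_blocks)
    counts = np.bincount(blocks[used], minlength=n_blocks).astype(np.float64)
    est, se, keep = _jackknife_from_sums(sums, counts)
    z = est / se if se and np.isfinite(se) and se > 0 else float("nan")
    return FStatResult(statistic=name, populations=pops, estimate=est, se=se,
                       z=z, n_snps=int(used.sum()),
                       block_values=(sums[keep] / counts[keep]),
                       block_weights=counts[keep], block_cm=block_cm)


# ---------------------------------------------------------------------------
# f3 / f4
# ---------------------------------------------------------------------------

def f3(freqs: AlleleFreqTable, target: str, a: str, b: str,
       block_cm: float = 5.0, blocks: np.ndarray | None = None,
       correction: bool | None = None) -> FStatResult:
    """f3(target; a, b) with block-jackknife SE.

    Sites enter where all three populations are observed and the target has
    at least two allele copies (needed by the bias correction).  For a
    target represented only by pseudohaploid individuals the heterozygosity
    is inestimable, so the correction is omitted with a warning; the
    resulting statistic is conservative (biased upward).
    """
    if freqs.panel is None and blocks is None:
        raise ValueError("need a panel or explicit blocks")
    c_i, a_i, b_i = freqs.row(target), freqs.row(a), freqs.row(b)
    fc, fa, fb = freqs.freq[c_i], freqs.freq[a_i], freqs.freq[b_i]
    nc = freqs.count[c_i]
    if correction is None:
        correction = not freqs.all_pseudohaploid.get(target, False)
        if freqs.all_pseudohaploid.get(target, False):
            warnings.warn(
                f"target {target!r} is pseudohaploid-only; omitting the "
                "f3 heterozygosity correction (estimate biased upward)",
                stacklevel=2)
    used = (~np.isnan(fc)) & (~np.isnan(fa)) & (~np.isnan(fb)) & (nc >= 2)
    contrib = (fc - fa) * (fc - fb)
    if correction:
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = contrib - fc * (1.0 - fc) / np.maximum(nc - 1, 1)
    if blocks is None:
        blocks = assign_blocks(freqs.panel, block_cm)
    return _finish("f3", (target, a, b), contrib, used, blocks, block_cm)


def f4(freqs: AlleleFreqTable, a: str, b: str, c: str, d: str,
       block_cm: float = 5.0, blocks: np.ndarray | None = None) -> FStatResult:
    """f4(a, b; c, d) with block-jackknife SE (no bias correction needed)."""
    if freqs.panel is None and blocks is None:
        raise ValueError("need a panel or explicit blocks")
    fa, fb = freqs.freq[freqs.row(a)], freqs.freq[freqs.row(b)]
    fc, fd = freqs.freq[freqs.row(c)], freqs.freq[freqs.row(d)]
    used = ~(np.isnan(fa) | np.isnan(fb) | np.isnan(fc) | np.isnan(fd))
    contrib = (fa - fb) * (fc - fd)
    if blocks is None:
        blocks = assign_blocks(freqs.panel, block_cm)
    return _finish("f4", (a, b, c, d), contrib, used, blocks, block_cm)
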