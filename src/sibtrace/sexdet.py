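"""Genetic sex determination from relative X/Y coverage.

Coverage on each chromosome class is reads per targeted site; the x-rate
and y-rate are X and Y coverage relative to autosomal coverage.  An XX
individual is expected at (1, 0) and an XY individual at (0.5, 0.5).
Error bars treat each class's read total as Poisson and propagate to the
ratio to first order:

    se_rate = rate * sqrt(1/n_reads_class + 1/n_reads_autosomal)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .formats import PileupSite, SnpPanel, X_CHROM, Y_CHROM
from .genotyping import CallerConfig, _passes


@dataclass
class SexResult:
    individual: str
    n_reads_aut: int
    n_reads_x: int
    n_reads_y: int
    n_sites_aut: int
    n_sites_x: int
    n_sites_y: int
    x_rate: float
    y_rate: float
    se_x: float
    se_y: float
    assignment: str                   # XX / XY / consistent-with-XX / consistent-with-XY / undetermined


def _rate_and_se(n_reads: int, n_sites: int, cov_aut: float,
                 n_reads_aut: int) -> tuple[float, float]:
    cov = n_reads / n_sites if n_sites else 0.0
    rate = cov / cov_aut
    if n_reads == 0:
        return rate, 0.0
    se = rate * math.sqrt(1.0 / n_reads + 1.0 / n_reads_aut)
    return rate, se


def determine_sex(n_reads: dict[str, int], n_sites: dict[str, int],
                  individual: str = "sample") -> SexResult:
    """Classify genetic sex from filtered read counts per chromosome class.

    ``n_reads`` and ``n_sites`` are keyed by ``"aut"``, ``"x"`` and ``"y"``.
    Classification: XX requires x_rate - 2 se_x > 0.75 and
    y_rate + 2 se_y < 0.1; XY requires |x_rate - 0.5| < 2 se_x + 0.1 and
    y_rate - 2 se_y > 0.3.  When only one of a karyotype's two criteria
    holds the call is downgraded to "consistent-with-"; when neither
    pattern dominates the call is undetermined.
    """
    ra, rx, ry = n_reads["aut"], n_reads["x"], n_reads["y"]
    sa, sx, sy = n_sites["aut"], n_sites["x"], n_sites["y"]
    if ra == 0 or sa == 0 or sx == 0 or sy == 0:
        return SexResult(individual, ra, rx, ry, sa, sx, sy,
                         float("nan"), float("nan"), float("nan"), float("nan"),
                         "undetermined")
    cov_aut = ra / sa
    x_rate, se_x = _rate_and_se(rx, sx, cov_aut, ra)
    y_rate, se_y = _rate_and_se(ry, sy, cov_aut, ra)

    xx_score = int(x_rate - 2 * se_x > 0.75) + int(y_rate + 2 * se_y < 0.1)
    xy_score = int(abs(x_rate - 0.5) < 2 * se_x + 0.1) + int(y_rate - 2 * se_y > 0.3)
    if xx_score == 2 and xy_score < 2:
        assignment = "XX"
    elif xy_score == 2 and xx_score < 2:
        assignment = "XY"
    elif xx_score == 1 and xy_score == 0:
        assignment = "consistent-with-XX"
    elif xy_score == 1 and xx_score == 0:
        assignment = "consistent-with-XY"
    else:
        assignment = "undetermined"
    return SexResult(individual, ra, rx, ry, sa, sx, sy,
                     x_rate, y_rate, se_x, se_y, assignment)


def count_reads_by_class(pileup: Iterable[PileupSite], panel: SnpPanel,
                         config: CallerConfig | None = None) -> dict[str, int]:
    """Filtered read totals per chromosome class for one individual."""
    config = config or CallerConfig(trim_bases=0)
    index = panel.site_index()
    counts = {"aut": 0, "x": 0, "y": 0}
    for site in pileup:
        if (site.chrom, site.ppos) not in index:
            continue
        n = sum(1 for o in site.observations if _passes(o, config))
        if site.chrom == X_CHROM:
            counts["x"] += n
        elif site.chrom == Y_CHROM:
            counts["y"] += n
        elif 1 <= site.chrom <= 22:
            counts["aut"] += n
    return counts


def panel_site_counts(panel: SnpPanel) -> dict[str, int]:
    return {"aut": int(panel.is_autosomal().sum()),
            "x": int((panel.chrom == X_CHROM).sum()),
            "y": int((panel.chrom == Y_CHROM).sum())}


def sex_from_pileup(pileup: Iterable[PileupSite], panel: SnpPanel,
                    individual: str = "sample",
                    config: CallerConfig | None = None) -> SexResult:
    reads = count_reads_by_class(pileup, panel, config)
    return determine_sex(reads, panel_site_counts(panel), individual)


def plot_sex(results: Sequence[SexResult], path: str, n_se: float = 1.0) -> None:
    """Scatter of x-rate vs y-rate with ``n_se``-SE error bars (default 1)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for res in results:
        if math.isnan(res.x_rate):
            continue
        ax.errorbar(res.x_rate, res.y_rate, xerr=n_se * res.se_x,
                    yerr=n_se * res.se_y, fmt="o", ms=4, capsize=2)
        ax.annotate(res.individual, (res.x_rate, res.y_rate), fontsize=6,
                    xytext=(3, 3), textcoords="offset points")
    ax.axhline(0.0, color="0.8", lw=0.5)
    ax.scatter([1.0, 0.5], [0.0, 0.5], marker="x", color="red", zorder=0,
               label="XX / XY expectation")
    ax.set_xlabel("x-rate (X coverage / autosomal coverage)")
    ax.set_ylabel("y-rate (Y coverage / autosomal coverage)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
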