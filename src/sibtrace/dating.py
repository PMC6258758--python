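"""Admixture dating by weighted linkage-disequilibrium decay.

For an admixed target population, the covariance between genotypes at two
sites separated by genetic distance d, weighted by the allele-frequency
difference between two reference populations at both sites, decays in
expectation as A exp(-g d) + c, where g is the number of generations since
the admixture pulse (d in Morgans).  Fitting the decay and multiplying by
a human generation time converts g into years; adding the (calibrated) age
of the target sample gives a calendar date for the admixture event, with
the two error sources combined by standard propagation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .formats import MISSING, GenotypeMatrix, SnpPanel
from .fstats import AlleleFreqTable, block_jackknife

DEFAULT_GENERATION_TIME = 29.0        # years per generation


# ---------------------------------------------------------------------------
# Weighted LD curve
# ---------------------------------------------------------------------------

@dataclass
class WeightedLdCurve:
    """Binned weighted-LD values with per-jackknife-unit partial sums.

    Jackknife units are contiguous genetic-map blocks that never span a
    chromosome boundary (a pair of sites belongs to the unit of its
    left-hand site).  ``unit_sums[u, b]`` and ``unit_counts[u, b]`` hold
    the contribution sum and pair count of unit ``u`` in distance bin
    ``b``, so a delete-one-unit replicate of the whole curve is exact.
    """

    bin_centers_cm: np.ndarray
    units: np.ndarray                 # unit labels
    unit_sums: np.ndarray             # (n_units, n_bins)
    unit_counts: np.ndarray           # (n_units, n_bins)
    ref_labels: tuple[str, str] = ("ref1", "ref2")
    bin_width_cm: float = 0.05

    def values(self, exclude_unit=None) -> tuple[np.ndarray, np.ndarray]:
        """(a(d), pair counts) per bin, optionally leaving one unit out."""
        keep = np.ones(len(self.units), dtype=bool)
        if exclude_unit is not None:
            keep &= self.units != exclude_unit
        sums = self.unit_sums[keep].sum(0)
        counts = self.unit_counts[keep].sum(0)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return a, counts


def weighted_ld_curve(target: GenotypeMatrix | np.ndarray,
                      ref1_freq: np.ndarray, ref2_freq: np.ndarray,
                      panel: SnpPanel | None = None,
                      bin_width_cm: float = 0.05, max_d_cm: float = 30.0,
                      target_population: str | None = None,
                      ref_labels: tuple[str, str] = ("ref1", "ref2"),
                      jackknife_block_cm: float = 20.0,
                      chunk_rows: int = 512) -> WeightedLdCurve:
    """Weighted LD a(d) binned by genetic distance.

    Each intra-chromosome site pair (x, y) with 0 < d <= max_d contributes
    cov(g_x, g_y) * delta(x) * delta(y), where the covariance is the
    pairwise-complete sample covariance of target genotype values and
    delta(s) = p_ref1(s) - p_ref2(s).  Pairs with a missing reference
    frequency or fewer than two complete observations are skipped.  Pairs
    are grouped into ``jackknife_block_cm`` map blocks (by their left
    site) for delete-one-unit resampling.
    """
    if isinstance(target, GenotypeMatrix):
        panel = target.panel
        if target_population is not None:
            idx = target.pop_indices(target_population)
        else:
            idx = np.arange(target.n_individuals)
        calls = target.calls[idx].astype(np.float64)
        calls[target.calls[idx] == MISSING] = np.nan
    else:
        if panel is None:
            raise ValueError("panel required when passing a raw call matrix")
        calls = np.asarray(target, dtype=np.float64)
    if np.all(panel.gpos == 0.0):
        raise ValueError("weighted LD needs a genetic map")
    delta = np.asarray(ref1_freq, dtype=np.float64) - np.asarray(ref2_freq, np.float64)

    bw = bin_width_cm / 100.0
    max_d = max_d_cm / 100.0
    n_bins = int(math.ceil(max_d / bw))
    block_w = jackknife_block_cm / 100.0

    # jackknife unit of each site: map block within chromosome
    site_unit = np.zeros(len(panel), dtype=np.int64)
    next_unit = 0
    for c in np.unique(panel.chrom):
        idx_c = np.flatnonzero(panel.chrom == c)
        g = panel.gpos[idx_c]
        local = np.floor((g - g[0]) / block_w).astype(np.int64)
        _, local = np.unique(local, return_inverse=True)
        site_unit[idx_c] = local + next_unit
        next_unit = site_unit[idx_c].max() + 1
    n_units = next_unit

    unit_sums = np.zeros((n_units, n_bins))
    unit_counts = np.zeros((n_units, n_bins), dtype=np.int64)

    for c in np.unique(panel.chrom):
        sites = np.flatnonzero((panel.chrom == c) & ~np.isnan(delta))
        if len(sites) < 2:
            continue
        g = panel.gpos[sites]
        units = site_unit[sites]
        v = calls[:, sites]
        obs = ~np.isnan(v)
        mu = np.nanmean(v, axis=0)
        a0 = np.where(obs, v - mu, 0.0)
        d_site = delta[sites]
        S = len(sites)
        for start in range(0, S, chunk_rows):
            stop = min(start + chunk_rows, S)
            # pairwise-complete covariance between rows [start:stop] and all
            num = a0[:, start:stop].T @ a0           # (chunk, S)
            npair = obs[:, start:stop].T.astype(np.float64) @ obs
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = np.where(npair >= 2, num / np.maximum(npair - 1, 1), np.nan)
            dist = np.abs(g[start:stop, None] - g[None, :])
            jj = np.arange(S)[None, :]
            ii = np.arange(start, stop)[:, None]
            valid = (jj > ii) & (dist <= max_d) & ~np.isnan(cov)
            if not valid.any():
                continue
            contrib = cov * (d_site[start:stop, None] * d_site[None, :])
            bins = np.minimum((dist / bw).astype(np.int64), n_bins - 1)
            flat = units[start:stop, None] * n_bins + bins   # (unit, bin) key
            unit_sums.reshape(-1)[:] += np.bincount(
                flat[valid], weights=contrib[valid],
                minlength=n_units * n_bins)
            unit_counts.reshape(-1)[:] += np.bincount(
                flat[valid], minlength=n_units * n_bins)
    centers = (np.arange(n_bins) + 0.5) * bin_width_cm
    return WeightedLdCurve(bin_centers_cm=centers, units=np.arange(n_units),
                           unit_sums=unit_sums, unit_counts=unit_counts,
                           ref_labels=ref_labels, bin_width_cm=bin_width_cm)


# ---------------------------------------------------------------------------
# Exponential fit
# ---------------------------------------------------------------------------

@dataclass
class DecayFit:
    amplitude: float
    generations: float
    affine: float
    se_amplitude: float
    se_generations: float
    se_affine: float
    min_distance_cm: float
    ok: bool                          # False when no positive-rate decay found
    loo_generations: np.ndarray | None = None


def _fit_exponential(d_morgan: np.ndarray, a: np.ndarray, w: np.ndarray,
                     ) -> tuple[float, float, float]:
    """Weighted LS of a = A exp(-g d) + c; raises on failure."""
    c0 = float(np.average(a[-max(3, len(a) // 5):],
                          weights=w[-max(3, len(a) // 5):]))
    resid = a - c0
    pos = resid > 0
    if pos.sum() >= 3:
        slope, intercept = np.polyfit(d_morgan[pos], np.log(resid[pos]), 1,
                                      w=np.sqrt(w[pos]))
        g0 = max(-slope, 1.0)
        a0 = math.exp(intercept)
    else:
        g0, a0 = 50.0, max(a.max() - c0, 1e-6)
    popt, _ = curve_fit(lambda d, A, g, c: A * np.exp(-g * d) + c,
                        d_morgan, a, p0=[a0, g0, c0],
                        sigma=1.0 / np.sqrt(w), maxfev=20_000)
    return float(popt[0]), float(popt[1]), float(popt[2])


def fit_decay(curve: WeightedLdCurve, min_distance_cm: float = 1.0,
              min_bins: int = 10) -> DecayFit:
    """Fit A exp(-g d) + c to the curve above a minimum distance.

    Distances enter in Morgans so the fitted rate is in generations.  Bins
    are weighted by pair count.  Standard errors come from a
    delete-one-map-block jackknife of the whole pipeline (curve
    re-aggregation plus refit per held-out unit).  A failed or
    non-positive-rate fit returns ``ok=False`` ("no decay").
    """
    a_all, counts = curve.values()
    sel = (curve.bin_centers_cm >= min_distance_cm) & (counts > 0) & ~np.isnan(a_all)
    if sel.sum() < min_bins:
        raise ValueError(f"only {int(sel.sum())} usable bins above "
                         f"{min_distance_cm} cM (need {min_bins})")
    d = curve.bin_centers_cm[sel] / 100.0
    try:
        amp, gen, aff = _fit_exponential(d, a_all[sel], counts[sel].astype(float))
    except RuntimeError:
        return DecayFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                        min_distance_cm, ok=False)
    if gen <= 0:
        return DecayFit(amp, gen, aff, np.nan, np.nan, np.nan,
                        min_distance_cm, ok=False)

    loo = []
    weights = []
    for u in curve.units:
        a_u, counts_u = curve.values(exclude_unit=u)
        sel_u = (curve.bin_centers_cm >= min_distance_cm) & (counts_u > 0) \
            & ~np.isnan(a_u)
        if sel_u.sum() < 3:
            continue
        ui = np.flatnonzero(curve.units == u)[0]
        w_u = curve.unit_counts[ui].sum()
        if w_u == 0:                  # unit holds no pairs (e.g. map endpoint)
            continue
        try:
            fit_u = _fit_exponential(curve.bin_centers_cm[sel_u] / 100.0,
                                     a_u[sel_u], counts_u[sel_u].astype(float))
        except RuntimeError:
            continue
        loo.append(fit_u)
        weights.append(w_u)
    ses = [np.nan, np.nan, np.nan]
    loo_g = None
    if len(loo) >= 2:
        loo_arr = np.array(loo)
        w = np.array(weights, dtype=float)
        for p, est in enumerate((amp, gen, aff)):
            ses[p] = _jackknife_se_from_loo(est, loo_arr[:, p], w)
        loo_g = loo_arr[:, 1]
    return DecayFit(amplitude=amp, generations=gen, affine=aff,
                    se_amplitude=ses[0], se_generations=ses[1],
                    se_affine=ses[2], min_distance_cm=min_distance_cm,
                    ok=True, loo_generations=loo_g)


def _jackknife_se_from_loo(theta: float, loo: np.ndarray, w: np.ndarray) -> float:
    keep = w > 0
    loo, w = loo[keep], w[keep]
    if len(loo) < 2:
        return float("nan")
    n = w.sum()
    g = len(loo)
    h = np.maximum(n / w, 1.0 + 1e-12)
    theta_jack = g * theta - float(np.sum((1.0 - w / n) * loo))
    tau = h * theta - (h - 1.0) * loo
    return float(np.sqrt(np.mean((tau - theta_jack) ** 2 / (h - 1.0))))


# ---------------------------------------------------------------------------
# Calendar conversion
# ---------------------------------------------------------------------------

def admixture_date(generations: float, se_generations: float = 0.0,
                   sample_age_bp: float = 0.0, sample_age_se: float = 0.0,
                   generation_time: float = DEFAULT_GENERATION_TIME,
                   ) -> tuple[float, float]:
    """Convert generations since admixture to a calendar date in years BP.

    t = sample_age + generation_time * g, with the sampling-age and
    generation-count uncertainties combined in quadrature:
    sigma_t = sqrt(sigma_age^2 + (generation_time * sigma_g)^2).
    For a modern target use sample_age 0 ± 0.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    t = sample_age_bp + generation_time * generations
    sigma = math.sqrt(sample_age_se ** 2 + (generation_time * se_generations) ** 2)
    return t, sigma


# ---------------------------------------------------------------------------
# Model interface
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureDateResults:
    curve: WeightedLdCurve
    fit: DecayFit
    sample_age_bp: float
    sample_age_se: float
    generation_time: float
    date_ybp: float
    date_se: float

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Admixture-LD decay fit "
            f"(refs {self.curve.ref_labels[0]}, {self.curve.ref_labels[1]}; "
            f"min distance {f.min_distance_cm} cM)",
            f"  amplitude  A = {f.amplitude:.4g} ± {f.se_amplitude:.3g}",
            f"  rate       g = {f.generations:.2f} ± {f.se_generations:.2f} generations",
            f"  affine     c = {f.affine:.4g} ± {f.se_affine:.3g}",
            f"  sample age   {self.sample_age_bp:.0f} ± {self.sample_age_se:.0f} calBP",
            f"  admixture date = {self.date_ybp:.0f} ± {self.date_se:.0f} yBP "
            f"({self.generation_time:g} yr/generation)",
        ]
        if not f.ok:
            lines.append("  WARNING: no significant decay; date unreliable")
        return "\n".join(lines)


class AdmixtureLdDecay:
    """Weighted-LD decay dating of a two-way admixture (ALDER-style).

    Parameters
    ----------
    target : GenotypeMatrix (optionally restricted by ``target_population``)
    ref1_freq, ref2_freq : allele-1 frequencies of the two reference
        (source-proxy) populations on the target's panel.
    """

    def __init__(self, target: GenotypeMatrix, ref1_freq: np.ndarray,
                 ref2_freq: np.ndarray, target_population: str | None = None,
                 ref_labels: tuple[str, str] = ("ref1", "ref2"),
                 bin_width_cm: float = 0.05, max_d_cm: float = 30.0,
                 min_distance_cm: float = 1.0) -> None:
        self.target = target
        self.ref1_freq = ref1_freq
        self.ref2_freq = ref2_freq
        self.target_population = target_population
        self.ref_labels = ref_labels
        self.bin_width_cm = bin_width_cm
        self.max_d_cm = max_d_cm
        self.min_distance_cm = min_distance_cm

    def fit(self, sample_age_bp: float = 0.0, sample_age_se: float = 0.0,
            generation_time: float = DEFAULT_GENERATION_TIME,
            ) -> AdmixtureDateResults:
        curve = weighted_ld_curve(self.target, self.ref1_freq, self.ref2_freq,
                                  bin_width_cm=self.bin_width_cm,
                                  max_d_cm=self.max_d_cm,
                                  target_population=self.target_population,
                                  ref_labels=self.ref_labels)
        fit = fit_decay(curve, min_distance_cm=self.min_distance_cm)
        if fit.ok:
            date, se = admixture_date(fit.generations, fit.se_generations
                                      if np.isfinite(fit.se_generations) else 0.0,
                                      sample_age_bp, sample_age_se,
                                      generation_time)
        else:
            date, se = float("nan"), float("nan")
        return AdmixtureDateResults(curve=curve, fit=fit,
                                    sample_age_bp=sample_age_bp,
                                    sample_age_se=sample_age_se,
                                    generation_time=generation_time,
                                    date_ybp=date, date_se=se)


def plot_decay(result: AdmixtureDateResults, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, counts = result.curve.values()
    sel = counts > 0
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.curve.bin_centers_cm[sel], a[sel], ".", ms=3, alpha=0.5,
            label="weighted LD")
    f = result.fit
    if f.ok:
        d = np.linspace(f.min_distance_cm, result.curve.bin_centers_cm[-1], 200)
        ax.plot(d, f.amplitude * np.exp(-f.generations * d / 100.0) + f.affine,
                "r-", label=f"fit: g = {f.generations:.1f}")
    ax.axvline(f.min_distance_cm, color="0.7", ls="--", lw=0.8)
    ax.set_xlabel("genetic distance d (cM)")
    ax.set_ylabel("weighted LD a(d)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
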