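"""Radiocarbon calibration against a supplied calibration curve.

A conventional radiocarbon determination r ± sigma_r is mapped onto the
calendar axis through the calibration curve mu(theta) ± sigma_curve(theta):
with a flat prior on calendar age theta (in calBP), the posterior density
on a 1-year grid is

    p(theta) ∝ exp( -(r - mu(theta))^2 / (2 (sigma_r^2 + sigma_curve(theta)^2)) )

The result carries the normalized density, its mean and SD, and the 95.4%
(2-sigma-equivalent) highest-density region, plus a calBCE rendering
(calBCE = calBP - 1950).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import CalCurve


@dataclass
class CalibrationResult:
    grid_cal_bp: np.ndarray
    density: np.ndarray               # sums to 1 on the grid
    mean_cal_bp: float
    sd_cal_bp: float
    hdi_95_4: list[tuple[float, float]]   # (older, younger) calBP intervals
    c14_age: float
    c14_sigma: float

    @property
    def mean_cal_bce(self) -> float:
        return self.mean_cal_bp - 1950.0

    def hdi_cal_bce(self) -> list[tuple[float, float]]:
        return [(o - 1950.0, y - 1950.0) for o, y in self.hdi_95_4]

    def summary(self) -> str:
        lines = [
            f"Radiocarbon calibration of {self.c14_age:.0f} ± "
            f"{self.c14_sigma:.0f} 14C BP",
            f"  mean  {self.mean_cal_bp:.0f} calBP "
            f"({self.mean_cal_bce:.0f} calBCE)",
            f"  sd    {self.sd_cal_bp:.0f} years",
            "  95.4% HDI:",
        ]
        for (o, y), (ob, yb) in zip(self.hdi_95_4, self.hdi_cal_bce()):
            lines.append(f"    {o:.0f}-{y:.0f} calBP  ({ob:.0f}-{yb:.0f} calBCE)")
        return "\n".join(lines)


def calibrate(c14_age: float, c14_sigma: float, curve: CalCurve,
              grid_step: float = 1.0, mass: float = 0.954,
              edge_tolerance: float = 1e-3) -> CalibrationResult:
    """Calibrate a radiocarbon determination on a 1-year calendar grid.

    Raises when more than ``edge_tolerance`` posterior mass falls in the
    outer 5 years of the curve's span, which means the curve does not
    cover the plausible calendar range.
    """
    if c14_sigma <= 0:
        raise ValueError("c14_sigma must be positive")
    theta = np.arange(curve.cal_bp[0], curve.cal_bp[-1] + grid_step, grid_step)
    mu = curve.mu(theta)
    var = c14_sigma ** 2 + curve.sigma_at(theta) ** 2
    log_post = -((c14_age - mu) ** 2) / (2.0 * var)
    post = np.exp(log_post - log_post.max())
    total = post.sum()
    if total <= 0:
        raise ValueError("posterior vanished on the grid")
    post /= total
    edge = 5.0
    edge_mass = post[theta <= theta[0] + edge].sum() + \
        post[theta >= theta[-1] - edge].sum()
    if edge_mass > edge_tolerance:
        raise ValueError(
            f"curve range insufficient: {edge_mass:.2g} posterior mass within "
            f"{edge:.0f} years of the grid edges")
    mean = float(np.sum(theta * post))
    sd = float(np.sqrt(np.sum((theta - mean) ** 2 * post)))
    hdi = _hdi_intervals(theta, post, mass)
    return CalibrationResult(grid_cal_bp=theta, density=post, mean_cal_bp=mean,
                             sd_cal_bp=sd, hdi_95_4=hdi, c14_age=c14_age,
                             c14_sigma=c14_sigma)


def _hdi_intervals(theta: np.ndarray, post: np.ndarray,
                   mass: float) -> list[tuple[float, float]]:
    """Highest-density region by density thresholding.

    Grid years are admitted in decreasing density order until the target
    mass is covered; ties broken toward older (larger calBP) years.  The
    admitted set is then split into contiguous runs, each reported as an
    (older, younger) calBP pair, oldest interval first.
    """
    order = np.lexsort((-theta, -post))   # by density desc, then older first
    cum = np.cumsum(post[order])
    n_in = int(np.searchsorted(cum, mass)) + 1
    inside = np.zeros(len(theta), dtype=bool)
    inside[order[:n_in]] = True
    idx = np.flatnonzero(inside)
    intervals: list[tuple[float, float]] = []
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            intervals.append((float(theta[prev]), float(theta[start])))
            start = i
        prev = i
    intervals.append((float(theta[prev]), float(theta[start])))
    # intervals as (older, younger); sort oldest first
    intervals.sort(key=lambda t: -t[0])
    return intervals
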