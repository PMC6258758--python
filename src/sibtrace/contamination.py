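"""Supervised ancestry decomposition and contamination power analysis.

A test individual's genotypes are decomposed onto K fixed reference
clusters by maximizing the binomial likelihood of its allele counts under
mixture frequencies sum_k q_k f_k — supervised clustering with frozen
cluster frequencies.  Contamination from a source outside the individual's
own ancestry shows up as weight on unexpected clusters; injecting
contaminant-templated calls at known rates and asking when that
off-target weight exceeds the clean-replicate null measures the method's
detection power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import MISSING


# ---------------------------------------------------------------------------
# Supervised decomposition
# ---------------------------------------------------------------------------

@dataclass
class AncestryResults:
    proportions: np.ndarray           # q_k, on the simplex
    labels: list[str]
    log_likelihood: float
    n_sites: int
    n_iter: int
    converged: bool
    loglik_path: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = ["Supervised ancestry decomposition"]
        for lab, q in zip(self.labels, self.proportions):
            lines.append(f"  {lab:<16s} {q: .4f}")
        lines.append(f"  logL = {self.log_likelihood:.2f}  "
                     f"({self.n_iter} EM iterations, "
                     f"{'converged' if self.converged else 'NOT converged'}, "
                     f"{self.n_sites} sites)")
        return "\n".join(lines)


class SupervisedAncestry:
    """Maximum-likelihood mixture of fixed reference cluster frequencies.

    Parameters
    ----------
    x : allele-1 copies observed per site (0/1/2 diploid; 0/1 pseudohaploid)
    m : copies observable per site (2 diploid, 1 pseudohaploid); sites with
        m = 0 (missing) are ignored.
    ref_freqs : (K, n_sites) cluster allele-1 frequencies; clamped away
        from 0/1 so the likelihood stays finite.
    """

    def __init__(self, x: np.ndarray, m: np.ndarray, ref_freqs: np.ndarray,
                 labels: list[str] | None = None,
                 clamp: float = 1e-3) -> None:
        x = np.asarray(x, dtype=np.float64)
        m = np.asarray(m, dtype=np.float64)
        f = np.asarray(ref_freqs, dtype=np.float64)
        keep = m > 0
        self.x = x[keep]
        self.m = m[keep]
        self.f = np.clip(f[:, keep], clamp, 1.0 - clamp)
        self.labels = labels or [f"cluster{k}" for k in range(f.shape[0])]
        if np.any(self.x > self.m):
            raise ValueError("allele copies exceed observable copies")
        if self.x.size < 1_000:
            raise ValueError(f"only {self.x.size} non-missing sites (< 1000)")

    @classmethod
    def from_calls(cls, calls: np.ndarray, ploidy_mode: str,
                   ref_freqs: np.ndarray, labels: list[str] | None = None,
                   **kw) -> "SupervisedAncestry":
        calls = np.asarray(calls)
        obs = calls != MISSING
        if ploidy_mode == "pseudohaploid":
            x = np.where(obs, calls / 2.0, 0.0)
            m = np.where(obs, 1.0, 0.0)
        else:
            x = np.where(obs, calls, 0.0)
            m = np.where(obs, 2.0, 0.0)
        return cls(x, m, ref_freqs, labels, **kw)

    def _loglik(self, q: np.ndarray) -> float:
        p = q @ self.f
        return float(np.sum(self.x * np.log(p) + (self.m - self.x) * np.log1p(-p)))

    def _em(self, q0: np.ndarray, tol: float, max_iter: int,
            ) -> tuple[np.ndarray, float, int, bool, np.ndarray]:
        q = q0.copy()
        total = self.m.sum()
        path = [self._loglik(q)]
        for it in range(1, max_iter + 1):
            p = q @ self.f
            # expected copies attributed to cluster k, allele1 + allele2 parts
            r1 = (self.x / p)[None, :] * self.f
            r0 = ((self.m - self.x) / (1.0 - p))[None, :] * (1.0 - self.f)
            q_new = q * (r1 + r0).sum(axis=1) / total
            q_new = q_new / q_new.sum()
            ll = self._loglik(q_new)
            path.append(ll)
            if ll + 1e-9 < path[-2]:
                raise AssertionError("EM log-likelihood decreased")
            if abs(ll - path[-2]) < tol:
                return q_new, ll, it, True, np.array(path)
            q = q_new
        return q, path[-1], max_iter, False, np.array(path)

    def _sqp(self, q0: np.ndarray, tol: float, max_iter: int,
             ) -> tuple[np.ndarray, float, int, bool, np.ndarray]:
        """Constrained quasi-Newton on the simplex (the likelihood is concave)."""
        from scipy.optimize import minimize

        f, x, m = self.f, self.x, self.m
        k = f.shape[0]

        def negll(q):
            p = np.clip(q @ f, 1e-12, 1.0 - 1e-12)
            return -np.sum(x * np.log(p) + (m - x) * np.log1p(-p))

        def grad(q):
            p = np.clip(q @ f, 1e-12, 1.0 - 1e-12)
            return -(f @ (x / p) - f @ ((m - x) / (1.0 - p)))

        res = minimize(negll, q0, jac=grad, method="SLSQP",
                       bounds=[(0.0, 1.0)] * k,
                       constraints={"type": "eq", "fun": lambda q: q.sum() - 1.0},
                       options={"maxiter": max_iter, "ftol": tol})
        q = np.clip(res.x, 0.0, 1.0)
        q /= q.sum()
        return q, -float(res.fun), int(res.nit), bool(res.success), np.empty(0)

    def fit(self, seed: int = 0, n_starts: int = 3, tol: float = 1e-8,
            max_iter: int = 2_000, method: str = "sqp") -> AncestryResults:
        """Maximize the mixture likelihood over the simplex.

        ``method="sqp"`` (default) solves the concave program directly with
        a constrained quasi-Newton step; ``method="em"`` runs the classic
        multiplicative EM update, whose log-likelihood is non-decreasing at
        every step (slower near the boundary, kept for its monotonicity
        guarantee).  Multi-start with a fixed seed guards against the flat
        directions K near-collinear clusters can produce.
        """
        k = self.f.shape[0]
        if k == 1:
            return AncestryResults(np.ones(1), self.labels, self._loglik(np.ones(1)),
                                   self.x.size, 0, True, np.empty(0))
        rng = np.random.default_rng(seed)
        starts = [np.full(k, 1.0 / k)]
        starts += [rng.dirichlet(np.ones(k)) for _ in range(n_starts - 1)]
        solver = self._sqp if method == "sqp" else self._em
        best = None
        for q0 in starts:
            q, ll, it, conv, path = solver(q0, tol, max_iter)
            if best is None or ll > best[1]:
                best = (q, ll, it, conv, path)
        q, ll, it, conv, path = best
        return AncestryResults(proportions=q, labels=list(self.labels),
                               log_likelihood=ll, n_sites=self.x.size,
                               n_iter=it, converged=conv, loglik_path=path)


# ---------------------------------------------------------------------------
# Contamination injection
# ---------------------------------------------------------------------------

def inject_contamination(calls: np.ndarray, contaminant_freq: np.ndarray,
                         rate: float, seed=0) -> np.ndarray:
    """Replace each pseudohaploid call by a contaminant draw with prob ``rate``.

    A replaced call becomes 2*Bernoulli(f_contaminant): the sampled read
    came from the contaminant individual instead of the target.  Missing
    calls stay missing.  rate = 0 returns the input unchanged.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    calls = np.asarray(calls)
    if rate == 0.0:
        return calls.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = calls.copy()
    hit = (rng.random(calls.shape) < rate) & (calls != MISSING)
    draws = 2 * rng.binomial(1, np.broadcast_to(contaminant_freq, calls.shape))
    out[hit] = draws[hit]
    return out


def inject_contamination_pileup(sites, panel, contaminant_freq: np.ndarray,
                                rate: float, seed=0):
    """Pileup-mode injection: each read is replaced, with probability ``rate``,
    by a contaminant-templated read carrying allele1 with the contaminant's
    frequency at that site (quality/position metadata kept)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from dataclasses import replace

    from .formats import PileupSite

    index = panel.site_index()
    out = []
    for site in sites:
        j = index.get((site.chrom, site.ppos))
        obs = []
        for o in site.observations:
            if j is not None and rate > 0.0 and rng.random() < rate:
                base = (panel.allele1[j] if rng.random() < contaminant_freq[j]
                        else panel.allele2[j])
                obs.append(replace(o, base=str(base)))
            else:
                obs.append(o)
        out.append(PileupSite(site.chrom, site.ppos, site.ref, obs))
    return out


# ---------------------------------------------------------------------------
# Power analysis
# ---------------------------------------------------------------------------

@dataclass
class PowerScenario:
    """Defines the truth for the power experiment.

    ``true_mixture`` gives the test individual's ancestry as weights over
    the reference clusters; clusters with zero weight are "off-target" and
    contamination is detected when their summed estimated proportion is
    anomalously high.
    """

    ref_freqs: np.ndarray             # (K, n_sites)
    labels: list[str]
    true_mixture: np.ndarray          # (K,) sums to 1
    contaminant_freq: np.ndarray      # (n_sites,)

    def __post_init__(self) -> None:
        self.true_mixture = np.asarray(self.true_mixture, dtype=np.float64)
        if abs(self.true_mixture.sum() - 1.0) > 1e-9:
            raise ValueError("true_mixture must sum to 1")


@dataclass
class PowerResult:
    rates: np.ndarray
    power: np.ndarray                 # per-rate detection fraction
    null_mean: float
    null_sd: float
    threshold: float
    min_detected_rate: float | None   # smallest rate with power >= 0.5
    off_target_stats: dict[float, np.ndarray]


def _simulate_individual(scenario: PowerScenario, rng: np.random.Generator,
                         ) -> np.ndarray:
    p = scenario.true_mixture @ scenario.ref_freqs
    return 2 * rng.binomial(1, p)     # pseudohaploid calls


def detection_power(scenario: PowerScenario, rates, n_reps: int = 50,
                    seed: int = 0, rule_sd: float = 3.0,
                    em_seed: int = 0) -> PowerResult:
    """Detection power of the supervised decomposition across injection rates.

    For each rate, ``n_reps`` contaminated replicates are decomposed;
    detection means the summed proportion on clusters outside the
    individual's true ancestry exceeds mean + ``rule_sd`` * SD of the
    clean (rate 0) replicates.  Reports per-rate power and the smallest
    rate reaching power 0.5.
    """
    if n_reps < 10:
        raise ValueError("need at least 10 replicates per rate")
    rates = np.asarray(sorted(set([0.0] + list(rates))), dtype=np.float64)
    rng = np.random.default_rng(seed)
    off_target = scenario.true_mixture == 0.0

    def off_stat(calls: np.ndarray) -> float:
        model = SupervisedAncestry.from_calls(calls, "pseudohaploid",
                                              scenario.ref_freqs,
                                              scenario.labels)
        res = model.fit(seed=em_seed, n_starts=1)
        return float(res.proportions[off_target].sum())

    stats_by_rate: dict[float, np.ndarray] = {}
    for rate in rates:
        vals = np.empty(n_reps)
        for rep in range(n_reps):
            calls = _simulate_individual(scenario, rng)
            calls = inject_contamination(calls, scenario.contaminant_freq,
                                         float(rate), seed=rng)
            vals[rep] = off_stat(calls)
        stats_by_rate[float(rate)] = vals

    null = stats_by_rate[0.0]
    threshold = float(null.mean() + rule_sd * null.std(ddof=1))
    power = np.array([(stats_by_rate[float(r)] > threshold).mean()
                      for r in rates])
    detected = rates[(power >= 0.5) & (rates > 0)]
    return PowerResult(rates=rates, power=power,
                       null_mean=float(null.mean()),
                       null_sd=float(null.std(ddof=1)),
                       threshold=threshold,
                       min_detected_rate=float(detected[0]) if len(detected) else None,
                       off_target_stats=stats_by_rate)
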