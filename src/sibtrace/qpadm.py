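"""qpWave rank tests and qpAdm admixture-proportion estimation.

Both operate on a matrix of f4 statistics X with X_ij = f4(L_i, L_0; R_j,
R_0), where L are "left" populations (the target and candidate sources)
and R are "right" outgroups.  If the target is a mixture of the sources,
the row space of X has rank k-1 and there is a weight vector w (summing
to 1) with w'X = 0; qpAdm estimates w by generalized least squares against
a block-jackknife covariance, and qpWave tests the rank by chi-square
minimization over low-rank approximations.

The model-search protocol mirrors common ancient-DNA practice: fit the
full source set against an ordered list of outgroup ("right") sets, drop
sources assigned negative weights, advance to the next outgroup set when
no working model emerges, and report the feasible model with the fewest
sources.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GenotypeMatrix
from .fstats import AlleleFreqTable, allele_freqs, assign_blocks

MIN_CELL_SITES_ERROR = 1_000
MIN_CELL_SITES_WARN = 10_000


# ---------------------------------------------------------------------------
# F4 matrix with block partials
# ---------------------------------------------------------------------------

@dataclass
class F4Matrix:
    """f4(L_i, L_0; R_j, R_0) matrix with per-block partial sums.

    Storing per-(cell, block) sums and site counts makes every
    delete-one-block replicate exact, which the jackknife covariance and
    the qpAdm weight SEs both need.  Under ``allsnps`` each cell uses its
    own maximal non-missing site set; otherwise all cells share the global
    intersection.
    """

    left: list[str]
    right: list[str]
    x: np.ndarray                     # (m, n) cell estimates
    block_sums: np.ndarray            # (B, m, n)
    block_counts: np.ndarray          # (B, m, n)
    block_weights: np.ndarray         # (B,) total usable sites per block
    cell_sites: np.ndarray            # (m, n) sites per cell

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape

    def delete_block(self, b: int) -> np.ndarray:
        sums = self.block_sums.sum(0) - self.block_sums[b]
        counts = self.block_counts.sum(0) - self.block_counts[b]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)

    def jackknife_covariance(self) -> np.ndarray:
        """Weighted-jackknife covariance of vec(x) over blocks."""
        B = self.block_sums.shape[0]
        keep = self.block_weights > 0
        w = self.block_weights[keep]
        n = w.sum()
        h = n / w
        theta = self.x.reshape(-1)
        loo = np.stack([self.delete_block(b).reshape(-1)
                        for b in range(B)])[keep]
        g = len(w)
        theta_jack = g * theta - ((1.0 - w[:, None] / n) * loo).sum(0)
        tau = h[:, None] * theta - (h[:, None] - 1.0) * loo
        dev = tau - theta_jack
        cov = (dev.T / (h - 1.0)) @ dev / g
        return 0.5 * (cov + cov.T)

    def submatrix(self, left: list[str], right: list[str]) -> "F4Matrix":
        """Restrict to subsets of left/right populations (bases kept)."""
        if left[0] != self.left[0] or right[0] != self.right[0]:
            raise ValueError("basis populations must be retained")
        li = [self.left.index(p) - 1 for p in left[1:]]
        ri = [self.right.index(p) - 1 for p in right[1:]]
        ix = np.ix_(li, ri)
        return F4Matrix(left=list(left), right=list(right),
                        x=self.x[ix],
                        block_sums=self.block_sums[(slice(None),) + ix],
                        block_counts=self.block_counts[(slice(None),) + ix],
                        block_weights=self.block_weights,
                        cell_sites=self.cell_sites[ix])


def build_f4_matrix(freqs: AlleleFreqTable | GenotypeMatrix,
                    left: list[str], right: list[str],
                    allsnps: bool = True, block_cm: float = 5.0,
                    min_cell_sites: int = MIN_CELL_SITES_ERROR) -> F4Matrix:
    """Assemble the f4 matrix for lefts (target first) against rights.

    ``left[0]`` and ``right[0]`` are the bases of the two difference
    systems.  Raises if any cell has fewer than ``min_cell_sites`` usable
    sites; warns below 10,000 (desk-scale panels routinely trip this, so
    the warning is informational).
    """
    import warnings

    if isinstance(freqs, GenotypeMatrix):
        freqs = allele_freqs(freqs)
    if len(right) < 2:
        raise ValueError("need at least 2 right populations")
    if len(set(left) & set(right)):
        raise ValueError("left and right sets overlap")
    blocks = assign_blocks(freqs.panel, block_cm)
    B = int(blocks.max()) + 1
    m, n = len(left) - 1, len(right) - 1
    fl = np.stack([freqs.freq[freqs.row(p)] for p in left])
    fr = np.stack([freqs.freq[freqs.row(p)] for p in right])
    obs_l = ~np.isnan(fl)
    obs_r = ~np.isnan(fr)
    global_ok = obs_l.all(0) & obs_r.all(0)

    block_sums = np.zeros((B, m, n))
    block_counts = np.zeros((B, m, n), dtype=np.int64)
    for i in range(m):
        da = fl[i + 1] - fl[0]
        ok_l = obs_l[i + 1] & obs_l[0]
        for j in range(n):
            db = fr[j + 1] - fr[0]
            ok = (ok_l & obs_r[j + 1] & obs_r[0]) if allsnps else global_ok
            contrib = np.where(ok, da * db, 0.0)
            block_sums[:, i, j] = np.bincount(blocks, weights=contrib, minlength=B)
            block_counts[:, i, j] = np.bincount(blocks, weights=ok, minlength=B)
    cell_sites = block_counts.sum(0)
    if cell_sites.min() < min_cell_sites:
        raise ValueError(
            f"f4 cell with only {int(cell_sites.min())} usable sites "
            f"(< {min_cell_sites})")
    if cell_sites.min() < MIN_CELL_SITES_WARN:
        warnings.warn(f"f4 cells as sparse as {int(cell_sites.min())} sites",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = block_sums.sum(0) / np.maximum(cell_sites, 1)
    any_ok = (obs_l.all(0) & obs_r.all(0)) if not allsnps else (
        obs_l[0] & obs_r[0])
    block_weights = np.bincount(blocks, weights=any_ok, minlength=B)
    return F4Matrix(left=list(left), right=list(right), x=x,
                    block_sums=block_sums, block_counts=block_counts,
                    block_weights=block_weights, cell_sites=cell_sites)


# ---------------------------------------------------------------------------
# Covariance inverse with regularization
# ---------------------------------------------------------------------------

def _regularized_inverse(q: np.ndarray, floor_frac: float = 1e-12) -> np.ndarray:
    """Eigenvalue-floored inverse: jackknife covariances are near-singular."""
    vals, vecs = np.linalg.eigh(q)
    floor = floor_frac * max(vals.max(), 0.0) * len(vals) or 1e-300
    vals = np.maximum(vals, floor)
    return (vecs / vals) @ vecs.T


# ---------------------------------------------------------------------------
# qpWave rank test
# ---------------------------------------------------------------------------

def qpwave_rank(f4mat: F4Matrix, rank: int, seed: int = 0,
                n_restarts: int = 5, tol: float = 1e-10,
                max_iter: int = 500) -> tuple[float, int, float]:
    """Chi-square test of rank(X) <= rank against the jackknife covariance.

    chi2 = min over rank-``rank`` matrices Xr of
    (vec(X - Xr))' Q^+ (vec(X - Xr)), minimized by alternating generalized
    least squares over the factors of Xr = A B' with multi-start; dof is
    (m - r)(n - r).
    """
    x = f4mat.x
    m, n = x.shape
    if not 0 <= rank < min(m, n):
        raise ValueError(f"rank must be in [0, {min(m, n) - 1}]")
    q = f4mat.jackknife_covariance()
    w = _regularized_inverse(q)
    xv = x.reshape(-1, order="F")
    dof = (m - rank) * (n - rank)
    if rank == 0:
        chi2 = float(xv @ w @ xv)
        return chi2, dof, float(stats.chi2.sf(chi2, dof))

    rng = np.random.default_rng(seed)
    eye_m = np.eye(m)
    best = np.inf
    u, s, vt = np.linalg.svd(x)
    for restart in range(n_restarts):
        if restart == 0:
            bmat = (vt[:rank].T * s[:rank])
        else:
            bmat = rng.standard_normal((n, rank)) * (np.abs(x).mean() + 1e-30)
        prev = np.inf
        for _ in range(max_iter):
            # solve for A given B: vec(AB') = (B kron I_m) vec(A)
            design = np.kron(bmat, eye_m)
            lhs = design.T @ w @ design
            rhs = design.T @ w @ xv
            a = np.linalg.lstsq(lhs, rhs, rcond=None)[0].reshape((m, rank), order="F")
            # solve for B given A: vec(AB') = (I_n kron A) vec(B')
            design = np.kron(np.eye(n), a)
            lhs = design.T @ w @ design
            rhs = design.T @ w @ xv
            bt = np.linalg.lstsq(lhs, rhs, rcond=None)[0].reshape((rank, n), order="F")
            bmat = bt.T
            resid = xv - (a @ bt).reshape(-1, order="F")
            obj = float(resid @ w @ resid)
            if abs(prev - obj) < tol * (1.0 + abs(obj)):
                break
            prev = obj
        best = min(best, obj)
    return best, dof, float(stats.chi2.sf(best, dof))


# ---------------------------------------------------------------------------
# qpAdm
# ---------------------------------------------------------------------------

@dataclass
class QpAdmResults:
    """Fitted admixture weights with jackknife SEs and the rank-test p."""

    target: str
    sources: list[str]
    right: list[str]
    weights: np.ndarray
    weight_se: np.ndarray
    chi2: float
    dof: int
    p_value: float
    feasible: bool
    snps_used: int
    n_iter: int
    converged: bool
    outgroup_set: str = "custom"
    block_weights_loo: np.ndarray | None = None

    def summary(self) -> str:
        lines = [
            f"qpAdm: {self.target} ~ " + " + ".join(self.sources),
            f"  rights: {', '.join(self.right)}  [{self.outgroup_set}]",
            f"  rank test: chi2 = {self.chi2:.3f}, dof = {self.dof}, "
            f"p = {self.p_value:.4g}",
            f"  feasible: {self.feasible}   SNPs: {self.snps_used}",
            "  weights:",
        ]
        for s, w, se in zip(self.sources, self.weights, self.weight_se):
            lines.append(f"    {s:<20s} {w: .4f} ± {se:.4f}")
        return "\n".join(lines)


class QpAdm:
    """Model a target population as a mixture of source populations.

    Parameters
    ----------
    data : GenotypeMatrix or AlleleFreqTable
    target, sources, right : population labels; ``right`` are the outgroups
        ("right" populations), the first of which is the f4 basis.
    allsnps : use each f4 cell's own maximal non-missing site set.
    """

    def __init__(self, data, target: str, sources: list[str],
                 right: list[str], allsnps: bool = True,
                 block_cm: float = 5.0) -> None:
        if len(sources) < 1:
            raise ValueError("need at least one source")
        if len(right) < len(sources) + 1:
            raise ValueError("need |right| >= number of sources + 1 "
                             "(model under-determined)")
        self.data = (allele_freqs(data) if isinstance(data, GenotypeMatrix)
                     else data)
        self.target = target
        self.sources = list(sources)
        self.right = list(right)
        self.allsnps = allsnps
        self.block_cm = block_cm
        # left set with the target as basis: X_ij = f4(S_i, T; R_j, R_0)
        self.f4mat = build_f4_matrix(self.data, [target] + self.sources, right,
                                     allsnps=allsnps, block_cm=block_cm)

    @staticmethod
    def _solve_weights(y: np.ndarray, loo: np.ndarray, w_blocks: np.ndarray,
                       tol: float = 1e-8, max_iter: int = 100,
                       ) -> tuple[np.ndarray, int, bool]:
        """Fixed-point GLS: re-estimate the covariance of w'Y at each iterate."""
        k = y.shape[0]
        ones = np.ones(k)
        w = ones / k
        n_tot = w_blocks.sum()
        h = n_tot / w_blocks
        g = len(w_blocks)
        for it in range(1, max_iter + 1):
            proj = w @ y                          # (n,)
            proj_loo = np.einsum("k,bkn->bn", w, loo)
            theta_jack = g * proj - ((1.0 - w_blocks[:, None] / n_tot) * proj_loo).sum(0)
            tau = h[:, None] * proj - (h[:, None] - 1.0) * proj_loo
            dev = tau - theta_jack
            sigma = (dev.T / (h - 1.0)) @ dev / g
            sw = _regularized_inverse(0.5 * (sigma + sigma.T))
            gmat = y @ sw @ y.T
            try:
                sol = np.linalg.solve(gmat, ones)
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(gmat, ones, rcond=None)[0]
            w_new = sol / sol.sum()
            if np.linalg.norm(w_new - w) < tol:
                return w_new, it, True
            w = w_new
        return w, max_iter, False

    def fit(self, seed: int = 0) -> QpAdmResults:
        f4mat = self.f4mat
        k = len(self.sources)
        y = f4mat.x                                # (k, n)
        B = f4mat.block_sums.shape[0]
        keep = f4mat.block_weights > 0
        loo_all = np.stack([f4mat.delete_block(b) for b in range(B)])[keep]
        w_blocks = f4mat.block_weights[keep]

        weights, n_iter, converged = self._solve_weights(y, loo_all, w_blocks)
        if not converged:
            raise RuntimeError(
                f"qpAdm weight iteration did not converge in {n_iter} steps; "
                f"last iterate {weights}")

        # SEs: refit on each delete-one-block replicate, jackknife over blocks
        g = len(w_blocks)
        w_loo = np.empty((g, k))
        for b in range(g):
            sums = f4mat.block_sums[keep].sum(0) - f4mat.block_sums[keep][b]
            counts = f4mat.block_counts[keep].sum(0) - f4mat.block_counts[keep][b]
            with np.errstate(invalid="ignore", divide="ignore"):
                y_b = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
            inner = np.delete(loo_all, b, axis=0)
            wb = np.delete(w_blocks, b)
            w_loo[b], _, _ = self._solve_weights(y_b, inner, wb,
                                                 tol=1e-8, max_iter=100)
        n_tot = w_blocks.sum()
        h = n_tot / w_blocks
        theta_jack = g * weights - ((1.0 - w_blocks[:, None] / n_tot) * w_loo).sum(0)
        tau = h[:, None] * weights - (h[:, None] - 1.0) * w_loo
        var = np.mean((tau - theta_jack) ** 2 / (h - 1.0)[:, None], axis=0)
        weight_se = np.sqrt(var)

        chi2, dof, p = qpwave_rank(f4mat, rank=k - 1, seed=seed)
        feasible = bool(np.all(weights >= -1e-9) and np.all(weights <= 1 + 1e-9))
        weights = weights / weights.sum()
        return QpAdmResults(
            target=self.target, sources=list(self.sources),
            right=list(self.right), weights=weights, weight_se=weight_se,
            chi2=chi2, dof=dof, p_value=p, feasible=feasible,
            snps_used=int(f4mat.cell_sites.max()), n_iter=n_iter,
            converged=converged, block_weights_loo=w_loo)


# ---------------------------------------------------------------------------
# Model search
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    selected: QpAdmResults | None
    ledger: pd.DataFrame

    @property
    def found(self) -> bool:
        return self.selected is not None


def model_search(data, target: str, source_pool: list[str],
                 outgroup_sets: list[tuple[str, list[str]]],
                 p_threshold: float = 0.05, allsnps: bool = True,
                 block_cm: float = 5.0, seed: int = 0,
                 minimality: bool = True) -> SearchResult:
    """Rotating-outgroup qpAdm model search.

    For each outgroup set in order: fit the full source set; while the fit
    is non-rejected (p >= threshold) but assigns some source a negative
    weight, drop the most negative source and refit.  If no working model
    emerges, advance to the next outgroup set.  Once a feasible model is
    found, smaller source subsets (of the working model's sources, smallest
    first) are tried against the same outgroup set and the minimal feasible
    model is reported.  Every fit attempted is recorded in the ledger.
    """
    if not source_pool:
        raise ValueError("empty source pool")
    if isinstance(data, GenotypeMatrix):
        data = allele_freqs(data)
    records = []
    selected: QpAdmResults | None = None

    def try_fit(sources: list[str], og_label: str, right: list[str],
                ) -> QpAdmResults | None:
        try:
            res = QpAdm(data, target, sources, right, allsnps=allsnps,
                        block_cm=block_cm).fit(seed=seed)
        except (ValueError, RuntimeError) as exc:
            records.append({"outgroup_set": og_label,
                            "sources": "+".join(sources), "p": np.nan,
                            "weights": "", "feasible": False,
                            "note": f"failed: {exc}"})
            return None
        res.outgroup_set = og_label
        records.append({"outgroup_set": og_label, "sources": "+".join(sources),
                        "p": res.p_value,
                        "weights": ",".join(f"{w:.4f}" for w in res.weights),
                        "feasible": res.feasible and res.p_value >= p_threshold,
                        "note": ""})
        return res

    for og_label, right in outgroup_sets:
        sources = [s for s in source_pool if s not in right]
        while sources:
            res = try_fit(sources, og_label, right)
            if res is None or res.p_value < p_threshold:
                break                              # this outgroup set fails
            if res.feasible:
                selected = res
                break
            worst = int(np.argmin(res.weights))
            sources = sources[:worst] + sources[worst + 1:]
        if selected is not None:
            if minimality and len(selected.sources) > 1:
                for size in range(1, len(selected.sources)):
                    for subset in itertools.combinations(selected.sources, size):
                        res = try_fit(list(subset), og_label, right)
                        if (res is not None and res.feasible
                                and res.p_value >= p_threshold):
                            selected = res
                            break
                    if len(selected.sources) == size:
                        break
            break
    ledger = pd.DataFrame(records, columns=["outgroup_set", "sources", "p",
                                            "weights", "feasible", "note"])
    return SearchResult(selected=selected, ledger=ledger)
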