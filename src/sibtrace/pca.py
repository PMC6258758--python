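"""PCA on a modern reference panel with least-squares projection.

Ancient samples have far too much missingness to enter a PCA directly, so
the standard trick is to build the principal components from complete
modern genotypes and then *project* each ancient sample: ordinary least
squares of its normalized genotypes on the site eigenvectors, restricted
to the sites actually observed.  An optional shrinkage correction rescales
projected scores by per-PC factors estimated from leave-one-out projection
of the panel itself, countering the inward bias of projecting onto
components estimated from finite panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .formats import MISSING, GenotypeMatrix


@dataclass
class PcaResults:
    """Fitted reference PCA: normalization, eigenvectors, panel scores."""

    site_mean: np.ndarray             # 2 p-hat per used site
    site_norm: np.ndarray             # sqrt(p-hat (1 - p-hat))
    used_sites: np.ndarray            # bool over the full panel
    eigenvectors: np.ndarray          # (n_used_sites, n_pc), orthonormal
    eigenvalues: np.ndarray           # non-increasing
    scores: np.ndarray                # (n_panel_individuals, n_pc)
    individual_ids: list[str]
    shrink_factors: np.ndarray | None = None

    @property
    def n_pc(self) -> int:
        return self.eigenvectors.shape[1]

    def project(self, calls: np.ndarray, shrink: bool = False,
                min_sites: int = 500) -> np.ndarray:
        """Least-squares scores for one sample with missingness.

        Only non-missing sites enter the OLS; missing sites are excluded,
        not imputed.  With ``shrink``, scores are multiplied by the per-PC
        leave-one-out factors (fit must have been run with them enabled).
        """
        calls = np.asarray(calls)
        x = calls[self.used_sites].astype(np.float64)
        obs = x != MISSING
        n_obs = int(obs.sum())
        if n_obs == 0:
            raise ValueError("sample shares no observed sites with the panel")
        if n_obs < min_sites:
            warnings.warn(f"projection uses only {n_obs} sites", stacklevel=2)
        xn = (x[obs] - self.site_mean[obs]) / self.site_norm[obs]
        v = self.eigenvectors[obs]
        s, *_ = np.linalg.lstsq(v, xn, rcond=None)
        if shrink:
            if self.shrink_factors is None:
                raise ValueError("fit was run without shrink factors")
            s = s * self.shrink_factors
        return s


class ReferencePca:
    """PCA of a (mostly complete, multi-population) reference panel.

    Genotypes are centered by twice the panel allele frequency and scaled
    by sqrt(p(1-p)); monomorphic sites are dropped.  Missing panel entries
    (tolerated up to ``max_missing`` per individual) are mean-imputed for
    the decomposition only.
    """

    def __init__(self, panel: GenotypeMatrix, n_pc: int = 10,
                 max_missing: float = 0.05) -> None:
        if panel.n_individuals <= n_pc:
            raise ValueError(f"{panel.n_individuals} individuals cannot "
                             f"support {n_pc} PCs")
        if len(panel.populations()) < 2:
            raise ValueError("reference panel needs at least 2 populations")
        miss = panel.missing_mask().mean(axis=1)
        if np.any(miss >= max_missing):
            bad = [panel.individuals[i].id for i in np.flatnonzero(miss >= max_missing)]
            raise ValueError(f"panel individuals exceed {max_missing:.0%} "
                             f"missingness: {bad[:5]}")
        self.panel = panel
        self.n_pc = n_pc

    def fit(self, shrink: bool = False, loo_individuals: int | None = 50,
            seed: int = 0) -> PcaResults:
        gm = self.panel
        calls = gm.calls.astype(np.float64)
        calls[gm.calls == MISSING] = np.nan
        p_hat = np.nanmean(calls, axis=0) / 2.0
        observed_any = ~np.isnan(p_hat)
        poly = observed_any & (p_hat > 0) & (p_hat < 1)
        mean = 2.0 * p_hat[poly]
        norm = np.sqrt(p_hat[poly] * (1.0 - p_hat[poly]))
        x = calls[:, poly]
        xn = (x - mean) / norm
        xn[np.isnan(xn)] = 0.0        # mean imputation of rare panel gaps
        u, s, vt = np.linalg.svd(xn, full_matrices=False)
        k = self.n_pc
        eigenvalues = s[:k] ** 2 / (gm.n_individuals - 1)
        eigenvectors = vt[:k].T
        scores = u[:, :k] * s[:k]
        result = PcaResults(site_mean=mean, site_norm=norm, used_sites=poly,
                            eigenvectors=eigenvectors, eigenvalues=eigenvalues,
                            scores=scores,
                            individual_ids=[i.id for i in gm.individuals])
        if shrink:
            result.shrink_factors = self._loo_shrink(xn, scores,
                                                     loo_individuals, seed)
        return result

    def _loo_shrink(self, xn: np.ndarray, full_scores: np.ndarray,
                    loo_individuals: int | None, seed: int) -> np.ndarray:
        """Mean |projected/fitted| score ratio under leave-one-out PCA.

        For each held-out panel individual, the PCA is refit without it and
        the individual projected; the per-PC ratio of projected to full-fit
        score estimates how much projection shrinks true scores toward 0.
        """
        n = xn.shape[0]
        idx = np.arange(n)
        if loo_individuals is not None and loo_individuals < n:
            idx = np.random.default_rng(seed).choice(n, loo_individuals,
                                                     replace=False)
        ratios = []
        for i in idx:
            rest = np.delete(xn, i, axis=0)
            _, s_i, vt_i = np.linalg.svd(rest, full_matrices=False)
            v_i = vt_i[: self.n_pc].T
            # sign-align the held-out basis with the full basis implicitly
            proj = xn[i] @ v_i
            full = full_scores[i]
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.abs(proj) / np.abs(full)
            ratios.append(np.where(np.abs(full) > 1e-12, r, np.nan))
        factors = np.nanmean(ratios, axis=0)
        return np.clip(np.nan_to_num(factors, nan=1.0), 1e-6, 1.0)


def plot_pca(result: PcaResults, populations: list[str], path: str,
             projected: dict[str, np.ndarray] | None = None) -> None:
    """PC1/PC2 scatter of panel individuals, with projected samples marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    pops = np.array(populations)
    for pop in np.unique(pops):
        sel = pops == pop
        ax.scatter(result.scores[sel, 0], result.scores[sel, 1], s=8,
                   alpha=0.6, label=pop)
    if projected:
        for name, sc in projected.items():
            ax.scatter(sc[0], sc[1], marker="*", s=120, edgecolor="k",
                       zorder=5)
            ax.annotate(name, (sc[0], sc[1]), fontsize=7,
                        xytext=(4, 4), textcoords="offset points")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
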