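"""Shared fixtures: small panels and the standard simulation topologies."""

import numpy as np
import pytest

from sibtrace.synthetic import (AdmixtureEvent, PopulationModel, default_panel,
                                simulate_freqs, simulate_genotypes)


@pytest.fixture(scope="session")
def small_panel():
    return default_panel(n_chrom=2, cm_per_chrom=50, sites_per_chrom=200, seed=1)


@pytest.fixture(scope="session")
def mapped_panel():
    """3 chromosomes x 100 cM, dense enough for block jackknives."""
    return default_panel(n_chrom=3, cm_per_chrom=100, sites_per_chrom=2000, seed=2)


def two_source_model(alpha=0.3, post_F=0.05, extra_source=False):
    """Two source clades, each with related rights, plus an outgroup.

    The nested drift gives every right population differential relatedness
    to the sources, which makes admixture weights identifiable.
    """
    pops = [("R0", 0.15),
            ("NorthAnc", 0.05), ("SouthAnc", 0.05),
            ("S1", 0.05, "NorthAnc"), ("R1", 0.05, "NorthAnc"),
            ("R2", 0.08, "NorthAnc"),
            ("S2", 0.05, "SouthAnc"), ("R3", 0.05, "SouthAnc"),
            ("R4", 0.08, "SouthAnc")]
    if extra_source:
        pops.append(("S3", 0.12))
    return PopulationModel(
        populations=pops,
        admixture_events=[AdmixtureEvent("T", "S1", "S2", alpha, post_F)])


RIGHTS = ["R0", "R1", "R2", "R3", "R4"]


def two_source_genotypes(panel, n_sites=None, alpha=0.3, n_per_pop=30,
                         seed=0, extra_source=False):
    model = two_source_model(alpha=alpha, extra_source=extra_source)
    n = n_sites or len(panel)
    freqs = simulate_freqs(model, n, seed=seed)
    keep = {"T", "S1", "S2", *RIGHTS}
    if extra_source:
        keep.add("S3")
    freqs = {k: v for k, v in freqs.items() if k in keep}
    return simulate_genotypes(freqs, n_per_pop, "diploid", seed + 1, panel=panel)
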