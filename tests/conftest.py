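"""Shared fixtures: a hand-built tiny library and seeded synthetic screens."""

from __future__ import annotations

import pytest

import phosphoscreen as ps


@pytest.fixture(scope="session")
def tiny_library() -> ps.PeptideLibrary:
    """Small library built from hand-written phosphosites (with multi-Tyr windows)."""
    sites = [
        ps.PhosphoSite("P001", "MAAAAAALYDEEEEEKRG", 9),
        ps.PhosphoSite("P002", "YAAAAAAAAA", 1),           # N-terminal padding
        ps.PhosphoSite("P003", "AAAAAAAAYA", 9),           # C-terminal padding
        ps.PhosphoSite("P004", "GGGGPLIYEGYEEPKGGG", 8),   # second Tyr -> mutant
        ps.PhosphoSite("P005", "KKKRLLLYKRKKAKAAQ", 8),
    ]
    return ps.build_library(sites, n_controls=2, seed=7)


@pytest.fixture(scope="session")
def sim_library() -> ps.PeptideLibrary:
    """Synthetic 500-peptide library at the default acidic-skewed composition."""
    return ps.sample_synthetic_library(500, seed=11)


@pytest.fixture(scope="session")
def planted_screen(sim_library):
    """Three replicate screens of a kinase preferring Ile at -1 and positive charge.

    Depth matches the emulated conditions: 1000 reads per peptide in the
    unsorted sample, top-25% sort, 25% mean phosphorylation extent.
    """
    model = ps.KinaseModel.with_preferences(
        {("I", -1): 1.5, ("P", 3): 1.0}, charge_coeff=0.25
    )
    config = ps.SimConfig(
        library=sim_library, reads_per_peptide_unsorted=1000, seed=202
    )
    table, results = ps.simulate_replicates(model, config, n_replicates=3)
    return model, config, table, results
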