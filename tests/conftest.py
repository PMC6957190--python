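"""Shared fixtures: panels, genotype pairs, and noise-free samples."""

from __future__ import annotations

import numpy as np
import pytest

import allofrac as af
from allofrac import GenotypeCall, SimConfig, SnpPanel, SnpTarget


@pytest.fixture(scope="session")
def panel() -> SnpPanel:
    return af.default_panel()


@pytest.fixture(scope="session")
def genotype_pair(panel):
    """A fixed unrelated recipient/donor genotype pair over the panel."""
    rec, don = af.simulate_genotype_pair(panel, 0.0, seed=5)
    return rec, don


@pytest.fixture()
def small_panel() -> SnpPanel:
    return SnpPanel([
        SnpTarget("T1", "A", "G", 0.5),
        SnpTarget("T2", "C", "T", 0.25),
        SnpTarget("T3", "G", "A", 0.4),
        SnpTarget("C1", "T", "C", 0.3, is_control=True),
    ])


def make_noiseless_sample(panel, recipient, donor, df_true, **overrides):
    """Simulate one sample with every noise source disabled."""
    cfg = SimConfig(seed=0, df_true=df_true, noise_cv=0.0,
                    crosstalk_median=0.0, **overrides)
    return af.simulate_qgt_sample(cfg, panel, recipient, donor)


@pytest.fixture()
def noiseless_sample_factory(panel, genotype_pair):
    rec, don = genotype_pair

    def factory(df_true, **overrides):
        return make_noiseless_sample(panel, rec, don, df_true, **overrides)

    return factory


def genotype_maps(panel, recipient, donor):
    targets = panel.informative_targets
    rec = {t.target_id: g for t, g in zip(targets, recipient)}
    don = {t.target_id: g for t, g in zip(targets, donor)}
    return rec, don
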