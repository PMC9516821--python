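"""Shared fixtures: small synthetic bundles generated at test time."""

import pytest

from falseloss.simulate import EVENT_TYPES, SimulationConfig, simulate_bundle


def small_config(seed: int = 9, events_per_type: int = 2, **overrides) -> SimulationConfig:
    base = dict(
        seed=seed,
        n_sequences=2,
        sequence_length=400_000,
        n_genes=40,
        n_noncoding_genes=6,
        n_repeat_copies=50,
        event_counts={t: events_per_type for t in EVENT_TYPES},
        het_site_count=30,
        n_base_errors=30,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    """A ~0.8 Mbp bundle with two engineered events per type."""
    return simulate_bundle(small_config())


@pytest.fixture(scope="session")
def null_config():
    """Degradation fully disabled: the degraded assembly equals truth."""
    return small_config(
        seed=11,
        events_per_type=0,
        dropout_steepness=0.0,
        repeat_break_fraction=0.0,
        het_site_count=0,
        n_base_errors=0,
    )
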