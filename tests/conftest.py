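import pytest

import ho1screen as h


@pytest.fixture(scope="session")
def qualifying_records():
    """300 structurally diverse qualifying imidazoles (labels all pass)."""
    records, labels = h.generate_library(h.LibrarySpec(
        n_total=300, frac_qualifying=1.0, frac_disqualified=0.0,
        frac_decoy=0.0, seed=9, max_decorations=3))
    assert all(v == "qualifying" for v in labels.values())
    return records


@pytest.fixture(scope="session")
def noise_free_activities(qualifying_records):
    spec = h.default_activity_spec(noise_sd=0.0, seed=9)
    return dict(h.simulate_activities(qualifying_records, spec))


@pytest.fixture(scope="session")
def trained_model(qualifying_records, noise_free_activities):
    """Model fit on the first 200 noise-free molecules (seeded)."""
    pairs = [(r.smiles, noise_free_activities[r.id])
             for r in qualifying_records[:200]]
    return h.train(pairs, n_epochs=20000, seed=3)


@pytest.fixture(scope="session")
def mixed_library():
    """200-compound library with a 50/30/20 qualifying mix and its labels."""
    return h.generate_library(h.LibrarySpec(n_total=200, seed=5))
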