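import numpy as np
import pytest

import nirstab as ns


@pytest.fixture
def small_grid():
    return ns.WavenumberGrid(start=4000.0, step=8.0, n_points=5)


def make_spectrum(values, grid, sample_id="s1", **meta):
    defaults = dict(brand="TT", batch_id="B001", role="product", cup="classical")
    defaults.update(meta)
    return ns.Spectrum(
        meta=ns.SpectrumMeta(sample_id=sample_id, **defaults),
        grid=grid,
        values=np.asarray(values, dtype=float),
    )


def random_set(rng, n, grid, brand="TT", role="product", prefix="s"):
    spectra = [
        make_spectrum(
            rng.normal(size=grid.n_points),
            grid,
            sample_id=f"{prefix}{i}",
            brand=brand,
            batch_id=f"B{i % 3}",
            role=role,
        )
        for i in range(n)
    ]
    return ns.SpectrumSet(grid=grid, spectra=spectra)


@pytest.fixture(scope="session")
def demo_study():
    """Desk-scale default study, fixed seed, shared across tests."""
    return ns.simulate_study(ns.scaled_study_config(seed=1))


@pytest.fixture(scope="session")
def demo_report(demo_study):
    """Full analysis of the desk-scale study (preprocess, fit, score, compare)."""
    return ns.analyze_study(demo_study)
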