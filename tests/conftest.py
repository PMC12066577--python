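import numpy as np
import pytest

from clonefate import classify as cls
from clonefate import synthetic as syn


@pytest.fixture(scope="session")
def th17_population():
    """Medium Th17 cohort with default study conditions (seeded)."""
    spec = syn.th17_spec(n_clones=150)
    return spec, syn.simulate_population(spec, seed=11)


@pytest.fixture(scope="session")
def treg_population():
    spec = syn.treg_spec(n_clones=150)
    return spec, syn.simulate_population(spec, seed=12)


@pytest.fixture(scope="session")
def calibrated_threshold(th17_population, treg_population):
    """Naive response threshold from the t0 signals of all simulated wells."""
    records = th17_population[1] + treg_population[1]
    t0_G = [r.trace.total_G[0] for r in records]
    t0_R = [r.trace.total_R[0] for r in records]
    return cls.compute_response_threshold(t0_G, t0_R, k=3.0)


def single_fate_population(fate, n, seed, **overrides):
    """Cohort with one forced fate under the fate's native condition."""
    maker = syn.treg_spec if fate == "SPF" else syn.th17_spec
    spec = maker(n_clones=n, fate_fractions={fate: 1.0}, **overrides)
    return spec, syn.simulate_population(spec, seed=seed)


def pixel_wells(fate, n, seed, last_only=True, **pixel_kwargs):
    """Pixel-rendered wells of one fate; only the last 5 frames by default."""
    spec, records = single_fate_population(fate, n, seed)
    idx = range(spec.n_frames - 5, spec.n_frames) if last_only else None
    return [syn.simulate_well_pixels(r.params, spec, well_id=r.well_id,
                                     frame_indices=idx, **pixel_kwargs)
            for r in records]
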