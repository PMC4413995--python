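import numpy as np
import pytest
from hypothesis import settings

from suscape import depth as dp
from suscape import simulate as sim

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """2 Mb masked genome shared by unit tests."""
    return sim.simulate_genome(2_000_000, seed=11)


@pytest.fixture(scope="session")
def cohort():
    """A small full cohort: genome, planted truth, grid, per-population CN.

    5 Mb, 7 populations x 2 individuals at 5x each (10x pooled), 20 planted
    variable regions; session-scoped because several modules test against
    the same world.
    """
    genome = sim.simulate_genome(5_000_000, seed=21)
    landscape = sim.plant_cn_landscape(genome, n_regions=20, seed=22)
    grid = dp.build_bins(genome)
    seeds = sim.simulate_seed_regions(genome, seed=23)
    cn_tracks = {}
    for pi, pop in enumerate(landscape.populations):
        individuals = [
            dp.track_from_bins(
                grid,
                sim.simulate_depth_track(
                    genome, landscape, pop, sim.ReadDepthSimConfig(5.0, seed=500 + pi * 10 + k)
                ),
                f"{pop}_{k + 1}",
            )
            for k in range(2)
        ]
        cn_tracks[pop] = dp.depth_to_cn(individuals, grid, seeds, population=pop).cn
    return {
        "genome": genome,
        "landscape": landscape,
        "grid": grid,
        "seed_regions": seeds,
        "cn_tracks": cn_tracks,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
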