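import numpy as np
import pytest

from spherotype.profiles import PlotProfile, SpheroidStack
from spherotype.synthetic import (CellLineSpec, SimulationConfig,
                                  TreatmentSchedule, default_cohort_specs,
                                  generate_cohort)


@pytest.fixture
def basic_spec():
    return CellLineSpec("TEST", doubling_time_h=48.0, gi50_true=1.0,
                        emax_true=0.9, hill=1.5, rim_fraction=0.3,
                        core_fraction=0.3, regrows_after_washout=False,
                        ocr_ecar=1.0)


@pytest.fixture
def schedule():
    return TreatmentSchedule()


@pytest.fixture
def noiseless_config():
    return SimulationConfig(noise_cv=0.0, n_growth_replicates=3,
                            n_viability_replicates=1, rng_seed=0)


@pytest.fixture
def small_image_config():
    return SimulationConfig(noise_cv=0.0, n_growth_replicates=3,
                            n_viability_replicates=1, rng_seed=0,
                            image_size_px=129, pixel_size_um=8.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Two lines, noiseless, coarse images: fast but fully analyzable."""
    cfg = SimulationConfig(noise_cv=0.0, n_growth_replicates=4,
                           n_viability_replicates=2, rng_seed=11,
                           image_size_px=129, pixel_size_um=8.0)
    return generate_cohort(default_cohort_specs()[:2], TreatmentSchedule(), cfg)


def make_profile(values_by_channel, spacing_um=1.0, smoothed=False):
    first = next(iter(values_by_channel.values()))
    n = len(first)
    return PlotProfile(
        positions_um=np.arange(n, dtype=float) * spacing_um,
        intensities={k: np.asarray(v, dtype=float)
                     for k, v in values_by_channel.items()},
        pixel_size_um=spacing_um,
        smoothed=smoothed,
    )


def uniform_stack(value=2.0, z=4, size=32, pixel_size_um=1.0):
    vox = np.full((3, z, size, size), float(value))
    return SpheroidStack(voxels=vox, pixel_size_um=pixel_size_um)
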