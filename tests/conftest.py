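import numpy as np
import pytest

from venalamina.core_io import StudyConfig
from venalamina.phantom import (
    MetricParams,
    PhantomSpec,
    QsmParams,
    generate_cohort,
    make_surfaces,
)


def small_spec(**overrides) -> PhantomSpec:
    """A fast phantom: 1 mm voxels, 48 mm slab, 3 veins."""
    kwargs = dict(
        n_young=3,
        n_old=3,
        grid_shape=(48, 48, 40),
        spacing=(1.0, 1.0, 1.0),
        fold_amplitude_mm=3.0,
        fold_wavelength_mm=24.0,
        thickness_mm=5.0,
        n_veins=3,
        vein_radius_mm=1.2,
        vein_min_separation_mm=12.0,
        seed=7,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def flat_spec(**overrides) -> PhantomSpec:
    return small_spec(fold_amplitude_mm=0.0, **overrides)


@pytest.fixture(scope="session")
def spec():
    return small_spec()

@pytest.fixture(scope="session")
def cohort(spec):
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def subject(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def surfaces(spec):
    return make_surfaces(spec)


@pytest.fixture()
def config():
    return StudyConfig(seed=7, B_perm=2000, B_boot=200,
                       vesselness_scales_mm=(1.0, 1.5))


def noise_free_spec(**overrides) -> PhantomSpec:
    """All randomness off except vein placement: for analytic checks."""
    qt1 = MetricParams(
        baselines=(1692.0, 1736.0), depth_gradient=-374.0,
        slope_young=-14.4, slope_old=1.8, group_offset_old=-24.0,
        subject_sd=0.0, voxel_sd=0.0,
    )
    pos = MetricParams(baselines=(0.013, 0.010), depth_gradient=-0.004,
                       curvature=1.5e-4, group_offset_old=0.0047,
                       subject_sd=0.0, voxel_sd=0.0)
    neg = MetricParams(baselines=(0.009, 0.011), depth_gradient=0.002,
                       curvature=1.0e-4, group_offset_old=0.003,
                       subject_sd=0.0, voxel_sd=0.0)
    kwargs = dict(qt1=qt1, qsm=QsmParams(pos=pos, neg=neg),
                  background_qsm_sd=0.0)
    kwargs.update(overrides)
    return small_spec(**kwargs)
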