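import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pmbrt import synthetic as syn
from pmbrt.pipeline import FieldSpec, PlanSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def glioma_cfg():
    """Bundled glioma-like 4 mm ctc field config, noise off."""
    cfg = syn.MinibeamPlanConfig.bundled("glioma_field2_ctc4")
    return dataclasses.replace(cfg, noise_rel=0.0)


@pytest.fixture(scope="session")
def glioma_field(glioma_cfg):
    """Noise-free glioma ctc-4 dose and LET grids on the default lattice."""
    dose, let = syn.generate_pmbrt_dose(glioma_cfg)
    return dose, let


@pytest.fixture(scope="session")
def glioma_cfg6():
    cfg = syn.MinibeamPlanConfig.bundled("glioma_field2_ctc6")
    return dataclasses.replace(cfg, noise_rel=0.0)


@pytest.fixture(scope="session")
def small_grid():
    """Compact lattice for pipeline-level tests (24 x 2 x 110 mm)."""
    return syn.GridSpec(shape=(49, 5, 220), spacing=(0.5, 0.5, 0.5),
                        origin=(-12.0, -1.0, 0.0))


@pytest.fixture(scope="session")
def small_plan(small_grid):
    """Two-field ctc-6 minibeam plan on the compact lattice."""
    base = syn.MinibeamPlanConfig(
        ctc=6.0, n_slits=5, target_band=(75.0, 95.0), noise_rel=0.03,
        fwhm_model=[[0.0, 1.0], [40.0, 1.6], [80.0, 3.1], [200.0, 3.2]],
        halo_fraction_model=[[0.0, 0.07], [60.0, 0.12], [78.0, 0.55],
                             [200.0, 0.65]],
        name="small_ctc6")
    fields = [
        FieldSpec(dataclasses.replace(base, slit_offset=0.0)),
        FieldSpec(dataclasses.replace(base, slit_offset=3.0)),
    ]
    return PlanSpec(
        name="small_ctc6_plan", fields=fields, grid=small_grid,
        ptv=((-6.5, -100.0, 75.0), (6.5, 100.0, 95.0)),
        organs={"brain": ((-10.0, -100.0, 2.0), (10.0, 100.0, 60.0))},
        depths=[10.0, 40.0], seed=11)


def gaussian_profile_array(ctc: float, n_slits: int, fwhm: float,
                           step: float = 0.05, margin: float = 4.0):
    """Idealised halo-free minibeam comb sampled on a fine lateral grid."""
    cfg = syn.MinibeamPlanConfig(
        ctc=ctc, n_slits=n_slits, halo_fraction_model=0.0,
        fwhm_model=[[0.0, fwhm], [200.0, fwhm]])
    half = (n_slits - 1) / 2.0 * ctc + margin
    x = np.arange(-half, half + step / 2, step)
    return x, syn.lateral_minibeam_profile(x, 50.0, cfg)
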