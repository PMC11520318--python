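import numpy as np
import pytest

from deformacyte.simkit import (AcquisitionSettings, ChannelGeometry,
                                CohortConfig, ParticleTruth)


@pytest.fixture(scope="session")
def geom():
    return ChannelGeometry()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionSettings()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_particle(kind="bead", diameter_um=10.0, deform=1.0, skew=0.0,
                  y_um=0.0, z_um=0.0, velocity=0.144, t_entry=5e-3,
                  pid=0) -> ParticleTruth:
    return ParticleTruth(id=pid, kind=kind, diameter_um=diameter_um,
                         deform_true=deform, deform_optical=deform,
                         tail_skew=skew, y_um=y_um, z_um=z_um,
                         velocity_m_s=velocity, t_entry_s=t_entry,
                         group="test", flow_ul_min=5.0)


def spaced_particles(n, kind="bead", diameter_um=10.0, deform=1.0,
                     velocity=0.144, gap_s=20e-3):
    """Well-separated particles: no event overlap, deterministic timing."""
    return [make_particle(kind=kind, diameter_um=diameter_um, deform=deform,
                          velocity=velocity, t_entry=5e-3 + i * gap_s, pid=i)
            for i in range(n)]


@pytest.fixture(scope="session")
def small_cohort_cfg():
    return CohortConfig(n_cells=60, n_beads=20, seed=11)
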