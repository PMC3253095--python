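import numpy as np
import pytest

from trialprep.core_io import VolumeSeries
from trialprep.synthetic import SimConfig, make_phantom, simulate_session

VOXELS = (2.0, 2.0, 2.0)
SHAPE = (32, 32, 8)


@pytest.fixture(scope="session")
def phantom():
    """One small phantom shared across tests: (baseline, brain, muscle)."""
    return make_phantom(SHAPE, VOXELS, seed=0)


@pytest.fixture(scope="session")
def clean_session():
    """Small session with activation + noise but no artefacts or motion."""
    cfg = SimConfig.small(seed=11).replace(
        shift_amplitude_mm=0.0, gap_shift_mm=0.0, ghost_fraction=0.0,
        affine_max_translation_mm=0.0, affine_max_rotation_rad=0.0,
        affine_max_scale_dev=0.0, affine_max_shear=0.0)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def corrupted_session():
    """Small session with the default corruption plus one bad trial."""
    cfg = SimConfig.small(seed=7).replace(bad_trial_ids=(2,))
    return cfg, simulate_session(cfg)


def series_from_volumes(volumes, tr=1.0, voxel_size=(1.0, 1.0, 1.0),
                        phase_axis="y", run_lengths=None):
    """1-run (or multi-run) series from a list of 3D volumes."""
    data = np.stack(volumes, axis=-1)
    if run_lengths is None:
        run_lengths = [data.shape[-1]]
    return VolumeSeries.from_runs(data, voxel_size, tr, phase_axis, run_lengths)
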