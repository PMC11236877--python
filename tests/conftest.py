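"""Shared fixtures: all synthetic inputs are generated at test time.

Session-scoped fixtures cache the expensive simulations (multifocal decode
runs) so several test modules can share them.
"""

import numpy as np
import pytest

from vepkit import stimulus as st
from vepkit import synth
from vepkit.mfvep import derive_channels, extract_sector_responses


@pytest.fixture(scope="session")
def geometry():
    return st.build_dartboard_geometry()


@pytest.fixture(scope="session")
def mseqs():
    return st.generate_msequences(seed=1)


@pytest.fixture(scope="session")
def mono_mf_schedule(mseqs):
    """Monocular (left-eye) 8-segment multifocal schedule."""
    return st.build_mfvep_schedule(mseqs, segments=8, eyes="L")


@pytest.fixture(scope="session")
def noiseless_single_sector(mono_mf_schedule, geometry):
    """Noiseless simulation with only sector 5 active, decoded on D1..D4.

    Returns (responses-by-(sector, channel), kernel, schedule, recording).
    """
    gains = np.zeros(36)
    gains[4] = 1.0
    cfg = synth.SimulationConfig(
        seed=0, sector_gains=gains, noise_rms_uv=0.0, alpha_rate_hz=0.0, artifact_rate_hz=0.0
    )
    rec = synth.simulate_mfvep_recording(mono_mf_schedule, cfg, geometry=geometry)
    derived = derive_channels(rec)
    responses = extract_sector_responses(derived, mono_mf_schedule, geometry=geometry)
    kern = synth.make_vep_template(100.0, 1.0, 25.0)
    by = {(r.sector_id, r.derived_channel): r for r in responses}
    return by, kern, mono_mf_schedule, rec


@pytest.fixture(scope="session")
def defect_dataset(mseqs):
    """Default-noise artificial-defect set, 3 ring-mask tests (108 sectors)."""
    return synth.make_artificial_defect_dataset(n_tests=3, seed=5, mseqs=mseqs)


@pytest.fixture(scope="session")
def ffvep_recording():
    """Default-noise full-field recording (both eyes, defaults)."""
    sched = st.build_ffvep_schedule(seed=2)
    return synth.simulate_ffvep_recording(sched, synth.SimulationConfig(seed=3))
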