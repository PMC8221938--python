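import numpy as np
import pytest

from refocal.model import OpticalSystem, apparent_positions
from refocal.tracking import Trajectory


@pytest.fixture
def etl_system() -> OpticalSystem:
    """Strongly non-telecentric tunable-lens system (worked-example values)."""
    return OpticalSystem(f=4.0, n=1.33, x_error=0.4, z_error=26.6)


@pytest.fixture
def aol_system() -> OpticalSystem:
    """Realistic acousto-optic-lens misalignments: (2.3, 1.3, -69) mm."""
    return OpticalSystem(f=12.5, n=1.33, x_error=2.3, y_error=1.3,
                         z_error=-69.0)


def synthetic_trajectories(system: OpticalSystem, kappas, beads,
                           noise_um: float = 0.0, rng=None):
    """Trajectory objects straight from the apparent-position model.

    ``noise_um`` is the RMS 2-D localization error (per-axis sigma is
    noise_um / sqrt(2)); z_cmd is the naive telecentric commanded depth.
    """
    beads = np.asarray(beads, dtype=float)
    kappas = np.asarray(kappas, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    z_cmd = -system.nf2 * kappas * 1e3
    trajs = []
    for b, bead in enumerate(beads):
        xy = np.array([apparent_positions(system, bead[None, :], k)[0]
                       for k in kappas])
        if noise_um > 0:
            xy = xy + rng.normal(0.0, noise_um / np.sqrt(2), size=xy.shape)
        trajs.append(Trajectory(b, np.arange(len(kappas)), z_cmd, xy))
    return trajs
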