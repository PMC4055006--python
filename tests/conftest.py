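import numpy as np
import pytest

from magtarget import MagnetSpec, calibrate_remanence


@pytest.fixture(scope="session")
def study_magnet() -> MagnetSpec:
    """8-mm-diameter, 8-mm-long cylinder calibrated to a 600-mT face field."""
    br = calibrate_remanence(0.600, 4e-3, 8e-3)
    return MagnetSpec(radius_m=4e-3, length_m=8e-3, remanence_t=br)


def disk_charge_oracle(rho, z, magnet: MagnetSpec, n=400):
    """Brute-force surface-charge field: fine midpoint Riemann sum over both
    charged pole-face disks. Independent of the closed-form implementation.

    Returns the (B_rho, B_z) pair in the magnet frame.
    """
    R, L, Br = magnet.radius_m, magnet.length_m, magnet.remanence_t
    r_edges = np.linspace(0.0, R, n + 1)
    rc = 0.5 * (r_edges[1:] + r_edges[:-1])
    phi = (np.arange(n) + 0.5) * 2 * np.pi / n
    dA = np.outer(np.diff(r_edges) * rc, np.full(n, 2 * np.pi / n))
    X = np.outer(rc, np.cos(phi))
    Y = np.outer(rc, np.sin(phi))
    out = np.zeros(3)
    for z_disk, sign in ((0.0, 1.0), (-L, -1.0)):
        dx = rho - X
        dy = -Y
        dz = z - z_disk
        d3 = (dx ** 2 + dy ** 2 + dz ** 2) ** 1.5
        out[0] += sign * np.sum(dx / d3 * dA)
        out[2] += sign * np.sum(dz / d3 * dA)
    out *= Br / (4 * np.pi)
    return out[0], out[2]


@pytest.fixture(scope="session")
def field_oracle():
    return disk_charge_oracle
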