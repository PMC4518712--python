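"""Shared fixtures: expensive multi-seed fit campaigns are session-scoped so
parameter-recovery, fit-statistic and mass-conservation checks reuse one run.
"""

import numpy as np
import pytest

import assocfit as af
from assocfit import synthetic as synth

FULL_LENGTH_KD = 7e-6  # molar, AUC dimerization constant, full-length
FRAGMENT_KD = 0.53e-6  # SH3-PR1-BH-PR2 fragment
WEAK_KD = 163e-6  # PR1-BH fragment (monomer-dimer only)


def run_se_recovery(kd, monomer_mass, seeds):
    """Generate + globally fit the 3-speed x 3-loading design per seed."""
    fits = []
    for seed in seeds:
        exp = synth.gen_se(kd, monomer_mass=monomer_mass, seed=seed)
        fits.append(af.SEGlobalFitter().fit(exp))
    return fits


@pytest.fixture(scope="session")
def full_length_se_fits():
    """25-seed recovery campaign at the full-length design (84 kDa)."""
    return run_se_recovery(FULL_LENGTH_KD, 84_000.0, range(1, 26))


@pytest.fixture(scope="session")
def sphere_radii():
    """Radii set for single-pseudo-atom toy spheres."""
    return {"C": 8.0}


@pytest.fixture()
def rng():
    return np.random.default_rng(20150729)
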