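import numpy as np
import pytest

from hgpair import ActivityPair, IsomerConstants, PhantomSpec, UniformCylinder

# the ten acquisition times (hours) of the 120 h uniformity imaging schedule
UNIFORMITY_SCHEDULE = (0.0, 2.0, 3.7, 23.3, 26.3, 31.7, 47.0, 70.1, 95.4, 118.5)

# uniformity-phantom initial concentrations (MBq/mL): ground 3.58, metastable 0.832
UNIFORMITY_CONC = ActivityPair(a_m=0.832, a_g=3.58)


@pytest.fixture(scope="session")
def k():
    """Default nuclear constants of the Hg-197m/g pair."""
    return IsomerConstants()


@pytest.fixture(scope="session")
def uniformity_spec():
    """Digital twin of the uniform syringe phantom."""
    return PhantomSpec(
        geometry=UniformCylinder(radius=7.0, length=22.0),
        concentration=UNIFORMITY_CONC,
    )


def rk4_activity_pair(a0_m, a0_g, t, k, model="published", n_steps=10000):
    """Fixed-step RK4 oracle for the coupled activity system.

    Integrates the atom-level linear system whose exact solution is the
    analytic expression under test: the metastable atom count decays at
    the total constant lambda_m, the ground-state production comes from a
    feed pool decaying at lambda_IT (published correction) or lambda_m
    (strict branched chain), feeding lambda_IT x pool into the ground
    state.  Vectorized over arrays of initial conditions and times.
    """
    a0_m = np.asarray(a0_m, float)
    a0_g = np.asarray(a0_g, float)
    t = np.asarray(t, float)
    lam_m, lam_g, lam_it = k.lam_m, k.lam_g, k.lam_it
    lam_f = lam_it if model == "published" else lam_m
    n_m = a0_m / lam_m
    u = a0_m / lam_m
    n_g = a0_g / lam_g
    h = t / n_steps

    def deriv(state):
        nm, uu, ng = state
        return np.array([-lam_m * nm, -lam_f * uu, lam_it * uu - lam_g * ng])

    state = np.array([n_m, u, n_g])
    for _ in range(n_steps):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * h * k1)
        k3 = deriv(state + 0.5 * h * k2)
        k4 = deriv(state + h * k3)
        state = state + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return lam_m * state[0], lam_g * state[2]
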