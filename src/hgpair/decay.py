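"""Coupled decay of the Hg-197m / Hg-197g isomer pair.

Hg-197m (t1/2 = 23.8 h) feeds Hg-197g (t1/2 = 64.14 h) by isomeric
transition with 91.4% branching, so the ground-state activity at any time
mixes its own decay with grow-in from the metastable parent.  This module
provides the analytic forward solution of that system, its exact inverse
(decay correction to a reference time), activity/atom/mole conversions,
and mono-exponential decay fitting for phantom time series.

Two grow-in conventions are supported:

``model="published"`` (default)
    The correction applied throughout the imaging workflow: the grow-in
    term uses the *partial* isomeric-transition constant
    lambda_IT = branch_it * lambda_m in both the exponent and the
    denominator,

        A_g(t) = lambda_IT/(lambda_g - lambda_IT) * (lambda_g/lambda_m)
                 * A_m(0) * (exp(-lambda_IT t) - exp(-lambda_g t))
                 + A_g(0) * exp(-lambda_g t).

``model="chain"``
    The strict branched Bateman chain, in which the parent population
    decays with its *total* constant lambda_m and only the branch fraction
    feeds the daughter (the grow-in exponent is exp(-lambda_m t) and the
    denominator lambda_g - lambda_m).

Over the 120 h study window the two differ by under 3% of the metastable
contribution; see docs/methods.md for the comparison.  All times are in
hours and activities in MBq; seconds and becquerels appear only inside the
atom-count conversions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AVOGADRO",
    "IsomerConstants",
    "ActivityPair",
    "DecayFit",
    "InconsistentActivityError",
    "decay_constant",
    "bateman_forward",
    "decay_correct",
    "atoms_from_activity",
    "metal_ligand_ratio",
    "ground_fraction",
    "fit_monoexp",
]

AVOGADRO = 6.02214076e23  # atoms / mol

#: relative |lambda_g - lambda_feed| below which the analytic limit is used
_DEGENERATE_RTOL = 1e-9

#: implied negative ground-state activity within this relative tolerance of
#: the grow-in contribution is treated as numerical zero by decay_correct
_CORRECT_CLAMP_RTOL = 1e-9


class InconsistentActivityError(ValueError):
    """Measured ground-state activity below the unavoidable grow-in.

    Raised by :func:`decay_correct` when the implied initial ground-state
    activity is negative beyond numerical tolerance — a signature of
    energy-window cross-talk or bad timestamps rather than of decay.
    """


def _default_photon_lines() -> dict[str, tuple[tuple[float, float], ...]]:
    # (energy keV, intensity fraction); IAEA chart values used for HPGe
    # quantification: 133.98 keV and 164.97 keV for m, 77.35 and 279 for g.
    return {
        "m": ((133.98, 0.335), (164.97, 0.002618)),
        "g": ((77.35, 0.187), (279.0, 0.061)),
    }


@dataclass(frozen=True)
class IsomerConstants:
    """Nuclear constants of the isomer pair (config-overridable).

    Parameters
    ----------
    half_life_m, half_life_g : float
        Physical half-lives in hours (defaults 23.8 and 64.14).
    branch_it : float
        Fraction of metastable decays proceeding by isomeric transition
        to the ground state (default 0.914).
    photon_lines : dict
        Per-isomer ``(energy_keV, intensity)`` tuples; metadata only.
    """

    half_life_m: float = 23.8
    half_life_g: float = 64.14
    branch_it: float = 0.914
    photon_lines: dict = field(default_factory=_default_photon_lines)

    def __post_init__(self) -> None:
        if not (self.half_life_m > 0 and self.half_life_g > 0):
            raise ValueError("half-lives must be positive")
        if not (0 < self.branch_it <= 1):
            raise ValueError("branch_it must lie in (0, 1]")

    @property
    def lam_m(self) -> float:
        """Total decay constant of the metastable state (1/h)."""
        return decay_constant(self.half_life_m)

    @property
    def lam_g(self) -> float:
        """Decay constant of the ground state (1/h)."""
        return decay_constant(self.half_life_g)

    @property
    def lam_it(self) -> float:
        """Partial isomeric-transition constant, branch_it * lam_m (1/h)."""
        return self.branch_it * self.lam_m


@dataclass(frozen=True)
class ActivityPair:
    """Activities of both isomers at a common time point.

    ``a_m`` and ``a_g`` are in MBq (or MBq/mL when used as concentrations);
    ``t`` is hours since the reference time.
    """

    a_m: float
    a_g: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.a_m < 0 or self.a_g < 0:
            raise ValueError("activities must be nonnegative")
        if not math.isfinite(self.t):
            raise ValueError("time must be finite")

    @property
    def total(self) -> float:
        return self.a_m + self.a_g


@dataclass(frozen=True)
class DecayFit:
    """Result of a mono-exponential fit A0 * exp(-lambda t)."""

    amplitude: float
    half_life: float
    half_life_sigma: float
    residual_rms: float

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("fitted half-life must be positive")
        if self.half_life_sigma < 0:
            raise ValueError("half-life sigma must be nonnegative")


def decay_constant(half_life: float) -> float:
    """Return lambda = ln 2 / half-life; units are 1/(unit of half_life)."""
    if half_life <= 0:
        raise ValueError(f"half-life must be positive, got {half_life}")
    return math.log(2.0) / half_life


def _feed_constant(k: IsomerConstants, model: str) -> float:
    """Effective decay constant of the grow-in source term."""
    if model == "published":
        return k.lam_it
    if model == "chain":
        return k.lam_m
    raise ValueError(f"unknown decay model {model!r}")


def _growin(a0_m: float, t, k: IsomerConstants, model: str = "published"):
    """Ground-state activity grown in from ``a0_m`` MBq of the metastable
    state after ``t`` hours (vectorized in ``t``)."""
    t = np.asarray(t, dtype=float)
    lam_f = _feed_constant(k, model)
    lam_g = k.lam_g
    if abs(lam_g - lam_f) < _DEGENERATE_RTOL * lam_g:
        # analytic limit of the singular quotient as lam_f -> lam_g
        return a0_m * k.branch_it * lam_g * t * np.exp(-lam_g * t)
    coeff = k.lam_it / (lam_g - lam_f) * (lam_g / k.lam_m)
    return coeff * a0_m * (np.exp(-lam_f * t) - np.exp(-lam_g * t))


def bateman_forward(
    a0: ActivityPair, t: float, k: IsomerConstants, model: str = "published"
) -> ActivityPair:
    """Evolve activities from the reference time of ``a0`` by ``t`` hours.

    The metastable state decays as ``a_m(t) = a0.a_m * exp(-lam_m t)``;
    the ground state adds grow-in from the metastable parent to its own
    exponential decay (see module docstring for the two conventions).
    Negative ``t`` evaluates the same analytic expressions (continuation
    backwards in time), which may yield a negative ground-state value when
    the queried pair could not have arisen from nonnegative initials.
    """
    am = a0.a_m * math.exp(-k.lam_m * t)
    ag = float(_growin(a0.a_m, t, k, model)) + a0.a_g * math.exp(-k.lam_g * t)
    if t < 0 and -1e-12 < ag < 0:
        ag = 0.0  # continuation roundoff at the nonnegativity boundary
    return ActivityPair(a_m=am, a_g=ag, t=a0.t + t)


def decay_correct(
    at: ActivityPair, k: IsomerConstants, model: str = "published"
) -> ActivityPair:
    """Invert :func:`bateman_forward`: activities at ``at.t`` back to t = 0.

    The metastable inversion is a pure exponential; the ground-state
    inversion subtracts the grow-in contribution of the corrected
    metastable activity before undoing the exponential.  The roundtrip
    ``bateman_forward(decay_correct(x), x.t)`` reproduces ``x`` to
    ~1e-10 relative.

    Raises
    ------
    InconsistentActivityError
        If the measured ground-state activity is smaller than the grow-in
        alone can explain (beyond 1e-9 relative), which indicates window
        cross-talk or a timestamp error.  Deficits within tolerance are
        treated as exactly zero initial ground-state activity.
    """
    t = at.t
    if t < 0:
        raise ValueError("measurement time must be >= 0 for decay correction")
    a0_m = at.a_m * math.exp(k.lam_m * t)
    growin = float(_growin(a0_m, t, k, model))
    residual = at.a_g - growin
    a0_g = residual * math.exp(k.lam_g * t)
    if a0_g < 0:
        scale = max(growin, abs(at.a_g), 1e-300) * math.exp(k.lam_g * t)
        if -a0_g <= _CORRECT_CLAMP_RTOL * scale:
            a0_g = 0.0
        else:
            raise InconsistentActivityError(
                f"measured ground-state activity {at.a_g:.6g} MBq at "
                f"t={t:.4g} h is {growin - at.a_g:.4g} MBq below the "
                f"unavoidable grow-in {growin:.6g} MBq from the metastable "
                "state; check energy-window cross-talk and timestamps"
            )
    return ActivityPair(a_m=a0_m, a_g=a0_g, t=0.0)


def atoms_from_activity(a: float, lam: float) -> float:
    """Number of atoms N = A / lambda for activity ``a`` in MBq.

    ``lam`` is the decay constant in 1/h; it is converted to 1/s so that
    the MBq activity (1e6 decays/s) divides consistently.
    """
    if lam <= 0:
        raise ValueError(f"decay constant must be positive, got {lam}")
    if a < 0:
        raise ValueError("activity must be nonnegative")
    return (a * 1e6) / (lam / 3600.0)


def metal_ligand_ratio(
    total_activity: float,
    fraction_m: float,
    ligand_amount: float,
    k: IsomerConstants,
) -> float:
    """Ligand-to-metal mole ratio of a radiolabeling reaction.

    The mercury inventory is inferred from the total activity split
    between the isomers: N = A_m/lam_m + A_g/lam_g atoms, converted to
    moles.  ``ligand_amount`` is in mol.  Returns ligand moles per metal
    mole (the "L" of an M:L = 1:L ratio).
    """
    if not 0 <= fraction_m <= 1:
        raise ValueError("fraction_m must lie in [0, 1]")
    if ligand_amount <= 0:
        raise ValueError("ligand amount must be positive")
    if total_activity <= 0:
        raise ZeroDivisionError(
            "total activity must be positive to infer the metal amount"
        )
    atoms = atoms_from_activity(
        total_activity * fraction_m, k.lam_m
    ) + atoms_from_activity(total_activity * (1.0 - fraction_m), k.lam_g)
    metal_moles = atoms / AVOGADRO
    return ligand_amount / metal_moles


def ground_fraction(a: ActivityPair) -> float:
    """Fraction of the total activity carried by the ground state."""
    if a.total <= 0:
        raise ValueError("total activity must be positive")
    return a.a_g / a.total


def _monoexp(t, a0, lam):
    return a0 * np.exp(-lam * t)


def fit_monoexp(times, values, sigmas=None) -> DecayFit:
    """Least-squares fit of A0 * exp(-lambda t) on the linear scale.

    Initialized from a log-linear regression when all values are positive,
    otherwise from a coarse grid over plausible decay constants.  The fit
    is unweighted unless per-point ``sigmas`` are supplied.  Returns the
    amplitude, the fitted half-life with its 1-sigma uncertainty from the
    parameter covariance, and the RMS residual.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be matching 1-D arrays")
    if t.size < 2:
        raise ValueError("need at least two points to fit a decay curve")
    if np.ptp(y) == 0:
        raise ValueError("flat series: no decay to fit")

    if np.all(y > 0):
        # log-linear initialization
        slope, intercept = np.polyfit(t, np.log(y), 1)
        lam0 = max(-slope, 1e-12)
        a0 = math.exp(intercept)
    else:
        span = np.ptp(t) or 1.0
        grid = np.log(2.0) / (span * np.array([0.05, 0.2, 1.0, 5.0, 20.0]))
        pos = y > 0
        if not pos.any():
            raise ValueError("all values nonpositive: cannot fit a decay")
        a0 = float(y[pos].max())
        sse = [np.sum((y - _monoexp(t, a0, g)) ** 2) for g in grid]
        lam0 = float(grid[int(np.argmin(sse))])

    popt, pcov = curve_fit(
        _monoexp,
        t,
        y,
        p0=(a0, lam0),
        sigma=None if sigmas is None else np.asarray(sigmas, float),
        absolute_sigma=sigmas is not None,
        maxfev=10000,
    )
    a0_fit, lam_fit = popt
    if lam_fit <= 0:
        raise ValueError("fitted decay constant is nonpositive")
    half_life = math.log(2.0) / lam_fit
    lam_var = pcov[1, 1] if np.all(np.isfinite(pcov)) else 0.0
    # delta method: d(t_half)/d(lambda) = -ln2 / lambda^2
    hl_sigma = math.log(2.0) / lam_fit**2 * math.sqrt(max(lam_var, 0.0))
    resid = y - _monoexp(t, a0_fit, lam_fit)
    return DecayFit(
        amplitude=float(a0_fit),
        half_life=float(half_life),
        half_life_sigma=float(hl_sigma),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
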