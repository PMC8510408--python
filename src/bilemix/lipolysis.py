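"""pH-stat lipolysis: NaOH titration volumes to %FFA release curves.

In a pH-stat digestion assay the free fatty acids (FFA) liberated by
pancreatic lipase are continuously neutralized with NaOH at fixed pH, so
the cumulative titrant volume tracks the extent of hydrolysis. With
sn-1,3-specific lipase each triacylglycerol yields two titratable FFA, so

    %FFA(t) = 100 * n_NaOH(t) / (2 * m_lipid / M_lipid)

with n_NaOH(t) = V(t) * c_NaOH. The factor 2 is configurable (3 for full
hydrolysis). Release curves are summarised by a first-order model
Phi(t) = Phi_max * (1 - exp(-k t)) and conditions compared by a Welch
t-test on %FFA at a common time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FittingError
from .meta_pls import welch_t_test

__all__ = [
    "LipolysisRun",
    "FfaProfile",
    "FirstOrderFit",
    "ffa_percent",
    "fit_first_order",
    "compare_conditions",
]

#: FFA equivalents titrated per triacylglycerol under sn-1,3 specificity.
DEFAULT_FFA_PER_TAG = 2.0
#: Conventional molar mass of sunflower-oil triacylglycerol, g/mol.
DEFAULT_OIL_MOLAR_MASS = 880.0


@dataclass
class LipolysisRun:
    """One pH-stat titration: cumulative NaOH volume (mL) over time (min)."""

    time: np.ndarray
    naoh_volume: np.ndarray
    naoh_molarity: float  # mol/L
    lipid_mass: float  # g
    lipid_molar_mass: float = DEFAULT_OIL_MOLAR_MASS  # g/mol
    condition: str = ""
    temperature: float = 310.15

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.naoh_volume = np.asarray(self.naoh_volume, dtype=float)
        if self.time.shape != self.naoh_volume.shape:
            raise DomainError("time and volume differ in length")
        if not np.all(np.diff(self.time) > 0):
            raise DomainError("time must be strictly increasing")
        if np.any(np.diff(self.naoh_volume) < -1e-12):
            raise DomainError("cumulative NaOH volume must be nondecreasing")
        if self.lipid_mass <= 0:
            raise DomainError("lipid mass must be positive")
        if self.naoh_molarity <= 0 or self.lipid_molar_mass <= 0:
            raise DomainError("molarity and molar mass must be positive")


@dataclass
class FfaProfile:
    """Percent FFA released over time, with optional propagated uncertainty."""

    time: np.ndarray
    ffa_percent: np.ndarray
    ffa_uncertainty: np.ndarray | None = None
    condition: str = ""


@dataclass
class FirstOrderFit:
    phi_max: float  # %
    k: float  # 1/min
    covariance: np.ndarray
    degenerate: bool = False
    diagnostics: dict = field(default_factory=dict)


def stoichiometric_volume_ml(
    lipid_mass: float,
    naoh_molarity: float,
    lipid_molar_mass: float = DEFAULT_OIL_MOLAR_MASS,
    ffa_per_tag: float = DEFAULT_FFA_PER_TAG,
) -> float:
    """NaOH volume (mL) corresponding to 100% FFA release."""
    moles_ffa = ffa_per_tag * lipid_mass / lipid_molar_mass
    return 1e3 * moles_ffa / naoh_molarity


def ffa_percent(
    run: LipolysisRun,
    ffa_per_tag: float = DEFAULT_FFA_PER_TAG,
    volume_uncertainty: float | None = None,
) -> FfaProfile:
    """Convert a titration run to a %FFA release profile.

    ``volume_uncertainty`` (mL, one sigma per reading) propagates linearly
    to a per-point %FFA uncertainty.
    """
    scale = 100.0 / stoichiometric_volume_ml(
        run.lipid_mass, run.naoh_molarity, run.lipid_molar_mass, ffa_per_tag
    )
    unc = None
    if volume_uncertainty is not None:
        unc = np.full_like(run.naoh_volume, scale * volume_uncertainty)
    return FfaProfile(
        time=run.time.copy(),
        ffa_percent=scale * run.naoh_volume,
        ffa_uncertainty=unc,
        condition=run.condition,
    )


def _first_order(t, phi_max, k):
    return phi_max * (1.0 - np.exp(-k * t))


def fit_first_order(profile: FfaProfile) -> FirstOrderFit:
    """Fit Phi(t) = Phi_max (1 - exp(-k t)) by nonlinear least squares.

    Initial guesses: Phi_max from the plateau, k from the initial slope.
    An all-zero profile is returned as a degenerate fit rather than an
    error; genuine non-convergence raises :class:`FittingError`.
    """
    t = profile.time
    phi = profile.ffa_percent
    if t.size < 5:
        raise DomainError("need at least 5 time points")
    phi_top = float(phi.max())
    if phi_top <= 0.0:
        return FirstOrderFit(
            phi_max=0.0,
            k=0.0,
            covariance=np.zeros((2, 2)),
            degenerate=True,
            diagnostics={"reason": "flat profile, no release observed"},
        )
    dt = t[1] - t[0]
    slope0 = (phi[1] - phi[0]) / dt if dt > 0 else 0.0
    k0 = slope0 / phi_top if slope0 > 0 else 1.0 / max(t[-1], 1.0)
    try:
        popt, pcov = curve_fit(
            _first_order,
            t,
            phi,
            p0=[phi_top, max(k0, 1e-6)],
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FittingError(
            "first-order release fit did not converge",
            diagnostics={"p0": [phi_top, k0], "error": str(exc)},
        ) from exc
    resid = phi - _first_order(t, *popt)
    return FirstOrderFit(
        phi_max=float(popt[0]),
        k=float(popt[1]),
        covariance=pcov,
        degenerate=False,
        diagnostics={"rmse": float(np.sqrt(np.mean(resid**2)))},
    )


def _ffa_at(profile: FfaProfile, at_time: float) -> float:
    t = profile.time
    if not (t[0] <= at_time <= t[-1]):
        raise DomainError(
            f"comparison time {at_time} outside measured range [{t[0]}, {t[-1]}]"
        )
    return float(np.interp(at_time, t, profile.ffa_percent))


def compare_conditions(
    a, b, at_time: float, tail: str = "right"
) -> tuple[float, float]:
    """Compare %FFA between two replicate sets at a common time point.

    Profiles on differing time grids are linearly interpolated to
    ``at_time`` (with a warning). Returns (mean difference a - b, p) from a
    Welch t-test; ``tail='right'`` tests release(a) > release(b), the
    one-tailed convention for an expected ordering.
    """
    a, b = list(a), list(b)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("need at least 2 replicates per condition")
    grids = [p.time for p in a + b]
    if any(
        g.shape != grids[0].shape or not np.allclose(g, grids[0]) for g in grids[1:]
    ):
        warnings.warn(
            "replicates measured on different time grids; interpolating to "
            f"t={at_time}",
            stacklevel=2,
        )
    va = np.array([_ffa_at(p, at_time) for p in a])
    vb = np.array([_ffa_at(p, at_time) for p in b])
    _, _, p_value = welch_t_test(va, vb, tail=tail)
    return float(va.mean() - vb.mean()), p_value
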