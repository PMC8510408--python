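"""Molar solubilization ratio (MSR) estimation and descriptor correlation.

Above the CMC, the amount of a poorly water-soluble compound carried into
solution grows linearly with the concentration of micellized surfactant; the
slope of solubilizate concentration against surfactant concentration in that
regime is the molar solubilization ratio (moles solubilized per mole of
micellized surfactant). Below the CMC only the flat aqueous baseline is
seen, so those points are excluded from the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError

__all__ = [
    "SolubilizationSeries",
    "SolubilizateDescriptor",
    "MsrEstimate",
    "compute_msr",
    "pearson_r",
]


@dataclass
class SolubilizationSeries:
    """Dissolved solubilizate vs total surfactant concentration (both mM)."""

    surfactant_conc: np.ndarray
    solubilizate_conc: np.ndarray
    cmc: float
    solubilizate: str = ""

    def __post_init__(self):
        self.surfactant_conc = np.asarray(self.surfactant_conc, dtype=float)
        self.solubilizate_conc = np.asarray(self.solubilizate_conc, dtype=float)
        if self.surfactant_conc.shape != self.solubilizate_conc.shape:
            raise DomainError("series lengths differ")
        if not np.all(np.diff(self.surfactant_conc) > 0):
            raise DomainError("surfactant concentrations must be increasing")
        if self.cmc <= 0:
            raise DomainError("cmc must be positive")


@dataclass(frozen=True)
class SolubilizateDescriptor:
    """Physicochemical descriptors of a solubilizate molecule."""

    name: str
    logkow: float
    molecular_volume: float  # nm^3

    def __post_init__(self):
        if self.molecular_volume <= 0:
            raise DomainError("molecular volume must be positive")


@dataclass(frozen=True)
class MsrEstimate:
    msr: float
    stderr: float
    intercept: float
    n_points: int
    diagnostics: dict = field(default_factory=dict)


def compute_msr(series: SolubilizationSeries) -> MsrEstimate:
    """MSR as the OLS slope above the CMC (strictly; the breakpoint itself
    is excluded) with the slope's standard error.

    Raises :class:`InsufficientDataError` with fewer than 3 micellar-regime
    points.
    """
    mask = series.surfactant_conc > series.cmc
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(
            f"only {n} points above the CMC ({series.cmc} mM); need >= 3"
        )
    x = series.surfactant_conc[mask]
    y = series.solubilizate_conc[mask]
    fit = stats.linregress(x, y)
    return MsrEstimate(
        msr=float(fit.slope),
        stderr=float(fit.stderr),
        intercept=float(fit.intercept),
        n_points=n,
        diagnostics={"rvalue": float(fit.rvalue)},
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("sequences differ in length")
    if x.size < 3:
        raise DomainError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("zero variance in one of the sequences")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
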