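"""Regular-solution theory for binary mixed micelles.

Binary surfactant mixtures (here, pairs of bile salts) rarely mix ideally.
The regular-solution treatment of mixed micelles summarises the non-ideality
in a single dimensionless interaction parameter ``beta``: negative values
mean synergism (the mixed CMC falls below the ideal-mixing prediction),
positive values antagonism (the mixed CMC rises above it).

Given a measured mixed CMC ``C12`` at bulk mole fraction ``alpha`` of
component 1 together with the pure-component CMCs ``C1`` and ``C2``, the
micellar mole fraction ``x1`` solves

    x1^2 * ln(alpha*C12 / (x1*C1)) = (1-x1)^2 * ln((1-alpha)*C12 / ((1-x1)*C2))

and the interaction parameter follows as

    beta = ln(alpha*C12 / (x1*C1)) / (1-x1)^2.

Activity coefficients are f1 = exp(beta*(1-x1)^2), f2 = exp(beta*x1^2).
The ideal-mixing baseline is the Clint equation
``1/C12 = alpha/C1 + (1-alpha)/C2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, IllConditionedError, NoPhysicalRootError

__all__ = [
    "PureSurfactantRecord",
    "BinaryMixtureMeasurement",
    "RstSolution",
    "clint_cmc",
    "solve_micellar_composition",
    "compute_beta",
    "predict_mixed_cmc",
    "classify_interaction",
    "analyze_mixtures",
    "BS_CATEGORIES",
]

#: Bile-salt categories: primary/secondary backbone x conjugated/unconjugated.
BS_CATEGORIES = ("PC", "PU", "SC", "SU")

#: |beta| below this default threshold is treated as ideal mixing.
DEFAULT_IDEALITY_TOL = 0.05

_X_EPS = 1e-10  # exclusion zone at the composition boundaries


@dataclass(frozen=True)
class PureSurfactantRecord:
    """One literature CMC measurement of a pure bile salt."""

    compound: str
    category: str
    cmc: float
    temperature: float
    method: str = ""
    year: int | None = None
    hydrophobicity_index: float | None = None

    def __post_init__(self):
        if self.category not in BS_CATEGORIES:
            raise DomainError(
                f"category {self.category!r} not one of {BS_CATEGORIES}"
            )
        if not self.cmc > 0:
            raise DomainError(f"cmc must be positive, got {self.cmc}")
        if not self.temperature > 0:
            raise DomainError("temperature must be positive kelvin")


@dataclass(frozen=True)
class BinaryMixtureMeasurement:
    """A mixed-CMC measurement for a binary pair at bulk mole fraction alpha.

    ``alpha`` refers to the first-named component of ``pair_label``;
    concentrations are in mM.
    """

    alpha: float
    cmc_mix: float
    cmc_1: float
    cmc_2: float
    pair_label: str = ""
    temperature: float = 298.15

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise DomainError(f"alpha must lie in (0, 1), got {self.alpha}")
        for name in ("cmc_mix", "cmc_1", "cmc_2"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")


@dataclass(frozen=True)
class RstSolution:
    """Solved interaction parameter and micellar composition."""

    beta: float
    x1: float
    f1: float
    f2: float
    residual: float
    label: str
    beta_consistency: float = field(default=0.0)

    def __post_init__(self):
        if not 0.0 < self.x1 < 1.0:
            raise DomainError("x1 must lie strictly inside (0, 1)")


def clint_cmc(alpha: float, c1: float, c2: float) -> float:
    """Ideal-mixing (Clint) CMC of a binary mixture.

    ``1/C12 = alpha/C1 + (1-alpha)/C2``; alpha may hit the boundaries, where
    the result reduces to the corresponding pure CMC.
    """
    if not 0.0 <= alpha <= 1.0:
        raise DomainError(f"alpha must lie in [0, 1], got {alpha}")
    if c1 <= 0 or c2 <= 0:
        raise DomainError("pure-component CMCs must be positive")
    return 1.0 / (alpha / c1 + (1.0 - alpha) / c2)


def _rubingh_residual(x1, alpha, c12, c1, c2):
    """F(x1) whose root gives the micellar composition; vectorised in x1."""
    x1 = np.asarray(x1, dtype=float)
    t1 = np.log(alpha * c12 / (x1 * c1))
    t2 = np.log((1.0 - alpha) * c12 / ((1.0 - x1) * c2))
    return x1**2 * t1 - (1.0 - x1) ** 2 * t2


def _beta_pair(x1, alpha, c12, c1, c2):
    """The two single-component beta estimates at composition x1."""
    b1 = math.log(alpha * c12 / (x1 * c1)) / (1.0 - x1) ** 2
    b2 = math.log((1.0 - alpha) * c12 / ((1.0 - x1) * c2)) / x1**2
    return b1, b2


def _beta_at(x1, alpha, c12, c1, c2):
    """Beta from the better-conditioned component equation.

    Near x1 = 1 the component-1 denominator (1-x1)^2 amplifies root error
    by ~1/(1-x1), so the component-2 expression is used there (and vice
    versa); at an exact root the two agree.
    """
    b1, b2 = _beta_pair(x1, alpha, c12, c1, c2)
    return (b1 if x1 <= 0.5 else b2), abs(b1 - b2)


def _bracketed_roots(fn, lo, hi, grid):
    """All roots of fn on (lo, hi): grid scan + Brent, exact hits kept."""
    xs = np.linspace(lo, hi, grid)
    fs = fn(xs)
    roots = [float(xs[i]) for i in np.nonzero(fs == 0.0)[0]]
    sign = np.sign(fs)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(
            brentq(fn, xs[i], xs[i + 1], xtol=1e-15, rtol=4 * np.finfo(float).eps)
        )
    return sorted(roots)


def solve_micellar_composition(
    m: BinaryMixtureMeasurement, tol: float = 1e-12, grid: int = 2001
) -> float:
    """Micellar mole fraction x1 of component 1 from a mixed-CMC measurement.

    Brackets sign changes of the defining residual on a dense grid over
    (0, 1) and polishes each with Brent's method. Strong antagonism
    (beta above ~2) makes the system multi-rooted; in that case the root
    whose implied beta reproduces the measured mixed CMC through the
    forward model (i.e. the fully mixed branch) is returned, keeping the
    inverse consistent with :func:`predict_mixed_cmc`.

    Raises
    ------
    NoPhysicalRootError
        If the residual does not change sign on (0, 1): the CMC triple is
        thermodynamically inconsistent.
    """
    a, c12, c1, c2 = m.alpha, m.cmc_mix, m.cmc_1, m.cmc_2
    roots = _bracketed_roots(
        lambda x: _rubingh_residual(x, a, c12, c1, c2), _X_EPS, 1.0 - _X_EPS, grid
    )
    if not roots:
        raise NoPhysicalRootError(
            f"no micellar composition solves the mixture "
            f"(alpha={a}, C12={c12}, C1={c1}, C2={c2}); "
            "check the CMC triple for consistency"
        )
    if len(roots) == 1:
        return float(roots[0])

    # disambiguate: keep the root whose beta maps back to the measured C12
    def forward_mismatch(x):
        beta = _beta_at(x, a, c12, c1, c2)[0]
        try:
            return abs(predict_mixed_cmc(a, c1, c2, beta)[0] - c12)
        except (OverflowError, ValueError):
            return math.inf

    return float(min(roots, key=forward_mismatch))


def compute_beta(
    m: BinaryMixtureMeasurement,
    tol: float = 1e-12,
    ideality_tol: float = DEFAULT_IDEALITY_TOL,
) -> RstSolution:
    """Interaction parameter beta (and composition) for one measurement.

    beta is evaluated from the component-1 equation at the solved x1; the
    component-2 estimate is recomputed as a consistency check and their gap
    reported as ``beta_consistency``.
    """
    x1 = solve_micellar_composition(m, tol=tol)
    if x1 < 1e-8 or x1 > 1.0 - 1e-8:
        raise IllConditionedError(
            f"micellar composition x1={x1:.3g} is numerically degenerate; "
            "beta cannot be evaluated reliably"
        )
    beta, consistency = _beta_at(x1, m.alpha, m.cmc_mix, m.cmc_1, m.cmc_2)
    residual = abs(
        float(_rubingh_residual(x1, m.alpha, m.cmc_mix, m.cmc_1, m.cmc_2))
    )
    return RstSolution(
        beta=beta,
        x1=x1,
        f1=math.exp(beta * (1.0 - x1) ** 2),
        f2=math.exp(beta * x1**2),
        residual=residual,
        label=classify_interaction(beta, ideality_tol),
        beta_consistency=consistency,
    )


def predict_mixed_cmc(
    alpha: float, c1: float, c2: float, beta: float
) -> tuple[float, float]:
    """Forward regular-solution model: mixed CMC and composition from beta.

    Solves the chemical-potential balance
    ``x1*f1*C1/alpha = (1-x1)*f2*C2/(1-alpha)`` for x1, then evaluates
    ``1/C12 = alpha/(f1*C1) + (1-alpha)/(f2*C2)``. A root always exists for
    finite beta because the balance changes sign across (0, 1); strong
    antagonism (beta above ~2) additionally admits near-demixed roots, and
    the fully mixed branch — the root with the highest mixed CMC, the
    continuous continuation of the ideal beta=0 solution — is returned so
    that C12 remains strictly increasing in beta.

    Returns
    -------
    (c12, x1)
    """
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    if c1 <= 0 or c2 <= 0:
        raise DomainError("pure-component CMCs must be positive")

    def balance(x1):
        f1 = np.exp(beta * (1.0 - x1) ** 2)
        f2 = np.exp(beta * x1**2)
        return x1 * f1 * c1 / alpha - (1.0 - x1) * f2 * c2 / (1.0 - alpha)

    def c12_of(x1):
        f1 = math.exp(beta * (1.0 - x1) ** 2)
        f2 = math.exp(beta * x1**2)
        return 1.0 / (alpha / (f1 * c1) + (1.0 - alpha) / (f2 * c2))

    roots = _bracketed_roots(balance, 1e-12, 1.0 - 1e-12, 4001)
    x1 = max(roots, key=c12_of)
    return float(c12_of(x1)), float(x1)


def classify_interaction(beta: float, tol: float = DEFAULT_IDEALITY_TOL) -> str:
    """Label a beta value: 'synergistic', 'antagonistic' or 'ideal'."""
    if tol < 0:
        raise DomainError("tolerance must be nonnegative")
    if beta > tol:
        return "antagonistic"
    if beta < -tol:
        return "synergistic"
    return "ideal"


def analyze_mixtures(measurements, ideality_tol: float = DEFAULT_IDEALITY_TOL):
    """Run compute_beta over a batch and tabulate the results.

    Returns a pandas DataFrame with one row per measurement; rows whose
    CMC triple admits no physical root carry NaNs and label
    'no-physical-root'.
    """
    import pandas as pd

    rows = []
    for m in measurements:
        row = {
            "pair_label": m.pair_label,
            "alpha": m.alpha,
            "cmc_mix_mM": m.cmc_mix,
            "cmc1_mM": m.cmc_1,
            "cmc2_mM": m.cmc_2,
            "temperature_K": m.temperature,
        }
        try:
            sol = compute_beta(m, ideality_tol=ideality_tol)
            row.update(
                beta=sol.beta, x1=sol.x1, label=sol.label, residual=sol.residual
            )
        except (NoPhysicalRootError, IllConditionedError) as exc:
            row.update(
                beta=float("nan"),
                x1=float("nan"),
                label="no-physical-root",
                residual=float("nan"),
            )
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
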