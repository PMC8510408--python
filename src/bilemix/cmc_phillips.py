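"""CMC detection from conductivity titration curves.

For ionic surfactants the specific conductivity grows roughly linearly with
concentration, with a slope drop at the critical micelle concentration where
added monomers start entering (partially counter-ion-bound) micelles. The
Phillips criterion places the CMC where the third derivative of conductivity
with respect to concentration vanishes — numerically, at the extremum of the
second derivative. A classical two-line segmented fit serves as an
independent cross-check, and the post/pre slope ratio estimates the micellar
degree of counter-ion ionization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, NoBreakpointError

__all__ = [
    "ConductivityTitration",
    "CmcEstimate",
    "smooth_second_derivative",
    "phillips_cmc",
    "segmented_cmc",
    "ionization_degree",
]

# an extremum of the second derivative is 'real' if the slope change it
# implies exceeds this fraction of the curve's overall slope scale
_SIGNIFICANCE = 1e-6


@dataclass
class ConductivityTitration:
    """An ordered conductivity-vs-concentration titration curve.

    concentration in mM (strictly increasing), conductivity in uS/cm.
    """

    concentration: np.ndarray
    conductivity: np.ndarray
    temperature: float = 298.15
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.conductivity = np.asarray(self.conductivity, dtype=float)
        if self.concentration.shape != self.conductivity.shape:
            raise DomainError("concentration and conductivity differ in length")
        if self.concentration.size < 8:
            raise DomainError("need at least 8 titration points")
        if not np.all(np.diff(self.concentration) > 0):
            raise DomainError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.conductivity)):
            raise DomainError("conductivities must be finite")

    def __len__(self):
        return self.concentration.size


@dataclass
class CmcEstimate:
    """A CMC estimate with its half-width uncertainty and diagnostics."""

    cmc: float
    uncertainty: float
    method: str
    diagnostics: dict = field(default_factory=dict)


def default_window(n: int) -> int:
    """Adaptive smoothing window: odd, at least 9, about n/6 points.

    Dense curves place many points inside the breakpoint region, so the
    window grows with n to keep the derivative estimate from chasing noise.
    """
    w = max(9, int(round(n / 6)))
    return w + 1 if w % 2 == 0 else w


def smooth_second_derivative(
    curve: ConductivityTitration, window: int | None = None, degree: int = 3
):
    """Moving local-polynomial second derivative of conductivity.

    A degree-``degree`` polynomial is least-squares fitted in a centred
    ``window`` around every interior point (endpoints within half a window
    of the edge are excluded) and differentiated twice at the centre. Works
    on non-uniform concentration grids, unlike a classical Savitzky-Golay
    convolution.

    Returns
    -------
    (centers, d2) : two ndarrays of length n - window + 1
    """
    n = len(curve)
    if window is None:
        window = default_window(n)
    if window % 2 == 0:
        raise DomainError("window must be odd")
    if window < degree + 2:
        raise DomainError(f"window {window} too small for degree {degree}")
    if window > n:
        raise DomainError(f"window {window} exceeds curve length {n}")
    h = window // 2
    c, k = curve.concentration, curve.conductivity
    centers = c[h : n - h]
    d2 = np.empty(n - 2 * h)
    for j, i in enumerate(range(h, n - h)):
        # centre the abscissa for conditioning
        coeffs = np.polyfit(c[i - h : i + h + 1] - c[i], k[i - h : i + h + 1], degree)
        d2[j] = 2.0 * coeffs[degree - 2]
    return centers, d2


def phillips_cmc(
    curve: ConductivityTitration, window: int | None = None, degree: int = 3
) -> CmcEstimate:
    """CMC by the Phillips criterion (extremum of the smoothed d2k/dC2).

    The discrete extremum is refined by fitting a parabola through it and
    its two neighbours and taking the vertex. Raises
    :class:`NoBreakpointError` when the second derivative carries no
    significant extremum (e.g. a straight line or a curve that does not
    span the CMC).
    """
    centers, d2 = smooth_second_derivative(curve, window=window, degree=degree)
    if d2.size < 3:
        raise NoBreakpointError("too few interior points after smoothing")
    i = int(np.argmax(np.abs(d2)))

    # significance: implied slope change vs the curve's overall slope scale
    c, k = curve.concentration, curve.conductivity
    slope_scale = (k.max() - k.min()) / (c[-1] - c[0])
    local_step = np.median(np.diff(c))
    if slope_scale <= 0 or np.abs(d2[i]) * local_step < _SIGNIFICANCE * slope_scale:
        raise NoBreakpointError(
            "second derivative shows no significant extremum: "
            "no micellization breakpoint in the measured range"
        )
    if i == 0 or i == d2.size - 1:
        raise NoBreakpointError(
            "second-derivative extremum sits at the edge of the measured "
            "range; the curve does not bracket the breakpoint"
        )

    x = centers[i - 1 : i + 2]
    y = d2[i - 1 : i + 2]
    a, b, _ = np.polyfit(x, y, 2)
    if a == 0.0:
        cmc = float(centers[i])
        half_width = float(0.5 * (x[2] - x[0]) / 2.0)
    else:
        cmc = float(np.clip(-b / (2.0 * a), x[0], x[-1]))
        half_width = float(0.5 * (x[2] - x[0]) / 2.0)
    return CmcEstimate(
        cmc=cmc,
        uncertainty=half_width,
        method="phillips",
        diagnostics={
            "window": window if window is not None else default_window(len(curve)),
            "degree": degree,
            "centers": centers,
            "second_derivative": d2,
            "extremum_index": i,
            "extremum_value": float(d2[i]),
        },
    )


def segmented_cmc(curve: ConductivityTitration, min_points: int = 3) -> CmcEstimate:
    """CMC as the intersection of two independently fitted straight lines.

    Every interior split with at least ``min_points`` on each side is
    scored by the summed squared residuals of the two line fits; the best
    split's line intersection is the CMC. Degenerate geometry (equal
    slopes) or an intersection outside the measured range is flagged in the
    diagnostics rather than raised, since the two-line picture may still be
    informative.
    """
    n = len(curve)
    if n < 10:
        raise DomainError("segmented fit needs at least 10 points")
    c, k = curve.concentration, curve.conductivity
    best = None
    for split in range(min_points, n - min_points + 1):
        c1, k1 = c[:split], k[:split]
        c2, k2 = c[split:], k[split:]
        p1, res1 = _line_fit(c1, k1)
        p2, res2 = _line_fit(c2, k2)
        sse = res1 + res2
        if best is None or sse < best[0]:
            best = (sse, split, p1, p2)
    sse, split, (m1, b1), (m2, b2) = best

    flags = []
    slope_scale = max(abs(m1), abs(m2), 1e-300)
    if abs(m1 - m2) < 1e-9 * slope_scale:
        flags.append("degenerate-equal-slopes")
        cmc = float(c[split - 1])
    else:
        cmc = float((b2 - b1) / (m1 - m2))
        if not (c[0] <= cmc <= c[-1]):
            flags.append("intersection-outside-range")
    step = float(np.median(np.diff(c)))
    return CmcEstimate(
        cmc=cmc,
        uncertainty=0.5 * step,
        method="segmented",
        diagnostics={
            "pre_slope": float(m1),
            "post_slope": float(m2),
            "pre_intercept": float(b1),
            "post_intercept": float(b2),
            "split_index": split,
            "sse": float(sse),
            "flags": flags,
        },
    )


def _line_fit(x, y):
    """Least-squares line fit returning ((slope, intercept), sse)."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return (coef[0], coef[1]), float(resid @ resid)


def ionization_degree(pre_slope: float, post_slope: float) -> float:
    """Micellar degree of counter-ion ionization from the two slopes.

    The classical conductometric estimate is the post-CMC to pre-CMC slope
    ratio; values outside [0, 1] are clipped with a warning.
    """
    if pre_slope <= 0:
        raise DomainError("pre-CMC slope must be positive")
    ratio = post_slope / pre_slope
    if ratio < 0.0 or ratio > 1.0:
        warnings.warn(
            f"slope ratio {ratio:.3g} outside [0, 1]; clipping",
            stacklevel=2,
        )
    return float(np.clip(ratio, 0.0, 1.0))
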