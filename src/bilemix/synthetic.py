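"""Seeded synthetic-data generators with planted ground truth.

Each generator emulates one input class of the analysis pipeline —
conductivity titrations, binary mixed-CMC tables, literature meta-tables,
pH-stat lipolysis runs, and solubilization series — and embeds the planted
parameters in a ``truth`` dict so that every estimation stage has a
parameter-recovery test. Identical seeds reproduce identical data.

Noise conventions: additive Gaussian (relative to signal) for conductivity,
solubility and lipolysis readings; additive Gaussian in response units for
meta-tables; multiplicative lognormal for CMCs, which must stay positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .cmc_phillips import ConductivityTitration
from .errors import DomainError
from .lipolysis import (
    DEFAULT_FFA_PER_TAG,
    DEFAULT_OIL_MOLAR_MASS,
    LipolysisRun,
    stoichiometric_volume_ml,
)
from .meta_pls import MetaRecord
from .micelle_rst import BS_CATEGORIES, BinaryMixtureMeasurement, predict_mixed_cmc
from .solubilization import SolubilizationSeries

__all__ = [
    "SyntheticDataset",
    "gen_conductivity",
    "gen_mixture_cmc_dataset",
    "gen_meta_table",
    "gen_lipolysis",
    "gen_solubility_series",
]


@dataclass
class SyntheticDataset:
    """A generated dataset together with its planted ground truth."""

    data: Any
    truth: dict


def gen_conductivity(
    cmc: float = 4.16,
    pre_slope: float = 60.0,
    post_slope: float = 30.0,
    c_range: tuple[float, float] = (0.5, 10.0),
    n: int = 60,
    noise: float = 0.0,
    seed: int = 0,
    intercept: float = 20.0,
    transition_width: float = 0.0,
    temperature: float = 310.15,
) -> ConductivityTitration:
    """Piecewise-linear conductivity titration with a slope break at the CMC.

    ``noise`` is the relative standard deviation of each conductivity
    reading. ``transition_width`` (mM) optionally rounds the kink with a
    softplus blend, since measured curves are never perfectly sharp; the
    default 0 keeps the break exact for deterministic tests. The planted
    parameters are stored in ``meta['truth']``.
    """
    lo, hi = c_range
    if not lo < cmc < hi:
        raise DomainError(f"cmc {cmc} must lie inside c_range {c_range}")
    if not pre_slope > post_slope > 0:
        raise DomainError("expected pre_slope > post_slope > 0")
    if noise < 0:
        raise DomainError("noise must be nonnegative")
    c = np.linspace(lo, hi, n)
    if transition_width > 0:
        w = transition_width
        excess = w * np.log1p(np.exp((c - cmc) / w))
    else:
        excess = np.maximum(0.0, c - cmc)
    kappa = intercept + pre_slope * c + (post_slope - pre_slope) * excess
    if noise > 0:
        rng = np.random.default_rng(seed)
        kappa = kappa + rng.normal(0.0, noise * np.abs(kappa))
    truth = {
        "cmc": cmc,
        "pre_slope": pre_slope,
        "post_slope": post_slope,
        "intercept": intercept,
        "noise": noise,
        "transition_width": transition_width,
        "seed": seed,
    }
    return ConductivityTitration(
        concentration=c, conductivity=kappa, temperature=temperature,
        meta={"truth": truth},
    )


def gen_mixture_cmc_dataset(
    c1: float = 13.0,
    c2: float = 6.0,
    beta: float = -2.0,
    alphas=(0.2, 0.4, 0.6, 0.8),
    noise: float = 0.0,
    seed: int = 0,
    pair_label: str = "PU:PC",
    temperature: float = 298.15,
) -> SyntheticDataset:
    """Binary mixed-CMC records from the forward regular-solution model.

    The default alpha grid follows the composition grid literature tables
    report (0.2, 0.4, 0.6, 0.8). ``noise`` is the standard deviation of
    multiplicative lognormal noise on the mixed CMC.
    """
    if noise < 0:
        raise DomainError("noise must be nonnegative")
    rng = np.random.default_rng(seed)
    records = []
    x1s = {}
    for a in alphas:
        c12, x1 = predict_mixed_cmc(a, c1, c2, beta)
        x1s[a] = x1
        if noise > 0:
            c12 = c12 * float(np.exp(rng.normal(0.0, noise)))
        records.append(
            BinaryMixtureMeasurement(
                alpha=a, cmc_mix=c12, cmc_1=c1, cmc_2=c2,
                pair_label=pair_label, temperature=temperature,
            )
        )
    truth = {
        "beta": beta, "c1": c1, "c2": c2, "x1": x1s,
        "noise": noise, "seed": seed,
    }
    return SyntheticDataset(data=records, truth=truth)


def gen_meta_table(
    level_effects: dict[str, dict[str, float]] | None = None,
    numeric_effects: dict[str, float] | None = None,
    numeric_ranges: dict[str, tuple[float, float]] | None = None,
    baseline: float = 10.0,
    n: int = 100,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> SyntheticDataset:
    """Literature-style meta-table with planted categorical/numeric effects.

    Each record draws one level per categorical descriptor uniformly over
    the declared levels, and each numeric covariate uniformly over its
    range (default (0, 1)); the response is baseline + category effects +
    numeric slopes * covariates + Gaussian(0, noise_sd).

    Default design: the four bile-salt classes with no planted effect —
    pass ``level_effects`` to plant one.
    """
    if n < 10:
        raise DomainError("need n >= 10")
    if noise_sd < 0:
        raise DomainError("noise_sd must be nonnegative")
    if level_effects is None:
        level_effects = {"bs_type": {lvl: 0.0 for lvl in BS_CATEGORIES}}
    numeric_effects = numeric_effects or {}
    numeric_ranges = numeric_ranges or {}
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n):
        cats, response = {}, baseline
        for col, effects in level_effects.items():
            levels = list(effects)
            lvl = levels[rng.integers(len(levels))]
            cats[col] = lvl
            response += effects[lvl]
        nums = {}
        for col, slope in numeric_effects.items():
            lo, hi = numeric_ranges.get(col, (0.0, 1.0))
            v = float(rng.uniform(lo, hi))
            nums[col] = v
            response += slope * v
        if noise_sd > 0:
            response += float(rng.normal(0.0, noise_sd))
        records.append(
            MetaRecord(response=response, categories=cats, numerics=nums,
                       source="synthetic")
        )
    truth = {
        "level_effects": level_effects,
        "numeric_effects": numeric_effects,
        "baseline": baseline,
        "noise_sd": noise_sd,
        "seed": seed,
        "declared_levels": {c: list(e) for c, e in level_effects.items()},
        "numeric_cols": list(numeric_effects),
    }
    return SyntheticDataset(data=records, truth=truth)


def gen_lipolysis(
    phi_max: float = 15.0,
    k: float = 0.08,
    t_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    condition: str = "NaTC 10 mM",
    naoh_molarity: float = 0.1,
    lipid_mass: float = 0.075,
    lipid_molar_mass: float = DEFAULT_OIL_MOLAR_MASS,
    ffa_per_tag: float = DEFAULT_FFA_PER_TAG,
    temperature: float = 310.15,
) -> SyntheticDataset:
    """pH-stat runs with first-order FFA release Phi_max (1 - exp(-k t)).

    Defaults mirror a duodenal in-vitro digestion: 0.1 M NaOH titrant,
    0.075 g oil (0.375 mL of a 20% w/w emulsion), 310.15 K, triplicate
    runs. ``noise_sd`` is in %FFA units; noisy volumes are monotonized so
    every run remains a valid cumulative titration.
    """
    if k <= 0 and phi_max > 0:
        raise DomainError("rate constant k must be positive")
    if phi_max < 0 or noise_sd < 0 or replicates < 1:
        raise DomainError("invalid generator parameters")
    if t_grid is None:
        t_grid = np.arange(0.0, 91.0, 3.0)
    t_grid = np.asarray(t_grid, dtype=float)
    v100 = stoichiometric_volume_ml(
        lipid_mass, naoh_molarity, lipid_molar_mass, ffa_per_tag
    )
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(replicates):
        phi = phi_max * (1.0 - np.exp(-k * t_grid)) if phi_max > 0 else np.zeros_like(t_grid)
        if noise_sd > 0:
            phi = phi + rng.normal(0.0, noise_sd, size=phi.shape)
        vol = np.maximum.accumulate(np.clip(phi, 0.0, None)) / 100.0 * v100
        runs.append(
            LipolysisRun(
                time=t_grid, naoh_volume=vol, naoh_molarity=naoh_molarity,
                lipid_mass=lipid_mass, lipid_molar_mass=lipid_molar_mass,
                condition=condition, temperature=temperature,
            )
        )
    truth = {
        "phi_max": phi_max, "k": k, "noise_sd": noise_sd,
        "replicates": replicates, "seed": seed, "ffa_per_tag": ffa_per_tag,
    }
    return SyntheticDataset(data=runs, truth=truth)


def gen_solubility_series(
    cmc: float = 5.0,
    msr: float = 0.12,
    baseline: float = 0.02,
    c_grid: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
    solubilizate: str = "synthetic-solubilizate",
) -> SyntheticDataset:
    """Solubility-vs-surfactant series: flat below the CMC, slope msr above.

    ``noise`` is the relative standard deviation of each solubilizate
    reading.
    """
    if noise < 0:
        raise DomainError("noise must be nonnegative")
    if c_grid is None:
        c_grid = np.linspace(1.0, 20.0, 10)
    c_grid = np.asarray(c_grid, dtype=float)
    if not np.any(c_grid > cmc):
        raise DomainError("c_grid must contain points above the cmc")
    s = baseline + msr * np.maximum(0.0, c_grid - cmc)
    if noise > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, noise * np.abs(s))
    series = SolubilizationSeries(
        surfactant_conc=c_grid, solubilizate_conc=s, cmc=cmc,
        solubilizate=solubilizate,
    )
    truth = {
        "cmc": cmc, "msr": msr, "baseline": baseline,
        "noise": noise, "seed": seed,
    }
    return SyntheticDataset(data=series, truth=truth)
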