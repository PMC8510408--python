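"""CSV/YAML input-output, unit canonicalisation and the pipeline driver.

Canonical units throughout the package: concentration mM, temperature K,
conductivity uS/cm, time min, volume mL, FFA release %. Concentration
columns may be supplied in M, mM or uM via the column-name suffix
(``cmc_mix_M`` is converted to mM on read); everything downstream sees
canonical units only.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cmc_phillips import ConductivityTitration, phillips_cmc, segmented_cmc
from .errors import BilemixError, SchemaError
from .lipolysis import LipolysisRun, compare_conditions, ffa_percent, fit_first_order
from .meta_pls import MetaRecord, fit_pls, one_hot_encode, vip_scores
from .micelle_rst import BinaryMixtureMeasurement, analyze_mixtures
from .solubilization import SolubilizationSeries, compute_msr
from .synthetic import (
    gen_conductivity,
    gen_lipolysis,
    gen_meta_table,
    gen_mixture_cmc_dataset,
    gen_solubility_series,
)

logger = logging.getLogger("bilemix")

__all__ = [
    "read_titration",
    "read_mixtures",
    "read_solubility",
    "read_meta",
    "read_lipolysis",
    "write_titration",
    "write_mixtures",
    "write_solubility",
    "write_meta",
    "write_lipolysis",
    "run_pipeline",
]

# concentration-unit suffix -> factor converting to mM
_CONC_FACTORS = {"mM": 1.0, "M": 1e3, "uM": 1e-3}


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    return pd.read_csv(path)


def _concentration(df: pd.DataFrame, base: str, path) -> np.ndarray:
    """Fetch a concentration column in mM, honouring unit suffixes."""
    for unit, factor in _CONC_FACTORS.items():
        col = f"{base}_{unit}"
        if col in df.columns:
            return _numeric(df, col, path) * factor
    raise SchemaError(
        f"{path}: missing column {base}_mM (or a {base}_M / {base}_uM variant)"
    )


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    if col not in df.columns:
        raise SchemaError(f"{path}: missing column {col!r}")
    values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(values))[0]
    if bad.size:
        # +2: header line plus 1-based indexing
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise SchemaError(f"{path}: unparseable value(s) in {col!r} at line(s) {lines}")
    return values


def read_titration(path, temperature: float = 298.15) -> ConductivityTitration:
    """Read a `titration.csv` (concentration_mM, conductivity_uS_cm)."""
    df = _read_csv(path)
    return ConductivityTitration(
        concentration=_concentration(df, "concentration", path),
        conductivity=_numeric(df, "conductivity_uS_cm", path),
        temperature=temperature,
        meta={"path": str(path)},
    )


def read_mixtures(path) -> list[BinaryMixtureMeasurement]:
    """Read a `mixtures.csv` into binary-mixture measurements."""
    df = _read_csv(path)
    alpha = _numeric(df, "alpha", path)
    c12 = _concentration(df, "cmc_mix", path)
    c1 = _concentration(df, "cmc1", path)
    c2 = _concentration(df, "cmc2", path)
    labels = df["pair_label"] if "pair_label" in df.columns else [""] * len(df)
    temps = (
        _numeric(df, "temperature_K", path)
        if "temperature_K" in df.columns
        else np.full(len(df), 298.15)
    )
    out = []
    for i in range(len(df)):
        try:
            out.append(
                BinaryMixtureMeasurement(
                    alpha=float(alpha[i]), cmc_mix=float(c12[i]),
                    cmc_1=float(c1[i]), cmc_2=float(c2[i]),
                    pair_label=str(labels[i]), temperature=float(temps[i]),
                )
            )
        except BilemixError as exc:
            raise SchemaError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def read_solubility(path, cmc: float, solubilizate: str = "") -> SolubilizationSeries:
    """Read a `solubility.csv` (surfactant_conc_mM, solubilizate_conc_mM)."""
    df = _read_csv(path)
    return SolubilizationSeries(
        surfactant_conc=_concentration(df, "surfactant_conc", path),
        solubilizate_conc=_concentration(df, "solubilizate_conc", path),
        cmc=cmc,
        solubilizate=solubilizate,
    )


def read_meta(path, schema) -> tuple[list[MetaRecord], dict, list]:
    """Read a meta-table CSV against a declared schema.

    ``schema`` is a dict or a YAML path with keys ``response`` (column
    name), ``categorical`` (mapping column -> declared levels) and
    optionally ``numeric`` (list of columns).

    Returns (records, declared_levels, numeric_cols).
    """
    if not isinstance(schema, dict):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    for key in ("response", "categorical"):
        if key not in schema:
            raise SchemaError(f"meta schema lacks key {key!r}")
    df = _read_csv(path)
    response = _numeric(df, schema["response"], path)
    declared = {col: list(levels) for col, levels in schema["categorical"].items()}
    numeric_cols = list(schema.get("numeric", []))
    numerics = {col: _numeric(df, col, path) for col in numeric_cols}
    records = []
    for i in range(len(df)):
        cats = {}
        for col in declared:
            if col not in df.columns:
                raise SchemaError(f"{path}: missing column {col!r}")
            cats[col] = str(df[col].iloc[i])
        records.append(
            MetaRecord(
                response=float(response[i]),
                categories=cats,
                numerics={c: float(v[i]) for c, v in numerics.items()},
                source=str(df["source"].iloc[i]) if "source" in df.columns else "",
            )
        )
    return records, declared, numeric_cols


def read_lipolysis(
    path,
    naoh_molarity: float = 0.1,
    lipid_mass: float = 0.075,
    lipid_molar_mass: float = 880.0,
) -> dict[str, list[LipolysisRun]]:
    """Read a `titration_timeseries.csv` into runs grouped by condition.

    Columns: time_min, naoh_mL, condition, replicate.
    """
    df = _read_csv(path)
    for col in ("time_min", "naoh_mL", "condition", "replicate"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    out: dict[str, list[LipolysisRun]] = {}
    for (cond, _rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        out.setdefault(str(cond), []).append(
            LipolysisRun(
                time=grp["time_min"].to_numpy(float),
                naoh_volume=grp["naoh_mL"].to_numpy(float),
                naoh_molarity=naoh_molarity,
                lipid_mass=lipid_mass,
                lipid_molar_mass=lipid_molar_mass,
                condition=str(cond),
            )
        )
    return out


def write_titration(curve: ConductivityTitration, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "concentration_mM": curve.concentration,
            "conductivity_uS_cm": curve.conductivity,
        }
    ).to_csv(path, index=False)
    return path


def write_mixtures(measurements, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "pair_label": m.pair_label,
                "alpha": m.alpha,
                "cmc_mix_mM": m.cmc_mix,
                "cmc1_mM": m.cmc_1,
                "cmc2_mM": m.cmc_2,
                "temperature_K": m.temperature,
            }
            for m in measurements
        ]
    ).to_csv(path, index=False)
    return path


def write_solubility(series: SolubilizationSeries, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "surfactant_conc_mM": series.surfactant_conc,
            "solubilizate_conc_mM": series.solubilizate_conc,
        }
    ).to_csv(path, index=False)
    return path


def write_meta(records, path, schema_path=None, response_name: str = "response"):
    """Write meta-records to CSV and, optionally, their YAML schema."""
    path = Path(path)
    rows = []
    for r in records:
        row = {response_name: r.response}
        row.update(r.categories)
        row.update(r.numerics)
        row["source"] = r.source
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if schema_path is not None:
        levels: dict[str, list] = {}
        for r in records:
            for col, val in r.categories.items():
                levels.setdefault(col, [])
                if val not in levels[col]:
                    levels[col].append(val)
        numeric = sorted({c for r in records for c in r.numerics})
        with open(schema_path, "w") as fh:
            yaml.safe_dump(
                {
                    "response": response_name,
                    "categorical": {c: sorted(v) for c, v in levels.items()},
                    "numeric": numeric,
                },
                fh,
            )
    return path


def write_lipolysis(runs_by_condition: dict[str, list[LipolysisRun]], path) -> Path:
    path = Path(path)
    rows = []
    for cond, runs in runs_by_condition.items():
        for rep, run in enumerate(runs, start=1):
            for t, v in zip(run.time, run.naoh_volume):
                rows.append(
                    {"time_min": t, "naoh_mL": v, "condition": cond, "replicate": rep}
                )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# pipeline driver

_STAGE_ORDER = ("simulate", "cmc", "beta", "msr", "meta_pls", "lipolysis")


def run_pipeline(config: dict | str | Path, output_dir=None) -> dict:
    """Run the configured analysis stages and write a JSON run manifest.

    ``config`` is a dict or YAML path with an optional ``seed``, an
    ``output_dir`` and a ``stages`` mapping; recognised stages, run in
    order: ``simulate`` (writes synthetic CSV fixtures), ``cmc`` (Phillips
    + segmented detection on a titration), ``beta`` (regular-solution
    analysis of a mixtures table), ``msr``, ``meta_pls`` and ``lipolysis``.
    A stage that fails is recorded in the manifest and stages depending on
    its outputs are skipped; the manifest alone (config echoed inside)
    suffices to rerun the identical analysis.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not config or "stages" not in config or not config["stages"]:
        raise SchemaError("pipeline config must declare at least one stage")
    stages = config["stages"]
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise SchemaError(f"unknown pipeline stage(s): {sorted(unknown)}")
    outdir = Path(output_dir or config.get("output_dir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    manifest = {
        "package": "bilemix",
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
        "outputs": [],
    }
    failed: set[str] = set()
    for name in _STAGE_ORDER:
        if name not in stages:
            continue
        needs = _STAGE_DEPS.get(name, ())
        blocked = [d for d in needs if d in stages and d in failed]
        if blocked:
            manifest["stages"][name] = {
                "status": "skipped",
                "reason": f"upstream stage(s) failed: {blocked}",
            }
            continue
        cfg = stages[name] or {}
        try:
            outputs = _STAGE_FUNCS[name](cfg, outdir, seed)
            manifest["stages"][name] = {"status": "ok", "outputs": outputs}
            manifest["outputs"].extend(outputs)
            logger.info("stage %s: ok (%d output(s))", name, len(outputs))
        except BilemixError as exc:
            failed.add(name)
            manifest["stages"][name] = {"status": "error", "error": str(exc)}
            logger.error("stage %s: %s", name, exc)
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    manifest["manifest_path"] = str(manifest_path)
    return manifest


_STAGE_DEPS = {
    "cmc": ("simulate",),
    "beta": ("simulate",),
    "msr": ("simulate",),
    "meta_pls": ("simulate",),
    "lipolysis": ("simulate",),
}


def _stage_simulate(cfg, outdir, seed):
    outputs = []
    if "conductivity" in cfg:
        curve = gen_conductivity(seed=seed, **cfg["conductivity"])
        outputs.append(str(write_titration(curve, outdir / "titration.csv")))
    if "mixtures" in cfg:
        ds = gen_mixture_cmc_dataset(seed=seed, **cfg["mixtures"])
        outputs.append(str(write_mixtures(ds.data, outdir / "mixtures.csv")))
    if "solubility" in cfg:
        ds = gen_solubility_series(seed=seed, **cfg["solubility"])
        outputs.append(str(write_solubility(ds.data, outdir / "solubility.csv")))
    if "meta" in cfg:
        ds = gen_meta_table(seed=seed, **cfg["meta"])
        write_meta(ds.data, outdir / "meta.csv", outdir / "meta_schema.yaml")
        outputs += [str(outdir / "meta.csv"), str(outdir / "meta_schema.yaml")]
    if "lipolysis" in cfg:
        conditions = cfg["lipolysis"]  # mapping condition -> generator params
        runs = {}
        for i, (cond, params) in enumerate(sorted(conditions.items())):
            ds = gen_lipolysis(seed=seed + i, condition=cond, **params)
            runs[cond] = ds.data
        outputs.append(str(write_lipolysis(runs, outdir / "lipolysis.csv")))
    if not outputs:
        raise SchemaError("simulate stage configured with no dataset kinds")
    return outputs


def _stage_cmc(cfg, outdir, seed):
    curve = read_titration(cfg.get("titration", outdir / "titration.csv"))
    rows = []
    for method, fn in (("phillips", phillips_cmc), ("segmented", segmented_cmc)):
        est = fn(curve)
        rows.append(
            {"method": method, "cmc_mM": est.cmc, "uncertainty_mM": est.uncertainty}
        )
    out = outdir / "cmc_estimates.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return [str(out)]


def _stage_beta(cfg, outdir, seed):
    measurements = read_mixtures(cfg.get("mixtures", outdir / "mixtures.csv"))
    df = analyze_mixtures(measurements)
    out = outdir / "beta_results.csv"
    df.to_csv(out, index=False)
    return [str(out)]


def _stage_msr(cfg, outdir, seed):
    series = read_solubility(
        cfg.get("solubility", outdir / "solubility.csv"), cmc=float(cfg["cmc"])
    )
    est = compute_msr(series)
    out = outdir / "msr.csv"
    pd.DataFrame(
        [{"msr": est.msr, "stderr": est.stderr, "n_points": est.n_points}]
    ).to_csv(out, index=False)
    return [str(out)]


def _stage_meta_pls(cfg, outdir, seed):
    records, declared, numeric_cols = read_meta(
        cfg.get("table", outdir / "meta.csv"),
        cfg.get("schema", outdir / "meta_schema.yaml"),
    )
    X, names = one_hot_encode(records, declared, numeric_cols)
    y = np.array([r.response for r in records])
    model = fit_pls(X, y, n_components=int(cfg.get("components", 2)), names=names)
    report = vip_scores(model)
    out = outdir / "vip.csv"
    report.as_frame().to_csv(out, index=False)
    coef_out = outdir / "coefficients.csv"
    pd.DataFrame({"variable": names, "coefficient": model.coefficients}).to_csv(
        coef_out, index=False
    )
    return [str(out), str(coef_out)]


def _stage_lipolysis(cfg, outdir, seed):
    runs = read_lipolysis(
        cfg.get("timeseries", outdir / "lipolysis.csv"),
        naoh_molarity=float(cfg.get("naoh_molarity", 0.1)),
        lipid_mass=float(cfg.get("lipid_mass", 0.075)),
        lipid_molar_mass=float(cfg.get("lipid_molar_mass", 880.0)),
    )
    rows = []
    profiles = {}
    for cond, cond_runs in sorted(runs.items()):
        profs = [ffa_percent(r) for r in cond_runs]
        profiles[cond] = profs
        for prof in profs:
            fit = fit_first_order(prof)
            rows.append(
                {
                    "condition": cond,
                    "phi_max_percent": fit.phi_max,
                    "k_per_min": fit.k,
                    "degenerate": fit.degenerate,
                }
            )
    out = outdir / "lipolysis_fits.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    outputs = [str(out)]
    if "compare" in cfg:
        a, b = cfg["compare"]["a"], cfg["compare"]["b"]
        at_time = float(cfg["compare"].get("at_time", 60.0))
        diff, p = compare_conditions(profiles[a], profiles[b], at_time=at_time)
        cmp_out = outdir / "lipolysis_comparison.csv"
        pd.DataFrame(
            [{"a": a, "b": b, "at_time_min": at_time, "difference_percent": diff, "p": p}]
        ).to_csv(cmp_out, index=False)
        outputs.append(str(cmp_out))
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cmc": _stage_cmc,
    "beta": _stage_beta,
    "msr": _stage_msr,
    "meta_pls": _stage_meta_pls,
    "lipolysis": _stage_lipolysis,
}
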