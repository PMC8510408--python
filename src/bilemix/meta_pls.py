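"""Meta-analysis statistics: grouped summaries, one-hot designs, NIPALS
partial least squares, VIP scores, and one-tailed Welch t-tests.

Literature-collated micellization data mix categorical descriptors (the four
bile-salt classes: primary/secondary x conjugated/unconjugated) with numeric
covariates (temperature, concentration, pH, salt, solubilizate descriptors).
PLS regression on the autoscaled design tolerates the collinearity of a
full one-hot encoding (no reference level is dropped, so importance is
reported for every class), and the Variable Importance in Projection (VIP)
score ranks descriptors; VIP > 1 is the conventional influence threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, SchemaError

__all__ = [
    "MetaRecord",
    "PlsModel",
    "VipReport",
    "group_summary",
    "one_hot_encode",
    "fit_pls",
    "vip_scores",
    "welch_t_test",
]


@dataclass(frozen=True)
class MetaRecord:
    """One literature datapoint: a response plus its descriptors.

    A categorical value may be a single level or, for binary-mixture
    systems, a pair of levels given as a tuple/list or an ``"A:B"`` string;
    pairs set both indicator columns.
    """

    response: float
    categories: dict = field(default_factory=dict)
    numerics: dict = field(default_factory=dict)
    source: str = ""
    year: int | None = None

    def __post_init__(self):
        if not np.isfinite(self.response):
            raise DomainError("response must be finite")
        for k, v in self.numerics.items():
            if not np.isfinite(v):
                raise DomainError(f"numeric descriptor {k!r} must be finite")


def group_summary(records, group_key: str) -> pd.DataFrame:
    """Per-group mean, sample standard deviation (ddof=1) and count.

    ``group_key`` names a categorical descriptor; records lacking it are
    ignored. Groups of size 1 report NaN for the standard deviation.
    """
    rows = [
        (r.categories[group_key], r.response)
        for r in records
        if group_key in r.categories
    ]
    if not rows:
        raise DomainError(f"no records carry category {group_key!r}")
    df = pd.DataFrame(rows, columns=["group", "response"])
    out = (
        df.groupby("group", sort=True)["response"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out.loc[out["n"] == 1, "sd"] = np.nan
    return out


def _levels_of(value):
    """Normalise a categorical value to a tuple of levels."""
    if isinstance(value, str):
        return tuple(value.split(":")) if ":" in value else (value,)
    if isinstance(value, (tuple, list, set, frozenset)):
        return tuple(value)
    return (value,)


def one_hot_encode(
    records,
    declared_levels: dict[str, list[str]],
    numeric_cols: list[str] | None = None,
):
    """Build a design matrix: full one-hot indicators plus numeric columns.

    Every declared level gets an indicator column in declared order (no
    reference level is dropped); a record tagged with a pair of levels sets
    both indicators. Numeric descriptors are appended unchanged.

    Returns
    -------
    (X, names) : (ndarray of shape (n, p), list of column names)

    Raises
    ------
    SchemaError
        On an empty record list, a level outside its declared set, or a
        missing descriptor.
    """
    records = list(records)
    if not records:
        raise SchemaError("no records to encode")
    numeric_cols = list(numeric_cols or [])
    names = [
        f"{col}={lvl}" for col, levels in declared_levels.items() for lvl in levels
    ]
    names += numeric_cols
    X = np.zeros((len(records), len(names)))
    col_index = {name: j for j, name in enumerate(names)}
    for i, r in enumerate(records):
        for col, levels in declared_levels.items():
            if col not in r.categories:
                raise SchemaError(f"record {i} lacks category {col!r}")
            for lvl in _levels_of(r.categories[col]):
                if lvl not in levels:
                    raise SchemaError(
                        f"record {i}: level {lvl!r} of {col!r} not among "
                        f"declared levels {levels}"
                    )
                X[i, col_index[f"{col}={lvl}"]] = 1.0
        for col in numeric_cols:
            if col not in r.numerics:
                raise SchemaError(f"record {i} lacks numeric descriptor {col!r}")
            X[i, col_index[col]] = r.numerics[col]
    return X, names


@dataclass
class PlsModel:
    """A fitted NIPALS PLS1 model on autoscaled X and y.

    weights, scores and loadings are stored per extracted component;
    ``coefficients`` are on the standardized (autoscaled) scale.
    """

    n_components: int
    x_means: np.ndarray
    x_scales: np.ndarray
    y_mean: float
    y_scale: float
    weights: np.ndarray  # p x A
    scores: np.ndarray  # n x A
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    coefficients: np.ndarray  # p, standardized scale
    names: list[str] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Fitted response on the original y scale."""
        Xs = (np.asarray(X, dtype=float) - self.x_means) / self.x_scales
        return self.y_mean + self.y_scale * (Xs @ self.coefficients)


def fit_pls(
    X: np.ndarray, y: np.ndarray, n_components: int = 2, names: list[str] | None = None
) -> PlsModel:
    """Fit PLS1 by NIPALS on autoscaled data.

    X and y are centred and scaled to unit sample standard deviation
    (ddof=1); components are extracted by the classical NIPALS sequence
    (weight from the X'y covariance, score, loading, deflation). If the
    design runs out of rank before ``n_components`` components, extraction
    stops early with a warning.

    Raises
    ------
    SchemaError
        For a zero-variance X column or constant y.
    DomainError
        For fewer than 3 samples or ``n_components`` < 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise DomainError("need at least 3 samples")
    if n_components < 1:
        raise DomainError("n_components must be >= 1")
    x_means = X.mean(axis=0)
    x_scales = X.std(axis=0, ddof=1)
    # relative threshold: axis reductions leave O(eps) residue on constants
    dead = np.nonzero(x_scales <= 1e-10 * np.maximum(1.0, np.abs(x_means)))[0]
    if dead.size:
        bad = [names[j] if names else str(j) for j in dead]
        raise SchemaError(f"zero-variance design column(s): {bad}")
    y_mean = float(y.mean())
    y_scale = float(y.std(ddof=1))
    if y_scale == 0:
        raise SchemaError("response has zero variance")

    Xs = (X - x_means) / x_scales
    ys = (y - y_mean) / y_scale
    Xa, ya = Xs.copy(), ys.copy()

    W, T, P, Q = [], [], [], []
    x_norm0 = np.linalg.norm(Xs)
    for _ in range(n_components):
        w = Xa.T @ ya
        wn = np.linalg.norm(w)
        if wn < 1e-12 * max(x_norm0, 1.0):
            warnings.warn(
                f"design rank exhausted after {len(W)} components; "
                f"requested {n_components}",
                stacklevel=2,
            )
            break
        w = w / wn
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-24:
            warnings.warn(
                f"degenerate score vector after {len(W)} components",
                stacklevel=2,
            )
            break
        pa = Xa.T @ t / tt
        qa = float(ya @ t / tt)
        Xa = Xa - np.outer(t, pa)
        ya = ya - qa * t
        W.append(w)
        T.append(t)
        P.append(pa)
        Q.append(qa)

    if not W:
        raise SchemaError("no PLS component could be extracted")
    W = np.column_stack(W)
    T = np.column_stack(T)
    P = np.column_stack(P)
    Q = np.asarray(Q)
    coef = W @ np.linalg.solve(P.T @ W, Q)
    return PlsModel(
        n_components=W.shape[1],
        x_means=x_means,
        x_scales=x_scales,
        y_mean=y_mean,
        y_scale=y_scale,
        weights=W,
        scores=T,
        x_loadings=P,
        y_loadings=Q,
        coefficients=coef,
        names=list(names) if names is not None else None,
    )


@dataclass
class VipReport:
    """VIP scores and standardized coefficients per design column."""

    vip: np.ndarray
    coefficients: np.ndarray
    names: list[str] | None = None
    p_values: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        names = self.names or [str(j) for j in range(self.vip.size)]
        return pd.DataFrame(
            {
                "variable": names,
                "vip": self.vip,
                "coefficient": self.coefficients,
            }
        ).sort_values("vip", ascending=False, ignore_index=True)


def vip_scores(model: PlsModel) -> VipReport:
    """Variable Importance in Projection for a fitted model.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ) with
    SSY_a = q_a^2 t_a't_a, the share of y-variance captured by component a.
    The squared scores average to 1 (sum VIP^2 = p) by construction.
    """
    W, T, Q = model.weights, model.scores, model.y_loadings
    p = W.shape[0]
    ssy = Q**2 * np.einsum("na,na->a", T, T)
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    vip = np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())
    return VipReport(vip=vip, coefficients=model.coefficients.copy(), names=model.names)


_TAILS = {"left": "less", "right": "greater", "two": "two-sided"}


def welch_t_test(a, b, tail: str = "two") -> tuple[float, float, float]:
    """Welch's unequal-variance t-test of mean(a) - mean(b).

    ``tail``: 'right' tests mean(a) > mean(b), 'left' the reverse, 'two'
    two-sided. Returns (t, Satterthwaite df, p).
    """
    if tail not in _TAILS:
        raise DomainError(f"tail must be one of {sorted(_TAILS)}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each sample needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=_TAILS[tail])
    return float(res.statistic), float(res.df), float(res.pvalue)
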