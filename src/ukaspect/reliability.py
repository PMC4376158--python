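"""Observer-reliability analysis: intraclass correlation and median differences.

Two observers each grade every case twice (sessions two weeks apart), both
for region uptake values and component angles.  Reliability is summarized
by single-measure intraclass correlation coefficients computed from the
two-way ANOVA mean squares of the items × raters matrix:

* ``oneway``                  ICC(1,1)  = (MSB − MSW) / (MSB + (k−1) MSW)
* ``twoway_random_absolute``  ICC(2,1)  = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE))
* ``twoway_mixed_consistency`` ICC(3,1) = (MSR − MSE) / (MSR + (k−1) MSE)

where MSR/MSC/MSE are the item, rater and residual mean squares, MSB/MSW
the one-way between/within-item mean squares, n the number of items and k
the number of columns.  Intra-observer reliability (same rater, two
sessions) uses the consistency form; inter-observer reliability uses
absolute agreement, so a systematic between-rater offset lowers it.
Negative estimates are reported as computed, flagged rather than clipped.

Values are graded as in routine musculoskeletal reliability work:
0.81–1.00 "very good", 0.61–0.80 "good"; a value of 1 indicates perfect
reliability.  A table with zero total variance has no defined ICC and
raises rather than returning 1 by fiat.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ReliabilityError

__all__ = [
    "ICCModel",
    "RatingsTable",
    "ICCResult",
    "icc",
    "intra_observer",
    "inter_observer",
    "median_difference",
    "reliability_grade",
    "ratings_from_tidy",
    "reliability_table",
]


class ICCModel(str, enum.Enum):
    ONEWAY = "oneway"
    TWOWAY_RANDOM_ABSOLUTE = "twoway_random_absolute"
    TWOWAY_MIXED_CONSISTENCY = "twoway_mixed_consistency"


class SessionPolicy(str, enum.Enum):
    FIRST_SESSION = "first_session"
    MEAN_OF_SESSIONS = "mean_of_sessions"


@dataclass(frozen=True)
class RatingsTable:
    """Items × (observer, session) matrix of readings.

    ``columns`` are (observer, session) pairs with unique labels; values
    must be finite, with at least two items and two columns.
    """

    items: tuple
    columns: tuple[tuple[str, int], ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        items = tuple(self.items)
        columns = tuple((str(o), int(s)) for o, s in self.columns)
        if vals.ndim != 2:
            raise ReliabilityError(f"values must be a 2D items x columns matrix, got {vals.ndim}D")
        if vals.shape != (len(items), len(columns)):
            raise ReliabilityError(
                f"shape {vals.shape} does not match {len(items)} items x {len(columns)} columns"
            )
        if len(items) < 2:
            raise ReliabilityError("need at least 2 items")
        if len(columns) < 2:
            raise ReliabilityError("need at least 2 rater/session columns")
        if len(set(columns)) != len(columns):
            raise ReliabilityError("column labels must be unique")
        if not np.all(np.isfinite(vals)):
            raise ReliabilityError("all ratings must be finite")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "items", items)
        object.__setattr__(self, "columns", columns)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def observers(self) -> list[str]:
        seen: dict[str, None] = {}
        for obs, _ in self.columns:
            seen.setdefault(obs, None)
        return list(seen)

    def select(self, columns: Sequence[tuple[str, int]]) -> "RatingsTable":
        idx = [self.columns.index(tuple(c)) for c in columns]
        return RatingsTable(self.items, [self.columns[i] for i in idx], self.values[:, idx])

    def observer_sessions(self, observer: str) -> list[int]:
        return [s for o, s in self.columns if o == observer]


@dataclass(frozen=True)
class ICCResult:
    """Single-measure ICC with its variance-component decomposition.

    ``variance_components`` holds (between-item, between-rater, residual)
    method-of-moments estimates; they may be negative in small samples and
    are reported as estimated.  ``negative`` flags a negative ICC estimate.
    ``ci95`` is the F-based two-sided 95% interval.
    """

    value: float
    model: ICCModel
    variance_components: tuple[float, float, float]
    n_items: int
    n_raters: int
    negative: bool = False
    label: Optional[str] = None
    ci95: Optional[tuple[float, float]] = None

    @property
    def grade(self) -> str:
        return reliability_grade(self.value)


def reliability_grade(value: float) -> str:
    """Qualitative band: >=0.81 'very good', 0.61-0.80 'good', else 'moderate or poor'."""
    if value >= 0.81:
        return "very good"
    if value >= 0.61:
        return "good"
    return "moderate or poor"


def _mean_squares(x: np.ndarray) -> dict[str, float]:
    """Two-way crossed ANOVA mean squares of an n x k matrix (no replication)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_cols + ss_err) / (n * (k - 1))
    return {"MSR": msr, "MSC": msc, "MSE": mse, "MSW": msw, "SST": ss_total}


def _f_ci(model: ICCModel, ms: dict[str, float], n: int, k: int, alpha: float = 0.05):
    """Two-sided F-based confidence interval (McGraw & Wong forms)."""
    msr, msc, mse, msw = ms["MSR"], ms["MSC"], ms["MSE"], ms["MSW"]
    try:
        if model is ICCModel.ONEWAY:
            if msw <= 0:
                return None
            fobs = msr / msw
            fl = fobs / stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
            fu = fobs * stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
            return ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
        if model is ICCModel.TWOWAY_MIXED_CONSISTENCY:
            if mse <= 0:
                return None
            fobs = msr / mse
            df2 = (n - 1) * (k - 1)
            fl = fobs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
            fu = fobs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
            return ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
        # ICC(2,1): Satterthwaite approximation
        if mse <= 0:
            return None
        icc2 = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        a = (k * icc2) / (n * (1 - icc2)) if icc2 != 1 else np.inf
        b = 1 + (k * icc2 * (n - 1)) / (n * (1 - icc2)) if icc2 != 1 else np.inf
        if not np.isfinite(a) or not np.isfinite(b):
            return None
        with np.errstate(invalid="ignore", divide="ignore"):
            v_num = (a * msc + b * mse) ** 2
            v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = v_num / v_den
            fl = stats.f.ppf(1 - alpha / 2, n - 1, v)
            fu = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
            upper = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
        if not (np.isfinite(lower) and np.isfinite(upper)):
            return None
        return (float(lower), float(upper))
    except (ZeroDivisionError, FloatingPointError):
        return None


def icc(table: RatingsTable, model: ICCModel | str, label: Optional[str] = None,
        with_ci: bool = True) -> ICCResult:
    """Single-measure intraclass correlation for the requested model.

    Raises :class:`~ukaspect.errors.ReliabilityError` when the table has
    zero total variance (every entry identical), where no ICC is defined.
    """
    model = ICCModel(model)
    x = table.values
    n, k = x.shape
    ms = _mean_squares(x)
    if ms["SST"] <= 0:
        raise ReliabilityError(
            "undefined ICC: zero total variance (all ratings identical)"
        )
    msr, msc, mse, msw = ms["MSR"], ms["MSC"], ms["MSE"], ms["MSW"]

    if model is ICCModel.ONEWAY:
        denom = msr + (k - 1) * msw
        value = (msr - msw) / denom if denom != 0 else 1.0
        components = ((msr - msw) / k, 0.0, msw)
    elif model is ICCModel.TWOWAY_RANDOM_ABSOLUTE:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        value = (msr - mse) / denom if denom != 0 else 1.0
        components = ((msr - mse) / k, (msc - mse) / n, mse)
    else:
        denom = msr + (k - 1) * mse
        value = (msr - mse) / denom if denom != 0 else 1.0
        components = ((msr - mse) / k, (msc - mse) / n, mse)

    return ICCResult(
        value=float(value),
        model=model,
        variance_components=tuple(float(c) for c in components),
        n_items=n,
        n_raters=k,
        negative=bool(value < 0),
        label=label,
        ci95=_f_ci(model, ms, n, k) if with_ci else None,
    )


def intra_observer(table: RatingsTable, observer: Optional[str] = None) -> ICCResult:
    """Test–retest ICC for one observer's two sessions (two-way mixed, consistency).

    ``observer`` may be omitted when the table holds exactly one observer.
    """
    observers = table.observers
    if observer is None:
        if len(observers) != 1:
            raise ReliabilityError(
                f"table holds observers {observers}; name the one to analyze"
            )
        observer = observers[0]
    sessions = table.observer_sessions(observer)
    if len(sessions) != 2:
        raise ReliabilityError(
            f"intra-observer ICC needs exactly two sessions for {observer!r}, found {sessions}"
        )
    sub = table.select([(observer, s) for s in sessions])
    return icc(sub, ICCModel.TWOWAY_MIXED_CONSISTENCY, label=observer)


def inter_observer(
    table: RatingsTable,
    session_policy: SessionPolicy | str = SessionPolicy.FIRST_SESSION,
) -> ICCResult:
    """Between-observer ICC (two-way random, absolute agreement).

    ``session_policy`` collapses repeated sessions to one column per
    observer: each observer's first session (default) or the mean of their
    sessions.
    """
    policy = SessionPolicy(session_policy)
    observers = table.observers
    if len(observers) < 2:
        raise ReliabilityError(f"inter-observer ICC needs >=2 observers, found {observers}")
    cols = []
    for obs in observers:
        sessions = sorted(table.observer_sessions(obs))
        if policy is SessionPolicy.FIRST_SESSION:
            idx = table.columns.index((obs, sessions[0]))
            cols.append(table.values[:, idx])
        else:
            idxs = [table.columns.index((obs, s)) for s in sessions]
            cols.append(table.values[:, idxs].mean(axis=1))
    collapsed = RatingsTable(
        table.items,
        [(obs, 0) for obs in observers],
        np.column_stack(cols),
    )
    label = "-".join(observers)
    return icc(collapsed, ICCModel.TWOWAY_RANDOM_ABSOLUTE, label=label)


def median_difference(a: Iterable[float], b: Iterable[float]) -> dict[str, float]:
    """Median signed and absolute paired difference between two reading vectors.

    For even lengths the median is the midpoint of the two central order
    statistics.
    """
    av = np.asarray(list(a), dtype=float)
    bv = np.asarray(list(b), dtype=float)
    if av.shape != bv.shape or av.ndim != 1 or av.size < 1:
        raise ReliabilityError(
            f"paired vectors of equal length >= 1 required, got shapes {av.shape} and {bv.shape}"
        )
    d = av - bv
    return {"median_signed": float(np.median(d)), "median_absolute": float(np.median(np.abs(d)))}


def ratings_from_tidy(df: pd.DataFrame, variable: Optional[str] = None) -> RatingsTable:
    """Pivot a tidy ratings frame (item, observer, session, variable, value) to a matrix.

    ``variable`` selects one variable when the frame holds several.
    """
    required = {"item", "observer", "session", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ReliabilityError(f"tidy ratings table is missing columns: {sorted(missing)}")
    if "variable" in df.columns:
        variables = df["variable"].unique()
        if variable is None:
            if len(variables) != 1:
                raise ReliabilityError(f"multiple variables present {list(variables)}; pick one")
            variable = variables[0]
        df = df[df["variable"] == variable]
        if df.empty:
            raise ReliabilityError(f"no rows for variable {variable!r}")
    wide = df.pivot_table(index="item", columns=["observer", "session"], values="value")
    if wide.isna().any().any():
        raise ReliabilityError("incomplete ratings: every item needs a value in every observer/session")
    columns = [(str(obs), int(sess)) for obs, sess in wide.columns]
    return RatingsTable(tuple(wide.index), columns, wide.to_numpy())


def reliability_table(
    df: pd.DataFrame,
    session_policy: SessionPolicy | str = SessionPolicy.FIRST_SESSION,
) -> pd.DataFrame:
    """Per-variable reliability summary: intra-observer ICCs and the inter-observer ICC.

    Mirrors the layout of a published reliability table: one row per
    variable with one intra-observer column per observer and one
    inter-observer column, model names recorded.
    """
    if "variable" not in df.columns:
        df = df.assign(variable="value")
    rows = []
    for variable in df["variable"].unique():
        table = ratings_from_tidy(df, variable)
        row: dict[str, object] = {"variable": variable}
        for obs in table.observers:
            try:
                res = intra_observer(table, obs)
                row[f"intra_{obs}"] = res.value
                row[f"intra_{obs}_grade"] = res.grade
            except ReliabilityError as exc:
                row[f"intra_{obs}"] = np.nan
                row[f"intra_{obs}_grade"] = f"undefined ({exc})"
        inter = inter_observer(table, session_policy)
        row["inter"] = inter.value
        row["inter_grade"] = inter.grade
        row["intra_model"] = ICCModel.TWOWAY_MIXED_CONSISTENCY.value
        row["inter_model"] = ICCModel.TWOWAY_RANDOM_ABSOLUTE.value
        rows.append(row)
    return pd.DataFrame(rows)
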