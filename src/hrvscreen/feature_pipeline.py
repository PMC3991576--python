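"""Feature processing: significance screen, min-max normalization, and the
three combined HRV features.

The screen runs a two-sample t-test per measure between the CHF and healthy
groups (Welch by default) and rejects measures with ``p > alpha``
(``alpha = 0.1`` by default).  The three combined features aggregate the nine
surviving measures:

    SUM_TD = SDNN + pNN50 - CVrr          (ms scale)
    SUM_FD = VLF + LF + HF + TP           (log-power scale)
    SUM_IE = ApEn + SampEn                (dimensionless)

CVrr enters with a negative sign because it moves opposite to SDNN and pNN50
between the two groups.  The combinations are applied to raw (unnormalized)
feature values; min-max normalization is available separately as classifier
preprocessing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hrv_features import FEATURE_NAMES, HRVFeatures

__all__ = [
    "GroupSummary",
    "ScreenResult",
    "CombinedFeatures",
    "COMBINED_NAMES",
    "welch_ttest_summary",
    "screen_features",
    "minmax_normalize",
    "combine",
    "combine_features",
    "combine_table",
]

COMBINED_NAMES = ("sum_td", "sum_fd", "sum_ie")

_SUMMARY_COLUMNS = ("mean_chf", "sd_chf", "n_chf", "mean_healthy", "sd_healthy", "n_healthy")


@dataclass(frozen=True)
class GroupSummary:
    """Per-feature group statistics: mean, SD and n for the CHF and healthy
    groups, as one row per feature."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _SUMMARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"group summary is missing columns {missing}")
        t = self.table
        if (t[["sd_chf", "sd_healthy"]] < 0).any().any():
            raise ValueError("group SDs must be nonnegative")
        if (t[["n_chf", "n_healthy"]] < 2).any().any():
            raise ValueError("each group needs n >= 2")

    @classmethod
    def from_csv(cls, path) -> "GroupSummary":
        df = pd.read_csv(path, comment="#")
        if "feature" in df.columns:
            df = df.set_index("feature")
        return cls(df)

    def to_csv(self, path) -> None:
        self.table.rename_axis("feature").to_csv(path)

    @property
    def features(self) -> list[str]:
        return list(self.table.index)


@dataclass(frozen=True)
class ScreenResult:
    """Per-feature t statistic, p value and retention flag at level alpha."""

    table: pd.DataFrame  # columns: t, p, retained
    alpha: float

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])

    @property
    def rejected(self) -> list[str]:
        return list(self.table.index[~self.table["retained"]])


@dataclass(frozen=True)
class CombinedFeatures:
    sum_td: float
    sum_fd: float
    sum_ie: float

    def as_dict(self) -> dict[str, float]:
        return {"sum_td": self.sum_td, "sum_fd": self.sum_fd, "sum_ie": self.sum_ie}


def welch_ttest_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var: bool = False):
    """Two-sample t-test from group summary statistics.

    Welch's unequal-variance form by default, with the Welch-Satterthwaite
    degrees of freedom; ``equal_var=True`` gives the pooled-variance test.
    Returns ``(t, df, p)`` with a two-sided p value.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a == 0 and sd_b == 0:
        raise ValueError("both group SDs are zero: t statistic undefined")
    t, p = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var)
    if equal_var:
        df = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(t), float(df), float(p)


def _screen_from_summary(summary: GroupSummary, alpha: float, equal_var: bool) -> ScreenResult:
    rows = {}
    for feat, row in summary.table.iterrows():
        t, _, p = welch_ttest_summary(
            row["mean_chf"], row["sd_chf"], int(row["n_chf"]),
            row["mean_healthy"], row["sd_healthy"], int(row["n_healthy"]),
            equal_var=equal_var,
        )
        rows[feat] = (t, p, p <= alpha)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["t", "p", "retained"])
    return ScreenResult(df, alpha)


def _screen_from_table(table: pd.DataFrame, alpha: float, equal_var: bool) -> ScreenResult:
    if "label" not in table.columns:
        raise ValueError("feature table must have a 'label' column (CHF=1, healthy=0)")
    labels = table["label"].astype(int)
    if labels.nunique() < 2:
        raise ValueError("feature screen needs both classes present")
    chf = table[labels == 1]
    healthy = table[labels == 0]
    feats = [c for c in table.columns if c in FEATURE_NAMES or c in COMBINED_NAMES]
    if not feats:
        feats = [c for c in table.columns if c not in ("label", "record_id", "path")]
    rows = {}
    for feat in feats:
        t, p = stats.ttest_ind(chf[feat], healthy[feat], equal_var=equal_var)
        rows[feat] = (float(t), float(p), p <= alpha)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["t", "p", "retained"])
    return ScreenResult(df, alpha)


def screen_features(data, alpha: float = 0.1, equal_var: bool = False) -> ScreenResult:
    """Significance screen of HRV measures between the two groups.

    ``data`` is either a per-record feature table (DataFrame with a ``label``
    column, CHF=1 / healthy=0) or a :class:`GroupSummary`.  A feature is
    rejected when its two-sided p exceeds ``alpha``.
    """
    if isinstance(data, GroupSummary):
        return _screen_from_summary(data, alpha, equal_var)
    if isinstance(data, pd.DataFrame):
        return _screen_from_table(data, alpha, equal_var)
    raise TypeError("data must be a feature DataFrame or a GroupSummary")


def group_summary_from_table(table: pd.DataFrame) -> GroupSummary:
    """Collapse a per-record feature table into per-feature group statistics."""
    if "label" not in table.columns:
        raise ValueError("feature table must have a 'label' column (CHF=1, healthy=0)")
    labels = table["label"].astype(int)
    chf = table[labels == 1]
    healthy = table[labels == 0]
    if len(chf) < 2 or len(healthy) < 2:
        raise ValueError("each group needs at least 2 records")
    feats = [c for c in table.columns if c not in ("label", "record_id", "path")]
    rows = {
        f: (
            chf[f].mean(), chf[f].std(ddof=1), len(chf),
            healthy[f].mean(), healthy[f].std(ddof=1), len(healthy),
        )
        for f in feats
    }
    return GroupSummary(pd.DataFrame.from_dict(rows, orient="index", columns=_SUMMARY_COLUMNS))


def minmax_normalize(values) -> np.ndarray:
    """Rescale a vector to [0, 1] by its own min and max.

    A constant vector maps to all zeros with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("min-max normalization needs at least 2 values")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        warnings.warn("constant feature vector: normalized to all zeros", stacklevel=2)
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def combine(f: HRVFeatures) -> CombinedFeatures:
    """Collapse the nine retained measures into SUM_TD, SUM_FD and SUM_IE.

    Operates on raw feature values (the combined time-domain feature lives on
    the ms scale).  An undefined entropy component yields an undefined
    (NaN) SUM_IE.
    """
    sum_td = f.sdnn + f.pnn50 - f.cvrr
    sum_fd = f.vlf + f.lf + f.hf + f.tp
    sum_ie = f.apen + f.sampen
    if not (math.isfinite(f.apen) and math.isfinite(f.sampen)):
        sum_ie = math.nan
    return CombinedFeatures(sum_td=sum_td, sum_fd=sum_fd, sum_ie=sum_ie)


# alias kept for symmetry with module naming elsewhere
combine_features = combine


def combine_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append sum_td / sum_fd / sum_ie columns to a per-record feature table."""
    out = table.copy()
    out["sum_td"] = table["sdnn"] + table["pnn50"] - table["cvrr"]
    out["sum_fd"] = table["vlf"] + table["lf"] + table["hf"] + table["tp"]
    out["sum_ie"] = table["apen"] + table["sampen"]
    return out
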