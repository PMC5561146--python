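"""Normalization, Pearson correlation and condition comparison.

The correlation analyses treat one module (reservoir or microchannel) at
one recording day as one data point.  Activity is normalised per module to
its own grand mean over the whole study, which neutralises the large
absolute activity differences between cultures and channels.  Missing
values propagate as NaN — "no events" is never coerced to zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int
    degenerate: bool = False


@dataclass
class ModuleSeries:
    """Per-DIV values of one named feature for one module."""

    module_id: int | str
    divs: np.ndarray
    values: np.ndarray
    feature: str = ""

    def __post_init__(self) -> None:
        self.divs = np.asarray(self.divs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.divs.size != self.values.size:
            raise ValueError("divs and values length mismatch")
        if self.divs.size and np.any(np.diff(self.divs) <= 0):
            raise ValueError("DIVs must be strictly increasing")


def normalize_series(series: ModuleSeries) -> ModuleSeries:
    """Divide by the series' own grand mean (over non-missing entries).

    The normalised series has mean 1 over its non-missing entries.
    Idempotent.  Raises if all values are missing or the mean is zero.
    """
    vals = series.values
    finite = np.isfinite(vals)
    if not np.any(finite):
        raise ValueError("normalize_series: no non-missing value")
    mean = float(np.mean(vals[finite]))
    if mean == 0:
        raise ValueError("normalize_series: zero mean")
    return replace(series, values=vals / mean)


def pearson_correlation(x: Sequence[float], y: Sequence[float]
                        ) -> PearsonResult:
    """Product-moment correlation with two-sided p from the t transform.

    Pairs with a missing member are dropped; fewer than 3 complete pairs is
    an error; zero variance on either side is flagged degenerate (r = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y length mismatch")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need n >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        return PearsonResult(r=0.0, p=math.nan, n=n, degenerate=True)
    r, p = sps.pearsonr(x, y)
    return PearsonResult(r=float(r), p=float(p), n=n)


def activity_velocity_table(features: pd.DataFrame,
                            velocities: pd.DataFrame,
                            pooled: bool = True,
                            velocity_col: str = "velocity") -> pd.DataFrame:
    """Correlate each activity feature with propagation velocity.

    ``features`` and ``velocities`` are tidy frames keyed by
    (module_id, div); every non-key column of ``features`` is one feature.
    ``pooled=True`` treats all module-DIV points as one sample (one row per
    feature); ``pooled=False`` correlates within each recording day
    separately (one row per feature and DIV).  Days or features with fewer
    than 3 complete pairs are reported with NaN r.
    """
    keys = ["module_id", "div"]
    for frame, name in ((features, "features"), (velocities, "velocities")):
        missing = [k for k in keys if k not in frame.columns]
        if missing:
            raise ValueError(f"{name} frame missing key column(s) {missing}")
    if velocity_col not in velocities.columns:
        raise ValueError(f"velocities frame missing column {velocity_col!r}")
    merged = features.merge(velocities[keys + [velocity_col]],
                            on=keys, how="inner")
    if merged.empty:
        raise ValueError("no aligned (module_id, div) keys between tables")
    feature_cols = [c for c in features.columns if c not in keys]

    def one_corr(sub: pd.DataFrame, feat: str) -> dict:
        try:
            res = pearson_correlation(sub[feat], sub[velocity_col])
            return {"r": res.r, "p": res.p, "n": res.n,
                    "degenerate": res.degenerate}
        except ValueError:
            return {"r": math.nan, "p": math.nan,
                    "n": int(sub[feat].notna().sum()), "degenerate": False}

    rows = []
    if pooled:
        for feat in feature_cols:
            rows.append({"feature": feat, **one_corr(merged, feat)})
    else:
        for div, sub in merged.groupby("div"):
            for feat in feature_cols:
                rows.append({"feature": feat, "div": div,
                             **one_corr(sub, feat)})
    return pd.DataFrame(rows)


def compare_conditions(baseline: pd.DataFrame,
                       treated: pd.DataFrame) -> pd.DataFrame:
    """Paired baseline-vs-treatment comparison of feature tables.

    Both frames are indexed by electrode/channel and share feature columns.
    Unpaired rows are excluded (with a warning giving the count).  Returns
    one row per feature: per-condition mean and StDev, paired mean
    difference, paired t statistic and two-sided p.
    """
    common = baseline.index.intersection(treated.index)
    dropped = (len(baseline) - len(common)) + (len(treated) - len(common))
    if dropped:
        warnings.warn(f"compare_conditions: excluded {dropped} unpaired rows")
    if len(common) == 0:
        raise ValueError("no paired electrodes/channels between conditions")
    b = baseline.loc[common]
    t = treated.loc[common]
    rows = []
    for col in baseline.columns:
        if col not in treated.columns:
            continue
        xb, xt = b[col].to_numpy(float), t[col].to_numpy(float)
        ok = np.isfinite(xb) & np.isfinite(xt)
        xb, xt = xb[ok], xt[ok]
        diff = xt - xb
        if xb.size >= 2 and np.std(diff) > 0:
            tstat, p = sps.ttest_rel(xt, xb)
        else:
            tstat, p = (0.0, math.nan) if np.allclose(diff, 0) \
                else (math.nan, math.nan)
        rows.append({
            "feature": col,
            "baseline_mean": float(np.mean(xb)) if xb.size else math.nan,
            "baseline_std": float(np.std(xb, ddof=1)) if xb.size > 1 else math.nan,
            "treated_mean": float(np.mean(xt)) if xt.size else math.nan,
            "treated_std": float(np.std(xt, ddof=1)) if xt.size > 1 else math.nan,
            "mean_diff": float(np.mean(diff)) if diff.size else math.nan,
            "t": float(tstat), "p": float(p), "n": int(xb.size),
        })
    return pd.DataFrame(rows)
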