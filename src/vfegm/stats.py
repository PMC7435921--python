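"""Cohort-level summaries and paired LV-vs-RV comparisons.

Per-patient parameters (spectral and information-theoretic) are aggregated
into a table of mean ± SD per channel with a two-sided paired Student t-test
per parameter and window.  Raw p-values are reported (matching common
practice for exploratory electrophysiology tables); a Holm-corrected column
is emitted additionally and clearly labelled as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTestError, ValidationError

logger = logging.getLogger(__name__)

#: Threshold below which a p-value is rendered numerically (else "ns").
NS_THRESHOLD = 0.05

#: Identifier columns; everything else in a parameter frame is summarized.
ID_COLUMNS = ("patient", "channel", "window")


class TTestResult(NamedTuple):
    t: float
    p: float
    df: int


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sided paired Student t-test.

    t = mean(a−b) / (sd(a−b)/√n) with df = n−1; antisymmetric in its
    arguments (swapping a and b flips the sign of t, p unchanged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired test needs two aligned 1-D vectors")
    n = a.size
    if n < 2:
        raise ValidationError("paired test needs at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise DegenerateTestError(
            "degenerate paired test: differences have zero variance"
        )
    res = sstats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=n - 1)


@dataclass(frozen=True)
class CohortTable:
    """Per-parameter, per-window cohort summary with paired tests.

    ``frame`` columns: parameter, window, n_pairs, mean_LV, sd_LV, mean_RV,
    sd_RV, t_statistic, p_value, p_holm.
    """

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_text(self) -> str:
        """Aligned text rendering, one block per window, "ns" for p ≥ 0.05."""
        lines = []
        for window, grp in self.frame.groupby("window", sort=True):
            lines.append(f"Window {window}")
            lines.append(f"{'parameter':<10} {'LV':>16} {'RV':>16} {'p':>8}")
            for _, row in grp.iterrows():
                p = row["p_value"]
                if not np.isfinite(p):
                    p_str = "degen"
                elif p >= NS_THRESHOLD:
                    p_str = "ns"
                elif p < 0.001:
                    p_str = "<0.001"
                else:
                    p_str = f"{p:.3f}"
                lv = f"{row['mean_LV']:.2f} ± {row['sd_LV']:.2f}"
                rv = f"{row['mean_RV']:.2f} ± {row['sd_RV']:.2f}"
                lines.append(f"{row['parameter']:<10} {lv:>16} {rv:>16} {p_str:>8}")
            lines.append("")
        return "\n".join(lines)


def summarize_cohort(params: pd.DataFrame) -> CohortTable:
    """Aggregate a tidy per-patient parameter frame into a cohort table.

    ``params`` must carry the identifier columns ``patient``, ``channel``
    (LV/RV) and ``window``; every other (numeric) column is treated as a
    parameter.  Patients missing one channel in a window are dropped from
    that window with a logged warning.  At least two complete pairs are
    required per window.
    """
    missing = [c for c in ID_COLUMNS if c not in params.columns]
    if missing:
        raise ValidationError(f"parameter frame lacks identifier columns {missing}")
    value_cols = [c for c in params.columns if c not in ID_COLUMNS]
    if not value_cols:
        raise ValidationError("parameter frame has no value columns")

    rows = []
    for window, grp in params.groupby("window", sort=True):
        wide = grp.pivot_table(
            index="patient", columns="channel", values=value_cols, aggfunc="first"
        )
        for param in value_cols:
            if ("LV" not in grp["channel"].values) or ("RV" not in grp["channel"].values):
                raise ValidationError(f"window {window} lacks one of the channels")
            sub = wide[param][["LV", "RV"]]
            complete = sub.dropna()
            dropped = sub.index.difference(complete.index)
            if len(dropped):
                logger.warning(
                    "window %s, parameter %s: dropping patients without both channels: %s",
                    window, param, list(dropped),
                )
            if len(complete) < 2:
                raise ValidationError(
                    f"window {window}, parameter {param}: fewer than 2 complete pairs"
                )
            lv = complete["LV"].to_numpy()
            rv = complete["RV"].to_numpy()
            try:
                test = paired_t_test(lv, rv)
                t, p = test.t, test.p
            except DegenerateTestError:
                t, p = np.nan, np.nan
            rows.append(
                {
                    "parameter": param,
                    "window": window,
                    "n_pairs": len(complete),
                    "mean_LV": lv.mean(),
                    "sd_LV": lv.std(ddof=1),
                    "mean_RV": rv.mean(),
                    "sd_RV": rv.std(ddof=1),
                    "t_statistic": t,
                    "p_value": p,
                }
            )
    frame = pd.DataFrame(rows)
    # Holm step-down within each window, over the parameters actually tested
    frame["p_holm"] = np.nan
    for window in frame["window"].unique():
        m = (frame["window"] == window) & frame["p_value"].notna()
        if m.any():
            frame.loc[m, "p_holm"] = multipletests(
                frame.loc[m, "p_value"], method="holm"
            )[1]
    return CohortTable(frame=frame)
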