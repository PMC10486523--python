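"""Imaging-immune association statistics.

Covers the radiology-pathology comparisons used in window-of-opportunity
breast-cancer studies: a grid of Spearman rank correlations between MRI
features (FTV, WF, SER, PE, ADC at each timepoint plus their treatment
changes) and TIL quantities, paired t-tests of pre vs post values, cohort
summary statistics, and the dichotomization of patients into
persistent/diminished change-in-PE and high/low pre-treatment ADC classes.

No multiplicity correction is applied to the correlation grid; each cell
reports its own two-sided p-value and the pairwise-complete sample size.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "spearman",
    "build_correlation_table",
    "paired_ttest",
    "PairedTestResult",
    "dichotomize",
    "DichotomyLabels",
    "cohort_summary",
    "DELTA_PE_CUT",
    "ADC_CUT",
]

DELTA_PE_CUT = -10.0  # %; change in peak PE at or below this is "diminished"
ADC_CUT = 0.92e-3  # mm^2/s; pre-treatment ADC strictly above this is "high"

FEATURES = ["ftv", "wf", "ser", "pe", "adc"]
TIL_COLUMNS = ["pre_til", "post_til", "delta_til"]


def spearman(
    x, y, method: str = "t-approx"
) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    ``method='t-approx'`` (default) uses the asymptotic t approximation for
    the two-sided p-value; ``method='exact'`` enumerates all permutations
    (supported for n <= 8). Zero variance in either vector is undefined and
    returns (nan, nan) with a log entry.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError(f"need n >= 3 pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite; drop missing values first")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("spearman: zero variance in an input; correlation undefined")
        return float("nan"), float("nan")

    if method == "t-approx":
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    if method == "exact":
        n = len(x)
        if n > 8:
            raise ValueError("exact permutation p supported for n <= 8")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = float(stats.spearmanr(x, y).statistic)
        count = 0
        total = math.factorial(n)
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= abs(obs) - 1e-12:
                count += 1
        return obs, count / total
    raise ValueError(f"unknown method {method!r}")


def build_correlation_table(
    features: pd.DataFrame, tils: pd.DataFrame, min_n: int = 3
) -> pd.DataFrame:
    """The feature x TIL Spearman grid.

    ``features`` is indexed by patient with columns ``pre_<f>`` and
    ``post_<f>`` for f in FTV/WF/SER/PE/ADC; ``tils`` is indexed by patient
    with columns pre_til, post_til, delta_til. Rows of the result are each
    feature at MRI #1 (pre), MRI #2 (post) and the change (delta); columns
    hold (rho, p, n) per TIL quantity, pairwise-complete. Cells with fewer
    than ``min_n`` complete pairs are left missing.
    """
    rows = []
    for f in FEATURES:
        for tp, label in (("pre", "mri1"), ("post", "mri2"), ("delta", "delta")):
            if tp == "delta":
                vals = features[f"post_{f}"] - features[f"pre_{f}"]
            else:
                vals = features[f"{tp}_{f}"]
            row: dict[str, float] = {}
            for til_col in TIL_COLUMNS:
                both = pd.concat([vals.rename("x"), tils[til_col].rename("y")],
                                 axis=1, join="inner").dropna()
                if len(both) < min_n:
                    row[f"{til_col}_rho"] = np.nan
                    row[f"{til_col}_p"] = np.nan
                    row[f"{til_col}_n"] = len(both)
                    continue
                rho, p = spearman(both["x"], both["y"])
                row[f"{til_col}_rho"] = rho
                row[f"{til_col}_p"] = p
                row[f"{til_col}_n"] = len(both)
            rows.append(pd.Series(row, name=f"{f}_{label}"))
    return pd.DataFrame(rows)


@dataclass
class PairedTestResult:
    t: float
    p: float
    mean_diff: float
    n: int
    degenerate: bool = False


def paired_ttest(pre, post) -> PairedTestResult:
    """Classical paired t-test on post - pre differences.

    Zero-variance differences (including post identical to pre) cannot be
    tested and come back flagged degenerate with the mean difference intact.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D and paired")
    if len(pre) < 2:
        raise ValueError("need at least two pairs")
    d = post - pre
    if np.ptp(d) == 0:
        log.warning("paired_ttest: zero-variance differences; test degenerate")
        return PairedTestResult(t=float("nan"), p=float("nan"),
                                mean_diff=float(d.mean()), n=len(d), degenerate=True)
    t, p = stats.ttest_rel(post, pre)
    return PairedTestResult(t=float(t), p=float(p), mean_diff=float(d.mean()), n=len(d))


@dataclass
class DichotomyLabels:
    """Per-patient persistent/diminished and high/low class labels."""

    delta_pe_class: pd.Series  # 'diminished' | 'persistent'
    adc_class: pd.Series  # 'high' | 'low'
    delta_pe_cut: float
    adc_cut: float
    strategy: str


def dichotomize(
    delta_pe: pd.Series,
    pre_adc: pd.Series,
    strategy: str = "fixed",
    delta_pe_cut: float = DELTA_PE_CUT,
    adc_cut: float = ADC_CUT,
) -> DichotomyLabels:
    """Split patients on change-in-peak-PE and pre-treatment ADC.

    ``strategy='fixed'``: 'diminished' means a PE decrease of |cut| percent
    or more (delta PE <= cut, default -10%); 'high' ADC means strictly above
    the cut (default 0.92e-3 mm^2/s), low otherwise. ``strategy='median'``
    uses each cohort median as the cut; values exactly at the median go to
    the non-extreme class ('persistent' / 'high') and are logged.
    """
    if strategy == "median":
        delta_pe_cut = float(delta_pe.median())
        adc_cut = float(pre_adc.median())
        n_ties = int((delta_pe == delta_pe_cut).sum() + (pre_adc == adc_cut).sum())
        if n_ties:
            log.info("dichotomize: %d value(s) exactly at a median cut -> non-extreme class",
                     n_ties)
        pe_class = np.where(delta_pe < delta_pe_cut, "diminished", "persistent")
        adc_class = np.where(pre_adc >= adc_cut, "high", "low")
    elif strategy == "fixed":
        pe_class = np.where(delta_pe <= delta_pe_cut, "diminished", "persistent")
        adc_class = np.where(pre_adc > adc_cut, "high", "low")
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return DichotomyLabels(
        delta_pe_class=pd.Series(pe_class, index=delta_pe.index, name="delta_pe_class"),
        adc_class=pd.Series(adc_class, index=pre_adc.index, name="adc_class"),
        delta_pe_cut=delta_pe_cut,
        adc_cut=adc_cut,
        strategy=strategy,
    )


def cohort_summary(table: pd.DataFrame) -> dict[str, dict]:
    """Median/min/max per numeric column; level counts per categorical column."""
    if table.empty:
        raise ValueError("cohort table is empty")
    out: dict[str, dict] = {}
    for col in table.columns:
        s = table[col].dropna()
        if s.empty:
            continue
        if pd.api.types.is_numeric_dtype(s):
            out[col] = {
                "median": float(s.median()),
                "min": float(s.min()),
                "max": float(s.max()),
                "n": int(s.size),
            }
        else:
            out[col] = {"counts": s.value_counts().to_dict(), "n": int(s.size)}
    return out
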