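"""IHC H-scores, cutpoint optimization and relapse-free survival analysis.

The H-score summarizes immunohistochemical staining: each cell is graded at
optical-density level 0-3 and the score is sum(level x percent of cells at
that level), range 0-300.  A biomarker cutpoint dichotomizing patients into
high/low groups is chosen by exhaustive search over midpoints between
consecutive distinct scores, maximizing sensitivity + specificity for
recurrence (positive call: score >= cutpoint; high score = high risk, no
direction auto-flip).  Survival curves are Kaplan-Meier product-limit
estimates and groups are compared with the two-sample log-rank test (via
lifelines); event=False marks right-censoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

H_LEVELS = (0, 1, 2, 3)


@dataclass
class CutpointResult:
    cutpoint: float
    sensitivity: float
    specificity: float
    metric: float  # sensitivity + specificity


def h_score(intensity_pct) -> float:
    """H-score = sum over levels 1-3 of level x percentage, range 0-300.

    ``intensity_pct`` maps level -> percentage (or is a length-4 sequence
    for levels 0..3); percentages must sum to 100.
    """
    if isinstance(intensity_pct, dict):
        pct = np.array([float(intensity_pct.get(lv, 0.0)) for lv in H_LEVELS])
    else:
        pct = np.asarray(intensity_pct, dtype=float)
        if pct.shape != (4,):
            raise ValueError("expected percentages for levels 0..3")
    if np.any(pct < 0):
        raise ValueError("percentages must be non-negative")
    total = pct.sum()
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"percentages must sum to 100, got {total}")
    return float(np.dot(pct, H_LEVELS))


def h_scores(tma: pd.DataFrame) -> pd.Series:
    """Row-wise H-scores from pct_l0..pct_l3 columns of a TMA table."""
    cols = [f"pct_l{lv}" for lv in H_LEVELS]
    return tma[cols].apply(lambda row: h_score(row.to_numpy()), axis=1).rename("h_score")


def optimal_cutpoint(scores, outcome) -> CutpointResult:
    """Cutpoint maximizing sensitivity + specificity for a binary outcome.

    Candidates are midpoints between consecutive distinct sorted scores; a
    patient is called positive when score >= cutpoint; sensitivity is with
    respect to ``outcome`` (recurrence).  Ties between candidates are broken
    toward the smallest cutpoint.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if outcome.all() or not outcome.any():
        raise ValueError("cutpoint undefined: only one outcome class present")
    distinct = np.unique(scores)
    if len(distinct) < 2:
        raise ValueError("cutpoint undefined: all scores identical")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    n_pos = outcome.sum()
    n_neg = (~outcome).sum()
    best = None
    for c in candidates:
        called = scores >= c
        sens = (called & outcome).sum() / n_pos
        spec = (~called & ~outcome).sum() / n_neg
        metric = sens + spec
        if best is None or metric > best.metric + 1e-12:
            best = CutpointResult(float(c), float(sens), float(spec), float(metric))
    return best


def km_logrank(time, event, group) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    ``group`` is boolean (True = biomarker-high).  Returns
    (curves, chi2, p); curves maps 'high'/'low' to a survival-function
    table.  With no events in either group the test is undefined and
    (chi2=0, p=1) is returned.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any():
        raise ValueError("both groups must be non-empty")

    curves = {}
    for name, mask in (("high", group), ("low", ~group)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask], label=name)
        curves[name] = kmf.survival_function_

    if not event.any():
        return curves, 0.0, 1.0

    res = logrank_test(time[group], time[~group], event[group], event[~group])
    return curves, float(res.test_statistic), float(res.p_value)


def biomarker_analysis(tma: pd.DataFrame) -> dict:
    """Cutpoint + survival pipeline on a TMA table.

    Expects columns pct_l0..pct_l3 (or h_score), recurrence, time_months,
    event.  Returns the cutpoint result, the high/low dichotomization and
    the log-rank comparison.
    """
    hs = tma["h_score"] if "h_score" in tma else h_scores(tma)
    cut = optimal_cutpoint(hs.to_numpy(), tma["recurrence"].to_numpy())
    high = hs.to_numpy() >= cut.cutpoint
    curves, chi2, p = km_logrank(
        tma["time_months"].to_numpy(), tma["event"].to_numpy(), high
    )
    return {
        "cutpoint": cut,
        "high": pd.Series(high, index=tma.index, name="biomarker_high"),
        "km_curves": curves,
        "logrank_chi2": chi2,
        "logrank_p": p,
    }
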