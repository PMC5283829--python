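"""Area-normalized strain occurrence by flow class and the replicate tests.

For each strain and flow class (open/blocked) the occurrence frequency is
the effective area of occupied regions in that class divided by the total
effective area of the class — i.e. normalized to the total area of blocked
versus open flow.  Replicate-level frequencies are compared between classes
with a pooled-variance two-sample t-test, with Bonferroni correction over
the per-strain comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TTestResult",
    "occurrence_by_flow_class",
    "pooled_two_sample_t",
    "bonferroni",
    "cooccurrence_report",
]

STRAINS = ("wt", "mutant")
FLOW_CLASSES = ("blocked", "open")


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance two-sample t-test outcome."""

    t: float
    df: int
    p: float
    significant: bool | None = None
    infinite: bool = False

    def with_significance(self, flag: bool) -> "TTestResult":
        return TTestResult(self.t, self.df, self.p, flag, self.infinite)


def occurrence_by_flow_class(
    calls: pd.DataFrame,
    areas: np.ndarray | None = None,
    mode: str = "area",
    replicate: str | int = 0,
) -> pd.DataFrame:
    """Per-strain, per-flow-class occurrence frequencies for one replicate.

    ``calls`` needs boolean columns ``wt_call`` and ``mut_call`` and a
    ``flow`` column of "open"/"blocked"; region areas come from an
    ``area_um2`` column or the ``areas`` argument.  ``mode="area"``
    (default) weights regions by effective area; ``mode="count"`` treats
    all regions equally (sensitivity-analysis variant).  A class with zero
    total area yields NaN frequency (flagged, excluded from tests).
    """
    if mode not in ("area", "count"):
        raise ValueError(f"unknown occurrence mode: {mode!r}")
    if areas is None:
        if "area_um2" not in calls.columns:
            raise ValueError("region areas required: pass `areas` or an area_um2 column")
        areas = calls["area_um2"].to_numpy(dtype=float)
    else:
        areas = np.asarray(areas, dtype=float)
    if len(areas) != len(calls):
        raise ValueError("areas length does not match calls")
    if mode == "count":
        areas = np.ones_like(areas)
    flow = calls["flow"].to_numpy()
    rows = []
    for strain, col in zip(STRAINS, ("wt_call", "mut_call")):
        occ = calls[col].to_numpy(dtype=bool)
        for cls in FLOW_CLASSES:
            in_cls = flow == cls
            total = areas[in_cls].sum()
            occupied = areas[in_cls & occ].sum()
            rows.append(
                {
                    "replicate": replicate,
                    "strain": strain,
                    "flow_class": cls,
                    "area_occupied_um2": occupied,
                    "area_total_um2": total,
                    "frequency": occupied / total if total > 0 else math.nan,
                }
            )
    return pd.DataFrame(rows)


def pooled_two_sample_t(x, y) -> TTestResult:
    """Two-tailed pooled-variance t-test; df = n1 + n2 - 2.

    Degenerate samples (zero pooled variance) return t=0, p=1 when the
    means agree and an infinite-t flag when they do not.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    df = len(x) + len(y) - 2
    sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
    if sp2 == 0.0:
        if x.mean() == y.mean():
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(
            t=math.copysign(math.inf, x.mean() - y.mean()), df=df, p=0.0, infinite=True
        )
    res = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni significance flags: p_i < alpha / m over m comparisons."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return p < alpha / p.size


def cooccurrence_report(summaries: list[pd.DataFrame], alpha: float = 0.05) -> dict:
    """Blocked-vs-open tests per strain across replicate summaries.

    For each strain, the replicate-level blocked and open frequencies are
    compared with a pooled two-sample t-test; the two p-values are
    Bonferroni-corrected jointly.  Replicates with an undefined (NaN)
    frequency in a class are dropped from that strain's test.
    """
    table = pd.concat(summaries, ignore_index=True)
    tests: dict[str, TTestResult] = {}
    for strain in STRAINS:
        sub = table[table["strain"] == strain]
        wide = sub.pivot(index="replicate", columns="flow_class", values="frequency").dropna()
        if len(wide) < 2:
            raise ValueError(f"need >= 2 complete replicates for strain {strain!r}")
        tests[strain] = pooled_two_sample_t(wide["blocked"], wide["open"])
    flags = bonferroni([tests[s].p for s in STRAINS], alpha=alpha)
    tests = {s: tests[s].with_significance(bool(f)) for s, f in zip(STRAINS, flags)}
    return {
        "alpha": alpha,
        "n_comparisons": len(STRAINS),
        "tests": {
            s: {
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "significant": r.significant,
                "mean_blocked": float(
                    table.query("strain == @s and flow_class == 'blocked'")["frequency"].mean()
                ),
                "mean_open": float(
                    table.query("strain == @s and flow_class == 'open'")["frequency"].mean()
                ),
            }
            for s, r in tests.items()
        },
    }
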