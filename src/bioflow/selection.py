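"""Frequency-dependent selection analysis of competition outcomes.

A competition replicate records the wild-type frequency at inoculation (f0)
and after 72 h (f72); the change Δf = f72 − f0 as a function of f0
characterizes the selection regime.  The selection function is modelled as

    Δf(f0) = f0 (1 − f0) (b0 + b1 f0),

a cubic whose basis functions {f0(1−f0), f0²(1−f0)} vanish at fixation
(Δf → 0 as f0 → 0 or 1, since an absent or fixed strain cannot change
frequency).  A positive-to-negative interior zero crossing of the fitted
curve is the estimated critical frequency f_c: below it the wild type is
favoured, above it the matrix-deficient mutant is favoured, the signature
of negative frequency-dependent selection and stable coexistence.

The module also provides the maximum-slope growth-rate estimator for OD600
curves and effluent frequency bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .synth import CompetitionRecord

__all__ = [
    "InsufficientDataError",
    "SelectionFunctionModel",
    "SelectionFunctionResults",
    "frequency_change",
    "fit_selection_function",
    "max_growth_rate",
    "effluent_frequency",
]

_GRID = np.linspace(1e-3, 1.0 - 1e-3, 999)
_SIGN_TOL = 1e-12


class InsufficientDataError(ValueError):
    """Too few records, or too narrow an f0 span, to fit the selection function."""


def frequency_change(records) -> pd.DataFrame:
    """Tabulate records as (condition, f0, f72, delta_f), validating bounds."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [{"condition": r.condition, "f0": r.f0, "f72": r.f72} for r in records]
        )
    if "condition" not in df.columns:
        df["condition"] = "unspecified"
    f0 = df["f0"].to_numpy(dtype=float)
    f72 = df["f72"].to_numpy(dtype=float)
    if np.any((f0 <= 0.0) | (f0 >= 1.0)):
        raise ValueError("initial frequency f0 must lie strictly in (0, 1)")
    if np.any((f72 < 0.0) | (f72 > 1.0)):
        raise ValueError("final frequency f72 must lie in [0, 1]")
    df["delta_f"] = f72 - f0
    return df


def _design(f0: np.ndarray) -> np.ndarray:
    return np.column_stack([f0 * (1.0 - f0), f0**2 * (1.0 - f0)])


def _classify(coef: np.ndarray) -> tuple[str, float | None]:
    """Regime from the sign pattern of the fitted Δf on an interior grid.

    On (0, 1) the factor f0(1-f0) is strictly positive, so the sign of the
    fitted Δf equals the sign of the linear factor b0 + b1*f0; the interior
    zero is bracketed on the grid and located by bisection.
    """
    b0, b1 = float(coef[0]), float(coef[1])
    h = b0 + b1 * _GRID
    pos = h > _SIGN_TOL
    neg = h < -_SIGN_TOL
    if not neg.any() and pos.any():
        return "uniform_positive", None
    if not pos.any() and neg.any():
        return "uniform_negative", None
    if not pos.any() and not neg.any():
        return "none", None
    sign = np.sign(h)
    changes = np.flatnonzero(np.diff(sign) != 0)
    for i in changes:
        if sign[i] > 0 and sign[i + 1] <= 0:
            f_c = optimize.bisect(
                lambda f: b0 + b1 * f, _GRID[i], _GRID[i + 1], xtol=1e-10
            )
            return "negative_freq_dependent", float(f_c)
    return "none", None


@dataclass
class SelectionFunctionResults:
    """Fit results: coefficients, regime call, f_c estimate and bootstrap CI."""

    model: "SelectionFunctionModel"
    params: np.ndarray  # (b0, b1)
    regime: str
    f_c_hat: float | None
    f_c_ci: tuple[float, float] | None
    n_boot: int
    resid_std: float

    def predict(self, f0) -> np.ndarray:
        return _design(np.asarray(f0, dtype=float)) @ self.params

    def summary(self) -> str:
        lines = [
            "Selection function fit: Δf(f0) = f0(1−f0)(b0 + b1·f0)",
            "=" * 56,
            f"records                 {self.model.nobs}",
            f"b0                      {self.params[0]: .4f}",
            f"b1                      {self.params[1]: .4f}",
            f"residual std            {self.resid_std: .4f}",
            f"regime                  {self.regime}",
        ]
        if self.f_c_hat is not None:
            lines.append(f"critical frequency f_c  {self.f_c_hat: .3f}")
            if self.f_c_ci is not None:
                lines.append(
                    f"bootstrap 95% CI        ({self.f_c_ci[0]:.3f}, {self.f_c_ci[1]:.3f})"
                    f"  [{self.n_boot} resamples]"
                )
        else:
            lines.append("critical frequency f_c  none (no interior crossing)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_records": int(self.model.nobs),
            "coefficients": {"b0": float(self.params[0]), "b1": float(self.params[1])},
            "regime": self.regime,
            "f_c_hat": self.f_c_hat,
            "f_c_ci95": list(self.f_c_ci) if self.f_c_ci else None,
            "n_boot": self.n_boot,
            "resid_std": self.resid_std,
        }


class SelectionFunctionModel:
    """Least-squares model of Δf versus initial frequency.

    Build from arrays, records, or a DataFrame; ``fit`` estimates the
    coefficients, classifies the regime, locates the critical frequency by
    bisection, and attaches a percentile bootstrap CI over records.
    """

    def __init__(self, f0, delta_f):
        f0 = np.asarray(f0, dtype=float)
        delta_f = np.asarray(delta_f, dtype=float)
        if f0.shape != delta_f.shape or f0.ndim != 1:
            raise ValueError("f0 and delta_f must be matching 1D arrays")
        if len(f0) < 8:
            raise InsufficientDataError("need at least 8 competition records")
        if f0.max() - f0.min() < 0.5:
            raise InsufficientDataError(
                "initial frequencies must span a range of at least 0.5"
            )
        self.f0 = f0
        self.delta_f = delta_f

    @classmethod
    def from_records(cls, records) -> "SelectionFunctionModel":
        df = frequency_change(records)
        return cls(df["f0"].to_numpy(), df["delta_f"].to_numpy())

    from_dataframe = from_records

    @property
    def nobs(self) -> int:
        return len(self.f0)

    def _lstsq(self, f0: np.ndarray, dfreq: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(_design(f0), dfreq, rcond=None)
        return coef

    def fit(self, n_boot: int = 1000, seed: int | None = None) -> SelectionFunctionResults:
        coef = self._lstsq(self.f0, self.delta_f)
        regime, f_c = _classify(coef)
        resid = self.delta_f - _design(self.f0) @ coef
        ci = None
        if f_c is not None and n_boot > 0:
            rng = np.random.default_rng(seed)
            boots = []
            n = self.nobs
            for _ in range(n_boot):
                idx = rng.integers(n, size=n)
                _, fb = _classify(self._lstsq(self.f0[idx], self.delta_f[idx]))
                if fb is not None:
                    boots.append(fb)
            if len(boots) >= max(10, n_boot // 10):
                lo, hi = np.percentile(boots, [2.5, 97.5])
                ci = (float(lo), float(hi))
        return SelectionFunctionResults(
            model=self,
            params=coef,
            regime=regime,
            f_c_hat=f_c,
            f_c_ci=ci,
            n_boot=n_boot,
            resid_std=float(resid.std(ddof=2)) if self.nobs > 2 else float("nan"),
        )


def fit_selection_function(
    records, n_boot: int = 1000, seed: int | None = None
) -> SelectionFunctionResults:
    """Convenience wrapper: records -> fitted :class:`SelectionFunctionResults`."""
    return SelectionFunctionModel.from_records(records).fit(n_boot=n_boot, seed=seed)


def max_growth_rate(t, od, window: int = 5) -> float:
    """Maximum slope of a growth curve over sliding windows of ``window`` points.

    The slope of each contiguous window is the least-squares regression
    slope of OD on time; the maximum over windows estimates the peak growth
    rate in OD per unit time (per hour if ``t`` is in hours).
    """
    t = np.asarray(t, dtype=float)
    od = np.asarray(od, dtype=float)
    if t.shape != od.shape or t.ndim != 1:
        raise ValueError("t and od must be matching 1D arrays")
    if window < 2:
        raise ValueError("window must span at least 2 points")
    if len(t) < window:
        raise ValueError(f"need at least {window} points, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    n = len(t)
    best = -np.inf
    for i in range(n - window + 1):
        tw = t[i : i + window]
        yw = od[i : i + window]
        tc = tw - tw.mean()
        denom = (tc**2).sum()
        slope = (tc * (yw - yw.mean())).sum() / denom
        best = max(best, slope)
    return float(best)


def effluent_frequency(wt_count: int, mut_count: int) -> float:
    """Wild-type frequency among counted effluent colonies."""
    if wt_count < 0 or mut_count < 0:
        raise ValueError("counts must be non-negative")
    total = wt_count + mut_count
    if total == 0:
        raise ValueError("undefined frequency: both counts are zero")
    return wt_count / total
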