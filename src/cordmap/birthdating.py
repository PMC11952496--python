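"""Cumulative EdU birthdating: litter averaging, cumulative curves and
sigmoid half-birthdate estimation.

The experimental design delivers one EdU pulse per litter at a known
embryonic day; a neuron born at or after the pulse retains the label.  Per
embryo, the co-labeled fraction of each family's neurons is computed; the
unweighted mean across embryos of a litter is one data point (litter-level
variance dominates embryo-level variance).  Per-timepoint litter means are
normalized so they sum to 100% across timepoints ("percent born at t"), and
the running sum of prior-timepoint means is added to each litter's
normalized value so that within-timepoint variation is preserved while the
mean cumulative co-labeling at the final timepoint is exactly 100%.

A four-parameter logistic (4PL, "X is concentration" form)

    Y = Bottom + (Top - Bottom) / (1 + (EC50 / X)^HillSlope)

is fitted to the litter-level cumulative points; its EC50 is the family's
half-birthdate.  Families with a negligible slow-growth phase (substantial
neurogenesis before the first pulse) are fitted with the asymmetric
five-parameter logistic (5PL)

    Y = Bottom + (Top - Bottom) / (1 + (Xb / X)^HillSlope)^S

whose half-birthdate is the x where the curve crosses (Bottom + Top) / 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Sigmoid fit failed to converge after multi-start."""


def colabel_fraction(n_colabeled: int, n_total: int) -> float:
    """Co-labeled neurons as a fraction of all neurons of the family."""
    if n_total <= 0:
        raise ValueError("n_total must be positive; embryo should be excluded upstream")
    if not (0 <= n_colabeled <= n_total):
        raise ValueError("require 0 <= n_colabeled <= n_total")
    return n_colabeled / n_total


def litter_points(panel: pd.DataFrame) -> pd.DataFrame:
    """Collapse an embryo-level pulse panel to litter-level mean fractions.

    One record per (family, pulse_day, litter); embryos with ``n_total`` = 0
    are dropped with a warning.
    """
    panel = panel.copy()
    zero = panel["n_total"] <= 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} embryo records with n_total=0", stacklevel=2
        )
        panel = panel[~zero]
    panel["fraction"] = panel["n_colabeled"] / panel["n_total"]
    out = (
        panel.groupby(["family", "pulse_day", "litter"], as_index=False)["fraction"]
        .mean()
    )
    return out


def birth_wave_percentages(litter_table: pd.DataFrame, family: str) -> pd.Series:
    """Percent of the family born at each pulse day.

    ``p_t = 100 * m_t / sum_s m_s`` with ``m_t`` the mean litter fraction at
    pulse day t; sums to 100 across timepoints.
    """
    sub = litter_table[litter_table["family"] == family]
    if sub["pulse_day"].nunique() < 2:
        raise ValueError("need at least two pulse days with data")
    means = sub.groupby("pulse_day")["fraction"].mean().sort_index()
    total = means.sum()
    if total <= 0:
        raise ValueError(f"all-zero co-labeling means for family {family!r}")
    return 100.0 * means / total


@dataclass(frozen=True)
class CumulativeCurve:
    """Per-family cumulative birth percentages across pulse days."""

    family: str
    pulse_days: np.ndarray
    litter_values: pd.DataFrame = field(repr=False)  # litter, pulse_day, cumulative_pct
    means: np.ndarray
    sds: np.ndarray
    percentages: np.ndarray  # percent born per pulse day

    @property
    def points(self) -> Tuple[np.ndarray, np.ndarray]:
        """All litter-level (x, y) points used for sigmoid fitting."""
        return (
            self.litter_values["pulse_day"].to_numpy(dtype=float),
            self.litter_values["cumulative_pct"].to_numpy(dtype=float),
        )


def cumulative_curve(litter_table: pd.DataFrame, family: str) -> CumulativeCurve:
    """Build a family's cumulative curve from litter-level fractions.

    Each litter's value at t is its normalized percentage plus the sum of the
    *mean* percentages of all prior timepoints, so per-timepoint spread is the
    spread of that timepoint's litters only and the final-timepoint mean is
    exactly 100.
    """
    p = birth_wave_percentages(litter_table, family)
    sub = litter_table[litter_table["family"] == family].copy()
    means = sub.groupby("pulse_day")["fraction"].mean().sort_index()
    total = means.sum()
    prior = p.cumsum().shift(fill_value=0.0)  # sum of p_s for s < t
    sub["cumulative_pct"] = (
        100.0 * sub["fraction"] / total
        + sub["pulse_day"].map(prior).to_numpy()
    )
    days = np.asarray(sorted(sub["pulse_day"].unique()), dtype=float)
    stats = sub.groupby("pulse_day")["cumulative_pct"].agg(["mean", "std"]).sort_index()
    return CumulativeCurve(
        family=family,
        pulse_days=days,
        litter_values=sub[["litter", "pulse_day", "cumulative_pct"]].reset_index(drop=True),
        means=stats["mean"].to_numpy(),
        sds=stats["std"].fillna(0.0).to_numpy(),
        percentages=p.to_numpy(),
    )


# ---------------------------------------------------------------------------
# sigmoid models


def logistic_4pl(x: np.ndarray, bottom: float, top: float, ec50: float, hill: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


def logistic_5pl(
    x: np.ndarray, bottom: float, top: float, xb: float, hill: float, s: float
) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (xb / x) ** hill) ** s


@dataclass(frozen=True)
class SigmoidFitResults:
    """Fitted sigmoid parameters, uncertainties and the half-birthdate.

    ``params`` holds Bottom/Top/EC50 (or Xb)/HillSlope (and S for the 5PL);
    ``bse`` the corresponding asymptotic standard errors from the least-
    squares covariance, ``half_birthdate`` the embryonic day at which the
    fitted curve crosses the midpoint of its span.
    """

    family: str
    model: str  # "4pl" | "5pl"
    params: Dict[str, float]
    bse: Dict[str, float]
    rss: float
    half_birthdate: float
    n_points: int
    degenerate: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        if self.model == "4pl":
            return logistic_4pl(x, p["Bottom"], p["Top"], p["EC50"], p["HillSlope"])
        return logistic_5pl(x, p["Bottom"], p["Top"], p["Xb"], p["HillSlope"], p["S"])

    def summary(self) -> str:
        lines = [
            f"Sigmoid fit ({self.model.upper()}) — family {self.family}",
            f"  points: {self.n_points}   RSS: {self.rss:.4g}"
            + ("   [degenerate]" if self.degenerate else ""),
            f"  half-birthdate: E{self.half_birthdate:.3f}",
        ]
        for k, v in self.params.items():
            se = self.bse.get(k, float("nan"))
            lines.append(f"  {k:>10s} = {v:10.4f}  (se {se:.4f})")
        return "\n".join(lines)


def _multistart_fit(func, x, y, p0, bounds, seed=0, n_starts=5):
    rng = np.random.default_rng(seed)
    lo, hi = np.asarray(bounds[0], dtype=float), np.asarray(bounds[1], dtype=float)
    best = None
    errors = []
    starts = [np.asarray(p0, dtype=float)]
    for _ in range(n_starts - 1):
        jitter = np.asarray(p0) * (1 + rng.uniform(-0.2, 0.2, size=len(p0)))
        starts.append(np.clip(jitter, lo, hi))
    for start in starts:
        try:
            popt, pcov = optimize.curve_fit(
                func, x, y, p0=start, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            errors.append(str(exc))
            continue
        rss = float(np.sum((func(x, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitError(f"sigmoid fit failed after {n_starts} starts: {errors}")
    return best


def fit_4pl(curve: CumulativeCurve, seed: int = 0) -> SigmoidFitResults:
    """Least-squares 4PL fit to all litter-level cumulative points.

    Initialization Bottom=0, Top=100, EC50=median pulse day, HillSlope=10;
    bounds Bottom [-10, 50], Top [50, 120], EC50 within the pulse range
    extended by half a day, HillSlope [0.5, 200].
    """
    x, y = curve.points
    if len(np.unique(x)) < 4:
        raise ValueError("4PL fit needs at least 4 distinct pulse days")
    x_min, x_max = float(x.min()), float(x.max())
    p0 = [0.0, 100.0, float(np.median(np.unique(x))), 10.0]
    bounds = ([-10.0, 50.0, x_min - 0.5, 0.5], [50.0, 120.0, x_max + 0.5, 200.0])
    popt, pcov, rss = _multistart_fit(logistic_4pl, x, y, p0, bounds, seed=seed)
    names = ["Bottom", "Top", "EC50", "HillSlope"]
    bse = np.sqrt(np.clip(np.diag(pcov), 0, None))
    degenerate = np.ptp(y) < 1e-9 or popt[2] <= x_min - 0.5 + 1e-6
    if degenerate:
        warnings.warn(
            f"degenerate 4PL fit for family {curve.family!r} "
            "(flat curve or EC50 pinned at lower bound)",
            stacklevel=2,
        )
    return SigmoidFitResults(
        family=curve.family,
        model="4pl",
        params=dict(zip(names, map(float, popt))),
        bse=dict(zip(names, map(float, bse))),
        rss=rss,
        half_birthdate=float(popt[2]),
        n_points=len(x),
        degenerate=bool(degenerate),
    )


def _half_crossing_5pl(bottom, top, xb, hill, s, x_lo, x_hi) -> float:
    """Numeric x where the 5PL crosses (Bottom+Top)/2."""
    target = (bottom + top) / 2.0

    def f(x):
        return logistic_5pl(x, bottom, top, xb, hill, s) - target

    lo, hi = x_lo, x_hi
    # widen the bracket if the crossing sits slightly outside the pulse range
    for _ in range(60):
        if f(lo) < 0 < f(hi):
            break
        lo, hi = max(lo * 0.9, 1e-6), hi * 1.1
    else:
        raise FitError("could not bracket the 5PL half-maximum crossing")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def fit_5pl(curve: CumulativeCurve, seed: int = 0) -> SigmoidFitResults:
    """Least-squares asymmetric 5PL fit; half-birthdate solved numerically."""
    x, y = curve.points
    if len(np.unique(x)) < 5:
        raise ValueError("5PL fit needs at least 5 distinct pulse days")
    x_min, x_max = float(x.min()), float(x.max())
    p0 = [0.0, 100.0, float(np.median(np.unique(x))), 10.0, 1.0]
    # Xb is the asymmetric inflection parameter, not the half-maximum point:
    # for strong asymmetry it can sit well below the pulse range, so its
    # bounds are wider than the 4PL EC50's; the half-birthdate itself is
    # still constrained to the extended pulse range by the crossing search.
    bounds = (
        [-10.0, 50.0, max(x_min - 4.0, 1e-3), 0.5, 0.05],
        [50.0, 120.0, x_max + 1.0, 200.0, 20.0],
    )
    popt, pcov, rss = _multistart_fit(logistic_5pl, x, y, p0, bounds, seed=seed)
    names = ["Bottom", "Top", "Xb", "HillSlope", "S"]
    bse = np.sqrt(np.clip(np.diag(pcov), 0, None))
    half = _half_crossing_5pl(*popt, x_min - 0.5, x_max + 0.5)
    return SigmoidFitResults(
        family=curve.family,
        model="5pl",
        params=dict(zip(names, map(float, popt))),
        bse=dict(zip(names, map(float, bse))),
        rss=rss,
        half_birthdate=half,
        n_points=len(x),
        degenerate=bool(np.ptp(y) < 1e-9),
    )


def _prefer_5pl(fit4: SigmoidFitResults, fit5: SigmoidFitResults, pulse_days: np.ndarray) -> bool:
    """Fall back to the 5PL when the 4PL shows a negligible slow-growth phase:
    its RSS exceeds the 5PL's by >20% and its EC50 sits within half an
    inter-pulse interval of the first pulse."""
    interval = float(np.median(np.diff(np.unique(pulse_days))))
    near_start = fit4.params["EC50"] <= float(pulse_days.min()) + 0.5 * interval
    worse = fit4.rss > 1.2 * fit5.rss
    return bool(worse and near_start)


class CumulativeBirthModel:
    """Cumulative birthdating model for one family's pulse panel.

    Parameters
    ----------
    panel : DataFrame
        Embryo-level records (litter, embryo, pulse_day, family,
        n_colabeled, n_total).
    family : str
        Family to model.

    ``fit()`` returns a :class:`SigmoidFitResults`; with ``model="auto"`` the
    4PL is used unless the 5PL fallback rule fires.
    """

    def __init__(self, panel: pd.DataFrame, family: str):
        self.family = family
        self.litter_table = litter_points(panel)
        if family not in set(self.litter_table["family"]):
            raise ValueError(f"family {family!r} absent from panel")
        self.curve = cumulative_curve(self.litter_table, family)

    @classmethod
    def from_counts(cls, path_or_df, family: str) -> "CumulativeBirthModel":
        if isinstance(path_or_df, pd.DataFrame):
            return cls(path_or_df, family)
        return cls(pd.read_csv(path_or_df), family)

    def fit(self, model: str = "auto", seed: int = 0) -> SigmoidFitResults:
        if model == "4pl":
            return fit_4pl(self.curve, seed=seed)
        if model == "5pl":
            return fit_5pl(self.curve, seed=seed)
        if model != "auto":
            raise ValueError("model must be 'auto', '4pl' or '5pl'")
        fit4 = fit_4pl(self.curve, seed=seed)
        if len(np.unique(self.curve.pulse_days)) < 5:
            return fit4
        try:
            fit5 = fit_5pl(self.curve, seed=seed)
        except FitError:
            return fit4
        if _prefer_5pl(fit4, fit5, self.curve.pulse_days):
            logger.info("family %s: 5PL fallback selected", self.family)
            return fit5
        return fit4


def half_birthdates(panel: pd.DataFrame, model: str = "auto", seed: int = 0) -> pd.DataFrame:
    """Half-birthdate table across all families of a panel.

    Families whose fit fails are reported with NaN and the error message;
    other families are unaffected.
    """
    rows = []
    for family in sorted(panel["family"].unique()):
        try:
            res = CumulativeBirthModel(panel, family).fit(model=model, seed=seed)
            rows.append(
                {
                    "family": family,
                    "model": res.model,
                    "half_birthdate": res.half_birthdate,
                    "rss": res.rss,
                    "degenerate": res.degenerate,
                    "error": "",
                }
            )
        except (FitError, ValueError) as exc:
            rows.append(
                {
                    "family": family,
                    "model": "",
                    "half_birthdate": float("nan"),
                    "rss": float("nan"),
                    "degenerate": True,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)
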