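"""First-order Aβ elimination kinetics from in vivo microdialysis fractions.

Hourly dialysate fractions are collected around a gamma-secretase-inhibitor
dose at t = 0 that shuts off Aβ production; the post-dose decline of the
interstitial-fluid concentration is first order, so log10(conc) falls
linearly with time. The fitted semi-log slope ``a`` gives the elimination
rate constant ``Ke = -ln(10) * a`` and the half-life ``T1/2 = ln(2) / Ke``.

A ``paper_constants`` flag swaps the full-precision constants ln(10) and
ln(2) for the rounded 2.3 and 0.693 commonly printed in pharmacokinetics
methods, for byte-level agreement with hand arithmetic done at that
precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import groupstats

__all__ = [
    "DialysateSeries",
    "EliminationFit",
    "baseline_mean",
    "fit_elimination",
    "compare_half_lives",
    "read_fraction_csv",
]

LN10 = math.log(10.0)
LN2 = math.log(2.0)


@dataclass
class DialysateSeries:
    """Hourly dialysate concentrations around an inhibitor dose at t = 0.

    ``t_h`` is hours relative to the dose (negative = baseline); fractions
    with ``t_h > 0`` are the post-drug decay points used for the fit. By
    convention the fraction collected during the dosing hour (t = 0) is not
    a decay point.
    """

    t_h: np.ndarray
    conc: np.ndarray
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.t_h.shape != self.conc.shape or self.t_h.ndim != 1:
            raise ValueError("t_h and conc must be 1-D arrays of equal length")
        if np.any(np.diff(self.t_h) <= 0):
            raise ValueError("fraction times must be strictly increasing")
        if not np.all(np.isfinite(self.conc)):
            raise ValueError("concentrations must be finite")

    @property
    def baseline(self) -> np.ndarray:
        return self.conc[self.t_h < 0]

    def post_drug(self, t0: float = 0.0):
        m = self.t_h > t0
        return self.t_h[m], self.conc[m]


@dataclass
class EliminationFit:
    """Semi-log decay fit: slope ``a`` (log10 units/h), Ke (/h), half-life (h)."""

    a_log10_per_h: float
    Ke_per_h: float
    half_life_h: float  # nan when the series does not decay
    r2: float
    n_points: int
    animal_id: str = ""
    paper_constants: bool = False
    flags: list = field(default_factory=list)

    @property
    def half_life_defined(self) -> bool:
        return math.isfinite(self.half_life_h)


def baseline_mean(series: DialysateSeries) -> float:
    """Arithmetic mean of the pre-dose (t < 0) fraction concentrations."""
    base = series.baseline
    if base.size == 0:
        raise ValueError("series has no baseline fractions (t < 0)")
    return float(base.mean())


def fit_elimination(
    series: DialysateSeries,
    *,
    t0: float = 0.0,
    paper_constants: bool = False,
) -> EliminationFit:
    """Fit the first-order elimination from the post-dose fractions.

    Ordinary least squares of log10(concentration) on time over fractions
    with ``t_h > t0``; the slope ``a`` is converted to ``Ke = -c10 * a`` and
    ``half_life = c2 / Ke`` with (c10, c2) = (ln 10, ln 2), or the rounded
    (2.3, 0.693) under ``paper_constants``.

    Raises on fewer than 2 post-dose points or any nonpositive post-dose
    concentration; a non-decaying series (a >= 0) is returned with the
    half-life marked undefined (NaN) and flagged.
    """
    t, c = series.post_drug(t0)
    if t.size < 2:
        raise ValueError("need at least 2 post-drug fractions to fit a slope")
    bad = np.nonzero(c <= 0)[0]
    if bad.size:
        raise ValueError(
            f"nonpositive concentration in post-drug fraction at t={t[bad[0]]:g} h "
            "cannot enter the semi-log fit"
        )
    res = stats.linregress(t, np.log10(c))
    a = float(res.slope)
    c10 = 2.3 if paper_constants else LN10
    c2 = 0.693 if paper_constants else LN2
    ke = -c10 * a
    flags = []
    if a >= 0:
        half = float("nan")
        flags.append("no-decay: slope >= 0, half-life undefined")
    else:
        half = c2 / ke
    r2 = float(res.rvalue**2) if np.ptp(np.log10(c)) > 0 else 1.0
    return EliminationFit(a, ke, half, r2, int(t.size),
                          animal_id=series.animal_id,
                          paper_constants=paper_constants, flags=flags)


def compare_half_lives(group_fits_a, group_fits_b, *, alpha_var: float = 0.05):
    """Compare per-animal half-lives between two groups.

    Half-lives are normalized to the mean of the reference group (the
    first), undefined half-lives are dropped with a warning, and the test
    is chosen by the study decision rule (:func:`groupstats.choose_test`).

    Returns a dict with the normalized values, group means, the chosen
    plan and the test result.
    """
    ha = _defined_half_lives(group_fits_a, "reference group")
    hb = _defined_half_lives(group_fits_b, "comparison group")
    if ha.size < 2 or hb.size < 2:
        raise ValueError("each group needs at least 2 animals with defined half-lives")
    ref_mean = ha.mean()
    na, nb = ha / ref_mean, hb / ref_mean
    plan, result = groupstats.run_comparison([na, nb], alpha_var=alpha_var)
    return {
        "normalized_a": na,
        "normalized_b": nb,
        "mean_a": float(na.mean()),
        "mean_b": float(nb.mean()),
        "plan": plan,
        "result": result,
    }


def read_fraction_csv(path) -> list[DialysateSeries]:
    """Read a fraction table (columns animal_id, t_h, conc) into series."""
    df = pd.read_csv(path)
    required = {"animal_id", "t_h", "conc"}
    if not required.issubset(df.columns):
        raise ValueError(f"fraction CSV must have columns {sorted(required)}")
    out = []
    for animal, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("t_h")
        out.append(DialysateSeries(sub["t_h"].to_numpy(), sub["conc"].to_numpy(),
                                   animal_id=str(animal)))
    return out


def _defined_half_lives(fits, label) -> np.ndarray:
    vals = []
    for f in fits:
        if f.half_life_defined:
            vals.append(f.half_life_h)
        else:
            warnings.warn(
                f"{label}: animal {f.animal_id or '?'} has undefined half-life; excluded",
                stacklevel=3,
            )
    return np.asarray(vals, dtype=float)
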