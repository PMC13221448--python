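"""HeLa standard-curve fitting and MS1-based peptide-amount estimation.

A dilution series of HeLa standards (by default 10-700 ng) relates the
summed MS1 precursor signal of a run to the injected peptide amount via
a quadratic polynomial in log10-log10 space. Clinical samples analyzed
at fixed volume are projected onto the inverse of this curve to obtain
the "MS-based quantity of matched peptides". The regression direction
is classical calibration: signal is modeled on amount (the controlled
variable of the series) and inverted on its monotone branch.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .errors import CalibrationError, InsufficientDataError, SampleLookupError

IN_RANGE = "in_range"
EXTRAPOLATED_LOW = "extrapolated_low"
EXTRAPOLATED_HIGH = "extrapolated_high"

_LINEAR_EPS = 1e-12  # |c2| below this -> treat the quadratic as a line


@dataclass(frozen=True)
class StandardCurveModel:
    """Quadratic calibration: log10(signal) = c0 + c1*x + c2*x^2, x = log10(ng)."""

    coefficients: tuple[float, float, float]
    calibration_range_ng: tuple[float, float] = (10.0, 700.0)
    fit_residual_sd: float = 0.0
    n_standards: int = 0

    def predict_log_signal(self, amount_ng: float | np.ndarray) -> np.ndarray:
        c0, c1, c2 = self.coefficients
        x = np.log10(np.asarray(amount_ng, dtype=float))
        return c0 + c1 * x + c2 * x**2

    def predict_signal(self, amount_ng: float | np.ndarray) -> np.ndarray:
        return np.power(10.0, self.predict_log_signal(amount_ng))

    def signal_span(self) -> tuple[float, float]:
        lo, hi = self.calibration_range_ng
        return float(self.predict_signal(lo)), float(self.predict_signal(hi))


def total_ms1_signal(precursors: pd.DataFrame, sample_id: str) -> float:
    """Summed MS1 area over a sample's detected precursor records."""
    sub = precursors.loc[precursors["sample_id"] == sample_id]
    if sub.empty:
        raise SampleLookupError(f"sample {sample_id!r} not present in precursor table")
    if "detected" in sub.columns:
        sub = sub.loc[sub["detected"].astype(bool)]
    return float(sub["ms1_area"].sum())


def total_ms1_by_sample(precursors: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`total_ms1_signal` for every sample in the table."""
    sub = precursors
    if "detected" in sub.columns:
        sub = sub.loc[sub["detected"].astype(bool)]
    return sub.groupby("sample_id", sort=True)["ms1_area"].sum()


def fit_standard_curve(standards: pd.DataFrame) -> StandardCurveModel:
    """Least-squares quadratic fit of log10(total_ms1) on log10(amount_ng).

    Requires >= 3 standards at distinct amounts with positive signal; the
    fitted curve must be strictly increasing over the calibration range
    (the span of the standards), otherwise the calibration is rejected.
    """
    amounts = np.asarray(standards["amount_ng"], dtype=float)
    signals = np.asarray(standards["total_ms1"], dtype=float)
    if np.unique(amounts).size < 3:
        raise InsufficientDataError("standard-curve fit needs >= 3 distinct amounts")
    if (amounts <= 0).any() or (signals <= 0).any():
        raise CalibrationError("standards must have positive amounts and signals")
    x, y = np.log10(amounts), np.log10(signals)
    c2, c1, c0 = np.polyfit(x, y, deg=2)
    rng = (float(amounts.min()), float(amounts.max()))
    # strict monotonicity of c1 + 2*c2*x over the calibration range
    xs = np.log10(rng)
    if min(c1 + 2 * c2 * xs[0], c1 + 2 * c2 * xs[1]) <= 0:
        raise CalibrationError(
            "fitted curve is not strictly increasing over the calibration range; "
            "add standards or narrow the range"
        )
    resid = y - (c0 + c1 * x + c2 * x**2)
    dof = max(x.size - 3, 1)
    return StandardCurveModel(
        coefficients=(float(c0), float(c1), float(c2)),
        calibration_range_ng=rng,
        fit_residual_sd=float(np.sqrt((resid**2).sum() / dof)),
        n_standards=int(x.size),
    )


def estimate_amount(model: StandardCurveModel, total_ms1: float) -> tuple[float, str]:
    """Invert the calibration curve at an observed summed-MS1 signal.

    Solves ``c2*x^2 + c1*x + (c0 - log10(signal)) = 0`` for
    ``x = log10(amount)``, keeping the root on the increasing branch that
    contains the calibration range. Returns the estimate in ng and a
    flag: ``in_range`` when the signal falls inside the signal span of
    the calibration range, otherwise ``extrapolated_low``/``_high``
    (extrapolated estimates are reported, never clamped).
    """
    if not total_ms1 > 0:
        raise CalibrationError("total_ms1 must be positive")
    c0, c1, c2 = model.coefficients
    target = np.log10(total_ms1)
    if abs(c2) < _LINEAR_EPS:
        if c1 == 0:
            raise CalibrationError("degenerate flat calibration curve")
        x = (target - c0) / c1
    else:
        disc = c1 * c1 - 4.0 * c2 * (c0 - target)
        if disc < 0:
            raise CalibrationError(
                "signal incompatible with calibration curve (no real root)"
            )
        sq = np.sqrt(disc)
        roots = ((-c1 - sq) / (2 * c2), (-c1 + sq) / (2 * c2))
        # increasing branch: derivative c1 + 2*c2*x > 0
        ok = [r for r in roots if c1 + 2 * c2 * r > 0]
        if not ok:
            raise CalibrationError(
                "signal incompatible with the increasing branch of the curve"
            )
        mid = np.mean(np.log10(model.calibration_range_ng))
        x = min(ok, key=lambda r: abs(r - mid))
    lo_sig, hi_sig = model.signal_span()
    rtol = 1e-9  # boundary standards count as in range
    if total_ms1 < lo_sig * (1 - rtol):
        flag = EXTRAPOLATED_LOW
    elif total_ms1 > hi_sig * (1 + rtol):
        flag = EXTRAPOLATED_HIGH
    else:
        flag = IN_RANGE
    return float(10.0**x), flag


def estimate_amounts(model: StandardCurveModel, totals: pd.Series) -> pd.DataFrame:
    """Apply :func:`estimate_amount` to a per-sample total-MS1 series."""
    rows = []
    for sid, sig in totals.items():
        est, flag = estimate_amount(model, float(sig))
        rows.append({"sample_id": sid, "total_ms1": float(sig), "estimate_ng": est, "flag": flag})
    return pd.DataFrame(rows)


INFEASIBLE = "infeasible"

#: minimum injection that still yields a usable run, ng
MIN_INJECTION_NG = 50.0
#: standard full-run loads per platform, ng
PLATFORM_LOAD_NG = {"astral": 50.0, "timstof": 200.0}


def plan_injection(
    estimate_ng_total: float, fraction_already_used: float, platform: str
) -> float | str:
    """Plan the full-run injection amount from the estimated total yield.

    Policy: the Astral runs a fixed 50 ng load; the timsTOF runs 200 ng
    when available, otherwise the remaining material — but never less
    than 50 ng. Returns the planned amount in ng, or ``"infeasible"``
    when the remaining material cannot support a 50 ng injection.
    """
    if estimate_ng_total <= 0:
        raise CalibrationError("estimate_ng_total must be positive")
    if not 0 <= fraction_already_used < 1:
        raise CalibrationError("fraction_already_used must be in [0, 1)")
    if platform not in PLATFORM_LOAD_NG:
        raise CalibrationError(f"unknown platform {platform!r}")
    remaining = estimate_ng_total * (1.0 - fraction_already_used)
    if remaining < MIN_INJECTION_NG:
        return INFEASIBLE
    return float(min(PLATFORM_LOAD_NG[platform], remaining))
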