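"""Ct-lg(N_DSBs) standard-curve fitting, quantification and validity gates.

The calibration model is the linear relation

    Ct = a + b * lg10(N_DSBs)

fitted by ordinary least squares with Ct as the response (measurement
error lives in Ct; the theoretical break numbers of the standards are
exact).  The slope is negative: a ten-fold increase in breaks advances
amplification by |b| cycles.  Amplification efficiency follows from the
slope as E = 10^(1/|b|) - 1; |b| = 1/lg10(2) ~ 3.32 means perfect
doubling per cycle (E = 100%).

An unknown sample's break number is the curve inverted at its mean Ct:

    N_DSBs = 10^((a - Ct) / |b|)

Curve validity gates: R^2 > 0.95, |b| within [3.0, 3.65] (efficiency
between ~88% and ~115%), and every no-template / no-ligase control
either Ct > 33 or no amplification at all.  The reportable range of the
method is 10 to 1e8 breaks; estimates outside it are flagged, not
rejected.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .standards import StandardPoint

__all__ = [
    "StandardCurve",
    "CtMeasurement",
    "QuantResult",
    "CurveValidity",
    "fit_standard_curve",
    "amplification_efficiency",
    "quantify_ct",
    "validate_curve",
    "read_ct_table",
    "ct_table_to_replicates",
    "write_quantification",
    "REPORTABLE_RANGE",
    "R_SQUARED_GATE",
    "SLOPE_GATE",
    "CONTROL_CT_GATE",
]

REPORTABLE_RANGE = (10.0, 1e8)
R_SQUARED_GATE = 0.95
SLOPE_GATE = (3.0, 3.65)
CONTROL_CT_GATE = 33.0


@dataclass(frozen=True)
class StandardCurve:
    """A fitted Ct = a + b*lgN calibration line (b < 0 in practice)."""

    organism: str
    intercept_a: float
    slope_b: float
    r_squared: float
    efficiency_percent: float
    n_points: int
    threshold_bp: int = 2000

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardCurve":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR replicate; ``ct=None`` encodes no amplification."""

    sample: str
    replicate: int
    ct: float | None

    def __post_init__(self) -> None:
        if self.ct is not None and not math.isfinite(self.ct):
            raise ValueError("ct must be finite or None")


@dataclass
class QuantResult:
    """Break-number estimate for one unknown sample."""

    sample: str
    ct_mean: float | None
    n_dsbs_estimate: float | None
    within_range: bool
    note: str = ""


def amplification_efficiency(slope_b: float) -> float:
    """Per-cycle amplification efficiency (percent) implied by the slope.

    E = 100 * (10^(1/|b|) - 1); strictly decreasing in |b|.
    """
    if slope_b == 0:
        raise ValueError("slope must be nonzero")
    return 100.0 * (10.0 ** (1.0 / abs(slope_b)) - 1.0)


def fit_standard_curve(
    points: Sequence[StandardPoint],
    organism: str = "",
    threshold_bp: int = 2000,
) -> StandardCurve:
    """Ordinary least squares of Ct on lg10(N_DSBs) over included points.

    R^2 is the squared Pearson correlation of Ct with lgN (identical to
    the OLS coefficient of determination for a simple linear fit).

    Raises
    ------
    ValueError
        With fewer than 3 included points, a non-positive break number,
        or zero variance in lgN (degenerate design).
    """
    used = [p for p in points if p.included]
    if len(used) < 3:
        raise ValueError(
            f"need at least 3 included standards, have {len(used)}"
        )
    if any(p.n_dsbs <= 0 for p in used):
        raise ValueError("included standards must have positive N_DSBs")
    lg_n = np.log10([p.n_dsbs for p in used])
    ct = np.array([p.ct for p in used], dtype=float)
    if np.ptp(lg_n) == 0:
        raise ValueError("degenerate design: zero variance in lgN")
    res = stats.linregress(lg_n, ct)
    return StandardCurve(
        organism=organism,
        intercept_a=float(res.intercept),
        slope_b=float(res.slope),
        r_squared=float(res.rvalue**2),
        efficiency_percent=amplification_efficiency(res.slope),
        n_points=len(used),
        threshold_bp=threshold_bp,
    )


def quantify_ct(
    curve: StandardCurve, measurements: Sequence[CtMeasurement]
) -> QuantResult:
    """Invert the calibration line at a sample's mean Ct.

    ``None`` replicates (no amplification) are dropped with a warning;
    if every replicate failed to amplify the result is flagged below
    detection instead of raising.
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    sample = measurements[0].sample
    numeric = [m.ct for m in measurements if m.ct is not None]
    n_none = len(measurements) - len(numeric)
    if not numeric:
        return QuantResult(
            sample=sample,
            ct_mean=None,
            n_dsbs_estimate=None,
            within_range=False,
            note="below detection, no amplification",
        )
    if n_none:
        warnings.warn(
            f"{sample}: dropped {n_none} non-amplifying replicate(s)",
            stacklevel=2,
        )
    ct_mean = float(np.mean(numeric))
    estimate = 10.0 ** ((curve.intercept_a - ct_mean) / abs(curve.slope_b))
    lo, hi = REPORTABLE_RANGE
    return QuantResult(
        sample=sample,
        ct_mean=ct_mean,
        n_dsbs_estimate=estimate,
        within_range=lo <= estimate <= hi,
    )


@dataclass
class CurveValidity:
    """Gate-by-gate validity report for a fitted curve."""

    r_squared_ok: bool
    slope_ok: bool
    controls_ok: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.r_squared_ok and self.slope_ok and self.controls_ok


def validate_curve(
    curve: StandardCurve,
    negative_controls: Sequence[CtMeasurement] = (),
    r_squared_gate: float = R_SQUARED_GATE,
    slope_gate: tuple[float, float] = SLOPE_GATE,
    control_ct_gate: float = CONTROL_CT_GATE,
) -> CurveValidity:
    """Check R^2, slope-band and negative-control gates.

    A negative control passes when it shows no amplification (``None``)
    or a Ct above the gate (default 33 cycles).
    """
    reasons: list[str] = []
    r2_ok = curve.r_squared > r_squared_gate
    if not r2_ok:
        reasons.append(
            f"R^2 {curve.r_squared:.4f} <= gate {r_squared_gate}"
        )
    lo, hi = slope_gate
    slope_ok = lo <= abs(curve.slope_b) <= hi
    if not slope_ok:
        reasons.append(
            f"slope out of range: |b| {abs(curve.slope_b):.3f} "
            f"outside [{lo}, {hi}]"
        )
    controls_ok = True
    for ctl in negative_controls:
        if ctl.ct is not None and ctl.ct <= control_ct_gate:
            controls_ok = False
            reasons.append(
                f"negative control amplified: {ctl.sample} "
                f"Ct {ctl.ct} <= {control_ct_gate}"
            )
    return CurveValidity(
        r_squared_ok=r2_ok,
        slope_ok=slope_ok,
        controls_ok=controls_ok,
        reasons=reasons,
    )


# ---------------------------------------------------------------------------
# Ct table I/O (CSV with columns sample, enzyme_or_condition, replicate, ct;
# the literal string "none" marks a replicate with no amplification)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct CSV, mapping the "none" sentinel to NaN."""
    df = pd.read_csv(path, dtype={"ct": str})
    required = {"sample", "enzyme_or_condition", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ct = df["ct"].str.strip().str.lower()
    df["ct"] = pd.to_numeric(ct.where(ct != "none"), errors="raise")
    return df


def ct_table_to_replicates(df: pd.DataFrame) -> dict[str, list[float]]:
    """Group numeric Ct replicates by enzyme/condition."""
    out: dict[str, list[float]] = {}
    for key, grp in df.groupby("enzyme_or_condition"):
        out[str(key)] = [float(v) for v in grp["ct"] if pd.notna(v)]
    return out


def measurements_from_table(df: pd.DataFrame) -> dict[str, list[CtMeasurement]]:
    """Per-sample measurement lists from a Ct table."""
    out: dict[str, list[CtMeasurement]] = {}
    for key, grp in df.groupby("sample"):
        out[str(key)] = [
            CtMeasurement(
                sample=str(key),
                replicate=int(row.replicate),
                ct=None if pd.isna(row.ct) else float(row.ct),
            )
            for row in grp.itertuples()
        ]
    return out


def write_quantification(
    results: Sequence[QuantResult], path: str | Path
) -> pd.DataFrame:
    """Write quantification TSV (sample, ct_mean, n_dsbs_estimate,
    within_range, note)."""
    df = pd.DataFrame(
        [
            {
                "sample": r.sample,
                "ct_mean": r.ct_mean,
                "n_dsbs_estimate": r.n_dsbs_estimate,
                "within_range": r.within_range,
                "note": r.note,
            }
            for r in results
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
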