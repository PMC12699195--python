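"""Assay quality control: replicate CVs and blank-based detection limit.

CVs are computed on the Ct scale, where replicate spread is roughly
constant; back-transforming to break numbers would inflate the spread
roughly eight-fold through the 10^(x/3.5) map.  The intra-assay CV is
the mean of per-group CVs over within-run replicates; the inter-assay CV
is the mean of per-condition CVs over across-run means.

The detection limit is a one-sided 95% limit of blank: the Ct below
which a measurement is distinguishable from blank noise is
mean(blank Ct) - 1.645*sd(blank Ct) (lower Ct means more template), and
the LOD in break numbers is the calibration curve inverted at that Ct.
"""

from __future__ import annotations

import json
import statistics
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .calibration import CtMeasurement, StandardCurve, quantify_ct

__all__ = [
    "QCReport",
    "coefficient_of_variation",
    "aggregate_cv",
    "detection_limit",
    "read_replicate_table",
    "qc_report",
]

_Z_ONE_SIDED_95 = 1.645


@dataclass
class QCReport:
    """Summary QC statistics for a run set."""

    intra_cv_percent: float
    inter_cv_percent: float
    lod_ndsbs: float | None = None
    blanks_n: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV in percent: 100 * sample sd / mean (n-1 denominator)."""
    if len(values) < 2:
        raise ValueError("need at least 2 values for a CV")
    mean = statistics.fmean(values)
    if mean == 0:
        raise ValueError("CV undefined at zero mean")
    return 100.0 * statistics.stdev(values) / mean


def aggregate_cv(
    groups: Mapping[str, Mapping[str, Sequence[float]]],
) -> tuple[float, float]:
    """Intra- and inter-assay CVs from condition -> run -> replicate Cts.

    intra = mean over (condition, run) groups of the within-run CV;
    inter = mean over conditions of the CV of per-run means.

    Raises
    ------
    ValueError
        On empty input or a within-run group with fewer than 2
        replicates.
    """
    if not groups:
        raise ValueError("no replicate groups supplied")
    intra_cvs: list[float] = []
    inter_cvs: list[float] = []
    for condition, runs in groups.items():
        if not runs:
            raise ValueError(f"condition {condition!r} has no runs")
        run_means = []
        for run, reps in runs.items():
            if len(reps) < 2:
                raise ValueError(
                    f"condition {condition!r} run {run!r} has fewer than "
                    "2 replicates"
                )
            intra_cvs.append(coefficient_of_variation(reps))
            run_means.append(statistics.fmean(reps))
        if len(run_means) >= 2:
            inter_cvs.append(coefficient_of_variation(run_means))
    intra = statistics.fmean(intra_cvs)
    inter = statistics.fmean(inter_cvs) if inter_cvs else float("nan")
    return intra, inter


def detection_limit(
    blank_cts: Sequence[float | None], curve: StandardCurve
) -> float:
    """Limit of detection in break numbers from repeated blanks.

    Non-amplifying blanks (``None``) are excluded with a warning; at
    least 3 numeric blanks are required.
    """
    numeric = [c for c in blank_cts if c is not None]
    if len(numeric) < len(blank_cts):
        warnings.warn(
            f"excluded {len(blank_cts) - len(numeric)} non-amplifying "
            "blank(s) from LOD",
            stacklevel=2,
        )
    if len(numeric) < 3:
        raise ValueError("need at least 3 numeric blank replicates")
    mean = statistics.fmean(numeric)
    sd = statistics.stdev(numeric)
    lod_ct = mean - _Z_ONE_SIDED_95 * sd
    result = quantify_ct(
        curve,
        [CtMeasurement(sample="blank-LOD", replicate=1, ct=lod_ct)],
    )
    assert result.n_dsbs_estimate is not None
    return result.n_dsbs_estimate


def read_replicate_table(path: str | Path) -> pd.DataFrame:
    """Read a replicates CSV (condition, run, replicate, ct)."""
    df = pd.read_csv(path)
    required = {"condition", "run", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"replicate table missing columns: {sorted(missing)}")
    return df


def qc_report(
    replicates: pd.DataFrame,
    blank_cts: Sequence[float | None] = (),
    curve: StandardCurve | None = None,
) -> QCReport:
    """Full QC report from a tidy replicate table and optional blanks."""
    groups: dict[str, dict[str, list[float]]] = {}
    for row in replicates.itertuples():
        groups.setdefault(str(row.condition), {}).setdefault(
            str(row.run), []
        ).append(float(row.ct))
    intra, inter = aggregate_cv(groups)
    lod = None
    numeric_blanks = [c for c in blank_cts if c is not None]
    if curve is not None and len(numeric_blanks) >= 3:
        lod = detection_limit(list(blank_cts), curve)
    return QCReport(
        intra_cv_percent=intra,
        inter_cv_percent=inter,
        lod_ndsbs=lod,
        blanks_n=len(numeric_blanks),
    )
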