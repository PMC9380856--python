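"""Subject-level morphometric indices of the lentiform nucleus (LN).

Two radiologists each measure both LN sides on the same slice, giving four
:class:`~lentimorph.morphometry.SideMeasurement` cells per subject plus a
per-rater CSF reference.  This module aggregates them into the indices used
for group comparison:

``SL, LL, SLLr, Area, SIm_LN, SIsd_LN, nSIm``
    plain indices — per rater the two sides are averaged, then the two
    raters are averaged.  ``SLLr`` averages the per-side ratios (each side's
    SL/LL first, then the mean), not the ratio of the averages.
``cSL, cSLLr``
    corrected short line: the side with the *smaller* rater-mean SL is
    selected; ``cSL`` is that minimum and ``cSLLr`` divides it by the
    rater-mean LL of the *same* side.  MSA-P narrows the posterior LN
    asymmetrically, so the smaller side carries the signal.
``cSIsd_LN``
    the side with the *larger* rater-mean intensity SD — iron deposition
    makes the affected side's signal inhomogeneous.
``nSIm``
    LN intensity normalized so the CSF mean maps to 200:
    ``200 * SIm_side / SIm_CSF`` per rater and side, then averaged.

Exact side ties are broken toward *left* and flagged; with continuous
measurements they have probability zero, but the pipeline must be
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .morphometry import CsfMeasurement, SideMeasurement

__all__ = [
    "RATERS",
    "SIDES",
    "INDEX_COLUMNS",
    "PER_RATER_INDEX_COLUMNS",
    "SubjectRecord",
    "SubjectIndices",
    "rater_side_means",
    "uncorrected_indices",
    "corrected_short_line",
    "corrected_ratio",
    "corrected_sisd",
    "normalize_intensity",
    "compute_subject_indices",
    "records_to_measurements_frame",
    "measurements_frame_to_records",
    "indices_table",
    "per_rater_table",
]

RATERS = (1, 2)
SIDES = ("left", "right")

#: Subject-level index columns, in the report's fixed order.
INDEX_COLUMNS = [
    "cSL", "SL", "LL", "cSLLr", "SLLr", "Area",
    "SIm_LN", "SIsd_LN", "cSIsd_LN", "SIm_CSF", "SIsd_CSF", "nSIm",
]

#: Per-rater side-mean columns retained for inter-rater agreement (ICC).
PER_RATER_INDEX_COLUMNS = ["SL", "LL", "SLLr", "Area", "SIm_LN", "SIsd_LN", "nSIm"]

#: Measurement-table columns, one row per (subject, rater, side).
MEASUREMENT_COLUMNS = [
    "subject_id", "group", "rater", "side",
    "LL_mm", "SL_mm", "area_mm2", "SIm", "SIsd", "SIm_CSF", "SIsd_CSF",
]


@dataclass
class SubjectRecord:
    """One subject's complete raw data: 2 raters x 2 sides plus CSF."""

    subject_id: str
    group_label: str
    measurements: Mapping[tuple[int, str], SideMeasurement]
    csf: Mapping[int, CsfMeasurement]
    truth: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        missing = [
            (r, s) for r in RATERS for s in SIDES if (r, s) not in self.measurements
        ]
        if missing:
            raise ValueError(
                f"subject {self.subject_id}: missing measurement cells {missing}"
            )
        missing_csf = [r for r in RATERS if r not in self.csf]
        if missing_csf:
            raise ValueError(
                f"subject {self.subject_id}: missing CSF cells for raters {missing_csf}"
            )


@dataclass(frozen=True)
class SubjectIndices:
    """All derived indices for one subject (field names follow the
    group-comparison table; lengths mm, areas mm**2, intensities in scanner
    signal units, ``nSIm`` on the CSF=200 scale)."""

    subject_id: str
    group: str
    cSL: float
    SL: float
    LL: float
    cSLLr: float
    SLLr: float
    Area: float
    SIm_LN: float
    SIsd_LN: float
    cSIsd_LN: float
    SIm_CSF: float
    SIsd_CSF: float
    nSIm: float
    csl_side: str
    csisd_side: str
    csl_tie: bool = False
    csisd_tie: bool = False


def rater_side_means(record: SubjectRecord) -> dict[str, SideMeasurement]:
    """Per-side mean over the two raters, field by field."""
    out: dict[str, SideMeasurement] = {}
    for side in SIDES:
        cells = [record.measurements[(r, side)] for r in RATERS]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # SL>LL warnings re-checked downstream
            out[side] = SideMeasurement(
                ll=float(np.mean([c.ll for c in cells])),
                sl=float(np.mean([c.sl for c in cells])),
                area=float(np.mean([c.area for c in cells])),
                si_mean=float(np.mean([c.si_mean for c in cells])),
                si_sd=float(np.mean([c.si_sd for c in cells])),
            )
    return out


def _rater_side_mean(record: SubjectRecord, attr: str) -> float:
    """Mean over sides within each rater, then over raters."""
    per_rater = [
        np.mean([getattr(record.measurements[(r, s)], attr) for s in SIDES])
        for r in RATERS
    ]
    return float(np.mean(per_rater))


def uncorrected_indices(record: SubjectRecord) -> dict[str, float]:
    """The plain (both-sides mean) indices SL, LL, SLLr, Area, SIm_LN, SIsd_LN."""
    return {
        "SL": _rater_side_mean(record, "sl"),
        "LL": _rater_side_mean(record, "ll"),
        "SLLr": _rater_side_mean(record, "sllr"),
        "Area": _rater_side_mean(record, "area"),
        "SIm_LN": _rater_side_mean(record, "si_mean"),
        "SIsd_LN": _rater_side_mean(record, "si_sd"),
    }


def _argmin_side(values: dict[str, float]) -> tuple[str, bool]:
    tie = values["left"] == values["right"]
    side = "left" if values["left"] <= values["right"] else "right"
    return side, tie


def corrected_short_line(record: SubjectRecord) -> tuple[float, str, bool]:
    """cSL: the smaller rater-mean SL of the two sides.

    Returns ``(cSL, side, tie_flag)``; ties go to the left side.
    """
    means = rater_side_means(record)
    sls = {s: means[s].sl for s in SIDES}
    side, tie = _argmin_side(sls)
    return sls[side], side, tie


def corrected_ratio(record: SubjectRecord) -> float:
    """cSLLr: cSL divided by the rater-mean LL of the same (smaller-SL) side."""
    means = rater_side_means(record)
    csl, side, _ = corrected_short_line(record)
    ll = means[side].ll
    if ll == 0:
        raise ZeroDivisionError(f"subject {record.subject_id}: zero LL on {side}")
    return csl / ll


def corrected_sisd(record: SubjectRecord) -> tuple[float, str, bool]:
    """cSIsd_LN: the larger rater-mean intensity SD of the two sides."""
    means = rater_side_means(record)
    sds = {s: means[s].si_sd for s in SIDES}
    tie = sds["left"] == sds["right"]
    side = "left" if sds["left"] >= sds["right"] else "right"
    return sds[side], side, tie


def normalize_intensity(si_mean_side: float, si_mean_csf: float) -> float:
    """Normalize an LN intensity to the CSF=200 scale: ``200 * SIm / SIm_CSF``."""
    if not si_mean_csf > 0:
        raise ValueError(f"SIm_CSF must be > 0, got {si_mean_csf}")
    return 200.0 * si_mean_side / si_mean_csf


def compute_subject_indices(record: SubjectRecord) -> SubjectIndices:
    """All subject-level indices for one complete record."""
    plain = uncorrected_indices(record)
    csl, csl_side, csl_tie = corrected_short_line(record)
    csllr = corrected_ratio(record)
    csisd, csisd_side, csisd_tie = corrected_sisd(record)
    # nSIm: per rater, each side normalized by that rater's CSF mean
    nsim_per_rater = [
        np.mean(
            [
                normalize_intensity(
                    record.measurements[(r, s)].si_mean, record.csf[r].si_mean
                )
                for s in SIDES
            ]
        )
        for r in RATERS
    ]
    if not 0 < csllr <= 1:
        warnings.warn(
            f"subject {record.subject_id}: cSLLr = {csllr:.3g} outside (0, 1]",
            stacklevel=2,
        )
    return SubjectIndices(
        subject_id=record.subject_id,
        group=record.group_label,
        cSL=csl,
        cSLLr=csllr,
        cSIsd_LN=csisd,
        SIm_CSF=float(np.mean([record.csf[r].si_mean for r in RATERS])),
        SIsd_CSF=float(np.mean([record.csf[r].si_sd for r in RATERS])),
        nSIm=float(np.mean(nsim_per_rater)),
        csl_side=csl_side,
        csisd_side=csisd_side,
        csl_tie=csl_tie,
        csisd_tie=csisd_tie,
        **plain,
    )


# ---------------------------------------------------------------------------
# tabular interchange


def records_to_measurements_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Long measurement table, one row per (subject, rater, side)."""
    rows = []
    for rec in records:
        for r in RATERS:
            for s in SIDES:
                m = rec.measurements[(r, s)]
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "group": rec.group_label,
                        "rater": r,
                        "side": s,
                        "LL_mm": m.ll,
                        "SL_mm": m.sl,
                        "area_mm2": m.area,
                        "SIm": m.si_mean,
                        "SIsd": m.si_sd,
                        "SIm_CSF": rec.csf[r].si_mean,
                        "SIsd_CSF": rec.csf[r].si_sd,
                    }
                )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def measurements_frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    """Rebuild subject records from a long measurement table.

    Partial records (a missing rater/side cell) are rejected, not imputed.
    """
    missing_cols = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"measurement table lacks columns {missing_cols}")
    records = []
    for sid, sub in df.groupby("subject_id", sort=False):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"subject {sid}: inconsistent group labels {groups}")
        meas: dict[tuple[int, str], SideMeasurement] = {}
        csf: dict[int, CsfMeasurement] = {}
        for _, row in sub.iterrows():
            key = (int(row["rater"]), str(row["side"]))
            if key in meas:
                raise ValueError(f"subject {sid}: duplicate cell {key}")
            meas[key] = SideMeasurement(
                ll=float(row["LL_mm"]),
                sl=float(row["SL_mm"]),
                area=float(row["area_mm2"]),
                si_mean=float(row["SIm"]),
                si_sd=float(row["SIsd"]),
            )
            csf_cell = CsfMeasurement(
                si_mean=float(row["SIm_CSF"]), si_sd=float(row["SIsd_CSF"])
            )
            prev = csf.setdefault(int(row["rater"]), csf_cell)
            if prev != csf_cell:
                raise ValueError(
                    f"subject {sid}: rater {row['rater']} CSF values differ between rows"
                )
        records.append(
            SubjectRecord(
                subject_id=str(sid), group_label=str(groups[0]),
                measurements=meas, csf=csf,
            )
        )
    return records


def indices_table(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """One row of :class:`SubjectIndices` per subject."""
    rows = [asdict(compute_subject_indices(rec)) for rec in records]
    cols = ["subject_id", "group", *INDEX_COLUMNS,
            "csl_side", "csisd_side", "csl_tie", "csisd_tie"]
    return pd.DataFrame(rows)[cols]


def per_rater_table(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Per-rater side-mean indices (for ICC), one row per (subject, rater)."""
    rows = []
    for rec in records:
        for r in RATERS:
            cells = [rec.measurements[(r, s)] for s in SIDES]
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group_label,
                    "rater": r,
                    "SL": float(np.mean([c.sl for c in cells])),
                    "LL": float(np.mean([c.ll for c in cells])),
                    "SLLr": float(np.mean([c.sllr for c in cells])),
                    "Area": float(np.mean([c.area for c in cells])),
                    "SIm_LN": float(np.mean([c.si_mean for c in cells])),
                    "SIsd_LN": float(np.mean([c.si_sd for c in cells])),
                    "nSIm": float(
                        np.mean(
                            [
                                normalize_intensity(c.si_mean, rec.csf[r].si_mean)
                                for c in cells
                            ]
                        )
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "rater", *PER_RATER_INDEX_COLUMNS]
    )
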