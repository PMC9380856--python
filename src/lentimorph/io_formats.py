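"""File formats for every artifact the pipeline touches.

Slice bundles (intensity image + left/right/CSF masks + measurement
metadata) are stored either as NIfTI (the neuroimaging standard; pixel
spacing lives in the header and is cross-checked against the sidecar) or as
PNG files with a JSON sidecar (dependency-light, 16-bit intensity).
Measurement and index tables are plain CSV (comma, UTF-8, header row,
decimal point).  Analysis reports serialize to ``report.json`` plus
flat CSVs (``comparisons.csv``, ``icc.csv``, ``roc.csv``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .indices import MEASUREMENT_COLUMNS
from .stats import AnalysisReport, GroupComparison, IccResult, RocResult

__all__ = [
    "SliceBundle",
    "SliceBundleError",
    "ReportSchemaError",
    "write_slice_bundle",
    "read_slice_bundle",
    "read_measurements_csv",
    "write_measurements_csv",
    "write_report",
    "read_report",
]


class SliceBundleError(ValueError):
    """A slice bundle on disk is inconsistent or incomplete."""


class ReportSchemaError(ValueError):
    """A serialized report violates the report schema."""


_MASK_NAMES = ("left_mask", "right_mask", "csf_mask")


@dataclass
class SliceBundle:
    """One measurement scene: image, three masks, and geometry metadata."""

    image: np.ndarray
    left_mask: np.ndarray
    right_mask: np.ndarray
    csf_mask: np.ndarray
    pixel_spacing: float  # mm/px
    x_ref_left: float  # mm
    x_ref_right: float  # mm
    provenance: str = ""

    def __post_init__(self) -> None:
        shapes = {
            a.shape
            for a in (self.image, self.left_mask, self.right_mask, self.csf_mask)
        }
        if len(shapes) != 1:
            raise SliceBundleError(f"array shapes differ: {sorted(shapes)}")
        for name in _MASK_NAMES:
            m = getattr(self, name)
            bad = set(np.unique(m)) - {0, 1, False, True}
            if bad:
                raise SliceBundleError(
                    f"non-binary mask {name}: values {sorted(bad)} present"
                )
        if not self.pixel_spacing > 0:
            raise SliceBundleError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")

    def masks(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n).astype(bool) for n in _MASK_NAMES}


def _sidecar(bundle: SliceBundle) -> dict:
    return {
        "pixel_spacing_mm": bundle.pixel_spacing,
        "x_ref_left_mm": bundle.x_ref_left,
        "x_ref_right_mm": bundle.x_ref_right,
        "provenance": bundle.provenance,
    }


def write_slice_bundle(bundle: SliceBundle, outdir, fmt: str = "nifti") -> Path:
    """Write a bundle as NIfTI (``fmt="nifti"``) or PNG (``fmt="png"``)
    plus a JSON sidecar; returns the directory written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "nifti":
        affine = np.diag([bundle.pixel_spacing, bundle.pixel_spacing, 1.0, 1.0])
        nib.save(
            nib.Nifti1Image(bundle.image.astype(np.float32), affine),
            outdir / "image.nii",
        )
        for name in _MASK_NAMES:
            nib.save(
                nib.Nifti1Image(
                    getattr(bundle, name).astype(np.uint8), affine
                ),
                outdir / f"{name}.nii",
            )
    elif fmt == "png":
        # intensity rounded to uint16; masks 0/255
        img = np.clip(np.rint(bundle.image), 0, 65535).astype(np.uint16)
        Image.fromarray(img).save(outdir / "image.png")
        for name in _MASK_NAMES:
            arr = (getattr(bundle, name).astype(np.uint8)) * 255
            Image.fromarray(arr).save(outdir / f"{name}.png")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    (outdir / "bundle.json").write_text(json.dumps(_sidecar(bundle), indent=2))
    return outdir


def _read_sidecar(outdir: Path) -> dict:
    sidecar = outdir / "bundle.json"
    if not sidecar.exists():
        raise SliceBundleError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("pixel_spacing_mm", "x_ref_left_mm", "x_ref_right_mm"):
        if key not in meta:
            raise SliceBundleError(f"sidecar lacks required key {key!r}")
    return meta


def read_slice_bundle(path) -> SliceBundle:
    """Read a bundle directory written by :func:`write_slice_bundle`.

    NIfTI takes precedence when both formats are present; the header pixel
    spacing is cross-checked against the sidecar.
    """
    outdir = Path(path)
    meta = _read_sidecar(outdir)
    spacing = float(meta["pixel_spacing_mm"])

    if (outdir / "image.nii").exists():
        arrays = {}
        for name in ("image", *_MASK_NAMES):
            img = nib.load(outdir / f"{name}.nii")
            arrays[name] = np.asarray(img.dataobj)
        hdr_spacing = float(nib.load(outdir / "image.nii").header.get_zooms()[0])
        if not np.isclose(hdr_spacing, spacing, rtol=1e-4):
            raise SliceBundleError(
                f"pixel spacing mismatch: NIfTI header {hdr_spacing} mm/px "
                f"vs sidecar {spacing} mm/px"
            )
    elif (outdir / "image.png").exists():
        arrays = {
            "image": np.asarray(Image.open(outdir / "image.png"), dtype=float)
        }
        for name in _MASK_NAMES:
            m = np.asarray(Image.open(outdir / f"{name}.png"))
            bad = set(np.unique(m)) - {0, 255}
            if bad:
                raise SliceBundleError(
                    f"non-binary mask {name}: values {sorted(bad)} present"
                )
            arrays[name] = m > 0
    else:
        raise SliceBundleError(f"no image.nii or image.png under {outdir}")

    return SliceBundle(
        image=np.asarray(arrays["image"], dtype=float),
        left_mask=np.asarray(arrays["left_mask"]).astype(bool),
        right_mask=np.asarray(arrays["right_mask"]).astype(bool),
        csf_mask=np.asarray(arrays["csf_mask"]).astype(bool),
        pixel_spacing=spacing,
        x_ref_left=float(meta["x_ref_left_mm"]),
        x_ref_right=float(meta["x_ref_right_mm"]),
        provenance=str(meta.get("provenance", "")),
    )


# ---------------------------------------------------------------------------
# tables


def write_measurements_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_measurements_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurements CSV lacks columns {missing}")
    return df


# ---------------------------------------------------------------------------
# analysis reports

_REPORT_KEYS = {"alpha", "comparisons", "roc", "icc", "roc_pairs"}


def _report_to_dict(report: AnalysisReport) -> dict:
    return {
        "alpha": report.alpha,
        "roc_pairs": [list(p) for p in report.roc_pairs],
        "comparisons": [
            {
                "index_name": c.index_name,
                "test_used": c.test_used,
                "pairwise_p": [[a, b, p] for (a, b), p in c.pairwise_p.items()],
                "normality_p": c.normality_p,
                "anova_p": c.anova_p,
            }
            for c in report.comparisons
        ],
        "roc": [
            {
                "index_name": r.index_name,
                "positive_group": r.positive_group,
                "comparison_group": r.comparison_group,
                "orientation": r.orientation,
                "auc": r.auc,
                "cutoff": r.cutoff,
                "youden_j": r.youden_j,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
            }
            for r in report.roc
        ],
        "icc": [
            {
                "index_name": i.index_name,
                "group": i.group,
                "icc": i.icc,
                "agreement_band": i.agreement_band,
                "model": i.model,
            }
            for i in report.icc
        ],
    }


def write_report(report: AnalysisReport, outdir) -> Path:
    """Write ``report.json`` plus comparisons/icc/roc CSVs; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(_report_to_dict(report), indent=2, allow_nan=True)
    )

    comp_rows = []
    for c in report.comparisons:
        row = {"index_name": c.index_name, "test_used": c.test_used,
               "anova_p": c.anova_p}
        for (a, b), p in c.pairwise_p.items():
            row[f"p[{a} vs {b}]"] = p
        comp_rows.append(row)
    pd.DataFrame(comp_rows).to_csv(outdir / "comparisons.csv", index=False)

    pd.DataFrame(
        [
            {
                "index_name": i.index_name, "group": i.group, "icc": i.icc,
                "agreement_band": i.agreement_band,
            }
            for i in report.icc
        ]
    ).to_csv(outdir / "icc.csv", index=False)

    roc_rows = []
    for r in report.roc:
        if r.curve is not None:
            cur = r.curve.assign(
                index_name=r.index_name,
                positive_group=r.positive_group,
                comparison_group=r.comparison_group,
            )
            roc_rows.append(cur)
    if roc_rows:
        pd.concat(roc_rows, ignore_index=True).to_csv(
            outdir / "roc.csv", index=False
        )
    else:
        pd.DataFrame(
            columns=["cutoff", "sensitivity", "specificity", "youden_j",
                     "index_name", "positive_group", "comparison_group"]
        ).to_csv(outdir / "roc.csv", index=False)
    return outdir


def read_report(path) -> AnalysisReport:
    """Read back a ``report.json`` (schema-validated)."""
    path = Path(path)
    if path.is_dir():
        path = path / "report.json"
    data = json.loads(path.read_text())
    missing = _REPORT_KEYS - set(data)
    if missing:
        raise ReportSchemaError(f"report lacks required keys {sorted(missing)}")
    comparisons = [
        GroupComparison(
            index_name=c["index_name"],
            test_used=c["test_used"],
            pairwise_p={(a, b): p for a, b, p in c["pairwise_p"]},
            normality_p=c["normality_p"],
            anova_p=c["anova_p"],
        )
        for c in data["comparisons"]
    ]
    roc = [RocResult(curve=None, **r) for r in data["roc"]]
    icc = [
        IccResult(
            index_name=i["index_name"], icc=i["icc"],
            agreement_band=i["agreement_band"], model=i["model"], group=i["group"],
        )
        for i in data["icc"]
    ]
    return AnalysisReport(
        comparisons=comparisons,
        roc=roc,
        icc=icc,
        roc_pairs=[tuple(p) for p in data["roc_pairs"]],
        alpha=float(data["alpha"]),
    )
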