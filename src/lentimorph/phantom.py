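"""Synthetic axial-slice phantoms and cohorts with known ground truth.

Real SWI slices of the lentiform nucleus (LN) are not redistributable, so
this module renders a geometric stand-in: each LN side is an ellipse (an
optional shear is accepted for sensitivity analysis but defaults to 0),
because an ellipse has closed-form chords and area against which the
morphometry can be checked exactly:

* longest horizontal chord ``LL = 2a``,
* vertical chord at the reference line
  ``SL(x) = 2b * sqrt(1 - ((x - cx)/a)**2)``,
* area ``pi * a * b``.

Cohort generation draws per-subject latent index values from per-group
normal distributions (negative draws are redrawn, i.e. truncation at zero),
imposes a left-right short-line asymmetry with a stated expected magnitude,
and emulates the two radiologists either by adding measurement noise to the
latent values (*tabular* mode) or by rendering a phantom and measuring it
twice through :mod:`lentimorph.morphometry` with per-rater reference-line
jitter and 1-px mask erosion (*image* mode).

The shipped ``published_cohort_defaults`` configuration encodes the three study
groups (MSA-P, PD, CG; n=19 each) with the published index means and SDs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from math import pi, sqrt

import numpy as np
from scipy import ndimage

from .indices import SubjectRecord
from .morphometry import (
    CsfMeasurement,
    MeasurementFrame,
    ReferenceLineMissError,
    SideMeasurement,
    measure_csf,
    measure_side,
)

__all__ = [
    "EllipseRoiSpec",
    "PhantomSpec",
    "GroupParams",
    "RaterNoiseModel",
    "render_slice",
    "generate_subject",
    "generate_cohort",
    "published_cohort_defaults",
    "load_cohort_config",
]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class EllipseRoiSpec:
    """Axis-aligned (optionally sheared) elliptical ROI, in mm."""

    center_x: float
    center_y: float
    semi_axis_a: float  # horizontal semi-axis, mm
    semi_axis_b: float  # vertical semi-axis, mm
    mean_intensity: float  # added to background inside the ROI
    sd_intensity: float  # within-ROI Gaussian texture SD
    shear: float = 0.0  # x shift per unit y (volume-preserving)

    def __post_init__(self) -> None:
        if not (self.semi_axis_a > 0 and self.semi_axis_b > 0):
            raise ValueError("ellipse semi-axes must be positive")
        if self.sd_intensity < 0:
            raise ValueError("sd_intensity must be >= 0")

    # -- closed forms -------------------------------------------------------

    @property
    def area(self) -> float:
        return pi * self.semi_axis_a * self.semi_axis_b

    @property
    def longest_horizontal_chord(self) -> float:
        # shear shifts each row horizontally, leaving row chords unchanged
        return 2.0 * self.semi_axis_a

    def vertical_chord(self, x: float) -> float:
        """Length of the vertical chord at abscissa ``x`` (0 outside)."""
        a, b, s = self.semi_axis_a, self.semi_axis_b, self.shear
        x0 = x - self.center_x
        # inside iff ((x0 - s*u)/a)^2 + (u/b)^2 <= 1 with u = y - cy
        A = s**2 / a**2 + 1.0 / b**2
        disc = (x0 * s / a**2) ** 2 - A * (x0**2 / a**2 - 1.0)
        if disc <= 0:
            return 0.0
        return 2.0 * sqrt(disc) / A

    @property
    def half_extent_x(self) -> float:
        return sqrt(self.semi_axis_a**2 + (self.shear * self.semi_axis_b) ** 2)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        u = y - self.center_y
        return ((x - self.center_x - self.shear * u) / self.semi_axis_a) ** 2 + (
            u / self.semi_axis_b
        ) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one rendered slice."""

    image_shape: tuple[int, int]  # rows, cols
    pixel_spacing: float  # mm/px, isotropic
    left_ln: EllipseRoiSpec
    right_ln: EllipseRoiSpec
    csf_roi: EllipseRoiSpec
    background_intensity: float
    noise_sd: float
    x_ref_left: float  # mm
    x_ref_right: float  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        h = self.image_shape[0] * self.pixel_spacing
        w = self.image_shape[1] * self.pixel_spacing
        for name, roi in (
            ("left_ln", self.left_ln),
            ("right_ln", self.right_ln),
            ("csf_roi", self.csf_roi),
        ):
            if (
                roi.center_x - roi.half_extent_x < 0
                or roi.center_x + roi.half_extent_x > w
                or roi.center_y - roi.semi_axis_b < 0
                or roi.center_y + roi.semi_axis_b > h
            ):
                raise ValueError(
                    f"{name} extends outside the {w:g} x {h:g} mm image"
                )
        for side, x_ref, roi in (
            ("left", self.x_ref_left, self.left_ln),
            ("right", self.x_ref_right, self.right_ln),
        ):
            if roi.vertical_chord(x_ref) <= 0:
                raise ReferenceLineMissError(
                    f"x_ref_{side} = {x_ref:g} mm does not intersect the {side} LN"
                )


def render_slice(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict]:
    """Render ``(intensity_image, left_mask, right_mask, csf_mask, truth)``.

    A pixel belongs to a mask iff its *centre* satisfies the ellipse
    inequality.  The intensity image is background + per-ROI mean +
    zero-mean Gaussian texture (the ROI's ``sd_intensity``) + global
    Gaussian noise.  ``truth`` carries the closed-form LL/SL/area and the
    intensity parameters for each ROI.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    x = (x + 0.5) * spec.pixel_spacing  # pixel centres
    y = (y + 0.5) * spec.pixel_spacing

    image = np.full((rows, cols), spec.background_intensity, dtype=float)
    masks = {}
    for name, roi in (
        ("left", spec.left_ln),
        ("right", spec.right_ln),
        ("csf", spec.csf_roi),
    ):
        m = roi.contains(x, y)
        masks[name] = m
        image[m] += roi.mean_intensity
        if roi.sd_intensity > 0:
            image[m] += rng.normal(0.0, roi.sd_intensity, size=int(m.sum()))
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)

    truth = {"x_ref": {"left": spec.x_ref_left, "right": spec.x_ref_right}}
    for name, roi, x_ref in (
        ("left", spec.left_ln, spec.x_ref_left),
        ("right", spec.right_ln, spec.x_ref_right),
    ):
        truth[name] = {
            "LL": roi.longest_horizontal_chord,
            "SL": roi.vertical_chord(x_ref),
            "area": roi.area,
            "si_mean": spec.background_intensity + roi.mean_intensity,
            "si_sd": roi.sd_intensity,
        }
    truth["csf"] = {
        "si_mean": spec.background_intensity + spec.csf_roi.mean_intensity,
        "si_sd": spec.csf_roi.sd_intensity,
        "area": spec.csf_roi.area,
    }
    return image, masks["left"], masks["right"], masks["csf"], truth


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class GroupParams:
    """Distribution of one group's latent index values.

    Lengths mm, areas mm**2, intensities in scanner signal units.  The
    bilateral indices are anchored on the side the corrected rules select:
    the *smaller* short line is drawn from ``N(csl_mean, csl_sd)`` and the
    other side adds a half-normal offset with expectation
    ``asymmetry_delta`` (the expected |left - right| difference), so the
    smaller-side and side-mean SL have means ``csl_mean`` and ``csl_mean +
    asymmetry_delta / 2``.  The intensity SD is anchored symmetrically on
    the *larger* side (``csisd_mean`` minus a half-normal offset with
    expectation ``sisd_asymmetry_delta``).  Anchoring the selected side
    keeps both the corrected and the plain group means exact expectations
    of the generator.
    """

    label: str
    n_subjects: int
    csl_mean: float
    csl_sd: float
    asymmetry_delta: float
    ll_mean: float
    ll_sd: float
    area_mean: float
    area_sd: float
    sim_ln_mean: float
    sim_ln_sd: float
    csisd_mean: float
    csisd_sd: float
    sisd_asymmetry_delta: float
    sim_csf_mean: float
    sim_csf_sd: float
    sisd_csf_mean: float
    sisd_csf_sd: float

    def __post_init__(self) -> None:
        for name in (
            "csl_sd", "ll_sd", "area_sd", "sim_ln_sd", "csisd_sd",
            "sim_csf_sd", "sisd_csf_sd", "asymmetry_delta", "sisd_asymmetry_delta",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")


@dataclass(frozen=True)
class RaterNoiseModel:
    """Additive per-rater measurement noise (zero-mean Gaussian).

    ``sd_length`` applies to every caliper length (and, in image mode, to
    the per-rater reference-line position); ``sd_intensity`` to intensity
    means and SDs; ``sd_area`` to areas.
    """

    sd_length: float = 0.5  # mm
    sd_intensity: float = 25.0  # signal units
    sd_area: float = 12.0  # mm**2

    def __post_init__(self) -> None:
        if min(self.sd_length, self.sd_intensity, self.sd_area) < 0:
            raise ValueError("noise SDs must be >= 0")

    @classmethod
    def zero(cls) -> "RaterNoiseModel":
        return cls(0.0, 0.0, 0.0)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at zero by redraw."""
    for _ in range(_MAX_REDRAWS):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise RuntimeError(
        f"could not draw a positive value from N({mean}, {sd}) "
        f"in {_MAX_REDRAWS} attempts"
    )


def _half_normal(rng: np.random.Generator, expected: float) -> float:
    """|N(0, s)| with scale chosen so the expectation equals ``expected``."""
    if expected == 0:
        return 0.0
    return float(abs(rng.normal(0.0, expected * sqrt(pi / 2.0))))


@dataclass
class _Latent:
    """Per-subject ground-truth values (before rater noise)."""

    sl: dict  # side -> mm
    ll: float
    area: float
    sim_ln: float
    sisd: dict  # side -> signal units
    sim_csf: float
    sisd_csf: float


def _draw_latent(group: GroupParams, rng: np.random.Generator, mode: str) -> _Latent:
    for _ in range(_MAX_REDRAWS):
        # anchor the smaller SL side; the other side adds a half-normal gap
        sl_small = _positive_normal(rng, group.csl_mean, group.csl_sd)
        sl_large = sl_small + _half_normal(rng, group.asymmetry_delta)
        ll = _positive_normal(rng, group.ll_mean, group.ll_sd)
        if sl_large > ll:  # a short line cannot exceed the long line
            continue
        area = _positive_normal(rng, group.area_mean, group.area_sd)
        if mode == "image" and (
            # rendered side ellipses need b < a so LL stays horizontal,
            # and a sub-pixel-scale short line cannot be rendered or measured
            sl_large >= _REF_CHORD_FRACTION_LIMIT * ll
            or sl_small < _MIN_RENDERABLE_SL
        ):
            continue
        small_side = "left" if rng.random() < 0.5 else "right"
        sl = {small_side: sl_small, _other(small_side): sl_large}

        # anchor the larger intensity-SD side; the other side subtracts a gap
        sd_hi = _positive_normal(rng, group.csisd_mean, group.csisd_sd)
        for _ in range(_MAX_REDRAWS):
            sd_lo = sd_hi - _half_normal(rng, group.sisd_asymmetry_delta)
            if sd_lo > 0:
                break
        else:
            continue
        hi_side = "left" if rng.random() < 0.5 else "right"
        sisd = {hi_side: sd_hi, _other(hi_side): sd_lo}

        return _Latent(
            sl=sl,
            ll=ll,
            area=area,
            sim_ln=_positive_normal(rng, group.sim_ln_mean, group.sim_ln_sd),
            sisd=sisd,
            sim_csf=_positive_normal(rng, group.sim_csf_mean, group.sim_csf_sd),
            sisd_csf=_positive_normal(rng, group.sisd_csf_mean, group.sisd_csf_sd),
        )
    raise RuntimeError(
        f"group {group.label}: no feasible latent geometry in {_MAX_REDRAWS} draws"
    )


def _other(side: str) -> str:
    return "right" if side == "left" else "left"


def _noisy_positive(rng: np.random.Generator, value: float, sd: float) -> float:
    if sd == 0:
        return float(value)
    return _positive_normal(rng, value, sd)


# layout constants for rendered subjects (mm); 256 px at 0.5 mm/px = 128 mm
_IMAGE_SHAPE = (256, 256)
_PIXEL_SPACING = 0.5
_BACKGROUND = 400.0
_IMAGE_NOISE_SD = 5.0
_LN_CENTERS = {"left": (38.0, 64.0), "right": (90.0, 64.0)}
_CSF_CENTER = (64.0, 100.0)
_CSF_AXES = (4.0, 3.0)
# the reference line sits at this fraction of the semi-axis from the centre,
# posteriorly; far enough out to emulate the narrowing posterior LN, but away
# from the ellipse tip where a rasterized chord degrades
_X_REF_FRACTION = 0.6
_REF_CHORD_FRACTION_LIMIT = 2.0 * sqrt(1.0 - _X_REF_FRACTION**2)  # keeps b < a
_MIN_RENDERABLE_SL = 3.0 * _PIXEL_SPACING  # mm; below this the chord is ~1 px


def phantom_spec_for_latent(latent: _Latent, seed: int) -> PhantomSpec:
    """Construct the slice whose closed-form chords equal ``latent``.

    Each side is an ellipse with ``a = LL/2``; the reference line sits at a
    fixed offset ``0.6 a`` from the centre (mirrored between sides, i.e.
    posteriorly) and the vertical semi-axis is sized so the chord there
    equals that side's SL: ``b = SL / (2 sqrt(1 - 0.6^2))``.  The rendered
    area is therefore a consequence of the chord geometry (``pi a b``), not
    the latent area draw — an ellipse cannot match LL, SL *and* area while
    keeping the reference chord away from its tip, and chord fidelity wins
    in image mode.
    """
    a = latent.ll / 2.0
    rois = {}
    x_ref = {}
    for side, sign in (("left", -1.0), ("right", +1.0)):
        cx, cy = _LN_CENTERS[side]
        b = latent.sl[side] / (2.0 * sqrt(1.0 - _X_REF_FRACTION**2))
        rois[side] = EllipseRoiSpec(
            center_x=cx,
            center_y=cy,
            semi_axis_a=a,
            semi_axis_b=b,
            mean_intensity=latent.sim_ln - _BACKGROUND,
            sd_intensity=latent.sisd[side],
        )
        x_ref[side] = cx + sign * _X_REF_FRACTION * a
    csf = EllipseRoiSpec(
        center_x=_CSF_CENTER[0],
        center_y=_CSF_CENTER[1],
        semi_axis_a=_CSF_AXES[0],
        semi_axis_b=_CSF_AXES[1],
        mean_intensity=latent.sim_csf - _BACKGROUND,
        sd_intensity=latent.sisd_csf,
    )
    return PhantomSpec(
        image_shape=_IMAGE_SHAPE,
        pixel_spacing=_PIXEL_SPACING,
        left_ln=rois["left"],
        right_ln=rois["right"],
        csf_roi=csf,
        background_intensity=_BACKGROUND,
        noise_sd=_IMAGE_NOISE_SD,
        x_ref_left=x_ref["left"],
        x_ref_right=x_ref["right"],
        seed=seed,
    )


def _perturb_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rater boundary variability: 1-px erosion or the mask unchanged.

    Raters sketch within the structure boundary; dilation is deliberately
    not drawn because the phantom's hard intensity step would let the
    out-of-ROI ring dominate the intensity-SD index, which no real
    partial-volume boundary does.
    """
    if rng.integers(0, 2) == 1:
        eroded = ndimage.binary_erosion(mask)
        return eroded if eroded.any() else mask
    return mask


def generate_subject(
    group: GroupParams,
    rater_noise: RaterNoiseModel,
    mode: str = "tabular",
    seed: int = 0,
    subject_id: str | None = None,
) -> SubjectRecord:
    """Draw one subject and its two raters' measurements.

    ``mode="tabular"`` adds rater noise directly to the latent values;
    ``mode="image"`` renders the phantom and measures it twice through the
    morphometry module, each rater with an independently jittered reference
    line and a randomly eroded/dilated mask.
    """
    if mode not in ("tabular", "image"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    latent = _draw_latent(group, rng, mode)
    sid = subject_id or f"{group.label}-{seed}"
    truth = {
        "sl": dict(latent.sl), "ll": latent.ll, "area": latent.area,
        "sim_ln": latent.sim_ln, "sisd_ln": dict(latent.sisd),
        "sim_csf": latent.sim_csf, "sisd_csf": latent.sisd_csf,
    }

    measurements: dict[tuple[int, str], SideMeasurement] = {}
    csf: dict[int, CsfMeasurement] = {}

    if mode == "tabular":
        for rater in (1, 2):
            for side in ("left", "right"):
                measurements[(rater, side)] = SideMeasurement(
                    ll=_noisy_positive(rng, latent.ll, rater_noise.sd_length),
                    sl=_noisy_positive(rng, latent.sl[side], rater_noise.sd_length),
                    area=_noisy_positive(rng, latent.area, rater_noise.sd_area),
                    si_mean=_noisy_positive(
                        rng, latent.sim_ln, rater_noise.sd_intensity
                    ),
                    si_sd=_noisy_positive(
                        rng, latent.sisd[side], rater_noise.sd_intensity
                    ),
                )
            csf[rater] = CsfMeasurement(
                si_mean=_noisy_positive(rng, latent.sim_csf, rater_noise.sd_intensity),
                si_sd=_noisy_positive(rng, latent.sisd_csf, rater_noise.sd_intensity),
            )
        return SubjectRecord(sid, group.label, measurements, csf, truth=truth)

    # image mode
    spec = phantom_spec_for_latent(latent, seed=int(rng.integers(2**31)))
    image, left, right, csf_mask, render_truth = render_slice(spec)
    truth["render"] = render_truth
    truth["phantom_seed"] = spec.seed
    side_masks = {"left": left, "right": right}
    x_ref = {"left": spec.x_ref_left, "right": spec.x_ref_right}
    for rater in (1, 2):
        for side in ("left", "right"):
            mask = _perturb_mask(side_masks[side], rng)
            frame = MeasurementFrame(
                pixel_spacing=spec.pixel_spacing,
                x_ref=x_ref[side] + rng.normal(0.0, rater_noise.sd_length),
            )
            try:
                measurements[(rater, side)] = measure_side(image, mask, frame)
            except ReferenceLineMissError:
                # jittered line (or eroded mask) slid off the ROI; fall back
                # to the true line on the unperturbed mask
                frame = MeasurementFrame(
                    pixel_spacing=spec.pixel_spacing, x_ref=x_ref[side]
                )
                measurements[(rater, side)] = measure_side(
                    image, side_masks[side], frame
                )
        csf[rater] = measure_csf(image, _perturb_mask(csf_mask, rng))
    return SubjectRecord(sid, group.label, measurements, csf, truth=truth)


def generate_cohort(
    groups: list[GroupParams],
    rater_noise: RaterNoiseModel,
    mode: str = "tabular",
    seed: int = 0,
) -> list[SubjectRecord]:
    """Generate all groups' subjects; subject ``i`` (in concatenation order)
    uses seed ``seed + i`` and is therefore individually reproducible."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels in {labels}")
    records = []
    i = 0
    for group in groups:
        for j in range(group.n_subjects):
            records.append(
                generate_subject(
                    group,
                    rater_noise,
                    mode=mode,
                    seed=seed + i,
                    subject_id=f"{group.label}-{j + 1:02d}",
                )
            )
            i += 1
    return records


# ---------------------------------------------------------------------------
# configuration


def _parse_config(cfg: dict) -> tuple[list[GroupParams], RaterNoiseModel]:
    groups = [GroupParams(**g) for g in cfg["groups"]]
    noise = RaterNoiseModel(**cfg.get("rater_noise", {}))
    return groups, noise


def published_cohort_defaults() -> tuple[list[GroupParams], RaterNoiseModel]:
    """The shipped default cohort: MSA-P / PD / CG, n=19 each, index
    distributions matching the published group means and SDs."""
    text = (
        resources.files("lentimorph").joinpath("data/published_cohort_defaults.json").read_text()
    )
    return _parse_config(json.loads(text))


def load_cohort_config(path) -> tuple[list[GroupParams], RaterNoiseModel]:
    """Read a cohort configuration (same schema as the shipped default)."""
    with open(path) as fh:
        return _parse_config(json.load(fh))


def group_params_to_config(
    groups: list[GroupParams], noise: RaterNoiseModel
) -> dict:
    return {"groups": [asdict(g) for g in groups], "rater_noise": asdict(noise)}
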