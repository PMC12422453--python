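"""Synthetic cooling-study generator with known ground truth.

Emulates a pre-post skin-cooling experiment on the lower back: a cohort of
subjects (melanin colorimetry, baseline skin temperature), and for every
subject a full factorial of imaging conditions — 2 cameras x 2 phases
(baseline/cooled) x 2 lighting x 2 distances x 3 postures = 48 images per
subject. Each image is an optical/thermal pair linked by a known affine map,
with the cooled site rendered as a smooth elliptical depression.

The generative temperature model is additive (all terms in °C):

    T(pixel) = [baseline_i - gap_i] + camera_offset + distance + posture
               + lighting + phase-dependent global shift + frame drift
               + gap_i * P_site(pixel) + local fluctuations
               + cooled * D_i,cam * P_cool(pixel) + pixel noise

where ``P_cool`` is a raised-cosine elliptical depression that is flat over
the whole drawn circle and tapers just outside it (so the ROI median equals
the nominal depth plus a symmetric pixel-noise term) and ``P_site`` is a
slightly larger plateau that separates the ROI baseline level from the
surrounding skin where the control region sits.
``D_i,cam`` combines the camera-specific cooling depth, the control-region
cooled-phase shift, and the melanin-dependent cooling modifier.

Every random draw descends from one root seed through named substreams, so a
fixed seed reproduces the whole study bit-for-bit regardless of the order in
which images are materialized.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import product
from math import pi
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .colorimetry import DEFAULT_CONVERSION, categorize_melanin
from .frames import OpticalFrame, ThermalFrame, write_optical, write_thermal
from .registration import AffineMap
from .roi import CONTROL_OFFSET_FACTOR, SUPERIOR_SIGN, EllipseROI

__all__ = [
    "GenerativeConfig",
    "SubjectProfile",
    "Condition",
    "SimulatedImage",
    "CAMERA_PRESETS",
    "FACTOR_GRID",
    "sample_cohort",
    "render_image_pair",
    "simulate_study",
    "generate_study",
    "simulate_measurements",
]

# --------------------------------------------------------------------------
# configuration

LIGHTING_LEVELS = ("room", "ring")
DISTANCE_LEVELS = (35, 50)
POSTURE_LEVELS = ("stacked", "knee_forward", "knee_behind")
PHASES = ("baseline", "cooled")
CAMERAS = ("E8XT", "ONEPro")

#: lighting x distance x posture grid of imaging conditions (12 per phase).
FACTOR_GRID = tuple(product(LIGHTING_LEVELS, DISTANCE_LEVELS, POSTURE_LEVELS))

# substream tags for the root seed
_STREAM_COHORT = 1
_STREAM_IMAGE = 2
_STREAM_MEASUREMENT = 3


@dataclass(frozen=True)
class CameraPreset:
    width: int
    height: int
    roi_semi_major_px: float  # at 35 cm
    roi_semi_minor_px: float


CAMERA_PRESETS: dict[str, CameraPreset] = {
    "E8XT": CameraPreset(320, 240, 34.0, 22.0),
    "ONEPro": CameraPreset(160, 120, 17.0, 11.0),
}

#: apparent-size shrink of the marked circle when imaged at 50 cm vs 35 cm
DISTANCE_SCALE = {35: 1.0, 50: 0.7}


@dataclass(frozen=True)
class GenerativeConfig:
    """All true effect parameters of the synthetic cohort.

    Effects are expressed exactly as the downstream mixed models estimate
    them: camera reference E8XT, distance reference 35 cm, phase reference
    baseline. ``cooling_depth_E8XT_C`` is the magnitude of the *marginal*
    (distance-averaged) ROI cooling — the phase coefficient of a model that
    omits distance from a balanced design — so the rendered depression at
    35 cm is deeper by half the distance-by-cooling interaction.
    """

    n_subjects: int = 35
    rng_seed: int = 0

    # cohort
    baseline_mean_C: float = 30.8
    baseline_sd_C: float = 0.9  # between-subject SD == subject random intercept SD
    melanin_mean: float = 55.94  # converted (DSM-II) scale
    melanin_sd: float = 13.54
    melanin_bounds: tuple[float, float] = (25.0, 100.0)

    # fixed effects (°C unless stated)
    cooling_depth_E8XT_C: float = 4.19
    cooling_x_camera_abs_C: float = 1.89
    camera_offset_ONEPro_C: float = -2.43
    cooling_x_camera_diff_C: float = 1.04
    control_cooled_shift_E8XT_C: float = -0.34
    distance_effect_C: float = -0.11  # 50 cm vs 35 cm, whole frame
    distance_x_cooling_C: float = 0.20
    posture_effect_C: float = 0.0
    lighting_effect_C: float = 0.0
    melanin_x_cooling_C_per_unit: float = -0.013
    control_baseline_gap_C: float = -0.3  # ROI minus control at baseline

    # dispersion
    gap_sd_C: float = 0.15  # subject-level SD of the ROI-control gap
    frame_drift_sd_C: float = 0.25  # per-image whole-frame drift
    region_fluct_sd_C: float = 0.20  # per-image local fluctuation per region
    pixel_noise_sd_E8XT_C: float = 0.15
    pixel_noise_sd_ONEPro_C: float = 0.30

    # rendering geometry: the cooled depression is flat over the whole drawn
    # circle (plateau slightly beyond r=1) and tapers outside it, so the ROI
    # median equals the nominal depth plus a symmetric noise term (unbiased);
    # an interior taper would make the plateau the profile minimum and bias
    # the median warm under pixel noise
    cooled_plateau_scale: float = 1.02
    cooled_taper_scale: float = 1.15
    boundary_points: int = 8
    boundary_jitter_px: float = 0.3  # optical-pixel jitter on clicked points

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (self.baseline_sd_C > 0 and self.melanin_sd > 0):
            raise ValueError("cohort SDs must be > 0")
        for name in ("gap_sd_C", "frame_drift_sd_C", "region_fluct_sd_C",
                     "pixel_noise_sd_E8XT_C", "pixel_noise_sd_ONEPro_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (1.0 <= self.cooled_plateau_scale < self.cooled_taper_scale <= 1.2):
            raise ValueError(
                "require 1 <= cooled_plateau_scale < cooled_taper_scale <= 1.2 "
                "(the taper must clear the control region at 1.25 a)")
        if self.boundary_points < 5:
            raise ValueError("need >= 5 boundary points to define the ROI")

    # ---- derived truths -------------------------------------------------
    def cooling_depth(self, camera: str) -> float:
        """Magnitude of the ROI cooled-baseline change for ``camera``."""
        d = self.cooling_depth_E8XT_C
        if camera == "ONEPro":
            d -= self.cooling_x_camera_abs_C
        return d

    def control_cooled_shift(self, camera: str) -> float:
        """Whole-frame (hence control-region) shift in the cooled phase."""
        c = self.control_cooled_shift_E8XT_C
        if camera == "ONEPro":
            c += self.cooling_x_camera_abs_C - self.cooling_x_camera_diff_C
        return c

    def pixel_noise_sd(self, camera: str) -> float:
        return (self.pixel_noise_sd_E8XT_C if camera == "E8XT"
                else self.pixel_noise_sd_ONEPro_C)

    def differential_cooling(self, camera: str) -> float:
        """True cooled-baseline change of the ROI-minus-control difference.

        Distance-free: the distance-by-cooling interaction is a whole-frame
        term and cancels between the regions.
        """
        return (-self.cooling_depth(camera) - 0.5 * self.distance_x_cooling_C
                - self.control_cooled_shift(camera))

    def true_effects(self) -> dict[str, float]:
        """Generative truths keyed by the fitted model terms they match."""
        return {
            "camera_offset_ONEPro": self.camera_offset_ONEPro_C,
            "cooling_E8XT_abs": -self.cooling_depth_E8XT_C,
            "cooling_x_camera_abs": self.cooling_x_camera_abs_C,
            "cooling_E8XT_diff": self.differential_cooling("E8XT"),
            "cooling_x_camera_diff": self.cooling_x_camera_diff_C,
            "distance_50cm": self.distance_effect_C,
            "distance_x_cooling": self.distance_x_cooling_C,
            "melanin_x_cooling": self.melanin_x_cooling_C_per_unit,
            "posture": self.posture_effect_C,
            "lighting": self.lighting_effect_C,
            "control_baseline_gap": self.control_baseline_gap_C,
        }

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["melanin_bounds"] = list(d["melanin_bounds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "GenerativeConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "melanin_bounds" in d:
            d["melanin_bounds"] = tuple(d["melanin_bounds"])
        return cls(**d)


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    melanin_raw: float
    melanin_converted: float
    eumelanin_category: str
    baseline_skin_temp_C: float  # ROI-site baseline == mean + random intercept
    control_gap_C: float  # subject-level ROI-minus-control baseline gap


@dataclass(frozen=True)
class Condition:
    camera: str
    distance_cm: int
    lighting: str
    posture: str
    phase: str

    def __post_init__(self) -> None:
        if (self.camera not in CAMERAS or self.distance_cm not in DISTANCE_LEVELS
                or self.lighting not in LIGHTING_LEVELS
                or self.posture not in POSTURE_LEVELS or self.phase not in PHASES):
            raise ValueError(f"unknown condition tuple: {self}")


@dataclass
class SimulatedImage:
    """One rendered optical/thermal pair with its ground truth."""

    image_id: str
    subject: SubjectProfile
    condition: Condition
    thermal: ThermalFrame
    optical: OpticalFrame | None
    roi_true: EllipseROI
    affine_true: AffineMap  # optical -> thermal
    fiducials_optical: np.ndarray
    fiducials_thermal: np.ndarray
    boundary_points_optical: np.ndarray
    sticker_bbox: tuple[int, int, int, int]  # x0, y0, x1, y1 in thermal px
    truth: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# cohort

def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *tags]))


def sample_cohort(config: GenerativeConfig) -> list[SubjectProfile]:
    """Draw the synthetic cohort.

    Converted-scale melanin is truncated-normal over the Intermediate-Low to
    Intermediate-High range so the category proportions resemble a cohort
    enrolled predominantly at darker skin tones; raw-device values follow by
    inverting the conversion. Baseline site temperatures are Normal(mean, sd²)
    across subjects.
    """
    rng = _rng(config.rng_seed, _STREAM_COHORT)
    lo, hi = config.melanin_bounds
    a = (lo - config.melanin_mean) / config.melanin_sd
    b = (hi - config.melanin_mean) / config.melanin_sd
    mel_conv = truncnorm.rvs(a, b, loc=config.melanin_mean, scale=config.melanin_sd,
                             size=config.n_subjects, random_state=rng)
    baseline = rng.normal(config.baseline_mean_C, config.baseline_sd_C,
                          size=config.n_subjects)
    gaps = rng.normal(config.control_baseline_gap_C, config.gap_sd_C,
                      size=config.n_subjects)
    cohort = []
    for i in range(config.n_subjects):
        conv = float(mel_conv[i])
        cohort.append(SubjectProfile(
            subject_id=f"S{i + 1:03d}",
            melanin_raw=float(DEFAULT_CONVERSION.invert(conv)),
            melanin_converted=conv,
            eumelanin_category=categorize_melanin(conv),
            baseline_skin_temp_C=float(baseline[i]),
            control_gap_C=float(gaps[i]),
        ))
    return cohort


def cohort_table(cohort: list[SubjectProfile]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in cohort])


# --------------------------------------------------------------------------
# rendering

def _elliptical_radius(xs, ys, roi: EllipseROI) -> np.ndarray:
    dx = xs - roi.cx
    dy = ys - roi.cy
    c, s = np.cos(roi.theta), np.sin(roi.theta)
    u = (dx * c + dy * s) / roi.a
    v = (-dx * s + dy * c) / roi.b
    return np.sqrt(u * u + v * v)


def _raised_cosine_profile(r: np.ndarray, r_plateau: float, r_outer: float) -> np.ndarray:
    """1 inside r_plateau, smooth cosine falloff to 0 at r_outer."""
    prof = np.zeros_like(r)
    prof[r <= r_plateau] = 1.0
    taper = (r > r_plateau) & (r < r_outer)
    frac = (r[taper] - r_plateau) / (r_outer - r_plateau)
    prof[taper] = 0.5 * (1.0 + np.cos(pi * frac))
    return prof


# site plateau must cover the full cooling taper (r <= 1) with margin, and
# vanish before the default control position at 1.5 a - a/4 = 1.25 a
_SITE_PLATEAU = 1.05
_SITE_OUTER = 1.15
_CTRL_PATCH_PLATEAU = 1.3  # in units of the control semi-axes
_CTRL_PATCH_OUTER = 1.8


def _global_offsets(condition: Condition, config: GenerativeConfig) -> float:
    """Whole-frame additive terms shared by ROI and control region."""
    t = 0.0
    if condition.camera == "ONEPro":
        t += config.camera_offset_ONEPro_C
    if condition.distance_cm == 50:
        t += config.distance_effect_C
        if condition.phase == "cooled":
            t += config.distance_x_cooling_C
    if condition.posture != "stacked":
        t += config.posture_effect_C
    if condition.lighting != "room":
        t += config.lighting_effect_C
    if condition.phase == "cooled":
        t += config.control_cooled_shift(condition.camera)
    return t


def _cooling_amplitude(subject: SubjectProfile, condition: Condition,
                       config: GenerativeConfig, cohort_mean_melanin: float) -> float:
    """Signed depth of the rendered depression (0 at baseline)."""
    if condition.phase != "cooled":
        return 0.0
    # config depths are marginal over the balanced distance factor; the
    # rendered 35-cm depth is deeper by half the distance interaction, and
    # the interaction itself is applied as a whole-frame term
    depth = config.cooling_depth(condition.camera) + 0.5 * config.distance_x_cooling_C
    depth -= config.melanin_x_cooling_C_per_unit * (
        subject.melanin_converted - cohort_mean_melanin)
    # the whole-frame cooled shift is already applied globally; the local
    # depression supplies the remainder so ROI change = -depth + melanin term
    return -depth - config.control_cooled_shift(condition.camera)


def render_image_pair(
    subject: SubjectProfile,
    condition: Condition,
    config: GenerativeConfig,
    *,
    image_index: int = 0,
    subject_index: int = 0,
    cohort_mean_melanin: float | None = None,
    render_optical_raster: bool = False,
) -> SimulatedImage:
    """Render one optical/thermal pair for a subject under a condition.

    Deterministic given (config.rng_seed, subject_index, image_index). The
    optical raster is only rasterized on request; the registration workflow
    needs the fiducial and boundary *points*, which are always produced.
    """
    if cohort_mean_melanin is None:
        cohort_mean_melanin = config.melanin_mean
    preset = CAMERA_PRESETS[condition.camera]
    w, h = preset.width, preset.height
    rng = _rng(config.rng_seed, _STREAM_IMAGE, subject_index, image_index)

    # --- ground-truth ROI geometry
    scale = DISTANCE_SCALE[condition.distance_cm]
    a = preset.roi_semi_major_px * scale
    b = preset.roi_semi_minor_px * scale
    cx = 0.62 * w + rng.uniform(-2.0, 2.0)
    cy = 0.50 * h + rng.uniform(-2.0, 2.0)
    theta = rng.uniform(0.0, 0.3)
    roi = EllipseROI(cx, cy, a, b, theta)

    # --- thermal field
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    r = _elliptical_radius(xs, ys, roi)
    p_site = _raised_cosine_profile(r, _SITE_PLATEAU, _SITE_OUTER)
    p_cool = _raised_cosine_profile(r, config.cooled_plateau_scale,
                                    config.cooled_taper_scale)

    ctrl_center_x = roi.cx + SUPERIOR_SIGN * CONTROL_OFFSET_FACTOR * roi.a
    ctrl = EllipseROI(ctrl_center_x, roi.cy, roi.a / 4, roi.b / 4, roi.theta)
    r_ctrl = _elliptical_radius(xs, ys, ctrl)
    q_ctrl = _raised_cosine_profile(r_ctrl, _CTRL_PATCH_PLATEAU, _CTRL_PATCH_OUTER)

    drift = rng.normal(0.0, config.frame_drift_sd_C)
    fluct_roi = rng.normal(0.0, config.region_fluct_sd_C)
    fluct_ctrl = rng.normal(0.0, config.region_fluct_sd_C)

    base_level = subject.baseline_skin_temp_C - subject.control_gap_C
    amp = _cooling_amplitude(subject, condition, config, cohort_mean_melanin)
    grid = np.full((h, w), base_level + _global_offsets(condition, config) + drift)
    grid += (subject.control_gap_C + fluct_roi) * p_site
    grid += fluct_ctrl * q_ctrl
    if amp != 0.0:
        grid += amp * p_cool
    sd_px = config.pixel_noise_sd(condition.camera)
    if sd_px > 0:
        grid += rng.normal(0.0, sd_px, size=grid.shape)

    thermal = ThermalFrame(grid=grid, camera_id=condition.camera,
                           meta={"subject_id": subject.subject_id,
                                 **asdict(condition)})

    # --- registration geometry: optical frame at 2x resolution, linked by a
    # known affine (optical -> thermal): scale 0.5 plus small rotation/shift
    phi = rng.uniform(-0.02, 0.02)
    shift = rng.uniform(-2.0, 2.0, size=2)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    affine = AffineMap(np.column_stack([0.5 * rot, shift]))
    inv = affine.inverse()

    x0, y0 = int(0.80 * w), int(0.06 * h)
    x1, y1 = int(0.95 * w), int(0.20 * h)
    fid_thermal = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)
    fid_optical = inv.apply(fid_thermal)

    angles = rng.uniform(0, 2 * pi) + np.linspace(0, 2 * pi, config.boundary_points,
                                                  endpoint=False)
    bpts_thermal = np.column_stack([
        roi.cx + roi.a * np.cos(angles) * np.cos(roi.theta)
        - roi.b * np.sin(angles) * np.sin(roi.theta),
        roi.cy + roi.a * np.cos(angles) * np.sin(roi.theta)
        + roi.b * np.sin(angles) * np.cos(roi.theta),
    ])
    bpts_optical = inv.apply(bpts_thermal)
    if config.boundary_jitter_px > 0:
        bpts_optical = bpts_optical + rng.normal(
            0.0, config.boundary_jitter_px, size=bpts_optical.shape)

    optical = None
    if render_optical_raster:
        optical = OpticalFrame(
            raster=_render_optical_raster(subject, roi, inv, fid_optical, (2 * h, 2 * w)),
            fiducials=fid_optical,
        )

    image_id = (f"{subject.subject_id}_{condition.camera}_{condition.phase}_"
                f"{condition.lighting}_{condition.distance_cm}_{condition.posture}")
    g = _global_offsets(condition, config)
    truth = {
        "roi_median_C": subject.baseline_skin_temp_C + g + drift + fluct_roi + amp,
        "control_median_C": base_level + g + drift + fluct_ctrl,
        "cooling_amplitude_C": amp,
    }
    return SimulatedImage(
        image_id=image_id, subject=subject, condition=condition, thermal=thermal,
        optical=optical, roi_true=roi, affine_true=affine,
        fiducials_optical=fid_optical, fiducials_thermal=fid_thermal,
        boundary_points_optical=bpts_optical, sticker_bbox=(x0, y0, x1, y1),
        truth=truth,
    )


_CATEGORY_RGB = {
    "Low": (234, 192, 160), "IntermediateLow": (210, 160, 125),
    "Intermediate": (185, 135, 100), "IntermediateMid": (140, 95, 65),
    "IntermediateHigh": (100, 65, 45), "High": (70, 45, 30),
}


def _render_optical_raster(subject, roi_thermal, inv_map, fid_optical, shape):
    """Simple skin-toned raster: drawn circle outline plus a white sticker."""
    h, w = shape
    raster = np.zeros((h, w, 3), dtype=np.uint8)
    raster[:] = _CATEGORY_RGB.get(subject.eumelanin_category, (160, 110, 80))
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    # drawn ellipse outline in optical coords: map pixel grid through the
    # forward affine and evaluate the thermal-space radius
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    fwd = inv_map.inverse()
    mapped = fwd.apply(pts)
    r = _elliptical_radius(mapped[:, 0].reshape(h, w), mapped[:, 1].reshape(h, w),
                           roi_thermal)
    outline = np.abs(r - 1.0) < 0.04
    raster[outline] = (30, 30, 30)
    fx0, fy0 = fid_optical.min(axis=0)
    fx1, fy1 = fid_optical.max(axis=0)
    sx0, sy0 = max(int(fx0), 0), max(int(fy0), 0)
    sx1, sy1 = min(int(fx1) + 1, w), min(int(fy1) + 1, h)
    raster[sy0:sy1, sx0:sx1] = (245, 245, 245)
    return raster


# --------------------------------------------------------------------------
# full study

def _subject_conditions() -> list[Condition]:
    conds = []
    for camera in CAMERAS:
        for phase in PHASES:
            for lighting, distance, posture in FACTOR_GRID:
                conds.append(Condition(camera, distance, lighting, posture, phase))
    return conds


class StudySimulation:
    """Lazy view over a complete simulated study (cohort + image stream)."""

    def __init__(self, config: GenerativeConfig):
        self.config = config
        self.cohort = sample_cohort(config)
        self.cohort_mean_melanin = float(
            np.mean([s.melanin_converted for s in self.cohort]))

    def iter_images(self, render_optical_raster: bool = False) -> Iterator[SimulatedImage]:
        conds = _subject_conditions()
        for si, subject in enumerate(self.cohort):
            for ii, cond in enumerate(conds):
                yield render_image_pair(
                    subject, cond, self.config,
                    image_index=ii, subject_index=si,
                    cohort_mean_melanin=self.cohort_mean_melanin,
                    render_optical_raster=render_optical_raster,
                )

    @property
    def n_images(self) -> int:
        return self.config.n_subjects * len(_subject_conditions())

    def manifest_row(self, img: SimulatedImage, thermal_path="", optical_path="") -> dict:
        c = img.condition
        return {
            "image_id": img.image_id,
            "subject_id": img.subject.subject_id,
            "camera": c.camera,
            "distance_cm": c.distance_cm,
            "lighting": c.lighting,
            "posture": c.posture,
            "phase": c.phase,
            "thermal_path": str(thermal_path),
            "optical_path": str(optical_path),
            "fiducials_optical": json.dumps(np.round(img.fiducials_optical, 6).tolist()),
            "fiducials_thermal": json.dumps(np.round(img.fiducials_thermal, 6).tolist()),
            "boundary_points_optical": json.dumps(
                np.round(img.boundary_points_optical, 6).tolist()),
            "sticker_bbox": json.dumps(list(img.sticker_bbox)),
        }


def simulate_study(config: GenerativeConfig) -> StudySimulation:
    return StudySimulation(config)


def generate_study(config: GenerativeConfig, outdir,
                   write_optical_rasters: bool = True) -> pd.DataFrame:
    """Materialize the full study to disk.

    Writes thermal TIFFs (and optical PNGs unless disabled), manifest.csv,
    colorimetry.csv, ground_truth.json and config.yaml under ``outdir`` and
    returns the manifest.
    """
    outdir = Path(outdir)
    frames_dir = outdir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    sim = StudySimulation(config)

    rows, truths = [], {}
    for img in sim.iter_images(render_optical_raster=write_optical_rasters):
        tpath = frames_dir / f"{img.image_id}_thermal.tif"
        try:
            write_thermal(img.thermal, tpath)
            opath = ""
            if write_optical_rasters and img.optical is not None:
                opath = frames_dir / f"{img.image_id}_optical.png"
                write_optical(img.optical.raster, opath)
        except OSError as exc:
            raise OSError(f"failed writing frame files for {img.image_id}: {exc}") from exc
        rows.append(sim.manifest_row(img, tpath, opath))
        truths[img.image_id] = {
            "roi": img.roi_true.to_dict(),
            **{k: round(v, 6) for k, v in img.truth.items()},
        }

    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    cohort_table(sim.cohort).to_csv(outdir / "colorimetry.csv", index=False)
    truth_payload = {
        "true_effects": sim.config.true_effects(),
        "cohort_mean_melanin": sim.cohort_mean_melanin,
        "images": truths,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth_payload, indent=1))
    config.to_yaml(outdir / "config.yaml")
    return manifest


# --------------------------------------------------------------------------
# measurement-level fast path

def simulate_measurements(config: GenerativeConfig) -> pd.DataFrame:
    """Sample the measurement table directly, bypassing image rendering.

    Shares the image path's additive effect structure and noise components;
    the pixel-median noise is approximated by its large-sample standard error
    (1.2533 * sigma / sqrt(n_pixels)). Used for simulation studies (type-I
    error, replicate coverage) where rendering every frame would dominate
    runtime without changing the statistics being checked.
    """
    sim = StudySimulation(config)
    conds = _subject_conditions()
    rows = []
    for si, subject in enumerate(sim.cohort):
        rng = _rng(config.rng_seed, _STREAM_MEASUREMENT, si)
        for ii, cond in enumerate(conds):
            preset = CAMERA_PRESETS[cond.camera]
            scale = DISTANCE_SCALE[cond.distance_cm]
            n_roi = pi * preset.roi_semi_major_px * preset.roi_semi_minor_px * scale**2
            sd_px = config.pixel_noise_sd(cond.camera)
            med_se_roi = 1.2533 * sd_px / np.sqrt(n_roi)
            med_se_ctrl = 1.2533 * sd_px / np.sqrt(n_roi / 16.0)

            g = _global_offsets(cond, config)
            drift = rng.normal(0.0, config.frame_drift_sd_C)
            fluct_roi = rng.normal(0.0, config.region_fluct_sd_C)
            fluct_ctrl = rng.normal(0.0, config.region_fluct_sd_C)
            amp = _cooling_amplitude(subject, cond, config, sim.cohort_mean_melanin)

            roi_med = (subject.baseline_skin_temp_C + g + drift + fluct_roi + amp
                       + rng.normal(0.0, med_se_roi))
            ctrl_med = (subject.baseline_skin_temp_C - subject.control_gap_C + g
                        + drift + fluct_ctrl + rng.normal(0.0, med_se_ctrl))
            image_id = (f"{subject.subject_id}_{cond.camera}_{cond.phase}_"
                        f"{cond.lighting}_{cond.distance_cm}_{cond.posture}")
            for region, value in (("roi", roi_med), ("control", ctrl_med)):
                rows.append({
                    "image_id": image_id,
                    "subject_id": subject.subject_id,
                    "camera": cond.camera,
                    "distance_cm": cond.distance_cm,
                    "lighting": cond.lighting,
                    "posture": cond.posture,
                    "phase": cond.phase,
                    "region": region,
                    "median_temp_C": value,
                    "melanin_raw": subject.melanin_raw,
                    "melanin_converted": subject.melanin_converted,
                })
    return pd.DataFrame(rows)
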