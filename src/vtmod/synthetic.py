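"""Synthetic rtMRI-like data with known ground truth.

The generator emulates the study conditions of a vocal size-exaggeration
experiment: midsagittal image series at 2.5 mm in-plane resolution with
static skull/vertebral structures and a labile air channel, acoustic
measurement tables consistent with a quarter-wave tube resonator whose
length is modulated per condition, and perception-rating tables with
listener and speaker random effects.  Every stage of the measurement
pipeline can therefore be validated against a recoverable target.

The vocal-tract template is a bent tube in the midsagittal plane: a
horizontal oral limb (lips at the left), a quarter-torus velar bend, and
a vertical pharyngeal limb ending at the glottis.  Five interpretable
shape parameters deform it:

* ``tongue_position`` slides a tongue-dorsum bulge along the oral limb
  (back vowel /a/ to front vowel /i/),
* ``larynx_height`` raises/lowers the glottal end (+-15 mm at full
  excursion), changing centreline length and nothing else,
* ``body_scale`` scales the whole tract about a fixed anatomical origin,
* ``tongue_shape`` changes the bulge amplitude,
* ``curvature`` shears the pharyngeal limb, bending the tract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from .acoustics import (
    AcousticTake,
    ConditionLabel,
    DomainError,
    build_stimulus_grid,
    enumerate_trials,
    quarter_wave_formants,
)
from .core import GeometryError, ImageFrame, ImageSeries, PixelMask, RigidTransform, VTOutline
from .fpca import ParametrizedCurve, resample_contour

# ---------------------------------------------------------------------------
# template geometry (mm, y down, origin at the top-left pixel centre)

LIP_X = 60.0
PALATE_Y = 54.0
TONGUE_Y = 66.0
BEND_CENTRE = (130.0, 90.0)
OUTER_R = 36.0
INNER_R = 24.0
CENTRELINE_R = 30.0
PHARYNX_ANT_X = 154.0
PHARYNX_POST_X = 166.0
GLOTTIS_Y0 = 150.0
MAX_LARYNX_EXCURSION_MM = 15.0
#: Fixed anatomical origin: the anterior arch of the atlas, behind the
#: velopharynx.  Anchoring the global scale here keeps the body-size
#: deformation mode near-orthogonal to the larynx and curvature modes.
ORIGIN = (160.0, 98.75)

TONGUE_BUMP_AMP = 3.5
TONGUE_TIP_AMP = 2.5
#: Coefficients of the odd tongue-shape pattern
#: (xi^5 + A xi^3 + B xi) exp(-xi^2).  An odd pattern preserves wall arc
#: length to first order (no spurious coupling into the larynx mode
#: through curve reparametrization), and these coefficients make the
#: resulting deformation mode numerically orthogonal to the
#: bump-translation and global-scale modes as well.
TONGUE_TIP_A = -1.9162
TONGUE_TIP_B = 0.5545
TONGUE_BUMP_SIGMA = 12.0
TONGUE_BUMP_CENTRE = 95.0
TONGUE_POSITION_GAIN = 20.0
CURVATURE_SHEAR = 0.15  # mm of x-shift per mm below the bend at |curvature| = 1

_POINT_SPACING = 1.5


@dataclass(frozen=True)
class ShapeParams:
    """Five-parameter description of a vocal-tract configuration.

    All-zero parameters with body_scale = 1 reproduce the template.
    """

    tongue_position: float = 0.0  # back (-1) .. front (+1)
    larynx_height: float = 0.0  # lowered (-1) .. raised (+1)
    body_scale: float = 1.0  # global isotropic scale about the palate landmark
    tongue_shape: float = 0.0
    curvature: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tongue_position", "larynx_height", "tongue_shape", "curvature"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise DomainError(f"{name} = {v} outside [-1, 1]")
        if self.body_scale <= 0:
            raise DomainError(f"body_scale = {self.body_scale} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.tongue_position,
                self.larynx_height,
                self.body_scale - 1.0,
                self.tongue_shape,
                self.curvature,
            ]
        )


PARAM_NAMES = ("tongue_position", "larynx_height", "body_scale", "tongue_shape", "curvature")


def _seg(p0, p1, include_end=False) -> np.ndarray:
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    n = max(int(math.ceil(np.hypot(*(p1 - p0)) / _POINT_SPACING)), 1)
    t = np.linspace(0.0, 1.0, n + 1)
    pts = p0 + t[:, None] * (p1 - p0)
    return pts if include_end else pts[:-1]


def _arc(centre, radius, a0_deg, a1_deg, include_end=False) -> np.ndarray:
    length = abs(math.radians(a1_deg - a0_deg)) * radius
    n = max(int(math.ceil(length / _POINT_SPACING)), 2)
    ang = np.radians(np.linspace(a0_deg, a1_deg, n + 1))
    pts = np.column_stack(
        [centre[0] + radius * np.cos(ang), centre[1] + radius * np.sin(ang)]
    )
    return pts if include_end else pts[:-1]


def _wall_down(x: float, y0: float, y1: float) -> np.ndarray:
    """Vertical wall sampled on a fixed grid anchored at y0, so shortening
    the larynx moves only the pharyngeal-end points."""
    ys = np.arange(y0, y1, _POINT_SPACING)
    ys = np.append(ys, y1) if ys.size == 0 or ys[-1] < y1 else ys
    return np.column_stack([np.full_like(ys, x), ys])


def _tongue_profile(x: np.ndarray, params: ShapeParams) -> np.ndarray:
    """y-coordinate of the tongue wall at oral positions x (template frame).

    ``tongue_shape`` adds an odd cubic-Hermite term to the dorsum bulge,
    skewing mass between the tongue tip and dorsum sides of the
    constriction without moving its centre or changing wall length.
    """
    centre = TONGUE_BUMP_CENTRE + TONGUE_POSITION_GAIN * params.tongue_position
    xi = (x - centre) / TONGUE_BUMP_SIGMA
    window = np.sin(np.pi * (x - LIP_X) / (BEND_CENTRE[0] - LIP_X)) ** 2
    gauss = np.exp(-(xi**2))
    tip = (xi**5 + TONGUE_TIP_A * xi**3 + TONGUE_TIP_B * xi) * gauss
    bump = (TONGUE_BUMP_AMP * gauss - TONGUE_TIP_AMP * params.tongue_shape * tip) * window
    return TONGUE_Y - bump


def glottis_y(params: ShapeParams) -> float:
    return GLOTTIS_Y0 - MAX_LARYNX_EXCURSION_MM * params.larynx_height


def _finish(pts: np.ndarray, params: ShapeParams) -> np.ndarray:
    """Apply the pharyngeal shear then the global scale about the origin."""
    pts = pts.copy()
    below = pts[:, 1] > BEND_CENTRE[1]
    pts[below, 0] += CURVATURE_SHEAR * params.curvature * (pts[below, 1] - BEND_CENTRE[1])
    origin = np.asarray(ORIGIN)
    return origin + params.body_scale * (pts - origin)


def _arc_displaced(centre, radius, a0_deg, a1_deg, bulge_mm: float) -> np.ndarray:
    """Arc with a radial displacement windowed to vanish at both ends."""
    length = abs(math.radians(a1_deg - a0_deg)) * radius
    n = max(int(math.ceil(length / _POINT_SPACING)), 2)
    ang = np.radians(np.linspace(a0_deg, a1_deg, n + 1))[:-1]
    frac = (np.degrees(ang) - a0_deg) / (a1_deg - a0_deg)
    r = radius + bulge_mm * np.sin(np.pi * frac)
    return np.column_stack([centre[0] + r * np.cos(ang), centre[1] + r * np.sin(ang)])


def make_vocal_tract_contour(
    params: ShapeParams = ShapeParams(),
    pharynx_sway_mm: float = 0.0,
    velum_mm: float = 0.0,
) -> VTOutline:
    """Closed air-channel contour from glottis to lips; deterministic in params.

    ``pharynx_sway_mm`` and ``velum_mm`` are nuisance articulatory degrees
    of freedom used by the session simulator: a lateral displacement of
    the pharyngeal limb (tongue-root/pharyngeal-wall motion, ramped in
    smoothly below the velar bend) and a radial displacement of the bend
    walls (velar movement, windowed to vanish at the junctions).  Neither
    is part of the five shape parameters.
    """
    yg = glottis_y(params)
    cx, cy = BEND_CENTRE
    parts = [
        _seg((LIP_X, PALATE_Y), (cx, PALATE_Y)),  # palate
        _arc_displaced((cx, cy), OUTER_R, -90.0, 0.0, velum_mm),  # outer velar bend
        _wall_down(PHARYNX_POST_X, cy, yg)[:-1],  # posterior pharyngeal wall
        _seg((PHARYNX_POST_X, yg), (PHARYNX_ANT_X, yg)),  # glottal cap
        _wall_down(PHARYNX_ANT_X, cy, yg)[::-1][:-1],  # anterior wall, upward
        _arc_displaced((cx, cy), INNER_R, 0.0, -90.0, velum_mm),  # inner velar bend
    ]
    # tongue wall with the dorsum bulge, lips-ward
    xs = np.arange(cx, LIP_X, -_POINT_SPACING)
    tongue = np.column_stack([xs, _tongue_profile(xs, params)])
    parts.append(tongue)
    parts.append(_seg((LIP_X, TONGUE_Y), (LIP_X, PALATE_Y)))  # lip cap
    pts = np.vstack(parts)
    if pharynx_sway_mm != 0.0:
        depth = np.clip((pts[:, 1] - BEND_CENTRE[1]) / 20.0, 0.0, 1.0)
        ramp = depth**2 * (3.0 - 2.0 * depth)  # smoothstep below the bend
        pts[:, 0] += pharynx_sway_mm * ramp
    pts = _finish(pts, params)
    return VTOutline(pts, closed=True)


def make_centerline(params: ShapeParams = ShapeParams()) -> np.ndarray:
    """Polyline along the tube axis from the lips to the glottal midpoint."""
    cx, cy = BEND_CENTRE
    mid_y = 0.5 * (PALATE_Y + TONGUE_Y)
    mid_x = 0.5 * (PHARYNX_ANT_X + PHARYNX_POST_X)
    parts = [
        _seg((LIP_X, mid_y), (cx, mid_y)),
        _arc((cx, cy), CENTRELINE_R, -90.0, 0.0),
        _seg((mid_x, cy), (mid_x, glottis_y(params)), include_end=True),
    ]
    return _finish(np.vstack(parts), params)


def centerline_length_mm(params: ShapeParams = ShapeParams()) -> float:
    """Closed-form tract length: oral limb + velar arc + (sheared) pharyngeal limb."""
    oral = BEND_CENTRE[0] - LIP_X
    arc = math.pi / 2.0 * CENTRELINE_R
    limb = (glottis_y(params) - BEND_CENTRE[1]) * math.hypot(
        1.0, CURVATURE_SHEAR * params.curvature
    )
    return params.body_scale * (oral + arc + limb)


def true_vtl_cm(params: ShapeParams = ShapeParams()) -> float:
    return centerline_length_mm(params) / 10.0


# ---------------------------------------------------------------------------
# rendering


@dataclass(frozen=True)
class FrameGeometry:
    """Field-of-view and intensity configuration of the synthetic scanner."""

    shape: tuple[int, int] = (110, 88)  # rows, cols
    pixel_size_mm: float = 2.5
    frame_rate_hz: float = 8.0
    background: float = 25.0
    tissue: float = 200.0
    air: float = 12.0
    skull: float = 245.0
    head_centre: tuple[float, float] = (120.0, 120.0)
    head_axes: tuple[float, float] = (95.0, 105.0)
    #: (x_mm, y_mm, amplitude, sigma_mm) of vertebral and cranial blobs;
    #: irregular spacing, amplitude and width make the static texture
    #: aperiodic, so the registration metric has no false optima where a
    #: shifted/rotated blob row re-aligns with itself
    blobs: tuple = (
        (192.0, 78.0, 55.0, 6.5),
        (193.0, 104.0, 40.0, 5.0),
        (191.0, 127.0, 62.0, 7.5),
        (192.0, 156.0, 45.0, 5.5),
        (60.0, 45.0, 52.0, 6.0),
        (100.0, 30.0, 38.0, 5.0),
    )

    @property
    def fov_mm(self) -> tuple[float, float]:
        return (
            (self.shape[1] - 1) * self.pixel_size_mm,
            (self.shape[0] - 1) * self.pixel_size_mm,
        )


DEFAULT_GEOMETRY = FrameGeometry()


def _scene(x: np.ndarray, y: np.ndarray, outline: VTOutline, geom: FrameGeometry) -> np.ndarray:
    """Noiseless intensity at reference-space coordinates (x, y) in mm.

    Static structures have smooth (sigmoid) edges, emulating the scanner
    point-spread function and keeping the image band-limited where the
    registration metric samples it; the air channel itself stays crisp,
    as the air-tissue contrast is the segmentation signal.
    """
    from scipy.special import expit

    w = 1.5  # edge softness, mm
    hx, hy = geom.head_centre
    ax, ay = geom.head_axes
    rho = np.sqrt(((x - hx) / ax) ** 2 + ((y - hy) / ay) ** 2)
    scale = 0.5 * (ax + ay)  # convert radial units to ~mm
    head_s = expit((1.0 - rho) * scale / w)
    img = geom.background + (geom.tissue - geom.background) * head_s
    band_s = head_s * expit((rho - 0.86) * scale / w) * expit((100.0 - y) / w)
    img += (geom.skull - geom.tissue) * band_s
    for bx, by, amp, sigma in geom.blobs:
        img += amp * np.exp(-((x - bx) ** 2 + (y - by) ** 2) / (2.0 * sigma**2))
    path = MplPath(np.vstack([outline.points, outline.points[:1]]), closed=True)
    inside = path.contains_points(np.column_stack([x.ravel(), y.ravel()])).reshape(x.shape)
    img[inside] = geom.air
    return img


def render_frame(
    outline: VTOutline,
    rigid: RigidTransform = RigidTransform(),
    noise_sd: float = 0.0,
    seed: int = 0,
    geometry: FrameGeometry = DEFAULT_GEOMETRY,
    supersample: int = 3,
) -> ImageFrame:
    """Rasterize one midsagittal frame with the head moved by ``rigid``.

    The scene (head, skull arc, vertebral blobs, air channel) is sampled at
    the inverse-transformed pixel positions with ``supersample``^2 sub-pixel
    averaging, so moving content by a rigid transform is exact.  Additive
    Gaussian noise is drawn from the given seed.
    """
    fx, fy = geometry.fov_mm
    moved = rigid.apply_points(
        outline.points, pivot=(fx / 2.0, fy / 2.0)
    )
    if (
        moved[:, 0].min() < 0
        or moved[:, 1].min() < 0
        or moved[:, 0].max() > fx
        or moved[:, 1].max() > fy
    ):
        raise GeometryError("outline exits the field of view after transform")
    nr, nc = geometry.shape
    px = geometry.pixel_size_mm
    offsets = (np.arange(supersample) + 0.5) / supersample - 0.5
    acc = np.zeros((nr, nc))
    inv = rigid.inverse()
    pivot = np.array([fx / 2.0, fy / 2.0])
    R = inv.matrix()
    t = np.asarray(inv.translation_mm)
    for oy in offsets:
        for ox in offsets:
            xs = (np.arange(nc) + ox) * px
            ys = (np.arange(nr) + oy) * px
            X, Y = np.meshgrid(xs, ys)
            P = np.stack([X, Y], axis=-1) - pivot
            Q = P @ R.T + pivot + t
            acc += _scene(Q[..., 0], Q[..., 1], outline, geometry)
    img = acc / supersample**2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return ImageFrame(img, px)


def rasterize_air_mask(
    outline: VTOutline, geometry: FrameGeometry = DEFAULT_GEOMETRY
) -> np.ndarray:
    """Ground-truth air mask: pixel centres inside the outline (reference pose)."""
    nr, nc = geometry.shape
    px = geometry.pixel_size_mm
    X, Y = np.meshgrid(np.arange(nc) * px, np.arange(nr) * px)
    path = MplPath(np.vstack([outline.points, outline.points[:1]]), closed=True)
    return path.contains_points(np.column_stack([X.ravel(), Y.ravel()])).reshape(nr, nc)


def static_structure_mask(geometry: FrameGeometry = DEFAULT_GEOMETRY) -> PixelMask:
    """Skull band and vertebral blobs, minus the envelope that the labile
    tract can ever occupy (so registration never sees vocal-tract pixels)."""
    nr, nc = geometry.shape
    px = geometry.pixel_size_mm
    X, Y = np.meshgrid(np.arange(nc) * px, np.arange(nr) * px)
    hx, hy = geometry.head_centre
    ax, ay = geometry.head_axes
    rho2 = ((X - hx) / ax) ** 2 + ((Y - hy) / ay) ** 2
    mask = (rho2 <= 1.0) & (rho2 >= 0.86**2) & (Y < 100.0)
    for bx, by, _, sigma in geometry.blobs:
        mask |= (X - bx) ** 2 + (Y - by) ** 2 <= (2.0 * sigma) ** 2
    tract_envelope = (X > 40.0) & (X < 185.0) & (Y > 42.0) & (Y < 215.0)
    return PixelMask(mask & ~tract_envelope, kind="static_structures")


def reference_frame(geometry: FrameGeometry = DEFAULT_GEOMETRY) -> ImageFrame:
    """The single representative registration target: template pose, no noise."""
    return render_frame(make_vocal_tract_contour(), geometry=geometry)


# ---------------------------------------------------------------------------
# speakers and imaging sessions


@dataclass
class SpeakerProfile:
    """Between-speaker variation: anatomy, skill, and noise levels."""

    speaker_id: str
    sex: str = "female"  # {male, female}
    singer: bool = False
    baseline_params: ShapeParams = field(default_factory=ShapeParams)
    modulation_amplitude: float = 0.5  # larynx excursion used for small/large targets
    baseline_f0_hz: float = 210.0
    baseline_vtl_cm: float = 14.5
    frame_noise_sd: float = 5.0
    trial_jitter_sd: float = 0.05  # trial-to-trial larynx variability (exposed, not fixed)
    # per-frame articulatory variability (roughly 1-2 mm of boundary
    # motion); keeps the whole air-tissue boundary labile, as continuous
    # speech does
    tongue_jitter_sd: float = 0.08
    scale_jitter_sd: float = 0.03
    curvature_jitter_sd: float = 0.10
    pharynx_sway_sd_mm: float = 1.5
    velum_sd_mm: float = 1.5
    acoustic_fidelity: float = 1.0  # fraction of the target formant ratio achieved
    f0_fidelity: float = 1.0
    vtl_jitter_cv: float = 0.01

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DomainError("sex must be 'male' or 'female'")
        if self.baseline_vtl_cm <= 0:
            raise DomainError("baseline_vtl_cm must be positive")
        if self.modulation_amplitude < 0:
            raise DomainError("modulation_amplitude must be >= 0")
        h = self.baseline_params.larynx_height
        if abs(h) + self.modulation_amplitude > 1.0 + 1e-12:
            raise DomainError(
                "modulation_amplitude drives larynx_height outside [-1, 1]"
            )


@dataclass
class TrialDesign:
    """The imaging trial list: which (word, condition) cells, how often."""

    trials: pd.DataFrame  # columns word, f0_shift_st, vtl_shift_st, vt_condition
    frames_per_trial: int = 2

    @classmethod
    def rtmri(cls, n_trials_per_condition: int | None = None, frames_per_trial: int = 2) -> "TrialDesign":
        """The scanner design: 10 word-conditions x 40 trials by default."""
        t = enumerate_trials("rtmri")
        if n_trials_per_condition is not None:
            t = (
                t.groupby(["word", "f0_shift_st", "vtl_shift_st"], sort=False)
                .head(n_trials_per_condition)
                .reset_index(drop=True)
            )
        return cls(t, frames_per_trial=frames_per_trial)

    def __post_init__(self) -> None:
        for _, row in self.trials.iterrows():
            ConditionLabel(int(row.f0_shift_st), int(row.vtl_shift_st))  # validates


@dataclass
class GroundTruth:
    """Per-frame and per-take truth recorded during simulation."""

    frames: pd.DataFrame
    outlines: dict[int, VTOutline]
    takes: pd.DataFrame

    @classmethod
    def concat(cls, parts: Sequence["GroundTruth"]) -> "GroundTruth":
        outlines: dict[int, VTOutline] = {}
        for p in parts:
            outlines.update(p.outlines)
        return cls(
            frames=pd.concat([p.frames for p in parts], ignore_index=True),
            outlines=outlines,
            takes=pd.concat([p.takes for p in parts], ignore_index=True),
        )


#: Carrier-word articulation: bead is a front vowel, bard a back vowel.
WORD_TONGUE_POSITION = {"bead": 0.45, "bard": -0.45}


def _condition_params(
    profile: SpeakerProfile, word: str, vt_condition: str, larynx_jitter: float
) -> ShapeParams:
    h = profile.baseline_params.larynx_height
    if vt_condition == "small":
        h = h + profile.modulation_amplitude
    elif vt_condition == "large":
        h = h - profile.modulation_amplitude
    h = float(np.clip(h + larynx_jitter, -1.0, 1.0))
    tp = float(
        np.clip(
            profile.baseline_params.tongue_position + WORD_TONGUE_POSITION.get(word, 0.0),
            -1.0,
            1.0,
        )
    )
    return replace(profile.baseline_params, larynx_height=h, tongue_position=tp)


def _frame_jitter(params: ShapeParams, profile: SpeakerProfile, rng: np.random.Generator) -> ShapeParams:
    return replace(
        params,
        tongue_position=float(
            np.clip(params.tongue_position + rng.normal(0.0, profile.tongue_jitter_sd), -1, 1)
        ),
        body_scale=float(
            params.body_scale * (1.0 + rng.normal(0.0, profile.scale_jitter_sd))
        ),
        curvature=float(
            np.clip(params.curvature + rng.normal(0.0, profile.curvature_jitter_sd), -1, 1)
        ),
    )


def simulate_speaker_session(
    profile: SpeakerProfile,
    design: TrialDesign,
    seed: int = 0,
    geometry: FrameGeometry = DEFAULT_GEOMETRY,
    motion_rot_sd_deg: float = 0.3,
    motion_trans_sd_mm: float = 0.8,
    frame_index_start: int = 0,
) -> tuple[ImageSeries, GroundTruth]:
    """Render one speaker's imaging session with per-frame head motion.

    Small-voice trials raise the larynx by the speaker's modulation
    amplitude, large-voice trials lower it; each trial adds larynx jitter
    and each frame a small random rigid head motion, all recorded in the
    ground truth.
    """
    rng = np.random.default_rng(seed)
    frames: list[ImageFrame] = []
    rows = []
    take_rows = []
    outlines: dict[int, VTOutline] = {}
    idx = frame_index_start
    for trial_no, row in enumerate(design.trials.itertuples()):
        jitter = rng.normal(0.0, profile.trial_jitter_sd)
        trial_params = _condition_params(profile, row.word, row.vt_condition, jitter)
        take_rows.append(
            {
                "speaker_id": profile.speaker_id,
                "word": row.word,
                "f0_shift_st": row.f0_shift_st,
                "vtl_shift_st": row.vtl_shift_st,
                "vt_condition": row.vt_condition,
                "trial": trial_no,
                "true_vtl_cm": true_vtl_cm(trial_params),
            }
        )
        for _ in range(design.frames_per_trial):
            params = _frame_jitter(trial_params, profile, rng)
            sway = float(rng.normal(0.0, profile.pharynx_sway_sd_mm))
            velum = float(rng.normal(0.0, profile.velum_sd_mm))
            outline = make_vocal_tract_contour(
                params, pharynx_sway_mm=sway, velum_mm=velum
            )
            motion = RigidTransform(
                float(np.clip(rng.normal(0.0, motion_rot_sd_deg), -8.0, 8.0)),
                (
                    float(np.clip(rng.normal(0.0, motion_trans_sd_mm), -10.0, 10.0)),
                    float(np.clip(rng.normal(0.0, motion_trans_sd_mm), -10.0, 10.0)),
                ),
            )
            frame = render_frame(
                outline,
                rigid=motion,
                noise_sd=profile.frame_noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                geometry=geometry,
            )
            frame.frame_index = idx
            frame.speaker_id = profile.speaker_id
            frame.word = row.word
            frame.vt_condition = row.vt_condition
            frames.append(frame)
            outlines[idx] = VTOutline(
                outline.points.copy(), closed=True, frame_index=idx
            )
            rows.append(
                {
                    "frame_index": idx,
                    "speaker_id": profile.speaker_id,
                    "word": row.word,
                    "f0_shift_st": row.f0_shift_st,
                    "vtl_shift_st": row.vtl_shift_st,
                    "vt_condition": row.vt_condition,
                    "trial": trial_no,
                    "tongue_position": params.tongue_position,
                    "larynx_height": params.larynx_height,
                    "body_scale": params.body_scale,
                    "tongue_shape": params.tongue_shape,
                    "curvature": params.curvature,
                    "pharynx_sway_mm": sway,
                    "velum_mm": velum,
                    "motion_rot_deg": motion.rotation_deg,
                    "motion_tx_mm": motion.translation_mm[0],
                    "motion_ty_mm": motion.translation_mm[1],
                    "true_vtl_cm": true_vtl_cm(params),
                }
            )
            idx += 1
    gt = GroundTruth(
        frames=pd.DataFrame(rows), outlines=outlines, takes=pd.DataFrame(take_rows)
    )
    return ImageSeries(frames), gt


# ---------------------------------------------------------------------------
# acoustics

WORD_COLORING = {"bard": (1.40, 0.75, 1.0, 1.0), "bead": (0.55, 1.45, 1.0, 1.0)}


def simulate_formants(
    true_vtl_cm: float,
    word: str = "bard",
    f0_hz: float = 210.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    coloring: bool = True,
    speaker_id: str = "",
    condition: ConditionLabel = ConditionLabel(),
    take_index: int = 0,
) -> AcousticTake:
    """Formant table of a quarter-wave tube of the given length.

    F_i = (2i-1) c / (4 L), optionally multiplied by a fixed word-specific
    coloring vector (bard raises F1 and lowers F2, bead the reverse) and by
    i.i.d. lognormal noise with coefficient of variation ``noise_cv``.
    """
    if true_vtl_cm <= 0:
        raise DomainError("tube length must be positive")
    f = quarter_wave_formants(true_vtl_cm)
    if coloring:
        f = f * np.asarray(WORD_COLORING[word])
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        f = f * rng.lognormal(-(sigma**2) / 2.0, sigma, size=4)
    return AcousticTake(
        speaker_id=speaker_id,
        word=word,
        condition=condition,
        take_index=take_index,
        f0_hz=f0_hz,
        f1_hz=float(f[0]),
        f2_hz=float(f[1]),
        f3_hz=float(f[2]),
        f4_hz=float(f[3]),
    )


def simulate_acoustic_session(
    profile: SpeakerProfile,
    session: str = "full",
    n_takes: int = 5,
    noise_cv: float = 0.02,
    seed: int = 0,
    coloring: bool = True,
) -> tuple[list[AcousticTake], pd.DataFrame]:
    """Acoustic takes for every grid cell, with imperfect target imitation.

    A speaker with acoustic fidelity phi achieves the fraction phi of each
    target's formant ratio: the realized tract length is
    L = baseline_vtl * 2^(-phi * vtl_shift / 12).
    """
    rng = np.random.default_rng(seed)
    takes: list[AcousticTake] = []
    rows = []
    for word in ("bead", "bard"):
        for cond in build_stimulus_grid(session):
            for k in range(n_takes):
                vtl = profile.baseline_vtl_cm * 2.0 ** (
                    -profile.acoustic_fidelity * cond.vtl_shift_st / 12.0
                )
                if profile.vtl_jitter_cv > 0:
                    sig = math.sqrt(math.log(1.0 + profile.vtl_jitter_cv**2))
                    vtl *= rng.lognormal(-(sig**2) / 2.0, sig)
                f0 = profile.baseline_f0_hz * 2.0 ** (
                    (2.0 + profile.f0_fidelity * cond.f0_shift_st) / 12.0
                )
                if noise_cv > 0:
                    sig0 = math.sqrt(math.log(1.0 + noise_cv**2))
                    f0 *= rng.lognormal(-(sig0**2) / 2.0, sig0)
                take = simulate_formants(
                    vtl,
                    word=word,
                    f0_hz=f0,
                    noise_cv=noise_cv,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    coloring=coloring,
                    speaker_id=profile.speaker_id,
                    condition=cond,
                    take_index=k,
                )
                takes.append(take)
                rows.append(
                    {
                        "speaker_id": profile.speaker_id,
                        "word": word,
                        "f0_shift_st": cond.f0_shift_st,
                        "vtl_shift_st": cond.vtl_shift_st,
                        "take_index": k,
                        "true_vtl_cm": vtl,
                    }
                )
    return takes, pd.DataFrame(rows)


def make_cohort(
    n_speakers: int = 20,
    seed: int = 0,
    sexes: Sequence[str] = ("female", "male"),
    skill_noise_sd: float = 0.1,
) -> list[SpeakerProfile]:
    """A graded cohort: modulation amplitude spans nearly incapable to nearly
    perfect, and acoustic fidelity follows the same latent skill with noise."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_speakers):
        sex = sexes[i % len(sexes)]
        skill = 0.05 + 0.9 * i / max(n_speakers - 1, 1)
        fidelity = float(np.clip(skill + rng.normal(0.0, skill_noise_sd), 0.0, 1.0))
        # pitch-matching ability is largely independent of tract modulation skill
        f0_fid = float(rng.uniform(0.4, 1.0))
        profiles.append(
            SpeakerProfile(
                speaker_id=f"spk{i:02d}",
                sex=sex,
                singer=bool(i % 3 == 0),
                baseline_params=ShapeParams(
                    tongue_position=float(rng.uniform(-0.2, 0.2)),
                    larynx_height=float(rng.uniform(-0.05, 0.05)) * 0.0,
                    body_scale=float(rng.uniform(0.95, 1.05))
                    * (1.08 if sex == "male" else 0.97),
                ),
                modulation_amplitude=float(skill),
                baseline_f0_hz=120.0 if sex == "male" else 210.0,
                baseline_vtl_cm=17.0 if sex == "male" else 14.5,
                acoustic_fidelity=fidelity,
                f0_fidelity=f0_fid,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# planted shape modes


def shape_mode_curves(n_points: int = 100, delta: float = 0.05) -> np.ndarray:
    """Central-difference deformation modes of the five parameters, evaluated
    on resampled contours; shape (5, n_points, 2), units mm per unit parameter."""
    modes = []
    for i in range(5):
        z = np.zeros(5)
        z[i] = delta
        plus = resample_contour(make_vocal_tract_contour(_params_from_z(z)), n_points)
        minus = resample_contour(make_vocal_tract_contour(_params_from_z(-z)), n_points)
        modes.append((plus.points - minus.points) / (2.0 * delta))
    return np.stack(modes)


def _params_from_z(z: Sequence[float]) -> ShapeParams:
    return ShapeParams(
        tongue_position=float(z[0]),
        larynx_height=float(z[1]),
        body_scale=1.0 + float(z[2]),
        tongue_shape=float(z[3]),
        curvature=float(z[4]),
    )


DEFAULT_VARIANCE_SHARES = (0.41, 0.34, 0.09, 0.08, 0.03)


def _mode_family_variance(i: int, sd: float, n_points: int) -> float:
    """Total curve variance (trace of the covariance) of the one-parameter
    family z_i ~ N(0, sd), by Gauss-Hermite quadrature.  Captures the
    nonlinear excess that a linearized mode norm would miss."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(9)
    w = weights / weights.sum()
    z = np.zeros((len(nodes), 5))
    z[:, i] = np.clip(nodes * sd, -0.95, 0.95)
    X = np.stack(
        [
            resample_contour(make_vocal_tract_contour(_params_from_z(zk)), n_points)
            .points.reshape(-1)
            for zk in z
        ]
    )
    mean = w @ X
    return float(w @ ((X - mean) ** 2).sum(axis=1))


def _calibrated_param_sd(
    shares: tuple, n_points: int, spread: float, n_iter: int = 2
) -> np.ndarray:
    return _calibrated_param_sd_cached(tuple(shares), n_points, spread, n_iter).copy()


from functools import lru_cache


@lru_cache(maxsize=8)
def _calibrated_param_sd_cached(
    shares: tuple, n_points: int, spread: float, n_iter: int
) -> np.ndarray:
    """Parameter SDs that realize the requested variance shares.

    Starts from the linearized mode norms and rescales each SD by the
    measured single-mode variance; ``spread`` caps 3 sigma of the widest
    parameter and keeps the deformation map in its near-linear regime.
    """
    shares_arr = np.asarray(shares, float)
    modes = shape_mode_curves(n_points)
    norms = np.linalg.norm(modes.reshape(5, -1), axis=1)
    sd = np.sqrt(shares_arr) / norms
    sd *= spread / (3.0 * sd.max())
    for _ in range(n_iter):
        realized = np.array(
            [_mode_family_variance(i, sd[i], n_points) for i in range(5)]
        )
        target = shares_arr / shares_arr.sum() * realized.sum()
        sd = sd * np.sqrt(target / realized)
        sd *= min(1.0, spread / (3.0 * sd.max()))
    return sd


def sample_shape_dataset(
    n_curves: int = 500,
    shares: Sequence[float] = DEFAULT_VARIANCE_SHARES,
    seed: int = 0,
    n_points: int = 100,
    spread: float = 0.25,
) -> tuple[np.ndarray, list[ParametrizedCurve], np.ndarray]:
    """Contours whose shape variance is split across the five planted modes.

    Parameter standard deviations are calibrated so that mode i
    contributes the fraction ``shares[i]`` of total curve variance;
    ``spread`` caps 3 sigma of the widest parameter and its default keeps
    the deformation map in the near-linear regime where the planted
    decomposition is recoverable.
    Returns (z parameters (n, 5), resampled curves, parameter SDs).
    """
    shares = np.asarray(shares, float)
    sd = _calibrated_param_sd(shares, n_points, spread)
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, 1.0, size=(n_curves, 5))
    # Exact empirical decorrelation (a standard variance-reduction device):
    # the drawn scores have sample covariance diag(sd^2) exactly, so the
    # planted variance split is realized at finite n instead of only in
    # expectation, and nearly-equal shares stay distinguishable.
    z = z - z.mean(axis=0)
    L = np.linalg.cholesky(np.cov(z.T, bias=False))
    z = z @ np.linalg.inv(L).T * sd
    z = np.clip(z, -0.95, 0.95)
    curves = [
        resample_contour(
            make_vocal_tract_contour(_params_from_z(zi)), n_points, labels={"row": k}
        )
        for k, zi in enumerate(z)
    ]
    return z, curves, sd


def canonical_deformations(n_points: int = 100) -> dict[str, np.ndarray]:
    """Reference deformations for fixing component signs: ``shorten`` is the
    raised-larynx (smaller tract) direction, ``front`` the tongue-fronting one."""
    modes = shape_mode_curves(n_points)
    return {
        "front": modes[0],
        "shorten": modes[1],
        "grow": modes[2],
        "bunch": modes[3],
        "bend": modes[4],
    }


# ---------------------------------------------------------------------------
# perception ratings

SLIDER_RANGE_CM = {"female": (145.0, 180.0), "male": (155.0, 190.0)}


@dataclass
class RatingEffects:
    """Generative parameters of the perceived-height rating model (cm)."""

    grand_mean_cm: dict = field(
        default_factory=lambda: {"female": 162.5, "male": 172.5}
    )
    vt_effect_cm: dict = field(
        default_factory=lambda: {"small": -3.0, "baseline": 0.0, "large": 3.0}
    )
    f0_slope_cm_per_st: float = -0.4
    vt_f0_interaction_cm_per_st: dict = field(
        default_factory=lambda: {"small": 0.25, "baseline": 0.0, "large": 0.25}
    )
    skill_group_effect_cm: dict = field(
        default_factory=lambda: {"good": 0.0, "poor": 0.0}
    )
    skill_vt_gain: float = 1.5  # vt effect multiplier for good modulators
    sex_vt_gain: dict = field(default_factory=lambda: {"female": 1.0, "male": 1.0})
    listener_sd_cm: float = 2.0
    speaker_intercept_sd_cm: float = 1.5
    speaker_f0_slope_sd: float = 0.08
    speaker_vt_slope_sd_cm: float = 0.5
    residual_sd_cm: float = 3.0

    @classmethod
    def null(cls, grand_mean: float = 165.0) -> "RatingEffects":
        return cls(
            grand_mean_cm={"female": grand_mean, "male": grand_mean},
            vt_effect_cm={"small": 0.0, "baseline": 0.0, "large": 0.0},
            f0_slope_cm_per_st=0.0,
            vt_f0_interaction_cm_per_st={"small": 0.0, "baseline": 0.0, "large": 0.0},
            skill_vt_gain=1.0,
            listener_sd_cm=0.0,
            speaker_intercept_sd_cm=0.0,
            speaker_f0_slope_sd=0.0,
            speaker_vt_slope_sd_cm=0.0,
            residual_sd_cm=0.0,
        )

    def cell_mean(self, sex: str, group: str, vt: str, f0_st: float) -> float:
        gain = self.skill_vt_gain if group == "good" else 1.0
        return (
            self.grand_mean_cm[sex]
            + gain * self.sex_vt_gain[sex] * self.vt_effect_cm[vt]
            + self.f0_slope_cm_per_st * f0_st
            + self.vt_f0_interaction_cm_per_st[vt] * f0_st
            + self.skill_group_effect_cm.get(group, 0.0)
        )


_VT_SLOPE_CODE = {"small": 1.0, "baseline": 0.0, "large": -1.0}


def simulate_perception_ratings(
    stimuli: pd.DataFrame,
    effects: RatingEffects,
    n_listeners: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Rating trials for every (listener, stimulus) pair.

    Listeners are split evenly over the voice sexes present (each listener
    rates one sex only); ratings are the fixed-effect cell mean plus
    listener and speaker random effects and residual noise, clipped to the
    sex-specific slider range.
    """
    if n_listeners < 1:
        raise ValueError("n_listeners must be >= 1")
    required = {"speaker_id", "voice_sex", "skill_group", "vt_condition", "f0_modulation_st"}
    missing = required - set(stimuli.columns)
    if missing:
        raise KeyError(f"stimulus table missing columns: {sorted(missing)}")
    for vt in stimuli["vt_condition"].unique():
        if vt not in effects.vt_effect_cm:
            raise KeyError(f"effect table has no vt_condition term {vt!r}")
    rng = np.random.default_rng(seed)
    sexes = sorted(stimuli["voice_sex"].unique())
    speakers = sorted(stimuli["speaker_id"].unique())
    sp_int = dict(zip(speakers, rng.normal(0.0, effects.speaker_intercept_sd_cm, len(speakers))))
    sp_f0 = dict(zip(speakers, rng.normal(0.0, effects.speaker_f0_slope_sd, len(speakers))))
    sp_vt = dict(zip(speakers, rng.normal(0.0, effects.speaker_vt_slope_sd_cm, len(speakers))))
    rows = []
    for li in range(n_listeners):
        sex = sexes[li % len(sexes)]
        intercept = rng.normal(0.0, effects.listener_sd_cm)
        sub = stimuli[stimuli["voice_sex"] == sex]
        for s in sub.itertuples():
            mu = effects.cell_mean(
                s.voice_sex, s.skill_group, s.vt_condition, s.f0_modulation_st
            )
            val = (
                mu
                + intercept
                + sp_int[s.speaker_id]
                + sp_f0[s.speaker_id] * s.f0_modulation_st
                + sp_vt[s.speaker_id] * _VT_SLOPE_CODE[s.vt_condition]
                + rng.normal(0.0, effects.residual_sd_cm)
            )
            lo, hi = SLIDER_RANGE_CM[s.voice_sex]
            rows.append(
                {
                    "listener_id": f"lsn{li:03d}",
                    "voice_sex": s.voice_sex,
                    "speaker_id": s.speaker_id,
                    "skill_group": s.skill_group,
                    "word": getattr(s, "word", ""),
                    "vt_condition": s.vt_condition,
                    "f0_modulation_st": float(s.f0_modulation_st),
                    "rating_cm": float(np.clip(val, lo, hi)),
                }
            )
    return pd.DataFrame(rows)
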