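"""Synthetic fundus-like images and cohorts with exact ground truth.

The generator emulates the features the measurement chain depends on: a
bright, smoothly uneven, noise-textured background; a brighter quasi-circular
optic disc; dark vessels of known width drawn along parametric (sinusoidal)
centerlines; an optional recursive branching tree of known depth; and
optional bright/dark lesion blobs (exudate / hemorrhage analogues). Every
drawn quantity — centerline coordinates, width, sinusoid amplitude/periods/
chord, disc geometry, branching depth, lesion mask — is returned as ground
truth so each measurement module can be validated against construction.

Vessels are rendered with an anti-aliased edge whose 50% level sits exactly
at the drawn half-width, so re-thresholding recovers the drawn width exactly
for odd integer widths (an odd-width vessel has a well-defined single-pixel
midline; generator defaults therefore use odd widths).

Cohorts are simulated at the index level with a matched-pairs
variance-components model (see :func:`generate_cohort`); per-subject image
specs can be derived for end-to-end integration runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ContractError, ParameterError
from .io import FundusImage, SegmentAnnotation

__all__ = [
    "VesselSpec",
    "LesionSpec",
    "SyntheticSpec",
    "GroundTruth",
    "EffectSizes",
    "default_image_spec",
    "generate",
    "generate_cohort",
    "subject_image_spec",
]


@dataclass(frozen=True)
class VesselSpec:
    """One parametric vessel: a sinusoid about a straight baseline.

    The centerline is p(t) = start + t*u + A*sin(2*pi*k*t/L)*n for t in
    [0, L], with u the unit vector at ``orientation_deg`` (degrees,
    measured from the +col axis toward +row) and n its left normal.
    """

    vessel_id: str
    vessel_class: str           # "arteriole" | "venule" | "branch"
    start: tuple[float, float]  # (row, col)
    orientation_deg: float
    chord: float                # L, px
    amplitude: float = 0.0      # A, px
    periods: float = 0.0        # k
    width: float = 9.0          # drawn width, px (odd integers are exact)

    def centerline(self, step: float = 0.5) -> np.ndarray:
        t = np.arange(0.0, self.chord + step / 2, step)
        theta = math.radians(self.orientation_deg)
        u = np.array([math.sin(theta), math.cos(theta)])
        n = np.array([math.cos(theta), -math.sin(theta)])
        dev = self.amplitude * np.sin(2 * np.pi * self.periods * t / self.chord) \
            if self.periods > 0 else np.zeros_like(t)
        return np.asarray(self.start, float) + t[:, None] * u + dev[:, None] * n


@dataclass(frozen=True)
class LesionSpec:
    center: tuple[float, float]
    radius: float
    polarity: str = "bright"    # "bright" (exudate) | "dark" (hemorrhage)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic fundus image."""

    shape: tuple[int, int] = (480, 480)
    disc_center: tuple[float, float] = (240.0, 120.0)
    disc_radius: float = 40.0
    disc_brightness: float = 45.0
    vessels: tuple[VesselSpec, ...] = ()
    branching_depth: int = 0
    lesions: tuple[LesionSpec, ...] = ()
    background_mean: float = 150.0
    background_gradient: float = 20.0
    background_noise_sd: float = 4.0
    vessel_depth: float = 70.0
    seed: int = 0

    def validate(self) -> None:
        H, W = self.shape
        if self.disc_radius <= 0:
            raise ParameterError("disc_radius must be positive")
        for v in self.vessels:
            if v.width < 2:
                raise ParameterError(f"vessel {v.vessel_id}: width must be >= 2 px")
            pts = v.centerline()
            margin = v.width / 2 + 1
            if (pts[:, 0].min() < margin or pts[:, 0].max() > H - margin
                    or pts[:, 1].min() < margin or pts[:, 1].max() > W - margin):
                raise ParameterError(
                    f"vessel {v.vessel_id} leaves the {H}x{W} image")


@dataclass
class GroundTruth:
    """Everything the generator drew, for validating the measurement chain."""

    centerlines: dict[str, np.ndarray]
    widths: dict[str, float]
    vessel_classes: dict[str, str]
    tortuosity_params: dict[str, tuple[float, float, float]]  # (A, k, L)
    disc_center: tuple[float, float]
    disc_radius: float
    lesion_mask: np.ndarray
    branching_depth: int
    annotations: list[SegmentAnnotation] = field(default_factory=list)


def _branch_tree(spec: SyntheticSpec, rng: np.random.Generator) -> list[VesselSpec]:
    """Recursive binary tree growing rightward from the disc edge."""
    vessels: list[VesselSpec] = []
    H, W = spec.shape

    def grow(start, angle, length, width, level, tag):
        if level >= spec.branching_depth or length < 9 or width < 3:
            return
        v = VesselSpec(
            vessel_id=f"tree_{tag}", vessel_class="branch",
            start=tuple(start), orientation_deg=angle, chord=length,
            amplitude=min(3.0, 0.04 * length), periods=1.0,
            width=max(3, int(width) | 1),
        )
        pts = v.centerline()
        m = v.width / 2 + 1
        if (pts[:, 0].min() < m or pts[:, 0].max() > H - m
                or pts[:, 1].min() < m or pts[:, 1].max() > W - m):
            return
        vessels.append(v)
        end = pts[-1]
        spread = 26.0 + rng.uniform(-4, 4)
        for j, da in enumerate((-spread, spread)):
            grow(end, angle + da, length * 0.7, width * 0.78,
                 level + 1, f"{tag}{j}")

    # compact trees: every level stays inside the 3.5x-disc-diameter ROI
    r0, c0 = spec.disc_center
    for i, base in enumerate((-72.0, 72.0)):
        grow((r0 + spec.disc_radius * math.sin(math.radians(base)),
              c0 + spec.disc_radius * math.cos(math.radians(base))),
             base + rng.uniform(-5, 5), 50.0, 9.0, 0, f"{i}_")
    return vessels


def default_image_spec(seed: int = 0, tortuous: bool = False) -> SyntheticSpec:
    """Standard test layout: disc at mid-left, 2 arterioles + 2 venules
    running rightward, plus a depth-4 branching tree."""
    k = 3.0 if tortuous else 1.0
    amp = 8.0 if tortuous else 4.0
    def _radial(angle_deg: float) -> tuple[float, float]:
        th = math.radians(angle_deg)
        return (240.0 + 42.0 * math.sin(th), 120.0 + 42.0 * math.cos(th))

    # interleaved around the disc rim, each running radially outward
    vessels = (
        VesselSpec("v1", "venule", _radial(-42.0), -42.0, 240.0, amp, k, 11.0),
        VesselSpec("a1", "arteriole", _radial(-15.0), -15.0, 240.0, amp, k, 7.0),
        VesselSpec("a2", "arteriole", _radial(15.0), 15.0, 240.0, amp, k, 7.0),
        VesselSpec("v2", "venule", _radial(42.0), 42.0, 240.0, amp, k, 11.0),
    )
    return SyntheticSpec(vessels=vessels, branching_depth=4, seed=seed)


def generate(spec: SyntheticSpec) -> tuple[FundusImage, GroundTruth]:
    """Render a spec into an RGB fundus-like image plus its ground truth.

    Deterministic: the same spec (including its seed) yields a bit-identical
    image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape

    # background: mean + radial illumination falloff + low-frequency texture
    rr, cc = np.mgrid[:H, :W].astype(float)
    rad = np.hypot(rr - H / 2, cc - W / 2) / (0.5 * math.hypot(H, W))
    canvas = spec.background_mean - spec.background_gradient * rad**2
    if spec.background_noise_sd > 0:
        noise = rng.normal(0.0, 1.0, (H, W))
        noise = ndi.gaussian_filter(noise, sigma=8.0)
        noise *= spec.background_noise_sd / max(noise.std(), 1e-9)
        canvas += noise

    # optic disc: bright disk with a 1.5-px soft rim
    d = np.hypot(rr - spec.disc_center[0], cc - spec.disc_center[1])
    canvas += spec.disc_brightness * np.clip(spec.disc_radius - d + 0.5, 0, 1.5) / 1.5

    vessels = list(spec.vessels) + _branch_tree(spec, rng)

    truth = GroundTruth(
        centerlines={}, widths={}, vessel_classes={}, tortuosity_params={},
        disc_center=spec.disc_center, disc_radius=spec.disc_radius,
        lesion_mask=np.zeros((H, W), dtype=bool),
        branching_depth=spec.branching_depth,
    )

    # vessels: distance-to-centerline rendering; 50% edge at half-width
    for v in vessels:
        pts = v.centerline()
        on = np.zeros((H, W), dtype=bool)
        ij = np.round(pts).astype(int)
        on[ij[:, 0], ij[:, 1]] = True
        edt = ndi.distance_transform_edt(~on)
        cover = np.clip((v.width - 1) / 2 + 1.0 - edt, 0.0, 1.0)
        canvas -= spec.vessel_depth * cover
        truth.centerlines[v.vessel_id] = pts
        truth.widths[v.vessel_id] = v.width
        truth.vessel_classes[v.vessel_id] = v.vessel_class
        truth.tortuosity_params[v.vessel_id] = (v.amplitude, v.periods, v.chord)
        if v.vessel_class in ("arteriole", "venule"):
            truth.annotations.append(SegmentAnnotation(
                vessel_id=v.vessel_id, vessel_class=v.vessel_class,
                start=tuple(int(round(x)) for x in pts[0]),
                end=tuple(int(round(x)) for x in pts[-1]),
            ))

    for lesion in spec.lesions:
        d = np.hypot(rr - lesion.center[0], cc - lesion.center[1])
        blob = d <= lesion.radius
        delta = 60.0 if lesion.polarity == "bright" else -60.0
        canvas += delta * blob
        truth.lesion_mask |= blob

    green = np.clip(canvas, 0, 255).astype(np.uint8)
    red = np.clip(canvas * 1.25 + 20, 0, 255).astype(np.uint8)
    blue = np.clip(canvas * 0.35, 0, 255).astype(np.uint8)
    rgb = np.stack([red, green, blue], axis=-1)
    return FundusImage(pixels=rgb, channel_mode="rgb"), truth


# --------------------------------------------------------------------------
# cohort simulation

#: Matched-control group means for (AVR, TI, mean-D).
CONTROL_MEANS = {"avr": 0.77, "ti": 64.0, "mean_d": 1.45}
#: Between-pair (subject-matching) SD components.
BETWEEN_PAIR_SD = {"avr": 0.067, "ti": 23.5, "mean_d": 0.031}
#: Within-pair residual SDs (biological residual after age/gender matching).
WITHIN_PAIR_SD = {"avr": 0.03, "ti": 3.5, "mean_d": 0.015}
#: Per-rater measurement noise SDs.
RATER_SD = {"avr": 0.03, "ti": 3.5, "mean_d": 0.015}


@dataclass(frozen=True)
class EffectSizes:
    """Disease-minus-control shifts of the three indices.

    Defaults are the hypertensive-retinopathy group separations (AVR and
    mean-D fall, TI rises in disease).
    """

    avr: float = -0.09
    ti: float = 8.0
    mean_d: float = -0.04

    def as_dict(self) -> dict[str, float]:
        return {"avr": self.avr, "ti": self.ti, "mean_d": self.mean_d}


def generate_cohort(
    n_pairs: int,
    effect_sizes: EffectSizes | None = None,
    seed: int = 0,
    second_rater: bool = True,
    include_specs: bool = False,
):
    """Simulate a matched disease/control cohort at the index level.

    Each pair shares a latent matching component (between-pair SD), each
    subject adds a within-pair residual, the disease member adds the effect
    shift, and each rater's measurement adds independent rater noise. The
    variance components sum to the cross-sectional spreads seen in matched
    cohorts (SD ~0.08 for AVR, ~24 for TI, ~0.04 for mean-D).

    Returns a DataFrame with columns ``subject_id, group, pair_id, avr, ti,
    mean_d`` (rater-1 measurements) plus ``avr_b, ti_b, mean_d_b`` when
    ``second_rater``; with ``include_specs`` also a parallel list of
    per-subject :class:`SyntheticSpec` for image-level integration runs.
    """
    if n_pairs < 5:
        raise ContractError(f"cohort needs >= 5 matched pairs, got {n_pairs}")
    effects = (effect_sizes or EffectSizes()).as_dict()
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_pairs):
        pair_latent = {k: rng.normal(0.0, BETWEEN_PAIR_SD[k]) for k in CONTROL_MEANS}
        for group in ("disease", "control"):
            true = {}
            for k, mu in CONTROL_MEANS.items():
                val = mu + pair_latent[k] + rng.normal(0.0, WITHIN_PAIR_SD[k])
                if group == "disease":
                    val += effects[k]
                true[k] = val
            row = {"subject_id": f"s{p:03d}_{group[0]}", "group": group,
                   "pair_id": f"p{p:03d}"}
            for k in CONTROL_MEANS:
                row[k] = true[k] + rng.normal(0.0, RATER_SD[k])
            if second_rater:
                for k in CONTROL_MEANS:
                    row[f"{k}_b"] = true[k] + rng.normal(0.0, RATER_SD[k])
            rows.append(row)
    df = pd.DataFrame(rows)
    if not include_specs:
        return df
    specs = [
        subject_image_spec(r["avr"], r["ti"], r["mean_d"],
                           seed=int(rng.integers(0, 2**31 - 1)))
        for r in rows
    ]
    return df, specs


def subject_image_spec(avr: float, ti: float, mean_d: float,
                       seed: int = 0) -> SyntheticSpec:
    """Map index values onto renderable image parameters.

    Narrower arterioles for lower AVR (venule width fixed at 11 px), more
    sinusoid periods for higher TI, shallower branching for lower mean-D.
    """
    w_a = max(3, int(round(11 * avr)) | 1)  # nearest odd width
    periods = float(np.clip(round((ti - 30.0) / 15.0), 1, 5))
    depth = 4 if mean_d >= 1.42 else 3
    base = default_image_spec(seed=seed)
    vessels = tuple(
        replace(v, width=float(w_a), periods=periods) if v.vessel_class == "arteriole"
        else replace(v, periods=periods)
        for v in base.vessels
    )
    return replace(base, vessels=vessels, branching_depth=depth, seed=seed)
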