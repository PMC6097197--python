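"""Synthetic ground-truth generator: vessel networks, fundus renders,
OCT layer surfaces and two-group cohorts.

Every downstream stage of the perfusion pipeline can be exercised
against scenes whose true diameters, velocities, flows and layer
volumes are known by construction:

* terminal arteriolar and venular branches converge on the fovea,
  alternating (staggered) in angle, each crossing the 2.5 mm circle;
* vessels render as dark ridges with Gaussian cross-sections whose FWHM
  equals the true diameter, so the FWHM caliper is unbiased by design;
* arterioles carry negative signed velocities, venules positive;
* six layer thickness maps with a foveal pit stack into seven ordered
  boundary surfaces on the 6 x 6 mm, 128 x 512 OCT raster;
* cohorts draw flow and volumes from truncated normal distributions and
  scenes are calibrated (velocities and thicknesses scaled) so the
  pipeline's ground truth matches the drawn values exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError, InvalidParameterError
from .flow import (
    FOV_EXTENT_MM,
    FWHM_PER_SIGMA,
    FundusImage,
    VesselSegment,
    convert_fov,
    polyline_circle_intersections,
    vessel_flow,
)
from .volume import (
    DEFAULT_EXTENT_MM,
    DEFAULT_GRID_SHAPE,
    INNER_LAYERS,
    LAYER_NAMES,
    LayerSurfaces,
    disc_mask,
    layer_volume,
)

#: default background intensity of rendered fundus images (arbitrary units)
BACKGROUND_INTENSITY = 0.82

#: no vessel centerline enters this central avascular zone (mm)
AVASCULAR_RADIUS_MM = 0.4


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VesselGroundTruth(VesselSegment):
    """A synthetic vessel: a `VesselSegment` plus its true caliber and
    rendering contrast. Diameter is constant along the centerline."""

    true_diameter_um: float = 60.0
    contrast: float = 0.5

    def __post_init__(self) -> None:
        super().__post_init__()
        if not (10.0 <= self.true_diameter_um <= 200.0):
            raise InvalidInputError(
                "true_diameter_um must lie in [10, 200] um"
            )
        if not (0.0 < self.contrast <= 1.0):
            raise InvalidInputError("contrast must lie in (0, 1]")
        expected_sign = -1.0 if self.kind == "arteriole" else 1.0
        if math.copysign(1.0, self.velocity_mm_s) != expected_sign:
            raise InvalidInputError(
                f"{self.kind} velocity must be "
                f"{'negative' if expected_sign < 0 else 'positive'}"
            )


@dataclass
class CohortParams:
    """Distribution parameters for one study arm.

    Flow and GCIPL defaults are the printed group statistics; the
    inner-retina volume distribution is not printed, so its mean is
    derived as flow_mean / perfusion_mean and its SD set to ~8% CV
    (matching the printed GCIPL CV).
    """

    group: str
    n_subjects: int
    flow_mean_nl_s: float
    flow_sd_nl_s: float
    inner_volume_mean_mm3: float
    inner_volume_sd_mm3: float
    gcipl_mean_mm3: float
    gcipl_sd_mm3: float
    seed: int = 0
    age_mean_yr: float = 70.0
    age_sd_yr: float = 8.0
    mmse_mean: float = 28.0
    mmse_sd: float = 1.5
    duration_mean_yr: float = 0.0
    duration_sd_yr: float = 0.0
    n_male: int = 0
    n_hypertension: int = 0
    n_dyslipidemia: int = 0
    n_diabetes: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidParameterError("n_subjects must be >= 2")
        for name in ("flow_sd_nl_s", "inner_volume_sd_mm3", "gcipl_sd_mm3",
                     "age_sd_yr", "mmse_sd", "duration_sd_yr"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @classmethod
    def cad_defaults(cls, seed: int = 0) -> "CohortParams":
        """Alzheimer's-disease arm at the published group statistics."""
        return cls(
            group="CAD", n_subjects=24, seed=seed,
            flow_mean_nl_s=2.82, flow_sd_nl_s=0.92,
            inner_volume_mean_mm3=1.0930, inner_volume_sd_mm3=0.09,
            gcipl_mean_mm3=0.47, gcipl_sd_mm3=0.04,
            age_mean_yr=72.9, age_sd_yr=7.5,
            mmse_mean=22.3, mmse_sd=4.2,
            duration_mean_yr=3.9, duration_sd_yr=1.6,
            n_male=11, n_hypertension=14, n_dyslipidemia=11, n_diabetes=3,
        )

    @classmethod
    def cn_defaults(cls, seed: int = 1) -> "CohortParams":
        """Cognitively-normal control arm at the published statistics."""
        return cls(
            group="CN", n_subjects=19, seed=seed,
            flow_mean_nl_s=4.09, flow_sd_nl_s=0.46,
            inner_volume_mean_mm3=1.1298, inner_volume_sd_mm3=0.09,
            gcipl_mean_mm3=0.50, gcipl_sd_mm3=0.05,
            age_mean_yr=68.6, age_sd_yr=9.0,
            mmse_mean=29.5, mmse_sd=0.8,
            n_male=10, n_hypertension=11, n_dyslipidemia=9, n_diabetes=2,
        )


@dataclass
class ThicknessField:
    """Six per-layer thickness maps (mm) on the OCT raster, with a
    foveal pit thinning the inner layers toward the center."""

    thickness_mm: dict[str, np.ndarray]
    extent_mm: tuple[float, float] = DEFAULT_EXTENT_MM
    fovea_mm: tuple[float, float] | None = None
    pit_depth_frac: float = 0.85
    pit_radius_mm: float = 0.35

    def __post_init__(self) -> None:
        missing = set(LAYER_NAMES) - set(self.thickness_mm)
        if missing:
            raise InvalidInputError(f"missing layers: {sorted(missing)}")
        shapes = {np.asarray(m).shape for m in self.thickness_mm.values()}
        if len(shapes) != 1:
            raise InvalidInputError("layer maps must share one grid shape")
        for name, m in self.thickness_mm.items():
            m = np.asarray(m, dtype=float)
            if (m < 0).any():
                raise InvalidInputError(f"negative thickness in {name}")
            self.thickness_mm[name] = m
        if self.fovea_mm is None:
            self.fovea_mm = (self.extent_mm[0] / 2, self.extent_mm[1] / 2)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return next(iter(self.thickness_mm.values())).shape


@dataclass
class Scene:
    """One synthetic eye: rendered image, vessel truth, OCT surfaces and
    the injected flow/volume/perfusion targets."""

    image: FundusImage
    vessels: list[VesselGroundTruth]
    surfaces: LayerSurfaces
    truth: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# vessel network
# ---------------------------------------------------------------------------

def generate_vessel_network(
    n_arterioles: int,
    n_venules: int,
    fovea: tuple[float, float] = (0.0, 0.0),
    seed: int | np.random.Generator | None = None,
    circle_diameter_mm: float = 2.5,
    avascular_radius_mm: float = AVASCULAR_RADIUS_MM,
    diameter_range_um: tuple[float, float] = (30.0, 90.0),
    n_points: int = 15,
) -> list[VesselGroundTruth]:
    """Terminal branches converging on the fovea, staggered in angle.

    Arterioles and venules alternate around the circle; each centerline
    starts outside the measurement circle, spirals gently inward with a
    monotonically decreasing radius, and stops short of the avascular
    center, so every vessel crosses the circle exactly once.
    """
    if n_arterioles < 1 or n_venules < 1:
        raise InvalidParameterError("vessel counts must be >= 1")
    rng = np.random.default_rng(seed)
    total = n_arterioles + n_venules
    # interleave kinds as evenly as possible (stagger)
    kinds: list[str] = []
    a, v = n_arterioles, n_venules
    while a or v:
        if a * (n_venules + 1) >= v * (n_arterioles + 1):
            kinds.append("arteriole"); a -= 1
        else:
            kinds.append("venule"); v -= 1
    spacing = 2 * math.pi / total
    fov = np.asarray(fovea, dtype=float)
    vessels: list[VesselGroundTruth] = []
    counts = {"arteriole": 0, "venule": 0}
    for i, kind in enumerate(kinds):
        theta0 = i * spacing + rng.uniform(-0.2, 0.2) * spacing
        r0 = rng.uniform(1.7, 2.0)
        r1 = rng.uniform(avascular_radius_mm + 0.05, avascular_radius_mm + 0.25)
        t = np.linspace(0.0, 1.0, n_points)
        radii = r0 + (r1 - r0) * t
        wobble = rng.uniform(0.02, 0.08) * np.sin(
            math.pi * t * rng.integers(1, 3) + rng.uniform(0, 2 * math.pi)
        )
        thetas = theta0 + wobble
        centerline = fov + np.column_stack(
            [radii * np.cos(thetas), radii * np.sin(thetas)]
        )
        counts[kind] += 1
        speed = (rng.uniform(3.0, 4.5) if kind == "arteriole"
                 else rng.uniform(2.2, 3.5))
        vessels.append(
            VesselGroundTruth(
                vessel_id=f"{'A' if kind == 'arteriole' else 'V'}"
                          f"{counts[kind]}",
                kind=kind,
                centerline=centerline,
                velocity_mm_s=-speed if kind == "arteriole" else speed,
                true_diameter_um=rng.uniform(*diameter_range_um),
                contrast=rng.uniform(0.45, 0.7),
            )
        )
    return vessels


# ---------------------------------------------------------------------------
# fundus rendering
# ---------------------------------------------------------------------------

def render_fundus(
    vessels: list[VesselGroundTruth],
    fov_setting: int = 20,
    image_size_px: int = 1024,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    fovea: tuple[float, float] = (0.0, 0.0),
    background: float = BACKGROUND_INTENSITY,
) -> FundusImage:
    """Render vessels as dark Gaussian ridges on a noisy background.

    The cross-section of each vessel is a Gaussian intensity dip whose
    FWHM equals the true diameter, so the FWHM caliper recovers the
    diameter without model bias. Pixel scale is ``FOV extent /
    image_size_px`` (4.3 mm at 20 degrees, 7.3 mm at 35). Overlapping
    vessels combine by maximum dip. Additive white Gaussian noise with
    SD ``noise_sd`` (in intensity units) is applied last.
    """
    if fov_setting not in FOV_EXTENT_MM:
        raise InvalidParameterError(
            f"fov_setting must be one of {sorted(FOV_EXTENT_MM)}"
        )
    if image_size_px < 128:
        raise InvalidParameterError("image_size_px must be >= 128")
    rng = np.random.default_rng(seed)
    mm_per_px = FOV_EXTENT_MM[fov_setting] / image_size_px
    center = (image_size_px - 1) / 2.0
    fovea_px = (center, center)
    dip = np.zeros((image_size_px, image_size_px))
    for v in vessels:
        sigma_px = (v.true_diameter_um / 1000.0 / FWHM_PER_SIGMA) / mm_per_px
        reach = int(math.ceil(4.0 * sigma_px)) + 1
        pts_px = np.empty_like(v.centerline)
        pts_px[:, 0] = fovea_px[0] + (v.centerline[:, 0] - fovea[0]) / mm_per_px
        pts_px[:, 1] = fovea_px[1] + (v.centerline[:, 1] - fovea[1]) / mm_per_px
        for j in range(len(pts_px) - 1):
            p0, p1 = pts_px[j], pts_px[j + 1]
            c0 = max(0, int(math.floor(min(p0[0], p1[0]))) - reach)
            c1 = min(image_size_px - 1, int(math.ceil(max(p0[0], p1[0]))) + reach)
            r0 = max(0, int(math.floor(min(p0[1], p1[1]))) - reach)
            r1 = min(image_size_px - 1, int(math.ceil(max(p0[1], p1[1]))) + reach)
            if c1 < c0 or r1 < r0:
                continue
            cols = np.arange(c0, c1 + 1)
            rows = np.arange(r0, r1 + 1)
            cc, rr = np.meshgrid(cols, rows)
            d = p1 - p0
            len2 = float(d @ d)
            px = cc - p0[0]
            py = rr - p0[1]
            if len2 == 0.0:
                dist2 = px ** 2 + py ** 2
            else:
                t = np.clip((px * d[0] + py * d[1]) / len2, 0.0, 1.0)
                dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2
            local = v.contrast * np.exp(-dist2 / (2.0 * sigma_px ** 2))
            np.maximum(dip[r0:r1 + 1, c0:c1 + 1], local,
                       out=dip[r0:r1 + 1, c0:c1 + 1])
    pixels = background * (1.0 - dip)
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, pixels.shape)
    return FundusImage(
        pixels=pixels,
        mm_per_px=mm_per_px,
        fovea_px=fovea_px,
        fov_setting=fov_setting,
    )


# ---------------------------------------------------------------------------
# OCT layer surfaces
# ---------------------------------------------------------------------------

#: baseline layer thicknesses (mm) away from the fovea
BASE_THICKNESS_MM = {
    "RNFL": 0.040, "GCIPL": 0.110, "INL": 0.080,
    "OPL": 0.050, "ONL": 0.090, "PR": 0.060,
}


def default_thickness_field(
    grid_shape: tuple[int, int] = DEFAULT_GRID_SHAPE,
    extent_mm: tuple[float, float] = DEFAULT_EXTENT_MM,
    pit_depth_frac: float = 0.85,
    pit_radius_mm: float = 0.35,
    seed: int | np.random.Generator | None = None,
) -> ThicknessField:
    """Smooth six-layer thickness maps with a foveal depression.

    Inner layers (RNFL..OPL) thin toward the fovea by a Gaussian pit
    factor; the ONL thickens slightly at the center as real retinas do;
    the photoreceptor layer is flat. A mild random global scale and
    low-frequency modulation (when seeded) vary subjects.
    """
    rng = np.random.default_rng(seed)
    rows, cols = grid_shape
    ey, ex = extent_mm
    fy, fx = ey / 2.0, ex / 2.0
    ys = (np.arange(rows) + 0.5) * (ey / rows)
    xs = (np.arange(cols) + 0.5) * (ex / cols)
    r2 = (ys[:, None] - fy) ** 2 + (xs[None, :] - fx) ** 2
    pit = np.exp(-r2 / (2.0 * pit_radius_mm ** 2))
    scale = rng.uniform(0.9, 1.1)
    # gentle large-scale modulation so maps are not perfectly flat
    ripple = 1.0 + 0.03 * np.sin(2 * math.pi * ys[:, None] / ey
                                 + rng.uniform(0, 2 * math.pi)) \
        * np.cos(2 * math.pi * xs[None, :] / ex + rng.uniform(0, 2 * math.pi))
    maps: dict[str, np.ndarray] = {}
    for name, base in BASE_THICKNESS_MM.items():
        if name in INNER_LAYERS:
            m = base * scale * ripple * (1.0 - pit_depth_frac * pit)
        elif name == "ONL":
            m = base * scale * ripple * (1.0 + 0.4 * pit)
        else:
            m = base * scale * np.ones_like(r2)
        maps[name] = np.clip(m, 0.0, None)
    return ThicknessField(
        thickness_mm=maps, extent_mm=extent_mm,
        pit_depth_frac=pit_depth_frac, pit_radius_mm=pit_radius_mm,
    )


def generate_layer_surfaces(thickness: ThicknessField) -> LayerSurfaces:
    """Stack thickness maps into seven ordered boundary depth surfaces.

    Boundary 0 is the inner retinal surface at depth 0; boundary k is
    the cumulative thickness of the first k layers, so boundaries are
    non-decreasing in depth wherever thicknesses are non-negative.
    """
    rows, cols = thickness.grid_shape
    boundaries = np.zeros((len(LAYER_NAMES) + 1, rows, cols))
    for i, name in enumerate(LAYER_NAMES):
        boundaries[i + 1] = boundaries[i] + thickness.thickness_mm[name]
    return LayerSurfaces(
        boundaries=boundaries,
        extent_mm=thickness.extent_mm,
        fovea_mm=thickness.fovea_mm,
    )


# ---------------------------------------------------------------------------
# subject scenes and cohorts
# ---------------------------------------------------------------------------

def draw_truncated_normal(
    mean: float, sd: float, n: int,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Normal(mean, sd) samples truncated at zero (physical quantities
    cannot be negative). ``sd = 0`` returns the constant mean."""
    rng = np.random.default_rng(rng)
    if sd == 0:
        return np.full(n, float(mean))
    a = (0.0 - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                             size=n, random_state=rng)


def build_scene(
    flow_target_nl_s: float,
    inner_volume_target_mm3: float,
    gcipl_target_mm3: float,
    seed: int | np.random.Generator | None = None,
    n_arterioles: int = 6,
    n_venules: int = 6,
    fov_setting: int = 20,
    image_size_px: int = 1024,
    noise_sd: float = 0.0,
    circle_diameter_mm: float = 2.5,
    disc_diameter_mm: float = 2.5,
) -> Scene:
    """One calibrated synthetic eye.

    Velocities are scaled (per side) so the analytic flow through the
    retained circle crossings equals ``flow_target_nl_s`` for arterioles
    and venules alike; inner-layer thickness maps are scaled so the
    GCIPL and composite inner-retina disc volumes equal their targets
    exactly. Velocity, not diameter, is the calibration knob because
    diameters also drive the rendered geometry.
    """
    rng = np.random.default_rng(seed)
    vessels = generate_vessel_network(
        n_arterioles, n_venules, seed=rng,
        circle_diameter_mm=circle_diameter_mm,
    )
    # analytic flow per side through the retained (single) crossing,
    # using the same FOV conversion the measurement applies
    totals = {"arteriole": 0.0, "venule": 0.0}
    for v in vessels:
        if polyline_circle_intersections(
                v.centerline, (0.0, 0.0), circle_diameter_mm):
            v20 = convert_fov(v.velocity_mm_s, v.kind, fov_setting)
            totals[v.kind] += vessel_flow(v20, v.true_diameter_um)
    if totals["arteriole"] <= 0 or totals["venule"] <= 0:
        raise InvalidInputError("generated network has an empty side")
    scaled = [
        replace(
            v,
            velocity_mm_s=v.velocity_mm_s * flow_target_nl_s / totals[v.kind],
            centerline=v.centerline.copy(),
        )
        for v in vessels
    ]
    image = render_fundus(
        scaled, fov_setting=fov_setting, image_size_px=image_size_px,
        noise_sd=noise_sd, seed=rng,
    )
    # calibrate layer volumes inside the disc
    thickness = default_thickness_field(seed=rng)
    surfaces = generate_layer_surfaces(thickness)
    mask = disc_mask(
        surfaces.grid_shape, surfaces.extent_mm, surfaces.fovea_mm,
        disc_diameter_mm,
    )
    vols = layer_volume(surfaces, mask, disc_diameter_mm)
    rest_target = inner_volume_target_mm3 - gcipl_target_mm3
    rest_current = vols.inner_retina_mm3 - vols.per_layer_mm3["GCIPL"]
    if rest_target <= 0 or rest_current <= 0:
        raise InvalidParameterError(
            "inner-volume target must exceed the GCIPL target"
        )
    gcipl_scale = gcipl_target_mm3 / vols.per_layer_mm3["GCIPL"]
    rest_scale = rest_target / rest_current
    for name in INNER_LAYERS:
        factor = gcipl_scale if name == "GCIPL" else rest_scale
        thickness.thickness_mm[name] = thickness.thickness_mm[name] * factor
    surfaces = generate_layer_surfaces(thickness)
    truth = {
        "flow_nl_s": flow_target_nl_s,
        "inner_volume_mm3": inner_volume_target_mm3,
        "gcipl_mm3": gcipl_target_mm3,
        "perfusion_nl_s_mm3": flow_target_nl_s / inner_volume_target_mm3,
    }
    return Scene(image=image, vessels=scaled, surfaces=surfaces, truth=truth)


def _assign_flags(n: int, counts: dict[str, int],
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    out = {}
    for name, k in counts.items():
        flags = np.zeros(n, dtype=int)
        flags[:min(k, n)] = 1
        rng.shuffle(flags)
        out[name] = flags
    return out


def simulate_cohort(
    params_cad: CohortParams | None = None,
    params_cn: CohortParams | None = None,
) -> pd.DataFrame:
    """Draw a two-arm subject table with the study's group structure.

    Flow, inner-retina volume and GCIPL volume are drawn per subject
    from zero-truncated normals at each arm's parameters; perfusion is
    the flow/volume quotient. Covariates (age, sex, MMSE, disease
    duration, risk flags) follow the demographic table; categorical
    counts are exact per arm, shuffled by the seed.
    """
    params_cad = params_cad or CohortParams.cad_defaults()
    params_cn = params_cn or CohortParams.cn_defaults()
    frames = []
    for p in (params_cad, params_cn):
        rng = np.random.default_rng(p.seed)
        n = p.n_subjects
        flow = draw_truncated_normal(p.flow_mean_nl_s, p.flow_sd_nl_s, n, rng)
        inner = draw_truncated_normal(
            p.inner_volume_mean_mm3, p.inner_volume_sd_mm3, n, rng
        )
        gcipl = draw_truncated_normal(p.gcipl_mean_mm3, p.gcipl_sd_mm3, n, rng)
        # keep the composite physically larger than its GCIPL part
        inner = np.maximum(inner, gcipl + 0.1)
        age = draw_truncated_normal(p.age_mean_yr, p.age_sd_yr, n, rng)
        mmse = np.clip(
            draw_truncated_normal(p.mmse_mean, p.mmse_sd, n, rng), 0, 30
        )
        duration = draw_truncated_normal(
            p.duration_mean_yr, p.duration_sd_yr, n, rng
        )
        sex = np.array(["M"] * min(p.n_male, n) + ["F"] * (n - min(p.n_male, n)))
        rng.shuffle(sex)
        flags = _assign_flags(
            n,
            {"hypertension": p.n_hypertension,
             "dyslipidemia": p.n_dyslipidemia,
             "diabetes": p.n_diabetes},
            rng,
        )
        frames.append(pd.DataFrame({
            "subject_id": [f"{p.group}{i + 1:03d}" for i in range(n)],
            "group": p.group,
            "macular_flow_nl_s": flow,
            "inner_volume_mm3": inner,
            "gcipl_mm3": gcipl,
            "perfusion_nl_s_mm3": flow / inner,
            "age_yr": age,
            "sex": sex,
            "mmse": mmse,
            "duration_yr": duration,
            **flags,
        }))
    return pd.concat(frames, ignore_index=True)
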