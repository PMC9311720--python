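"""Synthetic pelvic phantoms and analytic three-level "planned" dose.

The simulator emulates the statistical structure of dose-escalated prostate
plans: an ellipsoidal prostate with seminal-vesicle lobes, a rectum tube
posterior to the prostate, an anterior-superior bladder, and six boost
lesions placed in posterior-weighted sectors of the peripheral zone.  Target
volumes follow the clinical margin recipe: PTV60 = prostate + 5 mm,
PTV53 = (prostate + vesicles) + 9 mm, CTV68 = lesion + 3 mm cropped to the
prostate, PTV68 = CTV68 + 2 mm.

Planned dose is an analytic surrogate for an optimised volumetric-arc plan:
prescription plateaus (53 / 60 / 68 Gy) with sigmoidal distance-driven
fall-off outside each target and a rectum-sparing term that steepens the
fall-off inside the rectum, producing the characteristic concave isodoses.
Every emitted plan is checked against the planning objectives (95 % of
PTV60 >= 60 Gy, 95 % of PTV53 >= 53 Gy, PTV68 median 68 +- 0.3 Gy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dvh import compute_dvh
from .grids import DoseGrid, GridError, StructureSet
from .radiobiology import FractionationScheme, risk
from .stratify import ConstraintTable, check_constraints

BOOST_LETTERS = "abcdef"

#: Cohort statistics the volume sampler reproduces (mean, SD in cc).
PROSTATE_CC = (42.3, 15.7)
RECTUM_CC = (69.3, 19.7)
BLADDER_CC = (180.0, 45.0)  # not reported for the source cohort; typical comfortably-filled bladder


class PhantomError(ValueError):
    pass


class PlanCoverageError(RuntimeError):
    """A simulated plan failed one of the planning coverage objectives."""


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic recipe for one synthetic pelvis.

    ``boost_positions`` are axial azimuths in degrees measured from the +x
    axis towards +y (posterior); the defaults cover posterior-weighted
    sectors of the peripheral zone.
    """

    seed: int
    grid_shape: tuple[int, int, int] = (52, 64, 64)  # (z, y, x)
    spacing_mm: tuple[float, float, float] = (3.0, 2.5, 2.5)
    prostate_volume_cc: float = 42.3
    rectum_volume_cc: float = 69.3
    bladder_volume_cc: float = 180.0
    boost_positions: tuple[float, ...] = (30.0, 60.0, 85.0, 95.0, 120.0, 150.0)
    margin_ptv60_mm: float = 5.0
    margin_ptv53_mm: float = 9.0
    margin_ctv68_mm: float = 3.0
    margin_ptv68_mm: float = 2.0
    rectum_length_mm: float = 105.0
    dil_volumes_cc: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise PhantomError("grid_shape must be 3 positive integers")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise PhantomError("spacing_mm must be strictly positive")
        for name in ("prostate_volume_cc", "rectum_volume_cc", "bladder_volume_cc", "rectum_length_mm"):
            if getattr(self, name) <= 0:
                raise PhantomError(f"{name} must be positive")
        if len(self.boost_positions) != 6:
            raise PhantomError("exactly 6 boost positions are required")
        for name in ("margin_ptv60_mm", "margin_ptv53_mm", "margin_ctv68_mm", "margin_ptv68_mm"):
            if getattr(self, name) < 0:
                raise PhantomError(f"{name} must be non-negative")
        if self.dil_volumes_cc is not None and len(self.dil_volumes_cc) != 6:
            raise PhantomError("dil_volumes_cc must list 6 lesion volumes")

    @classmethod
    def sample(cls, seed: int, **overrides) -> "PhantomSpec":
        """Draw organ volumes from the cohort distributions (truncated +-2.5 SD)."""
        rng = np.random.default_rng(int(seed))

        def trunc_normal(mean, sd):
            while True:
                v = rng.normal(mean, sd)
                if abs(v - mean) <= 2.5 * sd and v > 1.0:
                    return float(v)

        fields = dict(
            seed=int(seed),
            prostate_volume_cc=trunc_normal(*PROSTATE_CC),
            rectum_volume_cc=trunc_normal(*RECTUM_CC),
            bladder_volume_cc=trunc_normal(*BLADDER_CC),
        )
        fields.update(overrides)
        return cls(**fields)

    @classmethod
    def desk(cls, seed: int, **overrides) -> "PhantomSpec":
        """Coarse preset whose crops fit the 32 x 32 x 16 network input."""
        defaults = dict(
            grid_shape=(26, 48, 48),
            spacing_mm=(6.0, 5.0, 5.0),
            rectum_length_mm=80.0,
        )
        defaults.update(overrides)
        return cls.sample(seed, **defaults)


@dataclass(frozen=True)
class FalloffConfig:
    """Analytic-plan shape parameters.

    ``w53/w60/w68`` are sigmoid fall-off widths (mm) outside each target;
    ``spare_weight`` scales the effective distance inside the rectum
    (larger = steeper fall-off through the rectum = better sparing).
    """

    w53_mm: float = 11.0
    w60_mm: float = 7.0
    w68_mm: float = 4.5
    spare_weight: float = 1.0
    bath_gy: float = 18.0
    bath_range_mm: float = 40.0
    noise_sigma_gy: float = 0.15
    noise_corr_mm: float = 8.0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.w53_mm, self.w60_mm, self.w68_mm) <= 0:
            raise PhantomError("fall-off widths must be strictly positive")
        if self.spare_weight < 0:
            raise PhantomError("spare_weight must be non-negative")
        if self.bath_gy < 0 or self.bath_range_mm <= 0:
            raise PhantomError("scatter bath must have non-negative dose and positive range")
        if self.noise_sigma_gy < 0:
            raise PhantomError("noise_sigma_gy must be non-negative")

    @classmethod
    def sample(cls, seed: int) -> "FalloffConfig":
        """Per-plan jitter emulating planner-to-planner variation in fall-off."""
        rng = np.random.default_rng(int(seed))
        return cls(
            w53_mm=11.0 * rng.uniform(0.8, 1.25),
            w60_mm=7.0 * rng.uniform(0.8, 1.25),
            w68_mm=4.5 * rng.uniform(0.8, 1.25),
            spare_weight=rng.uniform(0.5, 1.6),
            bath_gy=18.0 * rng.uniform(0.8, 1.2),
            noise_seed=int(rng.integers(0, 2**31 - 1)),
        )


@dataclass
class PlanLabel:
    """Ground-truth stratification labels for one simulated plan."""

    exceeds_optimal: bool
    exceeds_mandatory: bool
    risk_lrb: float
    risk_lfi: float

    def __post_init__(self) -> None:
        for r in (self.risk_lrb, self.risk_lfi):
            if not 0 <= r <= 1:
                raise PhantomError("risks must be probabilities")


# ---------------------------------------------------------------------------
# geometry helpers


def _dilate_mm(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Morphological dilation by a physical radius via the distance transform."""
    if radius_mm <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= radius_mm


def _ellipsoid(zz, yy, xx, centre, semi) -> np.ndarray:
    cz, cy, cx = centre
    az, ay, ax = semi
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _semi_axes(volume_cc: float, ratios) -> tuple[float, float, float]:
    """Ellipsoid semi-axes (mm) with given axis ratios and target volume."""
    rz, ry, rx = ratios
    # V[cc] = 4/3 pi az ay ax / 1000
    scale = (volume_cc * 1000.0 * 3.0 / (4.0 * np.pi * rz * ry * rx)) ** (1.0 / 3.0)
    return rz * scale, ry * scale, rx * scale


def generate_phantom(spec: PhantomSpec) -> StructureSet:
    """Build the full structure set (six PTV68 variants) for one phantom.

    Deterministic for a fixed spec: all stochastic choices derive from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = spec.spacing_mm
    extent = tuple(n * s for n, s in zip(shape, spacing))

    idx = np.indices(shape, dtype=np.float64)
    zz = (idx[0] + 0.5) * spacing[0]
    yy = (idx[1] + 0.5) * spacing[1]
    xx = (idx[2] + 0.5) * spacing[2]

    # prostate: ellipsoid, centre slightly inferior/posterior of grid centre
    pz = 0.45 * extent[0]
    py = 0.52 * extent[1]
    px = 0.50 * extent[2]
    ratios = np.array([0.95, 0.82, 1.0]) * rng.uniform(0.95, 1.05, 3)
    p_semi = _semi_axes(spec.prostate_volume_cc, ratios)
    prostate = _ellipsoid(zz, yy, xx, (pz, py, px), p_semi)

    # seminal-vesicle proxy: two superior-posterior lobes
    ves_vol = 0.12 * spec.prostate_volume_cc
    v_semi = _semi_axes(ves_vol, (1.2, 0.8, 0.7))
    vesicles = np.zeros(shape, dtype=bool)
    for side in (-1.0, 1.0):
        centre = (pz + 0.8 * p_semi[0], py + 0.45 * p_semi[1], px + side * 0.45 * p_semi[2])
        vesicles |= _ellipsoid(zz, yy, xx, centre, v_semi)

    ctv60 = prostate
    ctv53 = prostate | vesicles
    ptv60 = _dilate_mm(ctv60, spec.margin_ptv60_mm, spacing)
    ptv53 = _dilate_mm(ctv53, spec.margin_ptv53_mm, spacing)

    # rectum: posterior tube along z with mild wobble and radius modulation
    length = min(spec.rectum_length_mm, 0.9 * extent[0])
    r0 = np.sqrt(spec.rectum_volume_cc * 1000.0 / (np.pi * length))
    z_axis = (np.arange(shape[0]) + 0.5) * spacing[0]
    inside_z = np.abs(z_axis - pz) <= length / 2.0
    phase = rng.uniform(0, 2 * np.pi, 3)
    wobble_x = 2.5 * np.sin(2 * np.pi * z_axis / 90.0 + phase[0])
    wobble_y = 1.5 * np.sin(2 * np.pi * z_axis / 120.0 + phase[1])
    radius = r0 * (1.0 + 0.10 * np.sin(2 * np.pi * z_axis / 70.0 + phase[2]))
    rect_y = py + p_semi[1] + 2.0 + r0 + wobble_y
    rect_x = px + wobble_x
    ry2 = ((yy - rect_y[:, None, None]) / radius[:, None, None]) ** 2
    rx2 = ((xx - rect_x[:, None, None]) / radius[:, None, None]) ** 2
    rectum = (ry2 + rx2 <= 1.0) & inside_z[:, None, None]
    rectum &= ~prostate

    # bladder: anterior-superior ellipsoid
    b_semi = _semi_axes(spec.bladder_volume_cc, (1.0, 0.95, 1.05))
    b_centre = (
        pz + 0.30 * p_semi[0] + 0.60 * b_semi[0],
        py - 0.55 * p_semi[1] - 0.75 * b_semi[1],
        px,
    )
    bladder = _ellipsoid(zz, yy, xx, b_centre, b_semi)
    bladder &= ~prostate

    masks = {
        "prostate": prostate,
        "ctv53": ctv53,
        "ptv60": ptv60,
        "ptv53": ptv53,
        "rectum": rectum,
        "bladder": bladder,
    }

    # six peripheral-zone boost lesions -> CTV68 -> PTV68 variants
    if spec.dil_volumes_cc is not None:
        dil_volumes = list(spec.dil_volumes_cc)
    else:
        dil_volumes = np.clip(rng.lognormal(np.log(6.0), 0.40, 6), 3.0, 13.0).tolist()
    for i, azimuth in enumerate(spec.boost_positions):
        az_deg = azimuth + rng.uniform(-8.0, 8.0)
        theta = np.deg2rad(az_deg)
        u = rng.uniform(0.60, 0.78)
        centre = (
            pz + rng.uniform(-0.35, 0.35) * p_semi[0],
            py + np.sin(theta) * u * p_semi[1],
            px + np.cos(theta) * u * p_semi[2],
        )
        d_semi = _semi_axes(dil_volumes[i], (0.9, 0.85, 1.0))
        dil = _ellipsoid(zz, yy, xx, centre, d_semi)
        ctv68 = _dilate_mm(dil, spec.margin_ctv68_mm, spacing) & prostate
        if not ctv68.any():
            raise PhantomError(f"boost {BOOST_LETTERS[i]}: lesion fell outside the prostate")
        masks[f"ptv68_{BOOST_LETTERS[i]}"] = _dilate_mm(ctv68, spec.margin_ptv68_mm, spacing)

    # the grid must contain every structure with a margin of one voxel
    for name, mask in masks.items():
        if (
            mask[0].any()
            or mask[-1].any()
            or mask[:, 0].any()
            or mask[:, -1].any()
            or mask[:, :, 0].any()
            or mask[:, :, -1].any()
        ):
            raise PhantomError(f"grid too small: structure '{name}' reaches the grid boundary")

    return StructureSet(masks, spacing)


# ---------------------------------------------------------------------------
# analytic plan dose


def _coverage_check(dose: np.ndarray, anatomy: StructureSet, ptv68: np.ndarray) -> None:
    failures = []
    v60 = np.mean(dose[anatomy.masks["ptv60"]] >= 60.0) * 100.0
    if v60 < 95.0:
        failures.append(f"V60Gy(PTV60) = {v60:.1f}% < 95%")
    v53 = np.mean(dose[anatomy.masks["ptv53"]] >= 53.0) * 100.0
    if v53 < 95.0:
        failures.append(f"V53Gy(PTV53) = {v53:.1f}% < 95%")
    med = float(np.median(dose[ptv68]))
    if not 67.7 <= med <= 68.3:
        failures.append(f"median PTV68 dose = {med:.2f} Gy outside 68 +- 0.3 Gy")
    if failures:
        raise PlanCoverageError("plan fails coverage objectives: " + "; ".join(failures))


def simulate_plan_dose(
    anatomy: StructureSet, boost_index: int, falloff_cfg: FalloffConfig = FalloffConfig()
) -> DoseGrid:
    """Analytic planned dose for one boost variant of a phantom.

    Superposition of three prescription plateaus with sigmoidal fall-off of
    the *effective* distance outside each target; the effective distance is
    inflated inside the rectum by ``spare_weight``, which yields concave
    isodoses through the rectum without touching target coverage.
    """
    plan = anatomy.select_boost(boost_index) if anatomy.boost_names() else anatomy
    spacing = anatomy.spacing_mm
    masks = plan.masks
    ptv68 = masks["ptv68"]

    # smooth rectum indicator in [0, 1] driving the sparing term
    sigma_vox = [6.0 / s for s in spacing]
    rect_smooth = ndimage.gaussian_filter(masks["rectum"].astype(np.float64), sigma_vox)
    peak = rect_smooth.max()
    if peak > 0:
        rect_smooth /= peak

    dist53 = ndimage.distance_transform_edt(~masks["ptv53"], sampling=spacing)

    def component(dist, delta, width):
        d_eff = dist * (1.0 + falloff_cfg.spare_weight * rect_smooth)
        arg = np.clip(d_eff / width, 0.0, 60.0)
        return delta * 2.0 / (1.0 + np.exp(arg))

    # plateaus carry ~1 Gy headroom over the prescription (54 / 61 / 68 Gy)
    # so coverage survives plan noise; the PTV68 plateau lands on 68 exactly,
    # keeping its median inside the 68 +- 0.3 Gy objective.
    dose = (
        component(dist53, 54.0, falloff_cfg.w53_mm)
        + component(ndimage.distance_transform_edt(~masks["ptv60"], sampling=spacing), 7.0, falloff_cfg.w60_mm)
        + component(ndimage.distance_transform_edt(~ptv68, sampling=spacing), 7.0, falloff_cfg.w68_mm)
    )

    # long-range scatter bath (not shaped by the optimiser, hence unspared);
    # max-composed so it never raises the conformal plateaus
    bath = falloff_cfg.bath_gy * 2.0 / (1.0 + np.exp(np.clip(dist53 / falloff_cfg.bath_range_mm, 0.0, 60.0)))
    dose = np.maximum(dose, bath)

    if falloff_cfg.noise_sigma_gy > 0:
        rng = np.random.default_rng(falloff_cfg.noise_seed)
        white = rng.standard_normal(dose.shape)
        corr_vox = [falloff_cfg.noise_corr_mm / s for s in spacing]
        smooth = ndimage.gaussian_filter(white, corr_vox)
        sd = smooth.std()
        if sd > 0:
            dose = dose + falloff_cfg.noise_sigma_gy / sd * smooth

    # plan normalisation: the boost median is renormalised to the 68 Gy
    # prescription, mirroring clinical plan normalisation
    dose += 68.0 - float(np.median(dose[ptv68]))
    dose = np.clip(dose, 0.0, None)
    _coverage_check(dose, anatomy, ptv68)
    return DoseGrid(dose, spacing)


def label_plan(
    anatomy: StructureSet,
    dose: DoseGrid,
    constraints: ConstraintTable,
    fx: FractionationScheme = FractionationScheme(),
) -> PlanLabel:
    """Ground-truth labels computed by the same DVH / risk chain as the pipeline."""
    if dose.shape != anatomy.shape:
        raise GridError("dose and anatomy are on different grids")
    rectum = anatomy.masks.get("rectum")
    if rectum is None or not rectum.any():
        raise PhantomError("anatomy has no (non-empty) rectum mask")
    curve = compute_dvh(dose, rectum, structure="rectum")
    opt = check_constraints(curve, constraints, "optimal")
    mand = check_constraints(curve, constraints, "mandatory")
    return PlanLabel(
        exceeds_optimal=opt.is_high,
        exceeds_mandatory=mand.is_high,
        risk_lrb=risk(curve, "LRB", fx),
        risk_lfi=risk(curve, "LFI", fx),
    )
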