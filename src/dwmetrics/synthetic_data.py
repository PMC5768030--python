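"""Synthetic phantoms, anatomy profiles and a seeded patient cohort.

Everything the analysis consumes can be generated here with known ground
truth: uniform water cylinders and ellipses (validation phantoms, with an
optional synthetic couch), anatomy-shaped D_w(z) curves (chest with a
mid-scan lung dip, chest-abdomen-pelvis with an abdominal bulge), a
noise-constant tube-current modulation emulator with I_min/I_max clamps,
and a full cohort sampler with the weight/height structure of an adult
oncology population.

The cohort sampler's randomness contract: one root seed, one hierarchical
substream per patient (spawned per exam type), so the first k patients of
a stratum are unchanged when the stratum grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ct_io import AIR_HU, CTSlice, PatientBio, ScanSeries
from .dw_core import DwProfile, dw_metrics
from .ssde_conversion import ConversionTable, ssde
from .cohort_stats import ExamRecord

WATER_HU = 0.0

# synthetic couch: a homogeneous strip below the phantom
TABLE_WIDTH_CM = 36.0
TABLE_HEIGHT_CM = 2.0
TABLE_HU = -400.0
TABLE_GAP_CM = 0.5  # air gap between phantom bottom and couch top


@dataclass
class PhantomSpec:
    """Geometry of one uniform synthetic phantom slice.

    ``dimensions``: (diameter,) in cm for a disk, (a, b) semi-axes in cm
    for an ellipse (a lateral, b antero-posterior); ignored for a
    half-plane (water filling the lower half of the image, used for
    truncation checks).
    """

    shape: str  # 'disk' | 'ellipse' | 'half-plane'
    dimensions: tuple[float, ...] = ()
    uniform_hu: float = WATER_HU
    pixel_spacing: float = 0.8  # mm, isotropic
    image_size: int = 512  # pixels per side
    include_table: bool = False
    noise_sd: float = 0.0  # HU

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "ellipse", "half-plane"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.shape == "disk" and len(self.dimensions) != 1:
            raise ValueError("disk needs dimensions=(diameter,)")
        if self.shape == "ellipse" and len(self.dimensions) != 2:
            raise ValueError("ellipse needs dimensions=(a, b) semi-axes")

    @property
    def analytic_dw(self) -> Optional[float]:
        """Ground-truth D_w (cm) of the phantom body alone, if defined."""
        w = 1.0 + self.uniform_hu / 1000.0  # water-equivalence of the material
        if self.shape == "disk":
            (d,) = self.dimensions
            return d * math.sqrt(w)
        if self.shape == "ellipse":
            a, b = self.dimensions
            return 2.0 * math.sqrt(a * b * w)
        return None


def _pixel_grid(image_size: int, pixel_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates (x, y) in cm, origin at the image centre."""
    c = np.arange(image_size, dtype=float) - (image_size - 1) / 2.0
    coords = c * pixel_spacing / 10.0
    return np.meshgrid(coords, coords)  # x varies along columns, y along rows


def _render_body(spec: PhantomSpec) -> tuple[np.ndarray, float]:
    """Render the phantom body; returns (HU image, body half-height in cm)."""
    x, y = _pixel_grid(spec.image_size, spec.pixel_spacing)
    half_extent = spec.image_size * spec.pixel_spacing / 20.0  # cm
    if spec.shape == "disk":
        (d,) = spec.dimensions
        r = d / 2.0
        if r > half_extent:
            raise ValueError(f"disk of diameter {d} cm exceeds the {2*half_extent:.1f} cm image")
        mask = x**2 + y**2 <= r**2
        half_height = r
    elif spec.shape == "ellipse":
        a, b = spec.dimensions
        if a > half_extent or b > half_extent:
            raise ValueError("ellipse exceeds the image extent")
        mask = (x / a) ** 2 + (y / b) ** 2 <= 1.0
        half_height = b
    else:  # half-plane: water fills y >= 0 (lower half, image row convention)
        mask = y >= 0
        half_height = half_extent
    img = np.full(mask.shape, AIR_HU)
    img[mask] = spec.uniform_hu
    return img, half_height


def _render_table(spec: PhantomSpec, body_half_height: float) -> tuple[np.ndarray, float]:
    """Couch strip mask and its analytic water-equivalent area (cm^2)."""
    x, y = _pixel_grid(spec.image_size, spec.pixel_spacing)
    half_extent = spec.image_size * spec.pixel_spacing / 20.0
    top = body_half_height + TABLE_GAP_CM
    if top + TABLE_HEIGHT_CM > half_extent:
        raise ValueError("couch strip does not fit below the phantom")
    mask = (np.abs(x) <= TABLE_WIDTH_CM / 2.0) & (y >= top) & (y <= top + TABLE_HEIGHT_CM)
    aw = TABLE_WIDTH_CM * TABLE_HEIGHT_CM * (1.0 + TABLE_HU / 1000.0)
    return mask, aw


def make_phantom_series(
    spec: PhantomSpec,
    n_slices: int = 10,
    seed: Optional[int] = None,
    z_spacing: float = 5.0,
) -> ScanSeries:
    """A stack of identical phantom slices (plus independent noise per slice).

    The returned series carries its analytic ground truth in
    ``series.ground_truth``: the nominal D_w of the body (``dw_cm``), and,
    when a couch is included, its nominal water-equivalent area
    (``aw_table_cm2``) and boolean mask (``table_mask``) for calibration.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    body, half_height = _render_body(spec)
    ground_truth: dict = {"dw_cm": spec.analytic_dw}
    if spec.include_table:
        table_mask, aw_table = _render_table(spec, half_height)
        body = body.copy()
        body[table_mask] = TABLE_HU
        ground_truth["table_mask"] = table_mask
        ground_truth["aw_table_cm2"] = aw_table
    rng = np.random.default_rng(seed)
    slices = []
    for i in range(n_slices):
        img = body
        if spec.noise_sd > 0:
            img = body + rng.normal(0.0, spec.noise_sd, body.shape)
        slices.append(
            CTSlice(
                pixels=img.copy(),
                pixel_spacing=(spec.pixel_spacing, spec.pixel_spacing),
                z_position=i * z_spacing,
                slice_id=i,
            )
        )
    return ScanSeries(slices=slices, exam_type="phantom", ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# anatomy-shaped D_w(z) profiles

DEFAULT_SCAN_LENGTH_MM = {"chest": 320.0, "CAP": 650.0}
DEFAULT_RANGE_FRACTION = 0.23  # (D_w_max - D_w_min) / D_w_ave


def _anatomy_shape(exam_type: str, t: np.ndarray) -> np.ndarray:
    """Dimensionless anatomy template on t in [0, 1] (0 = superior end).

    chest: a cranio-caudal ramp (shoulders thinner in water-equivalent
    terms than the diaphragm/upper abdomen) with a lung dip centred
    mid-scan.  CAP: a lung dip in the upper scan third and a broad
    abdominal bulge peaking at ~60% of the scan, so the mid-scan slice
    sits on the rising flank of the liver region, above the scan mean.
    """
    if exam_type == "chest":
        return t - 0.25 * np.exp(-(((t - 0.5) / 0.15) ** 2))
    if exam_type == "CAP":
        return np.exp(-(((t - 0.60) / 0.28) ** 2)) - 0.6 * np.exp(-(((t - 0.15) / 0.12) ** 2))
    raise ValueError(f"no anatomy template for exam_type {exam_type!r}")


def anatomy_profile(
    exam_type: str,
    dw_ave_target: float,
    scan_length_mm: Optional[float] = None,
    n_slices: Optional[int] = None,
    range_fraction: float = DEFAULT_RANGE_FRACTION,
    window_shift: float = 0.0,
    slice_spacing_mm: float = 5.0,
) -> DwProfile:
    """Ground-truth D_w(z) curve for one synthetic examination.

    The template is normalised on the nominal scan window so that, at
    ``window_shift = 0``, the discrete mean equals ``dw_ave_target``
    exactly and max - min equals ``range_fraction * dw_ave_target``.
    ``window_shift`` (fraction of scan length) slides the scan window over
    the fixed anatomy, emulating scan-length/positioning variation: it
    moves the anatomical location of the mid-scan slice (perturbing D_w_c)
    while barely changing the scan mean.
    """
    if exam_type not in ("chest", "CAP"):
        raise ValueError(f"no anatomy template for exam_type {exam_type!r}")
    if dw_ave_target <= 0:
        raise ValueError("dw_ave_target must be positive")
    if scan_length_mm is None:
        scan_length_mm = DEFAULT_SCAN_LENGTH_MM[exam_type]
    if n_slices is None:
        n_slices = int(round(scan_length_mm / slice_spacing_mm)) + 1
    t_nominal = np.linspace(0.0, 1.0, n_slices)
    u_nominal = _anatomy_shape(exam_type, t_nominal)
    scale = range_fraction * dw_ave_target / np.ptp(u_nominal)
    offset = dw_ave_target - u_nominal.mean() * scale
    u = _anatomy_shape(exam_type, t_nominal + window_shift)
    dw = np.maximum(offset + u * scale, 1.0)
    z = t_nominal * scan_length_mm
    return DwProfile(z=z, dw=dw, exam_type=exam_type)


def profile_to_series(
    profile: DwProfile,
    pixel_spacing: float = 1.0,
    image_size: int = 448,
    include_table: bool = False,
    seed: Optional[int] = None,
    noise_sd: float = 0.0,
    aspect: float = 0.7,
) -> ScanSeries:
    """Render a D_w(z) curve as a stack of water-equivalent ellipse slices.

    Each slice is a uniform 0-HU ellipse with AP:LAT ratio ``aspect`` whose
    analytic D_w equals the curve value, so the imaging pipeline can be
    exercised end-to-end against the curve as ground truth.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    slices = []
    table_truth: dict = {}
    # one fixed couch position for the whole series, below the largest body
    max_half_height = float(profile.dw.max()) * math.sqrt(aspect) / 2.0
    for i, (z, dw) in enumerate(zip(profile.z, profile.dw)):
        a = dw / (2.0 * math.sqrt(aspect))  # lateral semi-axis, cm
        b = a * aspect
        spec = PhantomSpec(
            shape="ellipse",
            dimensions=(a, b),
            pixel_spacing=pixel_spacing,
            image_size=image_size,
            include_table=include_table,
        )
        img, _ = _render_body(spec)
        if include_table:
            table_mask, aw_table = _render_table(spec, max_half_height)
            img[table_mask] = TABLE_HU
            table_truth = {"table_mask": table_mask, "aw_table_cm2": aw_table}
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        current = None if profile.current is None else float(profile.current[i])
        slices.append(
            CTSlice(
                pixels=img,
                pixel_spacing=(pixel_spacing, pixel_spacing),
                z_position=float(z),
                tube_current=current,
                slice_id=i,
            )
        )
    exam = profile.exam_type if profile.exam_type in ("chest", "CAP") else "phantom"
    return ScanSeries(
        slices=slices,
        ctdi_vol=profile.ctdi_vol,
        exam_type=exam,
        ground_truth={"dw_curve": profile.dw.copy(), **table_truth},
    )


# ---------------------------------------------------------------------------
# ATCM emulation and cohort sampling


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    The dose model is noise-constant: I(z) = clamp(I_ref * exp(k * (D_w(z)
    - D_w_ref)), I_min, I_max), with CTDI_vol proportional to the mean
    current.  k defaults to ln2/6 per cm, so a 6-cm increase in D_w_ave
    (about 24% of a 25-cm patient) doubles CTDI_vol.
    """

    n_per_exam: dict = field(default_factory=lambda: {"CAP": 120, "chest": 80})
    scanner_id: str = "CT14"
    seed: int = 0

    # biometrics (adult oncology population, truncated distributions)
    weight_log_mean: dict = field(default_factory=lambda: {"F": math.log(63.0), "M": math.log(71.0)})
    weight_log_sd: float = 0.20
    weight_range_kg: tuple[float, float] = (43.0, 117.0)
    height_mean_cm: dict = field(default_factory=lambda: {"F": 160.0, "M": 168.0})
    height_sd_cm: dict = field(default_factory=lambda: {"F": 6.5, "M": 7.0})
    height_range_cm: dict = field(default_factory=lambda: {"F": (144.0, 175.0), "M": (145.0, 185.0)})

    # weight -> D_w_ave relation (cm = slope * kg + intercept + residual)
    dw_slope: float = 0.162
    dw_intercept: float = 14.0
    dw_resid_sd: float = 1.2

    # dose model
    k: float = math.log(2.0) / 6.0  # per cm
    i_ref: float = 170.0  # mA at dw_ref
    dw_ref: float = 26.0  # cm
    i_min: float = 80.0  # mA
    i_max: float = 500.0  # mA
    dose_const: float = 0.055  # mGy per mA of mean current
    dose_noise_sd: float = 0.08  # sd of log of the multiplicative dose noise

    # profile geometry
    range_fraction: float = DEFAULT_RANGE_FRACTION
    scan_length_mm: dict = field(default_factory=lambda: dict(DEFAULT_SCAN_LENGTH_MM))
    slice_spacing_mm: float = 5.0
    jitter_sd: float = 0.08  # scan-window shift, fraction of scan length

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        for name in ("weight_log_sd", "dw_resid_sd", "dose_noise_sd", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.i_min < self.i_max):
            raise ValueError("need 0 < i_min < i_max")
        if self.weight_range_kg[0] >= self.weight_range_kg[1]:
            raise ValueError("weight_range_kg must be ordered")


def emulate_atcm(
    dw_curve: np.ndarray, config: CohortConfig, i_ref: Optional[float] = None
) -> tuple[np.ndarray, float]:
    """Noise-constant modulation response to a D_w(z) curve.

    Returns the clamped per-slice current I(z) (mA) and the examination
    CTDI_vol (mGy, proportional to mean current).
    """
    dw_curve = np.asarray(dw_curve, dtype=float)
    if dw_curve.size == 0:
        raise ValueError("empty D_w curve")
    if i_ref is None:
        i_ref = config.i_ref
    current = np.clip(
        i_ref * np.exp(config.k * (dw_curve - config.dw_ref)), config.i_min, config.i_max
    )
    return current, float(config.dose_const * current.mean())


def _truncated(draw, lo: float, hi: float, max_tries: int = 1000) -> float:
    for _ in range(max_tries):
        v = draw()
        if lo <= v <= hi:
            return float(v)
    raise RuntimeError("truncated sampling failed; distribution/range mismatch")


def sample_cohort(
    config: CohortConfig, with_profiles: bool = False
) -> list[ExamRecord] | list[tuple[ExamRecord, DwProfile]]:
    """Sample the full synthetic cohort as analysis-ready exam records.

    Per patient: sex, truncated-lognormal weight, truncated-normal height;
    D_w_ave from the weight regression plus residual; an anatomy profile
    with scan-window jitter; modulated currents and CTDI_vol from the
    emulator (with multiplicative lognormal dose noise); D_w metrics
    recomputed from the profile; SSDE from f(D_w_c).  Pure function of
    (config, seed).
    """
    table = None  # default embedded conversion table
    out = []
    for exam_index, (exam_type, n) in enumerate(sorted(config.n_per_exam.items())):
        root = np.random.SeedSequence(config.seed, spawn_key=(exam_index,))
        for i, child in enumerate(root.spawn(n)):
            rng = np.random.default_rng(child)
            sex = "F" if rng.random() < 0.5 else "M"
            weight = _truncated(
                lambda: rng.lognormal(config.weight_log_mean[sex], config.weight_log_sd),
                *config.weight_range_kg,
            )
            height = _truncated(
                lambda: rng.normal(config.height_mean_cm[sex], config.height_sd_cm[sex]),
                *config.height_range_cm[sex],
            )
            age = float(rng.integers(21, 90))
            dw_target = config.dw_slope * weight + config.dw_intercept + rng.normal(0.0, config.dw_resid_sd)
            shift = rng.normal(0.0, config.jitter_sd)
            profile = anatomy_profile(
                exam_type,
                dw_target,
                scan_length_mm=config.scan_length_mm[exam_type],
                range_fraction=config.range_fraction,
                window_shift=shift,
                slice_spacing_mm=config.slice_spacing_mm,
            )
            i_ref_eff = config.i_ref * math.exp(rng.normal(0.0, config.dose_noise_sd))
            currents, ctdi = emulate_atcm(profile.dw, config, i_ref_eff)
            profile = DwProfile(
                z=profile.z, dw=profile.dw, current=currents, exam_type=exam_type, ctdi_vol=ctdi
            )
            m = dw_metrics(profile)
            record = ExamRecord(
                ctdi_vol=ctdi,
                dw_c=m.dw_c,
                dw_ave=m.dw_ave,
                dw_min=m.dw_min,
                dw_max=m.dw_max,
                ssde=ssde(ctdi, m.dw_c, table),
                exam_type=exam_type,
                scanner_id=config.scanner_id,
                patient=PatientBio(weight=weight, height=height, sex=sex, age=age),
                patient_id=f"{exam_type}-{i:04d}",
                ssde_metric="dwc",
                currents=currents,
            )
            out.append((record, profile) if with_profiles else record)
    return out
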