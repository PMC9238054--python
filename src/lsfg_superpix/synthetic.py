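"""Synthetic paired-eye LSFG cohorts with a programmable irradiation effect.

No public LSFG dataset accompanies the clinical setting this package
targets (plaque brachytherapy for uveal melanoma), so every downstream
stage is exercised against cohorts built here.  A synthetic patient has two
eyes, each imaged three times.  Each composite MBR map is assembled from:

* a spatially correlated choroidal background (low-pass-filtered Gaussian
  field around ~10 AU, giving patchy low-flow regions),
* a branching retinal vessel tree at high MBR (~25 AU) rooted at the optic
  disc,
* a high-flow disc region, and
* independent per-scan Gaussian noise plus a small fraction of undefined
  pixels.

The irradiation effect is multiplicative and time-dependent: the whole map
of the treated eye is scaled by ``m(t) = max(m_min, 1 - k * t_months)``
while the fellow eye always receives multiplier 1.  This is a deliberately
simple injury model that reproduces the qualitative clinical pattern —
irradiated-eye flow falling with time from treatment while the fellow eye
stays flat — and every parameter of it is configurable.

Anatomy (vessels, background) is shared across the three repeat scans of an
eye; only scan noise and the undefined-pixel pattern differ, mimicking
repeat acquisitions of the same fundus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.morphology import dilation, erosion

from .scan_io import CohortPatient, LSFGScan

__all__ = [
    "EffectModel",
    "SyntheticPatientSpec",
    "BranchingParams",
    "CohortGeometry",
    "generate_vessel_tree",
    "render_scan",
    "generate_cohort",
    "to_cohort_patients",
]


@dataclass(frozen=True)
class EffectModel:
    """Flow levels, noise, and the time-dependent irradiation multiplier.

    All MBR levels are in AU.  ``k_per_month`` and ``m_min`` parameterise
    the irradiated-eye multiplier ``m(t) = max(m_min, 1 - k * t)``; with
    ``k_per_month = 0`` (or ``m_min = 1``) the cohort is a null cohort in
    which the two eyes differ only by anatomy and noise.
    """

    baseline_vessel_mbr: float = 25.0
    baseline_choroid_mbr_mean: float = 10.0
    choroid_mbr_sd: float = 3.0
    disc_mbr: float = 30.0
    k_per_month: float = 0.01
    m_min: float = 0.4
    scan_noise_sd: float = 1.0
    undefined_pixel_fraction: float = 0.005

    def __post_init__(self) -> None:
        for name in ("baseline_vessel_mbr", "baseline_choroid_mbr_mean",
                     "choroid_mbr_sd", "disc_mbr", "scan_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative (flow cannot be negative)")
        if not (0 < self.m_min <= 1):
            raise ValueError(f"m_min must be in (0, 1], got {self.m_min}")
        if self.k_per_month < 0:
            raise ValueError(f"k_per_month must be non-negative, got {self.k_per_month}")
        if not (0 <= self.undefined_pixel_fraction < 1):
            raise ValueError("undefined_pixel_fraction must lie in [0, 1)")

    def flow_multiplier(self, t_months: float, irradiated: bool) -> float:
        """m(t) for the treated eye; the fellow eye always gets 1."""
        if not irradiated:
            return 1.0
        if t_months < 0:
            raise ValueError("time from treatment must be non-negative")
        return max(self.m_min, 1.0 - self.k_per_month * t_months)


@dataclass(frozen=True)
class SyntheticPatientSpec:
    """Covariates and the per-patient random seed."""

    patient_id: str
    time_from_treatment: float  # months
    irradiated_eye: str  # OD | OS
    sbp: float  # mmHg
    dbp: float  # mmHg
    iop_irradiated: float  # mmHg
    iop_fellow: float  # mmHg
    dose_to_disc: float  # Gy
    distance_tumor_to_disc: float  # mm
    rng_seed: int

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise ValueError(f"require sbp > dbp > 0, got {self.sbp}, {self.dbp}")
        if min(self.iop_irradiated, self.iop_fellow) < 0:
            raise ValueError("IOP must be non-negative")
        if self.time_from_treatment < 0:
            raise ValueError("time_from_treatment must be non-negative")
        if self.irradiated_eye not in ("OD", "OS"):
            raise ValueError(f"irradiated_eye must be OD or OS, got {self.irradiated_eye}")

    def iop(self, eye: str) -> float:
        return self.iop_irradiated if eye == self.irradiated_eye else self.iop_fellow


@dataclass(frozen=True)
class BranchingParams:
    """Controls the random vessel tree grown from the disc centre."""

    n_trunks: int = 5
    n_branches: int = 2  # children spawned at the end of each segment
    depth: int = 2  # branching generations beyond the trunks
    trunk_width_px: float = 12.0
    width_taper: float = 0.75  # child width = parent width * taper
    trunk_len_frac: float = 0.45  # trunk length as a fraction of min(shape)
    turn_sd: float = 0.06  # radians of random heading change per step

    def __post_init__(self) -> None:
        if self.n_trunks < 1 or self.trunk_width_px <= 0 or self.trunk_len_frac <= 0:
            raise ValueError("invalid branching parameters")
        if self.n_branches < 0 or self.depth < 0:
            raise ValueError("invalid branching parameters")


@dataclass(frozen=True)
class CohortGeometry:
    """Frame and disc geometry of the simulated sensor.

    The default frame matches a 750 x 360 px sensor stored row-major as
    (360, 750); the optic disc sits at the frame centre with a 40 px
    radius.  ``for_shape`` rescales disc size, background correlation
    length and vessel calibre proportionally for reduced-size frames, so
    small simulations preserve the full-frame composition.
    """

    shape: tuple[int, int] = (360, 750)
    disc_center: tuple[float, float] | None = None  # None -> frame centre
    disc_radius: float = 40.0
    correlation_length_px: float = 30.0
    branching: BranchingParams = field(default_factory=BranchingParams)

    def center(self) -> tuple[float, float]:
        if self.disc_center is not None:
            return self.disc_center
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    @classmethod
    def for_shape(cls, shape: tuple[int, int]) -> "CohortGeometry":
        s = min(shape) / 360.0
        base = BranchingParams()
        return cls(
            shape=tuple(shape),
            disc_radius=max(4.0, 40.0 * s),
            correlation_length_px=max(2.0, 30.0 * s),
            branching=replace(base, trunk_width_px=max(2.0, base.trunk_width_px * s)),
        )

    def matched_n_superpixels(self, n_full: int = 1500) -> int:
        """Superpixel target preserving the pitch-to-anatomy ratio.

        On the full 360 x 750 frame ~1500 superpixels give a ~13 px pitch,
        about one trunk-vessel calibre.  A frame scaled by ``s`` keeps the
        composition only if the pitch also scales by ``s``, which leaves
        the superpixel count approximately unchanged for aspect-preserving
        rescaling.
        """
        s = min(self.shape) / 360.0
        area_ratio = (self.shape[0] * self.shape[1]) / (360.0 * 750.0)
        return max(4, round(n_full * area_ratio / s**2))


def generate_vessel_tree(
    shape: tuple[int, int],
    seed: int | np.random.SeedSequence,
    branching: BranchingParams | None = None,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Grow a binary mask of branching curvilinear vessels from the disc.

    Trunks leave the disc centre at jittered, roughly evenly spaced
    headings and meander outwards as random walks of overlapping disks;
    each trunk spawns narrower children for ``depth`` generations.  The
    final vessel-pixel fraction is coerced into [2%, 20%] of the frame by
    morphological dilation/erosion, keeping each tree connected.
    """
    if min(shape) < 32:
        raise ValueError(f"frame too small for a vessel tree: shape {shape}")
    params = branching or BranchingParams()
    rng = np.random.default_rng(seed)
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    mask = np.zeros(shape, dtype=bool)

    def grow(pos, angle, width, length, depth):
        y, x = pos
        for _ in range(int(length)):
            angle += rng.normal(0.0, params.turn_sd)
            y += math.sin(angle)
            x += math.cos(angle)
            if not (-width <= y < shape[0] + width and -width <= x < shape[1] + width):
                return
            rr, cc = draw_disk((y, x), max(1.0, width / 2.0), shape=shape)
            mask[rr, cc] = True
        if depth > 0:
            for j in range(params.n_branches):
                spread = (j - (params.n_branches - 1) / 2.0) * 0.9 + rng.normal(0, 0.2)
                grow((y, x), angle + spread, width * params.width_taper,
                     length * 0.7, depth - 1)

    trunk_len = params.trunk_len_frac * min(shape)
    for i in range(params.n_trunks):
        heading = 2.0 * math.pi * i / params.n_trunks + rng.normal(0.0, 0.25)
        grow(center, heading, params.trunk_width_px, trunk_len, params.depth)

    lo, hi = 0.02, 0.20
    while mask.mean() < lo:
        mask = dilation(mask)
    while mask.mean() > hi:
        eroded = erosion(mask)
        if not eroded.any():
            break
        mask = eroded
    return mask


@lru_cache(maxsize=32)
def _anatomy(
    spec: SyntheticPatientSpec,
    eye: str,
    effect: EffectModel,
    geometry: CohortGeometry,
) -> np.ndarray:
    """Noise-free baseline MBR map of one eye (before irradiation scaling).

    Cached because the three repeat scans of an eye share one anatomy; the
    returned array must not be mutated by callers.
    """
    eye_idx = 0 if eye == "OD" else 1
    ss = np.random.SeedSequence(entropy=spec.rng_seed, spawn_key=(eye_idx,))
    ss_vessel, ss_field = ss.spawn(2)
    shape = geometry.shape
    vessels = generate_vessel_tree(
        shape, ss_vessel, geometry.branching, center=geometry.center()
    )
    rng = np.random.default_rng(ss_field)
    white = rng.standard_normal(shape)
    sigma = geometry.correlation_length_px / 2.0
    fieldmap = gaussian_filter(white, sigma, mode="reflect")
    sd = fieldmap.std()
    if sd > 0:
        fieldmap *= effect.choroid_mbr_sd / sd
    mbr = effect.baseline_choroid_mbr_mean + fieldmap
    mbr[vessels] = effect.baseline_vessel_mbr
    cy, cx = geometry.center()
    rr, cc = draw_disk((cy, cx), geometry.disc_radius, shape=shape)
    mbr[rr, cc] = effect.disc_mbr
    return np.clip(mbr, 0.0, None)


def render_scan(
    spec: SyntheticPatientSpec,
    eye: str,
    scan_index: int,
    effect: EffectModel | None = None,
    geometry: CohortGeometry | None = None,
) -> LSFGScan:
    """Render one composite MBR map for one eye and repeat-scan index.

    The anatomy is deterministic per (patient, eye); the irradiated eye's
    map is scaled by ``m(t)`` before scan noise is added; a random
    ``undefined_pixel_fraction`` of pixels is marked invalid.
    """
    if scan_index not in (1, 2, 3):
        raise ValueError(f"scan_index must be in 1..3, got {scan_index}")
    effect = effect or EffectModel()
    geometry = geometry or CohortGeometry()
    irradiated = eye == spec.irradiated_eye
    m = effect.flow_multiplier(spec.time_from_treatment, irradiated)
    mbr = _anatomy(spec, eye, effect, geometry) * m

    eye_idx = 0 if eye == "OD" else 1
    ss = np.random.SeedSequence(entropy=spec.rng_seed, spawn_key=(eye_idx, 10 + scan_index))
    rng = np.random.default_rng(ss)
    mbr = np.clip(mbr + rng.normal(0.0, effect.scan_noise_sd, mbr.shape), 0.0, None)
    valid = np.ones(mbr.shape, dtype=bool)
    if effect.undefined_pixel_fraction > 0:
        valid = rng.random(mbr.shape) >= effect.undefined_pixel_fraction
        mbr = mbr.copy()
        mbr[~valid] = np.nan
    return LSFGScan(
        mbr=mbr,
        valid=valid,
        patient_id=spec.patient_id,
        eye=eye,
        irradiated=irradiated,
        scan_index=scan_index,
    )


def generate_cohort(
    n_patients: int,
    effect: EffectModel | None = None,
    seed: int = 0,
    geometry: CohortGeometry | None = None,
    time_range_months: tuple[float, float] = (0.5, 144.0),
) -> list[tuple[SyntheticPatientSpec, list[LSFGScan]]]:
    """Simulate a full cross-sectional cohort: covariates plus 6 scans each.

    Times from treatment are spread uniformly over ``time_range_months``
    (defaults cover two weeks to twelve years); blood pressures and IOP are
    drawn around typical cohort means (SBP 136 +/- 17, DBP 80 +/- 10 mmHg,
    IOP ~14-15 mmHg), dose to disc around 38 Gy and tumor-to-disc distance
    around 5 mm.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients for paired statistics")
    effect = effect or EffectModel()
    geometry = geometry or CohortGeometry()
    master = np.random.SeedSequence(seed)
    cov_rng = np.random.default_rng(master.spawn(1)[0])
    patient_seeds = [
        int(child.generate_state(1)[0] % (2**31)) for child in master.spawn(n_patients + 1)[1:]
    ]
    lo, hi = time_range_months
    entries = []
    for i in range(n_patients):
        t = float(cov_rng.uniform(lo, hi))
        dbp = float(np.clip(cov_rng.normal(80.0, 10.0), 50.0, 120.0))
        pulse = float(np.clip(cov_rng.normal(56.0, 13.7), 10.0, None))
        spec = SyntheticPatientSpec(
            patient_id=f"P{i + 1:03d}",
            time_from_treatment=t,
            irradiated_eye="OD" if cov_rng.random() < 0.5 else "OS",
            sbp=dbp + pulse,
            dbp=dbp,
            iop_irradiated=float(np.clip(cov_rng.normal(14.4, 3.8), 5.0, 40.0)),
            iop_fellow=float(np.clip(cov_rng.normal(15.2, 3.2), 5.0, 40.0)),
            dose_to_disc=float(np.clip(cov_rng.normal(38.0, 20.0), 2.0, 150.0)),
            distance_tumor_to_disc=float(np.clip(cov_rng.normal(5.0, 3.0), 0.1, 15.0)),
            rng_seed=patient_seeds[i],
        )
        scans = [
            render_scan(spec, eye, idx, effect, geometry)
            for eye in ("OD", "OS")
            for idx in (1, 2, 3)
        ]
        entries.append((spec, scans))
    return entries


def to_cohort_patients(
    entries: list[tuple[SyntheticPatientSpec, list[LSFGScan]]],
    geometry: CohortGeometry | None = None,
) -> list[CohortPatient]:
    """Repackage generator output into the cohort container used by I/O."""
    geometry = geometry or CohortGeometry()
    patients = []
    for spec, scans in entries:
        by_eye: dict[str, list[LSFGScan]] = {"OD": [], "OS": []}
        for scan in scans:
            by_eye[scan.eye].append(scan)
        patients.append(
            CohortPatient(
                patient_id=spec.patient_id,
                irradiated_eye=spec.irradiated_eye,
                time_from_treatment=spec.time_from_treatment,
                sbp=spec.sbp,
                dbp=spec.dbp,
                iop={"OD": spec.iop("OD"), "OS": spec.iop("OS")},
                dose_to_disc=spec.dose_to_disc,
                distance_to_disc=spec.distance_tumor_to_disc,
                scans=by_eye,
                disc_center=geometry.center(),
                disc_radius=geometry.disc_radius,
            )
        )
    return patients
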