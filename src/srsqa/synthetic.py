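"""Synthetic multi-metastasis patients and technique-flavored dose fields.

The simulator stands in for a radiosurgery planning cohort: each patient
is an ellipsoidal brain containing 3-8 spherical lesions with individual
prescriptions between 10 and 24 Gy, plus a fixed template of organs at
risk (brainstem, chiasm, optic nerves, eyes, lenses).  The default
15-patient cohort reproduces the lesion-count frequencies of the clinical
cohort it emulates: eleven patients with 3 lesions and one patient each
with 5, 6 and 8 (the fifteenth patient is assigned 4 lesions, inside the
stated 3-8 range).

A delivery technique is represented purely by the *shape* of the dose it
deposits (no beam transport): each lesion contributes a spherical kernel
at its prescription with a radial heterogeneity ripple inside the sphere
and an exponential falloff of scale ``falloff_length`` outside; kernels
combine as max plus ``bridging_gain`` times the excess-over-max (so an
isolated lesion peaks at its prescription while nearby lesions can bridge);
a diffuse low-dose bath covers the brain; multiplicative log-normal noise
roughens the field.  Every rendered plan is normalized so that 95% of the
pooled target volume receives the prescription (V100% = 95%).

The three bundled profiles emulate the qualitative contrasts between
non-coplanar single-isocenter arcs (HA-like: steepest falloff, smallest
bath), conventional VMAT (VMAT-like: shallowest falloff, largest bath,
most homogeneous targets) and robotic radiosurgery (CK-like: smallest
bath, intermediate falloff).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .core import DoseGrid, Structure
from .metrics import NormalizationResult, normalize_plan

__all__ = [
    "LesionSpec",
    "TechniqueProfile",
    "SyntheticPatientSpec",
    "default_profiles",
    "sample_cohort",
    "sample_patient",
    "build_structures",
    "render_dose",
    "DEFAULT_BRAIN_SEMIAXES",
    "DEFAULT_OAR_TEMPLATE",
]

# mm, axis order (z, y, x); z superior, y anterior, x patient-left
DEFAULT_BRAIN_SEMIAXES = (60.0, 80.0, 65.0)
GRID_MARGIN_MM = 10.0

#: Geometric OAR primitives at fixed offsets from the brain center (mm).
DEFAULT_OAR_TEMPLATE: dict[str, dict] = {
    "brainstem": {"kind": "zcylinder", "center": (-37.5, -15.0, 0.0),
                  "radius": 8.0, "half_length": 22.5},
    "chiasm": {"kind": "box", "center": (-25.0, 12.0, 0.0),
               "half_size": (3.0, 4.0, 8.0)},
    "optic_nerve_l": {"kind": "ycylinder", "center": (-25.0, 29.0, 14.0),
                      "radius": 2.2, "half_length": 13.0},
    "optic_nerve_r": {"kind": "ycylinder", "center": (-25.0, 29.0, -14.0),
                      "radius": 2.2, "half_length": 13.0},
    "eye_l": {"kind": "sphere", "center": (-25.0, 58.0, 31.0), "radius": 12.0},
    "eye_r": {"kind": "sphere", "center": (-25.0, 58.0, -31.0), "radius": 12.0},
    "lens_l": {"kind": "sphere", "center": (-25.0, 68.0, 31.0), "radius": 2.5},
    "lens_r": {"kind": "sphere", "center": (-25.0, 68.0, -31.0), "radius": 2.5},
}

#: Lesion-count frequencies of the emulated 15-patient cohort.
COHORT_LESION_COUNTS = [3] * 11 + [4, 5, 6, 8]


@dataclass
class LesionSpec:
    center: tuple[float, float, float]  # mm, (z, y, x)
    radius: float  # mm
    prescription: float  # Gy

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("lesion radius must be > 0")
        if not 10.0 <= self.prescription <= 24.0:
            raise ValueError(
                f"prescription {self.prescription} Gy outside the 10-24 Gy range"
            )


@dataclass
class TechniqueProfile:
    """Dose-shape parameters standing in for a delivery technique."""

    name: str
    falloff_length: float  # mm, exponential gradient scale outside lesions
    bath_level: float  # fraction of the mean prescription, diffuse in brain
    intra_target_heterogeneity: float  # fractional dose spread inside lesions
    bridging_gain: float  # amplification of overlapping kernel tails
    noise_sd: float  # fractional multiplicative noise

    def __post_init__(self) -> None:
        if min(self.falloff_length, self.bath_level,
               self.intra_target_heterogeneity, self.bridging_gain,
               self.noise_sd) < 0:
            raise ValueError("profile parameters must be >= 0")
        if self.bath_level >= 0.5:
            raise ValueError("bath_level must be < 0.5")
        if self.intra_target_heterogeneity >= 1:
            raise ValueError("intra_target_heterogeneity must be < 1")


@dataclass
class SyntheticPatientSpec:
    patient_id: str
    lesions: list[LesionSpec]
    brain_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    brain_semiaxes: tuple[float, float, float] = DEFAULT_BRAIN_SEMIAXES
    oars: dict[str, dict] = field(default_factory=lambda: dict(DEFAULT_OAR_TEMPLATE))
    grid_spacing: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 3 <= len(self.lesions) <= 8:
            raise ValueError(
                f"lesion count must be 3-8, got {len(self.lesions)}"
            )
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")


def default_profiles() -> dict[str, TechniqueProfile]:
    """The three bundled technique profiles.

    Parameters were fixed once from the qualitative contrasts the
    simulator must reproduce: the HA-like profile has the steepest
    falloff (lowest gradient index, smallest low-dose spill), the
    VMAT-like profile the shallowest falloff and largest bath but the
    most homogeneous target dose, and the CK-like profile the smallest
    bath (best distant-OAR sparing) with intermediate falloff and high
    intra-target heterogeneity.
    """
    return {
        "HA-like": TechniqueProfile(
            name="HA-like", falloff_length=3.5, bath_level=0.03,
            intra_target_heterogeneity=0.20, bridging_gain=0.15, noise_sd=0.02,
        ),
        "VMAT-like": TechniqueProfile(
            name="VMAT-like", falloff_length=6.0, bath_level=0.08,
            intra_target_heterogeneity=0.05, bridging_gain=0.4, noise_sd=0.02,
        ),
        "CK-like": TechniqueProfile(
            name="CK-like", falloff_length=4.5, bath_level=0.02,
            intra_target_heterogeneity=0.15, bridging_gain=0.1, noise_sd=0.02,
        ),
    }


# ---------------------------------------------------------------------------
# cohort sampling

def _sample_lesions(
    rng: np.random.Generator,
    n_lesions: int,
    brain_semiaxes: tuple[float, float, float],
    min_separation: float,
    max_attempts: int = 5000,
) -> list[LesionSpec]:
    lesions: list[LesionSpec] = []
    semi = np.asarray(brain_semiaxes)
    for _ in range(max_attempts):
        if len(lesions) == n_lesions:
            break
        radius = float(rng.uniform(5.0, 12.5))
        # direction uniform in the unit ball, scaled so the lesion sphere
        # stays 3 mm inside the brain surface
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        rho = rng.uniform() ** (1 / 3)
        center = u * rho * np.maximum(semi - radius - 3.0, 0.0)
        ok = all(
            np.linalg.norm(center - np.asarray(l.center))
            >= radius + l.radius + min_separation
            for l in lesions
        )
        if not ok:
            continue
        # smaller lesions get higher prescriptions, as in clinical practice
        rx = 24.0 - (radius - 5.0) * 9.0 / 7.5 + rng.normal(0.0, 1.5)
        rx = float(np.clip(np.round(rx * 2) / 2, 10.0, 24.0))
        lesions.append(LesionSpec(tuple(center), radius, rx))
    if len(lesions) < n_lesions:
        raise RuntimeError(
            f"could not place {n_lesions} lesions with min separation "
            f"{min_separation} mm after {max_attempts} attempts"
        )
    return lesions


def sample_patient(
    patient_id: str,
    n_lesions: int,
    seed: int,
    min_separation: float = 10.0,
    grid_spacing: float = 2.0,
) -> SyntheticPatientSpec:
    """One synthetic patient with ``n_lesions`` rejection-sampled lesions."""
    rng = np.random.default_rng(seed)
    lesions = _sample_lesions(rng, n_lesions, DEFAULT_BRAIN_SEMIAXES, min_separation)
    return SyntheticPatientSpec(
        patient_id=patient_id,
        lesions=lesions,
        grid_spacing=grid_spacing,
        seed=seed,
    )


def sample_cohort(
    n_patients: int,
    seed: int,
    lesion_counts: list[int] | None = None,
    fixed_lesions: list[LesionSpec] | None = None,
    min_separation: float = 10.0,
    grid_spacing: float = 2.0,
) -> list[SyntheticPatientSpec]:
    """Sample a reproducible cohort of synthetic patients.

    With ``n_patients=15`` and no overrides, the lesion counts follow the
    emulated cohort exactly (11 patients with 3 lesions; one each with
    4, 5, 6, 8); other cohort sizes draw counts from those frequencies.
    ``fixed_lesions`` bypasses sampling and echoes the given lesions into
    every patient.  ``min_separation`` is the minimum surface-to-surface
    lesion distance in mm (>= 5 exercises dose bridging).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if min_separation < 5.0:
        raise ValueError("min_separation below 5 mm is not supported")
    ss = np.random.SeedSequence(seed)
    patient_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n_patients)]
    count_rng = np.random.default_rng(ss.spawn(1)[0])
    if lesion_counts is None:
        if n_patients == len(COHORT_LESION_COUNTS):
            lesion_counts = list(COHORT_LESION_COUNTS)
        else:
            lesion_counts = list(
                count_rng.choice(COHORT_LESION_COUNTS, size=n_patients)
            )
    if len(lesion_counts) != n_patients:
        raise ValueError("lesion_counts length must equal n_patients")

    cohort = []
    for i, (n_lesions, pseed) in enumerate(zip(lesion_counts, patient_seeds)):
        if fixed_lesions is not None:
            spec = SyntheticPatientSpec(
                patient_id=f"p{i + 1:02d}",
                lesions=list(fixed_lesions),
                grid_spacing=grid_spacing,
                seed=pseed,
            )
        else:
            spec = sample_patient(
                f"p{i + 1:02d}", int(n_lesions), pseed, min_separation, grid_spacing
            )
        cohort.append(spec)
    return cohort


# ---------------------------------------------------------------------------
# geometry rasterization

def _grid_geometry(spec: SyntheticPatientSpec):
    semi = np.asarray(spec.brain_semiaxes)
    center = np.asarray(spec.brain_center)
    s = spec.grid_spacing
    axes = []
    for ax in range(3):
        ext = semi[ax] + GRID_MARGIN_MM
        n = int(np.floor(2 * ext / s)) + 1
        coords = center[ax] + (np.arange(n) - (n - 1) / 2) * s
        axes.append(coords)
    return axes


def _window(coords: np.ndarray, lo: float, hi: float) -> slice:
    """Index slice of the 1-D coordinate axis covering [lo, hi]."""
    return slice(
        int(np.searchsorted(coords, lo, side="left")),
        int(np.searchsorted(coords, hi, side="right")),
    )


def _primitive_mask(kind: str, params: dict, axes, shape) -> np.ndarray:
    """Rasterize one geometric primitive; evaluated only in its bounding box."""
    z, y, x = axes
    cz, cy, cx = params["center"]
    if kind == "sphere":
        r = params["radius"]
        ext = (r, r, r)
    elif kind == "zcylinder":
        ext = (params["half_length"], params["radius"], params["radius"])
    elif kind == "ycylinder":
        ext = (params["radius"], params["half_length"], params["radius"])
    elif kind == "box":
        ext = params["half_size"]
    else:
        raise ValueError(f"unknown primitive kind {kind!r}")
    sz = _window(z, cz - ext[0], cz + ext[0])
    sy = _window(y, cy - ext[1], cy + ext[1])
    sx = _window(x, cx - ext[2], cx + ext[2])
    bz = z[sz][:, None, None] - cz
    by = y[sy][None, :, None] - cy
    bx = x[sx][None, None, :] - cx
    if kind == "sphere":
        box = bz**2 + by**2 + bx**2 <= params["radius"] ** 2
    elif kind == "zcylinder":
        box = (by**2 + bx**2 <= params["radius"] ** 2) & (
            np.abs(bz) <= params["half_length"]
        )
    elif kind == "ycylinder":
        box = (bz**2 + bx**2 <= params["radius"] ** 2) & (
            np.abs(by) <= params["half_length"]
        )
    else:
        box = (
            (np.abs(bz) <= ext[0]) & (np.abs(by) <= ext[1]) & (np.abs(bx) <= ext[2])
        )
    mask = np.zeros(shape, dtype=bool)
    mask[sz, sy, sx] = box
    return mask


def build_structures(spec: SyntheticPatientSpec) -> tuple[list[Structure], dict]:
    """Rasterize the patient's anatomy onto its grid.

    Returns the structure list (brain, per-lesion targets, healthy brain,
    OARs) and a geometry dict with the coordinate axes and grid info used
    by the renderer.
    """
    z, y, x = _grid_geometry(spec)
    shape = (z.size, y.size, x.size)
    cz, cy, cx = spec.brain_center
    az, ay, ax_ = spec.brain_semiaxes
    brain_mask = (
        ((z[:, None, None] - cz) / az) ** 2
        + ((y[None, :, None] - cy) / ay) ** 2
        + ((x[None, None, :] - cx) / ax_) ** 2
    ) <= 1.0

    structures = [Structure("brain", "oar", brain_mask)]
    target_union = np.zeros_like(brain_mask)
    for i, lesion in enumerate(spec.lesions):
        m = _primitive_mask(
            "sphere", {"center": lesion.center, "radius": lesion.radius},
            (z, y, x), shape,
        )
        if not m.any():
            raise ValueError(
                f"lesion {i + 1} of {spec.patient_id} covers no voxel center "
                f"at {spec.grid_spacing} mm spacing"
            )
        target_union |= m
        structures.append(
            Structure(f"lesion_{i + 1}", "target", m, prescription_dose=lesion.prescription)
        )
    structures.append(
        Structure("healthy_brain", "healthy_brain", brain_mask & ~target_union)
    )
    for name, params in spec.oars.items():
        mask = _primitive_mask(params["kind"], params, (z, y, x), shape)
        structures.append(Structure(name, "oar", mask))
    geometry = {
        "axes": (z, y, x),
        "origin": (float(z[0]), float(y[0]), float(x[0])),
        "spacing": (spec.grid_spacing,) * 3,
        "brain_mask": brain_mask,
        "target_union": target_union,
    }
    return structures, geometry


# ---------------------------------------------------------------------------
# dose rendering

def _technique_seed(spec_seed: int, profile_name: str) -> int:
    return int((spec_seed + zlib.crc32(profile_name.encode())) % 2**31)


#: Exponential tails are truncated at this many falloff lengths beyond the
#: lesion surface (relative dose < 1e-5 there); keeps kernels local.
KERNEL_CUTOFF_LAMBDAS = 12.0


def render_dose(
    spec: SyntheticPatientSpec,
    profile: TechniqueProfile,
    seed: int | None = None,
    normalize: bool = True,
    prebuilt: tuple[list[Structure], dict] | None = None,
) -> tuple[DoseGrid, list[Structure]]:
    """Render one technique-flavored plan for one patient.

    Deterministic given (spec, profile, seed); by default the noise seed
    is derived from ``spec.seed`` and the profile name so each technique
    gets an independent stream.  The returned grid is normalized so the
    pooled target's V100% equals 95% (unless ``normalize=False``).
    ``prebuilt`` accepts the output of :func:`build_structures` to avoid
    re-rasterizing the (profile-independent) anatomy when rendering the
    same patient for several techniques.
    """
    if profile.falloff_length <= 0:
        raise ValueError("falloff_length must be > 0 (degenerate kernel)")
    if seed is None:
        seed = _technique_seed(spec.seed, profile.name)
    rng = np.random.default_rng(seed)

    structures, geom = prebuilt if prebuilt is not None else build_structures(spec)
    z, y, x = geom["axes"]
    shape = geom["brain_mask"].shape

    total = np.zeros(shape)
    peak = np.zeros(shape)
    rx_map = np.zeros(shape)  # per-voxel prescription of the owning lesion
    h = profile.intra_target_heterogeneity
    lam = profile.falloff_length
    cutoff = KERNEL_CUTOFF_LAMBDAS * lam
    for lesion in spec.lesions:
        lz, ly, lx = lesion.center
        ext = lesion.radius + cutoff
        sz = _window(z, lz - ext, lz + ext)
        sy = _window(y, ly - ext, ly + ext)
        sx = _window(x, lx - ext, lx + ext)
        r = np.sqrt(
            (z[sz][:, None, None] - lz) ** 2
            + (y[sy][None, :, None] - ly) ** 2
            + (x[sx][None, None, :] - lx) ** 2
        )
        sdist = r - lesion.radius  # signed distance to the lesion surface
        kernel = np.zeros(r.shape)
        tail = (sdist > 0) & (sdist <= cutoff)
        kernel[tail] = lesion.prescription * np.exp(-sdist[tail] / lam)
        inside = sdist <= 0
        kernel[inside] = lesion.prescription * (
            1.0 + h * (1.0 - (r[inside] / lesion.radius) ** 2)
        )
        np.maximum(peak[sz, sy, sx], kernel, out=peak[sz, sy, sx])
        total[sz, sy, sx] += kernel
        rx_view = rx_map[sz, sy, sx]
        rx_view[inside] = lesion.prescription

    dose = peak + profile.bridging_gain * (total - peak)
    mean_rx = float(np.mean([l.prescription for l in spec.lesions]))
    dose += profile.bath_level * mean_rx * geom["brain_mask"]
    if profile.noise_sd > 0:
        dose *= np.exp(rng.normal(0.0, profile.noise_sd, size=shape))

    grid = DoseGrid(dose, geom["spacing"], geom["origin"])
    if normalize:
        union = geom["target_union"]
        rel_values = grid.values.copy()
        rel_values[union] = rel_values[union] / rx_map[union] * 100.0
        rel_grid = DoseGrid(rel_values, geom["spacing"], geom["origin"])
        pooled = Structure("total_target", "target", union, prescription_dose=100.0)
        result: NormalizationResult = normalize_plan(rel_grid, pooled)
        grid = grid.scaled(result.scale)
    return grid, structures
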