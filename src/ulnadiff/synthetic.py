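"""Synthetic ulna meshes with known ground truth, and simulated cohorts.

The mesh generator produces an ulna *analogue*: a lofted tube along a gently
bowed centerline with a bulbous proximal cap (olecranon analogue) and a
hemispherical distal cap (ulnar dome analogue).  It is not anatomically
faithful — it reproduces exactly the features the measurement pipeline
relies on: two detectable extremal landmarks whose separation is the bone
length, a larger girth at the proximal end, and a roughly circular shaft
cross-section at mid-bone.

The proximal (cap + taper) and distal (flare + dome) regions have fixed
millimetre dimensions, so two bones generated with different total lengths
differ only in the span of the constant-radius mid-shaft.  A left/right pair
with an imposed length difference therefore has congruent ends, mirroring
how real contralateral bones share their epiphyseal shape while differing
in shaft length.

The cohort simulator is independent of the mesh generator: it draws signed
left-right length differences from a normal distribution and adds
per-observer measurement noise, emulating the statistical structure of a
two-observer bilateral measurement study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import MeshValidationError
from .mesh_io import SurfaceMesh

__all__ = [
    "UlnaParams",
    "LandmarkSet",
    "CohortSimParams",
    "SimulatedPatient",
    "generate_ulna",
    "generate_pair",
    "simulate_cohort",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
]


@dataclass(frozen=True)
class LandmarkSet:
    """The two endpoints of the ulnar length chord (mm).

    ``olecranon_tip`` is the proximal prominence at the elbow;
    ``dome_tip`` is the apex of the rounded distal articular end.
    """

    olecranon_tip: np.ndarray
    dome_tip: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.olecranon_tip, dtype=np.float64).reshape(3)
        d = np.asarray(self.dome_tip, dtype=np.float64).reshape(3)
        object.__setattr__(self, "olecranon_tip", o)
        object.__setattr__(self, "dome_tip", d)
        if np.allclose(o, d):
            raise MeshValidationError("landmarks coincide")

    @property
    def chord_length(self) -> float:
        """Olecranon-tip to dome-tip distance (mm)."""
        return float(np.linalg.norm(self.dome_tip - self.olecranon_tip))

    def transformed(self, transform) -> "LandmarkSet":
        """Landmarks mapped through a rigid transform (frame change)."""
        pts = transform.apply(np.vstack([self.olecranon_tip, self.dome_tip]))
        return LandmarkSet(pts[0], pts[1])


@dataclass(frozen=True)
class UlnaParams:
    """Shape parameters of the synthetic ulna (all lengths in mm).

    Defaults approximate an adult ulna: ~260 mm long with a ~7 mm shaft
    radius, a slight lateral bow, a ~12 mm-girth olecranon and a ~9 mm
    distal dome.
    """

    total_length: float = 260.0
    shaft_radius: float = 7.0
    shaft_curvature: float = 0.015  # bow amplitude as fraction of length
    olecranon_bulge: float = 5.0  # added radius at the proximal cap
    dome_radius: float = 9.0
    side: str = "right"
    axial_resolution: int = 80  # mid-shaft ring count
    radial_resolution: int = 32  # points per ring
    surface_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise MeshValidationError("total_length must be > 0")
        if self.shaft_radius <= 0:
            raise MeshValidationError("shaft_radius must be > 0")
        if self.dome_radius <= 0:
            raise MeshValidationError("dome_radius must be > 0")
        if self.olecranon_bulge < 0:
            raise MeshValidationError("olecranon_bulge must be >= 0")
        if self.axial_resolution < 8 or self.radial_resolution < 8:
            raise MeshValidationError("resolutions must be >= 8")
        if self.surface_noise_sd < 0:
            raise MeshValidationError("surface_noise_sd must be >= 0")
        if self.side not in ("left", "right"):
            raise MeshValidationError("side must be 'left' or 'right'")
        if self.total_length < self._min_length():
            raise MeshValidationError(
                f"total_length {self.total_length} mm too short for the end "
                f"regions (need >= {self._min_length():.1f} mm)"
            )

    def _min_length(self) -> float:
        rp = self.shaft_radius + self.olecranon_bulge
        return rp + self._taper_length() + self._flare_length() + self.dome_radius + 2.0

    def _taper_length(self) -> float:
        return 6.0 * self.shaft_radius

    def _flare_length(self) -> float:
        return 4.0 * self.shaft_radius


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _ring_stations(p: UlnaParams) -> tuple[np.ndarray, np.ndarray]:
    """Axial stations and ring radii of the loft, proximal tip at z=0."""
    L = p.total_length
    rs, rd = p.shaft_radius, p.dome_radius
    rp = rs + p.olecranon_bulge
    taper_end = rp + p._taper_length()
    flare_start = L - rd - p._flare_length()
    dome_eq = L - rd

    n_cap_p, n_taper, n_flare, n_cap_d = 10, 16, 10, 12

    # proximal spherical cap: center (0, 0, rp), tip pole at z=0 (added later)
    phi = np.linspace(0.0, np.pi / 2.0, n_cap_p + 1)[1:]
    z_cap_p = rp * (1.0 - np.cos(phi))
    r_cap_p = rp * np.sin(phi)

    z_taper = np.linspace(rp, taper_end, n_taper + 1)[1:]
    r_taper = rp + (rs - rp) * _smoothstep((z_taper - rp) / (taper_end - rp))

    z_mid = np.linspace(taper_end, flare_start, p.axial_resolution + 2)[1:-1]
    r_mid = np.full_like(z_mid, rs)

    z_flare = np.linspace(flare_start, dome_eq, n_flare + 1)
    r_flare = rs + (rd - rs) * _smoothstep((z_flare - flare_start) / (dome_eq - flare_start))

    # distal hemispherical cap: center (0, 0, L - rd), tip pole at z=L
    psi = np.linspace(0.0, np.pi / 2.0, n_cap_d + 1)[1:-1]
    z_cap_d = dome_eq + rd * np.sin(psi)
    r_cap_d = rd * np.cos(psi)

    z = np.concatenate([z_cap_p, z_taper, z_mid, z_flare, z_cap_d])
    r = np.concatenate([r_cap_p, r_taper, r_mid, r_flare, r_cap_d])
    return z, r


def _loft(z: np.ndarray, r: np.ndarray, bow: np.ndarray, n_radial: int):
    """Triangulate poles + rings into a closed tube mesh (right-handed)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_radial + 1)[:-1]
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    n_rings = len(z)

    verts = np.empty((2 + n_rings * n_radial, 3))
    verts[0] = (0.0, 0.0, 0.0)  # proximal pole (olecranon tip)
    verts[-1] = (0.0, 0.0, z[-1] + (z[-1] - z[-2]) * 0.0)  # placeholder
    ring = np.empty((n_radial, 3))
    for i in range(n_rings):
        ring[:, 0] = bow[i] + r[i] * cos_t
        ring[:, 1] = r[i] * sin_t
        ring[:, 2] = z[i]
        verts[1 + i * n_radial : 1 + (i + 1) * n_radial] = ring

    faces = []
    first = lambda i: 1 + i * n_radial
    # proximal fan (outward normals point towards -z)
    for j in range(n_radial):
        jn = (j + 1) % n_radial
        faces.append((0, first(0) + jn, first(0) + j))
    # bands
    for i in range(n_rings - 1):
        a, b = first(i), first(i + 1)
        for j in range(n_radial):
            jn = (j + 1) % n_radial
            faces.append((a + j, b + jn, b + j))
            faces.append((a + j, a + jn, b + jn))
    # distal fan
    pole_d = len(verts) - 1
    a = first(n_rings - 1)
    for j in range(n_radial):
        jn = (j + 1) % n_radial
        faces.append((pole_d, a + j, a + jn))
    return verts, np.asarray(faces, dtype=np.int64), pole_d


def generate_ulna(params: UlnaParams) -> tuple[SurfaceMesh, LandmarkSet]:
    """Generate one synthetic ulna and its exact ground-truth landmarks.

    The returned landmarks are the noise-free tip positions; with surface
    noise the mesh vertices scatter around them, so the apparent landmark
    separation stays within ~3 noise SDs of ``total_length``.  ``side='left'``
    is the exact mirror image (across the y-z plane) of the right bone
    generated from identical parameters and seed.
    """
    p = params
    L = p.total_length
    z, r = _ring_stations(p)
    bow = p.shaft_curvature * L * np.sin(np.pi * z / L)
    verts, faces, pole_d = _loft(z, r, bow, p.radial_resolution)
    verts[pole_d] = (0.0, 0.0, L)

    if p.surface_noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        verts = verts + rng.normal(0.0, p.surface_noise_sd, size=verts.shape)

    if p.side == "left":
        verts = verts * np.array([-1.0, 1.0, 1.0])
        faces = faces[:, ::-1]  # restore outward winding after reflection

    landmarks = LandmarkSet(np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, L]))
    return SurfaceMesh(verts, faces), landmarks


def generate_pair(
    base: UlnaParams, signed_diff: float
) -> tuple[tuple[SurfaceMesh, LandmarkSet], tuple[SurfaceMesh, LandmarkSet]]:
    """Generate a (left, right) pair with an exact imposed length difference.

    ``signed_diff`` is right length minus left length (mm) and is split
    symmetrically around ``base.total_length``; all other shape parameters
    and the noise seed are shared.
    """
    half = signed_diff / 2.0
    left_len = base.total_length - half
    right_len = base.total_length + half
    if min(left_len, right_len) <= 0:
        raise MeshValidationError("imposed difference leaves a non-positive length")
    left = generate_ulna(replace(base, side="left", total_length=left_len))
    right = generate_ulna(replace(base, side="right", total_length=right_len))
    return left, right


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class CohortSimParams:
    """Statistical parameters of a simulated bilateral-measurement cohort.

    Defaults are the study conditions of a 65-patient distal-radius-malunion
    cohort: signed right-minus-left ulnar length difference normal with mean
    1.02 mm and SD 2.98 mm, 75% female, 52% non-dominant-side malunion,
    adult ages.
    """

    n_patients: int = 65
    signed_diff_mean: float = 1.02
    signed_diff_sd: float = 2.98
    base_length_mean: float = 260.0
    base_length_sd: float = 12.0
    female_fraction: float = 0.75
    age_range: tuple[float, float] = (18.0, 80.0)
    nondominant_malunion_fraction: float = 0.52
    observer_noise_sd: float = 0.1
    n_observers: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise MeshValidationError("n_patients must be >= 1")
        if self.signed_diff_sd < 0 or self.base_length_sd < 0 or self.observer_noise_sd < 0:
            raise MeshValidationError("standard deviations must be >= 0")
        for frac in (self.female_fraction, self.nondominant_malunion_fraction):
            if not 0.0 <= frac <= 1.0:
                raise MeshValidationError("fractions must lie in [0, 1]")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise MeshValidationError("invalid age_range")
        if self.n_observers < 1:
            raise MeshValidationError("n_observers must be >= 1")


@dataclass(frozen=True)
class SimulatedPatient:
    """One simulated patient: ground truth plus per-observer measurements."""

    id: str
    age: float
    sex: str  # 'male' | 'female'
    malunion_side: str  # 'dominant' | 'non-dominant'
    true_left_length: float
    true_right_length: float
    observed_diffs: tuple[float, ...]  # signed, right minus left, per observer

    @property
    def true_signed_diff(self) -> float:
        return self.true_right_length - self.true_left_length

    @property
    def longer_length(self) -> float:
        return max(self.true_left_length, self.true_right_length)


def simulate_cohort(params: CohortSimParams) -> list[SimulatedPatient]:
    """Draw a cohort of patients with normal signed length differences.

    Signed differences ~ N(signed_diff_mean, signed_diff_sd); ages uniform
    over ``age_range``; sex and malunion side Bernoulli with the stated
    fractions; each observer reads the true signed difference plus
    independent normal noise.  Fully determined by ``params.seed``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_patients
    diffs = rng.normal(p.signed_diff_mean, p.signed_diff_sd, size=n)
    ages = rng.uniform(p.age_range[0], p.age_range[1], size=n)
    female = rng.random(n) < p.female_fraction
    nondom = rng.random(n) < p.nondominant_malunion_fraction
    base = rng.normal(p.base_length_mean, p.base_length_sd, size=n)
    noise = rng.normal(0.0, p.observer_noise_sd, size=(n, p.n_observers))
    if p.observer_noise_sd == 0:
        noise[:] = 0.0

    patients = []
    for i in range(n):
        patients.append(
            SimulatedPatient(
                id=f"P{i + 1:03d}",
                age=float(ages[i]),
                sex="female" if female[i] else "male",
                malunion_side="non-dominant" if nondom[i] else "dominant",
                true_left_length=float(base[i] - diffs[i] / 2.0),
                true_right_length=float(base[i] + diffs[i] / 2.0),
                observed_diffs=tuple(float(d) for d in diffs[i] + noise[i]),
            )
        )
    return patients


def cohort_to_frame(
    patients: list[SimulatedPatient], adjudication_threshold: float = 1.0
) -> pd.DataFrame:
    """Tabulate a simulated cohort in the on-disk CSV layout.

    Columns: id, age, sex, side, ulna_length_mm, obs1_mm, obs2_mm, obs3_mm.
    ``obs3_mm`` (the adjudicator) is filled only where the first two
    observers disagree by more than the threshold; the adjudicator picks
    the observer value closer to the simulated truth, which is known here.
    """
    rows = []
    for pt in patients:
        row = {
            "id": pt.id,
            "age": pt.age,
            "sex": pt.sex,
            "side": pt.malunion_side,
            "ulna_length_mm": pt.longer_length,
        }
        for j, obs in enumerate(pt.observed_diffs, start=1):
            row[f"obs{j}_mm"] = obs
        if len(pt.observed_diffs) >= 2:
            o1, o2 = pt.observed_diffs[0], pt.observed_diffs[1]
            if abs(o1 - o2) > adjudication_threshold:
                truth = pt.true_signed_diff
                row["obs3_mm"] = o1 if abs(o1 - truth) <= abs(o2 - truth) else o2
            else:
                row["obs3_mm"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(
    patients: list[SimulatedPatient], path: str, adjudication_threshold: float = 1.0
) -> None:
    cohort_to_frame(patients, adjudication_threshold).to_csv(path, index=False)


def read_cohort_csv(path: str) -> pd.DataFrame:
    """Read a cohort CSV, validating the required columns."""
    df = pd.read_csv(path)
    required = {"id", "age", "sex", "side", "ulna_length_mm", "obs1_mm", "obs2_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
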