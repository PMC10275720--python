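"""Synthetic inputs with planted ground truth.

Three generators stand in for the inputs such clinical analyses use but
cannot redistribute:

* a phantom atlas with bilateral ellipsoidal "pallidal" structures (a GPi
  stand-in as the stimulation target and a lateral GPe-like neighbor);
* a DBS cohort whose clinical improvement is an exact function of how much
  of a planted spherical sweetspot each patient's bilateral stimulation
  volume covers, plus Gaussian noise — so the voxel-wise statistics
  downstream have recoverable ground truth;
* multi-subject resting-state BOLD with planted spatial networks, smooth
  latent time courses, CSF/WM/global nuisance signals, motion traces, and a
  configurable number of deliberate motion-QC violators.

Everything is deterministic given the generator seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .connectome import ConnectomeSubject
from .efield import (DEFAULT_CONDUCTIVITY, DEFAULT_THRESHOLD, ElectrodeModel,
                     StimulationVolume, bilateral_stimulation_volume)
from .images import ImageVolume, TimeSeriesImage, centered_grid, grid_world_coordinates

# ---------------------------------------------------------------------------
# Phantom atlas

#: World-mm centres and semi-axes of the right-hemisphere structures; the
#: left hemisphere is the exact mirror (x -> -x). Coordinates echo the
#: pallidal region of a pediatric MNI-like frame.
TARGET_CENTER = np.array([21.0, -7.0, -5.0])     # GPi stand-in
TARGET_SEMIAXES = np.array([5.0, 7.0, 6.0])
NEIGHBOR_CENTER = np.array([27.0, -2.0, 0.0])    # GPe stand-in
NEIGHBOR_SEMIAXES = np.array([5.0, 9.0, 8.0])

STRUCTURE_NAMES = {0: "background", 1: "target-left", 2: "target-right",
                   3: "neighbor-left", 4: "neighbor-right"}

#: Default cohort analysis grid: 1 mm isotropic (the resolution of the
#: pediatric template space), world extent 96 x 120 x 96 mm, mid-sagittal
#: plane x = 0 on-grid so left/right mirror symmetry is exact.
COHORT_EXTENT_MM = (96, 120, 96)
DEFAULT_COHORT_SPACING = 1.0

# Generator design constants (chosen once; see docs/methods.md).
# Electrodes are accurately implanted (small scatter) and both hemispheres
# share one stimulation amplitude per patient, as is typical in bilateral
# pallidal stimulation for dystonia; the outcome driver is therefore how far
# each patient's stimulation volume grows into the planted effective sphere.
CONTACT_JITTER_SD = 0.5        # mm, electrode placement scatter around target
AMPLITUDE_RANGE = (1.5, 4.5)   # mA, uniform per patient (both sides equal)
PRE_SCORE_RANGE = (40.0, 100.0)  # BFMDRS points


@dataclass
class PhantomAtlas:
    labels: ImageVolume
    structure_names: dict

    def structure_mask(self, label: int) -> np.ndarray:
        return self.labels.data == label

    def structure_centroid(self, label: int) -> np.ndarray:
        """World-mm centroid of one labeled structure."""
        idx = np.argwhere(self.structure_mask(label))
        if idx.size == 0:
            raise ValueError(f"label {label} is empty")
        return self.labels.voxel_to_world(idx.mean(axis=0))


def cohort_grid(spacing: float = DEFAULT_COHORT_SPACING) -> tuple[np.ndarray, tuple]:
    """Canonical cohort grid at the given isotropic spacing (mm)."""
    shape = tuple(int(round(e / spacing)) + 1 for e in COHORT_EXTENT_MM)
    return centered_grid(shape, spacing), shape


def default_cohort_grid() -> tuple[np.ndarray, tuple]:
    return cohort_grid(DEFAULT_COHORT_SPACING)


def hemisphere_mask(grid, side: str = "right") -> ImageVolume:
    """Binary mask of one hemisphere (world x > 0 or x < 0) on a grid."""
    affine, shape = grid
    x = grid_world_coordinates(affine, shape)[..., 0]
    m = x > 0 if side == "right" else x < 0
    return ImageVolume(m.astype(np.uint8), affine)


def _ellipsoid(coords: np.ndarray, center, semiaxes) -> np.ndarray:
    return (((coords - center) / semiaxes) ** 2).sum(axis=-1) <= 1.0


def make_phantom_atlas(grid_affine=None, grid_shape=None) -> PhantomAtlas:
    """Deterministic bilateral phantom atlas on the given grid.

    Requires at least 40 voxels per axis at <= 2 mm spacing, and a grid
    large enough to contain all four structures.
    """
    if grid_affine is None:
        grid_affine, grid_shape = default_cohort_grid()
    grid_affine = np.asarray(grid_affine, dtype=float)
    spacing = np.linalg.norm(grid_affine[:3, :3], axis=0)
    if min(grid_shape) < 40 or spacing.max() > 2.0 + 1e-9:
        raise ValueError("atlas grid must have >= 40 voxels per axis at "
                         "<= 2 mm spacing")
    coords = grid_world_coordinates(grid_affine, grid_shape)
    lo, hi = coords.reshape(-1, 3).min(axis=0), coords.reshape(-1, 3).max(axis=0)
    for c, s in ((TARGET_CENTER, TARGET_SEMIAXES), (NEIGHBOR_CENTER, NEIGHBOR_SEMIAXES)):
        for sign in (1, -1):
            cc = c * np.array([sign, 1, 1])
            if np.any(cc - s < lo) or np.any(cc + s > hi):
                raise ValueError("grid too small to hold the atlas structures")
    mirror = np.array([-1.0, 1.0, 1.0])
    labels = np.zeros(grid_shape, dtype=np.int16)
    # neighbors first so targets win where the ellipsoids overlap
    labels[_ellipsoid(coords, NEIGHBOR_CENTER * mirror, NEIGHBOR_SEMIAXES)] = 3
    labels[_ellipsoid(coords, NEIGHBOR_CENTER, NEIGHBOR_SEMIAXES)] = 4
    labels[_ellipsoid(coords, TARGET_CENTER * mirror, TARGET_SEMIAXES)] = 1
    labels[_ellipsoid(coords, TARGET_CENTER, TARGET_SEMIAXES)] = 2
    for lab in (1, 2, 3, 4):
        if not (labels == lab).any():
            raise ValueError(f"structure {STRUCTURE_NAMES[lab]} is empty on this grid")
    return PhantomAtlas(ImageVolume(labels, grid_affine, "phantom"), dict(STRUCTURE_NAMES))


# ---------------------------------------------------------------------------
# DBS cohort

@dataclass
class CohortSpec:
    """Generator settings for the synthetic DBS cohort.

    ``max_improvement`` is the improvement (%) when the planted sweetspot
    sphere is fully covered; ``noise_sd`` (%) is added on top. Defaults echo
    a 20-patient pallidal cohort with wide outcome spread including
    worseners (the statistics must tolerate negative weights).
    """

    n_patients: int = 20
    planted_center: np.ndarray | None = None   # default: right target centroid
    planted_radius: float = 4.0                # mm
    max_improvement: float = 70.0              # %
    noise_sd: float = 15.0                     # %
    seed: int = 0
    grid: tuple | None = None                  # (affine, shape)

    def __post_init__(self) -> None:
        if self.n_patients < 5:
            raise ValueError("n_patients must be >= 5")
        if self.planted_radius <= 0:
            raise ValueError("planted_radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.grid is None:
            self.grid = default_cohort_grid()
        if self.planted_center is not None:
            self.planted_center = np.asarray(self.planted_center, dtype=float)


@dataclass
class PatientRecord:
    """One cohort row: identifiers, BFMDRS scores and electrode description."""

    patient_id: str
    pre_score: float
    post_score: float
    improvement_pct: float
    electrodes: dict  # side -> ElectrodeModel
    mode: str = "current"


def planted_sphere_mask(spec: CohortSpec) -> np.ndarray:
    affine, shape = spec.grid
    coords = grid_world_coordinates(affine, shape)
    center = spec.planted_center
    return np.linalg.norm(coords - center, axis=-1) <= spec.planted_radius


def simulate_cohort(spec: CohortSpec, atlas: PhantomAtlas,
                    threshold: float = DEFAULT_THRESHOLD,
                    conductivity: float = DEFAULT_CONDUCTIVITY) -> list[PatientRecord]:
    """Generate a seeded cohort with a planted spherical sweetspot.

    Each patient receives one active contact per hemisphere, jittered around
    the atlas target centroids, with one uniform-random current amplitude
    shared by both sides (bilaterally symmetric programming). Improvement is
    ``max_improvement`` times the fraction of the planted sphere covered by
    the patient's combined bilateral stimulation volume, plus Gaussian noise
    (never clipped — worseners are allowed).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.planted_center is None:
        spec.planted_center = atlas.structure_centroid(2)
    affine, shape = spec.grid
    sphere = planted_sphere_mask(spec)
    if not sphere.any():
        raise ValueError("planted sphere contains no voxels on the cohort grid")
    target_l = atlas.structure_centroid(1)
    target_r = atlas.structure_centroid(2)
    records: list[PatientRecord] = []
    coverages = np.empty(spec.n_patients)
    for i in range(spec.n_patients):
        electrodes = {}
        amp = rng.uniform(*AMPLITUDE_RANGE)
        for side, target in (("left", target_l), ("right", target_r)):
            center = target + rng.normal(0.0, CONTACT_JITTER_SD, 3)
            electrodes[side] = ElectrodeModel(contact_centers=center[None, :],
                                              active=[(0, 1, float(amp))],
                                              mode="current")
        pid = f"sub-{i + 1:02d}"
        combined = bilateral_stimulation_volume(electrodes, affine, shape,
                                                threshold, conductivity, pid)
        coverages[i] = ((combined.mask.data > 0) & sphere).sum() / sphere.sum()
        improvement = spec.max_improvement * coverages[i]
        if spec.noise_sd > 0:
            improvement += rng.normal(0.0, spec.noise_sd)
        pre = rng.uniform(*PRE_SCORE_RANGE)
        post = pre * (1.0 - improvement / 100.0)
        records.append(PatientRecord(pid, float(pre), float(post),
                                     float(improvement), electrodes))
    if spec.noise_sd == 0 and np.all(coverages == 0):
        warnings.warn("degenerate cohort: no stimulation volume covers the "
                      "planted sphere and noise_sd is 0", stacklevel=2)
    return records


def cohort_stimulation_volumes(records, grid, threshold: float = DEFAULT_THRESHOLD,
                               conductivity: float = DEFAULT_CONDUCTIVITY):
    """Combined bilateral stimulation volume for every cohort record."""
    affine, shape = grid
    return [bilateral_stimulation_volume(r.electrodes, affine, shape,
                                         threshold, conductivity, r.patient_id)
            for r in records]


def write_cohort_table(records, path) -> None:
    """Tab-separated cohort table (one row per patient)."""
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "pre_score": r.pre_score,
               "post_score": r.post_score, "improvement_pct": r.improvement_pct,
               "mode": r.mode}
        for side in ("left", "right"):
            el = r.electrodes[side]
            row[f"{side}_x"], row[f"{side}_y"], row[f"{side}_z"] = el.contact_centers[0]
            row[f"{side}_amplitude"] = el.active[0][2]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> list[PatientRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        electrodes = {}
        for side in ("left", "right"):
            center = np.array([row[f"{side}_x"], row[f"{side}_y"], row[f"{side}_z"]])
            electrodes[side] = ElectrodeModel(contact_centers=center[None, :],
                                              active=[(0, 1, float(row[f"{side}_amplitude"]))],
                                              mode=str(row["mode"]))
        records.append(PatientRecord(str(row["patient_id"]), float(row["pre_score"]),
                                     float(row["post_score"]),
                                     float(row["improvement_pct"]), electrodes,
                                     str(row["mode"])))
    return records


# ---------------------------------------------------------------------------
# Synthetic connectome

@dataclass
class ConnectomeSpec:
    """Generator settings for the synthetic multi-subject BOLD data.

    Defaults mirror the scale of a pediatric normative cohort: 107 subjects
    of which 7 are deliberate motion violators, 180 volumes at TR = 2 s.
    The spatial grid is a desk-scale 3 mm stand-in.
    """

    n_subjects: int = 107
    n_violators: int = 7
    n_volumes: int = 180
    tr: float = 2.0
    grid: tuple | None = None        # (affine, shape)
    n_networks: int = 3
    network_amplitude: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_violators > self.n_subjects:
            raise ValueError("n_violators must not exceed n_subjects")
        if self.n_volumes < 30:
            raise ValueError("n_volumes must be >= 30")
        if self.grid is None:
            self.grid = (centered_grid((30, 36, 30), 3.0), (30, 36, 30))


#: Brain-ellipsoid semi-axes, mm; tissue compartments are nested shells of
#: the normalized ellipsoidal radius (CSF core, white shell, gray rind).
BRAIN_SEMIAXES = np.array([40.0, 50.0, 40.0])
CSF_RHO, WM_RHO = 0.25, 0.55
NETWORK_FWHM_SIGMA = 8.0   # mm, Gaussian width of planted network blobs
#: Unit-ellipsoid directions of the planted network centres (scaled by
#: BRAIN_SEMIAXES x 0.75 so they sit in the gray rind).
_NETWORK_DIRECTIONS = np.array([
    [-0.80, 0.45, 0.20],
    [0.80, -0.50, 0.20],
    [0.00, -0.30, 0.95],
    [0.00, 0.90, -0.10],
    [-0.55, -0.60, -0.45],
])


def tissue_masks(spec: ConnectomeSpec) -> dict:
    """Deterministic nested-ellipsoid tissue masks on the spec grid."""
    affine, shape = spec.grid
    coords = grid_world_coordinates(affine, shape)
    rho = np.sqrt((((coords) / BRAIN_SEMIAXES) ** 2).sum(axis=-1))
    brain = rho <= 1.0
    csf = rho <= CSF_RHO
    white = (rho > CSF_RHO) & (rho <= WM_RHO)
    gray = (rho > WM_RHO) & brain

    def vol(m):
        return ImageVolume(m.astype(np.uint8), affine, "phantom")

    return {"brain": vol(brain), "csf": vol(csf), "white": vol(white),
            "gray": vol(gray)}


def network_spatial_maps(spec: ConnectomeSpec) -> list[ImageVolume]:
    """Planted network blobs (Gaussian, peak 1) restricted to the brain."""
    if spec.n_networks > len(_NETWORK_DIRECTIONS):
        raise ValueError(f"at most {len(_NETWORK_DIRECTIONS)} planted networks")
    affine, shape = spec.grid
    coords = grid_world_coordinates(affine, shape)
    brain = tissue_masks(spec)["brain"].data > 0
    maps = []
    for k in range(spec.n_networks):
        center = _NETWORK_DIRECTIONS[k] * BRAIN_SEMIAXES * 0.75
        d2 = ((coords - center) ** 2).sum(axis=-1)
        m = np.exp(-d2 / (2.0 * NETWORK_FWHM_SIGMA**2))
        m[~brain] = 0.0
        m[m < 0.05] = 0.0
        maps.append(ImageVolume(m, affine, "phantom"))
    return maps


def _smooth_course(rng, n: int, sigma: float = 3.0) -> np.ndarray:
    """Standardized low-pass latent time course (GP-like; survives the
    0.01-0.08 Hz band-pass at TR = 2 s)."""
    x = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma)
    return (x - x.mean()) / x.std()


def simulate_motion_trace(spec: ConnectomeSpec, subject_index: int) -> np.ndarray:
    """Seeded 6-parameter motion trace (translations mm, rotations rad).

    Subjects with index < ``n_violators`` get large jumps (FD > 0.5 mm) in
    60 % of the volumes; all others are guaranteed max FD <= 0.18 mm.
    """
    rng = np.random.default_rng([spec.seed, 7001, subject_index])
    t = spec.n_volumes
    steps = np.column_stack([rng.normal(0.0, 0.03, (t - 1, 3)),
                             rng.normal(0.0, 0.0004, (t - 1, 3))])
    fd = np.abs(steps[:, :3]).sum(axis=1) + 50.0 * np.abs(steps[:, 3:]).sum(axis=1)
    too_big = fd > 0.18
    steps[too_big] *= (0.18 / fd[too_big])[:, None]
    if subject_index < spec.n_violators:
        n_jump = int(round(0.6 * t))
        jump_at = rng.choice(t - 1, size=n_jump, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_jump)
        steps[jump_at, 0] += signs * rng.uniform(0.7, 1.2, n_jump)
    motion = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    return motion


def simulate_connectome_subject(spec: ConnectomeSpec,
                                subject_index: int) -> ConnectomeSubject:
    """One subject's BOLD series, motion trace and tissue masks.

    BOLD = baseline + planted networks (spatial map x smooth latent course)
    + CSF/WM/global nuisance courses in their compartments + a small
    motion-coupled component + white noise; zero outside the brain.
    """
    if subject_index >= spec.n_subjects:
        raise ValueError("subject_index out of range")
    rng = np.random.default_rng([spec.seed, 4242, subject_index])
    affine, shape = spec.grid
    t = spec.n_volumes
    masks = tissue_masks(spec)
    brain = masks["brain"].data > 0
    maps = network_spatial_maps(spec)

    data = np.zeros(shape + (t,), dtype=np.float32)
    data[brain] = 100.0
    for m in maps:
        latent = _smooth_course(rng, t)
        data += (spec.network_amplitude * m.data[..., None] * latent).astype(np.float32)
    data[masks["csf"].data > 0] += _smooth_course(rng, t).astype(np.float32)
    data[masks["white"].data > 0] += _smooth_course(rng, t).astype(np.float32)
    data[brain] += (0.5 * _smooth_course(rng, t)).astype(np.float32)

    motion = simulate_motion_trace(spec, subject_index)
    leak = motion.sum(axis=1)
    leak_sd = leak.std()
    if leak_sd > 0:
        data[brain] += (0.3 * (leak - leak.mean()) / leak_sd).astype(np.float32)
    data[brain] += rng.normal(0.0, spec.noise_sd,
                              (int(brain.sum()), t)).astype(np.float32)

    bold = TimeSeriesImage(data, affine, spec.tr, "phantom")
    return ConnectomeSubject(subject_id=f"conn-{subject_index + 1:03d}",
                             bold=bold, motion=motion, masks=masks)


# ---------------------------------------------------------------------------
# Network-mapping cohort (improvement generated from connectivity)

SEED_SPHERE_RADIUS = 6.0   # mm


def simulate_network_cohort(spec: ConnectomeSpec, n_patients: int = 20,
                            max_improvement: float = 70.0,
                            noise_sd: float = 2.0,
                            seed: int = 0):
    """Patient seed volumes whose improvement follows connectivity to the
    first planted network.

    Seed spheres are placed along the line between the first two network
    centres (with jitter), so patients vary smoothly in how strongly their
    seed loads on network 0; improvement is proportional to the seed-mean
    of network 0's spatial map (normalized to its own peak sphere), plus
    noise. Returns (list of StimulationVolume, improvements array).
    """
    rng = np.random.default_rng([seed, 9313])
    affine, shape = spec.grid
    coords = grid_world_coordinates(affine, shape)
    maps = network_spatial_maps(spec)
    if len(maps) < 2:
        raise ValueError("need at least two planted networks")
    c0 = _NETWORK_DIRECTIONS[0] * BRAIN_SEMIAXES * 0.75
    c1 = _NETWORK_DIRECTIONS[1] * BRAIN_SEMIAXES * 0.75
    brain = tissue_masks(spec)["brain"].data > 0

    def sphere_at(center):
        return (np.linalg.norm(coords - center, axis=-1) <= SEED_SPHERE_RADIUS) & brain

    w_ref = maps[0].data[sphere_at(c0)].mean()
    seeds, improvements = [], np.empty(n_patients)
    for i in range(n_patients):
        frac = i / max(n_patients - 1, 1)
        center = c0 + frac * (c1 - c0) + rng.normal(0.0, 2.0, 3)
        m = sphere_at(center)
        if not m.any():
            raise ValueError("seed sphere fell outside the brain")
        w = maps[0].data[m].mean() / w_ref
        improvements[i] = max_improvement * w + rng.normal(0.0, noise_sd)
        seeds.append(StimulationVolume(
            ImageVolume(m.astype(np.uint8), affine, "phantom"),
            patient_id=f"net-{i + 1:02d}", side="combined"))
    return seeds, improvements
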