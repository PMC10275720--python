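"""Whole-brain network mapping from seed-based normative connectivity.

For each patient, the mean BOLD course of the (bilateral) stimulation
volume is correlated with every in-brain voxel's course in every connectome
subject; the subject-average r-map is Fisher-Z scored (average first, then
arctanh — the documented order) to give the patient's connectivity
fingerprint. Across patients, the voxel-wise correlation of fingerprint
values with clinical improvement yields the R-map ("optimal network"
model), validated by correlating per-patient fingerprint/R-map spatial
similarity with improvement under permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import ConnectomeMatrix
from .efield import StimulationVolume
from .images import ImageVolume
from .stats import PermutationResult, fisher_z, permutation_pvalue


@dataclass
class Fingerprint:
    """One patient's group-average Fisher-Z connectivity profile."""

    zmap: ImageVolume
    patient_id: str
    n_subjects_used: int


@dataclass
class RMap:
    """Voxel-wise correlation of connectivity strength with improvement."""

    rmap: ImageVolume
    included: ImageVolume  # voxels with nonzero across-patient variance


def seed_fingerprint(seed: StimulationVolume,
                     subject: ConnectomeMatrix) -> ImageVolume:
    """Correlate the seed-average course with every in-mask voxel course.

    The seed must already live on the connectome grid. Constant voxel time
    courses get r = 0 (degenerate, not undefined). Returns an r-value volume
    (0 outside the brain mask).
    """
    if seed.mask.shape != subject.brain_mask.shape or \
            not np.allclose(seed.mask.affine, subject.brain_mask.affine):
        raise ValueError("seed is not on the connectome grid")
    i, j, k = subject.voxel_index.T
    in_seed = seed.mask.data[i, j, k] > 0
    if not in_seed.any():
        raise ValueError(f"seed {seed.patient_id!r} does not intersect the "
                         "brain mask")
    course = subject.values[in_seed].mean(axis=0)
    course = course - course.mean()
    cnorm = np.linalg.norm(course)
    if cnorm == 0:
        raise ValueError("seed-average time course is constant")
    rows = subject.values - subject.values.mean(axis=1, keepdims=True)
    rnorm = np.linalg.norm(rows, axis=1)
    ok = rnorm > 0
    r = np.zeros(subject.n_voxels)
    r[ok] = (rows[ok] @ course) / (rnorm[ok] * cnorm)
    np.clip(r, -1.0, 1.0, out=r)
    return subject.to_volume(r)


def group_fingerprint(per_subject_maps: list[ImageVolume], patient_id: str = "",
                      order: str = "average_then_z") -> Fingerprint:
    """Average the per-subject r-maps, then Fisher-Z score the mean.

    ``order="z_then_average"`` transforms each subject map first (the more
    common convention); the default follows the documented average-first
    order.
    """
    if not per_subject_maps:
        raise ValueError("need at least one subject map")
    affine = per_subject_maps[0].affine
    shape = per_subject_maps[0].shape
    for m in per_subject_maps[1:]:
        if m.shape != shape or not np.allclose(m.affine, affine):
            raise ValueError("subject maps are on different grids")
    stack = np.stack([m.data for m in per_subject_maps], axis=0)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # |r|>=1 clamp inside fisher_z
        if order == "average_then_z":
            z = fisher_z(stack.mean(axis=0))
        elif order == "z_then_average":
            z = fisher_z(stack).mean(axis=0)
        else:
            raise ValueError(f"unknown order {order!r}")
    return Fingerprint(zmap=ImageVolume(z, affine), patient_id=patient_id,
                       n_subjects_used=len(per_subject_maps))


def compute_rmap(fingerprints: list[Fingerprint], improvements) -> RMap:
    """Voxel-wise Pearson correlation of fingerprint values with improvement
    across patients; zero-variance voxels are excluded."""
    improvements = np.asarray(improvements, dtype=float)
    if len(fingerprints) != improvements.size or len(fingerprints) < 5:
        raise ValueError("need matching fingerprints/improvements, length >= 5")
    if np.ptp(improvements) == 0:
        raise ValueError("improvements are constant: R-map undefined")
    affine = fingerprints[0].zmap.affine
    shape = fingerprints[0].zmap.shape
    z = np.stack([f.zmap.data.reshape(-1) for f in fingerprints], axis=0)  # (P, V)
    zc = z - z.mean(axis=0)
    yc = improvements - improvements.mean()
    znorm = np.linalg.norm(zc, axis=0)
    included = znorm > 0
    r = np.zeros(z.shape[1])
    r[included] = (yc @ zc[:, included]) / (znorm[included] * np.linalg.norm(yc))
    np.clip(r, -1.0, 1.0, out=r)
    return RMap(rmap=ImageVolume(r.reshape(shape), affine),
                included=ImageVolume(included.reshape(shape).astype(np.uint8),
                                     affine))


def spatial_similarity(fingerprint: Fingerprint, rmap: RMap,
                       min_voxels: int = 10) -> float:
    """Pearson correlation between the fingerprint and the R-map over the
    jointly included voxels."""
    if fingerprint.zmap.shape != rmap.rmap.shape:
        raise ValueError("fingerprint and R-map are on different grids")
    sel = (rmap.included.data > 0) & np.isfinite(fingerprint.zmap.data)
    if np.count_nonzero(sel) < min_voxels:
        raise ValueError(f"fewer than {min_voxels} jointly included voxels")
    x = fingerprint.zmap.data[sel]
    y = rmap.rmap.data[sel]
    xc, yc = x - x.mean(), y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("similarity undefined: constant map over the mask")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def validate_network_model(fingerprints, improvements, n_perm: int = 1000,
                           seed: int = 0, refit: bool = True) -> PermutationResult:
    """Correlate per-patient fingerprint/R-map similarity with improvement,
    permuting improvements.

    The R-map is fit on the full cohort (in-sample, the convention of this
    analysis family). With ``refit`` (default) the R-map is *rebuilt under every
    permutation* before similarities are evaluated: because the map is fitted
    on the improvements themselves, similarities are mechanically aligned
    with them, and a null that keeps the map fixed is radically
    anticonservative. Voxel inclusion (nonzero across-patient variance) is
    permutation-invariant.
    """
    improvements = np.asarray(improvements, dtype=float)
    rmap = compute_rmap(fingerprints, improvements)
    sims = [spatial_similarity(f, rmap) for f in fingerprints]
    if not refit:
        return permutation_pvalue(sims, improvements, n_perm=n_perm, seed=seed)
    from .stats import pearson_r
    observed = pearson_r(sims, improvements)
    inc = rmap.included.data.reshape(-1) > 0
    z = np.stack([f.zmap.data.reshape(-1)[inc] for f in fingerprints], axis=0)
    zc_pat = z - z.mean(axis=0)                       # centered across patients
    znorm_pat = np.linalg.norm(zc_pat, axis=0)
    zc_vox = z - z.mean(axis=1, keepdims=True)        # centered across voxels
    znorm_vox = np.linalg.norm(zc_vox, axis=1)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        w = rng.permutation(improvements)
        wc = w - w.mean()
        r_map = (wc @ zc_pat) / (znorm_pat * np.linalg.norm(wc))
        rc = r_map - r_map.mean()
        sims_perm = (zc_vox @ rc) / (znorm_vox * np.linalg.norm(rc))
        null[i] = pearson_r(sims_perm, w)
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(observed_r=observed, permuted_p=float(p),
                             null_values=null, n_perm=n_perm, seed=seed)
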