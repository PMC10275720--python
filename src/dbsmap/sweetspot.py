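"""Improvement-weighted voxel-wise sweetspot mapping.

Each patient's binary stimulation volume is weighted by the percentage
clinical improvement; at every voxel covered by strictly more than the
coverage fraction (default 20 %) of the cohort, the improvements of the
covering volumes *only* are tested against zero with a one-sample t-test.
The resulting t-score map (the "T-model") is validated by correlating each
patient's sum of overlapped t-scores with improvement under a permutation
test, and summarized by its t-weighted centre of gravity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .efield import StimulationVolume
from .images import ImageVolume
from .stats import DEGENERATE_T, PermutationResult, permutation_pvalue

DEFAULT_MIN_COVERAGE = 0.2


def percent_improvement(pre: float, post: float) -> float:
    """Improvement as the percentage drop from the preoperative score:
    100 (pre - post) / pre. Negative when the patient worsens."""
    if pre <= 0:
        raise ValueError("preoperative score must be positive")
    return 100.0 * (pre - post) / pre


@dataclass
class TModel:
    """Voxel-wise sweetspot statistic.

    ``t_map`` carries NaN outside ``included``; ``coverage`` counts how many
    cohort volumes contain each voxel; ``n_total`` is the cohort size.
    """

    t_map: ImageVolume
    coverage: ImageVolume
    included: ImageVolume
    n_total: int

    @property
    def n_included(self) -> int:
        return int(np.count_nonzero(self.included.data))


def _check_shared_grid(volumes) -> tuple[np.ndarray, tuple]:
    affine = volumes[0].mask.affine
    shape = volumes[0].mask.shape
    for v in volumes[1:]:
        if v.mask.shape != shape or not np.allclose(v.mask.affine, affine):
            raise ValueError("stimulation volumes are on different grids")
    return affine, shape


def compute_tmodel(volumes: list[StimulationVolume], improvements,
                   min_coverage_fraction: float = DEFAULT_MIN_COVERAGE) -> TModel:
    """Voxel-wise one-sample t-map of improvement-weighted stimulation volumes.

    A voxel enters the model iff its coverage is *strictly* greater than
    ``min_coverage_fraction`` x cohort size (for 20 of 20 patients: n > 4).
    At included voxels the t statistic is computed over the covering
    patients' improvements only; elsewhere the map is NaN.
    """
    improvements = np.asarray(improvements, dtype=float)
    if len(volumes) != improvements.size or len(volumes) < 5:
        raise ValueError("need matching volumes/improvements of length >= 5")
    affine, shape = _check_shared_grid(volumes)
    n_total = len(volumes)
    stack = np.stack([v.mask.data > 0 for v in volumes], axis=0)  # (P, x, y, z)
    coverage = stack.sum(axis=0)
    included = coverage > min_coverage_fraction * n_total
    # inclusion implies n >= 2 whenever the fraction is >= 1/n_total; guard anyway
    included &= coverage >= 2

    flat = stack.reshape(n_total, -1)
    n = coverage.reshape(-1).astype(float)
    w = improvements
    s1 = w @ flat
    s2 = (w**2) @ flat
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n
        var = (s2 - n * mean**2) / (n - 1)
        var = np.maximum(var, 0.0)
        t = mean / np.sqrt(var / n)
    zero_sd = var == 0
    t[zero_sd & (mean == 0)] = 0.0
    t[zero_sd & (mean != 0)] = np.sign(mean[zero_sd & (mean != 0)]) * DEGENERATE_T
    t = t.reshape(shape)
    t[~included] = np.nan

    if not included.any():
        import warnings
        warnings.warn("empty T-model: every voxel fell below the coverage "
                      "bound", stacklevel=2)
    return TModel(t_map=ImageVolume(t, affine),
                  coverage=ImageVolume(coverage.astype(np.int32), affine),
                  included=ImageVolume(included.astype(np.uint8), affine),
                  n_total=n_total)


def overlap_score(tmodel: TModel, volume: StimulationVolume) -> float:
    """Sum of T-model t-scores over the voxels the volume overlaps.

    Only included voxels contribute; excluded voxels count 0.
    """
    if volume.mask.shape != tmodel.t_map.shape or \
            not np.allclose(volume.mask.affine, tmodel.t_map.affine):
        raise ValueError("volume is not on the T-model grid")
    sel = (volume.mask.data > 0) & (tmodel.included.data > 0)
    return float(tmodel.t_map.data[sel].sum())


def _tmap_columns(flat_masks: np.ndarray, n_cov: np.ndarray,
                  improvements: np.ndarray) -> np.ndarray:
    """Vectorized per-voxel one-sample t over covering improvements only.

    ``flat_masks`` is (patients, voxels) boolean; ``n_cov`` the per-voxel
    coverage counts (all >= 2)."""
    s1 = improvements @ flat_masks
    s2 = (improvements**2) @ flat_masks
    mean = s1 / n_cov
    var = np.maximum((s2 - n_cov * mean**2) / (n_cov - 1), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(var / n_cov)
    zero_sd = var == 0
    t[zero_sd] = np.sign(mean[zero_sd]) * DEGENERATE_T
    return t


def validate_sweetspot(tmodel: TModel, volumes, improvements,
                       n_perm: int = 1000, seed: int = 0,
                       refit: bool = True) -> PermutationResult:
    """Correlate per-patient sum-of-t overlap scores with improvement and
    assess significance by permuting the improvement scores.

    With ``refit`` (default) the T-model is rebuilt under every permutation
    before scoring, so the null distribution carries the same in-sample
    circularity as the observed statistic — the fixed-map shortcut is wildly
    anticonservative (the map was fitted on the unpermuted improvements).
    The voxel inclusion gate depends on coverage only and is permutation-
    invariant.
    """
    improvements = np.asarray(improvements, dtype=float)
    scores = [overlap_score(tmodel, v) for v in volumes]
    if not refit:
        return permutation_pvalue(scores, improvements, n_perm=n_perm, seed=seed)
    if np.ptp(improvements) == 0.0:
        raise ValueError("improvements are constant: correlation undefined "
                         "under permutation")
    from .stats import pearson_r
    inc = tmodel.included.data.reshape(-1) > 0
    flat = np.stack([v.mask.data.reshape(-1)[inc] > 0 for v in volumes], axis=0)
    n_cov = tmodel.coverage.data.reshape(-1)[inc].astype(float)
    observed = pearson_r(scores, improvements)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        w = rng.permutation(improvements)
        t_perm = _tmap_columns(flat, n_cov, w)
        null[i] = pearson_r(flat @ t_perm, w)
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(observed_r=observed, permuted_p=float(p),
                             null_values=null, n_perm=n_perm, seed=seed)


def sweetspot_cog(tmodel: TModel, t_threshold: float | None = None,
                  region: ImageVolume | None = None) -> np.ndarray:
    """t-weighted centre of gravity (world mm) over included voxels with
    t strictly above max(0, ``t_threshold``).

    ``region`` optionally restricts the centroid to a binary mask (e.g. one
    hemisphere or an atlas structure) — with bilateral stimulation the
    sweetspot map is near mirror-symmetric, so a single reported COG is a
    per-structure summary.
    """
    thr = max(0.0, t_threshold) if t_threshold is not None else 0.0
    t = tmodel.t_map.data
    sel = (tmodel.included.data > 0) & np.isfinite(t) & (t > thr)
    if region is not None:
        sel &= region.data > 0
    if not sel.any():
        raise ValueError("no included voxel with positive t above the threshold")
    idx = np.argwhere(sel).astype(float)
    weights = t[sel]
    centroid_vox = (idx * weights[:, None]).sum(axis=0) / weights.sum()
    return tmodel.t_map.voxel_to_world(centroid_vox)
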