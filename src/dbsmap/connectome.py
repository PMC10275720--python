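"""Normative rs-fMRI connectome assembly.

Per-subject pipeline (in order): motion QC -> motion regression -> spatial
smoothing (6 mm FWHM) -> band-pass 0.01-0.08 Hz -> CSF/WM (+ global)
nuisance regression -> masked voxels x volumes matrix.

Conventions fixed here:

* Framewise displacement follows the Power convention: sum of absolute
  backward differences of the three translations (mm) plus the three
  rotations (rad) converted to arc length on a 50 mm sphere.
* Subjects are excluded when FD exceeds 0.5 mm in more than half of the
  volumes (both inequalities strict).
* The temporal filter is a second-order Butterworth band-pass applied
  forward-backward (zero phase); the printed cutoffs are the -3 dB points
  of the single-pass design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .images import ImageVolume, TimeSeriesImage

DEFAULT_FD_THRESHOLD = 0.5     # mm
DEFAULT_FD_FRACTION = 0.5      # of volumes
DEFAULT_HEAD_RADIUS = 50.0     # mm, rotation -> arc length
DEFAULT_FWHM = 6.0             # mm
DEFAULT_BAND = (0.01, 0.08)    # Hz
FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class ConnectomeSubject:
    """One subject's BOLD series, motion trace and tissue masks."""

    subject_id: str
    bold: TimeSeriesImage
    motion: np.ndarray  # (n_volumes, 6): translations mm, rotations rad
    masks: dict         # keys: gray, white, csf, brain -> binary ImageVolume

    def __post_init__(self) -> None:
        self.motion = np.asarray(self.motion, dtype=float)
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError("motion trace must be (n_volumes, 6)")
        if self.motion.shape[0] != self.bold.n_volumes:
            raise ValueError("motion trace length must match BOLD volumes")
        for name, m in self.masks.items():
            if m.shape != self.bold.spatial_shape:
                raise ValueError(f"mask {name!r} is not on the BOLD grid")


@dataclass
class ConnectomeMatrix:
    """Masked voxels x volumes BOLD matrix with recorded voxel ordering.

    Rows follow raster order with the x index fastest, then y, then z, so
    the matrix round-trips exactly to and from the volume.
    """

    values: np.ndarray        # (n_voxels, n_volumes)
    voxel_index: np.ndarray   # (n_voxels, 3) integer voxel coordinates
    brain_mask: ImageVolume
    tr: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.values.shape[0] != self.voxel_index.shape[0]:
            raise ValueError("row count must equal voxel count")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    def to_volume(self, row_values) -> ImageVolume:
        """Scatter one value per row back into a volume (0 outside mask)."""
        row_values = np.asarray(row_values)
        out = np.zeros(self.brain_mask.shape, dtype=float)
        i, j, k = self.voxel_index.T
        out[i, j, k] = row_values
        return ImageVolume(out, self.brain_mask.affine, self.brain_mask.space)

    def save(self, path) -> None:
        np.savez_compressed(
            path, values=self.values, voxel_index=self.voxel_index,
            mask=self.brain_mask.data.astype(np.uint8),
            affine=self.brain_mask.affine, tr=self.tr,
            subject_id=np.array(self.subject_id))

    @classmethod
    def load(cls, path) -> "ConnectomeMatrix":
        with np.load(path, allow_pickle=False) as z:
            mask = ImageVolume(z["mask"], z["affine"])
            return cls(values=z["values"], voxel_index=z["voxel_index"],
                       brain_mask=mask, tr=float(z["tr"]),
                       subject_id=str(z["subject_id"]))


def compute_fd(motion, head_radius: float = DEFAULT_HEAD_RADIUS) -> np.ndarray:
    """Per-volume framewise displacement in mm (Power convention).

    FD of the first volume is 0; thereafter the sum of absolute backward
    differences of translations plus ``head_radius`` times the rotations.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise ValueError("motion trace must be (n_volumes >= 2, 6)")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def qc_filter(subjects, fd_threshold: float = DEFAULT_FD_THRESHOLD,
              volume_fraction: float = DEFAULT_FD_FRACTION,
              head_radius: float = DEFAULT_HEAD_RADIUS):
    """Split subjects into (retained, excluded) by the motion criterion.

    A subject is excluded iff the fraction of volumes with FD strictly above
    ``fd_threshold`` is strictly above ``volume_fraction``.
    """
    if not subjects:
        raise ValueError("empty subject list")
    retained, excluded = [], []
    for s in subjects:
        fd = compute_fd(s.motion, head_radius)
        frac = np.count_nonzero(fd > fd_threshold) / fd.size
        (excluded if frac > volume_fraction else retained).append(s)
    return retained, excluded


def _residualize(data2d: np.ndarray, design: np.ndarray,
                 what: str) -> np.ndarray:
    """OLS residuals of each row of ``data2d`` (voxels x time) against the
    columns of ``design`` (time x k); the voxel mean is re-added."""
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(f"{what}: design is rank-deficient "
                      f"({rank}/{design.shape[1]}); collinear columns are "
                      "effectively dropped", stacklevel=3)
    beta, *_ = np.linalg.lstsq(design, data2d.T, rcond=None)
    resid = data2d.T - design @ beta
    return (resid.T + data2d.mean(axis=1, keepdims=True)).astype(data2d.dtype)


def regress_motion(bold: TimeSeriesImage, motion) -> TimeSeriesImage:
    """Regress an intercept, a linear trend and the 6 motion parameters out
    of every voxel time course (residual + voxel mean)."""
    motion = np.asarray(motion, dtype=float)
    t = bold.n_volumes
    if motion.shape != (t, 6):
        raise ValueError("motion trace length must match BOLD volumes")
    trend = np.linspace(-1.0, 1.0, t)
    design = np.column_stack([np.ones(t), trend, motion])
    flat = bold.data.reshape(-1, t)
    out = _residualize(flat, design, "motion regression")
    return TimeSeriesImage(out.reshape(bold.data.shape), bold.affine, bold.tr,
                           bold.space)


def smooth_spatial(bold, fwhm: float = DEFAULT_FWHM):
    """Per-volume 3-D Gaussian smoothing with the kernel width given as
    full width at half maximum in mm (converted per axis to voxels)."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    spacing = bold.spacing
    if np.any(spacing <= 0):
        raise ValueError("zero voxel spacing")
    sigma_vox = fwhm * FWHM_TO_SIGMA / spacing
    if isinstance(bold, ImageVolume):
        return ImageVolume(ndimage.gaussian_filter(bold.data.astype(float),
                                                   sigma_vox, mode="constant"),
                           bold.affine, bold.space)
    out = np.empty_like(bold.data, dtype=np.result_type(bold.data, np.float32))
    for t in range(bold.n_volumes):
        out[..., t] = ndimage.gaussian_filter(
            bold.data[..., t].astype(float), sigma_vox, mode="constant")
    return TimeSeriesImage(out, bold.affine, bold.tr, bold.space)


def bandpass_sos(low_cut: float, high_cut: float, tr: float) -> np.ndarray:
    """Second-order Butterworth band-pass design (single pass) in SOS form.

    The printed cutoffs are the -3 dB points of this single-pass design.
    """
    nyquist = 0.5 / tr
    if not 0 < low_cut < high_cut < nyquist:
        raise ValueError(f"cutoffs must satisfy 0 < low < high < Nyquist "
                         f"({nyquist:g} Hz at tr={tr:g} s)")
    return signal.butter(2, [low_cut, high_cut], btype="bandpass",
                         fs=1.0 / tr, output="sos")


def temporal_filter(bold: TimeSeriesImage, low_cut: float = DEFAULT_BAND[0],
                    high_cut: float = DEFAULT_BAND[1]) -> TimeSeriesImage:
    """Zero-phase band-pass (forward-backward Butterworth); the voxel mean
    is re-added after filtering."""
    sos = bandpass_sos(low_cut, high_cut, bold.tr)
    t = bold.n_volumes
    flat = bold.data.reshape(-1, t).astype(float)
    mean = flat.mean(axis=1, keepdims=True)
    filt = signal.sosfiltfilt(sos, flat - mean, axis=1) + mean
    return TimeSeriesImage(filt.astype(bold.data.dtype).reshape(bold.data.shape),
                           bold.affine, bold.tr, bold.space)


def _mask_mean_course(flat: np.ndarray, mask: ImageVolume, name: str) -> np.ndarray:
    m = mask.data.reshape(-1) > 0
    if not m.any():
        raise ValueError(f"{name} mask is empty")
    return flat[m].mean(axis=0)


def nuisance_regress(bold: TimeSeriesImage, csf_mask: ImageVolume,
                     wm_mask: ImageVolume, global_signal: bool = True,
                     brain_mask: ImageVolume | None = None) -> TimeSeriesImage:
    """Regress the mean CSF and white-matter courses (and, when
    ``global_signal`` is on, the global mean course over ``brain_mask`` or
    the whole volume) out of every voxel (residual + voxel mean)."""
    t = bold.n_volumes
    flat = bold.data.reshape(-1, t)
    cols = [np.ones(t),
            _mask_mean_course(flat, csf_mask, "CSF"),
            _mask_mean_course(flat, wm_mask, "white-matter")]
    if global_signal:
        if brain_mask is not None:
            cols.append(_mask_mean_course(flat, brain_mask, "brain"))
        else:
            cols.append(flat.mean(axis=0))
    out = _residualize(flat, np.column_stack(cols), "nuisance regression")
    return TimeSeriesImage(out.reshape(bold.data.shape), bold.affine, bold.tr,
                           bold.space)


def build_matrix(bold: TimeSeriesImage, brain_mask: ImageVolume,
                 subject_id: str = "") -> ConnectomeMatrix:
    """Extract the in-mask voxels x volumes matrix in x-fastest raster order."""
    if brain_mask.shape != bold.spatial_shape:
        raise ValueError("brain mask is not on the BOLD grid")
    idx = np.argwhere(brain_mask.data > 0)
    if idx.size == 0:
        raise ValueError("brain mask is empty")
    order = np.lexsort((idx[:, 0], idx[:, 1], idx[:, 2]))  # z, then y, then x fastest
    idx = idx[order]
    values = bold.data[idx[:, 0], idx[:, 1], idx[:, 2], :].astype(float)
    return ConnectomeMatrix(values=values, voxel_index=idx,
                            brain_mask=brain_mask, tr=bold.tr,
                            subject_id=subject_id)


def preprocess_subject(subject: ConnectomeSubject,
                       fwhm: float = DEFAULT_FWHM,
                       band: tuple = DEFAULT_BAND,
                       global_signal: bool = True) -> ConnectomeMatrix:
    """Run the full post-QC pipeline on one subject and return its matrix."""
    bold = regress_motion(subject.bold, subject.motion)
    bold = smooth_spatial(bold, fwhm)
    bold = temporal_filter(bold, band[0], band[1])
    bold = nuisance_regress(bold, subject.masks["csf"], subject.masks["white"],
                            global_signal=global_signal,
                            brain_mask=subject.masks["brain"])
    return build_matrix(bold, subject.masks["brain"], subject.subject_id)


def measure_smoothing_fwhm(fwhm: float = DEFAULT_FWHM, n: int = 61,
                           spacing: float = 1.0) -> float:
    """Empirical FWHM (mm) of the smoothing operator's impulse response.

    A unit impulse at the centre of an ``n``-cubed isotropic grid is
    smoothed with the pipeline operator; the 1-D profile through the peak is
    extracted and the width between the half-maximum crossings is located by
    linear interpolation.
    """
    aff = np.diag([spacing, spacing, spacing, 1.0])
    data = np.zeros((n, n, n))
    c = n // 2
    data[c, c, c] = 1.0
    sm = smooth_spatial(ImageVolume(data, aff), fwhm)
    profile = sm.data[:, c, c]
    half = profile[c] / 2.0
    x = np.arange(n) * spacing

    def crossing(lo_side: bool) -> float:
        if lo_side:
            below = np.nonzero(profile[:c] < half)[0]
            i = below[-1]
            return x[i] + spacing * (half - profile[i]) / (profile[i + 1] - profile[i])
        below = np.nonzero(profile[c:] < half)[0] + c
        i = below[0]
        return x[i - 1] + spacing * (profile[i - 1] - half) / (profile[i - 1] - profile[i])

    return crossing(False) - crossing(True)


def measure_filter_cutoff(low_cut: float = DEFAULT_BAND[0],
                          high_cut: float = DEFAULT_BAND[1],
                          tr: float = 2.0, n_volumes: int = 1200,
                          freqs=None) -> float:
    """Empirical high-side -3 dB frequency (Hz) of the single-pass band-pass.

    Pure sinusoids are filtered with a single (causal) pass; the steady-state
    output amplitude is estimated by projection onto the sin/cos pair at the
    driving frequency over the second half of the series, and the frequency
    where the amplitude ratio crosses 1/sqrt(2) on the high-frequency side is
    located by linear interpolation.
    """
    if freqs is None:
        freqs = np.arange(0.02, 0.1501, 0.002)
    freqs = np.asarray(freqs, dtype=float)
    sos = bandpass_sos(low_cut, high_cut, tr)
    t = np.arange(n_volumes) * tr
    half = n_volumes // 2
    ratios = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        x = np.sin(2 * np.pi * f * t)
        y = signal.sosfilt(sos, x)
        basis = np.column_stack([np.sin(2 * np.pi * f * t[half:]),
                                 np.cos(2 * np.pi * f * t[half:])])
        coef, *_ = np.linalg.lstsq(basis, y[half:], rcond=None)
        ratios[i] = np.hypot(*coef)
    target = 1.0 / np.sqrt(2.0)
    above = ratios >= target
    # last frequency still in the passband, first one below -3 dB after it
    i = np.nonzero(above)[0][-1]
    if i + 1 >= freqs.size:
        raise RuntimeError("frequency grid does not bracket the -3 dB point")
    f0, f1 = freqs[i], freqs[i + 1]
    r0, r1 = ratios[i], ratios[i + 1]
    return float(f0 + (r0 - target) / (r0 - r1) * (f1 - f0))
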