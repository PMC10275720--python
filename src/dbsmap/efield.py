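"""Stimulation-volume modeling.

Binary stimulation volumes ("VTAs") are obtained by thresholding the
magnitude of a simplified electric field at 0.2 V/mm. Each active contact is
treated as a spherical source in a uniform medium (default conductivity
0.14 S/m, the standard value for combined gray/white matter):

* current mode (amplitude I in mA): |E|(r) = I / (4 pi sigma r^2) [V/mm]
  with sigma in S/m and r in mm — the monopole field of a point current
  source in an infinite homogeneous conductor;
* voltage mode (amplitude V in volts): |E|(r) = V r0 / r^2, the field of a
  conducting sphere of radius r0 held at potential V.

Multi-contact fields superpose *vectorially* with their polarity signs
before the magnitude is taken (linear media). Inside a contact sphere the
magnitude is held at its surface value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .images import ImageVolume, grid_world_coordinates

#: Activation threshold on the E-field vector magnitude, V/mm.
DEFAULT_THRESHOLD = 0.2
#: Uniform gray/white-matter conductivity, S/m.
DEFAULT_CONDUCTIVITY = 0.14
#: Default contact sphere radius, mm (typical cylindrical DBS contact radius).
DEFAULT_CONTACT_RADIUS = 0.635


@dataclass
class ElectrodeModel:
    """Active-contact description for one electrode (or one hemisphere).

    ``active`` lists (contact index, polarity +-1, amplitude) triples;
    amplitude is mA in current mode, volts in voltage mode.
    """

    contact_centers: np.ndarray  # (n_contacts, 3) world mm
    active: list = field(default_factory=list)
    contact_radius: float = DEFAULT_CONTACT_RADIUS
    mode: str = "current"

    def __post_init__(self) -> None:
        self.contact_centers = np.atleast_2d(np.asarray(self.contact_centers, float))
        if self.mode not in ("current", "voltage"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.active:
            raise ValueError("need at least one active contact")
        if self.contact_radius <= 0:
            raise ValueError("contact_radius must be positive")
        for idx, pol, amp in self.active:
            if amp <= 0:
                raise ValueError("amplitude must be positive (use polarity for sign)")
            if pol not in (-1, 1):
                raise ValueError("polarity must be +-1")
            if not 0 <= idx < len(self.contact_centers):
                raise ValueError(f"active contact index {idx} out of range")


@dataclass
class StimulationVolume:
    """Binary stimulation volume tied to a patient."""

    mask: ImageVolume
    patient_id: str = ""
    side: str = "combined"
    empty: bool = False

    def __post_init__(self) -> None:
        if not self.mask.is_binary():
            raise ValueError("stimulation volume mask must be binary {0,1}")
        if self.n_voxels == 0 and not self.empty:
            raise ValueError("empty mask must be explicitly flagged empty")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask.data))


def compute_efield(electrode: ElectrodeModel, grid_affine, grid_shape,
                   conductivity: float = DEFAULT_CONDUCTIVITY) -> ImageVolume:
    """|E| in V/mm on the given grid from the analytic source superposition.

    The field of each active contact points radially from its centre; the
    radial distance is clamped at the contact radius so the magnitude inside
    the sphere equals its surface value.
    """
    if conductivity <= 0:
        raise ValueError("conductivity must be positive")
    coords = grid_world_coordinates(grid_affine, grid_shape)  # (nx,ny,nz,3)
    e_vec = np.zeros_like(coords)
    r0 = electrode.contact_radius
    for idx, pol, amp in electrode.active:
        d = coords - electrode.contact_centers[idx]
        r = np.linalg.norm(d, axis=-1)
        r_eff = np.maximum(r, r0)
        if electrode.mode == "current":
            # I [mA], sigma [S/m], r [mm]  ->  V/mm (the unit factors cancel)
            mag = amp / (4.0 * np.pi * conductivity * r_eff**2)
        else:
            mag = amp * r0 / r_eff**2
        unit = d / np.maximum(r, 1e-12)[..., None]
        e_vec += pol * mag[..., None] * unit
    emag = np.linalg.norm(e_vec, axis=-1)
    # a voxel sitting exactly on a contact centre has no radial direction;
    # hold it at the clamped (surface) magnitude of that contact
    for idx, pol, amp in electrode.active:
        d = coords - electrode.contact_centers[idx]
        at_center = np.linalg.norm(d, axis=-1) < 1e-9
        if at_center.any():
            if electrode.mode == "current":
                emag[at_center] = amp / (4.0 * np.pi * conductivity * r0**2)
            else:
                emag[at_center] = amp / r0
    return ImageVolume(emag, np.asarray(grid_affine, float))


def binarize_efield(efield: ImageVolume, threshold: float = DEFAULT_THRESHOLD,
                    patient_id: str = "", side: str = "combined") -> StimulationVolume:
    """Threshold |E| strictly above ``threshold`` (V/mm) into a binary volume.

    A voxel at exactly the threshold is excluded ("above" read strictly).
    An all-subthreshold field yields an empty volume flagged ``empty``.
    """
    if np.any(efield.data < 0):
        raise ValueError("E-field magnitude must be nonnegative")
    mask = (efield.data > threshold).astype(np.uint8)
    empty = not mask.any()
    if empty:
        warnings.warn(f"stimulation volume for {patient_id or 'unnamed'} is empty "
                      f"(no voxel above {threshold} V/mm)", stacklevel=2)
    return StimulationVolume(ImageVolume(mask, efield.affine, efield.space),
                             patient_id=patient_id, side=side, empty=empty)


def bilateral_stimulation_volume(electrodes: dict, grid_affine, grid_shape,
                                 threshold: float = DEFAULT_THRESHOLD,
                                 conductivity: float = DEFAULT_CONDUCTIVITY,
                                 patient_id: str = "") -> StimulationVolume:
    """Model both hemispheres' E-fields, threshold each, and take the union.

    ``electrodes`` maps side ("left"/"right") to an :class:`ElectrodeModel`;
    a missing side contributes an empty volume.
    """
    sides = {}
    for side in ("left", "right"):
        if side in electrodes and electrodes[side] is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # per-side emptiness is expected
                ef = compute_efield(electrodes[side], grid_affine, grid_shape,
                                    conductivity)
                sides[side] = binarize_efield(ef, threshold, patient_id, side)
    if not sides:
        raise ValueError(f"patient {patient_id or 'unnamed'} has no electrodes")
    if len(sides) == 1:
        vol = next(iter(sides.values()))
        return StimulationVolume(vol.mask, patient_id, "combined", vol.empty)
    return combine_bilateral(sides["left"], sides["right"])


def combine_bilateral(left: StimulationVolume, right: StimulationVolume) -> StimulationVolume:
    """Voxel-wise OR of the two hemispheric volumes (union semantics)."""
    if left.mask.shape != right.mask.shape or not np.allclose(left.mask.affine,
                                                              right.mask.affine):
        raise ValueError("left/right stimulation volumes are on different grids")
    mask = ((left.mask.data > 0) | (right.mask.data > 0)).astype(np.uint8)
    pid = left.patient_id or right.patient_id
    return StimulationVolume(ImageVolume(mask, left.mask.affine, left.mask.space),
                             patient_id=pid, side="combined",
                             empty=not mask.any())
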