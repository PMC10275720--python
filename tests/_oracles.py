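"""Shared brute-force oracles and micro-cohort builders.

These stay independent of the code paths they check: the finite-difference
Laplace solver is the physics oracle for the analytic E-field model, and the
random micro-cohorts feed per-voxel recomputation checks.
"""

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from dbsmap.efield import StimulationVolume
from dbsmap.images import ImageVolume, centered_grid


def vol_from_mask(mask, affine=None, pid=""):
    affine = np.eye(4) if affine is None else affine
    mask = np.asarray(mask, dtype=np.uint8)
    return StimulationVolume(ImageVolume(mask, affine), pid,
                             "combined", empty=not mask.any())


def random_micro_cohort(rng, n_patients=10, shape=(6, 6, 6)):
    vols = [vol_from_mask(rng.random(shape) > 0.5, pid=f"p{i}")
            for i in range(n_patients)]
    improvements = rng.normal(25, 30, n_patients)
    return vols, improvements


def fd_laplace_field(contact_center, contact_radius, shape, spacing,
                     potential=1.0, conductivity=0.14):
    """Brute-force finite-difference Laplace solve on a regular grid.

    Dirichlet conditions: ``potential`` on voxels inside the contact sphere,
    0 on the grid boundary. Returns (|E| in V/mm, measured source current in
    mA) — the current is the discrete flux out of the contact surface.
    """
    aff = centered_grid(shape, spacing)
    from dbsmap.images import grid_world_coordinates
    coords = grid_world_coordinates(aff, shape)
    r = np.linalg.norm(coords - np.asarray(contact_center), axis=-1)
    contact = r <= contact_radius
    boundary = np.zeros(shape, bool)
    boundary[[0, -1], :, :] = boundary[:, [0, -1], :] = boundary[:, :, [0, -1]] = True
    fixed = contact | boundary
    phi_fixed = np.where(contact, potential, 0.0)

    n = np.prod(shape)
    index = np.arange(n).reshape(shape)
    free = ~fixed
    free_idx = index[free]
    pos = -np.ones(n, dtype=np.int64)
    pos[free_idx] = np.arange(free_idx.size)

    rows, cols, vals = [], [], []
    rhs = np.zeros(free_idx.size)
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    fi, fj, fk = np.nonzero(free)
    row_ids = pos[index[fi, fj, fk]]
    rows.extend(row_ids)
    cols.extend(row_ids)
    vals.extend(np.full(row_ids.size, 6.0))
    for di, dj, dk in offsets:
        ni, nj, nk = fi + di, fj + dj, fk + dk
        neigh_fixed = fixed[ni, nj, nk]
        # free-free couplings
        sel = ~neigh_fixed
        rows.extend(row_ids[sel])
        cols.extend(pos[index[ni[sel], nj[sel], nk[sel]]])
        vals.extend(np.full(sel.sum(), -1.0))
        # fixed neighbors move to the right-hand side
        np.add.at(rhs, row_ids[neigh_fixed],
                  phi_fixed[ni[neigh_fixed], nj[neigh_fixed], nk[neigh_fixed]])
    a = scipy.sparse.csr_matrix((vals, (rows, cols)),
                                shape=(free_idx.size, free_idx.size))
    sol, info = scipy.sparse.linalg.cg(a, rhs, rtol=1e-10, maxiter=5000)
    assert info == 0, "CG did not converge"
    phi = phi_fixed.copy()
    phi[free] = sol

    grad = np.gradient(phi, spacing)
    emag = np.sqrt(sum(g**2 for g in grad))  # V/mm
    # measured current out of the contact: sigma * sum of face fluxes, in mA.
    # (V/mm * S/m * mm^2) * 1e-3 m/mm = A  ->  x1e3 = mA, net factor 1.
    current = 0.0
    for di, dj, dk in offsets:
        shifted = np.roll(contact, (di, dj, dk), axis=(0, 1, 2))
        face = shifted & ~contact  # voxels just outside the contact
        src = np.roll(face, (-di, -dj, -dk), axis=(0, 1, 2))
        current += conductivity * np.sum((phi[src] - phi[face])) * spacing
    return emag, current, r
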