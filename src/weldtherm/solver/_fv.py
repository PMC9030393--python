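"""Shared finite-volume plumbing: face enumeration over a voxel mask.

Faces connect cell centres of adjacent cells that are both inside a mask.
Each face carries a geometric factor area/dist so that a face conductance is
``geo * harmonic_mean(prop_a, prop_b)`` (conservative flux across material
interfaces). The z spacing is per-layer (coarse electrode layers, fine
tissue layers), so geometric factors are computed per face.
"""

from __future__ import annotations

import numpy as np


def face_pairs(mask: np.ndarray):
    """Flat index pairs (a, b) of adjacent in-mask cells, per axis."""
    shape = mask.shape
    flat = np.arange(mask.size).reshape(shape)
    pairs = []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        pm = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        pairs.append((flat[tuple(sl_a)][pm], flat[tuple(sl_b)][pm]))
    return pairs


def pair_halfweights(geom, a: np.ndarray, b: np.ndarray, axis: int):
    """Half-distance / area for each side of the faces between cells a and b.

    The face conductance for cell properties (k_a, k_b) is the
    distance-weighted harmonic mean ``1 / (w_a / k_a + w_b / k_b)``, which is
    the exact composite of the two half-cell resistances and reduces to
    ``area * harmonic_mean(k) / dist`` for equal spacings.
    """
    dz = geom.dz_layers
    nz = geom.nz
    iz_a = a % nz
    if axis == 0:
        w = 0.5 * geom.dx / (geom.dy * dz[iz_a])
        return w, w
    if axis == 1:
        w = 0.5 * geom.dy / (geom.dx * dz[iz_a])
        return w, w
    iz_b = b % nz
    area = geom.dx * geom.dy
    return 0.5 * dz[iz_a] / area, 0.5 * dz[iz_b] / area


def face_area(geom, cells: np.ndarray, axis: int) -> np.ndarray:
    """Boundary face area for flat cell indices along an axis."""
    if axis == 2:
        return np.full(cells.shape, geom.dx * geom.dy)
    dz = geom.dz_layers[cells % geom.nz]
    return (geom.dy if axis == 0 else geom.dx) * dz


def face_conductance(w_a, w_b, prop_a, prop_b):
    """Face conductance (W/K or S): distance-weighted harmonic mean."""
    return 1.0 / (w_a / prop_a + w_b / prop_b)


def exposed_faces(mask: np.ndarray):
    """Flat cell index, axis, direction (+1/-1) for each exposed face.

    A face is exposed when the neighbouring cell is outside the domain or
    outside the mask (void).
    """
    shape = mask.shape
    flat = np.arange(mask.size).reshape(shape)
    out = []
    for axis in range(3):
        for direction in (-1, +1):
            nb_ok = np.zeros(shape, dtype=bool)
            sl_c = [slice(None)] * 3
            sl_n = [slice(None)] * 3
            if direction == +1:
                sl_c[axis] = slice(None, -1)
                sl_n[axis] = slice(1, None)
            else:
                sl_c[axis] = slice(1, None)
                sl_n[axis] = slice(None, -1)
            nb_ok[tuple(sl_c)] = mask[tuple(sl_n)]
            exp = mask & ~nb_ok
            out.append((flat[exp], axis, direction))
    return out
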