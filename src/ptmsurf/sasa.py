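"""Deterministic Shrake–Rupley solvent-accessible surface area.

For each heavy atom, ``n_points`` test points are distributed
quasi-uniformly on the sphere of radius (vdW + probe) using a golden-section
spiral — a deterministic construction, so SASA is bit-reproducible across
runs. A point is accessible if it lies outside every neighboring atom's
expanded sphere; the atom's SASA is the accessible fraction times the sphere
area, and a residue's SASA is exactly the sum over its atoms.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .datamodel import StructureModel

__all__ = ["VDW_RADII", "PROBE_RADIUS", "sphere_points", "compute_sasa"]

#: Bondi-style van der Waals radii (Å) for the heavy elements of proteins.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: Water-probe radius (Å).
PROBE_RADIUS = 1.4


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (golden-section spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    # z descends uniformly; azimuth advances by the golden angle
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_sasa(
    model: StructureModel,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = 960,
) -> tuple[np.ndarray, dict[int, float]]:
    """Per-atom and per-residue absolute SASA (Å²).

    Returns ``(atom_sasa, residue_sasa)`` where ``atom_sasa`` is aligned with
    :meth:`StructureModel.all_coords` and ``residue_sasa`` maps residue
    position → summed SASA. Elements outside the vdW table raise.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    if n_points < 92:
        raise ValueError("n_points must be at least 92 for acceptable accuracy")
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")

    coords = model.all_coords()
    elements = [a.element for r in model.residues for a in r.atoms]
    try:
        radii = np.array([VDW_RADII[e] for e in elements], dtype=float) + probe_radius
    except KeyError as exc:
        raise ValueError(f"unknown element {exc.args[0]!r}; vdW table covers {sorted(VDW_RADII)}") from None

    unit = sphere_points(n_points)
    n_atoms = len(coords)
    atom_sasa = np.empty(n_atoms, dtype=float)

    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()
    neighbor_lists = tree.query_ball_point(coords, r=max_reach)

    for i in range(n_atoms):
        ri = radii[i]
        nbrs = [j for j in neighbor_lists[i] if j != i]
        pts = coords[i] + ri * unit  # (n_points, 3)
        if nbrs:
            nc = coords[nbrs]
            nr = radii[np.asarray(nbrs)]
            # true occluders only: expanded spheres that can reach this one
            d = np.linalg.norm(nc - coords[i], axis=1)
            close = d < (ri + nr)
            if close.any():
                nc, nr = nc[close], nr[close]
                d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
                accessible = (d2 >= (nr**2)[None, :]).all(axis=1)
            else:
                accessible = np.ones(n_points, dtype=bool)
        else:
            accessible = np.ones(n_points, dtype=bool)
        atom_sasa[i] = accessible.mean() * 4.0 * math.pi * ri * ri

    residue_sasa: dict[int, float] = {}
    atom_res = model.atom_residue_positions()
    for pos in model.positions:
        residue_sasa[pos] = float(atom_sasa[atom_res == pos].sum())
    return atom_sasa, residue_sasa
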