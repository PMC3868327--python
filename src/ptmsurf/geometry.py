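"""Geometric classification on a structure model.

Exposure classes from relative SASA, residue-to-residue proximity at a fixed
heavy-atom distance cutoff, hemispheric face partitioning around the variant
cluster axis, and charged-neighborhood annotation. All distances are minimum
heavy-atom-to-heavy-atom Euclidean distances — the quantity a 5-Å sphere
probe around a residue measures in a molecular viewer.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .datamodel import (
    ExposureProfile,
    ExposureRecord,
    FacePartition,
    ProximitySet,
    StructureModel,
    VariantSite,
)

__all__ = [
    "MAX_ASA",
    "classify_exposure",
    "proximity_to_targets",
    "assign_faces",
    "charge_environment",
    "side_chain_centroid",
]

#: Theoretical maximum accessible surface area per residue type (Å²),
#: from extended Gly-X-Gly tripeptides (Tien et al. 2013, theoretical set).
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Default relative-SASA threshold below which a residue is called buried.
BURIED_BELOW = 0.05


def classify_exposure(
    model: StructureModel,
    residue_sasa: dict[int, float],
    max_asa: dict[str, float] | None = None,
    buried_below: float = BURIED_BELOW,
) -> ExposureProfile:
    """Classify each residue as buried or exposed from its relative SASA.

    ``sasa_rel = sasa_abs / max_asa[residue type]``; a residue is buried when
    ``sasa_rel < buried_below`` and exposed (the "largely or partly exposed"
    tier) otherwise. Relative values are capped at 1.0 for reporting; the
    class is unaffected since thresholds are well below 1.
    """
    reference = MAX_ASA if max_asa is None else max_asa
    if not (0.0 <= buried_below <= 1.0):
        raise ValueError("buried_below must be a fraction in [0, 1]")
    records: dict[int, ExposureRecord] = {}
    for res in model.residues:
        if res.aa not in reference:
            raise ValueError(f"no max-ASA reference for residue type {res.aa!r}")
        sasa_abs = residue_sasa[res.position]
        rel = sasa_abs / reference[res.aa]
        cls = "buried" if rel < buried_below else "exposed"
        records[res.position] = ExposureRecord(
            position=res.position,
            aa=res.aa,
            sasa_abs=sasa_abs,
            sasa_rel=min(rel, 1.0),
            exposure_class=cls,
        )
    return ExposureProfile(records=records, buried_below=buried_below)


def _min_residue_distances(
    model: StructureModel, queries: Sequence[int], targets: Sequence[int], radius: float
) -> dict[tuple[int, int], float]:
    """Minimum heavy-atom distance for every (query, target) pair within radius.

    Spatial binning via a KD-tree sparse query; exactly equivalent to the
    all-pairs scan because every atom pair within ``radius`` is enumerated.
    """
    coords = model.all_coords()
    atom_res = model.atom_residue_positions()
    qset, tset = set(queries), set(targets)
    q_mask = np.isin(atom_res, list(qset))
    t_mask = np.isin(atom_res, list(tset))
    if not q_mask.any() or not t_mask.any():
        return {}
    q_idx = np.flatnonzero(q_mask)
    t_idx = np.flatnonzero(t_mask)
    q_tree = cKDTree(coords[q_idx])
    t_tree = cKDTree(coords[t_idx])
    sparse = q_tree.sparse_distance_matrix(t_tree, max_distance=radius, output_type="coo_matrix")
    best: dict[tuple[int, int], float] = {}
    for qi, ti, d in zip(sparse.row, sparse.col, sparse.data):
        qpos = int(atom_res[q_idx[qi]])
        tpos = int(atom_res[t_idx[ti]])
        if qpos == tpos:
            continue
        key = (qpos, tpos)
        if d < best.get(key, np.inf):
            best[key] = float(d)
    return best


def proximity_to_targets(
    model: StructureModel,
    queries: Iterable[int],
    targets: Iterable[int],
    radius: float = 5.0,
) -> ProximitySet:
    """Pairs (q, t), q ≠ t, whose minimum heavy-atom distance is ≤ radius."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    queries = sorted(set(queries))
    targets = sorted(set(targets))
    for pos in list(queries) + list(targets):
        if not model.has_position(pos):
            raise ValueError(f"position {pos} is not modelled")
    dists = _min_residue_distances(model, queries, targets, radius)
    pairs = set(dists)
    return ProximitySet(radius=radius, pairs=pairs, distances=dists)


def side_chain_centroid(residue) -> np.ndarray:
    """Centroid of side-chain heavy atoms; falls back to Cα (then to all
    atoms) when no side chain is present, e.g. glycine."""
    backbone = {"N", "CA", "C", "O", "OXT"}
    side = [a for a in residue.atoms if a.name not in backbone]
    if side:
        return np.mean([[a.x, a.y, a.z] for a in side], axis=0)
    ca = [a for a in residue.atoms if a.name == "CA"]
    if ca:
        return ca[0].coords()
    return residue.coord_array().mean(axis=0)


def assign_faces(
    model: StructureModel,
    variants: Sequence[VariantSite],
    exposure: ExposureProfile,
) -> FacePartition:
    """Partition residues into the variable and conserved hemispheres.

    The axis points from the all-atom centroid of the model toward the
    centroid of side-chain atoms of surface-exposed variant residues. A
    residue is variable-face iff its side-chain centroid has a positive
    projection on the axis; ties (projection exactly 0) go to the conserved
    face.
    """
    exposed_variants = [
        v for v in variants
        if model.has_position(v.position) and not exposure.is_buried(v.position)
    ]
    if not exposed_variants:
        raise ValueError("no surface-exposed variant residues: faces are undefined")
    center = model.all_coords().mean(axis=0)
    var_centroid = np.mean(
        [side_chain_centroid(model[v.position]) for v in exposed_variants], axis=0
    )
    axis = var_centroid - center
    norm = float(np.linalg.norm(axis))
    if norm == 0.0:
        raise ValueError("variant centroid coincides with model centroid; axis undefined")
    axis = axis / norm
    face = {
        res.position: (
            "variable" if float(np.dot(side_chain_centroid(res) - center, axis)) > 0.0 else "conserved"
        )
        for res in model.residues
    }
    return FacePartition(axis=axis, face=face)


_NEGATIVE = frozenset("DE")
_POSITIVE = frozenset("KR")


def _charge(aa: str) -> int:
    if aa in _NEGATIVE:
        return -1
    if aa in _POSITIVE:
        return +1
    return 0


def charge_environment(
    model: StructureModel,
    site: int,
    radius: float,
    variants: Sequence[VariantSite] = (),
) -> list[dict]:
    """Charged residues (D/E negative, K/R positive) within ``radius`` of a
    site, each flagged when its position is a variant whose alleles differ in
    charge (e.g. a D→A change: negative charge present in one isoform,
    absent in the other)."""
    if not model.has_position(site):
        raise ValueError(f"site {site} is not modelled")
    if radius <= 0:
        raise ValueError("radius must be positive")
    variant_by_pos = {v.position: v for v in variants}
    charged = [r.position for r in model.residues if _charge(r.aa) != 0 and r.position != site]
    prox = _min_residue_distances(model, [site], charged, radius)
    out = []
    for (_, pos), dist in sorted(prox.items(), key=lambda kv: kv[1]):
        aa = model[pos].aa
        entry = {
            "position": pos,
            "aa": aa,
            "charge": _charge(aa),
            "distance": dist,
            "isoform_difference": False,
        }
        v = variant_by_pos.get(pos)
        if v is not None and _charge(v.aa_A1) != _charge(v.aa_A2):
            entry["isoform_difference"] = True
            entry["variant"] = v.label
        out.append(entry)
    return out
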