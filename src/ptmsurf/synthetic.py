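"""Desk-scale synthetic structures, variants, PTM tables and alignments with
planted ground truth.

The globule generator emulates what the analysis needs from a real protein
model — a compact chain with genuinely buried residues and a surface shell —
at pseudo-atom resolution: one Cα plus one side-chain sphere per residue
(glycine gets only Cα), which is sufficient for accessibility, proximity and
face logic at a fraction of the all-atom cost. It does not emulate secondary
structure, rotamers, or realistic packing. Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import COMPATIBILITY
from .datamodel import (
    AlignmentMap,
    Atom,
    PTMRecord,
    PTMTable,
    ResidueRecord,
    StructureModel,
    VariantSite,
)

__all__ = [
    "SyntheticTruth",
    "generate_globule",
    "plant_variants",
    "sample_ptms",
    "generate_alignment",
]

CA_SPACING = 3.8  # Å between consecutive lattice positions
JITTER = 0.08  # Å uniform jitter per coordinate; keeps min Cα distance > 3.5
SIDE_CHAIN_OFFSET = 1.8  # Å from Cα to the side-chain pseudo-sphere center

#: Residues that get a sulfur-radius (larger) side-chain pseudo-sphere.
_BULKY = frozenset("RKFWYEQM")

_AA_CHOICES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticTruth:
    """Exact record of what a synthetic bundle planted."""

    seed: int
    interior_positions: set[int] = field(default_factory=set)
    shell_positions: set[int] = field(default_factory=set)
    variant_positions: dict[int, int] = field(default_factory=dict)  # position -> cluster
    proximal_site_positions: set[int] = field(default_factory=set)
    distal_site_positions: set[int] = field(default_factory=set)
    planted_fold: float = 1.0
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "interior_positions": sorted(self.interior_positions),
            "shell_positions": sorted(self.shell_positions),
            "variant_positions": {str(k): v for k, v in sorted(self.variant_positions.items())},
            "proximal_site_positions": sorted(self.proximal_site_positions),
            "distal_site_positions": sorted(self.distal_site_positions),
            "planted_fold": self.planted_fold,
            "params": self.params,
        }


def _serpentine_lattice(n: int) -> tuple[np.ndarray, np.ndarray]:
    """First ``n`` sites of a boustrophedon walk through an L³ cube.

    Returns (integer lattice coordinates, site order); consecutive sites are
    lattice neighbors, so the chain is self-avoiding with constant spacing.
    """
    L = math.ceil(n ** (1 / 3))
    sites = []
    for z in range(L):
        ys = range(L) if z % 2 == 0 else range(L - 1, -1, -1)
        for y in ys:
            parity = (z * L + (y if z % 2 == 0 else L - 1 - y)) % 2
            xs = range(L) if parity == 0 else range(L - 1, -1, -1)
            for x in xs:
                sites.append((x, y, z))
    lattice = np.array(sites[:n], dtype=int)
    return lattice, np.arange(n)


def generate_globule(n_residues: int, seed: int) -> tuple[StructureModel, SyntheticTruth]:
    """A compact self-avoiding chain on a jittered cubic lattice.

    Residues whose 26 lattice neighbors are all occupied form the designated
    interior subset (fully enclosed, so their relative SASA is below the
    buried threshold); the rest form the shell. Deterministic per seed.
    """
    if n_residues < 20:
        raise ValueError("need at least 20 residues for a globule")
    rng = np.random.default_rng(seed)
    lattice, _ = _serpentine_lattice(n_residues)
    occupied = {tuple(p) for p in lattice}

    interior: set[int] = set()
    for i, (x, y, z) in enumerate(lattice):
        neighbors = [
            (x + dx, y + dy, z + dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
        if all(nb in occupied for nb in neighbors):
            interior.add(i + 1)
    if not interior:
        raise ValueError(f"{n_residues} residues are too few to enclose an interior")

    coords = lattice.astype(float) * CA_SPACING
    coords += rng.uniform(-JITTER, JITTER, size=coords.shape)
    center = coords.mean(axis=0)

    aa_seq = rng.choice(list(_AA_CHOICES), size=n_residues)
    residues: list[ResidueRecord] = []
    for i in range(n_residues):
        pos = i + 1
        aa = str(aa_seq[i])
        ca = Atom("CA", "C", *coords[i])
        atoms = [ca]
        if aa != "G":
            # side-chain sphere pushed outward from the globule center so
            # shell side chains face solvent and interior ones stay packed
            direction = coords[i] - center
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
            sc = coords[i] + SIDE_CHAIN_OFFSET * direction
            element = "S" if aa in _BULKY else "C"
            atoms.append(Atom("CB", element, *sc))
        residues.append(ResidueRecord(pos, aa, atoms))

    model = StructureModel(residues=residues, chain_id="A")
    truth = SyntheticTruth(
        seed=seed,
        interior_positions=interior,
        shell_positions=set(range(1, n_residues + 1)) - interior,
        params={"n_residues": n_residues, "ca_spacing": CA_SPACING, "jitter": JITTER},
    )
    return model, truth


def plant_variants(
    model: StructureModel,
    truth: SyntheticTruth,
    n_clusters: int = 2,
    cluster_size: int = 6,
    seed: int = 0,
    max_cluster_radius: float = 8.0,
) -> list[VariantSite]:
    """Plant 1–2 spatially contiguous variant clusters on one hemisphere.

    Cluster seeds are shell residues on the +z hemisphere; members are the
    nearest shell residues to each seed (all within ``max_cluster_radius``).
    Allele pairs mix capability-changing (S→A, C→T, K→R, T→A) and
    charge-changing (D→A, D→Q, Q→E, T→E) substitutions; the model's sequence
    is set to the reference (A1) allele at each variant position.
    """
    if not 0 <= n_clusters <= 2:
        raise ValueError("n_clusters must be 0, 1 or 2")
    if n_clusters == 0:
        return []
    rng = np.random.default_rng(seed)
    ca = {r.position: next(a for a in r.atoms if a.name == "CA").coords() for r in model.residues}
    center = model.all_coords().mean(axis=0)
    shell = sorted(truth.shell_positions)
    hemisphere = [p for p in shell if ca[p][2] > center[2]]
    if len(hemisphere) < n_clusters * cluster_size:
        raise ValueError(
            f"hemisphere shell has {len(hemisphere)} residues, need {n_clusters * cluster_size}"
        )

    # first seed: the topmost shell residue; second: the hemisphere residue
    # farthest from the first, so the two clusters do not merge
    seeds = [max(hemisphere, key=lambda p: ca[p][2])]
    if n_clusters == 2:
        seeds.append(max(hemisphere, key=lambda p: float(np.linalg.norm(ca[p] - ca[seeds[0]]))))

    allele_pairs = [("S", "A"), ("C", "T"), ("K", "R"), ("D", "A"), ("T", "A"), ("D", "Q"), ("Q", "E"), ("T", "E")]
    variants: list[VariantSite] = []
    taken: set[int] = set()
    pair_i = 0
    for ci, seed_pos in enumerate(seeds, start=1):
        candidates = sorted(
            (p for p in hemisphere if p not in taken),
            key=lambda p: float(np.linalg.norm(ca[p] - ca[seed_pos])),
        )
        members = candidates[:cluster_size]
        radius = float(np.linalg.norm(ca[members[-1]] - ca[seed_pos]))
        if radius > max_cluster_radius:
            raise ValueError(
                f"cluster {ci} would span {radius:.1f} Å > {max_cluster_radius} Å; "
                "hemisphere shell too sparse for the requested cluster size"
            )
        for pos in members:
            aa1, aa2 = allele_pairs[pair_i % len(allele_pairs)]
            pair_i += 1
            model[pos].aa = aa1
            variants.append(VariantSite(position=pos, aa_A1=aa1, aa_A2=aa2, cluster=ci, exposed=True))
            taken.add(pos)
            truth.variant_positions[pos] = ci
    return variants


def sample_ptms(
    model: StructureModel,
    variants: Sequence[VariantSite],
    surface_positions: Sequence[int],
    p_near: float = 0.5,
    p_far: float = 0.25,
    radius: float = 5.0,
    mean_citations_high: float = 12.0,
    mean_citations_low: float = 1.5,
    p_high_evidence: float = 0.6,
    p_site_specific: float = 0.08,
    seed: int = 0,
) -> tuple[PTMTable, SyntheticTruth]:
    """Sample a PTM table with elevated site probability near variants.

    Each surface residue with at least one chemically compatible modification
    becomes a site with probability ``p_near`` when within ``radius`` Å
    (minimum heavy-atom distance) of a variant, else ``p_far``; the planted
    enrichment is thus ``p_near / p_far``. The modification type is uniform
    over the types compatible with the residue; citation counts come from a
    two-component geometric mixture so the evidence filter has both tiers to
    separate.
    """
    from .geometry import proximity_to_targets

    for name, p in (("p_near", p_near), ("p_far", p_far)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if p_far > p_near:
        raise ValueError("p_far must not exceed p_near")
    rng = np.random.default_rng(seed)

    variant_positions = [v.position for v in variants]
    surface = sorted(set(surface_positions))
    proximal: set[int] = set()
    if variant_positions and p_near > 0:
        prox = proximity_to_targets(model, surface, variant_positions, radius=radius)
        proximal = prox.proximal_queries()
        # variant positions are themselves near a variant (distance 0 to self
        # is excluded by the pair definition, so add them explicitly)
        proximal |= set(variant_positions) & set(surface)

    compat_by_aa = {
        aa: sorted(m for m, allowed in COMPATIBILITY.items() if aa in allowed)
        for aa in set(r.aa for r in model.residues)
    }

    records: list[PTMRecord] = []
    truth = SyntheticTruth(
        seed=seed,
        planted_fold=(p_near / p_far) if p_far > 0 else float("inf"),
        params={
            "p_near": p_near, "p_far": p_far, "radius": radius,
            "mean_citations_high": mean_citations_high,
            "mean_citations_low": mean_citations_low,
            "p_high_evidence": p_high_evidence,
            "p_site_specific": p_site_specific,
        },
    )
    for pos in surface:
        res = model[pos]
        mods = compat_by_aa.get(res.aa, [])
        if not mods:
            continue
        p_site = p_near if pos in proximal else p_far
        if rng.random() >= p_site:
            continue
        mod = mods[int(rng.integers(len(mods)))]
        if rng.random() < p_high_evidence:
            citations = int(rng.geometric(1.0 / mean_citations_high)) + 4
        else:
            citations = int(rng.geometric(1.0 / mean_citations_low)) - 1
        records.append(
            PTMRecord(
                isoform="eEF1A1",
                position=pos,
                aa=res.aa,
                mod_type=mod,
                n_citations=citations,
                site_specific=bool(rng.random() < p_site_specific),
                species=("human",),
            )
        )
        (truth.proximal_site_positions if pos in proximal else truth.distal_site_positions).add(pos)

    table = PTMTable(records=records, provenance=f"synthetic(seed={seed})")
    return table, truth


def generate_alignment(
    reference: str,
    n_orthologs: int,
    divergence: float,
    planted_site_substitutions: Sequence[int] = (),
    seed: int = 0,
) -> AlignmentMap:
    """An ungapped ortholog alignment plus one divergent row.

    Orthologs mutate each position independently at ``divergence`` but never
    at a planted position; the ``distant`` row additionally carries a forced
    substitution at every planted position (emulating sites lost in a distant
    homolog). Row names: ``reference``, ``ortholog_<i>``, ``distant``.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    reference = reference.upper()
    planted = set(planted_site_substitutions)
    bad = [p for p in planted if not 1 <= p <= len(reference)]
    if bad:
        raise ValueError(f"planted positions outside the reference: {bad}")

    def mutate(aa: str) -> str:
        choices = [c for c in _AA_CHOICES if c != aa]
        return choices[int(rng.integers(len(choices)))]

    rows: dict[str, str] = {"reference": reference}
    for i in range(1, n_orthologs + 1):
        rows[f"ortholog_{i}"] = "".join(
            mutate(aa) if (pos not in planted and rng.random() < divergence) else aa
            for pos, aa in enumerate(reference, start=1)
        )
    rows["distant"] = "".join(
        mutate(aa)
        if (pos in planted or (pos not in planted and rng.random() < divergence))
        else aa
        for pos, aa in enumerate(reference, start=1)
    )

    from .io import _column_state

    n_cols = len(reference)
    column_to_position = {
        name: {c: c + 1 for c in range(n_cols)} for name in rows
    }
    conservation = [_column_state([row[c] for row in rows.values()]) for c in range(n_cols)]
    return AlignmentMap(sequences=rows, column_to_position=column_to_position, conservation=conservation)
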