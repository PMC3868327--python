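"""Shared domain types for structure-based PTM analysis.

All residue positions are 1-based in the canonical numbering of the reference
isoform (for the eEF1A pair this is eEF1A1 numbering; the paralogs align
without internal gaps over the modelled region, so every variant label such
as ``T176A`` uses one shared position).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: The twenty standard one-letter amino-acid codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Heavy-atom elements covered by the van der Waals radii table.
SUPPORTED_ELEMENTS = frozenset({"C", "N", "O", "S"})

#: Controlled vocabulary of modification types.
MOD_TYPES = (
    "phosphorylation",
    "acetylation",
    "methylation",
    "ubiquitination",
    "S-nitrosylation",
    "S-glutathionylation",
    "O-glucosylation",
    "ethanolamination",
    "carbonylation",
)

ISOFORMS = ("eEF1A1", "eEF1A2", "ambiguous")


@dataclass(frozen=True)
class Atom:
    """A heavy atom: PDB atom name, element symbol, coordinates in Å."""

    name: str
    element: str
    x: float
    y: float
    z: float

    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class ResidueRecord:
    """One modelled residue: 1-based position, one-letter code, heavy atoms."""

    position: int
    aa: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if self.aa not in STANDARD_AA:
            raise ValueError(f"non-standard amino acid code {self.aa!r} at position {self.position}")
        if not self.atoms:
            raise ValueError(f"residue {self.position} has no heavy atoms")
        for a in self.atoms:
            if a.element not in SUPPORTED_ELEMENTS:
                raise ValueError(
                    f"unsupported element {a.element!r} in residue {self.position}; "
                    f"supported: {sorted(SUPPORTED_ELEMENTS)}"
                )
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinate in residue {self.position}")

    def coord_array(self) -> np.ndarray:
        """(n_atoms, 3) array of heavy-atom coordinates."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """Ordered modelled residues of one chain.

    ``resolved_range`` is the (first, last) modelled position, 1-based
    inclusive; positions must be strictly increasing and unique.
    """

    residues: list[ResidueRecord]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        positions = [r.position for r in self.residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("residue positions must be strictly increasing and unique")

    @property
    def resolved_range(self) -> tuple[int, int]:
        if not self.residues:
            raise ValueError("empty model has no resolved range")
        return (self.residues[0].position, self.residues[-1].position)

    @property
    def positions(self) -> list[int]:
        return [r.position for r in self.residues]

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, position: int) -> ResidueRecord:
        try:
            return self._index[position]
        except AttributeError:
            self._index = {r.position: r for r in self.residues}
            return self._index[position]

    def __contains__(self, position: int) -> bool:
        return any(r.position == position for r in self.residues)

    def has_position(self, position: int) -> bool:
        try:
            self[position]
            return True
        except KeyError:
            return False

    def all_coords(self) -> np.ndarray:
        """(n_atoms_total, 3) coordinates of every heavy atom in chain order."""
        return np.vstack([r.coord_array() for r in self.residues])

    def atom_residue_positions(self) -> np.ndarray:
        """Residue position of each atom, aligned with :meth:`all_coords`."""
        return np.concatenate([np.full(len(r.atoms), r.position, dtype=int) for r in self.residues])


@dataclass(frozen=True)
class PTMRecord:
    """One curated modification record.

    ``n_citations`` counts mass-spectrometry records supporting the site;
    ``site_specific`` marks confirmation by a targeted experiment.
    """

    isoform: str
    position: int
    aa: str
    mod_type: str
    n_citations: int = 0
    site_specific: bool = False
    species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.isoform not in ISOFORMS:
            raise ValueError(f"unknown isoform {self.isoform!r}; expected one of {ISOFORMS}")
        if self.mod_type not in MOD_TYPES:
            raise ValueError(
                f"unknown modification {self.mod_type!r}; controlled vocabulary: {', '.join(MOD_TYPES)}"
            )
        if self.aa not in STANDARD_AA:
            raise ValueError(f"non-standard amino acid {self.aa!r}")
        if self.position < 1:
            raise ValueError("positions are 1-based; got %d" % self.position)
        if self.n_citations < 0:
            raise ValueError("n_citations must be non-negative")


@dataclass
class PTMTable:
    """Curated modification records plus load-time bookkeeping.

    ``flagged`` holds records whose (residue, modification) pair failed the
    chemical-compatibility check; they are retained and reported, never
    silently dropped: ``records_in == len(records) + len(flagged)``.
    """

    records: list[PTMRecord]
    provenance: str = ""
    flagged: list[PTMRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        deduped = []
        for rec in self.records:
            key = (rec.isoform, rec.position, rec.mod_type)
            if key in seen:
                continue
            seen.add(key)
            deduped.append(rec)
        self.records = deduped

    def __len__(self) -> int:
        return len(self.records)

    def positions(self) -> list[int]:
        """Distinct modified positions, ascending."""
        return sorted({r.position for r in self.records})

    def mods_at(self, position: int) -> set[str]:
        return {r.mod_type for r in self.records if r.position == position}


@dataclass(frozen=True)
class VariantSite:
    """A paralog sequence difference in ``X{pos}Y`` notation.

    ``aa_A1`` is the residue in the reference isoform (eEF1A1), ``aa_A2`` in
    the other (eEF1A2); ``cluster`` is 1, 2 or None for unclustered.
    """

    position: int
    aa_A1: str
    aa_A2: str
    cluster: int | None = None
    exposed: bool = True

    def __post_init__(self) -> None:
        if self.aa_A1 == self.aa_A2:
            raise ValueError(f"variant at {self.position} has identical alleles {self.aa_A1}")
        for aa in (self.aa_A1, self.aa_A2):
            if aa not in STANDARD_AA:
                raise ValueError(f"non-standard amino acid {aa!r}")
        if self.cluster not in (None, 1, 2):
            raise ValueError("cluster must be 1, 2 or None")

    @property
    def label(self) -> str:
        return f"{self.aa_A1}{self.position}{self.aa_A2}"


@dataclass
class AlignmentMap:
    """A multiple sequence alignment with per-column conservation state.

    ``sequences`` maps row name → aligned row (with gaps ``-``);
    ``column_to_position[name]`` maps alignment column (0-based) → ungapped
    1-based position, absent for gap columns; ``conservation[c]`` is one of
    ``strict`` / ``conservative`` / ``variable``.
    """

    sequences: dict[str, str]
    column_to_position: dict[str, dict[int, int]]
    conservation: list[str]

    @property
    def n_columns(self) -> int:
        return len(self.conservation)

    def position_to_column(self, name: str) -> dict[int, int]:
        """Inverse map: ungapped 1-based position → alignment column."""
        return {pos: col for col, pos in self.column_to_position[name].items()}

    def degapped(self, name: str) -> str:
        return self.sequences[name].replace("-", "")


@dataclass(frozen=True)
class ExposureRecord:
    position: int
    aa: str
    sasa_abs: float
    sasa_rel: float
    exposure_class: str  # "buried" | "exposed"


@dataclass
class ExposureProfile:
    """Per-residue solvent accessibility and buried/exposed class."""

    records: dict[int, ExposureRecord]
    buried_below: float

    def exposure_class(self, position: int) -> str:
        return self.records[position].exposure_class

    def is_buried(self, position: int) -> bool:
        return self.records[position].exposure_class == "buried"

    def exposed_positions(self) -> list[int]:
        return sorted(p for p, r in self.records.items() if r.exposure_class != "buried")

    def buried_positions(self) -> list[int]:
        return sorted(p for p, r in self.records.items() if r.exposure_class == "buried")


@dataclass
class FacePartition:
    """Hemispheric partition of the model into a variable and a conserved face.

    ``axis`` is the unit vector from the model centroid toward the centroid of
    exposed variant side chains; a residue belongs to the variable face iff its
    side-chain centroid falls on the positive side of the equatorial plane.
    """

    axis: np.ndarray
    face: dict[int, str]  # position -> "variable" | "conserved"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        norm = float(np.linalg.norm(self.axis))
        if not math.isclose(norm, 1.0, rel_tol=1e-6):
            raise ValueError("face axis must be a unit vector")
        bad = {v for v in self.face.values()} - {"variable", "conserved"}
        if bad:
            raise ValueError(f"unknown face labels: {bad}")

    def of(self, position: int) -> str:
        return self.face[position]


@dataclass
class ProximitySet:
    """Pairs (query, target) whose minimum heavy-atom distance ≤ radius."""

    radius: float
    pairs: set[tuple[int, int]]
    distances: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if any(q == t for q, t in self.pairs):
            raise ValueError("proximity pairs exclude self-pairs")

    def proximal_queries(self) -> set[int]:
        return {q for q, _ in self.pairs}

    def targets_of(self, query: int) -> set[int]:
        return {t for q, t in self.pairs if q == query}


@dataclass
class EnrichmentResult:
    """Observed enrichment of hits among observed sites vs a candidate pool."""

    n_observed: int
    n_observed_hits: int
    n_pool: int
    n_pool_hits: int
    fold: float
    p_perm: float
    n_perm: int
    seed: int | None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_perm <= 1.0):
            raise ValueError("p_perm must lie in [0, 1]")
        if self.n_observed_hits > self.n_observed:
            raise ValueError("hit count exceeds observed count")
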