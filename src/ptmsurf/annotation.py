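"""Sequence-level PTM logic.

Chemical compatibility of modifications with side chains, isoform-altered
modifiability at variant positions, mapping of curated sites onto the
modelled region, multi-modification and evidence-tier accounting,
conservation transfer across an alignment, and binding-site overlap.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .datamodel import (
    MOD_TYPES,
    STANDARD_AA,
    AlignmentMap,
    PTMRecord,
    PTMTable,
    StructureModel,
    VariantSite,
)

__all__ = [
    "COMPATIBILITY",
    "modification_compatibility",
    "AlteredCapability",
    "detect_altered_capability",
    "MappedSiteSet",
    "map_ptm_to_structure",
    "multi_modification_sites",
    "reliability_filter",
    "conservation_of_sites",
    "binding_site_overlap",
]

#: Side chains that support each modification chemistry. Data-driven and
#: editable: pass a custom table to :func:`modification_compatibility`.
#: N-terminal acetylation is deliberately excluded — only side-chain
#: chemistry is modelled. The carbonylation set follows the standard
#: metal-catalyzed-oxidation targets (K, R, P, T).
COMPATIBILITY: dict[str, frozenset[str]] = {
    "phosphorylation": frozenset("STY"),
    "acetylation": frozenset("K"),
    "methylation": frozenset("KR"),
    "ubiquitination": frozenset("K"),
    "S-nitrosylation": frozenset("C"),
    "S-glutathionylation": frozenset("C"),
    "O-glucosylation": frozenset("S"),
    "ethanolamination": frozenset("E"),
    "carbonylation": frozenset("KRPT"),
}


def modification_compatibility(
    aa: str, mod_type: str, table: Mapping[str, frozenset[str]] | None = None
) -> bool:
    """True iff the side chain of ``aa`` supports the chemistry of ``mod_type``."""
    rules = COMPATIBILITY if table is None else table
    if aa not in STANDARD_AA:
        raise ValueError(f"non-standard amino acid {aa!r}")
    if mod_type not in rules:
        raise ValueError(f"unknown modification {mod_type!r}; known: {sorted(rules)}")
    return aa in rules[mod_type]


@dataclass(frozen=True)
class AlteredCapability:
    """Modifications chemically possible for only one isoform's residue at a
    variant position — e.g. phosphorylation of T176 in eEF1A1 but not of A176
    in eEF1A2."""

    variant: VariantSite
    mods_only_A1: frozenset[str]
    mods_only_A2: frozenset[str]


def detect_altered_capability(
    variants: Sequence[VariantSite],
    table: PTMTable,
    rules: Mapping[str, frozenset[str]] | None = None,
) -> list[AlteredCapability]:
    """Isoform-specific modifiability at variant positions.

    For each variant carrying at least one observed modification, a mod type
    lands in ``mods_only_A1`` iff it is compatible with the eEF1A1 allele but
    not the eEF1A2 allele (and symmetrically). Variants with no differential
    capability over their observed modifications are omitted.
    """
    out: list[AlteredCapability] = []
    for v in variants:
        observed = table.mods_at(v.position)
        if not observed:
            continue
        only_a1 = frozenset(
            m for m in observed
            if modification_compatibility(v.aa_A1, m, rules)
            and not modification_compatibility(v.aa_A2, m, rules)
        )
        only_a2 = frozenset(
            m for m in observed
            if modification_compatibility(v.aa_A2, m, rules)
            and not modification_compatibility(v.aa_A1, m, rules)
        )
        if only_a1 or only_a2:
            out.append(AlteredCapability(variant=v, mods_only_A1=only_a1, mods_only_A2=only_a2))
    return out


@dataclass
class MappedSiteSet:
    """Distinct modified positions split into those within the modelled range
    and those beyond the C-terminal boundary (the disordered tail)."""

    mapped: list[int]
    unmapped_tail: list[int]
    mods_by_position: dict[int, set[str]] = field(default_factory=dict)
    isoforms_by_position: dict[int, set[str]] = field(default_factory=dict)
    evidence_by_position: dict[int, dict] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return len(self.mapped) + len(self.unmapped_tail)


def map_ptm_to_structure(
    table: PTMTable,
    model: StructureModel,
    c_terminal_boundary: int | None = None,
    sequence_length: int | None = None,
) -> MappedSiteSet:
    """Split the table's distinct positions into mapped vs C-terminal tail.

    ``c_terminal_boundary`` defaults to the last resolved residue of the
    model; positions beyond it belong to the disordered tail. Mod-type sets
    and evidence summaries are merged across species and isoforms — the
    accounting counts positions, not species-records.
    """
    positions = table.positions()
    if not positions:
        return MappedSiteSet(mapped=[], unmapped_tail=[])
    boundary = model.resolved_range[1] if c_terminal_boundary is None else c_terminal_boundary
    if sequence_length is not None:
        bad = [p for p in positions if p > sequence_length]
        if bad:
            raise ValueError(f"positions beyond sequence length {sequence_length}: {bad}")
    mapped = [p for p in positions if p <= boundary]
    tail = [p for p in positions if p > boundary]
    unmodelled = [p for p in mapped if not model.has_position(p)]
    if unmodelled:
        raise ValueError(f"positions within the boundary but not modelled: {unmodelled}")

    mods: dict[int, set[str]] = defaultdict(set)
    isoforms: dict[int, set[str]] = defaultdict(set)
    evidence: dict[int, dict] = {}
    for rec in table.records:
        mods[rec.position].add(rec.mod_type)
        isoforms[rec.position].add(rec.isoform)
        ev = evidence.setdefault(
            rec.position, {"n_citations_max": 0, "site_specific_any": False, "species": set()}
        )
        ev["n_citations_max"] = max(ev["n_citations_max"], rec.n_citations)
        ev["site_specific_any"] = ev["site_specific_any"] or rec.site_specific
        ev["species"].update(rec.species)
    return MappedSiteSet(
        mapped=mapped,
        unmapped_tail=tail,
        mods_by_position=dict(mods),
        isoforms_by_position=dict(isoforms),
        evidence_by_position=evidence,
    )


def multi_modification_sites(table: PTMTable) -> dict[int, set[str]]:
    """Positions carrying ≥2 distinct modification types, with their mod sets.

    Invariant to record order and to species-level duplication of the same
    (position, mod_type) observation.
    """
    mods: dict[int, set[str]] = defaultdict(set)
    for rec in table.records:
        mods[rec.position].add(rec.mod_type)
    return {pos: s for pos, s in mods.items() if len(s) >= 2}


def reliability_filter(
    table: PTMTable, min_citations: int = 5
) -> tuple[PTMTable, dict[str, tuple[int, int]]]:
    """High-confidence subset: records confirmed by a targeted experiment or
    carried by at least ``min_citations`` mass-spectrometry citations.

    Returns the filtered table and per-mod-type (pass, total) counts;
    pass + fail = total for every mod type.
    """
    if min_citations < 0:
        raise ValueError("min_citations must be non-negative")
    passed = [r for r in table.records if r.site_specific or r.n_citations >= min_citations]
    counts: dict[str, tuple[int, int]] = {}
    for mod in MOD_TYPES:
        total = sum(1 for r in table.records if r.mod_type == mod)
        npass = sum(1 for r in passed if r.mod_type == mod)
        if total:
            counts[mod] = (npass, total)
    subset = PTMTable(records=passed, provenance=f"{table.provenance} [reliable subset]")
    return subset, counts


def conservation_of_sites(
    aln: AlignmentMap,
    table: PTMTable,
    reference_row: str,
    comparison_row: str,
) -> tuple[dict[int, bool], int]:
    """Per-site conservation of modified positions in a distant homolog.

    A site is non-conserved iff the comparison row's residue at the aligned
    column differs from the reference residue; a gap in the comparison row
    counts as non-conserved. Returns (position → conserved flag, number
    non-conserved).
    """
    for row in (reference_row, comparison_row):
        if row not in aln.sequences:
            raise ValueError(f"row {row!r} not in alignment; rows: {sorted(aln.sequences)}")
    pos_to_col = aln.position_to_column(reference_row)
    comparison = aln.sequences[comparison_row]
    reference = aln.sequences[reference_row]
    flags: dict[int, bool] = {}
    for pos in table.positions():
        if pos not in pos_to_col:
            raise ValueError(f"position {pos} falls outside the reference row {reference_row!r}")
        col = pos_to_col[pos]
        flags[pos] = comparison[col] == reference[col] and comparison[col] not in ("-", ".")
    n_non_conserved = sum(1 for ok in flags.values() if not ok)
    return flags, n_non_conserved


def binding_site_overlap(
    table: PTMTable, site_lists: Mapping[str, Iterable[int]]
) -> dict[str, dict[int, set[str]]]:
    """Modified positions intersecting each named binding-site list, carrying
    the modification types observed at each overlapping position."""
    modified = set(table.positions())
    out: dict[str, dict[int, set[str]]] = {}
    for name, positions in site_lists.items():
        overlap = modified & set(positions)
        out[name] = {pos: table.mods_at(pos) for pos in sorted(overlap)}
    return out
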