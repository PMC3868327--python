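"""Readers and writers for every external artifact.

Coordinates are exchanged as PDB (via gemmi), alignments as FASTA or Clustal
(via Bio.AlignIO), PTM tables and variant lists as tab-separated text with a
declared header, binding-site lists as plain text, and reports as JSON.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
from Bio import AlignIO

from .datamodel import (
    MOD_TYPES,
    STANDARD_AA,
    SUPPORTED_ELEMENTS,
    AlignmentMap,
    Atom,
    PTMRecord,
    PTMTable,
    ResidueRecord,
    StructureModel,
    VariantSite,
)

__all__ = [
    "LoadReport",
    "read_structure",
    "write_annotated_structure",
    "read_ptm_table",
    "read_alignment",
    "read_variants",
    "read_site_lists",
    "parse_variant_label",
    "ANNOTATION_CATEGORIES",
    "read_annotation_codes",
]


@dataclass
class LoadReport:
    """What a reader skipped or flagged; attached so nothing is silent."""

    source: str = ""
    n_input: int = 0
    n_loaded: int = 0
    skipped: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "source": self.source,
            "n_input": self.n_input,
            "n_loaded": self.n_loaded,
            "skipped": list(self.skipped),
            "flagged": list(self.flagged),
        }


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def _one_letter(resname: str) -> str | None:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    return code if code in STANDARD_AA else None


def read_structure(path: str | Path, chain: str = "A") -> StructureModel:
    """Read one chain of a PDB file into a :class:`StructureModel`.

    Hydrogens, waters and HETATM records are skipped; alternate locations are
    resolved to the first conformer; non-standard residues are skipped with a
    warning and recorded in ``model.load_report``. Insertion codes are a hard
    error: homology models never carry them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = st[0]
    available = [ch.name for ch in model]
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise ValueError(f"{path}: chain {chain!r} not found; available chains: {available}")

    report = LoadReport(source=str(path))
    residues: list[ResidueRecord] = []
    for res in target:
        report.n_input += 1
        if res.het_flag == "H" or res.is_water():
            report.skipped.append(f"HETATM residue {res.name} {res.seqid.num}")
            continue
        if res.seqid.icode not in (" ", "", "\x00"):
            raise ValueError(
                f"{path}: residue {res.name} {res.seqid.num}{res.seqid.icode} carries an "
                "insertion code; models are expected to be insertion-code free"
            )
        aa = _one_letter(res.name)
        if aa is None:
            msg = f"non-standard residue {res.name} at {res.seqid.num}: skipped"
            warnings.warn(msg)
            report.skipped.append(msg)
            continue
        atoms: list[Atom] = []
        seen_names: set[str] = set()
        for atom in res:
            if atom.is_hydrogen():
                continue
            if atom.name in seen_names:  # later altloc conformers
                continue
            el = atom.element.name
            if el not in SUPPORTED_ELEMENTS:
                report.skipped.append(f"atom {atom.name} ({el}) in residue {res.seqid.num}: skipped")
                continue
            seen_names.add(atom.name)
            atoms.append(Atom(atom.name, el, atom.pos.x, atom.pos.y, atom.pos.z))
        if not atoms:
            report.skipped.append(f"residue {res.name} {res.seqid.num} has no usable heavy atoms")
            continue
        residues.append(ResidueRecord(res.seqid.num, aa, atoms))
        report.n_loaded += 1

    if not residues:
        raise ValueError(f"{path}: chain {chain!r} has no standard ATOM residues")
    out = StructureModel(residues=residues, chain_id=chain)
    out.load_report = report  # type: ignore[attr-defined]
    return out


#: Annotation categories in the order of their numeric B-factor codes,
#: with the display color each receives in the companion PyMOL script.
ANNOTATION_CATEGORIES: dict[str, tuple[int, str]] = {
    "none": (0, "gray80"),
    "variant": (1, "green"),
    "phosphorylation": (2, "orange"),
    "lysine_chemistry": (3, "blue"),  # acetylation / methylation / ubiquitination
    "ethanolamination": (4, "yellow"),
    "cysteine_chemistry": (5, "red"),  # S-nitrosylation / S-glutathionylation
    "O-glucosylation": (6, "pink"),
    "binding_site": (7, "brown"),
    "altered": (8, "black"),
}

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "E": "GLU",
    "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def write_annotated_structure(
    model: StructureModel,
    annotations: Mapping[int, str],
    path: str | Path,
    script_path: str | Path | None = None,
) -> None:
    """Write the model as PDB with a numeric category code in the B-factor
    column, plus a PyMOL command script coloring each category.

    ``annotations`` maps residue position → category name from
    :data:`ANNOTATION_CATEGORIES`. Unannotated residues carry code 0.
    """
    for pos, cat in annotations.items():
        if not model.has_position(pos):
            raise ValueError(f"annotation at unmodelled position {pos}")
        if cat not in ANNOTATION_CATEGORIES:
            raise ValueError(
                f"unknown annotation category {cat!r}; known: {sorted(ANNOTATION_CATEGORIES)}"
            )

    st = gemmi.Structure()
    st.name = "ptmsurf-annotated"
    gm = gemmi.Model("1")
    ch = gemmi.Chain(model.chain_id)
    for res in model.residues:
        code = float(ANNOTATION_CATEGORIES[annotations.get(res.position, "none")][0])
        gr = gemmi.Residue()
        gr.name = _AA3[res.aa]
        gr.seqid = gemmi.SeqId(res.position, " ")
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(atom.x, atom.y, atom.z)
            ga.occ = 1.0
            ga.b_iso = code
            gr.add_atom(ga)
        ch.add_residue(gr)
    gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))

    if script_path is None:
        script_path = Path(path).with_suffix(".pml")
    lines = [f"load {Path(path).name}", "hide everything", "show surface", "color gray80"]
    for cat, (code, color) in ANNOTATION_CATEGORIES.items():
        if cat == "none":
            continue
        lines.append(f"color {color}, b > {code - 0.5} and b < {code + 0.5}")
    Path(script_path).write_text("\n".join(lines) + "\n")


def read_annotation_codes(path: str | Path, chain: str = "A") -> dict[int, int]:
    """Parse back per-residue category codes from an annotated PDB B-factor column."""
    st = gemmi.read_structure(str(path))
    codes: dict[int, int] = {}
    for ch in st[0]:
        if ch.name != chain:
            continue
        for res in ch:
            if len(res) > 0:
                codes[res.seqid.num] = int(round(res[0].b_iso))
    return codes


# ---------------------------------------------------------------------------
# PTM tables
# ---------------------------------------------------------------------------

_PTM_COLUMNS = ("isoform", "position", "residue", "modification", "citations", "site_specific", "species")
_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n", ""}


def read_ptm_table(path: str | Path, provenance: str | None = None) -> PTMTable:
    """Read a curated PTM table from tab-separated text.

    Expected header columns: isoform, position, residue, modification,
    citations, site_specific, species. ``#`` lines are comments. Rows whose
    (residue, modification) pair fails the chemical-compatibility rules are
    flagged and kept in ``table.flagged`` — counted, reported, never silently
    dropped. Unknown modification names and non-integer citation counts are
    hard errors naming the offending line.
    """
    from .annotation import modification_compatibility

    path = Path(path)
    records: list[PTMRecord] = []
    flagged: list[PTMRecord] = []
    report = LoadReport(source=str(path))

    with open(path, newline="", encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if header is None:
                header = [f.lower() for f in fields]
                missing = [c for c in _PTM_COLUMNS if c not in header]
                if missing:
                    raise ValueError(f"{path}:{lineno}: header missing columns {missing}")
                idx = {c: header.index(c) for c in _PTM_COLUMNS}
                continue
            if len(fields) < len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            report.n_input += 1
            mod = fields[idx["modification"]]
            if mod not in MOD_TYPES:
                raise ValueError(
                    f"{path}:{lineno}: unknown modification {mod!r}; "
                    f"controlled vocabulary: {', '.join(MOD_TYPES)}"
                )
            try:
                citations = int(fields[idx["citations"]])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: citations must be an integer, got {fields[idx['citations']]!r}"
                ) from None
            ss_raw = fields[idx["site_specific"]].lower()
            if ss_raw in _TRUE:
                site_specific = True
            elif ss_raw in _FALSE:
                site_specific = False
            else:
                raise ValueError(f"{path}:{lineno}: site_specific must be boolean, got {ss_raw!r}")
            species = tuple(
                s.strip() for s in fields[idx["species"]].replace(";", ",").split(",") if s.strip()
            )
            rec = PTMRecord(
                isoform=fields[idx["isoform"]],
                position=int(fields[idx["position"]]),
                aa=fields[idx["residue"]].upper(),
                mod_type=mod,
                n_citations=citations,
                site_specific=site_specific,
                species=species,
            )
            if modification_compatibility(rec.aa, rec.mod_type):
                records.append(rec)
                report.n_loaded += 1
            else:
                flagged.append(rec)
                report.flagged.append(
                    f"line {lineno}: {rec.aa}{rec.position} incompatible with {rec.mod_type}"
                )

    table = PTMTable(records=records, provenance=provenance or str(path), flagged=flagged)
    table.load_report = report  # type: ignore[attr-defined]
    return table


def write_ptm_table(table: PTMTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_PTM_COLUMNS) + "\n")
        for rec in list(table.records) + list(table.flagged):
            fh.write(
                "\t".join(
                    [
                        rec.isoform,
                        str(rec.position),
                        rec.aa,
                        rec.mod_type,
                        str(rec.n_citations),
                        "true" if rec.site_specific else "false",
                        ",".join(rec.species),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

#: Conservative-substitution groups (the Clustal "strong" groups).
CONSERVATIVE_GROUPS = (
    frozenset("STA"),
    frozenset("NEQK"),
    frozenset("NHQK"),
    frozenset("NDEQ"),
    frozenset("QHRK"),
    frozenset("MILV"),
    frozenset("MILF"),
    frozenset("HY"),
    frozenset("FYW"),
)


def _column_state(column: Sequence[str]) -> str:
    chars = set(column)
    if "-" in chars or "." in chars:
        return "variable"
    if len(chars) == 1:
        return "strict"
    if any(chars <= group for group in CONSERVATIVE_GROUPS):
        return "conservative"
    return "variable"


def read_alignment(path: str | Path) -> AlignmentMap:
    """Read a FASTA or Clustal multiple sequence alignment.

    All rows must be equal length (a ragged alignment is an error naming the
    offending sequence); per-sequence column↔position maps and per-column
    conservation states (strict / conservative / variable) are computed.
    """
    path = Path(path)
    text = path.read_text()
    fmt = "fasta" if text.lstrip().startswith(">") else "clustal"
    if fmt == "fasta":
        # check raggedness ourselves so the error can name the sequence
        from Bio import SeqIO

        seqs = list(SeqIO.parse(str(path), "fasta"))
        if len(seqs) < 2:
            raise ValueError(f"{path}: alignment needs at least 2 sequences")
        length = len(seqs[0].seq)
        for rec in seqs:
            if len(rec.seq) != length:
                raise ValueError(
                    f"{path}: sequence {rec.id!r} has length {len(rec.seq)}, expected {length}"
                )
        rows = {rec.id: str(rec.seq).upper() for rec in seqs}
    else:
        aln = AlignIO.read(str(path), "clustal")
        if len(aln) < 2:
            raise ValueError(f"{path}: alignment needs at least 2 sequences")
        rows = {rec.id: str(rec.seq).upper() for rec in aln}

    column_to_position: dict[str, dict[int, int]] = {}
    for name, row in rows.items():
        mapping: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(row):
            if ch not in ("-", "."):
                pos += 1
                mapping[col] = pos
        column_to_position[name] = mapping

    n_cols = len(next(iter(rows.values())))
    conservation = [_column_state([row[c] for row in rows.values()]) for c in range(n_cols)]
    return AlignmentMap(sequences=rows, column_to_position=column_to_position, conservation=conservation)


def write_alignment(aln: AlignmentMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, row in aln.sequences.items():
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# Variant and binding-site lists
# ---------------------------------------------------------------------------

def parse_variant_label(label: str) -> tuple[str, int, str]:
    """Split ``"T176A"`` into ``("T", 176, "A")``."""
    if len(label) < 3 or label[0] not in STANDARD_AA or label[-1] not in STANDARD_AA:
        raise ValueError(f"malformed variant label {label!r}")
    try:
        pos = int(label[1:-1])
    except ValueError:
        raise ValueError(f"malformed variant label {label!r}") from None
    return label[0], pos, label[-1]


def read_variants(path: str | Path) -> list[VariantSite]:
    """Read a variant table: TSV with columns position, aa_A1, aa_A2 and
    optional cluster (1/2/none) and exposed (boolean)."""
    variants: list[VariantSite] = []
    with open(path, newline="", encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if header is None:
                header = [f.lower() for f in fields]
                for col in ("position", "aa_a1", "aa_a2"):
                    if col not in header:
                        raise ValueError(f"{path}:{lineno}: header missing column {col!r}")
                continue
            row = dict(zip(header, fields))
            cluster_raw = row.get("cluster", "none").lower()
            cluster = None if cluster_raw in ("", "none", "na") else int(cluster_raw)
            exposed = row.get("exposed", "true").lower() in _TRUE
            variants.append(
                VariantSite(
                    position=int(row["position"]),
                    aa_A1=row["aa_a1"].upper(),
                    aa_A2=row["aa_a2"].upper(),
                    cluster=cluster,
                    exposed=exposed,
                )
            )
    return variants


def write_variants(variants: Iterable[VariantSite], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("position\taa_a1\taa_a2\tcluster\texposed\n")
        for v in variants:
            fh.write(
                f"{v.position}\t{v.aa_A1}\t{v.aa_A2}\t"
                f"{v.cluster if v.cluster is not None else 'none'}\t"
                f"{'true' if v.exposed else 'false'}\n"
            )


def read_site_lists(path: str | Path) -> dict[str, set[int]]:
    """Read named binding-site residue lists from plain text.

    Each non-comment line is ``name pos pos ...`` (whitespace- or
    comma-separated positions; an optional ``:`` after the name is accepted).
    """
    lists: dict[str, set[int]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.replace(":", " ").replace(",", " ").split()
        if len(tokens) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'name positions...'")
        name, positions = tokens[0], tokens[1:]
        try:
            lists[name] = {int(p) for p in positions}
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer position in list {name!r}") from None
    return lists


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
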