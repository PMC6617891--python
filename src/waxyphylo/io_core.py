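"""Readers and writers shared by every pipeline stage.

Three plain-text formats are exchanged between stages: FASTA for
nucleotide amplicons, Newick for trees (bootstrap supports carried as
internal-node labels), and a delimited table (comma or tab, auto
detected) for per-individual sample metadata — one row per individual
with taxon name, section/subsection and ploidy, mirroring the voucher
tables that accompany herbarium-based amplicon studies.

All coordinates exchanged between modules are 0-based, half-open.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SampleRecord",
    "SequenceRecord",
    "PLOIDY_UNKNOWN",
    "FastaParseError",
    "AlignmentLengthError",
    "MetadataError",
    "NewickError",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "tree_from_newick_string",
    "tree_to_newick_string",
]

#: Sentinel for a ploidy level that the metadata does not state.
PLOIDY_UNKNOWN = 0

_METADATA_COLUMNS = ("individual_id", "taxon_name", "section", "subsection", "ploidy", "accessions")

_IUPAC_NT = set("ACGTRYSWKMBDHVN")


class FastaParseError(ValueError):
    """Raised for malformed or empty FASTA input."""


class AlignmentLengthError(ValueError):
    """Raised when sequences read with ``aligned=True`` differ in length."""


class MetadataError(ValueError):
    """Raised for schema or uniqueness violations in the sample table."""


class NewickError(ValueError):
    """Raised for unparseable or invalid Newick input."""


@dataclass(frozen=True)
class SampleRecord:
    """One sampled individual: taxonomy, ploidy and sequence accessions.

    ``ploidy`` is a positive integer when known and :data:`PLOIDY_UNKNOWN`
    (0) otherwise.
    """

    individual_id: str
    taxon_name: str
    section: str
    subsection: str = ""
    ploidy: int = PLOIDY_UNKNOWN
    accessions: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ploidy_known(self) -> bool:
        return self.ploidy != PLOIDY_UNKNOWN


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence keyed to the individual it came from."""

    seq_id: str
    individual_id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty residues for sequence {self.seq_id!r}")

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "").replace("?", "")


def _normalize_residues(raw: str, seq_id: str, aligned: bool) -> str:
    residues = raw.upper().replace("U", "T")
    allowed = _IUPAC_NT | ({"-", "?"} if aligned else set())
    bad = set(residues) - allowed
    if bad:
        raise FastaParseError(
            f"sequence {seq_id!r} contains non-IUPAC characters: {sorted(bad)!r}"
        )
    return residues


def _split_fasta_id(header_id: str, description: str) -> tuple[str, str]:
    # Convention: "seqid" or "seqid|individual". An explicit individual id
    # wins; otherwise the individual defaults to the sequence id with a
    # trailing copy suffix (".1", "_copyA" style) stripped.
    if "|" in header_id:
        seq_id, individual = header_id.split("|", 1)
        return seq_id, individual
    individual = re.sub(r"[._][A-Za-z0-9]+$", "", header_id) or header_id
    return header_id, individual


def read_fasta(path: str | Path, aligned: bool = False) -> list[SequenceRecord]:
    """Read nucleotide FASTA into :class:`SequenceRecord` objects.

    Residues are upper-cased and RNA ``U`` is mapped to ``T``.  With
    ``aligned=True`` the records must be rectangular ('-' and '?' are
    then permitted and preserved).
    """
    path = Path(path)
    with open(path) as handle:
        head = handle.read(1)
        if not head:
            raise FastaParseError(f"{path}: empty file")
        if head != ">":
            raise FastaParseError(f"{path}: not FASTA (first byte {head!r})")
    records: list[SequenceRecord] = []
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        if not bio_rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        seq_id, individual = _split_fasta_id(bio_rec.id, bio_rec.description)
        residues = _normalize_residues(str(bio_rec.seq), seq_id, aligned)
        if not residues:
            raise FastaParseError(f"{path}: record {seq_id!r} has no residues")
        desc = bio_rec.description[len(bio_rec.id):].strip()
        records.append(SequenceRecord(seq_id, individual, residues, desc))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    if aligned:
        lengths = {len(r.residues) for r in records}
        if len(lengths) > 1:
            raise AlignmentLengthError(
                f"{path}: aligned input with unequal lengths {sorted(lengths)}"
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, headers encoded ``seq_id|individual_id``."""
    bio_records = [
        _BioSeqRecord(
            Seq(r.residues),
            id=f"{r.seq_id}|{r.individual_id}",
            description=r.description,
        )
        for r in records
    ]
    SeqIO.write(bio_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# sample metadata table
# ---------------------------------------------------------------------------

def _parse_ploidy(raw: str) -> int:
    raw = raw.strip()
    if raw in {"", "NA", "N/A", "na", "?", "unknown"}:
        return PLOIDY_UNKNOWN
    try:
        value = int(raw)
    except ValueError as exc:
        raise MetadataError(f"unparseable ploidy {raw!r}") from exc
    if value < 2:
        raise MetadataError(f"ploidy must be >= 2, got {value}")
    return value


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the per-individual sample table (comma or tab delimited)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise MetadataError(f"{path}: empty metadata file")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    header = [h.strip() for h in (reader.fieldnames or [])]
    missing = [c for c in _METADATA_COLUMNS[:5] if c not in header]
    if missing:
        raise MetadataError(f"{path}: missing required column(s) {missing}")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for row in reader:
        row = {(k or "").strip(): (v or "").strip() for k, v in row.items()}
        ind = row["individual_id"]
        if not ind:
            raise MetadataError(f"{path}: row with empty individual_id")
        if ind in seen:
            raise MetadataError(f"{path}: duplicate individual_id {ind!r}")
        seen.add(ind)
        accessions = tuple(
            a for a in re.split(r"[;|]", row.get("accessions", "")) if a
        )
        records.append(
            SampleRecord(
                individual_id=ind,
                taxon_name=row["taxon_name"],
                section=row["section"],
                subsection=row.get("subsection", ""),
                ploidy=_parse_ploidy(row["ploidy"]),
                accessions=accessions,
            )
        )
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_METADATA_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.individual_id,
                    r.taxon_name,
                    r.section,
                    r.subsection,
                    r.ploidy if r.ploidy_known else "NA",
                    ";".join(r.accessions),
                ]
            )


def check_links(
    sequences: Sequence[SequenceRecord], samples: Sequence[SampleRecord]
) -> None:
    """Every sequence must resolve to exactly one metadata row."""
    known = {s.individual_id for s in samples}
    orphans = sorted({r.individual_id for r in sequences} - known)
    if orphans:
        raise MetadataError(f"sequences reference unknown individual(s): {orphans}")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------
#
# Trees are dendropy.Tree objects throughout the package.  Bootstrap
# supports are internal-node labels in [0, 100]; after parsing they live
# on ``node.label`` as strings and are read numerically by the phylogeny
# helpers.


def tree_from_newick_string(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"unparseable Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate leaf label(s): {dupes}")
    for node in tree.preorder_internal_node_iter():
        if node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                continue
            if not 0.0 <= support <= 100.0:
                raise NewickError(f"support {support} outside [0, 100]")
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read one Newick tree; supports parsed from internal-node labels."""
    return tree_from_newick_string(Path(path).read_text())


def tree_to_newick_string(tree: dendropy.Tree) -> str:
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        + "\n"
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick_string(tree))
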