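"""Alignment statistics, uncorrected-P distances and the orthology screen.

Gaps ('-', '?') and IUPAC ambiguity codes are treated as missing data
throughout: they never make a site variable and are excluded from the
compared sites of a p-distance.  This mirrors the gaps-as-missing
convention of the standard alignment viewers used for such amplicon
datasets.

The orthology screen is an amino-acid identity filter: query and
reference exons are translated, globally aligned, and the query passes
when identity over aligned non-gap columns reaches ``identity_min``
(default 90%) across at least ``min_aligned_aa`` residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .gene_structure import GeneModel, ReferenceModel, translate_exons
from .io_core import SequenceRecord

__all__ = [
    "Alignment",
    "SeqStats",
    "DistanceMatrix",
    "OrthologyConfig",
    "ScreenResult",
    "UndefinedDistanceError",
    "SITE_CONSTANT",
    "SITE_VARIABLE",
    "SITE_INFORMATIVE",
    "SITE_ALL_MISSING",
    "site_classification",
    "summary_stats",
    "p_distance",
    "distance_matrix",
    "orthology_screen",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

SITE_CONSTANT = "constant"
SITE_VARIABLE = "variable"
SITE_INFORMATIVE = "parsimony_informative"  # informative sites are also variable
SITE_ALL_MISSING = "all_missing"


class UndefinedDistanceError(ValueError):
    """Raised when two rows share no comparable (non-missing) sites."""


@dataclass(frozen=True)
class Alignment:
    """Rectangular ids × columns nucleotide alignment."""

    ids: tuple[str, ...]
    matrix: np.ndarray  # dtype 'S1', shape (n_sequences, n_columns)

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("alignment ids must be unique")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match ids")

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord]) -> "Alignment":
        lengths = {len(r.residues) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"unequal aligned lengths {sorted(lengths)}")
        matrix = np.array(
            [np.frombuffer(r.residues.encode(), dtype="S1") for r in records]
        )
        return cls(tuple(r.seq_id for r in records), matrix)

    @classmethod
    def from_strings(cls, rows: dict[str, str]) -> "Alignment":
        return cls.from_records(
            [SequenceRecord(k, k, v) for k, v in rows.items()]
        )

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, seq_id: str) -> np.ndarray:
        return self.matrix[self.ids.index(seq_id)]

    def ungapped_lengths(self) -> dict[str, int]:
        # ungapped length counts every residue character (incl. ambiguity)
        residue = ~np.isin(self.matrix, np.frombuffer(b"-?", dtype="S1"))
        return {sid: int(n) for sid, n in zip(self.ids, residue.sum(axis=1))}

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        idx = [self.ids.index(i) for i in wanted]
        return Alignment(tuple(wanted), self.matrix[idx])

    def columns(self, col_index: np.ndarray) -> "Alignment":
        return Alignment(self.ids, self.matrix[:, col_index])


def _unambiguous_mask(matrix: np.ndarray) -> np.ndarray:
    """True where the character is an unambiguous base (A/C/G/T)."""
    return np.isin(matrix, _BASES)


def site_classification(aln: Alignment) -> list[str]:
    """Classify every column as constant / variable / informative / missing.

    A column is variable iff ≥2 distinct unambiguous bases occur, and
    parsimony-informative iff ≥2 distinct bases each occur in ≥2
    sequences.  Informative columns are reported as
    :data:`SITE_INFORMATIVE` (a subclass of variable).
    """
    valid = _unambiguous_mask(aln.matrix)
    counts = np.stack(
        [((aln.matrix == b) & valid).sum(axis=0) for b in _BASES]
    )  # shape (4, n_columns)
    n_states = (counts > 0).sum(axis=0)
    n_rich = (counts >= 2).sum(axis=0)
    classes: list[str] = []
    for k, (states, rich) in enumerate(zip(n_states, n_rich)):
        if states == 0:
            classes.append(SITE_ALL_MISSING)
        elif states < 2:
            classes.append(SITE_CONSTANT)
        elif rich >= 2:
            classes.append(SITE_INFORMATIVE)
        else:
            classes.append(SITE_VARIABLE)
    return classes


@dataclass(frozen=True)
class SeqStats:
    """Per-region alignment summary (variable / informative site tallies)."""

    n_sequences: int
    aligned_length: int
    length_range: tuple[int, int]
    variable_sites: int
    parsimony_informative_sites: int

    def __post_init__(self) -> None:
        if not (
            self.parsimony_informative_sites <= self.variable_sites <= self.aligned_length
        ):
            raise ValueError("informative <= variable <= aligned_length violated")

    @property
    def variable_pct(self) -> float:
        return round(100.0 * self.variable_sites / self.aligned_length, 2)

    @property
    def informative_pct(self) -> float:
        return round(100.0 * self.parsimony_informative_sites / self.aligned_length, 2)

    def as_row(self) -> dict[str, object]:
        return {
            "n_sequences": self.n_sequences,
            "aligned_length": self.aligned_length,
            "length_min": self.length_range[0],
            "length_max": self.length_range[1],
            "variable_sites": self.variable_sites,
            "variable_pct": self.variable_pct,
            "informative_sites": self.parsimony_informative_sites,
            "informative_pct": self.informative_pct,
        }


def summary_stats(aln: Alignment) -> SeqStats:
    classes = site_classification(aln)
    variable = sum(c in (SITE_VARIABLE, SITE_INFORMATIVE) for c in classes)
    informative = sum(c == SITE_INFORMATIVE for c in classes)
    lengths = list(aln.ungapped_lengths().values())
    return SeqStats(
        n_sequences=aln.n_sequences,
        aligned_length=aln.n_columns,
        length_range=(min(lengths), max(lengths)),
        variable_sites=variable,
        parsimony_informative_sites=informative,
    )


# ---------------------------------------------------------------------------
# uncorrected-P distances
# ---------------------------------------------------------------------------

def p_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Uncorrected-P distance between two aligned rows (pairwise deletion).

    Compared sites are those unambiguous in *both* rows; gaps and
    ambiguity codes are missing data.
    """
    if a.shape != b.shape:
        raise ValueError("rows must have equal length")
    comparable = _unambiguous_mask(a) & _unambiguous_mask(b)
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites between rows")
    return float((a[comparable] != b[comparable]).sum()) / n


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    deletion: Literal["pairwise", "complete"] = "pairwise"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def distance_matrix(
    aln: Alignment, deletion: Literal["pairwise", "complete"] = "pairwise"
) -> DistanceMatrix:
    """All-pairs uncorrected-P distances.

    ``complete`` deletion drops every column with any missing character
    before computing distances; ``pairwise`` excludes missing sites per
    pair.
    """
    matrix = aln.matrix
    valid = _unambiguous_mask(matrix)
    if deletion == "complete":
        keep = valid.all(axis=0)
        matrix = matrix[:, keep]
        valid = valid[:, keep]
    n = aln.n_sequences
    # vectorised pair comparison: mismatches and comparable-site counts
    eq = matrix[:, None, :] == matrix[None, :, :]
    both = valid[:, None, :] & valid[None, :, :]
    comparable = both.sum(axis=2)
    if np.any((comparable == 0) & ~np.eye(n, dtype=bool)):
        i, j = np.argwhere((comparable == 0) & ~np.eye(n, dtype=bool))[0]
        raise UndefinedDistanceError(
            f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )
    mismatch = (~eq & both).sum(axis=2)
    with np.errstate(invalid="ignore"):
        values = np.where(comparable > 0, mismatch / np.maximum(comparable, 1), 0.0)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(aln.ids, values, deletion)


# ---------------------------------------------------------------------------
# amino-acid identity orthology screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologyConfig:
    identity_min: float = 0.90
    min_aligned_aa: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_min <= 1.0:
            raise ValueError("identity_min must be in (0, 1]")


@dataclass(frozen=True)
class ScreenResult:
    seq_id: str
    passed: bool
    identity: float
    aligned_aa: int
    skipped: bool = False
    note: str = ""


def _align_proteins(query: str, reference: str) -> tuple[float, int]:
    """Identity fraction and aligned non-gap column count for two proteins."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    alignment = aligner.align(reference, query)[0]
    indices = alignment.indices
    matches = 0
    aligned = 0
    for r, q in zip(indices[0], indices[1]):
        if r >= 0 and q >= 0:
            aligned += 1
            if reference[r] == query[q]:
                matches += 1
    return (matches / aligned if aligned else 0.0), aligned


def orthology_screen(
    query: SequenceRecord,
    model: GeneModel,
    ref: ReferenceModel,
    cfg: OrthologyConfig = OrthologyConfig(),
) -> ScreenResult:
    """Amino-acid identity filter against the reference exons."""
    query_protein = translate_exons(query, model)
    if not query_protein:
        return ScreenResult(
            query.seq_id, passed=False, identity=0.0, aligned_aa=0,
            skipped=True, note="untranslatable query",
        )
    ref_protein = translate_exons(ref.record, ref.model)
    identity, aligned = _align_proteins(query_protein, ref_protein)
    passed = identity >= cfg.identity_min and aligned >= cfg.min_aligned_aa
    return ScreenResult(query.seq_id, passed=passed, identity=identity, aligned_aa=aligned)
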