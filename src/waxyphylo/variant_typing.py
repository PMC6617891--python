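"""Structural-variant typing of annotated amplicons and genotyping.

Three gene forms are distinguished by intron architecture alone:

* **1a** — long fourth intron, fifth intron present (the ancestral-like
  structure);
* **1b** — fourth intron several hundred bp shorter than 1a;
* **1c** — the short fourth intron of 1b *plus* loss of the fifth intron.

The primary rule is an absolute intron-4 length threshold ``tau4``:
the observed 1a and 1b intron-4 length ranges are disjoint and ``tau4``
sits in the gap between them.  ``deficit_min`` (the minimum shortfall
against the reference intron-4 length) is retained as a corroborating
cross-check only.  A sequence with a long intron 4 but a lost intron 5
matches no described form and is left UNCLASSIFIED.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .gene_structure import (
    DEFAULT_MIN_INTRON_LEN,
    GeneModel,
    PseudogeneReport,
    ReferenceModel,
    intron_lengths,
)
from .io_core import SampleRecord
from .seqstats import Alignment

__all__ = [
    "VariantLabel",
    "TypingConfig",
    "TypingError",
    "GenotypeRecord",
    "IndelEvent",
    "classify_variant",
    "genotype_individual",
    "catalogue_indels",
    "cross_tabulate",
]

INTRON4 = 4
INTRON5 = 5


class VariantLabel(str, Enum):
    V1A = "1a"
    V1B = "1b"
    V1C = "1c"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TypingError(ValueError):
    """Raised when a model lacks the annotation the typing rule needs."""


@dataclass(frozen=True)
class TypingConfig:
    """Thresholds of the structural typing rule (all in bp)."""

    tau4: int = 300                # intron 4 below this is "short"
    deficit_min: int = 260         # corroborating shortfall vs reference
    intron5_lost_max: int = DEFAULT_MIN_INTRON_LEN

    def __post_init__(self) -> None:
        if min(self.tau4, self.deficit_min, self.intron5_lost_max) <= 0:
            raise ValueError("typing thresholds must be positive")


def classify_variant(
    model: GeneModel, ref: ReferenceModel, cfg: TypingConfig = TypingConfig()
) -> VariantLabel:
    """Type a sequence from its intron-4 length and intron-5 presence.

    Pure function of the intron lengths: exonic content never changes
    the label.
    """
    lengths = intron_lengths(model)
    if INTRON4 not in lengths:
        raise TypingError(f"{model.seq_id!r}: model has no intron {INTRON4}")
    if INTRON5 not in lengths:
        raise TypingError(f"{model.seq_id!r}: model has no intron {INTRON5}")
    short4 = lengths[INTRON4] < cfg.tau4
    lost5 = lengths[INTRON5] <= cfg.intron5_lost_max
    if short4 and lost5:
        return VariantLabel.V1C
    if short4:
        return VariantLabel.V1B
    if lost5:
        return VariantLabel.UNCLASSIFIED  # long intron 4 but intron 5 gone
    return VariantLabel.V1A


def intron4_deficit(model: GeneModel, ref: ReferenceModel) -> int:
    """Shortfall of the model's intron 4 against the reference's (bp)."""
    return ref.model.intron(INTRON4).length - intron_lengths(model)[INTRON4]


@dataclass(frozen=True)
class GenotypeRecord:
    """Multiset of variant labels carried by one individual."""

    individual_id: str
    per_sequence: tuple[tuple[str, VariantLabel, PseudogeneReport], ...]

    @property
    def labels(self) -> tuple[VariantLabel, ...]:
        return tuple(label for _, label, _ in self.per_sequence)

    @property
    def distinct_labels(self) -> frozenset[VariantLabel]:
        return frozenset(self.labels)

    @property
    def n_copies(self) -> int:
        return len(self.per_sequence)

    @property
    def combination(self) -> str:
        """Canonical string for the set of variants present, e.g. '1a+1b'."""
        order = [VariantLabel.V1A, VariantLabel.V1B, VariantLabel.V1C,
                 VariantLabel.UNCLASSIFIED]
        return "+".join(l.value for l in order if l in self.distinct_labels)

    @property
    def seq_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _, _ in self.per_sequence)


def genotype_individual(
    typed: list[tuple[str, VariantLabel, PseudogeneReport]], individual_id: str
) -> GenotypeRecord:
    if not typed:
        raise ValueError(f"no typed sequences for individual {individual_id!r}")
    return GenotypeRecord(individual_id, tuple(typed))


# ---------------------------------------------------------------------------
# alignment indel catalogue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndelEvent:
    """A maximal run of gap columns shared by one set of sequences."""

    start: int  # 0-based half-open column range
    end: int
    member_ids: frozenset[str]  # the gapped sequences
    polarity: str  # "insertion" | "deletion"

    @property
    def length(self) -> int:
        return self.end - self.start


def catalogue_indels(aln: Alignment) -> list[IndelEvent]:
    """Maximal same-member gap-column runs, with majority-based polarity.

    Adjacent gap runs whose gapped-member sets differ are reported as
    separate events.  Polarity is defined against the column-majority
    state: when the sequences *carrying residues* are the minority the
    event is an insertion, otherwise a deletion.
    """
    is_gap = aln.matrix == b"-"
    events: list[IndelEvent] = []
    current_members: frozenset[str] | None = None
    start = 0
    for col in range(aln.n_columns + 1):
        if col < aln.n_columns and is_gap[:, col].any() and not is_gap[:, col].all():
            members = frozenset(
                sid for sid, g in zip(aln.ids, is_gap[:, col]) if g
            )
        else:
            members = None
        if members != current_members:
            if current_members is not None:
                n_gapped = len(current_members)
                n_resident = aln.n_sequences - n_gapped
                polarity = "insertion" if n_resident < n_gapped else "deletion"
                events.append(IndelEvent(start, col, current_members, polarity))
            current_members = members
            start = col
    return events


# ---------------------------------------------------------------------------
# cross tabulation
# ---------------------------------------------------------------------------

def cross_tabulate(
    genotypes: list[GenotypeRecord], meta: list[SampleRecord]
) -> pd.DataFrame:
    """Individual counts by section × ploidy × variant combination.

    Returns a tidy frame with columns section, ploidy, combination,
    n_individuals; the counts partition the genotyped individuals.
    """
    by_id = {m.individual_id: m for m in meta}
    rows = []
    for g in genotypes:
        if g.individual_id not in by_id:
            raise KeyError(
                f"genotyped individual {g.individual_id!r} absent from metadata"
            )
        m = by_id[g.individual_id]
        rows.append(
            {
                "section": m.section,
                "ploidy": m.ploidy,
                "combination": g.combination,
                "individual_id": g.individual_id,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["section", "ploidy", "combination", "n_individuals"]
        )
    frame = pd.DataFrame(rows)
    table = (
        frame.groupby(["section", "ploidy", "combination"], as_index=False)
        .agg(n_individuals=("individual_id", "nunique"))
        .sort_values(["section", "ploidy", "combination"], ignore_index=True)
    )
    return table
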