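"""Sequence simulator with the structure the analysis assumes.

Two diploid gene pools (A and B) diverge from a common ancestral
amplicon; pool B's stem lineage carries a large structural deletion in
intron 4 (the short-intron gene form), and designated B sublineages
additionally lose intron 5 entirely (the intron-lost form).
Allotetraploids carry one copy drawn from a contemporary A lineage and
one from a B lineage; autotetraploids carry two copies duplicated from
a single lineage.  Substitutions follow JC69; introns accumulate
geometric-length indels; occasional 1–2 bp exonic indels create
frameshift pseudogenes.  A pair of outgroup sequences diverging before
the A/B split provides a non-degenerate rooting anchor.

The true multiple alignment is maintained throughout (every insertion
opens a column), so alignment-consuming stages can be tested without an
external aligner, and every emitted sequence carries ground truth:
source pool, variant lineage, pseudogene status, and the generating
tree.

Exons evolve more slowly than introns (``exon_rate_scale``) and never
fix nonsense substitutions: purifying selection on a conserved enzyme.
The splice-site GT/AG dinucleotides are likewise conserved.  Copies of
a polyploid branch off their source *lineage* at
``polyploid_split_depth`` — ascending past any more recent coalescences
of the sampled diploid — and the two copies of an autopolyploid
coalesce at the recent ``polyploid_age``, when they were a single
allele at genome doubling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .gene_structure import GeneModel, ReferenceModel, Segment
from .io_core import SampleRecord, SequenceRecord
from .seqstats import Alignment

__all__ = [
    "SimConfig",
    "SeqTruth",
    "IndividualTruth",
    "SimTruth",
    "SimResult",
    "make_reference",
    "simulate_dataset",
    "truth_report",
    "truth_from_report",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

#: Segment layout of the built-in reference amplicon: the tail of exon 3,
#: exons 4–7 with introns 3–7, and the head of exon 8.  Exonic total is a
#: multiple of 3 (frame offset 0).  Intron 4 is several-fold longer than
#: the others, as in the real gene region this emulates.
_REF_LAYOUT: tuple[tuple[str, int, int], ...] = (
    ("exon", 3, 7),
    ("intron", 3, 90),
    ("exon", 4, 150),
    ("intron", 4, 440),
    ("exon", 5, 120),
    ("intron", 5, 85),
    ("exon", 6, 110),
    ("intron", 6, 95),
    ("exon", 7, 131),
    ("intron", 7, 90),
    ("exon", 8, 7),
)

_REFERENCE_SEED = 20190710  # fixed: the reference is a constant of the model


class SimConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


def _sense_codons(rng: np.random.Generator, n: int) -> str:
    out: list[str] = []
    while len(out) < n:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def make_reference(seed: int = _REFERENCE_SEED) -> ReferenceModel:
    """Deterministically construct the annotated reference amplicon."""
    rng = np.random.default_rng(seed)
    exonic_total = sum(l for k, _, l in _REF_LAYOUT if k == "exon")
    exonic = _sense_codons(rng, exonic_total // 3)
    parts: list[str] = []
    segments: list[Segment] = []
    cursor = 0
    exon_cursor = 0
    for kind, index, length in _REF_LAYOUT:
        if kind == "exon":
            chunk = exonic[exon_cursor : exon_cursor + length]
            exon_cursor += length
        else:
            interior = "".join(rng.choice(_BASES, size=length - 4))
            chunk = "GT" + interior + "AG"
        parts.append(chunk)
        segments.append(Segment(kind, index, cursor, cursor + length))
        cursor += length
    record = SequenceRecord("REF", "REF", "".join(parts), "synthetic reference amplicon")
    model = GeneModel("REF", tuple(segments), frame_offset=0)
    return ReferenceModel(record, model)


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated dataset.

    Depths are expected substitutions/site.  ``stem_depth`` is the time
    of the A/B pool split, so the expected between-pool divergence is
    ``2 * stem_depth``.  ``intron_indel_rate`` is the expected number of
    indel events per intron along one root-to-tip lineage.
    """

    seed: int = 0
    n_diploids_A: int = 12
    n_diploids_B: int = 12
    n_allo: int = 10
    n_auto: int = 10
    stem_depth: float = 0.08
    crown_depth: float = 0.02
    outgroup_depth: float | None = None  # default 2 * stem_depth
    polyploid_split_depth: float = 0.015  # parental lineage vs sampled diploid
    polyploid_age: float = 0.002          # time of genome doubling
    sub_model: str = "JC69"
    exon_rate_scale: float = 0.10
    intron_indel_rate: float = 0.3
    indel_len_mean: float = 8.0
    intron4_deletion_bp: int = 280
    intron5_loss_in: tuple[int, ...] = ()  # indices of B diploids forming form 1c
    pseudogene_rate: float = 0.03
    ref_model: ReferenceModel | None = None

    def resolved_outgroup_depth(self) -> float:
        return 2.0 * self.stem_depth if self.outgroup_depth is None else self.outgroup_depth

    def validate(self, ref: ReferenceModel) -> None:
        if self.sub_model != "JC69":
            raise SimConfigError(f"unsupported substitution model {self.sub_model!r}")
        if min(self.stem_depth, self.crown_depth, self.intron_indel_rate,
               self.indel_len_mean, self.pseudogene_rate) < 0:
            raise SimConfigError("rates and depths must be non-negative")
        if self.crown_depth > self.stem_depth:
            raise SimConfigError("crown_depth cannot exceed stem_depth")
        if self.resolved_outgroup_depth() < self.stem_depth:
            raise SimConfigError("outgroup_depth cannot precede the pool split")
        intron4_len = ref.model.intron(4).length
        if self.intron4_deletion_bp >= intron4_len - 4:
            raise SimConfigError(
                f"intron-4 deletion of {self.intron4_deletion_bp} bp does not fit "
                f"inside the {intron4_len} bp ancestral intron"
            )
        if self.n_diploids_A < 1 or self.n_diploids_B < 1:
            raise SimConfigError("each pool needs at least one diploid")
        bad = [i for i in self.intron5_loss_in if not 0 <= i < self.n_diploids_B]
        if bad:
            raise SimConfigError(f"intron5_loss_in indices out of range: {bad}")
        if (self.n_allo or self.n_auto) and self.polyploid_split_depth > self.stem_depth:
            raise SimConfigError(
                "polyploid_split_depth must not exceed stem_depth"
            )


#: Named study conditions.  "easy" is the default condition set; "hard"
#: halves the pool separation and doubles the indel and pseudogene rates;
#: "null" switches all rates and depths off (every pool-A sequence is
#: then identical to the ancestor).
PRESETS: dict[str, "SimConfig"] = {}


@dataclass(frozen=True)
class SeqTruth:
    seq_id: str
    individual_id: str
    pool: str  # "A" | "B" | "OG"
    variant: str  # "1a" | "1b" | "1c" | "og"
    pseudogene: bool
    terminal_branch: float


@dataclass(frozen=True)
class IndividualTruth:
    individual_id: str
    ploidy: int
    origin_mode: str  # diploid | allopolyploid | autopolyploid | outgroup


@dataclass(frozen=True)
class SimTruth:
    sequences: tuple[SeqTruth, ...]
    individuals: tuple[IndividualTruth, ...]
    tree_newick: str

    def sequence(self, seq_id: str) -> SeqTruth:
        for s in self.sequences:
            if s.seq_id == seq_id:
                return s
        raise KeyError(seq_id)

    def individual(self, individual_id: str) -> IndividualTruth:
        for i in self.individuals:
            if i.individual_id == individual_id:
                return i
        raise KeyError(individual_id)


@dataclass(frozen=True)
class SimResult:
    sequences: tuple[SequenceRecord, ...]  # unaligned
    samples: tuple[SampleRecord, ...]
    truth_alignment: Alignment
    column_segments: tuple[tuple[str, int], ...]  # (kind, index) per column
    truth: SimTruth
    reference: ReferenceModel


PRESETS.update(
    easy=SimConfig(),
    hard=SimConfig(stem_depth=0.04, crown_depth=0.02, intron_indel_rate=0.6,
                   pseudogene_rate=0.06),
    null=SimConfig(stem_depth=0.0, crown_depth=0.0, outgroup_depth=0.0,
                   polyploid_split_depth=0.0, intron_indel_rate=0.0,
                   pseudogene_rate=0.0),
)


# ---------------------------------------------------------------------------
# genealogy construction
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("name", "depth", "children", "events")

    def __init__(self, name: str | None, depth: float):
        self.name = name
        self.depth = depth
        self.children: list[_Node] = []
        self.events: list[tuple] = []  # applied on the branch entering this node

    def add(self, child: "_Node") -> "_Node":
        self.children.append(child)
        return child

    def newick(self) -> str:
        def fmt(node: _Node, parent_depth: float) -> str:
            bl = parent_depth - node.depth
            if node.children:
                inner = ",".join(fmt(c, node.depth) for c in node.children)
                label = node.name or ""
                return f"({inner}){label}:{bl:.6f}"
            return f"{node.name}:{bl:.6f}"
        inner = ",".join(fmt(c, self.depth) for c in self.children)
        return f"({inner});"


def _build_pool(
    names: list[str], crown_depth: float, rng: np.random.Generator
) -> tuple[_Node, dict[str, _Node]]:
    """Random coalescent-style ultrametric subtree over the pool's tips.

    Merge times are spaced quadratically: recent coalescences are dense
    and the basal internides are long, as in real species-level clades
    whose deepest splits are old.  (Evenly spaced merges would leave the
    crown base star-like, with basal edges far shorter than the
    sampling noise on deep branches.)
    """
    leaves = {name: _Node(name, 0.0) for name in names}
    clusters: list[_Node] = list(leaves.values())
    k = len(clusters)
    if k == 1:
        return clusters[0], leaves
    for j in range(1, k):
        depth = crown_depth * (j / (k - 1)) ** 2
        i1, i2 = sorted(rng.choice(len(clusters), size=2, replace=False))
        parent = _Node(None, depth)
        parent.add(clusters[i1])
        parent.add(clusters[i2])
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i1, i2)]
        clusters.append(parent)
    return clusters[0], leaves


# ---------------------------------------------------------------------------
# sequence evolution over a tracked alignment
# ---------------------------------------------------------------------------

class _AlignmentRegistry:
    """Global column bookkeeping: a total order of column ids, each column
    labelled with the gene segment it belongs to."""

    def __init__(self, ref: ReferenceModel):
        seq = ref.record.residues
        self.order: list[int] = list(range(len(seq)))
        self.segment: dict[int, tuple[str, int]] = {}
        self.frame_offset = ref.model.frame_offset
        self.next_id = len(seq)
        for seg in ref.model.segments:
            for pos in range(seg.start, seg.end):
                self.segment[pos] = (seg.kind, seg.index)
        self.root_seq: dict[int, str] = {i: b for i, b in enumerate(seq)}

    def new_columns(self, after: int, count: int, segment: tuple[str, int]) -> list[int]:
        ids = list(range(self.next_id, self.next_id + count))
        self.next_id += count
        at = self.order.index(after) + 1
        self.order[at:at] = ids
        for cid in ids:
            self.segment[cid] = segment
        return ids


def _jc_substitute(
    seq: dict[int, str], cols: list[int], t: float, rng: np.random.Generator
) -> list[int]:
    """JC69 substitutions over branch length ``t`` on the given columns;
    returns the columns that changed."""
    if t <= 0 or not cols:
        return []
    p_change = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
    hits = np.nonzero(rng.random(len(cols)) < p_change)[0]
    changed: list[int] = []
    for idx in hits:
        cid = cols[idx]
        current = seq[cid]
        others = [b for b in "ACGT" if b != current]
        seq[cid] = others[rng.integers(0, 3)]
        changed.append(cid)
    return changed


def _repair_nonsense(
    seq: dict[int, str],
    parent_seq: dict[int, str],
    exon_cols: list[int],
    changed: Iterable[int],
    frame_offset: int,
) -> None:
    """Revert substitutions that created in-frame stop codons.

    Purifying selection: a functional gene copy does not fix nonsense
    mutations.  Exonic columns are frame-stable during branch evolution
    (exonic indels occur only as terminal pseudogenization events), so
    the reading frame is the reference frame throughout.
    """
    changed_set = set(changed)
    if not changed_set:
        return
    coding = exon_cols[frame_offset:]
    for i in range(0, len(coding) - 2, 3):
        codon_cols = coding[i : i + 3]
        if "".join(seq[c] for c in codon_cols) in _STOPS:
            for c in codon_cols:
                if c in changed_set:
                    seq[c] = parent_seq[c]


def _intron_columns(
    seq: dict[int, str], registry: _AlignmentRegistry, index: int
) -> list[int]:
    return [
        cid for cid in registry.order
        if cid in seq and registry.segment[cid] == ("intron", index)
    ]


def _apply_intron_deletion(
    seq: dict[int, str], registry: _AlignmentRegistry, index: int, length: int,
    rng: np.random.Generator, keep_splice: bool = True,
) -> None:
    cols = _intron_columns(seq, registry, index)
    margin = 2 if keep_splice else 0
    usable = cols[margin : len(cols) - margin]
    if length >= len(usable):
        for cid in usable:
            del seq[cid]
        return
    start = int(rng.integers(0, len(usable) - length + 1))
    for cid in usable[start : start + length]:
        del seq[cid]


def _apply_intron_loss(seq: dict[int, str], registry: _AlignmentRegistry, index: int) -> None:
    for cid in _intron_columns(seq, registry, index):
        del seq[cid]


def _apply_intron_insertion(
    seq: dict[int, str], registry: _AlignmentRegistry, index: int, length: int,
    rng: np.random.Generator,
) -> None:
    cols = _intron_columns(seq, registry, index)
    if len(cols) < 5:
        return
    anchor = cols[int(rng.integers(2, len(cols) - 2))]
    new_ids = registry.new_columns(anchor, length, ("intron", index))
    for cid in new_ids:
        seq[cid] = str(rng.choice(_BASES))


def _apply_exonic_indel(
    seq: dict[int, str], registry: _AlignmentRegistry, rng: np.random.Generator
) -> bool:
    """1–2 bp indel in a random complete exon; returns True when applied."""
    exon_indices = sorted(
        {idx for (kind, idx) in registry.segment.values() if kind == "exon"}
    )
    # interior exons only: the partial flanking exon stubs are too short
    candidates = [i for i in exon_indices[1:-1]]
    exon = candidates[int(rng.integers(0, len(candidates)))]
    cols = [
        cid for cid in registry.order
        if cid in seq and registry.segment[cid] == ("exon", exon)
    ]
    if len(cols) < 8:
        return False
    length = int(rng.integers(1, 3))
    if rng.random() < 0.5:
        start = int(rng.integers(2, len(cols) - 2 - length))
        for cid in cols[start : start + length]:
            del seq[cid]
    else:
        anchor = cols[int(rng.integers(2, len(cols) - 2))]
        for cid in registry.new_columns(anchor, length, ("exon", exon)):
            seq[cid] = str(rng.choice(_BASES))
    return True


@dataclass
class _Flags:
    pool: str
    del4: bool = False
    lost5: bool = False


def _evolve_branch(
    parent_seq: dict[int, str],
    branch: float,
    events: Iterable[tuple],
    cfg: SimConfig,
    registry: _AlignmentRegistry,
    rng: np.random.Generator,
    flags: _Flags,
) -> dict[int, str]:
    seq = dict(parent_seq)
    for event in events:
        if event[0] == "del_intron4":
            _apply_intron_deletion(seq, registry, 4, event[1], rng)
            flags.del4 = True
        elif event[0] == "lose_intron5":
            _apply_intron_loss(seq, registry, 5)
            flags.lost5 = True
    # introns evolve at the nominal neutral rate; exons slower (purifying
    # selection), with nonsense substitutions rejected.  The terminal
    # GT/AG dinucleotides of each intron are conserved (splice-site
    # selection), matching the 2 bp margins the indel machinery keeps.
    cols_by_seg: dict[tuple[str, int], list[int]] = {}
    for c in registry.order:
        if c in seq:
            cols_by_seg.setdefault(registry.segment[c], []).append(c)
    intron_cols = [
        c
        for (kind, _), cols in cols_by_seg.items()
        if kind == "intron"
        for c in cols[2:-2]
    ]
    exon_cols = [
        c for (kind, _), cols in cols_by_seg.items() if kind == "exon" for c in cols
    ]
    _jc_substitute(seq, intron_cols, branch, rng)
    changed = _jc_substitute(seq, exon_cols, branch * cfg.exon_rate_scale, rng)
    _repair_nonsense(seq, parent_seq, exon_cols, changed, registry.frame_offset)
    if cfg.intron_indel_rate > 0 and branch > 0:
        total_depth = cfg.resolved_outgroup_depth()
        mean_events = (
            cfg.intron_indel_rate * branch / total_depth if total_depth > 0 else 0.0
        )
        intron_indices = sorted(
            {idx for (kind, idx) in registry.segment.values() if kind == "intron"}
        )
        for index in intron_indices:
            if index == 5 and flags.lost5:
                continue
            for _ in range(int(rng.poisson(mean_events))):
                length = int(rng.geometric(1.0 / cfg.indel_len_mean))
                if rng.random() < 0.5:
                    _apply_intron_deletion(seq, registry, index, length, rng)
                else:
                    _apply_intron_insertion(seq, registry, index, length, rng)
    return seq


# ---------------------------------------------------------------------------
# top-level simulation
# ---------------------------------------------------------------------------

def _parent_map(root: _Node) -> dict[int, _Node]:
    parents: dict[int, _Node] = {}
    stack = [root]
    while stack:
        node = stack.pop()
        for child in node.children:
            parents[id(child)] = node
            stack.append(child)
    return parents


def _wrap_with_event_node(
    node: _Node, parents: dict[int, _Node], events: list[tuple]
) -> _Node:
    """Insert a zero-length node carrying ``events`` just above ``node``,
    so later lineage splices below it inherit the events."""
    parent = parents[id(node)]
    wrapper = _Node(None, parent.depth)
    wrapper.events = events
    parent.children[parent.children.index(node)] = wrapper
    wrapper.children.append(node)
    parents[id(wrapper)] = parent
    parents[id(node)] = wrapper
    return wrapper


def _splice_on_lineage(
    tip: _Node, depth: float, sub: _Node, parents: dict[int, _Node]
) -> None:
    """Attach ``sub`` to the lineage ancestral to ``tip`` at ``depth``.

    Ascends past coalescences more recent than ``depth``: the polyploid's
    parental lineage diverged from the sampled diploid's lineage then,
    regardless of how recently that diploid coalesced with its relatives.
    """
    node = tip
    while parents[id(node)].depth < depth:
        node = parents[id(node)]
    parent = parents[id(node)]
    attach = _Node(None, depth)
    parent.children[parent.children.index(node)] = attach
    attach.children.append(sub)
    attach.children.append(node)
    parents[id(attach)] = parent
    parents[id(node)] = attach
    parents[id(sub)] = attach


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Generate sequences, metadata, the truth alignment and ground truth."""
    ref = cfg.ref_model if cfg.ref_model is not None else make_reference()
    cfg.validate(ref)
    rng = np.random.default_rng(cfg.seed)

    a_names = [f"A{i+1:02d}" for i in range(cfg.n_diploids_A)]
    b_names = [f"B{i+1:02d}" for i in range(cfg.n_diploids_B)]
    og_depth = cfg.resolved_outgroup_depth()
    root = _Node("root", og_depth)
    split = _Node("split", cfg.stem_depth)
    # two outgroup tips (a non-degenerate rooting anchor): their stem
    # keeps the root edge off the pool-split node
    og_pair = _Node(None, (og_depth + cfg.stem_depth) / 2.0)
    og_pair.add(_Node("OG01", 0.0))
    og_pair.add(_Node("OG02", 0.0))
    root.add(og_pair)
    root.add(split)

    pool_a_root, a_leaves = _build_pool(a_names, cfg.crown_depth, rng)
    pool_b_root, b_leaves = _build_pool(b_names, cfg.crown_depth, rng)
    split.add(pool_a_root)
    split.add(pool_b_root)
    parents = _parent_map(root)
    # structural events live on zero-length wrapper nodes so that
    # polyploid lineages spliced below them inherit the structure
    _wrap_with_event_node(
        pool_b_root, parents, [("del_intron4", cfg.intron4_deletion_bp)]
    )
    for idx in cfg.intron5_loss_in:
        _wrap_with_event_node(b_leaves[b_names[idx]], parents, [("lose_intron5",)])

    individuals: list[IndividualTruth] = []
    copy_pool: dict[str, str] = {}  # seq_id -> pool
    copy_individual: dict[str, str] = {}

    def attach_depth() -> float:
        return float(rng.uniform(0.5, 0.95)) * cfg.polyploid_split_depth

    for i in range(cfg.n_allo):
        ind = f"T{i+1:02d}"
        src_a = a_leaves[a_names[int(rng.integers(0, len(a_names)))]]
        src_b = b_leaves[b_names[int(rng.integers(0, len(b_names)))]]
        for copy_no, (src, pool) in enumerate(((src_a, "A"), (src_b, "B")), 1):
            seq_id = f"{ind}_{copy_no}"
            _splice_on_lineage(src, attach_depth(), _Node(seq_id, 0.0), parents)
            copy_pool[seq_id] = pool
            copy_individual[seq_id] = ind
        individuals.append(IndividualTruth(ind, 4, "allopolyploid"))
    for i in range(cfg.n_auto):
        ind = f"U{i+1:02d}"
        pool = "A" if rng.random() < 0.5 else "B"
        names, leaves_of = (a_names, a_leaves) if pool == "A" else (b_names, b_leaves)
        src = leaves_of[names[int(rng.integers(0, len(names)))]]
        t0 = attach_depth()
        # both copies were a single allele at the (recent) genome doubling
        dup = _Node(None, min(cfg.polyploid_age, t0 / 2.0))
        for copy_no in (1, 2):
            seq_id = f"{ind}_{copy_no}"
            dup.add(_Node(seq_id, 0.0))
            copy_pool[seq_id] = pool
            copy_individual[seq_id] = ind
        _splice_on_lineage(src, t0, dup, parents)
        individuals.append(IndividualTruth(ind, 4, "autopolyploid"))

    # evolve down the tree
    registry = _AlignmentRegistry(ref)
    tip_seqs: dict[str, dict[int, str]] = {}
    tip_flags: dict[str, _Flags] = {}
    tip_branch: dict[str, float] = {}

    def walk(node: _Node, seq: dict[int, str], flags: _Flags) -> None:
        for child in node.children:
            branch = node.depth - child.depth
            child_flags = _Flags(flags.pool, flags.del4, flags.lost5)
            if child is split:
                child_flags.pool = "split"
            child_seq = _evolve_branch(
                seq, branch, child.events, cfg, registry, rng, child_flags
            )
            if not child.children:  # a tip
                name = child.name
                assert name is not None
                if name.startswith("OG"):
                    child_flags.pool = "OG"
                elif name in a_leaves or copy_pool.get(name) == "A":
                    child_flags.pool = "A"
                elif name in b_leaves or copy_pool.get(name) == "B":
                    child_flags.pool = "B"
                tip_seqs[name] = child_seq
                tip_flags[name] = child_flags
                tip_branch[name] = branch
            else:
                walk(child, child_seq, child_flags)

    walk(root, dict(registry.root_seq), _Flags("ancestral"))

    # pseudogenization: terminal 1–2 bp exonic indels
    pseudo: dict[str, bool] = {}
    for name in sorted(tip_seqs):
        flagged = False
        if cfg.pseudogene_rate > 0 and rng.random() < cfg.pseudogene_rate:
            flagged = _apply_exonic_indel(tip_seqs[name], registry, rng)
        pseudo[name] = flagged

    # assemble outputs
    emitted = sorted(tip_seqs)
    used_cols = [
        cid for cid in registry.order if any(cid in tip_seqs[n] for n in emitted)
    ]
    aligned_rows = {
        name: "".join(tip_seqs[name].get(cid, "-") for cid in used_cols)
        for name in emitted
    }
    column_segments = tuple(registry.segment[cid] for cid in used_cols)

    sequences: list[SequenceRecord] = []
    seq_truths: list[SeqTruth] = []
    samples: list[SampleRecord] = []
    for name in emitted:
        if name in copy_individual:
            individual = copy_individual[name]
        else:
            individual = name
            mode = "outgroup" if name.startswith("OG") else "diploid"
            section = {
                "A": "sectA", "B": "sectB", "OG": "outgroup"
            }[tip_flags[name].pool]
            samples.append(
                SampleRecord(individual, f"Taxon {individual}", section,
                             ploidy=2, accessions=(name,))
            )
            individuals.append(IndividualTruth(individual, 2, mode))
        flags = tip_flags[name]
        if flags.pool == "OG":
            variant = "og"
        elif not flags.del4:
            variant = "1a"  # ancestral-like structure (pool A)
        else:
            variant = "1c" if flags.lost5 else "1b"
        seq_id = name if name in copy_individual else f"{name}_1"
        sequences.append(
            SequenceRecord(seq_id, individual,
                           aligned_rows[name].replace("-", ""))
        )
        seq_truths.append(
            SeqTruth(seq_id, individual, flags.pool, variant,
                     pseudo[name], tip_branch[name])
        )
    for ind in individuals:
        if ind.origin_mode in ("allopolyploid", "autopolyploid"):
            samples.append(
                SampleRecord(ind.individual_id, f"Taxon {ind.individual_id}",
                             "sectPoly", ploidy=4,
                             accessions=tuple(
                                 s.seq_id for s in seq_truths
                                 if s.individual_id == ind.individual_id
                             ))
            )
    samples.sort(key=lambda s: s.individual_id)
    individuals.sort(key=lambda i: i.individual_id)

    truth_alignment = Alignment.from_records(
        [SequenceRecord(s.seq_id, s.individual_id, aligned_rows[n])
         for n, s in zip(emitted, seq_truths)]
    )
    truth = SimTruth(tuple(seq_truths), tuple(individuals), root.newick())
    return SimResult(
        sequences=tuple(sequences),
        samples=tuple(samples),
        truth_alignment=truth_alignment,
        column_segments=column_segments,
        truth=truth,
        reference=ref,
    )


def neutral_intron_columns(result: SimResult) -> np.ndarray:
    """Indices of truth-alignment columns that evolve neutrally.

    Intron columns minus the terminal two positions of each intron,
    which hold the conserved GT/AG splice dinucleotides and are exempt
    from substitution.  These are the sites on which the JC69 closed
    form holds exactly.
    """
    by_intron: dict[int, list[int]] = {}
    for col, (kind, index) in enumerate(result.column_segments):
        if kind == "intron":
            by_intron.setdefault(index, []).append(col)
    keep: list[int] = []
    for cols in by_intron.values():
        keep.extend(cols[2:-2])
    return np.array(sorted(keep), dtype=int)


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------

def truth_report(truth: SimTruth) -> pd.DataFrame:
    """One row per emitted sequence, joined with its individual's truth."""
    by_ind = {i.individual_id: i for i in truth.individuals}
    rows = [
        {
            "seq_id": s.seq_id,
            "individual_id": s.individual_id,
            "pool": s.pool,
            "variant": s.variant,
            "pseudogene": s.pseudogene,
            "terminal_branch": s.terminal_branch,
            "ploidy": by_ind[s.individual_id].ploidy,
            "origin_mode": by_ind[s.individual_id].origin_mode,
        }
        for s in truth.sequences
    ]
    columns = ["seq_id", "individual_id", "pool", "variant", "pseudogene",
               "terminal_branch", "ploidy", "origin_mode"]
    return pd.DataFrame(rows, columns=columns)


def truth_from_report(frame: pd.DataFrame, tree_newick: str = "") -> SimTruth:
    """Inverse of :func:`truth_report` (the tree is supplied separately)."""
    sequences = tuple(
        SeqTruth(
            row.seq_id, row.individual_id, row.pool, row.variant,
            bool(row.pseudogene), float(row.terminal_branch),
        )
        for row in frame.itertuples()
    )
    individuals: dict[str, IndividualTruth] = {}
    for row in frame.itertuples():
        individuals.setdefault(
            row.individual_id,
            IndividualTruth(row.individual_id, int(row.ploidy), row.origin_mode),
        )
    return SimTruth(
        sequences,
        tuple(sorted(individuals.values(), key=lambda i: i.individual_id)),
        tree_newick,
    )
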