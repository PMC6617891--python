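"""End-to-end orchestration: annotate → screen → type → stats → tree → infer.

The functional core :func:`run_analysis` takes in-memory objects (so the
simulator output can be analysed without touching disk); the
config-driven :func:`run_pipeline` wraps it with file I/O and report
writing.  Every input sequence appears exactly once in the typing table
with a status of ``typed``, ``screened_out`` or ``failed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .gene_structure import (
    GeneModel,
    ProjectionError,
    ReferenceModel,
    detect_pseudogene,
    intron_lengths,
    project_exon_boundaries,
)
from .io_core import (
    SampleRecord,
    SequenceRecord,
    check_links,
    read_fasta,
    read_metadata,
    read_newick,
    write_newick,
)
from .phylogeny import bootstrap_support, root_with_outgroup
from .polyploid_inference import (
    DEFAULT_SUPPORT_MIN,
    CladeExemplars,
    OriginCall,
    classify_origin,
)
from .seqstats import Alignment, OrthologyConfig, orthology_screen, summary_stats
from .variant_typing import (
    GenotypeRecord,
    TypingConfig,
    VariantLabel,
    classify_variant,
    cross_tabulate,
    genotype_individual,
)

__all__ = ["PipelineConfig", "RunReport", "run_analysis", "run_pipeline",
           "make_figures_tables", "derive_exemplars", "write_report"]

logger = logging.getLogger("waxyphylo")


@dataclass(frozen=True)
class PipelineConfig:
    sequences_path: str
    metadata_path: str
    reference_fasta: str
    reference_segments: str  # delimited table: kind, index, start, end
    out_dir: str
    tree_path: str | None = None
    aligned_input: bool = False
    typing: TypingConfig = field(default_factory=TypingConfig)
    orthology: OrthologyConfig = field(default_factory=OrthologyConfig)
    n_bootstrap: int = 1000
    seed: int = 1
    support_min: float = DEFAULT_SUPPORT_MIN
    deletion: Literal["pairwise", "complete"] = "complete"
    outgroup_ids: tuple[str, ...] = ()


@dataclass
class RunReport:
    typing_table: pd.DataFrame
    genotypes: list[GenotypeRecord]
    stats_table: pd.DataFrame
    tree: dendropy.Tree | None
    origin_calls: list[OriginCall]
    origin_table: pd.DataFrame
    cross_tab: pd.DataFrame
    provenance: dict


def load_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML (or JSON) file.

    Nested ``typing`` and ``orthology`` mappings populate the
    corresponding sub-configs; remaining keys map to PipelineConfig
    fields directly.
    """
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    typing = TypingConfig(**data.pop("typing", {}))
    orthology = OrthologyConfig(**data.pop("orthology", {}))
    outgroup_ids = tuple(data.pop("outgroup_ids", ()))
    return PipelineConfig(
        typing=typing, orthology=orthology, outgroup_ids=outgroup_ids, **data
    )


def load_reference(fasta_path: str, segments_path: str) -> ReferenceModel:
    """Reference = FASTA record + a small segment table (kind, index,
    start, end; 0-based half-open), GFF-like but flat."""
    from .gene_structure import Segment

    records = read_fasta(fasta_path)
    if len(records) != 1:
        raise ValueError("reference FASTA must contain exactly one record")
    table = pd.read_csv(segments_path, sep=None, engine="python")
    segments = tuple(
        Segment(str(r.kind), int(r.index), int(r.start), int(r.end))
        for r in table.itertuples()
    )
    frame_offset = 0
    if "frame_offset" in table.columns:
        frame_offset = int(table["frame_offset"].iloc[0])
    model = GeneModel(records[0].seq_id, segments, frame_offset)
    return ReferenceModel(records[0], model)


def derive_exemplars(
    typing_table: pd.DataFrame, samples: Sequence[SampleRecord]
) -> CladeExemplars:
    """Auto-derive the two major clades' exemplars from diploid carriers:
    diploid sequences typed 1a anchor clade I, diploid 1b/1c anchor
    clade II."""
    ploidy = {s.individual_id: s.ploidy for s in samples}
    section = {s.individual_id: s.section for s in samples}
    typed = typing_table[typing_table.status == "typed"]
    clade_i: set[str] = set()
    clade_ii: set[str] = set()
    for row in typed.itertuples():
        if ploidy.get(row.individual_id) != 2:
            continue
        if section.get(row.individual_id) == "outgroup":
            continue
        if row.variant == VariantLabel.V1A.value:
            clade_i.add(row.seq_id)
        elif row.variant in (VariantLabel.V1B.value, VariantLabel.V1C.value):
            clade_ii.add(row.seq_id)
    clades = {}
    if clade_i:
        clades["I"] = frozenset(clade_i)
    if clade_ii:
        clades["II"] = frozenset(clade_ii)
    if not clades:
        raise ValueError("no diploid exemplars found to anchor major clades")
    return CladeExemplars(clades)


def _annotate_and_type(
    sequences: Sequence[SequenceRecord],
    ref: ReferenceModel,
    typing: TypingConfig,
    orthology: OrthologyConfig,
) -> tuple[pd.DataFrame, dict[str, GeneModel]]:
    rows = []
    models: dict[str, GeneModel] = {}
    for rec in sequences:
        row: dict[str, object] = {
            "seq_id": rec.seq_id,
            "individual_id": rec.individual_id,
            "status": "failed",
            "variant": "",
            "intron4_len": np.nan,
            "intron5_len": np.nan,
            "frameshift": False,
            "internal_stop": False,
            "identity": np.nan,
            "note": "",
        }
        try:
            model = project_exon_boundaries(rec, ref)
            report = detect_pseudogene(rec, model, ref)
            if report.frameshift or report.undetermined:
                # amino-acid identity is meaningless after a frameshift;
                # pseudogenes keep their structural type
                row["note"] = "pseudogene suspect; orthology screen skipped"
                logger.warning("orthology screen skipped for %s (frameshift)",
                               rec.seq_id)
            else:
                screen = orthology_screen(rec, model, ref, orthology)
                row["identity"] = round(screen.identity, 4)
                if not screen.passed and not screen.skipped:
                    row["status"] = "screened_out"
                    row["note"] = f"aa identity {screen.identity:.2%} below threshold"
                    rows.append(row)
                    continue
            label = classify_variant(model, ref, typing)
            lengths = intron_lengths(model)
            models[rec.seq_id] = model
            row.update(
                status="typed",
                variant=label.value,
                intron4_len=lengths.get(4, np.nan),
                intron5_len=lengths.get(5, np.nan),
                frameshift=report.frameshift,
                internal_stop=report.internal_stop,
            )
            row["_label"] = label
            row["_report"] = report
        except (ProjectionError, ValueError) as exc:
            row["note"] = str(exc)
            logger.warning("annotation failed for %s: %s", rec.seq_id, exc)
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame, models


def _group_alignment(aln: Alignment, ids: Sequence[str]) -> Alignment:
    """Subset rows and drop the columns that are then all-gap."""
    sub = aln.subset(ids)
    keep = ~(np.isin(sub.matrix, np.frombuffer(b"-?", dtype="S1")).all(axis=0))
    return sub.columns(np.nonzero(keep)[0])


def _stats_by_variant(aln: Alignment | None, typing_table: pd.DataFrame) -> pd.DataFrame:
    columns = ["region", "n_sequences", "aligned_length", "length_min",
               "length_max", "variable_sites", "variable_pct",
               "informative_sites", "informative_pct"]
    if aln is None:
        return pd.DataFrame(columns=columns)
    typed = typing_table[typing_table.status == "typed"]
    rows = []
    in_aln = [sid for sid in typed.seq_id if sid in aln.ids]
    if len(in_aln) >= 2:
        rows.append({"region": "all", **summary_stats(_group_alignment(aln, in_aln)).as_row()})
    for variant in sorted(typed.variant.unique()):
        ids = [
            r.seq_id for r in typed.itertuples()
            if r.variant == variant and r.seq_id in aln.ids
        ]
        if len(ids) >= 2:
            stats = summary_stats(_group_alignment(aln, ids))
            rows.append({"region": variant, **stats.as_row()})
    return pd.DataFrame(rows, columns=columns)


def run_analysis(
    sequences: Sequence[SequenceRecord],
    samples: Sequence[SampleRecord],
    ref: ReferenceModel,
    alignment: Alignment | None = None,
    tree: dendropy.Tree | None = None,
    typing: TypingConfig = TypingConfig(),
    orthology: OrthologyConfig = OrthologyConfig(),
    n_bootstrap: int = 1000,
    seed: int = 1,
    support_min: float = DEFAULT_SUPPORT_MIN,
    deletion: Literal["pairwise", "complete"] = "complete",
    outgroup_ids: Sequence[str] = (),
    exemplars: CladeExemplars | None = None,
) -> RunReport:
    """Run annotate → screen → type → stats → tree → infer on records.

    When ``tree`` is supplied the tree-building stage is skipped and the
    imported tree feeds inference (support gating is disabled if it
    carries no supports).  When ``alignment`` is None, alignment-based
    stats and tree building are skipped (an external tree is then
    required for inference).
    """
    if not sequences:
        raise ValueError("empty sequence set")
    check_links(sequences, samples)
    logger.info("annotating %d sequences", len(sequences))
    typing_table, models = _annotate_and_type(sequences, ref, typing, orthology)
    n_typed = int((typing_table.status == "typed").sum())
    logger.info("typed %d / %d sequences", n_typed, len(sequences))

    typed = typing_table[typing_table.status == "typed"]
    genotypes = []
    for individual_id, group in typed.groupby("individual_id", sort=True):
        triples = [
            (row["seq_id"], row["_label"], row["_report"])
            for _, row in group.iterrows()
        ]
        genotypes.append(genotype_individual(triples, str(individual_id)))

    stats_table = _stats_by_variant(alignment, typing_table)

    supported_tree = tree
    built = False
    if supported_tree is None and alignment is not None and alignment.n_sequences >= 3:
        logger.info("building NJ tree with %d bootstrap replicates", n_bootstrap)
        tree_ids = [sid for sid in typed.seq_id if sid in alignment.ids]
        extra = [sid for sid in outgroup_ids if sid in alignment.ids and sid not in tree_ids]
        supported_tree = bootstrap_support(
            alignment.subset(tree_ids + extra), n_reps=n_bootstrap,
            seed=seed, deletion=deletion,
        )
        built = True
    rooted = None
    if supported_tree is not None:
        leaf_ids = {l.taxon.label for l in supported_tree.leaf_node_iter()}
        og = [o for o in outgroup_ids if o in leaf_ids]
        if og:
            rooted = root_with_outgroup(supported_tree, og)
        elif supported_tree.is_rooted:
            rooted = supported_tree
        else:
            rooted = supported_tree.clone(depth=1)
            rooted.reroot_at_midpoint(update_bipartitions=False)
            rooted.is_rooted = True

    origin_calls: list[OriginCall] = []
    if rooted is not None:
        has_supports = any(
            node.label for node in rooted.preorder_internal_node_iter()
            if node is not rooted.seed_node
        )
        ex = exemplars if exemplars is not None else derive_exemplars(typing_table, samples)
        ploidy_of = {s.individual_id: s.ploidy for s in samples}
        leaf_ids = {l.taxon.label for l in rooted.leaf_node_iter()}
        for genotype in genotypes:
            if set(genotype.seq_ids) - leaf_ids:
                continue  # e.g. outgroup excluded from the inference tree
            origin_calls.append(
                classify_origin(
                    rooted, genotype, ex, support_min=support_min,
                    ploidy=ploidy_of.get(genotype.individual_id, 0),
                    require_support=has_supports,
                )
            )
    origin_table = pd.DataFrame(
        [
            {
                "individual_id": c.individual_id,
                "ploidy": c.ploidy,
                "n_copies": len(c.copies),
                "labels": "+".join(sorted({l.value for _, l, _ in c.copies})),
                "clades": "+".join(sorted({cl for _, _, cl in c.copies})),
                "monophyly": c.monophyly.value,
                "min_separating_support": c.min_separating_support,
                "verdict": c.display_verdict,
                "rationale": c.rationale,
            }
            for c in origin_calls
        ],
        columns=["individual_id", "ploidy", "n_copies", "labels", "clades",
                 "monophyly", "min_separating_support", "verdict", "rationale"],
    )

    cross = cross_tabulate(genotypes, list(samples))
    public_table = typing_table.drop(
        columns=[c for c in ("_label", "_report") if c in typing_table.columns]
    )
    provenance = {
        "package": "waxyphylo",
        "version": _pkg_version,
        "seed": seed,
        "n_bootstrap": n_bootstrap if built else None,
        "deletion": deletion,
        "support_min": support_min,
        "tree_source": "built" if built else ("imported" if tree is not None else "none"),
        "distance": "uncorrected-P",
        "n_sequences": len(sequences),
        "n_typed": n_typed,
    }
    return RunReport(
        typing_table=public_table,
        genotypes=genotypes,
        stats_table=stats_table,
        tree=rooted if rooted is not None else supported_tree,
        origin_calls=origin_calls,
        origin_table=origin_table,
        cross_tab=cross,
        provenance=provenance,
    )


def make_figures_tables(report: RunReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary twins: per-region variation table and a variant-presence
    count matrix by section × ploidy."""
    table1 = report.stats_table.copy()
    if report.cross_tab.empty:
        fig1 = pd.DataFrame(columns=["section", "ploidy", "combination", "n_individuals"])
    else:
        fig1 = report.cross_tab.copy()
    return table1, fig1


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """File-based pipeline entry point; writes the report to cfg.out_dir."""
    sequences = read_fasta(cfg.sequences_path, aligned=cfg.aligned_input)
    samples = read_metadata(cfg.metadata_path)
    ref = load_reference(cfg.reference_fasta, cfg.reference_segments)
    alignment = None
    if cfg.aligned_input:
        alignment = Alignment.from_records(sequences)
        sequences = [
            SequenceRecord(r.seq_id, r.individual_id, r.ungapped, r.description)
            for r in sequences
        ]
    tree = read_newick(cfg.tree_path) if cfg.tree_path else None
    report = run_analysis(
        sequences, samples, ref,
        alignment=alignment, tree=tree,
        typing=cfg.typing, orthology=cfg.orthology,
        n_bootstrap=cfg.n_bootstrap, seed=cfg.seed,
        support_min=cfg.support_min, deletion=cfg.deletion,
        outgroup_ids=cfg.outgroup_ids,
    )
    write_report(report, cfg.out_dir)
    return report


def write_report(report: RunReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.typing_table.to_csv(out / "typing.csv", index=False)
    report.stats_table.to_csv(out / "seqstats.csv", index=False)
    report.origin_table.to_csv(out / "origin_calls.csv", index=False)
    report.cross_tab.to_csv(out / "cross_tabulation.csv", index=False)
    if report.tree is not None:
        write_newick(report.tree, out / "tree.nwk")
    (out / "provenance.json").write_text(json.dumps(report.provenance, indent=2))
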