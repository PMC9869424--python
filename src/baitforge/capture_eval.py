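"""Capture-result evaluation: gene recovery, low-representation filter,
and paralog triage.

Recovery follows the per-sample bookkeeping of HybPiper-style runs: the
recovered fraction of a gene is the longest assembled contig length over
the reference length, capped at 1 so supercontigs (exon plus flanking
sequence) cannot inflate recovery.  A sample raises a paralog warning on
a gene when it assembles two or more long contigs; genes warned in more
than ``paralog_specimen_threshold`` specimens, or whose gene tree shows
same-sample copies failing to group together, are excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import pandas as pd

from .core import Tree
from .locus_selection import TargetLocus

logger = logging.getLogger("baitforge")


@dataclass
class SampleAssembly:
    """Per-sample assembled contigs, keyed by gene id."""

    sample_id: str
    contigs: dict[str, list[str]] = field(default_factory=dict)
    total_reads: Optional[int] = None
    on_target_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.total_reads is not None and self.on_target_reads is not None
                and self.on_target_reads > self.total_reads):
            raise ValueError(
                f"{self.sample_id}: on_target_reads > total_reads")


def _ref_lengths(references: Sequence[TargetLocus]) -> dict[str, int]:
    return {r.gene_id: len(r.reference.sequence) for r in references}


def recovery_matrix(
    assemblies: Sequence[SampleAssembly],
    references: Sequence[TargetLocus],
) -> pd.DataFrame:
    """Samples x genes matrix of recovered fraction, in [0, 1].

    Entry = min(1, longest contig length / reference length); 0 when the
    gene was not assembled.  A gene present in an assembly but absent
    from the references is an error.
    """
    ref_len = _ref_lengths(references)
    genes = [r.gene_id for r in references]
    data = {}
    for asm in assemblies:
        unknown = set(asm.contigs) - set(genes)
        if unknown:
            raise KeyError(
                f"sample {asm.sample_id}: genes not in references: "
                f"{sorted(unknown)[:5]}"
            )
        row = {}
        for g in genes:
            contigs = asm.contigs.get(g, [])
            best = max((len(c) for c in contigs), default=0)
            row[g] = min(1.0, best / ref_len[g])
        data[asm.sample_id] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=genes)


def sample_summary(
    matrix: pd.DataFrame,
    assemblies: Sequence[SampleAssembly],
    references: Sequence[TargetLocus],
) -> pd.DataFrame:
    """Per-sample summary rows (Table-1 style).

    loci_obtained: genes with any recovery; percent_recovery_length:
    100 * sum of capped recovered length / sum of reference lengths;
    percent_on_target: from read totals where supplied, else NaN.
    """
    ref_len = pd.Series(_ref_lengths(references))[matrix.columns]
    reads = {a.sample_id: (a.total_reads, a.on_target_reads)
             for a in assemblies}
    rows = []
    for sample in matrix.index:
        frac = matrix.loc[sample]
        total, on = reads.get(sample, (None, None))
        pct_on = (100.0 * on / total
                  if total not in (None, 0) and on is not None else float("nan"))
        rows.append({
            "sample": sample,
            "loci_obtained": int((frac > 0).sum()),
            "percent_recovery_length":
                100.0 * float((frac * ref_len).sum()) / float(ref_len.sum()),
            "percent_on_target": pct_on,
        })
    return pd.DataFrame(rows).set_index("sample")


def capture_summary_stats(summary: pd.DataFrame,
                          n_targeted: int) -> dict[str, float]:
    """Column statistics over a per-sample summary table.

    mean_percent_on_target is rounded to the nearest integer (the
    convention of the source tables); mean_percent_genes_recovered is
    100 * mean loci obtained / number of targeted genes, rounded.
    """
    return {
        "mean_percent_on_target":
            round(float(summary["percent_on_target"].mean())),
        "min_loci_obtained": int(summary["loci_obtained"].min()),
        "max_loci_obtained": int(summary["loci_obtained"].max()),
        "mean_loci_obtained": float(summary["loci_obtained"].mean()),
        "min_percent_recovery_length":
            float(summary["percent_recovery_length"].min()),
        "mean_percent_recovery_length":
            float(summary["percent_recovery_length"].mean()),
        "mean_percent_genes_recovered":
            round(100.0 * float(summary["loci_obtained"].mean()) / n_targeted),
    }


def low_representation_filter(matrix: pd.DataFrame,
                              min_fraction: float) -> list[str]:
    """Genes recovered in fewer than min_fraction of the samples (strict)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    presence = (matrix > 0).sum(axis=0) / matrix.shape[0]
    excluded = sorted(presence.index[presence < min_fraction])
    logger.info("low-representation filter: %d genes excluded", len(excluded))
    return excluded


def flag_paralog_samples(
    assemblies: Sequence[SampleAssembly],
    references: Sequence[TargetLocus],
    long_fraction: float = 0.85,
) -> dict[str, set[str]]:
    """Per gene, the samples with >=2 contigs each >= long_fraction of ref."""
    if not 0 < long_fraction <= 1:
        raise ValueError("long_fraction must be in (0, 1]")
    ref_len = _ref_lengths(references)
    flags: dict[str, set[str]] = {r.gene_id: set() for r in references}
    for asm in assemblies:
        for gene, contigs in asm.contigs.items():
            n_long = sum(
                1 for c in contigs if len(c) >= long_fraction * ref_len[gene]
            )
            if n_long >= 2:
                flags[gene].add(asm.sample_id)
    return flags


def default_tip_sample(label: str) -> str:
    """Tip labels encode sample plus copy index as `sample@copy`."""
    return label.split("@")[0]


def tree_paralogy_evidence(
    gene_tree: Tree,
    flagged_samples: set[str],
    tip_sample: Callable[[str], str] = default_tip_sample,
) -> bool:
    """True iff some flagged sample's copies are NOT monophyletic.

    The gene tree is treated as unrooted: a sample's copies are
    monophyletic iff some edge separates exactly those tips from all
    others.  Copies grouping together is the allele signature; copies in
    distant clades is evidence of paralogy.  Flagged samples with fewer
    than two tips are skipped with a warning.
    """
    taxa = gene_tree.taxon_namespace
    by_sample: dict[str, list] = {}
    for leaf in gene_tree.leaf_node_iter():
        by_sample.setdefault(tip_sample(leaf.taxon.label), []).append(
            leaf.taxon)
    all_mask = taxa.all_taxa_bitmask()
    gene_tree.encode_bipartitions()
    edge_masks = {e.bipartition.leafset_bitmask
                  for e in gene_tree.preorder_edge_iter()
                  if e.bipartition is not None}
    edge_masks |= {all_mask & ~m for m in edge_masks}
    for sample in sorted(flagged_samples):
        tips = by_sample.get(sample, [])
        if len(tips) < 2:
            warnings.warn(
                f"flagged sample {sample} has {len(tips)} tip(s) in the "
                "gene tree; skipped")
            continue
        mask = 0
        for t in tips:
            mask |= taxa.taxon_bitmask(t)
        if mask not in edge_masks:
            return True
    return False


@dataclass
class ParalogReport:
    gene_id: str
    flagged_samples: set[str]
    tree_evidence: bool
    decision: str  # "retain" | "exclude"
    reason: str = ""


def triage_gene(
    gene_id: str,
    flagged_samples: set[str],
    tree_evidence: bool,
    specimen_threshold: int = 3,
) -> ParalogReport:
    """Exclude iff flagged in more than specimen_threshold specimens
    (strict) or the gene tree shows paralogy."""
    if len(flagged_samples) > specimen_threshold:
        return ParalogReport(gene_id, flagged_samples, tree_evidence,
                             "exclude", "flagged_specimens")
    if tree_evidence:
        return ParalogReport(gene_id, flagged_samples, tree_evidence,
                             "exclude", "tree_paralogy")
    return ParalogReport(gene_id, flagged_samples, tree_evidence, "retain")


def triage_pipeline(
    matrix: pd.DataFrame,
    flags: dict[str, set[str]],
    tree_evidence: dict[str, bool],
    min_fraction: float = 0.70,
    specimen_threshold: int = 3,
) -> dict[str, list]:
    """Full post-assembly bookkeeping, low representation applied first.

    Returns disjoint gene lists: assembled (any recovery), excluded by
    low representation, excluded by triage, retained; with the identity
    retained = assembled - low_rep - triaged.
    """
    assembled = sorted(matrix.columns[(matrix > 0).any(axis=0)])
    low_rep = [g for g in low_representation_filter(matrix, min_fraction)
               if g in assembled]
    reports = [
        triage_gene(g, flags.get(g, set()), tree_evidence.get(g, False),
                    specimen_threshold)
        for g in assembled if g not in set(low_rep)
    ]
    triaged = [r.gene_id for r in reports if r.decision == "exclude"]
    retained = [r.gene_id for r in reports if r.decision == "retain"]
    logger.info("triage: %d assembled, %d low-representation, %d paralog-"
                "excluded, %d retained", len(assembled), len(low_rep),
                len(triaged), len(retained))
    return {"assembled": assembled, "low_representation": low_rep,
            "triaged": triaged, "retained": retained, "reports": reports}


def read_reads_tsv(path) -> pd.DataFrame:
    """TSV with columns sample, total_reads, on_target_reads."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "total_reads", "on_target_reads"}
    if not required <= set(df.columns):
        raise ValueError(f"reads TSV must have columns {sorted(required)}")
    return df.set_index("sample")
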