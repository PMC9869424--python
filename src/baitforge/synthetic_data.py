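"""Seeded generators emulating every input the pipeline consumes.

The generators plant ground truth — gene models with known exon/intron
structure, transcriptomes at controlled K80 divergence, assemblies with
controlled recovery and paralog duplications, reads with known on/off
target origin, and gene trees with controlled quartet discordance — so
every downstream module can be tested against what was planted, without
any external data.

Sequence divergence is simulated *exactly* under the K80 model: each
site substitutes according to the K80 transition probabilities at the
requested distance (expected substitutions/site) and kappa, so the K80
distance estimator is internally consistent with the generator.  Indels
are off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import SeqRecord, Tree, read_newick_string
from .capture_eval import SampleAssembly
from .locus_selection import TargetLocus
from .tree_concordance import _branch_groups

_BASES = np.frombuffer(b"ACGT", dtype="S1")
# index: A=0 C=1 G=2 T=3; transition partner of each base
_TRANSITION = np.array([2, 3, 0, 1])
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study; defaults mirror the real one.

    Divergences are expected substitutions per site; the three default
    transcriptome taxa sit comfortably inside the per-dataset identity
    thresholds (0.92 / 0.90 / 0.95).  ``discordance`` gives the
    (concordant, alt1, alt2, polytomy) gene-tree proportions.
    """

    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 12_000
    n_genes: int = 12
    exon_count_range: tuple[int, int] = (1, 6)
    exon_length_range: tuple[int, int] = (120, 360)
    intron_length_range: tuple[int, int] = (150, 350)
    taxon_divergence: dict = field(default_factory=lambda: {
        "K_africana": 0.04, "M_alliacea": 0.05, "T_umbellata": 0.025,
    })
    kappa: float = 2.0
    transcriptome_dropout: float = 0.0
    n_samples: int = 38
    recovery_zero_prob: float = 0.02
    recovery_range: tuple[float, float] = (0.85, 1.0)
    sample_divergence: float = 0.02
    paralog_fraction: float = 0.1
    paralog_sample_prob: float = 1.0
    duplicate_divergence: float = 0.08
    read_count: int = 100_000
    off_target_fraction: float = 0.27
    discordance: tuple[float, float, float, float] = (0.6, 0.2, 0.2, 0.0)
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.discordance) - 1.0) > 1e-9:
            raise ValueError("discordance proportions must sum to 1")
        for p in (self.transcriptome_dropout, self.recovery_zero_prob,
                  self.paralog_fraction, self.paralog_sample_prob,
                  self.off_target_fraction, self.indel_rate,
                  *self.discordance):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def k80_site_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each specific transversion)) after distance d.

    From the K80 substitution process normalized to one expected
    substitution per site per unit distance.
    """
    e1 = np.exp(-4.0 * d / (kappa + 2.0))
    e2 = np.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
    p_transition = 0.25 + 0.25 * e1 - 0.5 * e2
    p_each_transversion = 0.25 - 0.25 * e1
    return float(p_transition), float(p_each_transversion)


def mutate_k80(seq: str, d: float, kappa: float,
               rng: np.random.Generator) -> str:
    """Evolve a sequence for distance d under K80 (site-independent)."""
    if d == 0:
        return seq
    idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = np.full(idx.shape, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[idx == b] = i
    p_ts, p_tv = k80_site_probs(d, kappa)
    u = rng.random(code.shape)
    out = code.copy()
    ts = u < p_ts
    out[ts] = _TRANSITION[code[ts]]
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    out[tv1] = _TRANSVERSIONS[code[tv1], 0]
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[tv2] = _TRANSVERSIONS[code[tv2], 1]
    valid = code >= 0
    res = idx.copy()
    res[valid] = np.frombuffer(b"ACGT", dtype=np.uint8)[out[valid]]
    return res.tobytes().decode("ascii")


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:          # deletion
            continue
        out.append(ch)
        if r > 1 - rate / 2:      # insertion
            out.append(str(rng.choice(_BASES), "ascii"))
    return "".join(out) or seq[:1]


# ---------------------------------------------------------------------------


def simulate_reference_set(
    spec: SimulationSpec,
) -> tuple[list[SeqRecord], dict[str, list[SeqRecord]], pd.DataFrame]:
    """Plant genes in contigs; derive transcriptomes by splicing+mutating.

    Returns (contigs, per-taxon transcriptomes, truth table).  The truth
    table has one row per planted gene: gene_id, contig_id, strand,
    exon_count, intron_count, exonic_length, contig_start, contig_end,
    and the comma-joined taxa whose transcriptome carries the gene.
    """
    rng = spec.rng()
    contig_seqs = [random_sequence(rng, spec.contig_length)
                   for _ in range(spec.n_contigs)]
    cursors = [100] * spec.n_contigs
    truth_rows = []
    spliced: dict[str, str] = {}
    for g in range(spec.n_genes):
        gene_id = f"gene{g:04d}"
        ci = g % spec.n_contigs
        n_exons = int(rng.integers(*spec.exon_count_range, endpoint=True))
        exon_lens = rng.integers(*spec.exon_length_range, endpoint=True,
                                 size=n_exons)
        intron_lens = rng.integers(*spec.intron_length_range, endpoint=True,
                                   size=max(n_exons - 1, 0))
        total = int(exon_lens.sum() + intron_lens.sum())
        if total > spec.contig_length - 200:
            raise ValueError(
                f"{gene_id}: gene ({total} bp) longer than its contig")
        if cursors[ci] + total > spec.contig_length - 100:
            contig_seqs.append(random_sequence(rng, spec.contig_length))
            cursors.append(100)
            ci = len(contig_seqs) - 1
        start = cursors[ci]
        pos = start
        exon_parts = []
        blocks = []
        for i, el in enumerate(exon_lens):
            exon_parts.append(contig_seqs[ci][pos:pos + int(el)])
            blocks.append(f"{pos}-{pos + int(el)}")
            pos += int(el)
            if i < len(intron_lens):
                pos += int(intron_lens[i])
        cursors[ci] = pos + int(rng.integers(120, 260))
        spliced[gene_id] = "".join(exon_parts)
        truth_rows.append({
            "gene_id": gene_id, "contig_id": f"contig{ci}", "strand": "+",
            "exon_count": n_exons, "intron_count": n_exons - 1,
            "exonic_length": int(exon_lens.sum()),
            "contig_start": start, "contig_end": pos,
            "exon_blocks": ";".join(blocks),
        })
    contigs = [SeqRecord(f"contig{i}", s, dataset="genome")
               for i, s in enumerate(contig_seqs)]

    transcriptomes: dict[str, list[SeqRecord]] = {}
    gene_taxa: dict[str, list[str]] = {r["gene_id"]: [] for r in truth_rows}
    for taxon, div in spec.taxon_divergence.items():
        recs = []
        for row in truth_rows:
            gid = row["gene_id"]
            if rng.random() < spec.transcriptome_dropout:
                continue
            seq = mutate_k80(spliced[gid], div, spec.kappa, rng)
            if spec.indel_rate:
                seq = _apply_indels(seq, spec.indel_rate, rng)
            recs.append(SeqRecord(f"{taxon}|{gid}", seq, dataset=taxon))
            gene_taxa[gid].append(taxon)
        transcriptomes[taxon] = recs

    truth = pd.DataFrame(truth_rows)
    truth["taxa"] = [",".join(gene_taxa[g]) for g in truth["gene_id"]]
    return contigs, transcriptomes, truth


def references_from_truth(
    contigs: Sequence[SeqRecord], truth: pd.DataFrame,
    panel: str = "custom",
) -> list[TargetLocus]:
    """Exact spliced reference per planted gene, re-cut from the genome
    using the truth table's exon blocks."""
    by_id = {c.id: c.sequence for c in contigs}
    out = []
    for _, row in truth.iterrows():
        cseq = by_id[row["contig_id"]]
        parts = []
        for block in row["exon_blocks"].split(";"):
            s, e = (int(x) for x in block.split("-"))
            parts.append(cseq[s:e])
        out.append(TargetLocus(
            gene_id=row["gene_id"], panel=panel,
            reference_seqs=[SeqRecord(row["gene_id"], "".join(parts),
                                      dataset="genome")],
            provenance="planted",
        ))
    return out


def simulate_assemblies(
    spec: SimulationSpec,
    references: Sequence[TargetLocus],
) -> tuple[list[SampleAssembly], pd.DataFrame, dict]:
    """Per-sample assemblies with planted recovery, paralogs and reads.

    Returns (assemblies, reads table, truth) where truth records the
    planted paralog genes, per-gene duplicated samples, and the planted
    on-target fraction.
    """
    if not references:
        raise ValueError("references must be non-empty")
    rng = spec.rng()
    genes = [r.gene_id for r in references]
    seqs = {r.gene_id: r.reference.sequence for r in references}
    paralog_genes = [g for g in genes if rng.random() < spec.paralog_fraction]
    dup_samples: dict[str, set[str]] = {g: set() for g in paralog_genes}

    assemblies = []
    reads_rows = []
    for s in range(spec.n_samples):
        sid = f"sample{s:02d}"
        contigs: dict[str, list[str]] = {}
        for g in genes:
            if rng.random() < spec.recovery_zero_prob:
                continue
            frac = float(rng.uniform(*spec.recovery_range))
            L = max(1, round(frac * len(seqs[g])))
            main = mutate_k80(seqs[g][:L], spec.sample_divergence,
                              spec.kappa, rng)
            contigs[g] = [main]
            if g in dup_samples and rng.random() < spec.paralog_sample_prob:
                dup_len = max(1, round(
                    float(rng.uniform(0.9, 1.0)) * len(seqs[g])))
                dup = mutate_k80(seqs[g][:dup_len],
                                 spec.duplicate_divergence, spec.kappa, rng)
                contigs[g].append(dup)
                dup_samples[g].add(sid)
        on_target = int(rng.binomial(spec.read_count,
                                     1.0 - spec.off_target_fraction))
        assemblies.append(SampleAssembly(
            sample_id=sid, contigs=contigs,
            total_reads=spec.read_count, on_target_reads=on_target))
        reads_rows.append({"sample": sid, "total_reads": spec.read_count,
                           "on_target_reads": on_target})
    truth = {
        "paralog_genes": paralog_genes,
        "duplicated_samples": dup_samples,
        "on_target_fraction": 1.0 - spec.off_target_fraction,
    }
    return assemblies, pd.DataFrame(reads_rows), truth


# ---------------------------------------------------------------------------
# gene trees


def simulate_gene_trees(
    species_tree: Tree,
    spec: SimulationSpec,
    n_trees: int,
    focal_branch_index: int = 0,
    dropout: float = 0.0,
) -> tuple[list[Tree], dict]:
    """Gene trees with planted discordance around one focal branch.

    For the chosen internal branch of the species tree with around-
    branch groups (A,B | C,D), each gene tree keeps the four group
    subtrees intact and rearranges them as AB|CD (concordant), AC|BD,
    AD|BC, or a four-way polytomy, drawn at the planted proportions.
    ``dropout`` removes each taxon independently (for decisiveness
    tests).  Returns (trees, truth) with the planted category counts.
    """
    rng = spec.rng()
    branches = list(_branch_groups(species_tree))
    if not branches:
        raise ValueError("species tree has no internal branch")
    bp, A, B, C, D = branches[focal_branch_index]

    def subtree_newick(group: frozenset[str]) -> str:
        if len(group) == 1:
            return next(iter(group))
        sub = species_tree.extract_tree_with_taxa_labels(labels=group)
        s = sub.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()
        return s.rstrip(";").strip()

    nA, nB, nC, nD = (subtree_newick(g) for g in (A, B, C, D))
    templates = [
        f"(({nA},{nB}),({nC},{nD}));",   # concordant
        f"(({nA},{nC}),({nB},{nD}));",   # first alternative
        f"(({nA},{nD}),({nB},{nC}));",   # second alternative
        f"({nA},{nB},{nC},{nD});",       # polytomy
    ]
    cats = rng.choice(4, size=n_trees, p=list(spec.discordance))
    trees = []
    for c in cats:
        t = read_newick_string(templates[int(c)])
        if dropout:
            labels = [l.taxon.label for l in t.leaf_node_iter()]
            keep = [lab for lab in labels if rng.random() >= dropout]
            if len(keep) >= 4:
                t = t.extract_tree_with_taxa_labels(labels=keep)
        trees.append(t)
    counts = {k: int((cats == i).sum())
              for i, k in enumerate(("concordant", "alt1", "alt2", "polytomy"))}
    truth = {"focal_branch": bp, "groups": (A, B, C, D), "counts": counts}
    return trees, truth
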