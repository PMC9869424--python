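"""Hyb-Seq-style target locus selection.

Transcripts are placed on genome contigs with a k-mer seeded, chained,
ungapped-extension spliced matcher (a deliberate stand-in for BLAT: the
contract is the identity and exon-block output, not bit-parity with any
particular aligner).  Gene models inferred from the placements are
filtered on intron count and exonic length, intersected across
transcriptome datasets by greedy CD-HIT-style clustering, and screened
for copy number against the genome.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .core import Alignment, RunConfig, SeqRecord

logger = logging.getLogger("baitforge")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SplicedMatch:
    """Exon-block placement of a transcript on a contig.

    ``blocks`` are (contig_start, contig_end, transcript_start,
    transcript_end), half-open, ordered by transcript coordinate.  For
    '-' strand matches contig coordinates are on the forward strand and
    therefore descend along the transcript.  ``identity`` is matched
    bases over aligned transcript bases (query-centric).
    """

    transcript_id: str
    contig_id: str
    strand: str
    blocks: list[tuple[int, int, int, int]]
    identity: float

    @property
    def exonic_length(self) -> int:
        return sum(te - ts for _, _, ts, te in self.blocks)

    @property
    def contig_span(self) -> tuple[int, int]:
        starts = [b[0] for b in self.blocks]
        ends = [b[1] for b in self.blocks]
        return min(starts), max(ends)


@dataclass
class GeneModel:
    gene_id: str
    contig_id: str
    exon_count: int
    exonic_length: int
    source_datasets: set[str] = field(default_factory=set)

    @property
    def intron_count(self) -> int:
        return self.exon_count - 1


@dataclass
class TargetLocus:
    """A selected gene destined for the bait kit."""

    gene_id: str
    panel: str  # one of {"custom", "angio353", "functional"}
    reference_seqs: list[SeqRecord]
    copy_count: Optional[int] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.reference_seqs:
            raise ValueError(f"locus {self.gene_id}: no reference sequence")
        if self.panel not in {"custom", "angio353", "functional"}:
            raise ValueError(f"invalid panel label {self.panel!r}")

    @property
    def reference(self) -> SeqRecord:
        return self.reference_seqs[0]


# ---------------------------------------------------------------------------
# spliced matching

_K = 11            # seed k-mer size
_MAX_MISMATCH_RUN = 4   # ungapped extension stops after this many misses


def _seed_blocks(tseq: str, cseq: str) -> list[tuple[int, int, int, int, int]]:
    """Candidate ungapped blocks (cstart, cend, tstart, tend, matches).

    Seeds are exact k-mer hits grouped by diagonal; consecutive hits on a
    diagonal merge into a run, and each run is extended outwards without
    gaps until _MAX_MISMATCH_RUN consecutive mismatches (the mismatch
    tail is trimmed back).
    """
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(cseq) - _K + 1):
        index[cseq[i:i + _K]].append(i)

    by_diag: dict[int, list[int]] = defaultdict(list)
    for t in range(len(tseq) - _K + 1):
        for c in index.get(tseq[t:t + _K], ()):
            by_diag[c - t].append(t)

    blocks = []
    for diag, tpos in by_diag.items():
        tpos.sort()
        # split hit positions into runs; a gap > k between consecutive
        # k-mer hits on one diagonal means an unseeded (mismatch-rich)
        # stretch we leave to the extension step
        runs: list[list[int]] = [[tpos[0]]]
        for t in tpos[1:]:
            if t - runs[-1][-1] <= 2 * _K:
                runs[-1].append(t)
            else:
                runs.append([t])
        for run in runs:
            ts, te = run[0], run[-1] + _K
            cs = ts + diag
            ts, te = _extend(tseq, cseq, diag, ts, te)
            cs, ce = ts + diag, te + diag
            matches = sum(
                1 for i in range(ts, te) if tseq[i] == cseq[i + diag]
            )
            blocks.append((cs, ce, ts, te, matches))
    # dedupe identical blocks arising from overlapping runs
    return sorted(set(blocks), key=lambda b: (b[2], b[0]))


def _extend(tseq: str, cseq: str, diag: int, ts: int, te: int) -> tuple[int, int]:
    # left
    miss = 0
    i = ts - 1
    last_good = ts
    while i >= 0 and i + diag >= 0 and miss < _MAX_MISMATCH_RUN:
        if tseq[i] == cseq[i + diag]:
            miss = 0
            last_good = i
        else:
            miss += 1
        i -= 1
    ts = last_good
    # right
    miss = 0
    i = te
    last_good = te
    while i < len(tseq) and i + diag < len(cseq) and miss < _MAX_MISMATCH_RUN:
        if tseq[i] == cseq[i + diag]:
            miss = 0
            last_good = i + 1
        else:
            miss += 1
        i += 1
    return ts, last_good


def _chain(blocks: list[tuple[int, int, int, int, int]]
           ) -> list[list[tuple[int, int, int, int, int]]]:
    """Greedy best-first chaining into collinear non-overlapping chains.

    Returns chains in decreasing match order; each block used once.
    """
    chains = []
    remaining = list(blocks)
    while remaining:
        remaining.sort(key=lambda b: b[2])
        n = len(remaining)
        score = [b[4] for b in remaining]
        prev = [-1] * n
        # extension can overshoot an exon boundary on chance matches, so
        # adjacent exon blocks may overlap; allow overlap short of half
        # a block (so alternative placements of the same exon never
        # chain) and trim it after chaining
        for j in range(n):
            for i in range(j):
                bi, bj = remaining[i], remaining[j]
                shorter = min(bi[3] - bi[2], bj[3] - bj[2])
                if (bj[2] > bi[2] and bj[0] > bi[0]
                        and bj[3] > bi[3] and bj[1] > bi[1]
                        and bi[3] - bj[2] < 0.5 * shorter
                        and bi[1] - bj[0] < 0.5 * shorter):
                    if score[i] + remaining[j][4] > score[j]:
                        score[j] = score[i] + remaining[j][4]
                        prev[j] = i
        best = max(range(n), key=lambda j: score[j])
        chain_idx = []
        j = best
        while j != -1:
            chain_idx.append(j)
            j = prev[j]
        chain_idx.reverse()
        chains.append([remaining[j] for j in chain_idx])
        used = set(chain_idx)
        remaining = [b for j, b in enumerate(remaining) if j not in used]
        if len(chains[-1]) == 1 and chains[-1][0][4] < 2 * _K:
            break  # residual noise
    return chains


def _matches_in(tseq: str, cseq: str, diag: int, lo: int, hi: int) -> int:
    return sum(1 for i in range(lo, hi) if tseq[i] == cseq[i + diag])


def _trim_overlaps(chain: list[tuple[int, int, int, int, int]], tseq: str,
                   cseq: str) -> list[tuple[int, int, int, int]]:
    """Resolve transcript-coordinate overlaps between chained blocks.

    The overlap zone belongs to whichever neighbouring block matches it
    better (ties go to the earlier block, the leftmost convention).
    """
    out: list[list[int]] = []
    for cs, ce, ts, te, _ in chain:
        if out and ts < out[-1][3]:
            pcs, pce, pts, pte = out[-1]
            delta = pte - ts
            prev_m = _matches_in(tseq, cseq, pcs - pts, pte - delta, pte)
            next_m = _matches_in(tseq, cseq, cs - ts, ts, ts + delta)
            if next_m > prev_m:
                out[-1][3] -= delta
                out[-1][1] -= delta
            else:
                ts += delta
                cs += delta
        if ts < te and (not out or ts >= out[-1][3]):
            out.append([cs, ce, ts, te])
    return [tuple(b) for b in out if b[2] < b[3]]


def match_transcript_to_genome(
    transcript: SeqRecord,
    contigs: Sequence[SeqRecord],
    min_identity: float,
) -> list[SplicedMatch]:
    """Place a transcript on contigs; spliced, strand-aware.

    Returns all placements with identity >= min_identity, best first
    (highest identity, then longest exonic span).  Multiple placements
    per contig (gene copies) are recovered by iterative chain peeling.
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    tseq = transcript.sequence
    results: list[SplicedMatch] = []
    for contig in contigs:
        for strand in "+-":
            cseq = contig.sequence if strand == "+" else revcomp(contig.sequence)
            blocks = _seed_blocks(tseq, cseq)
            if not blocks:
                continue
            for chain in _chain(blocks):
                trimmed = _trim_overlaps(chain, tseq, cseq)
                if not trimmed:
                    continue
                aligned = sum(te - ts for _, _, ts, te in trimmed)
                matches = sum(
                    sum(1 for i in range(ts, te)
                        if tseq[i] == cseq[i + (cs - ts)])
                    for cs, ce, ts, te in trimmed
                )
                # query-centric identity; placements covering less than
                # half the transcript are seed noise, not gene copies
                if aligned < 0.5 * len(tseq):
                    continue
                identity = matches / aligned
                if identity < min_identity:
                    continue
                if strand == "-":
                    L = len(cseq)
                    trimmed = [(L - ce, L - cs, ts, te)
                               for cs, ce, ts, te in trimmed]
                results.append(SplicedMatch(
                    transcript_id=transcript.id,
                    contig_id=contig.id,
                    strand=strand,
                    blocks=trimmed,
                    identity=identity,
                ))
    results.sort(key=lambda m: (-m.identity, -m.exonic_length))
    return results


def infer_gene_model(match: SplicedMatch, gene_id: str,
                     dataset: str) -> GeneModel:
    if not match.blocks:
        raise ValueError("match has no blocks")
    return GeneModel(
        gene_id=gene_id,
        contig_id=match.contig_id,
        exon_count=len(match.blocks),
        exonic_length=match.exonic_length,
        source_datasets={dataset},
    )


def filter_candidate_genes(
    models: Sequence[GeneModel], config: RunConfig
) -> tuple[list[GeneModel], list[tuple[GeneModel, str]]]:
    """Keep genes with < max_introns introns and < max_gene_length bp.

    Both bounds strict.  Rejected models carry the reason of the first
    failing rule ("introns" before "length").
    """
    kept, rejected = [], []
    for m in models:
        if m.intron_count >= config.max_introns:
            rejected.append((m, "introns"))
        elif m.exonic_length >= config.max_gene_length:
            rejected.append((m, "length"))
        else:
            kept.append(m)
    logger.info("gene filter: %d kept, %d rejected", len(kept), len(rejected))
    return kept, rejected


# ---------------------------------------------------------------------------
# clustering / intersection


def pair_identity(a: str, b: str) -> float:
    """Global-alignment identity: 1 - edit distance / longer length."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


@dataclass
class Cluster:
    representative: SeqRecord
    members: list[SeqRecord]

    @property
    def datasets(self) -> set[str]:
        return {m.dataset for m in self.members}


def cluster_and_intersect(
    gene_seqs: Sequence[SeqRecord], identity: float
) -> tuple[list[Cluster], list[Cluster]]:
    """Greedy longest-first clustering; keep clusters spanning >=2 datasets.

    CD-HIT-EST strategy: sort by length descending; each sequence joins
    the first existing cluster whose *representative* it matches at
    >= identity, else founds a new cluster.  Returns (all_clusters, kept).
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    clusters: list[Cluster] = []
    for rec in sorted(gene_seqs, key=lambda r: (-len(r.sequence), r.id)):
        for cl in clusters:
            if pair_identity(rec.sequence, cl.representative.sequence) >= identity:
                cl.members.append(rec)
                break
        else:
            clusters.append(Cluster(representative=rec, members=[rec]))
    kept = [cl for cl in clusters if len(cl.datasets) >= 2]
    logger.info("clustering: %d clusters, %d span >=2 datasets",
                len(clusters), len(kept))
    return clusters, kept


# ---------------------------------------------------------------------------
# panel reference selection


def select_panel_references(
    panel_alignments: dict[str, Alignment],
    family_taxa: set[str],
    fallback_taxa: Sequence[str],
) -> tuple[dict[str, SeqRecord], list[str]]:
    """Pick one degapped reference per panel locus.

    Family rows win; among them the longest ungapped row (ties broken by
    lexicographically smaller id).  With no family row, the first
    fallback taxon present is used and the provenance notes the outgroup
    origin.  Loci with neither are returned as unresolvable.
    """
    refs: dict[str, SeqRecord] = {}
    unresolved: list[str] = []
    for locus, aln in panel_alignments.items():
        if aln.n_taxa == 0:
            raise ValueError(f"panel alignment {locus} is empty")
        fam = [(t, r) for t, r in zip(aln.taxa, aln.rows) if t in family_taxa]
        if fam:
            taxon, row = min(
                fam, key=lambda tr: (-len(tr[1].replace("-", "")), tr[0])
            )
        else:
            taxon = next((t for t in fallback_taxa if t in aln.taxa), None)
            if taxon is None:
                unresolved.append(locus)
                continue
            row = aln.row(taxon)
        refs[locus] = SeqRecord(id=locus, sequence=row.replace("-", ""),
                                dataset=taxon)
    return refs, unresolved


# ---------------------------------------------------------------------------
# copy number


def copy_number_check(
    reference: SeqRecord, contigs: Sequence[SeqRecord], min_identity: float
) -> int:
    """Count non-overlapping genomic loci matching the reference.

    Loci whose contig spans overlap by more than 50% of the shorter span
    are merged before counting.
    """
    matches = match_transcript_to_genome(reference, contigs, min_identity)
    spans: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for m in matches:
        spans[m.contig_id].append(m.contig_span)
    count = 0
    for contig_spans in spans.values():
        contig_spans.sort()
        merged: list[list[int]] = []
        for s, e in contig_spans:
            if merged:
                ps, pe = merged[-1]
                ov = min(pe, e) - max(ps, s)
                if ov > 0.5 * min(pe - ps, e - s):
                    merged[-1] = [min(ps, s), max(pe, e)]
                    continue
            merged.append([s, e])
        count += len(merged)
    return count


# ---------------------------------------------------------------------------
# cross-panel dedup

PANEL_PRIORITY = ("angio353", "functional", "custom")


def dedupe_panels(
    panels: dict[str, list[TargetLocus]],
    identity: float,
    priority: Sequence[str] = PANEL_PRIORITY,
) -> list[TargetLocus]:
    """Merge panels, resolving cross-panel duplicates by panel priority.

    Loci clustering at >= identity keep only the copy from the
    highest-priority panel; within panels, input order is preserved.
    """
    merged: list[TargetLocus] = []
    reps: list[TargetLocus] = []
    for panel in priority:
        for locus in panels.get(panel, []):
            dup = any(
                pair_identity(locus.reference.sequence, r.reference.sequence)
                >= identity
                for r in reps
            )
            if dup:
                logger.info("dedupe: dropping %s (%s) as cross-panel duplicate",
                            locus.gene_id, panel)
                continue
            reps.append(locus)
            merged.append(locus)
    return merged
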