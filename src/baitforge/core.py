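"""Shared domain types, sequence/tree I/O, and the run configuration.

All coordinates in this package are 0-based, half-open.  Partition ranges
written to files are converted to 1-based inclusive (RAxML convention).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import yaml

logger = logging.getLogger("baitforge")

IUPAC_NT = set("ACGTRYSWKMBDHVN-")
_SEQ_RE = re.compile(r"^[ACGTRYSWKMBDHVN\-]+$")


@dataclass
class SeqRecord:
    """A nucleotide sequence with an id and a dataset label.

    ``dataset`` tags provenance: a genome, a transcriptome taxon, or a
    panel name.  Sequences are uppercase IUPAC nucleotides; '-' is allowed
    so aligned rows can be carried in the same type.
    """

    id: str
    sequence: str
    dataset: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if not _SEQ_RE.match(self.sequence):
            bad = sorted(set(self.sequence) - IUPAC_NT)
            raise ValueError(
                f"record {self.id!r} contains non-IUPAC characters: {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


@dataclass
class Alignment:
    """A multiple sequence alignment: ordered taxa and equal-length rows.

    ``partition_map`` optionally records per-locus column ranges as
    (locus_id, start, end) with 0-based half-open coordinates.
    """

    taxa: list[str]
    rows: list[str]
    partition_map: Optional[list[tuple[str, int, int]]] = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        if self.partition_map is not None:
            prev_end = 0
            for name, start, end in self.partition_map:
                if start < prev_end or end > self.length or start >= end:
                    raise ValueError(f"bad partition range for {name}")
                prev_end = end

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def subset(self, taxa: Iterable[str]) -> "Alignment":
        keep = set(taxa)
        missing = keep - set(self.taxa)
        if missing:
            raise KeyError(f"taxa not in alignment: {sorted(missing)}")
        pairs = [(t, r) for t, r in zip(self.taxa, self.rows) if t in keep]
        return Alignment([t for t, _ in pairs], [r for _, r in pairs])


# dendropy trees are used directly as the tree type; internal-node labels
# that parse as numbers are interpreted as branch supports (attached as
# ``node.support``).
Tree = dendropy.Tree


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, with the study defaults.

    Fractions are in (0, 1]; see docs/methods.md for the provenance of
    each default.
    """

    per_dataset_identity: dict = field(
        default_factory=lambda: {
            "K_africana": 0.92,
            "M_alliacea": 0.90,
            "T_umbellata": 0.95,
        }
    )
    cluster_identity: float = 0.90
    max_gene_length: int = 2040       # exclusive: kept genes are < this
    max_introns: int = 10             # exclusive: kept genes have < this
    bait_length: int = 80             # synthesis default; 120 for design math
    tiling_density: int = 2
    column_missing_max: float = 0.75  # exclusive: delete if missing > this
    low_representation_min: float = 0.70
    paralog_specimen_threshold: int = 3   # exclusive: exclude if flagged > this
    paralog_long_contig_fraction: float = 0.85
    collapse_support_threshold: float = 30.0
    saturation_slope_threshold: float = 0.7

    def __post_init__(self) -> None:
        for name in (
            "cluster_identity",
            "column_missing_max",
            "low_representation_min",
            "paralog_long_contig_fraction",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for k, v in self.per_dataset_identity.items():
            if not 0 < v <= 1:
                raise ValueError(f"per_dataset_identity[{k}] out of (0,1]: {v}")
        for name in ("max_gene_length", "max_introns", "bait_length",
                     "tiling_density", "paralog_specimen_threshold"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a YAML or JSON mapping with keys matching the fields."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        return cls(**(data or {}))

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, dataset: str = "") -> list[SeqRecord]:
    """Read a FASTA file, preserving record order and gaps; uppercases.

    Raises ValueError naming the offending line on malformed input.
    """
    records: list[SeqRecord] = []
    header: Optional[str] = None
    chunks: list[str] = []

    def _flush(lineno: int) -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"{path}: record {header!r} has no sequence "
                             f"(before line {lineno})")
        records.append(SeqRecord(id=header, sequence=seq, dataset=dataset))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise ValueError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                chunks.append(line)
        _flush(lineno="EOF")  # type: ignore[arg-type]
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def alignment_from_records(records: Sequence[SeqRecord]) -> Alignment:
    return Alignment([r.id for r in records], [r.sequence for r in records])


def read_alignment(path: str | Path) -> Alignment:
    return alignment_from_records(read_fasta(path))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    write_fasta(
        [SeqRecord(t, r) for t, r in zip(aln.taxa, aln.rows)], path
    )


def write_partitions(aln: Alignment, path: str | Path) -> None:
    """RAxML-style partition file; converts to 1-based inclusive ranges."""
    if not aln.partition_map:
        raise ValueError("alignment has no partition map")
    with open(path, "w") as fh:
        for name, start, end in aln.partition_map:
            fh.write(f"DNA, {name} = {start + 1}-{end}\n")


# ---------------------------------------------------------------------------
# Newick I/O


def _attach_supports(tree: Tree) -> Tree:
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf() or node.label is None:
            continue
        try:
            node.support = float(node.label)
        except ValueError:
            pass
    return tree


def read_newick(path: str | Path) -> Tree:
    """Read one Newick tree; numeric internal-node labels become supports."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    return _attach_supports(tree)


def read_newick_string(newick: str) -> Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    return _attach_supports(tree)


def read_gene_trees(path: str | Path) -> list[Tree]:
    """Read a multi-tree Newick file (one tree per line)."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  preserve_underscores=True)
    return [_attach_supports(t) for t in trees]


def write_newick(tree: Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)
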