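"""Tiled bait (probe) generation over selected target sequences.

k-times tiling places baits every bait_length/k bases, so every target
base is covered ~k times; a terminal bait is placed flush with the
target end so coverage never drops at the 3' edge and all baits keep the
uniform length synthesis requires.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import SeqRecord

logger = logging.getLogger("baitforge")


@dataclass
class Bait:
    target_id: str
    start: int  # 0-based offset on the target
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("bait start must be >= 0")


@dataclass
class BaitSet:
    bait_length: int
    tiling_density: int
    baits: list[Bait] = field(default_factory=list)

    @property
    def per_target_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for b in self.baits:
            counts[b.target_id] = counts.get(b.target_id, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.baits)


def estimate_bait_count(target_length: int, bait_length: int,
                        density: int) -> int:
    """Design-arithmetic probe count: ceil(length * density / bait_length).

    E.g. a 2,040 bp target at 2x tiling with 120 bp probes needs 34.
    """
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    if bait_length % density != 0:
        raise ValueError(
            f"bait_length {bait_length} not divisible by density {density}"
        )
    return math.ceil(target_length * density / bait_length)


def tile_target(target: SeqRecord, bait_length: int,
                density: int) -> list[Bait]:
    """Tile one target: starts at 0, step, 2*step, ... plus a flush bait.

    step = bait_length / density.  Targets shorter than one bait are
    untileable and yield no baits.
    """
    if bait_length % density != 0:
        raise ValueError(
            f"bait_length {bait_length} not divisible by density {density}"
        )
    L = len(target.sequence)
    if L < bait_length:
        logger.info("target %s (%d bp) shorter than bait length %d: untileable",
                    target.id, L, bait_length)
        return []
    step = bait_length // density
    starts = list(range(0, L - bait_length + 1, step))
    if starts[-1] + bait_length < L:
        starts.append(L - bait_length)
    return [
        Bait(target.id, s, target.sequence[s:s + bait_length]) for s in starts
    ]


def tile_targets(targets: Iterable[SeqRecord], bait_length: int,
                 density: int) -> BaitSet:
    bs = BaitSet(bait_length=bait_length, tiling_density=density)
    for t in targets:
        bs.baits.extend(tile_target(t, bait_length, density))
    logger.info("tiled %d baits", len(bs.baits))
    return bs


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def screen_baits(
    baits: Sequence[Bait],
    max_ambiguous_fraction: float = 0.1,
    gc_range: tuple[float, float] = (0.25, 0.75),
) -> tuple[list[Bait], list[tuple[Bait, str]]]:
    """Drop baits that are too ambiguous or outside the GC window."""
    kept, dropped = [], []
    lo, hi = gc_range
    for b in baits:
        amb = sum(1 for c in b.sequence if c not in "ACGT") / len(b.sequence)
        if amb > max_ambiguous_fraction:
            dropped.append((b, "ambiguity"))
        elif not lo <= gc_fraction(b.sequence) <= hi:
            dropped.append((b, "gc"))
        else:
            kept.append(b)
    return kept, dropped


def write_bait_fasta(baitset: BaitSet, path) -> None:
    """Headers are `target_id|start|bait_index`; byte-deterministic."""
    with open(path, "w") as fh:
        for i, b in enumerate(baitset.baits):
            fh.write(f">{b.target_id}|{b.start}|{i}\n{b.sequence}\n")


def write_bait_bed(baitset: BaitSet, path) -> None:
    with open(path, "w") as fh:
        for i, b in enumerate(baitset.baits):
            fh.write(f"{b.target_id}\t{b.start}\t{b.start + len(b.sequence)}"
                     f"\tbait_{i}\n")
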