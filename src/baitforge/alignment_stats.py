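"""Alignment masking, informativeness, concatenation, K80 distances and
substitution-saturation flagging.

Distances use the Kimura two-parameter (K80) model with pairwise
deletion: for each pair, only columns where both taxa carry an
unambiguous A/C/G/T are compared.  With transition fraction P
(A<->G, C<->T) and transversion fraction Q,

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))

which is undefined when 1-2P-Q <= 0 or 1-2Q <= 0 (saturated pairs).
Saturation of an alignment is summarized by the through-origin
regression slope of the observed p-distance on the corrected K80
distance over all defined pairs; corrected distances far above observed
ones pull the slope below 1, and alignments with slope below the
threshold (default 0.7) are flagged.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Alignment

logger = logging.getLogger("baitforge")

_ACGT = (b"A"[0], b"C"[0], b"G"[0], b"T"[0])


def _to_array(aln: Alignment) -> np.ndarray:
    """(n_taxa, length) byte matrix view of the alignment."""
    if not aln.rows:
        return np.empty((0, 0), dtype="S1")
    return np.frombuffer(
        "".join(aln.rows).encode("ascii"), dtype="S1"
    ).reshape(aln.n_taxa, aln.length)


def _unambiguous_mask(arr: np.ndarray) -> np.ndarray:
    m = np.zeros(arr.shape, dtype=bool)
    for b in b"ACGT":
        m |= arr == np.bytes_([b])
    return m


def mask_columns(aln: Alignment, max_missing: float = 0.75) -> Alignment:
    """Delete columns where missing data exceeds max_missing (strict).

    Gaps and ambiguity codes both count as missing.  A column at exactly
    the threshold is kept.  Row order is preserved; partition bookkeeping
    does not survive column deletion and is dropped.
    """
    if not 0 < max_missing <= 1:
        raise ValueError("max_missing must be in (0, 1]")
    arr = _to_array(aln)
    if arr.size == 0:
        return aln
    missing_frac = (~_unambiguous_mask(arr)).sum(axis=0) / aln.n_taxa
    keep = missing_frac <= max_missing
    if not keep.any():
        warnings.warn("column masking removed every column")
    kept = arr[:, keep]
    rows = [kept[i].tobytes().decode("ascii") for i in range(aln.n_taxa)]
    logger.info("masking: %d of %d columns kept", int(keep.sum()), aln.length)
    return Alignment(list(aln.taxa), rows)


@dataclass
class PisReport:
    scope: str
    alignment_id: str
    aligned_length: int
    pis: int


def count_pis(aln: Alignment, taxa_subset: Optional[set[str]] = None,
              scope: str = "all", alignment_id: str = "") -> PisReport:
    """Count parsimony-informative sites, optionally on a taxon subset.

    A column is informative iff at least two distinct unambiguous
    nucleotide states each occur in at least two of the (subset) taxa.
    Gaps and ambiguity codes never count as states.
    """
    sub = aln if taxa_subset is None else aln.subset(taxa_subset)
    if sub.n_taxa < 4:
        warnings.warn(
            f"PIS on {sub.n_taxa} taxa: no column can be informative")
    arr = _to_array(sub)
    if arr.size == 0:
        return PisReport(scope, alignment_id, sub.length, 0)
    counts = np.stack([(arr == np.bytes_([b])).sum(axis=0) for b in b"ACGT"])
    pis = int(((counts >= 2).sum(axis=0) >= 2).sum())
    return PisReport(scope, alignment_id, sub.length, pis)


def concatenate(alignments: dict[str, Alignment]) -> Alignment:
    """Concatenate loci into a supermatrix with a partition map.

    Taxa are the union in order of first appearance; a taxon absent from
    a locus is filled with gaps there.
    """
    taxa: list[str] = []
    for aln in alignments.values():
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    offset = 0
    for locus, aln in alignments.items():
        L = aln.length
        lookup = dict(zip(aln.taxa, aln.rows))
        for t in taxa:
            chunks[t].append(lookup.get(t, "-" * L))
        parts.append((locus, offset, offset + L))
        offset += L
    out = Alignment(taxa, ["".join(chunks[t]) for t in taxa],
                    partition_map=parts)
    assert out.length == sum(e - s for _, s, e in parts)
    logger.info("concatenated %d loci, %d taxa, %d columns",
                len(alignments), len(taxa), out.length)
    return out


@dataclass
class DistancePair:
    taxon_a: str
    taxon_b: str
    sites_compared: int
    P: float
    Q: float
    d: float
    defined: bool

    @property
    def p_dist(self) -> float:
        return self.P + self.Q


_TRANSITIONS = {(b"A"[0], b"G"[0]), (b"G"[0], b"A"[0]),
                (b"C"[0], b"T"[0]), (b"T"[0], b"C"[0])}


def k80_distance(seq_a: str, seq_b: str, taxon_a: str = "a",
                 taxon_b: str = "b") -> DistancePair:
    """K80 distance between two equal-length gapped sequences.

    Pairwise deletion: only columns with unambiguous A/C/G/T in both
    sequences are compared.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be equal length")
    a = np.frombuffer(seq_a.upper().encode("ascii"), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode("ascii"), dtype="S1")
    ok = (_unambiguous_mask(a[None, :])[0]
          & _unambiguous_mask(b[None, :])[0])
    n = int(ok.sum())
    if n == 0:
        return DistancePair(taxon_a, taxon_b, 0, 0.0, 0.0, float("nan"), False)
    av, bv = a[ok], b[ok]
    diff = av != bv
    purine = (av == b"A") | (av == b"G")
    purine_b = (bv == b"A") | (bv == b"G")
    transitions = int((diff & (purine == purine_b)).sum())
    transversions = int(diff.sum()) - transitions
    P = transitions / n
    Q = transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return DistancePair(taxon_a, taxon_b, n, P, Q, float("nan"), False)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return DistancePair(taxon_a, taxon_b, n, P, Q, d, True)


def k80_standard_error(pair: DistancePair) -> float:
    """Delta-method standard error of the K80 distance estimate."""
    if not pair.defined or pair.sites_compared == 0:
        return float("nan")
    P, Q, n = pair.P, pair.Q, pair.sites_compared
    a = 1.0 / (1.0 - 2.0 * P - Q)
    b = 0.5 * (a + 1.0 / (1.0 - 2.0 * Q))
    var = (a * a * P + b * b * Q - (a * P + b * Q) ** 2) / n
    return math.sqrt(max(var, 0.0))


def pairwise_k80(aln: Alignment,
                 taxa_subset: Optional[set[str]] = None) -> list[DistancePair]:
    sub = aln if taxa_subset is None else aln.subset(taxa_subset)
    return [
        k80_distance(sub.rows[i], sub.rows[j], sub.taxa[i], sub.taxa[j])
        for i, j in itertools.combinations(range(sub.n_taxa), 2)
    ]


def distance_table(aln: Alignment,
                   taxa_subset: Optional[set[str]] = None) -> pd.DataFrame:
    """Symmetric percent K80 distance matrix, one decimal; NaN where the
    distance is undefined (saturated pair)."""
    sub = aln if taxa_subset is None else aln.subset(taxa_subset)
    if sub.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    mat = pd.DataFrame(0.0, index=sub.taxa, columns=sub.taxa)
    for pair in pairwise_k80(sub):
        val = round(100.0 * pair.d, 1) if pair.defined else float("nan")
        mat.loc[pair.taxon_a, pair.taxon_b] = val
        mat.loc[pair.taxon_b, pair.taxon_a] = val
    return mat


def saturation_slope(aln: Alignment,
                     threshold: float = 0.7) -> tuple[float, bool]:
    """Through-origin slope of p-distance on K80 distance; flag if shallow.

    Requires >=3 defined pairwise distances.  All-zero distances give an
    undefined (NaN) slope and no flag.
    """
    pairs = [p for p in pairwise_k80(aln) if p.defined]
    if len(pairs) < 3:
        raise ValueError(
            f"need >=3 defined pairwise distances, have {len(pairs)}")
    d = np.array([p.d for p in pairs])
    pd_ = np.array([p.p_dist for p in pairs])
    denom = float((d * d).sum())
    if denom == 0.0:
        return float("nan"), False
    slope = float((pd_ * d).sum()) / denom
    return slope, slope < threshold
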