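"""Consensus reconstruction, copy-number estimation and divergence summary.

Copies of a family are multiple-aligned with a progressive aligner (k-mer
guide distances, UPGMA guide tree, profile-profile Needleman-Wunsch), the
majority-rule consensus is taken after deleting majority-gap columns, the
consensus is searched back against the genome to count copies under the
"> 1000 bp and > 90% identity" rule, and per-copy divergence from the
consensus is summarized as a mean Kimura 2-parameter distance +- SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._align import alignment_identity, gapped_rows, kmer_distance, nt_aligner
from .distances import k2p_distance
from .io import AlignmentSet, GenomeAssembly, revcomp

__all__ = [
    "ConsensusElement", "DivergenceSummary", "CopyHit",
    "progressive_align", "build_consensus", "estimate_copy_number",
    "divergence_from_consensus", "species_representative",
]

_GAP_PEN = -2.0
_MATCH = 1.0
_MISMATCH = -1.0


@dataclass
class ConsensusElement:
    """Majority-rule consensus (or the best-hit representative when the
    family has fewer copies than the consensus threshold)."""

    species: str
    sequence: str
    n_support: int
    is_best_hit_representative: bool = False

    def __post_init__(self) -> None:
        if "-" in self.sequence:
            raise ValueError("consensus must be gap-free")
        if self.n_support < 1:
            raise ValueError("n_support must be >= 1")


@dataclass
class DivergenceSummary:
    """Mean K2P divergence from the consensus, as used in per-family
    summary tables (reported as percent +- SE)."""

    mean_divergence: float   # percent
    se: float                # percent
    n: int


@dataclass
class CopyHit:
    contig: str
    start: int
    end: int
    strand: str
    length: int              # aligned columns incl. gaps
    identity: float
    score: float


@njit(cache=True)
def _nw_profile_dp(S, ga, gb):  # pragma: no cover - exercised via wrapper
    la, lb = S.shape
    H = np.zeros((la + 1, lb + 1))
    T = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 0 diag, 1 up, 2 left
    for i in range(1, la + 1):
        H[i, 0] = H[i - 1, 0] + ga[i - 1]
        T[i, 0] = 1
    for j in range(1, lb + 1):
        H[0, j] = H[0, j - 1] + gb[j - 1]
        T[0, j] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            up = H[i - 1, j] + ga[i - 1]
            left = H[i, j - 1] + gb[j - 1]
            best = diag
            move = 0
            if up > best:
                best = up
                move = 1
            if left > best:
                best = left
                move = 2
            H[i, j] = best
            T[i, j] = move
    # traceback
    path = np.empty((la + lb, 2), dtype=np.int64)
    k = 0
    i, j = la, lb
    while i > 0 or j > 0:
        move = T[i, j]
        if move == 0:
            i -= 1
            j -= 1
            path[k, 0] = i
            path[k, 1] = j
        elif move == 1:
            i -= 1
            path[k, 0] = i
            path[k, 1] = -1
        else:
            j -= 1
            path[k, 0] = -1
            path[k, 1] = j
        k += 1
    return path[:k][::-1].copy()


_NT_IDX = {c: i for i, c in enumerate("ACGT")}


def _profile(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(L, 4) base-frequency matrix and per-column non-gap occupancy."""
    length = len(rows[0])
    freq = np.zeros((length, 4))
    occ = np.zeros(length)
    for row in rows:
        for j, c in enumerate(row):
            if c == "-":
                continue
            occ[j] += 1.0
            if c in _NT_IDX:
                freq[j, _NT_IDX[c]] += 1.0
    n = len(rows)
    return freq / n, occ / n


def _merge_profiles(rows_a: list[str], rows_b: list[str]) -> list[str]:
    fa, occ_a = _profile(rows_a)
    fb, occ_b = _profile(rows_b)
    M = np.full((4, 4), _MISMATCH)
    np.fill_diagonal(M, _MATCH)
    S = fa @ M @ fb.T
    ga = _GAP_PEN * occ_a
    gb = _GAP_PEN * occ_b
    path = _nw_profile_dp(S, ga, gb)
    out_a = ["".join(r[i] if i >= 0 else "-" for i, _ in path) for r in rows_a]
    out_b = ["".join(r[j] if j >= 0 else "-" for _, j in path) for r in rows_b]
    return out_a + out_b


def progressive_align(seqs: dict[str, str] | Sequence[tuple[str, str]]
                      ) -> AlignmentSet:
    """Progressive multiple alignment of unaligned nucleotide sequences.

    Guide distances are shared-k-mer distances, clustered by UPGMA; merges
    are profile-profile Needleman-Wunsch (match +1 / mismatch -1 / linear
    gap -2, occupancy-weighted). Deterministic for a fixed input order.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if not items:
        raise ValueError("no sequences to align")
    labels = [k for k, _ in items]
    if len(items) == 1:
        return AlignmentSet(taxa=labels, rows=[items[0][1]])
    n = len(items)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = kmer_distance(items[i][1], items[j][1])
    Z = linkage(squareform(dm, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([labels[i]], [items[i][1]]) for i in range(n)}
    for step, (a, b, _dist, _cnt) in enumerate(Z):
        la, ra = clusters.pop(int(a))
        lb, rb = clusters.pop(int(b))
        merged = _merge_profiles(ra, rb)
        clusters[n + step] = (la + lb, merged[:len(ra)] + merged[len(ra):])
    (final_labels, final_rows), = clusters.values()
    order = [final_labels.index(l) for l in labels]
    return AlignmentSet(taxa=labels, rows=[final_rows[i] for i in order])


def build_consensus(alignment: AlignmentSet, species: str = "consensus",
                    gap_rule: str = "majority") -> ConsensusElement:
    """Majority-rule consensus after gap-column removal.

    Columns where gaps are in the majority are deleted ("majority" rule;
    "any" deletes every column containing a gap); remaining columns emit
    the plurality base, ties resolved to the base of the first row holding
    a tied base. N never votes. The output is gap-free.
    """
    rows = alignment.rows
    n = len(rows)
    if n == 0:
        raise ValueError("empty alignment")
    out = []
    for j in range(alignment.length):
        col = [r[j] for r in rows]
        gaps = col.count("-")
        if gap_rule == "any" and gaps > 0:
            continue
        if 2 * gaps > n:
            continue
        counts: dict[str, int] = {}
        for c in col:
            if c in "ACGT":
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            if gaps == n:
                continue
            continue  # all-N column carries no information
        top = max(counts.values())
        tied = {b for b, c in counts.items() if c == top}
        if len(tied) == 1:
            out.append(tied.pop())
        else:
            out.append(next(c for c in col if c in tied))
    if not out:
        raise ValueError("consensus is empty (all-gap alignment?)")
    return ConsensusElement(species=species, sequence="".join(out),
                            n_support=n)


def _seed_windows_nt(query: str, target: str, k: int, pad: int) -> list[tuple[int, int]]:
    index = set()
    for i in range(len(query) - k + 1):
        index.add(query[i:i + k])
    hits = [j for j in range(len(target) - k + 1) if target[j:j + k] in index]
    if not hits:
        return []
    windows: list[list[int]] = []
    for j in hits:
        if windows and j - windows[-1][1] <= len(query):
            windows[-1][1] = j
        else:
            windows.append([j, j])
    return [(max(0, a - pad), min(len(target), b + k + pad)) for a, b in windows]


def _window_hits(query: str, contig: str, contig_id: str, strand: str,
                 aligner, lo: int, hi: int, min_keep: int,
                 depth: int = 0) -> list[CopyHit]:
    """Best local hit in contig[lo:hi], recursing left and right of it so
    several copies sharing one seed window are all reported."""
    if hi - lo < min_keep or depth > 8:
        return []
    window = contig[lo:hi]
    alns = aligner.align(query, window)
    if len(alns) == 0 or alns.score <= min_keep * 0.2:
        return []
    aln = alns[0]
    ident, compared = alignment_identity(aln, query, window)
    if compared == 0:
        return []
    tb = aln.aligned[1]
    t0, t1 = int(tb[0][0]), int(tb[-1][1])
    qb = aln.aligned[0]
    q_span = int(qb[-1][1]) - int(qb[0][0])
    aln_len = max(t1 - t0, q_span)  # aligned span incl. gaps
    out = [CopyHit(contig=contig_id, start=lo + t0, end=lo + t1,
                   strand=strand, length=aln_len,
                   identity=ident / compared, score=float(aln.score))]
    out += _window_hits(query, contig, contig_id, strand, aligner,
                        lo, lo + t0, min_keep, depth + 1)
    out += _window_hits(query, contig, contig_id, strand, aligner,
                        lo + t1, hi, min_keep, depth + 1)
    return out


def _local_nt_hits(consensus: str, contig: str, contig_id: str, strand: str,
                   aligner, k: int = 11, min_keep: int = 200) -> list[CopyHit]:
    query = consensus if strand == "+" else revcomp(consensus)
    out = []
    for lo, hi in _seed_windows_nt(query, contig, k, pad=len(consensus) // 2):
        out.extend(_window_hits(query, contig, contig_id, strand, aligner,
                                lo, hi, min_keep))
    return out


def estimate_copy_number(consensus: ConsensusElement, genome: GenomeAssembly,
                         min_len: int = 1000, min_ident: float = 0.90
                         ) -> tuple[int, list[CopyHit]]:
    """Count genomic loci matching the consensus.

    Seeded (exact 11-mer) local nucleotide alignment on both strands;
    a locus counts when its alignment spans strictly more than ``min_len``
    columns at strictly more than ``min_ident`` identity (identity over
    aligned columns, N excluded). Overlapping hits (> 50% reciprocal)
    are resolved best-score-first.
    """
    if len(consensus.sequence) < min_len:
        raise ValueError("consensus shorter than the copy length threshold")
    aligner = nt_aligner("local", match=1.0, mismatch=-2.0, gap=-3.0)
    raw: list[CopyHit] = []
    for contig_id, contig in genome.items():
        for strand in "+-":
            raw.extend(_local_nt_hits(consensus.sequence, contig, contig_id,
                                      strand, aligner))
    raw.sort(key=lambda h: (-h.score, h.contig, h.start))
    kept: list[CopyHit] = []
    for h in raw:
        overlap_frac = 0.0
        for k2 in kept:
            if k2.contig != h.contig:
                continue
            ov = min(h.end, k2.end) - max(h.start, k2.start)
            if ov > 0:
                overlap_frac = max(overlap_frac,
                                   ov / min(h.end - h.start, k2.end - k2.start))
        if overlap_frac > 0.5:
            continue
        kept.append(h)
    passing = [h for h in kept if h.length > min_len and h.identity > min_ident]
    passing.sort(key=lambda h: (h.contig, h.start))
    return len(passing), passing


def divergence_from_consensus(copies: dict[str, str] | Sequence[str],
                              consensus: ConsensusElement
                              ) -> Optional[DivergenceSummary]:
    """Mean +- SE of per-copy K2P distances to the consensus (percent).

    Each copy is globally aligned to the consensus first. Saturated copies
    are skipped with a warning; with fewer than two usable copies the
    average is undefined (None), mirroring low-copy-number families whose
    divergence cannot be determined.
    """
    seqs = list(copies.values()) if isinstance(copies, dict) else list(copies)
    aligner = nt_aligner("global")
    dists = []
    for seq in seqs:
        aln = aligner.align(consensus.sequence, seq)[0]
        ga, gb = gapped_rows(aln, consensus.sequence, seq)
        res = k2p_distance(ga, gb, aligned=True)
        if not res.defined:
            warnings.warn("saturated copy skipped in divergence summary")
            continue
        dists.append(res.d)
    if len(dists) < 2:
        return None
    arr = np.asarray(dists)
    return DivergenceSummary(
        mean_divergence=float(arr.mean() * 100),
        se=float(arr.std(ddof=1) / np.sqrt(arr.size) * 100),
        n=arr.size)


def species_representative(copies: dict[str, str], genome: GenomeAssembly,
                           species: str, consensus_min_copies: int = 10,
                           best_hit: Optional[str] = None
                           ) -> ConsensusElement:
    """Species-level representative sequence.

    With at least ``consensus_min_copies`` copies the majority-rule
    consensus of their multiple alignment is used; below that the
    best-scoring genomic hit stands in as the representative.
    """
    if len(copies) >= consensus_min_copies:
        aln = progressive_align(copies)
        cons = build_consensus(aln, species=species)
        return cons
    if best_hit is None:
        best_hit = next(iter(copies.values()))
    return ConsensusElement(species=species, sequence=best_hit,
                            n_support=len(copies),
                            is_best_hit_representative=True)
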