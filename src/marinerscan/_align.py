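"""Shared pairwise-alignment plumbing.

Thin factories around Bio.Align.PairwiseAligner plus small utilities to
walk aligned column pairs. Scoring conventions used across the package:

* protein: BLOSUM62, gap open -11 / extend -1 (translated-search practice);
  triad transfer uses open -10 / extend -1 global.
* nucleotide: match +1 / mismatch -1 / linear gap -2; N scores 0 against
  everything so ambiguous positions never count as matches.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterator

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

_NT_ORDER = "ACGTN"


@lru_cache(maxsize=None)
def _nt_matrix(match: float, mismatch: float) -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet=_NT_ORDER, dims=2)
    for a in _NT_ORDER:
        for b in _NT_ORDER:
            if a == "N" or b == "N":
                m[a, b] = 0.0
            else:
                m[a, b] = match if a == b else mismatch
    return m


def nt_aligner(mode: str = "global", match: float = 1.0, mismatch: float = -1.0,
               gap: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _nt_matrix(match, mismatch)
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def protein_aligner(mode: str = "local", open_gap: float = -11.0,
                    extend_gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def aligned_pairs(alignment) -> Iterator[tuple[int, int]]:
    """Yield (i, j) index pairs of aligned (non-gap) columns."""
    blocks_a, blocks_b = alignment.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for k in range(a1 - a0):
            yield a0 + k, b0 + k


def alignment_identity(alignment, a: str, b: str, *, skip_n: bool = True) -> tuple[int, int]:
    """(identical, compared) over aligned columns; N never matches."""
    ident = compared = 0
    for i, j in aligned_pairs(alignment):
        x, y = a[i], b[j]
        if skip_n and ("N" in (x, y)):
            continue
        compared += 1
        if x == y:
            ident += 1
    return ident, compared


def gapped_rows(alignment, a: str, b: str) -> tuple[str, str]:
    """Render a pairwise alignment as two equal-length gapped strings."""
    ra, rb = [], []
    pa = pb = 0
    for i, j in aligned_pairs(alignment):
        while pa < i:
            ra.append(a[pa]); rb.append("-"); pa += 1
        while pb < j:
            ra.append("-"); rb.append(b[pb]); pb += 1
        ra.append(a[i]); rb.append(b[j]); pa, pb = i + 1, j + 1
    # global mode: trailing overhangs
    while pa < len(a):
        ra.append(a[pa]); rb.append("-"); pa += 1
    while pb < len(b):
        ra.append("-"); rb.append(b[pb]); pb += 1
    return "".join(ra), "".join(rb)


def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def kmer_distance(a: str, b: str, k: int = 8) -> float:
    """1 − shared-k-mer fraction; cheap guide-tree distance proxy."""
    sa, sb = kmer_set(a, k), kmer_set(b, k)
    if not sa or not sb:
        return 1.0
    return 1.0 - len(sa & sb) / min(len(sa), len(sb))


def seed_positions(query: str, target: str, k: int) -> list[tuple[int, int]]:
    """Exact shared k-mer (query_pos, target_pos) pairs."""
    index: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        index.setdefault(query[i:i + k], []).append(i)
    out = []
    for j in range(len(target) - k + 1):
        for i in index.get(target[j:j + k], ()):
            out.append((i, j))
    return out


def sample_substitution(base_idx: np.ndarray, t: float, kappa: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Evolve encoded bases (0..3 = A,C,G,T) for time t under K2P.

    Rates normalized so t is the expected substitutions/site. Transition
    partners: A<->G, C<->T.
    """
    if t <= 0:
        return base_idx.copy()
    e4b = np.exp(-4.0 * t / (kappa + 2.0))
    e2ab = np.exp(-2.0 * t * (kappa + 1.0) / (kappa + 2.0))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab        # to the transition partner
    p_tv = 0.25 - 0.25 * e4b                      # to each transversion partner
    n = base_idx.size
    u = rng.random(n)
    out = base_idx.copy()
    # partner tables indexed by base: transition partner, two transversions
    ts_partner = np.array([2, 3, 0, 1])           # A<->G, C<->T
    tv1 = np.array([1, 0, 1, 0])                  # A->C, C->A, G->C, T->A
    tv2 = np.array([3, 2, 3, 2])                  # A->T, C->G, G->T, T->G
    ts_mask = u < p_ts
    tv1_mask = (~ts_mask) & (u < p_ts + p_tv)
    tv2_mask = (~ts_mask) & (~tv1_mask) & (u < p_ts + 2 * p_tv)
    out[ts_mask] = ts_partner[base_idx[ts_mask]]
    out[tv1_mask] = tv1[base_idx[tv1_mask]]
    out[tv2_mask] = tv2[base_idx[tv2_mask]]
    return out


_NT_TO_IDX = {c: i for i, c in enumerate("ACGT")}


def encode_nt(seq: str) -> np.ndarray:
    return np.array([_NT_TO_IDX[c] for c in seq], dtype=np.int64)


def decode_nt(idx: np.ndarray) -> str:
    lut = np.array(list("ACGT"))
    return "".join(lut[idx])
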