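"""Element hallmark annotation: TIRs, TA TSD, ORF, catalytic triad, status.

Tc1/mariner elements carry a terminal inverted repeat (TIR) at each end, a
TA target-site duplication immediately outside the element, and a single
transposase ORF whose DDE/D catalytic triad spacing (residues between the
second D and the final D/E, e.g. 36 in DD36E) names the family. Copies are
classified as intact (two TIRs + triad-bearing ORF), full_length (two TIRs),
MITE (short TIR-bearing derivative without a qualifying ORF), or truncated.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from ._align import protein_aligner, aligned_pairs
from .io import revcomp
from .mining import ElementCopy

__all__ = [
    "TIRPair", "TSD", "CatalyticTriad", "ReferenceTransposase",
    "find_tirs", "check_tsd", "find_longest_orf", "detect_triad",
    "scan_grpr", "classify_status", "refine_boundaries", "annotate_copy",
]

_TIR_MISMATCH_PENALTY = 2.0  # local-alignment mismatch cost, match = +1
_ANCHOR_SLACK = 5            # TIR must start within this many nt of a terminus
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class TIRPair:
    """Ungapped inverted-repeat match between the two element termini."""

    left_start_offset: int    # offset of the left TIR start from the 5' end
    right_end_offset: int     # offset of the right TIR end from the 3' end
    length: int
    mismatches: int


@dataclass
class TSD:
    """Dinucleotides immediately outside the element on both sides."""

    left_copy: str
    right_copy: str

    @property
    def is_TA(self) -> bool:
        return self.left_copy == "TA" and self.right_copy == "TA"


@dataclass
class CatalyticTriad:
    """D, D, E/D residue positions in a transposase (0-based)."""

    d1_pos: int
    d2_pos: int
    e3_pos: int
    third_residue: str

    def __post_init__(self) -> None:
        if not self.d1_pos < self.d2_pos < self.e3_pos:
            raise ValueError("triad positions out of order")
        if self.third_residue not in ("D", "E"):
            raise ValueError("third residue must be D or E")

    @property
    def spacer1(self) -> int:
        return self.d2_pos - self.d1_pos - 1

    @property
    def spacer2(self) -> int:
        return self.e3_pos - self.d2_pos - 1

    @property
    def family_label(self) -> str:
        return f"DD{self.spacer2}{self.third_residue}"


@dataclass
class ReferenceTransposase:
    """A curated transposase whose triad columns are annotated."""

    name: str
    sequence: str
    triad: CatalyticTriad


def _terminal_best_alignment(seq: str, window: int):
    """Optimal ungapped local alignment of the 5' window vs the
    reverse-complemented 3' window, anchored within _ANCHOR_SLACK nt of
    each terminus. Returns (score, a, b, length, mismatches) or None.

    Scoring: match +1, mismatch -2 (N never matches). The maximal-scoring
    prefix of each anchored diagonal is taken, so a perfect repeat is not
    extended into unrelated interior sequence.
    """
    n = len(seq)
    w = min(window, n // 2)
    left = seq[:w]
    right_rc = "".join(_COMP.get(c, "N") for c in reversed(seq[n - w:]))
    best = None
    for a in range(_ANCHOR_SLACK + 1):
        for b in range(_ANCHOR_SLACK + 1):
            score = 0.0
            mism = 0
            run_best = None  # (score, L, mismatches)
            max_l = min(w - a, w - b)
            for k in range(max_l):
                x, y = left[a + k], right_rc[b + k]
                if x != "N" and x == y:
                    score += 1.0
                else:
                    score -= _TIR_MISMATCH_PENALTY
                    mism += 1
                if run_best is None or score > run_best[0]:
                    run_best = (score, k + 1, mism)
            if run_best is None:
                continue
            cand = (run_best[0], -run_best[2], run_best[1], -a, -b)
            if best is None or cand > best[0]:
                best = (cand, a, b, run_best[1], run_best[2])
    if best is None:
        return None
    (_, a, b, length, mism) = best
    return best[0][0], a, b, length, mism


def find_tirs(copy: ElementCopy | str, min_len: int = 20,
              max_mismatch_frac: float = 0.1,
              search_window: int = 150) -> Optional[TIRPair]:
    """Locate the terminal inverted repeat pair of an element.

    The element's first ``search_window`` nt are locally aligned (ungapped)
    against the reverse complement of its last ``search_window`` nt; the
    best alignment anchored within 5 nt of each terminus is accepted if it
    reaches ``min_len`` aligned columns at a mismatch fraction no greater
    than ``max_mismatch_frac``. Absence is a valid result.
    """
    seq = copy if isinstance(copy, str) else copy.sequence
    if len(seq) < 2 * min_len:
        return None
    hit = _terminal_best_alignment(seq, search_window)
    if hit is None:
        return None
    _score, a, b, length, mism = hit
    if length < min_len or mism > max_mismatch_frac * length:
        return None
    return TIRPair(left_start_offset=a, right_end_offset=b,
                   length=length, mismatches=mism)


def check_tsd(copy: ElementCopy) -> Optional[TSD]:
    """Read the putative TSD: last 2 nt of the left flank and first 2 of
    the right flank. Returns None (with a warning) at contig edges."""
    if len(copy.left_flank) < 2 or len(copy.right_flank) < 2:
        warnings.warn("flank shorter than 2 nt; TSD undetermined")
        return None
    return TSD(left_copy=copy.left_flank[-2:], right_copy=copy.right_flank[:2])


def _orfs_in_frame(prot: str):
    """(start_aa, protein) for every ATG-to-stop ORF in a translated frame."""
    out = []
    i = 0
    while True:
        m = prot.find("M", i)
        if m == -1:
            break
        stop = prot.find("*", m)
        if stop == -1:
            break
        out.append((m, prot[m:stop]))
        i = m + 1
    return out


def find_longest_orf(seq: str, min_aa: int = 300) -> Optional[str]:
    """Longest ATG-to-stop ORF over all six frames, as a protein string.

    Requires a stop codon (the ORF must be complete). Ties break to the
    leftmost start on '+' before '-'. Returns None when no ORF reaches
    ``min_aa`` residues.
    """
    if len(seq) < 3:
        return None
    rc = revcomp(seq)
    candidates = []  # (length, strand_rank, nt_start_on_searched_strand, prot)
    for strand_rank, src in ((0, seq), (1, rc)):
        for frame in range(3):
            core = src[frame:frame + 3 * ((len(src) - frame) // 3)]
            prot = str(Seq(core).translate())
            for aa_start, p in _orfs_in_frame(prot):
                if len(p) >= min_aa:
                    candidates.append((len(p), strand_rank,
                                       frame + 3 * aa_start, p))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    return candidates[0][3]


def detect_triad(protein: str, references: Sequence[ReferenceTransposase]
                 ) -> Optional[CatalyticTriad]:
    """Transfer annotated D/D/E(D) columns from the best-matching reference.

    The query is globally aligned (BLOSUM62, gap open -10 / extend -1) to
    each reference; the highest-scoring reference (ties by reference order)
    donates its triad columns. The triad is reported only if all three
    transferred positions carry D/D/(D or E) in the query.
    """
    if not references:
        raise ValueError("empty reference set")
    aligner = protein_aligner("global", open_gap=-10.0, extend_gap=-1.0)
    best = None
    for order, ref in enumerate(references):
        alns = aligner.align(protein, ref.sequence)
        if len(alns) == 0:
            continue
        score = alns.score
        if score <= 0:
            continue
        if best is None or score > best[0]:
            best = (score, order, ref, alns[0])
    if best is None:
        return None
    _, _, ref, aln = best
    ref_to_query = {j: i for i, j in aligned_pairs(aln)}
    t = ref.triad
    pos = [ref_to_query.get(p) for p in (t.d1_pos, t.d2_pos, t.e3_pos)]
    if any(p is None for p in pos):
        return None
    d1, d2, e3 = pos
    if protein[d1] != "D" or protein[d2] != "D" or protein[e3] not in "DE":
        return None
    return CatalyticTriad(d1_pos=d1, d2_pos=d2, e3_pos=e3,
                          third_residue=protein[e3])


_GRPR_RE = re.compile("(?=GR[PK]R)")


def scan_grpr(protein: str) -> list[int]:
    """Positions of GRPR and single-substitution GRPR-like (G-R-[PK]-R)
    matches, in order."""
    return [m.start() for m in _GRPR_RE.finditer(protein)]


def classify_status(copy: ElementCopy,
                    full_len_range: tuple[int, int] = (1000, 1500),
                    mite_max_orf_aa: int = 300,
                    orf_min_aa: int = 300) -> str:
    """Total, mutually exclusive status classification.

    intact: two TIRs plus an ORF of >= orf_min_aa residues with a detected
    triad; MITE: two TIRs, total length below the full-length minimum and
    no ORF reaching mite_max_orf_aa; full_length: two TIRs otherwise;
    truncated: everything else.
    """
    has_tirs = copy.tir is not None
    orf_len = len(copy.orf_aa) if copy.orf_aa else 0
    if has_tirs and copy.family_label and orf_len >= orf_min_aa:
        return "intact"
    if has_tirs and len(copy.sequence) < full_len_range[0] and orf_len < mite_max_orf_aa:
        return "MITE"
    if has_tirs:
        return "full_length"
    return "truncated"


# --- boundary refinement ---------------------------------------------------

def _tir_score_at(window: str, p: int, q: int, search_window: int,
                  seed_len: int = 0, seed_max_mism: int = 0):
    """Best ungapped TIR alignment with the left TIR starting exactly at p
    and the right TIR ending exactly at q. Returns (score, L, mismatches).

    When ``seed_len`` is set, candidates whose first ``seed_len`` columns
    exceed ``seed_max_mism`` mismatches are rejected early (fast path for
    boundary scanning)."""
    w = min(search_window, (q - p) // 2)
    if seed_len and w >= seed_len:
        mism = 0
        for k in range(seed_len):
            x = window[p + k]
            y = _COMP.get(window[q - 1 - k], "N")
            if x == "N" or x != y:
                mism += 1
                if mism > seed_max_mism:
                    return None
    best = None
    score = 0.0
    mism = 0
    for k in range(w):
        x = window[p + k]
        y = _COMP.get(window[q - 1 - k], "N")
        if x != "N" and x == y:
            score += 1.0
        else:
            score -= _TIR_MISMATCH_PENALTY
            mism += 1
        if best is None or score > best[0]:
            best = (score, k + 1, mism)
    return best


def refine_boundaries(copy: ElementCopy, min_len: int = 20,
                      max_mismatch_frac: float = 0.1,
                      search_window: int = 150,
                      max_element_len: int = 4000) -> ElementCopy:
    """Resolve element boundaries around a mined hit.

    A mined hit covers only the transposase-homologous core; the true
    element extends into the extracted flanks up to the TIRs, which abut
    the TA target-site duplication. Candidate boundaries are TA-anchored
    positions in the flanks; the pair with the best terminal inverted-repeat
    alignment (subject to the usual min-length and mismatch bounds) wins.
    Copies without a qualifying TIR pair (e.g. truncated ones) are returned
    unchanged.
    """
    window = copy.left_flank + copy.sequence + copy.right_flank
    llen = len(copy.left_flank)
    core_end = llen + len(copy.sequence)
    # element start candidates: TA just before p, p in the left flank
    # (allow a small overhang into the hit); element end candidates: TA at q
    lefts = [p for p in range(2, llen + 11)
             if window[p - 2:p] == "TA"]
    rights = [q for q in range(max(core_end - 10, 0), len(window) - 1)
              if window[q:q + 2] == "TA"]
    seed_max_mism = int(max_mismatch_frac * min_len)
    best = None
    for p in lefts:
        for q in rights:
            if not (2 * min_len <= q - p <= max_element_len):
                continue
            hit = _tir_score_at(window, p, q, search_window,
                                seed_len=min_len, seed_max_mism=seed_max_mism)
            if hit is None:
                continue
            score, length, mism = hit
            if length < min_len or mism > max_mismatch_frac * length:
                continue
            cand = (score, -mism, -p, q)
            if best is None or cand > best[0]:
                best = (cand, p, q)
    if best is None:
        return copy
    _, p, q = best
    if copy.strand == "+":
        g0 = copy.start - llen + p
        g1 = copy.start - llen + q
    else:
        g0 = copy.end + llen - q
        g1 = copy.end + llen - p
    return ElementCopy(
        contig=copy.contig, start=g0, end=g1, strand=copy.strand,
        sequence=window[p:q], left_flank=window[:p], right_flank=window[q:],
        status="unclassified")


def annotate_copy(copy: ElementCopy,
                  references: Sequence[ReferenceTransposase],
                  min_len: int = 20, max_mismatch_frac: float = 0.1,
                  search_window: int = 150,
                  full_len_range: tuple[int, int] = (1000, 1500),
                  mite_max_orf_aa: int = 300,
                  orf_min_aa: int = 300) -> ElementCopy:
    """Run the full hallmark annotation on a boundary-resolved copy,
    filling tir/tsd/orf/triad/grpr fields and the final status in place."""
    copy.tir = find_tirs(copy, min_len, max_mismatch_frac, search_window)
    copy.tsd = check_tsd(copy)
    copy.orf_aa = find_longest_orf(copy.sequence, min_aa=1)
    copy.family_label = None
    copy.grpr_pos = []
    if copy.orf_aa:
        triad = detect_triad(copy.orf_aa, references)
        if triad is not None:
            copy.family_label = triad.family_label
        copy.grpr_pos = scan_grpr(copy.orf_aa)
    copy.status = classify_status(copy, full_len_range, mite_max_orf_aa,
                                  orf_min_aa)
    return copy
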