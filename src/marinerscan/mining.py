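"""Translated homology mining: find transposase-coding loci in a genome.

A desk-scale reimplementation of a protein-vs-translated-DNA (tblastn-style)
search: exact amino-acid k-mer seeds locate candidate regions in all six
reading frames, which are then aligned with BLOSUM62-scored local dynamic
programming. Hits are mapped back to forward-strand genome coordinates and
extracted together with flanking sequence for boundary annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from ._align import protein_aligner, aligned_pairs
from .io import GenomeAssembly, AlphabetError, revcomp

__all__ = [
    "TranslatedHit",
    "ElementCopy",
    "six_frame_translate",
    "translated_search",
    "extract_with_flanks",
    "dedupe_copies",
]

_AA_QUERY = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class TranslatedHit:
    """One protein-vs-genome local alignment, in forward-strand coordinates."""

    contig: str
    strand: str            # '+' or '-'
    frame: int             # 0..2, offset on the searched strand
    nt_start: int          # 0-based half-open, forward strand
    nt_end: int
    aa_score: float
    aa_identity: float
    query_id: str = ""

    def __post_init__(self) -> None:
        if self.nt_end <= self.nt_start:
            raise ValueError("empty hit interval")
        if not 0.0 <= self.aa_identity <= 1.0:
            raise ValueError("identity out of [0,1]")

    @property
    def length(self) -> int:
        return self.nt_end - self.nt_start


@dataclass
class ElementCopy:
    """One genomic occurrence of a candidate element.

    The sequence is stored in transposase-sense orientation: for '-' strand
    copies it is the reverse complement of the genome slice and the flanks
    are swapped so that ``left_flank`` always precedes the element 5'->3'
    in element orientation.
    """

    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    left_flank: str = ""
    right_flank: str = ""
    status: str = "unclassified"
    tir: Optional[object] = None          # annotation.TIRPair
    tsd: Optional[object] = None          # annotation.TSD
    orf_aa: Optional[str] = None
    family_label: Optional[str] = None
    grpr_pos: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("coordinate span does not match sequence length")


_FRAME_STRANDS = [("+", 0), ("+", 1), ("+", 2), ("-", 0), ("-", 1), ("-", 2)]


def six_frame_translate(seq: str) -> list[tuple[str, int, str]]:
    """Translate all six reading frames.

    Returns (strand, frame, protein) triples; stops are '*', codons with N
    become 'X'. Reverse frames are translated from the reverse complement,
    so frame f on '-' starts f nucleotides from the 3' end of the input.
    """
    if len(seq) < 3:
        warnings.warn("sequence shorter than one codon; no frames translated")
        return []
    rc = revcomp(seq)
    out = []
    for strand, frame in _FRAME_STRANDS:
        src = seq if strand == "+" else rc
        core = src[frame:frame + 3 * ((len(src) - frame) // 3)]
        prot = str(Seq(core).translate())
        out.append((strand, frame, prot))
    return out


def _aa_to_nt_interval(strand: str, frame: int, aa_start: int, aa_end: int,
                       contig_len: int) -> tuple[int, int]:
    """Map an aa interval in a translated frame to forward-strand nt coords."""
    s = frame + 3 * aa_start
    e = frame + 3 * aa_end
    if strand == "+":
        return s, e
    return contig_len - e, contig_len - s


def _seed_windows(query: str, prot: str, word_len: int, pad: int) -> list[tuple[int, int]]:
    """Candidate aa windows of the target around exact k-mer seeds."""
    index: dict[str, bool] = {query[i:i + word_len]: True
                              for i in range(len(query) - word_len + 1)}
    hits = [j for j in range(len(prot) - word_len + 1)
            if prot[j:j + word_len] in index]
    if not hits:
        return []
    windows: list[list[int]] = []
    gap = 2 * len(query)
    for j in hits:
        if windows and j - windows[-1][1] <= gap:
            windows[-1][1] = j
        else:
            windows.append([j, j])
    return [(max(0, a - pad), min(len(prot), b + word_len + pad))
            for a, b in windows]


def _local_hits(aligner, query: str, prot: str, lo: int, hi: int,
                min_score: float, depth: int = 0) -> list[tuple[int, int, float, float]]:
    """Best local alignment in prot[lo:hi], recursing left/right of it.

    Recursion lets one seed window yield several non-overlapping copies.
    Returns (aa_start, aa_end, score, identity) tuples in prot coordinates.
    """
    if hi - lo < len(query) // 4 or depth > 6:
        return []
    window = prot[lo:hi]
    alns = aligner.align(query, window)
    if len(alns) == 0 or alns.score < min_score:
        return []
    aln = alns[0]
    ident = compared = 0
    for i, j in aligned_pairs(aln):
        compared += 1
        if query[i] == window[j]:
            ident += 1
    blocks = aln.aligned[1]
    t0, t1 = int(blocks[0][0]), int(blocks[-1][1])
    out = [(lo + t0, lo + t1, float(aln.score),
            ident / compared if compared else 0.0)]
    out += _local_hits(aligner, query, prot, lo, lo + t0, min_score, depth + 1)
    out += _local_hits(aligner, query, prot, lo + t1, hi, min_score, depth + 1)
    return out


def _merge_hits(hits: list[TranslatedHit], merge_nt: int = 50) -> list[TranslatedHit]:
    """Merge overlapping/nearby hits on the same contig+strand+frame.

    The best-scoring hit's envelope wins; ties break to the leftmost
    coordinate, then '+' before '-'.
    """
    keyed: dict[tuple[str, str, int], list[TranslatedHit]] = {}
    for h in hits:
        keyed.setdefault((h.contig, h.strand, h.frame), []).append(h)
    merged: list[TranslatedHit] = []
    for group in keyed.values():
        group.sort(key=lambda h: h.nt_start)
        cluster = [group[0]]
        for h in group[1:]:
            if h.nt_start <= max(c.nt_end for c in cluster) + merge_nt:
                cluster.append(h)
            else:
                merged.append(max(cluster, key=lambda c: c.aa_score))
                cluster = [h]
        merged.append(max(cluster, key=lambda c: c.aa_score))
    merged.sort(key=lambda h: (-h.aa_score, h.nt_start, 0 if h.strand == "+" else 1))
    return merged


def translated_search(query: str, genome: GenomeAssembly, word_len: int = 4,
                      min_score: float = 80.0, query_id: str = "query") -> list[TranslatedHit]:
    """Search a protein against all six translated frames of a genome.

    Exact ``word_len``-mer seeds nominate candidate windows; each window is
    scored by BLOSUM62 local alignment (gap open -11 / extend -1) and kept
    if the score reaches ``min_score``. Output is sorted by descending
    score and deterministic for fixed inputs.
    """
    query = query.upper()
    bad = set(query) - _AA_QUERY
    if bad:
        raise AlphabetError(f"query contains non-amino-acid characters: {sorted(bad)}")
    if len(query) < word_len:
        raise ValueError("query shorter than seed word length")
    aligner = protein_aligner("local")
    pad = len(query) + 10
    hits: list[TranslatedHit] = []
    for contig, seq in genome.items():
        if len(seq) < 3:
            continue
        for strand, frame, prot in six_frame_translate(seq):
            for lo, hi in _seed_windows(query, prot, word_len, pad):
                for a0, a1, score, ident in _local_hits(
                        aligner, query, prot, lo, hi, min_score):
                    s, e = _aa_to_nt_interval(strand, frame, a0, a1, len(seq))
                    hits.append(TranslatedHit(
                        contig=contig, strand=strand, frame=frame,
                        nt_start=s, nt_end=e, aa_score=score,
                        aa_identity=ident, query_id=query_id))
    return _merge_hits(hits)


def extract_with_flanks(hit: TranslatedHit, genome: GenomeAssembly,
                        flank_bp: int = 2000) -> ElementCopy:
    """Extract the hit span plus up to ``flank_bp`` of flank on each side.

    Flanks are clipped at contig boundaries. '-' strand hits are returned
    in transposase-sense orientation: the sequence is reverse-complemented
    and the flanks are swapped (each flank itself reverse-complemented).
    """
    if hit.contig not in genome:
        raise KeyError(f"contig {hit.contig!r} not in assembly")
    seq = genome[hit.contig]
    if hit.nt_end > len(seq):
        raise ValueError("hit extends past contig end")
    left = seq[max(0, hit.nt_start - flank_bp):hit.nt_start]
    core = seq[hit.nt_start:hit.nt_end]
    right = seq[hit.nt_end:hit.nt_end + flank_bp]
    if hit.strand == "-":
        left, core, right = revcomp(right), revcomp(core), revcomp(left)
    return ElementCopy(
        contig=hit.contig, start=hit.nt_start, end=hit.nt_end,
        strand=hit.strand, sequence=core,
        left_flank=left, right_flank=right, status="unclassified")


def dedupe_copies(copies: list[ElementCopy],
                  max_overlap: float = 0.5) -> list[ElementCopy]:
    """Collapse copies describing the same locus.

    A single element can yield several hits (one per reading frame of a
    fragmented transposase); after boundary resolution these converge on
    the same interval. Copies overlapping an already kept copy by more
    than ``max_overlap`` of the shorter interval are dropped, first kept
    wins (input order, i.e. descending mining score)."""
    kept: list[ElementCopy] = []
    for c in copies:
        dup = False
        for k in kept:
            if k.contig != c.contig:
                continue
            ov = min(c.end, k.end) - max(c.start, k.start)
            if ov > 0 and ov > max_overlap * min(c.end - c.start,
                                                 k.end - k.start):
                dup = True
                break
        if not dup:
            kept.append(c)
    return kept
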