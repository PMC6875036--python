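"""Readers and writers for the external formats the pipeline touches.

Genomes, protein sets and element libraries travel as FASTA; multiple
alignments as aligned FASTA or Clustal; element coordinates as BED6
(0-based, half-open); per-copy reports as TSV. Every other module consumes
and produces only the containers defined here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeAssembly",
    "AlignmentSet",
    "PipelineConfig",
    "FastaParseError",
    "AlphabetError",
    "AlignmentShapeError",
    "read_fasta",
    "read_alignment",
    "write_outputs",
    "revcomp",
]

_NT_CHARS = frozenset("ACGTN")
# 20 canonical residues plus X (unknown) and * (stop, from in-silico translation)
_AA_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


class FastaParseError(ValueError):
    """Malformed FASTA; message carries the offending line number."""


class AlphabetError(ValueError):
    """Sequence contains characters outside the declared alphabet."""


class AlignmentShapeError(ValueError):
    """Alignment rows are not all the same length."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return str(Seq(seq).reverse_complement())


@dataclass
class GenomeAssembly:
    """A set of contigs addressed by id; sequences uppercase A/C/G/T/N."""

    records: dict[str, str]
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("assembly holds no contigs")
        total = 0
        for cid, seq in self.records.items():
            if not cid:
                raise ValueError("empty contig id")
            bad = set(seq) - _NT_CHARS
            if bad:
                raise AlphabetError(
                    f"contig {cid!r} contains non-nucleotide characters: {sorted(bad)}"
                )
            total += len(seq)
        if total == 0:
            raise ValueError("assembly has zero total length")

    def __getitem__(self, contig: str) -> str:
        return self.records[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.records

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self.records.items())


@dataclass
class AlignmentSet:
    """A rectangular multiple alignment; gap character is '-'."""

    taxa: list[str]
    rows: list[str]
    alphabet: str = "nt"  # {"nt", "aa"}

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise AlignmentShapeError("taxa/row count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentShapeError(f"rows of unequal length: {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass
class PipelineConfig:
    """Tunable thresholds of the whole pipeline, JSON-serializable.

    Defaults encode the study conventions: 2 kb flanks around each mined
    hit, copy-number counting of loci > 1000 bp and > 90% identity, consensus
    building only for families with >= 10 copies (below that the best hit
    is the species representative).
    """

    flank_bp: int = 2000
    copy_min_len: int = 1000
    copy_min_ident: float = 0.90
    consensus_min_copies: int = 10
    tir_min_len: int = 20
    tir_max_mismatch_frac: float = 0.1
    tir_search_window: int = 150
    orf_min_aa: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flank_bp", "copy_min_len", "consensus_min_copies",
                     "tir_min_len", "tir_search_window", "orf_min_aa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("copy_min_ident", "tir_max_mismatch_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _validate_chars(seq: str, alphabet: str, record_id: str) -> None:
    allowed = _NT_CHARS if alphabet == "nt" else _AA_CHARS
    bad = set(seq) - allowed
    if bad:
        raise AlphabetError(
            f"record {record_id!r} contains characters outside the "
            f"{alphabet} alphabet: {sorted(bad)}"
        )


def read_fasta(path: str | Path, alphabet: str = "nt"):
    """Load a FASTA file, uppercased, order preserved.

    Returns a :class:`GenomeAssembly` for ``alphabet='nt'`` and a plain
    ``dict[str, str]`` for ``alphabet='aa'``. Raises
    :class:`FastaParseError` with the line number for structural problems
    and :class:`AlphabetError` for illegal characters.
    """
    path = Path(path)
    # cheap structural pre-check so errors can carry a line number,
    # which SeqIO does not report
    first_content_line = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first_content_line = (lineno, line)
                break
    if first_content_line is None:
        raise FastaParseError(f"{path}:1: empty FASTA file")
    lineno, line = first_content_line
    if not line.startswith(">"):
        raise FastaParseError(
            f"{path}:{lineno}: expected FASTA header ('>'), got {line[:30]!r}"
        )

    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper()
        _validate_chars(seq, alphabet, rec.id)
        records[rec.id] = seq
    if alphabet == "nt":
        return GenomeAssembly(records=records, source_path=str(path))
    return records


def _sniff_alignment_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "clustal" if line.upper().startswith("CLUSTAL") else "fasta"
    raise FastaParseError(f"{path}:1: empty alignment file")


def _guess_alphabet(rows: list[str]) -> str:
    chars = set("".join(rows)) - {"-"}
    return "nt" if chars <= _NT_CHARS else "aa"


def read_alignment(path: str | Path) -> AlignmentSet:
    """Read an aligned-FASTA or Clustal multiple alignment.

    The two dialects yield identical :class:`AlignmentSet` objects. Ragged
    alignments raise :class:`AlignmentShapeError`.
    """
    path = Path(path)
    fmt = _sniff_alignment_format(path)
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        # Biopython rejects ragged FASTA "alignments" with a ValueError
        raise AlignmentShapeError(f"{path}: {exc}") from exc
    taxa = [rec.id for rec in aln]
    rows = [str(rec.seq).upper() for rec in aln]
    return AlignmentSet(taxa=taxa, rows=rows, alphabet=_guess_alphabet(rows))


def write_alignment_fasta(aln: AlignmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n{row}\n")


# --- element-copy output bundle ------------------------------------------

_REPORT_COLUMNS = [
    "copy_id", "contig", "start", "end", "strand", "status",
    "tir_len", "tir_mismatches", "tsd", "orf_aa", "family_label", "grpr_pos",
]


def write_outputs(copies, prefix: str | Path) -> dict[str, Path]:
    """Write BED6 + FASTA + TSV for a list of element copies.

    BED is 0-based half-open with the copy id in the name column; FASTA
    sequences are the element sequences in transposase-sense orientation
    (i.e. '-' strand copies are already reverse-complemented); the TSV
    report carries status and annotation columns. Round-tripping the BED
    reproduces coordinates exactly.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = prefix.with_suffix(".bed")
    fa_path = prefix.with_suffix(".fa")
    tsv_path = prefix.with_suffix(".tsv")

    with open(bed_path, "w") as bed, open(fa_path, "w") as fa, open(tsv_path, "w") as tsv:
        tsv.write("\t".join(_REPORT_COLUMNS) + "\n")
        for i, c in enumerate(copies):
            cid = f"{c.contig}:{c.start}-{c.end}({c.strand})"
            bed.write(f"{c.contig}\t{c.start}\t{c.end}\t{cid}\t0\t{c.strand}\n")
            fa.write(f">{cid}\n{c.sequence}\n")
            tir_len = c.tir.length if c.tir else "NA"
            tir_mm = c.tir.mismatches if c.tir else "NA"
            tsd = (c.tsd.left_copy if c.tsd and c.tsd.is_TA else
                   (f"{c.tsd.left_copy}/{c.tsd.right_copy}" if c.tsd else "NA"))
            orf_aa = len(c.orf_aa) if c.orf_aa else "NA"
            fam = c.family_label or "NA"
            grpr = ",".join(map(str, c.grpr_pos)) if c.grpr_pos else "NA"
            tsv.write("\t".join(map(str, [
                cid, c.contig, c.start, c.end, c.strand, c.status,
                tir_len, tir_mm, tsd, orf_aa, fam, grpr,
            ])) + "\n")
    return {"bed": bed_path, "fasta": fa_path, "tsv": tsv_path}


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Read back a BED6 file as (contig, start, end, name, strand) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, end, name, _score, strand = line.rstrip("\n").split("\t")
            out.append((contig, int(start), int(end), name, strand))
    return out
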