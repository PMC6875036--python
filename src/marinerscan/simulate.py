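"""Synthetic data with known truth for every stage of the pipeline.

Three generators:

* :func:`make_master` — a structurally exact element: TIRs, TA-ready
  termini, a single transposase ORF with a planted catalytic triad and
  GRPR box, built on the synthetic reference scaffold so triad transfer
  from the bundled references works.
* :func:`plant_elements` — a background genome with the master inserted at
  known coordinates, each copy diverged under a K2P substitution process,
  optionally truncated or collapsed to a MITE, with an exact truth table.
  Copies whose intended status requires a hallmark (detectable TIR pair,
  intact ORF) have disruptive substitutions resampled, emulating the
  purifying selection that keeps such copies recognizable in real genomes.
* :func:`simulate_scenario` — host-gene and element alignments co-evolved
  along a species tree, with optional horizontal transfer events that
  regraft the recipient's element lineage onto the donor's.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
from Bio.Data import CodonTable

from ._align import encode_nt, decode_nt, sample_substitution
from .annotation import find_tirs, find_longest_orf, detect_triad
from .io import AlignmentSet, GenomeAssembly, revcomp
from .references import ancestor_layout, build_protein, default_references

__all__ = [
    "ElementBlueprint", "MasterElement", "PlantedCopy", "PlantTruth",
    "ScenarioConfig", "make_master", "plant_elements", "simulate_scenario",
    "ladder_tree", "two_cluster_tree",
]

_BASES = np.array(list("ACGT"))


@dataclass
class ElementBlueprint:
    """Architecture of the element to synthesize (defaults: the typical
    intact element — 1225 bp, 29 bp TIRs, TA TSD, 346 aa ORF, DD36E)."""

    total_len: int = 1225
    tir_len: int = 29
    tsd: str = "TA"
    orf_aa: int = 346
    spacer2: int = 36
    third_residue: str = "E"

    def __post_init__(self) -> None:
        if self.tir_len < 1:
            raise ValueError("tir_len must be positive")
        if self.third_residue not in ("D", "E"):
            raise ValueError("third residue must be D or E")
        if self.total_len < 2 * self.tir_len + 3 * self.orf_aa + 6:
            raise ValueError("total_len cannot accommodate TIRs + ORF")


@dataclass
class MasterElement:
    """A synthesized element plus the structural truth needed to mutate it
    without destroying its planted hallmarks."""

    sequence: str
    protein: str
    blueprint: ElementBlueprint
    orf_start: int          # offset of the ATG within the element
    orf_end: int            # offset past the stop codon
    triad_aa: tuple[int, int, int]

    @property
    def tir_len(self) -> int:
        return self.blueprint.tir_len


@dataclass
class PlantedCopy:
    contig: str
    start: int
    end: int
    strand: str
    divergence: float
    status: str
    sequence: str
    breakpoints: Optional[tuple[int, int]] = None  # kept interval of master


@dataclass
class PlantTruth:
    records: list[PlantedCopy] = field(default_factory=list)


_STOPS = ("TAA", "TAG", "TGA")


def _codon_map() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


_CODONS = _codon_map()


def _backtranslate(protein: str, rng: np.random.Generator) -> str:
    parts = []
    for aa in protein:
        options = _CODONS[aa]
        parts.append(options[rng.integers(len(options))])
    parts.append(_STOPS[rng.integers(3)])
    return "".join(parts)


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_master(blueprint: ElementBlueprint = ElementBlueprint(),
                seed: int = 0, max_attempts: int = 80) -> MasterElement:
    """Synthesize an element that the annotation stage re-annotates exactly.

    Candidate layouts are drawn and validated until the TIR finder reports
    exactly (tir_len, 0 mismatches), the longest ORF has exactly orf_aa
    residues, and triad transfer from the bundled references yields the
    blueprint's family label; the construction is rejected otherwise (the
    usual cause is a chance inverted-repeat extension or a spurious ATG
    upstream of the ORF).
    """
    bp = blueprint
    rng = np.random.default_rng(seed)
    layout = ancestor_layout(bp.orf_aa, bp.spacer2)
    spacer_total = bp.total_len - 2 * bp.tir_len - (3 * bp.orf_aa + 3)
    len5 = spacer_total // 2
    len3 = spacer_total - len5
    expected_label = f"DD{bp.spacer2}{bp.third_residue}"
    for _ in range(max_attempts):
        protein, _ = build_protein(spacer2=bp.spacer2,
                                   third_residue=bp.third_residue,
                                   orf_aa=bp.orf_aa, mutate_frac=0.10, rng=rng)
        orf_nt = _backtranslate(protein, rng)
        tir = _random_nt(bp.tir_len, rng)
        spacer5 = _random_nt(len5, rng)
        spacer3 = _random_nt(len3, rng)
        element = tir + spacer5 + orf_nt + spacer3 + revcomp(tir)
        assert len(element) == bp.total_len
        tir_hit = find_tirs(element, min_len=min(20, bp.tir_len),
                            max_mismatch_frac=0.1, search_window=150)
        if (tir_hit is None or tir_hit.length != bp.tir_len
                or tir_hit.mismatches != 0 or tir_hit.left_start_offset != 0
                or tir_hit.right_end_offset != 0):
            continue
        orf = find_longest_orf(element, min_aa=1)
        if orf != protein:
            continue
        triad = detect_triad(protein, default_references())
        if triad is None or triad.family_label != expected_label:
            continue
        orf_start = bp.tir_len + len5
        return MasterElement(
            sequence=element, protein=protein, blueprint=bp,
            orf_start=orf_start, orf_end=orf_start + 3 * bp.orf_aa + 3,
            triad_aa=(layout["d1"], layout["d2"], layout["e3"]))
    raise RuntimeError("could not synthesize a valid master element; "
                       "blueprint may be infeasible")


# --- copy mutation with hallmark preservation ------------------------------

def _tir_mismatch_columns(seq: list[str], tir_len: int) -> list[int]:
    n = len(seq)
    return [k for k in range(tir_len)
            if seq[k] != revcomp(seq[n - 1 - k])]


def _repair_tirs(seq: list[str], master: str, tir_len: int,
                 max_mismatch_frac: float, rng: np.random.Generator) -> None:
    allowed = int(max_mismatch_frac * tir_len)
    cols = _tir_mismatch_columns(seq, tir_len)
    rng.shuffle(cols)
    n = len(seq)
    while len(cols) > allowed:
        k = cols.pop()
        seq[k] = master[k]
        seq[n - 1 - k] = master[len(master) - 1 - k]


def _translate_codons(seq: list[str], start: int, n_codons: int) -> str:
    from Bio.Seq import Seq
    return str(Seq("".join(seq[start:start + 3 * n_codons])).translate())


def _repair_orf(seq: list[str], master: MasterElement,
                rng: np.random.Generator) -> None:
    bp = master.blueprint
    start = master.orf_start
    for _ in range(60):
        prot = _translate_codons(seq, start, bp.orf_aa)
        bad_codons = [i for i, aa in enumerate(prot) if aa == "*"]
        if prot[0] != "M":
            bad_codons.append(0)
        for pos, want in zip(master.triad_aa, ("D", "D", bp.third_residue)):
            if prot[pos] != want:
                bad_codons.append(pos)
        if not bad_codons:
            return
        for i in set(bad_codons):
            lo = start + 3 * i
            seq[lo:lo + 3] = list(master.sequence[lo:lo + 3])
    raise RuntimeError("ORF repair did not converge")


def _break_orf(seq: list[str], master: MasterElement,
               rng: np.random.Generator) -> None:
    """Ensure the copy is not intact: plant one premature stop codon."""
    bp = master.blueprint
    prot = _translate_codons(seq, master.orf_start, bp.orf_aa)
    if "*" in prot[:-1] and prot.index("*") < 290:
        return
    i = int(rng.integers(100, 250))
    lo = master.orf_start + 3 * i
    seq[lo:lo + 3] = list(_STOPS[rng.integers(3)])


def _mutate_copy(master: MasterElement, status: str, t: float, kappa: float,
                 rng: np.random.Generator, mite_len: int,
                 exact_diff_frac: Optional[float] = None,
                 truncate_to: Optional[int] = None,
                 tir_max_mismatch_frac: float = 0.1
                 ) -> tuple[str, Optional[tuple[int, int]]]:
    """Produce one diverged copy with the intended status; returns the copy
    sequence and the kept (start, end) interval of the master."""
    m = master.sequence
    if exact_diff_frac is not None:
        seq = list(m)
        n_sub = int(round(exact_diff_frac * len(m)))
        for i in rng.choice(len(m), size=n_sub, replace=False):
            seq[i] = "ACGT".replace(seq[i], "")[rng.integers(3)]
    else:
        seq = list(decode_nt(sample_substitution(encode_nt(m), t, kappa, rng)))
    tir_len = master.tir_len
    if status in ("intact", "full_length", "MITE"):
        _repair_tirs(seq, m, tir_len, tir_max_mismatch_frac, rng)
    if status == "intact":
        _repair_orf(seq, master, rng)
    elif status == "full_length":
        _break_orf(seq, master, rng)
    if status == "MITE":
        keep5 = mite_len // 2
        keep3 = mite_len - keep5
        if keep5 < tir_len + 5 or mite_len >= len(m):
            raise ValueError("mite_len incompatible with the master layout")
        seq = seq[:keep5] + seq[len(m) - keep3:]
        return "".join(seq), None
    if status == "truncated":
        if truncate_to is None:
            frac = rng.uniform(0.35, 0.75)
            truncate_to = max(300, int(frac * len(m)))
        if rng.random() < 0.5:
            kept = (0, truncate_to)
        else:
            kept = (len(m) - truncate_to, len(m))
        return "".join(seq[kept[0]:kept[1]]), kept
    return "".join(seq), (0, len(m))


def plant_elements(genome_len: int, master: MasterElement, n_copies: int,
                   mean_divergence: float, kappa: float = 2.0,
                   frac_truncated: float = 0.0, frac_mite: float = 0.0,
                   mite_len: int = 810, seed: int = 0,
                   extra_copies: Optional[list[dict]] = None,
                   min_separation: int = 400,
                   contig_id: str = "chr1"
                   ) -> tuple[GenomeAssembly, PlantTruth]:
    """Plant diverged element copies in a uniform-composition background.

    ``frac_mite`` and ``frac_truncated`` of the ``n_copies`` become MITEs
    (internal deletion to ``mite_len``, both TIRs kept) and truncated
    copies (one terminus lost at a uniform breakpoint); the remainder stay
    intact. Intact/full-length/MITE insertions are flanked by a duplicated
    TA. ``extra_copies`` plants bespoke copies, e.g.
    ``{"exact_diff_frac": 0.15}`` or ``{"exact_diff_frac": 0.02,
    "truncate_to": 900, "status": "truncated"}``.
    """
    if genome_len <= n_copies * len(master.sequence) * 2:
        raise ValueError("genome too small for requested copy packing")
    rng = np.random.default_rng(seed)

    n_mite = int(round(frac_mite * n_copies))
    n_trunc = int(round(frac_truncated * n_copies))
    if n_mite + n_trunc > n_copies:
        raise ValueError("status fractions exceed 1")
    plans = ([{"status": "MITE"}] * n_mite
             + [{"status": "truncated"}] * n_trunc
             + [{"status": "intact"}] * (n_copies - n_mite - n_trunc))
    for spec in (extra_copies or []):
        plans.append({"status": spec.get("status", "intact"), **spec})

    background = _random_nt(genome_len, rng)
    # insertion sites in background coordinates, spaced apart
    sites: list[int] = []
    for _ in range(10_000):
        if len(sites) == len(plans):
            break
        cand = int(rng.integers(100, genome_len - 100))
        if all(abs(cand - s) >= min_separation for s in sites):
            sites.append(cand)
    if len(sites) < len(plans):
        raise ValueError("could not place all copies; genome too small")
    order = np.argsort(sites)

    pieces: list[str] = []
    records: list[PlantedCopy] = []
    prev = 0
    out_len = 0
    for idx in order:
        site, plan = sites[idx], plans[idx]
        status = plan["status"]
        copy_seq, kept = _mutate_copy(
            master, status, plan.get("t", mean_divergence), kappa, rng,
            mite_len, plan.get("exact_diff_frac"), plan.get("truncate_to"))
        strand = "+" if rng.random() < 0.5 else "-"
        ins_seq = copy_seq if strand == "+" else revcomp(copy_seq)
        with_tsd = status in ("intact", "full_length", "MITE")
        insert = ("TA" + ins_seq + "TA") if with_tsd else ins_seq
        pieces.append(background[prev:site])
        out_len += site - prev
        start = out_len + (2 if with_tsd else 0)
        pieces.append(insert)
        out_len += len(insert)
        prev = site
        records.append(PlantedCopy(
            contig=contig_id, start=start, end=start + len(copy_seq),
            strand=strand,
            divergence=plan.get("exact_diff_frac", plan.get("t", mean_divergence)),
            status=status, sequence=copy_seq, breakpoints=kept))
    pieces.append(background[prev:])
    genome = GenomeAssembly(records={contig_id: "".join(pieces)},
                            source_path="<synthetic>")
    return genome, PlantTruth(records=records)


# --- scenario simulation along a species tree ------------------------------

@dataclass
class ScenarioConfig:
    """Co-evolution scenario: a host gene under vertical transmission and
    an element evolving along the same tree at ``te_rate_multiplier`` times
    the host rate, unless a transfer event regrafts it."""

    species_tree: str                   # newick, branch lengths in subs/site
    host_gene_len: int = 1000
    te_len: int = 1225
    kappa: float = 2.0
    te_rate_multiplier: float = 1.5
    transfer_events: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.te_rate_multiplier < 1.0:
            raise ValueError("te_rate_multiplier must be >= 1")
        for donor, recipient, tf in self.transfer_events:
            if donor == recipient:
                raise ValueError("transfer donor == recipient")
            if not 0.0 < tf < 1.0:
                raise ValueError("transfer time fraction must be in (0,1)")


def _load_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def _node_ages(tree: dendropy.Tree) -> dict:
    """Age (time before present) per node, from root-to-node depths."""
    depth: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[node] = (depth[parent] + edge) if parent is not None else 0.0
    max_depth = max((depth[lf] for lf in tree.leaf_node_iter()), default=0.0)
    return {node: max_depth - d for node, d in depth.items()}


def _leaf(tree: dendropy.Tree, label: str):
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == label:
            return lf
    raise KeyError(f"taxon {label!r} not in tree")


def _apply_transfer(tree: dendropy.Tree, donor: str, recipient: str,
                    time_frac: float, depth: float) -> None:
    """Regraft the recipient leaf onto the donor lineage at the transfer
    age ``(1 - time_frac) * depth`` (time_frac runs root -> present)."""
    t_x = (1.0 - time_frac) * depth
    r_leaf = _leaf(tree, recipient)
    parent = r_leaf.parent_node
    parent.remove_child(r_leaf)
    tree.suppress_unifurcations()
    ages = _node_ages(tree)
    node = _leaf(tree, donor)
    while node.parent_node is not None and ages[node.parent_node] < t_x:
        node = node.parent_node
    if node.parent_node is None:
        raise ValueError("transfer age predates the root")
    above = node.parent_node
    above.remove_child(node)
    mid = dendropy.Node()
    above.add_child(mid)
    mid.edge.length = ages[above] - t_x
    mid.add_child(node)
    node.edge.length = t_x - ages[node]
    mid.add_child(r_leaf)
    r_leaf.edge.length = t_x


def _evolve_along(tree: dendropy.Tree, seq_len: int, rate: float,
                  kappa: float, rng: np.random.Generator) -> dict[str, str]:
    root_state = rng.integers(0, 4, size=seq_len)
    states = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = root_state
        else:
            t = (node.edge.length or 0.0) * rate
            states[node] = sample_substitution(states[node.parent_node],
                                               t, kappa, rng)
    return {lf.taxon.label: decode_nt(states[lf])
            for lf in tree.leaf_node_iter() if lf.taxon is not None}


def _pairwise_mrca_ages(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    ages = _node_ages(tree)
    paths: dict[str, list] = {}
    for lf in tree.leaf_node_iter():
        if lf.taxon is None:
            continue
        path = []
        node = lf
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths[lf.taxon.label] = path
    labels = sorted(paths)
    out = {}
    for i, a in enumerate(labels):
        seen = set(paths[a])
        for b in labels[i + 1:]:
            mrca = next(n for n in paths[b] if n in seen)
            out[(a, b)] = ages[mrca]
    return out


def simulate_scenario(cfg: ScenarioConfig
                      ) -> tuple[AlignmentSet, AlignmentSet, dict[tuple[str, str], bool]]:
    """Simulate host-gene and element alignments plus truth flags.

    Truth flags mark species pairs whose element most-recent-common-origin
    postdates the species split (i.e. pairs connected by a transfer), for
    which the element distance is expected to undercut the host distance.
    """
    rng = np.random.default_rng(cfg.seed)
    sp_tree = _load_tree(cfg.species_tree)
    sp_ages = _pairwise_mrca_ages(sp_tree)
    depth = max(_node_ages(sp_tree).values(), default=0.0)

    te_tree = _load_tree(cfg.species_tree)
    for donor, recipient, tf in cfg.transfer_events:
        _apply_transfer(te_tree, donor, recipient, tf, depth)
    te_ages = _pairwise_mrca_ages(te_tree)

    host_seqs = _evolve_along(sp_tree, cfg.host_gene_len, 1.0, cfg.kappa, rng)
    te_seqs = _evolve_along(te_tree, cfg.te_len, cfg.te_rate_multiplier,
                            cfg.kappa, rng)
    labels = sorted(host_seqs)
    host = AlignmentSet(taxa=labels, rows=[host_seqs[l] for l in labels])
    te = AlignmentSet(taxa=labels, rows=[te_seqs[l] for l in labels])
    truth = {pair: te_ages[pair] < sp_ages[pair] - 1e-12 for pair in sp_ages}
    return host, te, truth


# --- tree builders ---------------------------------------------------------

def ladder_tree(labels: list[str], depth: float) -> str:
    """Ultrametric caterpillar tree with evenly spaced split ages."""
    n = len(labels)
    if n == 1:
        return f"{labels[0]}:0.0;"
    ages = [depth * (i + 1) / (n - 1) for i in range(n - 1)]
    newick = f"{labels[0]}:{ages[0]:.8f}"
    prev_age = 0.0
    for i in range(1, n):
        age = ages[i - 1]
        newick = f"({newick},{labels[i]}:{age:.8f})"
        if i < n - 1:
            newick += f":{ages[i] - age:.8f}"
        prev_age = age
    return newick + ";"


def two_cluster_tree(labels_a: list[str], labels_b: list[str],
                     depth: float, cluster_depth: float) -> str:
    """Two ultrametric clades of depth ``cluster_depth`` joined at
    ``depth``."""

    def clade(labels: list[str]) -> str:
        sub = ladder_tree(labels, cluster_depth).rstrip(";")
        # strip the trailing branch length of the clade root, if any
        return sub

    stem = depth - cluster_depth
    if stem <= 0:
        raise ValueError("cluster_depth must be smaller than depth")
    a = clade(labels_a)
    b = clade(labels_b)
    return f"({a}:{stem:.8f},{b}:{stem:.8f});"
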