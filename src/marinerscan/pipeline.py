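"""End-to-end orchestration: mine -> annotate -> consensus -> distances ->
tree -> horizontal-transfer test, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .annotation import annotate_copy, refine_boundaries
from .consensus import (divergence_from_consensus, estimate_copy_number,
                        progressive_align, species_representative)
from .distances import identity_matrix, k2p_distance, mcl_distance_matrix, \
    DistanceMatrix
from .ht import ht_compare, ht_report
from .io import (PipelineConfig, read_alignment, read_fasta,
                 write_alignment_fasta, write_outputs)
from .mining import dedupe_copies, extract_with_flanks, translated_search
from .phylo import nj_tree
from .references import default_references

logger = logging.getLogger("marinerscan")

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit for bit."""

    version: str
    seed: int
    config: dict
    input_checksums: dict[str, str]
    stage_outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, genome_path: str | Path,
                 query_path: str | Path, outdir: str | Path,
                 host_alignment_path: Optional[str | Path] = None,
                 te_alignment_path: Optional[str | Path] = None,
                 species: str = "species") -> RunManifest:
    """Run the whole workflow on one genome; returns the manifest.

    Stages: translated mining with flank extraction; boundary refinement
    and hallmark annotation; family consensus (or best-hit representative)
    with copy-number and divergence; identity + K2P distance matrices over
    the annotated copies; NJ tree; and, when both a host ortholog
    alignment and a cross-species element alignment are supplied, the
    element-vs-host distance comparison. A missing ht input skips that
    stage with a warning; other stage failures abort, naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {"genome": _sha256(genome_path), "query": _sha256(query_path)}
    if host_alignment_path:
        checksums["host_alignment"] = _sha256(host_alignment_path)
    if te_alignment_path:
        checksums["te_alignment"] = _sha256(te_alignment_path)
    manifest = RunManifest(version=__version__, seed=config.seed,
                           config=asdict(config), input_checksums=checksums)

    genome = read_fasta(genome_path, alphabet="nt")
    queries = read_fasta(query_path, alphabet="aa")
    refs = default_references()

    stage = "mine"
    try:
        hits = []
        for qid, qseq in queries.items():
            hits.extend(translated_search(qseq.replace("*", ""), genome,
                                          query_id=qid))
        copies = [extract_with_flanks(h, genome, config.flank_bp)
                  for h in hits]
        logger.info("mine: %d hits", len(hits))

        stage = "annotate"
        refined = [refine_boundaries(c, config.tir_min_len,
                                     config.tir_max_mismatch_frac,
                                     config.tir_search_window)
                   for c in copies]
        annotated = [annotate_copy(
            c, refs, config.tir_min_len, config.tir_max_mismatch_frac,
            config.tir_search_window, orf_min_aa=config.orf_min_aa)
            for c in dedupe_copies(refined)]
        paths = write_outputs(annotated, outdir / "copies")
        manifest.stage_outputs["mine"] = str(paths["bed"])
        manifest.stage_outputs["annotate"] = str(paths["tsv"])

        stage = "consensus"
        usable = {f"copy{i}": c.sequence for i, c in enumerate(annotated)
                  if c.status != "truncated"} or \
                 {f"copy{i}": c.sequence for i, c in enumerate(annotated)}
        if not usable:
            raise RuntimeError("no copies recovered from mining")
        best = max(annotated, key=lambda c: len(c.sequence)).sequence
        rep = species_representative(usable, genome, species,
                                     config.consensus_min_copies,
                                     best_hit=best)
        cons_path = outdir / "consensus.fa"
        cons_path.write_text(f">{species}\n{rep.sequence}\n")
        manifest.stage_outputs["consensus"] = str(cons_path)

        stage = "copy_number"
        n_copies, hits2 = estimate_copy_number(
            rep, genome, config.copy_min_len, config.copy_min_ident)
        div = divergence_from_consensus(list(usable.values()), rep)
        report = outdir / "family_report.tsv"
        with open(report, "w") as fh:
            fh.write("species\tcopy_number\tmean_divergence_pct\tse_pct\tn\n")
            if div is None:
                fh.write(f"{species}\t{n_copies}\tNA\tNA\t{len(usable)}\n")
            else:
                fh.write(f"{species}\t{n_copies}\t{div.mean_divergence:.2f}"
                         f"\t{div.se:.2f}\t{div.n}\n")
        manifest.stage_outputs["copy_number"] = str(report)

        stage = "distance"
        aln = progressive_align(usable)
        write_alignment_fasta(aln, outdir / "copies.aln.fa")
        idm = identity_matrix(aln)
        idm.to_tsv(outdir / "identity.tsv")
        import numpy as np
        n = aln.n_taxa
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                res = k2p_distance(aln.rows[i], aln.rows[j], aligned=True)
                d[i, j] = d[j, i] = res.d
        kdm = DistanceMatrix(taxa=list(aln.taxa), d=d, model="K2P")
        kdm.to_tsv(outdir / "k2p.tsv")
        manifest.stage_outputs["distance"] = str(outdir / "k2p.tsv")

        stage = "tree"
        if n >= 3 and not kdm.undefined_pairs():
            tree = nj_tree(kdm)
            (outdir / "copies.nwk").write_text(tree.newick + "\n")
            manifest.stage_outputs["tree"] = str(outdir / "copies.nwk")
        else:
            warnings.warn("tree stage skipped: need >= 3 copies with "
                          "defined distances")

        stage = "ht"
        if host_alignment_path and te_alignment_path:
            host_aln = read_alignment(host_alignment_path)
            te_aln = read_alignment(te_alignment_path)
            cmp = ht_compare(mcl_distance_matrix(te_aln),
                             mcl_distance_matrix(host_aln))
            ht_report(cmp, outdir / "ht.tsv")
            manifest.stage_outputs["ht"] = str(outdir / "ht.tsv")
        else:
            warnings.warn("ht stage skipped: host and/or element alignment "
                          "not provided")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed ({exc}); outputs so far: "
            f"{sorted(manifest.stage_outputs)}") from exc

    manifest.write(outdir / "manifest.json")
    return manifest
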