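"""End-to-end orchestration: simulate -> reconstruct -> classify -> filter
-> report.

One pipeline run realizes the full detection funnel on synthetic data with
known truth: the scion reference is reconstructed from simulated DNA
resequencing reads, heterograft RNA samples are classified against it with
rootstock rescue, homograft samples of the matching condition supply the
false-positive subtraction, and the per-condition mobile sets are reported
together with their Venn partition, expression screening and enrichment
tables, and truth-comparison metrics.  A manifest records the configuration
snapshot, seeds and content hashes of every stage output so a run can be
audited and reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as gio
from .classify import MappingParams, MatchParams, classify_sample
from .config import SimulationConfig
from .consensus import ConsensusParams, PileupParams, reconstruct
from .expression import (compute_fpkm, hypergeom_enrich, screen_degs,
                         venn_partition)
from .filtering import MobileCallSet, derive_false_positives, filter_candidates
from .simulate import (GenomeTriple, SampleKey, TranscriptSet,
                       simulate_counts, simulate_dna_reads, simulate_genomes,
                       simulate_reads, simulate_transcriptome)

log = logging.getLogger(__name__)

DETECTION_DAS = 11


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    version: str = "0.1.0"

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = info

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "seed": self.seed,
                       "version": self.version, "stages": self.stages},
                      fh, indent=2, sort_keys=True)


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def detect_condition(condition: str, transcripts: TranscriptSet,
                     genomes: GenomeTriple, config: SimulationConfig,
                     reference: dict[str, str],
                     rootstock_genes: dict[str, str],
                     mapping: MappingParams, matching: MatchParams,
                     min_read_support: int = 2,
                     apply_filter: bool = True,
                     das: int = DETECTION_DAS) -> MobileCallSet:
    """Candidate calling plus condition-matched homograft filtering."""
    hetero = simulate_reads(transcripts, genomes, config,
                            SampleKey("hetero", condition, das))
    candidates = classify_sample(hetero, reference, rootstock_genes,
                                 mapping, matching, min_read_support)
    if not apply_filter:
        return filter_candidates(candidates, set())
    homo = simulate_reads(transcripts, genomes, config,
                          SampleKey("homo", condition, das))
    fp = derive_false_positives(homo, reference, rootstock_genes,
                                mapping, matching, min_read_support)
    return filter_candidates(candidates, fp)


def run_pipeline(config: SimulationConfig | str | Path, out_dir,
                 seed: int | None = None,
                 mapping: MappingParams | None = None,
                 matching: MatchParams | None = None,
                 min_read_support: int = 2) -> RunManifest:
    """Execute every stage in order and write the report under ``out_dir``."""
    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.from_yaml(config)
    if seed is not None:
        config = SimulationConfig.from_dict({**config.to_dict(),
                                             "seed": seed})
    mapping = mapping or MappingParams()
    matching = matching or MatchParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)

    def finish(stage: str, **paths):
        hashes = {k: _sha256_file(p) for k, p in paths.items()}
        manifest.record(stage, files={k: str(p) for k, p in paths.items()},
                        hashes=hashes)
        log.info("stage %s done (%d artifact(s))", stage, len(paths))

    # --- simulate ----------------------------------------------------
    stage = "simulate"
    try:
        genomes = simulate_genomes(config)
        transcripts = simulate_transcriptome(genomes, config)
        p_pub = out / "published_ref.fasta"
        p_root = out / "rootstock.fasta"
        p_gff = out / "genes.gff3"
        p_var = out / "scion_variants.tsv"
        gio.write_fasta(genomes.published_ref, p_pub)
        gio.write_fasta(genomes.rootstock, p_root)
        gio.write_gff3(genomes.scion_genes + genomes.rootstock_genes, p_gff)
        gio.write_variants_tsv(genomes.scion_variants, p_var)
        finish(stage, published_ref=p_pub, rootstock=p_root, genes=p_gff,
               variants=p_var)

        # --- reconstruct ---------------------------------------------
        stage = "reconstruct"
        dna = simulate_dna_reads(genomes, config)
        recon = reconstruct(dna, genomes.published_ref, PileupParams(),
                            ConsensusParams())
        p_recon = out / "reconstructed_ref.fasta"
        p_called = out / "called_variants.tsv"
        gio.write_fasta(recon.sequences, p_recon)
        gio.write_variants_tsv(recon.called_variants, p_called)
        finish(stage, reconstructed=p_recon, called_variants=p_called)

        # --- detect --------------------------------------------------
        stage = "detect"
        from .classify import gene_sequences
        rootstock_genes = gene_sequences(genomes.rootstock,
                                         genomes.rootstock_genes)
        calls: dict[str, MobileCallSet] = {}
        detect_paths = {}
        for cond in config.mobile_condition_profile:
            calls[cond] = detect_condition(
                cond, transcripts, genomes, config, recon.sequences,
                rootstock_genes, mapping, matching, min_read_support)
            p = out / f"mobile_{cond}.tsv"
            gio.write_mobile_calls_tsv(calls[cond], p)
            detect_paths[f"mobile_{cond}"] = p
        finish(stage, **detect_paths)

        # --- report --------------------------------------------------
        stage = "report"
        venn = venn_partition({c: calls[c].gene_ids() for c in calls})
        venn_json = {"+".join(k): sorted(v)
                     for k, v in venn.regions.items()}

        counts = pd.concat(
            [simulate_counts(transcripts, config,
                             SampleKey("hetero", cond, DETECTION_DAS))
             for cond in ("WW", "WS")], axis=1)
        p_counts = out / "counts.tsv"
        gio.write_counts_tsv(counts, p_counts)
        expr = compute_fpkm(counts, transcripts.lengths())
        ww_cols = [c for c in counts.columns if "_WW_" in c]
        ws_cols = [c for c in counts.columns if "_WS_" in c]
        degs = screen_degs(counts, ww_cols, ws_cols)
        p_degs = out / "degs.tsv"
        degs.rename_axis("gene_id").to_csv(p_degs, sep="\t")

        scion_ids = {g.gene_id for g in genomes.scion_genes}
        selected = set(degs.index[degs["passed"]]) & scion_ids
        enrich = hypergeom_enrich(selected, scion_ids,
                                  transcripts.annotations)
        p_enrich = out / "enrichment.tsv"
        enrich.to_csv(p_enrich, sep="\t", index=False)

        truth = transcripts.mobile_truth
        metrics = {}
        for cond, cs in calls.items():
            found = cs.gene_ids()
            tp = len(found & truth)
            metrics[cond] = {
                "n_final": len(found),
                "n_false_positive_filtered": len(cs.false_positives),
                "precision": tp / len(found) if found else 1.0,
                "recall": tp / len(truth) if truth else 1.0,
            }
        report = {
            "mobile": {c: {g: int(n) for g, n in sorted(cs.final.items())}
                       for c, cs in calls.items()},
            "venn": venn_json,
            "venn_counts": {"+".join(k): v for k, v in venn.counts.items()},
            "n_degs": int(degs["passed"].sum()),
            "top_enriched_term": (enrich.iloc[0]["term"]
                                  if len(enrich) else None),
            "truth_metrics": metrics,
            "mean_fpkm": float(expr.fpkm.to_numpy().mean()),
        }
        p_report = out / "report.json"
        with open(p_report, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        finish(stage, counts=p_counts, degs=p_degs, enrichment=p_enrich,
               report=p_report)
    except Exception:
        log.error("pipeline failed at stage %r; partial outputs kept in %s",
                  stage, out)
        raise

    manifest.to_json(out / "manifest.json")
    return manifest
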