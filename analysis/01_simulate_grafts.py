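"""Generate the synthetic grafting study.

Builds the default study design — homografts and heterografts under
well-watered and progressive-drought conditions.  Small truth tables go
under results/sim/; bulky sequence artifacts (genomes, reads) are written
to scratch/sim/ since every downstream script re-derives them in memory
from the same seed.
"""

from pathlib import Path

import graftrace as gt
from graftrace import io as gio

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "sim"
SCRATCH = ROOT / "scratch" / "sim"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cfg = gt.SimulationConfig(seed=SEED)
    genomes = gt.simulate_genomes(cfg)
    transcripts = gt.simulate_transcriptome(genomes, cfg)

    gio.write_fasta(genomes.published_ref, SCRATCH / "published_ref.fasta")
    gio.write_fasta(genomes.true_scion, SCRATCH / "true_scion.fasta")
    gio.write_fasta(genomes.rootstock, SCRATCH / "rootstock.fasta")
    gio.write_gff3(genomes.scion_genes + genomes.rootstock_genes,
                   OUT / "genes.gff3")
    gio.write_variants_tsv(genomes.scion_variants, OUT / "scion_variants.tsv")
    transcripts.weights.round(6).to_csv(OUT / "abundance_weights.tsv",
                                        sep="\t")
    # a small example library so the FASTQ layout is on disk
    batch = gt.simulate_reads(transcripts, genomes, cfg,
                              gt.SampleKey("hetero", "WS", 11), depth=150)
    gio.write_fastq_pair(batch, SCRATCH / "example_hetero_WS_d11")
    cfg.to_yaml(OUT / "sim.yaml")

    print(f"genomes: {sum(len(s) for s in genomes.true_scion.values())} bp "
          f"true scion over {len(genomes.true_scion)} contig(s), "
          f"{len(genomes.scion_variants)} planted cultivar SNPs")
    print(f"rootstock gene space: {len(genomes.rootstock_genes)} genes, "
          f"{len(genomes.conserved_gene_ids)} conserved bait "
          f"({len(genomes.unassembled_gene_ids)} absent from the published "
          "assembly)")
    print(f"planted mobile transcripts: {sorted(transcripts.mobile_truth)}")
    print(f"planted DE genes: {sorted(transcripts.de_truth)}")
    print(f"tables under {OUT}; sequence artifacts under {SCRATCH}")


if __name__ == "__main__":
    main()
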