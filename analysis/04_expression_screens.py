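"""Expression quantification, DEG screening and enrichment.

Simulates replicate fragment-count tables for the heterograft under both
watering conditions, computes FPKM, screens for differential expression
(P < .05 and |log2FC| > 1), and runs hypergeometric term enrichment of the
passing genes over the synthetic annotation terms.
"""

from pathlib import Path

import pandas as pd

import graftrace as gt
from graftrace import io as gio

OUT = Path(__file__).resolve().parent.parent / "results" / "expression"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = gt.SimulationConfig(seed=SEED)
    genomes = gt.simulate_genomes(cfg)
    transcripts = gt.simulate_transcriptome(genomes, cfg)

    counts = pd.concat(
        [gt.simulate_counts(transcripts, cfg, gt.SampleKey("hetero", c, 11))
         for c in ("WW", "WS")], axis=1)
    gio.write_counts_tsv(counts, OUT / "counts.tsv")
    expr = gt.compute_fpkm(counts, transcripts.lengths())
    expr.fpkm.round(3).rename_axis("gene_id").to_csv(OUT / "fpkm.tsv",
                                                     sep="\t")

    ww = [c for c in counts.columns if "_WW_" in c]
    ws = [c for c in counts.columns if "_WS_" in c]
    degs = gt.screen_degs(counts, ww, ws)
    degs.rename_axis("gene_id").to_csv(OUT / "degs.tsv", sep="\t")
    passed = set(degs.index[degs["passed"]])
    planted = transcripts.de_truth
    print(f"{len(passed)} gene(s) pass the screen "
          f"({len(passed & planted)}/{len(planted)} planted DE genes "
          "recovered)")

    universe = {g.gene_id for g in genomes.scion_genes}
    enrich = gt.hypergeom_enrich(passed & universe, universe,
                                 transcripts.annotations)
    enrich.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    top = enrich.iloc[0]
    print(f"top enriched term: {top['term']} "
          f"(overlap {top['overlap']}/{top['annotated']}, "
          f"p = {top['pvalue']:.2e})")
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    main()
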