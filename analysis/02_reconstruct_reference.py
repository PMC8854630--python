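"""Reconstruct the scion cultivar's reference from resequencing reads.

Simulates the DNA resequencing of the true scion genome, rebuilds the
reference by majority consensus over the read pileup against the published
assembly, and scores the called variants against the planted truth.
"""

from pathlib import Path

import graftrace as gt
from graftrace import io as gio

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "reconstruction"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scratch = ROOT / "scratch" / "reconstruction"
    scratch.mkdir(parents=True, exist_ok=True)
    cfg = gt.SimulationConfig(seed=SEED)
    genomes = gt.simulate_genomes(cfg)
    dna = gt.simulate_dna_reads(genomes, cfg)
    pileup = gt.build_pileup(dna, genomes.published_ref)
    recon = gt.call_consensus(pileup, genomes.published_ref)

    gio.write_fasta(recon.sequences, scratch / "reconstructed_ref.fasta")
    gio.write_variants_tsv(recon.called_variants, OUT / "called_variants.tsv")

    recall, false_calls = gt.variant_recovery(recon.called_variants,
                                              genomes.scion_variants)
    print(f"{len(dna)} read pairs piled up "
          f"({pileup.n_reads_used} mates used, "
          f"{pileup.n_reads_discarded} discarded as unplaced/ambiguous)")
    print(f"{len(recon.called_variants)} variants called; "
          f"recall of {len(genomes.scion_variants)} planted SNPs: "
          f"{recall:.3f}; false calls: {false_calls}")
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    main()
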