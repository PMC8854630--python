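"""Two-stage read-origin classification: scion mapping, rootstock rescue."""

import numpy as np
import pytest

import graftrace as gt
from graftrace import _seq
from graftrace.align import ReferenceIndex, best_local_hit

from oracles import brute_best_local_hit, brute_glocal_placements


def make_batch(pairs, read_length, sample=None):
    ids = [f"r{i}" for i in range(len(pairs))]
    n = len(pairs)
    return gt.ReadBatch(ids, [p[0] for p in pairs], [p[1] for p in pairs],
                        ["?"] * n, ["?"] * n, read_length=read_length,
                        sample=sample)


@pytest.fixture(scope="module")
def detection_setup(small_config, small_genomes, small_transcripts,
                    small_reconstruction):
    rs_genes = gt.gene_sequences(small_genomes.rootstock,
                                 small_genomes.rootstock_genes)
    return small_config, small_genomes, small_transcripts, \
        small_reconstruction.sequences, rs_genes


class TestMapToScion:
    def test_error_free_scion_read_maps(self, detection_setup):
        cfg, genomes, transcripts, ref, _ = detection_setup
        gene = next(g for g in genomes.scion_genes if g.contig == "chr1")
        seq = transcripts.sequences[gene.gene_id]
        batch = make_batch([(seq[:100], _seq.revcomp(seq[100:200]))], 100)
        mapped, unmapped = gt.map_to_scion(batch, genomes.true_scion)
        assert mapped == {"r0"} and unmapped == set()

    def test_divergent_rootstock_read_is_unmapped(self, detection_setup):
        cfg, genomes, transcripts, ref, rs_genes = detection_setup
        # a gene diverged at 10% cannot reach 95% identity against the scion
        gid = next(iter(small for small in
                        (g.gene_id for g in genomes.rootstock_genes)
                        if small not in genomes.conserved_gene_ids))
        seq = rs_genes[gid]
        batch = make_batch([(seq[:100], _seq.revcomp(seq[100:200]))], 100)
        mapped, unmapped = gt.map_to_scion(batch, ref)
        assert unmapped == {"r0"}

    def test_partition_invariant(self, detection_setup):
        cfg, genomes, transcripts, ref, _ = detection_setup
        batch = gt.simulate_reads(transcripts, genomes, cfg,
                                  gt.SampleKey("hetero", "WS", 11),
                                  depth=400)
        mapped, unmapped = gt.map_to_scion(batch, ref)
        assert mapped | unmapped == set(batch.ids)
        assert mapped & unmapped == set()

    def test_raising_min_identity_never_maps_more(self, detection_setup):
        cfg, genomes, transcripts, ref, _ = detection_setup
        batch = gt.simulate_reads(transcripts, genomes, cfg,
                                  gt.SampleKey("hetero", "WS", 11),
                                  depth=300)
        loose, _ = gt.map_to_scion(batch, ref,
                                   gt.MappingParams(min_identity=0.90))
        strict, _ = gt.map_to_scion(batch, ref,
                                    gt.MappingParams(min_identity=0.98))
        assert strict <= loose

    def test_empty_reference_unmaps_everything(self, detection_setup):
        cfg, genomes, transcripts, ref, _ = detection_setup
        batch = gt.simulate_reads(transcripts, genomes, cfg,
                                  gt.SampleKey("homo", "WW", 0), depth=50)
        mapped, unmapped = gt.map_to_scion(batch, {})
        assert mapped == set() and unmapped == set(batch.ids)

    def test_empty_batch_rejected(self, detection_setup):
        _, _, _, ref, _ = detection_setup
        empty = gt.ReadBatch([], [], [], [], [], read_length=100)
        with pytest.raises(ValueError):
            gt.map_to_scion(empty, ref)

    def test_pair_rules_differ_only_on_split_pairs(self, detection_setup):
        cfg, genomes, transcripts, ref, rs_genes = detection_setup
        scion_gene = next(g.gene_id for g in genomes.scion_genes
                          if g.contig == "chr1")
        rs_id = next(iter(transcripts.mobile_truth))
        s, r = transcripts.sequences[scion_gene], rs_genes[rs_id]
        batch = make_batch([(s[:100], _seq.revcomp(r[:100]))], 100)
        either, _ = gt.map_to_scion(batch, ref,
                                    gt.MappingParams(pair_rule="either_mate"))
        both, _ = gt.map_to_scion(batch, ref,
                                  gt.MappingParams(pair_rule="both_mates"))
        assert either == {"r0"} and both == set()


class TestRootstockMatch:
    def test_verbatim_read_hits_its_gene_at_full_identity(self,
                                                          detection_setup):
        cfg, genomes, transcripts, ref, rs_genes = detection_setup
        gid = next(iter(transcripts.mobile_truth))
        seq = rs_genes[gid]
        batch = make_batch([(seq[:100], _seq.revcomp(seq[100:200]))], 100)
        hits = gt.match_unmapped_to_rootstock(batch, {"r0"}, rs_genes)
        assert {h.gene_id for h in hits} == {gid}
        assert all(h.identity == 1.0 for h in hits)

    def test_random_read_without_shared_kmer_has_no_hit(self,
                                                        detection_setup):
        *_, rs_genes = detection_setup
        rng = np.random.default_rng(123)
        seq = _seq.decode(_seq.random_codes(rng, 100))
        batch = make_batch([(seq, seq)], 100)
        hits = gt.match_unmapped_to_rootstock(batch, {"r0"}, rs_genes)
        assert hits == []

    def test_assignments_match_local_alignment_oracle(self):
        """Best-gene assignment equals exhaustive gapless local alignment."""
        cfg = gt.SimulationConfig(seed=31, n_genes=3,
                                  gene_length_range=(200, 260),
                                  read_length=60, rootstock_divergence=0.10,
                                  sequencing_error_rate=0.01,
                                  n_conserved_genes=0, n_mobile_genes=3,
                                  n_de_genes=0, intergenic_length=60)
        genomes = gt.simulate_genomes(cfg)
        rs_genes = gt.gene_sequences(genomes.rootstock,
                                     genomes.rootstock_genes)
        rng = np.random.default_rng(7)
        params = gt.MatchParams(min_identity=0.90, min_hit_length=30)
        index = ReferenceIndex(rs_genes, params.k)
        n_checked = 0
        for _ in range(60):
            gid = list(rs_genes)[rng.integers(0, len(rs_genes))]
            seq = rs_genes[gid]
            start = rng.integers(0, len(seq) - 60 + 1)
            codes = _seq.encode(seq[start:start + 60])
            read, _ = _seq.mutate_codes(rng, codes, 0.01)
            read_s = _seq.decode(read)
            if rng.random() < 0.5:
                read_s = _seq.revcomp(read_s)
            expected = brute_best_local_hit(read_s, rs_genes,
                                            params.min_identity,
                                            params.min_hit_length)
            got = best_local_hit(read_s, index, params.min_identity,
                                 params.min_hit_length)
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert (got.score, got.name) == expected
            n_checked += 1
        assert n_checked == 60

    def test_mapping_decisions_match_sliding_oracle(self):
        cfg = gt.SimulationConfig(seed=37, n_genes=3,
                                  gene_length_range=(300, 400),
                                  read_length=100,
                                  sequencing_error_rate=0.02,
                                  n_conserved_genes=0, n_mobile_genes=0,
                                  n_de_genes=0, intergenic_length=80)
        genomes = gt.simulate_genomes(cfg)
        transcripts = gt.simulate_transcriptome(genomes, cfg)
        batch = gt.simulate_reads(transcripts, genomes, cfg,
                                  gt.SampleKey("homo", "WW", 0), depth=100)
        params = gt.MappingParams()
        mapped, unmapped = gt.map_to_scion(batch, genomes.published_ref,
                                           params)
        for rid, m1, m2 in zip(batch.ids, batch.mate1, batch.mate2):
            oracle_ok = [
                bool(brute_glocal_placements(m, genomes.published_ref,
                                             params.min_identity,
                                             params.min_aligned_fraction))
                for m in (m1, m2)]
            assert (rid in mapped) == (oracle_ok[0] or oracle_ok[1])


class TestCandidates:
    def test_no_hits_no_candidates(self):
        assert gt.call_candidates([], 2).support == {}

    def test_support_threshold_is_forced(self):
        hits = [gt.RootstockHit(f"r{i}", "G", 1.0, 100, 100)
                for i in range(3)]
        cs = gt.call_candidates(hits, min_read_support=2)
        assert cs.support == {"G": 3}
        assert gt.call_candidates(hits[:1], 2).support == {}

    def test_min_support_below_one_rejected(self):
        with pytest.raises(ValueError):
            gt.call_candidates([], 0)

    def test_hetero_candidates_cover_truth_and_bait(self, detection_setup):
        """In a drought heterograft sample, candidates include every planted
        mobile gene plus the conserved bait misrouted from the scion."""
        cfg, genomes, transcripts, ref, rs_genes = detection_setup
        batch = gt.simulate_reads(transcripts, genomes, cfg,
                                  gt.SampleKey("hetero", "WS", 11))
        cs = gt.classify_sample(batch, ref, rs_genes)
        found = cs.gene_ids()
        assert transcripts.mobile_truth <= found
        assert genomes.conserved_gene_ids <= found
        assert found <= transcripts.mobile_truth | genomes.conserved_gene_ids


def test_homograft_null_property():
    """Without conserved bait and sequencing error, homograft samples
    produce zero rootstock hits."""
    cfg = gt.SimulationConfig(seed=41, n_genes=10,
                              gene_length_range=(400, 700), read_length=100,
                              rna_depth=2000, dna_depth=15.0,
                              sequencing_error_rate=0.0,
                              n_conserved_genes=0, n_mobile_genes=2)
    genomes = gt.simulate_genomes(cfg)
    transcripts = gt.simulate_transcriptome(genomes, cfg)
    recon = gt.reconstruct(gt.simulate_dna_reads(genomes, cfg),
                           genomes.published_ref)
    rs_genes = gt.gene_sequences(genomes.rootstock, genomes.rootstock_genes)
    batch = gt.simulate_reads(transcripts, genomes, cfg,
                              gt.SampleKey("homo", "WS", 11))
    _, unmapped = gt.map_to_scion(batch, recon.sequences)
    hits = gt.match_unmapped_to_rootstock(batch, unmapped, rs_genes)
    assert hits == []
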