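"""Read-origin classification: scion mapping and rootstock rescue.

The two-stage order is the method's core contract: scion RNA-seq reads are
first mapped against the reconstructed scion reference; only the pairs that
fail that mapping are matched against the rootstock gene space.  Rootstock
genes collecting enough rescued reads become candidate mobile mRNAs.  There
is no joint scoring across the two genomes — a read that maps to the scion
is never considered rootstock-derived, however well it might match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import ReferenceIndex, best_local_hit, choose_seed_k, map_read
from .simulate import GeneModel, ReadBatch, SampleKey, extract_transcript

log = logging.getLogger(__name__)

PAIR_RULES = ("either_mate", "both_mates")


@dataclass
class MappingParams:
    """Thresholds for reference mapping of read pairs."""

    k: int = 21
    min_identity: float = 0.95
    min_aligned_fraction: float = 0.9
    #: 'either_mate': a pair with one mapped mate counts as mapped (default,
    #: mirrors typical aligner behaviour); 'both_mates': both must map.
    pair_rule: str = "either_mate"

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in (0, 1]")
        if not 0.0 < self.min_aligned_fraction <= 1.0:
            raise ValueError("min_aligned_fraction must lie in (0, 1]")
        if self.pair_rule not in PAIR_RULES:
            raise ValueError(f"pair_rule must be one of {PAIR_RULES}")


@dataclass
class MatchParams:
    """Thresholds for local matching of rescued reads to rootstock genes."""

    k: int = 21
    min_identity: float = 0.90
    min_hit_length: int = 50


@dataclass(frozen=True)
class RootstockHit:
    read_id: str
    gene_id: str
    identity: float
    length: int
    score: int


@dataclass
class CandidateSet:
    """Rootstock genes nominated by rescued reads in one sample."""

    support: dict[str, int]
    sample: SampleKey | None = None
    params: dict = field(default_factory=dict)

    def gene_ids(self) -> set[str]:
        return set(self.support)


def gene_sequences(genome: dict[str, str],
                   genes: list[GeneModel]) -> dict[str, str]:
    """Transcript sequence per gene id, extracted from a genome."""
    return {g.gene_id: extract_transcript(genome, g) for g in genes}


def map_to_scion(reads: ReadBatch, reference: dict[str, str],
                 params: MappingParams | None = None
                 ) -> tuple[set[str], set[str]]:
    """Partition pair ids into (mapped, unmapped) against the scion reference."""
    params = params or MappingParams()
    if len(reads) == 0:
        raise ValueError("read batch is empty")
    if not reference or all(len(s) == 0 for s in reference.values()):
        log.warning("empty scion reference: every read pair is unmapped")
        return set(), set(reads.ids)
    k = choose_seed_k(params.k, reads.read_length, params.min_identity)
    index = ReferenceIndex(reference, k)
    mapped: set[str] = set()
    unmapped: set[str] = set()
    for rid, m1, m2 in zip(reads.ids, reads.mate1, reads.mate2):
        ok1 = bool(map_read(m1, index, params.min_identity,
                            params.min_aligned_fraction))
        ok2 = bool(map_read(m2, index, params.min_identity,
                            params.min_aligned_fraction))
        if params.pair_rule == "either_mate":
            is_mapped = ok1 or ok2
        else:
            is_mapped = ok1 and ok2
        (mapped if is_mapped else unmapped).add(rid)
    log.info("map_to_scion: %d mapped / %d unmapped of %d pairs",
             len(mapped), len(unmapped), len(reads))
    return mapped, unmapped


def match_unmapped_to_rootstock(reads: ReadBatch, unmapped_ids: set[str],
                                rootstock_genes: dict[str, str],
                                params: MatchParams | None = None
                                ) -> list[RootstockHit]:
    """Best qualifying rootstock-gene hit per rescued mate.

    Each mate of an unmapped pair is matched independently; mates with no
    qualifying hit (or a score tie between genes) are silently dropped.
    """
    params = params or MatchParams()
    if not rootstock_genes:
        return []
    index = ReferenceIndex(rootstock_genes, params.k)
    hits: list[RootstockHit] = []
    for rid, m1, m2 in zip(reads.ids, reads.mate1, reads.mate2):
        if rid not in unmapped_ids:
            continue
        for mate_no, seq in ((1, m1), (2, m2)):
            hit = best_local_hit(seq, index, params.min_identity,
                                 params.min_hit_length)
            if hit is not None:
                hits.append(RootstockHit(f"{rid}/{mate_no}", hit.name,
                                         hit.identity, hit.length,
                                         hit.score))
    log.info("match_unmapped_to_rootstock: %d hits from %d unmapped pairs",
             len(hits), len(unmapped_ids))
    return hits


def call_candidates(hits: list[RootstockHit], min_read_support: int = 2,
                    sample: SampleKey | None = None) -> CandidateSet:
    """Genes with at least ``min_read_support`` supporting rescued reads."""
    if min_read_support < 1:
        raise ValueError("min_read_support must be at least 1")
    support: dict[str, int] = {}
    for h in hits:
        support[h.gene_id] = support.get(h.gene_id, 0) + 1
    support = {g: c for g, c in support.items() if c >= min_read_support}
    return CandidateSet(support=support, sample=sample,
                        params={"min_read_support": min_read_support})


def classify_sample(reads: ReadBatch, reference: dict[str, str],
                    rootstock_genes: dict[str, str],
                    mapping: MappingParams | None = None,
                    matching: MatchParams | None = None,
                    min_read_support: int = 2) -> CandidateSet:
    """Full per-sample classification: map, rescue, nominate candidates."""
    _, unmapped = map_to_scion(reads, reference, mapping)
    if not unmapped:
        return CandidateSet(support={}, sample=reads.sample,
                            params={"min_read_support": min_read_support})
    hits = match_unmapped_to_rootstock(reads, unmapped, rootstock_genes,
                                       matching)
    return call_candidates(hits, min_read_support, sample=reads.sample)
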