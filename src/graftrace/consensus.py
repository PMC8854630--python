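"""Consensus reconstruction of the true scion reference.

The cultivar actually grown differs from its published reference assembly by
point variants, so reads from that cultivar are best interpreted against a
reconstructed reference: DNA resequencing reads are placed on the published
assembly (gapless seed-and-extend, best unique placement), base counts are
piled up per reference column, and at well-supported columns the majority
base replaces the published one.  Columns below the depth or majority
thresholds conservatively retain the published base, as do ties, so the
procedure never fabricates variants from thin or conflicting evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import _seq
from .align import ReferenceIndex, choose_seed_k, map_read
from .simulate import ReadBatch, Variant

log = logging.getLogger(__name__)


@dataclass
class PileupParams:
    k: int = 21
    #: identity required over the full read for a placement to count
    min_identity: float = 0.9


@dataclass
class ConsensusParams:
    min_depth: int = 3
    min_majority: float = 0.8


@dataclass
class Pileup:
    """Per-column base counts against the published reference.

    ``counts[contig]`` is a 4 x L array over the A/C/G/T code alphabet;
    column depth is the vertical sum.  Reads that fail the identity
    threshold, or align equally well to more than one location, contribute
    nothing.
    """

    counts: dict[str, np.ndarray]
    n_reads_used: int = 0
    n_reads_discarded: int = 0

    def depth(self, contig: str) -> np.ndarray:
        return self.counts[contig].sum(axis=0)


class CalledVariant(NamedTuple):
    contig: str
    pos: int
    ref: str
    alt: str
    depth: int
    fraction: float


@dataclass
class ReconstructedReference:
    sequences: dict[str, str]
    called_variants: list[CalledVariant] = field(default_factory=list)


def _iter_mates(reads: ReadBatch):
    for rid, m1, m2 in zip(reads.ids, reads.mate1, reads.mate2):
        yield f"{rid}/1", m1
        yield f"{rid}/2", m2


def build_pileup(dna_reads: ReadBatch, published_ref: dict[str, str],
                 params: PileupParams | None = None) -> Pileup:
    """Place each mate at its best unique location and count bases."""
    params = params or PileupParams()
    if not published_ref:
        raise ValueError("published reference is empty")
    k = choose_seed_k(params.k, dna_reads.read_length, params.min_identity)
    index = ReferenceIndex(published_ref, k)
    counts = {c: np.zeros((4, len(s)), dtype=np.int32)
              for c, s in published_ref.items()}
    used = discarded = 0
    for _, seq in _iter_mates(dna_reads):
        if len(seq) != dna_reads.read_length:
            raise ValueError("malformed read: length differs from batch "
                             "read_length")
        placements = map_read(seq, index, params.min_identity,
                              min_aligned_fraction=1.0)
        if len(placements) != 1:
            # unplaced, or ambiguous between equally good locations
            discarded += 1
            continue
        p = placements[0]
        codes = _seq.encode(seq if p.strand == "+" else _seq.revcomp(seq))
        cols = np.arange(p.pos, p.pos + p.aligned_length)
        np.add.at(counts[p.contig], (codes, cols), 1)
        used += 1
    return Pileup(counts=counts, n_reads_used=used,
                  n_reads_discarded=discarded)


def call_consensus(pileup: Pileup, published_ref: dict[str, str],
                   params: ConsensusParams | None = None
                   ) -> ReconstructedReference:
    """Majority-base consensus over the pileup; published base elsewhere."""
    params = params or ConsensusParams()
    sequences: dict[str, str] = {}
    variants: list[CalledVariant] = []
    for contig, ref_seq in published_ref.items():
        ref_codes = _seq.encode(ref_seq)
        if contig not in pileup.counts:
            sequences[contig] = ref_seq
            continue
        counts = pileup.counts[contig]
        depth = counts.sum(axis=0)
        top = counts.argmax(axis=0).astype(np.uint8)
        top_count = counts.max(axis=0)
        # a tie for the top base resolves to the published base
        n_top = (counts == top_count[None, :]).sum(axis=0)
        tied = (n_top > 1) & (depth > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(depth > 0, top_count / depth, 0.0)
        call = (depth >= params.min_depth) & (frac >= params.min_majority) \
            & ~tied
        out = np.where(call, top, ref_codes).astype(np.uint8)
        for pos in np.flatnonzero(out != ref_codes):
            variants.append(CalledVariant(
                contig, int(pos), _seq.BASES[ref_codes[pos]],
                _seq.BASES[out[pos]], int(depth[pos]), float(frac[pos])))
        sequences[contig] = _seq.decode(out)
    log.info("consensus: %d variant positions called", len(variants))
    return ReconstructedReference(sequences=sequences,
                                  called_variants=variants)


def reconstruct(dna_reads: ReadBatch, published_ref: dict[str, str],
                pileup_params: PileupParams | None = None,
                consensus_params: ConsensusParams | None = None
                ) -> ReconstructedReference:
    """Convenience: pileup construction followed by consensus calling."""
    pileup = build_pileup(dna_reads, published_ref, pileup_params)
    return call_consensus(pileup, published_ref, consensus_params)


def variant_recovery(called: list[CalledVariant],
                     truth: list[Variant]) -> tuple[float, int]:
    """(recall of planted variants, number of false variant calls)."""
    truth_set = {(v.contig, v.pos, v.alt) for v in truth}
    called_set = {(v.contig, v.pos, v.alt) for v in called}
    recall = (len(truth_set & called_set) / len(truth_set)) if truth_set else 1.0
    false_calls = len(called_set - truth_set)
    return recall, false_calls
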