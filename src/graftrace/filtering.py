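"""Homograft-based false-positive removal.

A homograft carries the same species on both sides of the graft union, so
any of its scion reads that escape the reconstructed reference and match the
rootstock genome cannot be mobile transcripts — they expose systematic
artifacts (conserved genes, reference gaps, error-mangled reads).  Rootstock
genes nominated by homograft data are therefore subtracted, gene-level,
from the heterograft candidate set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .classify import (CandidateSet, MappingParams, MatchParams,
                       call_candidates, map_to_scion,
                       match_unmapped_to_rootstock)
from .simulate import ReadBatch

log = logging.getLogger(__name__)


@dataclass
class MobileCallSet:
    """Final mobile calls for one condition after the homograft filter."""

    final: dict[str, int]            # gene id -> supporting read count
    false_positives: set[str]
    condition: str | None = None
    provenance: dict = field(default_factory=dict)

    def gene_ids(self) -> set[str]:
        return set(self.final)


def derive_false_positives(homograft_reads: ReadBatch,
                           reference: dict[str, str],
                           rootstock_genes: dict[str, str],
                           mapping: MappingParams | None = None,
                           matching: MatchParams | None = None,
                           min_read_support: int = 2) -> set[str]:
    """Rootstock genes matched by rescued *homograft* reads.

    Runs the identical two-stage classification the heterograft sample went
    through; the same thresholds must be used for the subtraction to be
    meaningful.
    """
    sample = homograft_reads.sample
    if sample is not None and sample.graft != "homo":
        raise ValueError(
            f"false-positive derivation requires a homograft sample, got "
            f"graft type {sample.graft!r}")
    if len(homograft_reads) == 0:
        return set()
    _, unmapped = map_to_scion(homograft_reads, reference, mapping)
    if not unmapped:
        return set()
    hits = match_unmapped_to_rootstock(homograft_reads, unmapped,
                                       rootstock_genes, matching)
    fp = call_candidates(hits, min_read_support).gene_ids()
    log.info("derive_false_positives: %d gene(s) flagged", len(fp))
    return fp


def filter_candidates(candidates: CandidateSet,
                      false_positives: set[str]) -> MobileCallSet:
    """Subtract the false-positive genes; support counts are preserved."""
    final = {g: c for g, c in candidates.support.items()
             if g not in false_positives}
    condition = candidates.sample.condition if candidates.sample else None
    return MobileCallSet(
        final=final,
        false_positives=set(false_positives),
        condition=condition,
        provenance={"n_candidates": len(candidates.support),
                    "params": dict(candidates.params)},
    )
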