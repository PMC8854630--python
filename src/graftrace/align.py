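"""Gapless seed-and-extend alignment.

Two primitives back the whole pipeline:

* :func:`map_read` — end-to-end (glocal) placement of a read on a reference,
  scored by matches over the aligned span, used for reference mapping and
  pileup construction.  Indels are not modelled anywhere in the simulator,
  so the alignment model is deliberately gapless.
* :func:`best_local_hit` — best gapless local alignment of a read against a
  collection of gene sequences (match +1 / mismatch -2), used to rescue
  unmapped reads against the rootstock gene space.

Seeding uses exact k-mers.  For end-to-end mapping the seed windows are
disjoint and their length is shrunk (never grown) from the configured ``k``
so that, by pigeonhole, any placement with at most ``floor((1-min_identity)
* L)`` mismatches shares at least one exact seed window with the reference;
when the read is too short for that guarantee every k-mer start position is
probed instead.  Local matching probes every k-mer of the read; like any
seeded local aligner it can only recover alignments that contain one exact
k-mer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seq

_MIN_SEED = 11


@dataclass(frozen=True)
class Placement:
    contig: str
    pos: int            # 0-based leftmost reference column
    strand: str         # '+' or '-'
    matches: int
    aligned_length: int

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length if self.aligned_length else 0.0

    @property
    def mismatches(self) -> int:
        return self.aligned_length - self.matches


@dataclass(frozen=True)
class LocalHit:
    name: str           # gene id
    score: int          # +1 match / -2 mismatch over the best segment
    length: int
    matches: int
    strand: str

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


class ReferenceIndex:
    """Exact k-mer index over a named collection of sequences."""

    def __init__(self, sequences: dict[str, str], k: int):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.names = list(sequences)
        self.codes = {n: _seq.encode(s) for n, s in sequences.items()}
        index: dict[str, list[tuple[str, int]]] = {}
        for name, s in sequences.items():
            for i in range(len(s) - k + 1):
                index.setdefault(s[i:i + k], []).append((name, i))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, ())


def choose_seed_k(k: int, read_length: int, min_identity: float) -> int:
    """Index k-mer size for end-to-end mapping at the given threshold.

    Shrinks ``k`` (never below a floor of 11) so that ``read_length // k``
    disjoint seed windows exceed the maximum tolerated mismatch count; any
    qualifying placement then shares at least one exact seed by pigeonhole.
    If even the floor cannot provide the guarantee the configured ``k`` is
    kept and the mapper probes every k-mer start instead (best effort).
    """
    max_mm = int((1.0 - min_identity) * read_length)
    k_eff = min(k, read_length // (max_mm + 1))
    return k_eff if k_eff >= _MIN_SEED else k


def _candidate_diagonals(read: str, index: ReferenceIndex,
                         offsets: range) -> set[tuple[str, int]]:
    k = index.k
    cands: set[tuple[str, int]] = set()
    for off in offsets:
        for name, pos in index.lookup(read[off:off + k]):
            cands.add((name, pos - off))
    return cands


def _score_glocal(read_codes: np.ndarray, ref_codes: np.ndarray,
                  start: int, min_aligned: int) -> tuple[int, int, int] | None:
    """Matches over the clipped overlap of a diagonal placement."""
    L = read_codes.size
    s = max(start, 0)
    e = min(start + L, ref_codes.size)
    aligned = e - s
    if aligned < min_aligned:
        return None
    mm = int(np.count_nonzero(read_codes[s - start:e - start]
                              != ref_codes[s:e]))
    return s, aligned, aligned - mm


def map_read(read: str, index: ReferenceIndex, min_identity: float,
             min_aligned_fraction: float = 1.0) -> list[Placement]:
    """All best-scoring qualifying end-to-end placements of ``read``.

    Returns the (possibly tied) placements with the highest match count among
    those with identity >= ``min_identity`` over at least
    ``min_aligned_fraction`` of the read; empty list if none qualifies.
    """
    L = len(read)
    if L < index.k:
        return []
    min_aligned = max(int(np.ceil(min_aligned_fraction * L)), index.k)
    max_mm = int((1.0 - min_identity) * L)
    if L // index.k > max_mm:
        # disjoint windows suffice: pigeonhole guarantees seed survival
        offsets = range(0, (L // index.k) * index.k, index.k)
    else:
        offsets = range(0, L - index.k + 1)

    best: list[Placement] = []
    best_matches = -1
    for strand, seq in (("+", read), ("-", _seq.revcomp(read))):
        codes = _seq.encode(seq)
        for name, start in _candidate_diagonals(seq, index, offsets):
            scored = _score_glocal(codes, index.codes[name], start,
                                   min_aligned)
            if scored is None:
                continue
            s, aligned, matches = scored
            if matches / aligned < min_identity:
                continue
            if matches > best_matches:
                best = [Placement(name, s, strand, matches, aligned)]
                best_matches = matches
            elif matches == best_matches:
                p = Placement(name, s, strand, matches, aligned)
                if p not in best:
                    best.append(p)
    return best


def _best_segment(match: np.ndarray) -> tuple[int, int, int, int]:
    """Best-scoring gapless local segment of a match/mismatch column vector.

    Kadane's scan with match +1, mismatch -2.  Returns (score, start, end,
    matches) with end exclusive; all zeros when every column mismatches.
    """
    best_score = 0
    best_s = best_e = 0
    cur = 0
    cur_s = 0
    for i, m in enumerate(match):
        cur += 1 if m else -2
        if cur <= 0:
            cur = 0
            cur_s = i + 1
        elif cur > best_score:
            best_score = cur
            best_s, best_e = cur_s, i + 1
    if best_e == best_s:
        return 0, 0, 0, 0
    n_match = int(np.count_nonzero(match[best_s:best_e]))
    return best_score, best_s, best_e, n_match


def best_local_hit(read: str, index: ReferenceIndex, min_identity: float,
                   min_length: int) -> LocalHit | None:
    """Best qualifying gapless local hit of ``read`` across indexed genes.

    At most one hit is reported; a score tie between *different* genes
    yields ``None`` so downstream candidate calls stay deterministic.
    """
    L = len(read)
    if L < index.k:
        return None
    offsets = range(0, L - index.k + 1)
    best: LocalHit | None = None
    tied_other_gene = False
    for strand, seq in (("+", read), ("-", _seq.revcomp(read))):
        codes = _seq.encode(seq)
        for name, start in _candidate_diagonals(seq, index, offsets):
            ref = index.codes[name]
            s = max(start, 0)
            e = min(start + L, ref.size)
            if e - s < min_length:
                continue
            match = codes[s - start:e - start] == ref[s:e]
            score, seg_s, seg_e, n_match = _best_segment(match)
            seg_len = seg_e - seg_s
            if seg_len < min_length or n_match / seg_len < min_identity:
                continue
            hit = LocalHit(name, score, seg_len, n_match, strand)
            if best is None or score > best.score:
                best = hit
                tied_other_gene = False
            elif score == best.score and name != best.name:
                tied_other_gene = True
    if best is not None and tied_other_gene:
        return None
    return best
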