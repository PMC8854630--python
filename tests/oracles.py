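"""Independent brute-force oracles for alignment and enrichment.

Deliberately naive re-implementations: exhaustive sliding-window scans and
exact combinatorial sums, sharing no code with the package's seed-and-extend
paths.  Small inputs only.
"""

from __future__ import annotations

import math

import numpy as np

COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def brute_glocal_placements(read: str, refs: dict[str, str],
                            min_identity: float,
                            min_aligned_fraction: float):
    """Every best-scoring end-to-end placement by exhaustive sliding windows.

    Scans every contig, strand and offset (including partial overlaps at the
    contig ends), counts mismatches column by column, applies the thresholds
    and returns the best-match-count placements as
    (contig, ref_start, strand, matches, aligned_length) tuples.
    """
    L = len(read)
    min_aligned = math.ceil(min_aligned_fraction * L)
    best, best_matches = [], -1
    for strand in "+-":
        seq = read if strand == "+" else rc(read)
        for name, ref in refs.items():
            for diag in range(-L + 1, len(ref)):
                s = max(diag, 0)
                e = min(diag + L, len(ref))
                aligned = e - s
                if aligned < min_aligned:
                    continue
                matches = sum(1 for i in range(s, e)
                              if ref[i] == seq[i - diag])
                if matches / aligned < min_identity:
                    continue
                if matches > best_matches:
                    best_matches = matches
                    best = [(name, s, strand, matches, aligned)]
                elif matches == best_matches:
                    best.append((name, s, strand, matches, aligned))
    return best


def brute_best_local_hit(read: str, genes: dict[str, str],
                         min_identity: float, min_length: int):
    """Best gapless local alignment by exhaustive segment enumeration.

    For every gene, strand and diagonal, every (start, end) sub-segment of
    the overlap is scored (+1 match / -2 mismatch) via prefix sums; the
    best qualifying segment wins.  Ties between different genes return
    None, matching the pipeline's deterministic-candidate rule.
    """
    L = len(read)
    best = None  # (score, gene)
    tied = False
    for strand in "+-":
        seq = read if strand == "+" else rc(read)
        for name, gene in genes.items():
            for diag in range(-L + 1, len(gene)):
                s = max(diag, 0)
                e = min(diag + L, len(gene))
                if e - s < min_length:
                    continue
                m = np.fromiter((gene[i] == seq[i - diag]
                                 for i in range(s, e)), dtype=bool)
                pref = np.concatenate([[0], np.cumsum(np.where(m, 1, -2))])
                mpref = np.concatenate([[0], np.cumsum(m.astype(int))])
                n = len(m)
                # all (i, j) segments at once: rows i, columns j
                score = pref[None, :] - pref[:, None]
                nm = mpref[None, :] - mpref[:, None]
                span = np.arange(n + 1)[None, :] - np.arange(n + 1)[:, None]
                ok = (span >= min_length) & (nm >= min_identity * span)
                if not ok.any():
                    continue
                seg_best = int(score[ok].max())
                if best is None or seg_best > best[0]:
                    best = (seg_best, name)
                    tied = False
                elif seg_best == best[0] and name != best[1]:
                    tied = True
    if best is None or tied:
        return None
    return best  # (score, gene_id)


def hypergeom_upper_tail(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeom(N, K, n), by exact enumeration."""
    denom = math.comb(N, n)
    total = 0
    for i in range(x, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def venn_regions_by_membership(named_sets: dict[str, set]):
    """Exclusive-region counts by per-element membership tabulation."""
    names = list(named_sets)
    regions: dict[tuple[str, ...], int] = {}
    universe = set().union(*named_sets.values())
    for el in universe:
        key = tuple(n for n in names if el in named_sets[n])
        regions[key] = regions.get(key, 0) + 1
    return regions


def fpkm_single(count: float, length_bp: float, library_size: float) -> float:
    return count * 1e9 / (length_bp * library_size)


def ddct_single(ct_t: float, ct_r: float, cal_dcts: list[float]) -> float:
    return 2.0 ** -((ct_t - ct_r) - sum(cal_dcts) / len(cal_dcts))
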