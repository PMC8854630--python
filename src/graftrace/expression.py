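"""Expression quantification, DEG screening, set algebra, enrichment.

FPKM is computed from raw fragment counts; differential expression uses the
screening rule P < .05 and |log2 fold change| > 1 on top of a deliberately
simple two-group test (Welch's t on log2 of median-of-ratios-normalized
counts plus one).  The screen reproduces the selection rule, not any
particular dispersion model.  Venn partitioning is exact over memberships,
and term enrichment is the upper-tail hypergeometric probability.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# FPKM


@dataclass
class ExpressionTable:
    counts: pd.DataFrame         # genes x samples, integer fragments
    lengths: pd.Series           # bp per gene
    fpkm: pd.DataFrame
    library_sizes: pd.Series


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> ExpressionTable:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM(g, s) = count(g, s) * 1e9 / (length(g) * library_size(s)) with the
    library size being the column sum of raw counts.
    """
    counts = counts.loc[:, :]
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(counts.to_numpy(),
                       np.round(counts.to_numpy())):
        raise ValueError("counts must be integral")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    lib = counts.sum(axis=0)
    zero_lib = lib[lib == 0]
    if len(zero_lib):
        log.warning("zero library size for sample(s) %s: FPKM set to 0",
                    list(zero_lib.index))
    denom = lengths.to_numpy()[:, None] * lib.to_numpy()[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        fpkm = np.where(denom > 0, counts.to_numpy() * 1e9 / denom, 0.0)
    return ExpressionTable(counts=counts, lengths=lengths,
                           fpkm=pd.DataFrame(fpkm, index=counts.index,
                                             columns=counts.columns),
                           library_sizes=lib)


# ----------------------------------------------------------------------
# DEG screening


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Ratios are taken against the geometric mean over genes with all-positive
    counts; if no such gene exists, factors fall back to relative library
    sizes.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if positive.sum() == 0:
        lib = x.sum(axis=0)
        ref = np.exp(np.mean(np.log(lib[lib > 0]))) if (lib > 0).any() else 1.0
        return pd.Series(np.where(lib > 0, lib / ref, 1.0),
                         index=counts.columns)
    logs = np.log(x[positive])
    log_gm = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_gm, axis=0))
    return pd.Series(sf, index=counts.columns)


def screen_degs(counts: pd.DataFrame, group_a: list[str],
                group_b: list[str], alpha: float = 0.05,
                lfc_threshold: float = 1.0, pseudocount: float = 1.0,
                adjust: str | None = None) -> pd.DataFrame:
    """Two-group differential-expression screen.

    Fold change is log2((mean_b + c) / (mean_a + c)) on normalized counts
    (treatment ``group_b`` over control ``group_a``); the p-value is a
    two-sided Welch t-test on log2(normalized count + c).  A gene passes
    when p < ``alpha`` and |log2FC| > ``lfc_threshold``.  ``adjust='bh'``
    additionally reports Benjamini-Hochberg q-values (and then gates the
    pass flag on the adjusted value).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two samples per group")
    sub = counts[list(group_a) + list(group_b)]
    sf = size_factors(sub)
    norm = sub / sf
    a = norm[list(group_a)].to_numpy(dtype=float)
    b = norm[list(group_b)].to_numpy(dtype=float)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    lfc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)

    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    # identical groups (zero variance, zero difference) -> no evidence
    p = np.where(np.isnan(p), 1.0, p)

    out = pd.DataFrame({
        "log2fc": lfc,
        "pvalue": p,
    }, index=sub.index)
    crit = out["pvalue"].to_numpy()
    if adjust == "bh":
        out["padj"] = _benjamini_hochberg(out["pvalue"].to_numpy())
        crit = out["padj"].to_numpy()
    elif adjust not in (None, "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["passed"] = (crit < alpha) & (np.abs(out["log2fc"]) > lfc_threshold)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


# ----------------------------------------------------------------------
# Venn partitioning


@dataclass
class VennPartition:
    """Exclusive-region membership for a family of named sets.

    ``regions`` maps a tuple of set names (the sets a region belongs to,
    in input order) to the ids exclusive to exactly those sets; empty
    regions are retained with empty member sets.
    """

    names: list[str]
    regions: dict[tuple[str, ...], set] = field(default_factory=dict)

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def only(self, name: str) -> set:
        return self.regions[(name,)]

    def common(self) -> set:
        return self.regions[tuple(self.names)]


def venn_partition(named_sets: dict[str, set]) -> VennPartition:
    """Exact exclusive-region partition of >= 2 named sets."""
    if len(named_sets) < 2:
        raise ValueError("need at least two sets")
    names = list(named_sets)
    sets = {n: set(s) for n, s in named_sets.items()}
    regions: dict[tuple[str, ...], set] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names
                                  if n not in combo)) \
                if len(combo) < len(names) else set()
            regions[combo] = inside - outside
    return VennPartition(names=names, regions=regions)


def sets_with_overlap(n_a: int, n_b: int, n_common: int,
                      prefix: str = "id") -> tuple[set, set]:
    """Construct two id sets realizing given cardinalities and overlap."""
    if n_common > min(n_a, n_b):
        raise ValueError("overlap exceeds a set size")
    common = {f"{prefix}_c{i:05d}" for i in range(n_common)}
    only_a = {f"{prefix}_a{i:05d}" for i in range(n_a - n_common)}
    only_b = {f"{prefix}_b{i:05d}" for i in range(n_b - n_common)}
    return common | only_a, common | only_b


# ----------------------------------------------------------------------
# hypergeometric enrichment


def hypergeom_enrich(selected: set, universe: set,
                     annotations: dict[str, set],
                     adjust: str | None = "bh") -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment.

    For a term annotating K of the N universe genes, with n genes selected
    and x of them annotated, p = P(X >= x) for X ~ Hypergeom(N, K, n).
    Terms with no annotated universe member are skipped with a warning.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N = len(universe)
    n = len(selected)
    rows = []
    for term, members in annotations.items():
        ann = set(members) & universe
        K = len(ann)
        if K == 0:
            log.warning("term %s annotates no universe member; skipped", term)
            continue
        x = len(ann & selected)
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        rows.append({"term": term, "universe": N, "annotated": K,
                     "selected": n, "overlap": x, "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows,
                       columns=["term", "universe", "annotated", "selected",
                                "overlap", "pvalue"])
    if len(out) and adjust == "bh":
        out["padj"] = _benjamini_hochberg(out["pvalue"].to_numpy())
    elif len(out):
        out["padj"] = out["pvalue"]
    return out.sort_values("pvalue", kind="stable").reset_index(drop=True)
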