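"""Synthetic grafted-transcriptome generator.

Emulates the grafting study design the detection pipeline is built for:

* a **published scion reference** that differs from the **true scion genome**
  by point variants (the cultivar actually grown is never identical to the
  assembly it is mapped against);
* a **rootstock genome** whose gene space mirrors the scion's at a controlled
  divergence, except for a small set of genes conserved verbatim between the
  two species — the classic source of false-positive mobility calls;
* per-sample transcript abundances over a (graft type x watering condition x
  days-after-stress) grid, with a planted mobile subset whose abundance in
  heterograft scions grows with stress exposure, and a planted set of
  differentially expressed scion genes;
* paired-end reads with independent substitution errors, retaining the gene
  and genome of origin of every read as hidden truth.

By default the conserved bait genes sit on an unassembled scaffold of the
true scion genome that the published reference lacks: their scion-origin
reads systematically fail reference mapping and rescue against the conserved
rootstock homolog, in homografts and heterografts alike, which is precisely
the artifact the homograft control is designed to subtract.  Set
``n_unassembled_conserved=0`` for a fully assembled reference.

Randomness: one root seed; every operation and sample draws from its own
child stream derived as ``sha256(root_seed, tag)``, so adding a sample never
shifts another sample's reads.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import _seq
from .config import SimulationConfig

GRAFTS = ("homo", "hetero")


def rng_stream(seed: int, *tags) -> np.random.Generator:
    """Child RNG for (root seed, tag...) — documented derivation.

    The tag tuple is rendered to text, hashed with SHA-256 together with the
    root seed, and the first 8 bytes seed a PCG64 generator.
    """
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for t in tags:
        h.update(b"\x1f")
        h.update(str(t).encode())
    child = int.from_bytes(h.digest()[:8], "little")
    return np.random.default_rng(child)


# ----------------------------------------------------------------------
# domain types


class Variant(NamedTuple):
    contig: str
    pos: int          # 0-based
    ref: str
    alt: str


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    strand: str                       # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # 0-based half-open
    origin: str                       # 'scion' or 'rootstock'

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GenomeTriple:
    """Published scion reference, true scion genome, rootstock genome.

    ``true_scion`` equals ``published_ref`` plus ``scion_variants`` on every
    published contig; it may additionally carry one unassembled contig
    holding conserved bait genes.  Every conserved gene's rootstock sequence
    is identical to its true-scion counterpart.
    """

    published_ref: dict[str, str]
    true_scion: dict[str, str]
    rootstock: dict[str, str]
    scion_variants: list[Variant]
    conserved_gene_ids: set[str]
    unassembled_gene_ids: set[str]
    scion_genes: list[GeneModel]
    rootstock_genes: list[GeneModel]
    provenance: str = ""

    def genes_of(self, origin: str) -> list[GeneModel]:
        return self.scion_genes if origin == "scion" else self.rootstock_genes


@dataclass(frozen=True)
class SampleKey:
    graft: str       # 'homo' | 'hetero'
    condition: str   # 'WW' | 'WS'
    das: int         # days after stress onset

    @property
    def label(self) -> str:
        return f"{self.graft}_{self.condition}_d{self.das}"


@dataclass
class TranscriptSet:
    """Gene models plus per-sample expected abundances and planted truth.

    ``weights`` holds unnormalized expected fragment weights (gene x sample);
    ``abundance`` is the per-sample normalization of ``weights`` to sum 1.
    ``mobile_truth`` is the planted set of rootstock gene ids present in
    heterograft scion samples; ``de_truth`` the scion genes carrying the
    planted fold change between WW and WS.
    """

    genes: list[GeneModel]
    sequences: dict[str, str]             # gene id -> transcript sequence
    weights: pd.DataFrame                 # index gene id, columns sample label
    samples: list[SampleKey]
    mobile_truth: set[str]
    de_truth: set[str]
    de_log2fc: dict[str, float]           # signed planted effect per DE gene
    annotations: dict[str, set[str]] = field(default_factory=dict)

    @property
    def abundance(self) -> pd.DataFrame:
        sums = self.weights.sum(axis=0)
        return self.weights / sums.replace(0.0, np.nan)

    def sample(self, graft: str, condition: str, das: int) -> SampleKey:
        key = SampleKey(graft, condition, das)
        if key.label not in self.weights.columns:
            raise KeyError(f"sample {key.label} not in abundance table")
        return key

    def lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.length for g in self.genes},
                         name="length")


@dataclass
class ReadBatch:
    """Paired-end reads with hidden per-read truth labels."""

    ids: list[str]
    mate1: list[str]
    mate2: list[str]
    truth_gene: list[str]      # gene (or contig, for DNA reads) of origin
    truth_genome: list[str]    # 'scion' | 'rootstock'
    read_length: int
    sample: SampleKey | None = None

    def __len__(self) -> int:
        return len(self.ids)

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("mate1", "mate2", "truth_gene", "truth_genome"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} does not cover every read")


# ----------------------------------------------------------------------
# genome simulation


def _spacer(rng: np.random.Generator, n: int) -> np.ndarray:
    return _seq.random_codes(rng, n)


def simulate_genomes(config: SimulationConfig) -> GenomeTriple:
    """Generate the published/true scion pair and the rootstock genome."""
    config.validate()
    rng = rng_stream(config.seed, "genomes")
    n = config.n_genes
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    conserved_idx = list(range(config.n_conserved_genes))
    unassembled_idx = set(conserved_idx[: config.effective_n_unassembled])
    mobile_pool = [i for i in range(n) if i not in set(conserved_idx)]
    mobile_idx = set(mobile_pool[: config.n_mobile_genes])

    scion_ids = [f"CsaSynG{i:04d}" for i in range(n)]
    rootstock_ids = [f"CmoSynG{i:04d}" for i in range(n)]

    # true scion gene sequences are the ground truth everything derives from
    gene_codes = [_seq.random_codes(rng, int(L)) for L in lengths]

    spacer = config.intergenic_length

    def build_contig(idx: list[int], seqs: list[np.ndarray], ids: list[str],
                     contig: str, origin: str):
        parts, genes, cursor = [], [], 0
        for i in idx:
            gap = _spacer(rng, spacer)
            parts.append(gap)
            cursor += gap.size
            start = cursor
            parts.append(seqs[i])
            cursor += seqs[i].size
            genes.append(GeneModel(ids[i], contig, str(strands[i]),
                                   ((start, cursor),), origin))
        parts.append(_spacer(rng, spacer))
        return np.concatenate(parts) if parts else np.empty(0, np.uint8), genes

    assembled = [i for i in range(n) if i not in unassembled_idx]
    chr1_true, genes_chr1 = build_contig(assembled, gene_codes, scion_ids,
                                         "chr1", "scion")

    # published reference = true scion minus the planted cultivar variants
    published_chr1, var_pos = _seq.mutate_codes(rng, chr1_true,
                                                config.scion_snp_rate)
    variants = [
        Variant("chr1", int(p), _seq.BASES[published_chr1[p]],
                _seq.BASES[chr1_true[p]])
        for p in var_pos
    ]

    published = {"chr1": _seq.decode(published_chr1)}
    true_scion = {"chr1": _seq.decode(chr1_true)}
    scion_genes = list(genes_chr1)

    if unassembled_idx:
        chr_un, genes_un = build_contig(sorted(unassembled_idx), gene_codes,
                                        scion_ids, "chrUn", "scion")
        true_scion["chrUn"] = _seq.decode(chr_un)
        scion_genes += genes_un
    scion_genes.sort(key=lambda g: g.gene_id)

    # rootstock gene space mirrors the scion's: conserved genes verbatim,
    # the rest diverged at the configured substitution rate
    rs_seqs = []
    for i in range(n):
        if i in set(conserved_idx):
            rs_seqs.append(gene_codes[i].copy())
        else:
            mutated, _ = _seq.mutate_codes(rng, gene_codes[i],
                                           config.rootstock_divergence)
            rs_seqs.append(mutated)
    rs_chr, rootstock_genes = build_contig(list(range(n)), rs_seqs,
                                           rootstock_ids, "rs_chr1",
                                           "rootstock")

    triple = GenomeTriple(
        published_ref=published,
        true_scion=true_scion,
        rootstock={"rs_chr1": _seq.decode(rs_chr)},
        scion_variants=variants,
        conserved_gene_ids={rootstock_ids[i] for i in conserved_idx},
        unassembled_gene_ids={scion_ids[i] for i in unassembled_idx},
        scion_genes=scion_genes,
        rootstock_genes=rootstock_genes,
        provenance=f"{config.content_hash()}:seed={config.seed}",
    )
    triple._mobile_candidate_ids = [rootstock_ids[i]  # type: ignore[attr-defined]
                                    for i in sorted(mobile_idx)]
    return triple


def extract_transcript(genome: dict[str, str], gene: GeneModel) -> str:
    seq = "".join(genome[gene.contig][s:e] for s, e in gene.exons)
    return _seq.revcomp(seq) if gene.strand == "-" else seq


# ----------------------------------------------------------------------
# transcriptome simulation


def default_samples(config: SimulationConfig,
                    das_points: tuple[int, ...] = (0, 4, 6, 11)
                    ) -> list[SampleKey]:
    return [SampleKey(g, c, d)
            for g in GRAFTS
            for c in config.mobile_condition_profile
            for d in das_points]


def simulate_transcriptome(genomes: GenomeTriple,
                           config: SimulationConfig,
                           das_points: tuple[int, ...] = (0, 4, 6, 11)
                           ) -> TranscriptSet:
    """Expected transcript abundances for every sample in the design grid."""
    rng = rng_stream(config.seed, "transcriptome")
    scion_ids = [g.gene_id for g in genomes.scion_genes]
    mobile_ids: list[str] = getattr(genomes, "_mobile_candidate_ids", None) or [
        g.gene_id for g in genomes.rootstock_genes
        if g.gene_id not in genomes.conserved_gene_ids
    ][: config.n_mobile_genes]
    if config.n_mobile_genes > len(genomes.rootstock_genes):
        raise ValueError("requested mobile genes exceed rootstock gene count")
    mobile_ids = mobile_ids[: config.n_mobile_genes]

    sequences = {g.gene_id: extract_transcript(
        genomes.true_scion if g.origin == "scion" else genomes.rootstock, g)
        for g in genomes.scion_genes + genomes.rootstock_genes}

    base = pd.Series(rng.lognormal(mean=0.0, sigma=0.8, size=len(scion_ids)),
                     index=scion_ids)

    de_ids = [str(g) for g in rng.choice(
        scion_ids, size=min(config.n_de_genes, len(scion_ids)),
        replace=False)]
    de_sign = {g: (1.0 if i % 2 == 0 else -1.0)
               for i, g in enumerate(de_ids)}
    de_lfc = {g: s * config.de_log2fc for g, s in de_sign.items()}

    samples = default_samples(config, das_points)
    mobile_base = config.mobile_expression * float(base.mean())

    cols = {}
    for key in samples:
        w = base.copy()
        if key.condition == "WS":
            for g, lfc in de_lfc.items():
                w[g] = w[g] * (2.0 ** lfc)
        mult = config.mobile_condition_profile.get(key.condition, 0.0)
        exposure = config.stress_exposure(key.condition, key.das)
        mobile_w = mobile_base * mult * (1.0 + config.mobile_stress_gain
                                         * exposure)
        rs = pd.Series(0.0, index=[g.gene_id for g in genomes.rootstock_genes])
        if key.graft == "hetero":
            rs[mobile_ids] = mobile_w
        cols[key.label] = pd.concat([w, rs])

    weights = pd.DataFrame(cols)
    genes = genomes.scion_genes + genomes.rootstock_genes

    # synthetic functional annotations: a handful of terms over the scion
    # universe, one of which collects the planted DE genes so the enrichment
    # screen has signal to find
    annotations: dict[str, set[str]] = {}
    pool = list(scion_ids)
    for t in range(6):
        size = int(rng.integers(5, 12))
        annotations[f"TERM:{t:04d}"] = set(
            rng.choice(pool, size=min(size, len(pool)), replace=False))
    annotations["TERM:STRESS"] = set(de_ids) | set(
        rng.choice(pool, size=min(4, len(pool)), replace=False))

    return TranscriptSet(
        genes=genes,
        sequences=sequences,
        weights=weights,
        samples=samples,
        mobile_truth=set(mobile_ids),
        de_truth=set(de_ids),
        de_log2fc=de_lfc,
        annotations=annotations,
    )


# ----------------------------------------------------------------------
# read simulation


def _fragments_to_reads(seq_codes: np.ndarray, starts: np.ndarray,
                        frag_len: int, read_len: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Extract mate code matrices for fragments at ``starts`` on one sequence."""
    idx = starts[:, None] + np.arange(frag_len)[None, :]
    frags = seq_codes[idx]
    m1 = frags[:, :read_len].copy()
    # mate 2 reads the reverse-complement strand from the fragment's far end
    m2 = (3 - frags[:, frag_len - read_len:])[:, ::-1].copy()
    return m1, m2


def _emit_batch(sources: list[tuple[str, str, np.ndarray, int]],
                config: SimulationConfig, rng: np.random.Generator,
                id_prefix: str, sample: SampleKey | None) -> ReadBatch:
    """Shared fragment machinery for RNA and DNA batches.

    ``sources`` rows are (label, genome_of_origin, code array, n_fragments).
    """
    L = config.read_length
    F = config.effective_fragment_length
    ids: list[str] = []
    m1s: list[str] = []
    m2s: list[str] = []
    tg: list[str] = []
    to: list[str] = []
    counter = 0
    for label, origin, codes, n_frag in sources:
        if n_frag <= 0:
            continue
        max_start = codes.size - F
        if max_start < 0:
            raise ValueError(
                f"sequence {label} shorter than fragment length {F}")
        starts = rng.integers(0, max_start + 1, size=n_frag)
        m1, m2 = _fragments_to_reads(codes, starts, F, L)
        _seq.apply_errors(rng, m1, config.sequencing_error_rate)
        _seq.apply_errors(rng, m2, config.sequencing_error_rate)
        for r in range(n_frag):
            ids.append(f"{id_prefix}{counter:07d}")
            m1s.append(_seq.decode(m1[r]))
            m2s.append(_seq.decode(m2[r]))
            tg.append(label)
            to.append(origin)
            counter += 1
    return ReadBatch(ids, m1s, m2s, tg, to, read_length=L, sample=sample)


def simulate_reads(transcripts: TranscriptSet, genomes: GenomeTriple,
                   config: SimulationConfig, sample: SampleKey,
                   depth: int | None = None) -> ReadBatch:
    """Paired-end RNA reads for one sample, multinomial over abundances."""
    if sample.label not in transcripts.weights.columns:
        raise KeyError(f"sample {sample.label} not in abundance table")
    depth = config.rna_depth if depth is None else depth
    rng = rng_stream(config.seed, "rna_reads", sample.label)
    if depth <= 0:
        return ReadBatch([], [], [], [], [], read_length=config.read_length,
                         sample=sample)
    ab = transcripts.abundance[sample.label]
    ab = ab.fillna(0.0)
    counts = rng.multinomial(depth, ab.to_numpy())
    origin = {g.gene_id: g.origin for g in transcripts.genes}
    sources = [
        (gid, origin[gid], _seq.encode(transcripts.sequences[gid]), int(c))
        for gid, c in zip(ab.index, counts) if c > 0
    ]
    return _emit_batch(sources, config, rng,
                       id_prefix=f"{sample.label}:", sample=sample)


def simulate_dna_reads(genomes: GenomeTriple,
                       config: SimulationConfig) -> ReadBatch:
    """Paired-end DNA resequencing reads, uniform over the true scion genome."""
    rng = rng_stream(config.seed, "dna_reads")
    F = config.effective_fragment_length
    total = sum(len(s) for s in genomes.true_scion.values())
    n_frag = int(round(total * config.dna_depth / F))
    if n_frag <= 0:
        return ReadBatch([], [], [], [], [], read_length=config.read_length)
    lens = np.array([len(genomes.true_scion[c]) - F + 1
                     for c in genomes.true_scion], dtype=float)
    lens = np.clip(lens, 0, None)
    if lens.sum() <= 0:
        raise ValueError("no contig is long enough for the fragment length")
    per = rng.multinomial(n_frag, lens / lens.sum())
    sources = [
        (contig, "scion", _seq.encode(genomes.true_scion[contig]), int(c))
        for contig, c in zip(genomes.true_scion, per)
    ]
    return _emit_batch(sources, config, rng, id_prefix="dna:", sample=None)


# ----------------------------------------------------------------------
# count-level simulation (expression screening)


def simulate_counts(transcripts: TranscriptSet, config: SimulationConfig,
                    sample: SampleKey, n_replicates: int | None = None,
                    depth: int | None = None) -> pd.DataFrame:
    """Replicate fragment-count vectors for one sample group (multinomial)."""
    depth = config.rna_depth if depth is None else depth
    n_rep = config.n_replicates if n_replicates is None else n_replicates
    ab = transcripts.abundance[sample.label].fillna(0.0).to_numpy()
    cols = {}
    for r in range(n_rep):
        rng = rng_stream(config.seed, "counts", sample.label, r)
        cols[f"{sample.label}_r{r + 1}"] = rng.multinomial(depth, ab)
    return pd.DataFrame(cols, index=transcripts.weights.index)


def simulate_deg_counts(n_genes: int, n_per_group: int, mean_depth: float,
                        dispersion: float, log2fc: float, frac_de: float,
                        rng: np.random.Generator
                        ) -> tuple[pd.DataFrame, list[str], list[str], set[str]]:
    """Negative-binomial two-group count table with a planted DE fraction.

    Per-gene means are lognormal around ``mean_depth``; counts are
    gamma-Poisson with the given dispersion.  Returns (table, group A
    columns, group B columns, planted DE gene ids).
    """
    genes = [f"g{i:05d}" for i in range(n_genes)]
    mu = mean_depth * rng.lognormal(0.0, 0.5, size=n_genes)
    n_de = int(round(frac_de * n_genes))
    de = set(rng.choice(genes, size=n_de, replace=False)) if n_de else set()
    sign = rng.choice([-1.0, 1.0], size=n_genes)

    def draw(mu_vec: np.ndarray, n_samples: int) -> np.ndarray:
        out = np.empty((n_genes, n_samples), dtype=np.int64)
        for j in range(n_samples):
            if dispersion > 0:
                lam = rng.gamma(shape=1.0 / dispersion,
                                scale=mu_vec * dispersion)
            else:
                lam = mu_vec
            out[:, j] = rng.poisson(lam)
        return out

    mu_b = mu.copy()
    for i, g in enumerate(genes):
        if g in de:
            mu_b[i] = mu[i] * 2.0 ** (sign[i] * log2fc)
    a = draw(mu, n_per_group)
    b = draw(mu_b, n_per_group)
    cols_a = [f"A_r{j + 1}" for j in range(n_per_group)]
    cols_b = [f"B_r{j + 1}" for j in range(n_per_group)]
    table = pd.DataFrame(np.hstack([a, b]), index=genes,
                         columns=cols_a + cols_b)
    return table, cols_a, cols_b, de
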