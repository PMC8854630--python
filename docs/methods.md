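# Methods

## Problem and model

A grafted plant joins a rootstock (root system) and a scion (aerial part),
possibly of different species.  Some rootstock transcripts cross the graft
union and accumulate in scion tissue; identifying them from scion RNA-seq
is a read-origin classification problem complicated by two facts: the
scion cultivar never matches its published reference assembly exactly, and
many genes are conserved between the grafted species, so a scion read that
fails reference mapping for any reason can spuriously match the rootstock
genome.  The package implements the subtractive design that addresses
both: reconstruct the cultivar's own reference from DNA resequencing
reads, rescue only reference-unmapped RNA reads against the rootstock gene
space, and subtract every rootstock gene that the same funnel nominates
from a *homograft* control, where no cross-species transport is possible.

## Synthetic study design

The generator emulates the grafting experiment the detection method is
built for: two graft types (homograft, heterograft) × two watering
conditions (WW = well-watered, WS = progressive drought) × time points 0,
4, 6 and 11 days after stress onset (DAS).  The drought schedule is
expressed as fractions of soil field capacity: 0.8 at onset, then 0.7,
0.6, 0.5, 0.4 on days 1–4 and 0.3 from day 5 onward; the configuration
validates that the schedule never increases.  Stress exposure is the
normalized water deficit `(fc_max − fc(DAS)) / (fc_max − fc_min)`, zero
for WW samples.

**Genomes.**  Fifty single-exon genes of 600–1200 bp (uniform), separated
by 200 bp random intergenic spacers, on one chromosome.  The published
reference differs from the true scion genome by independent substitutions
at rate 0.005/bp (SNPs only; an `indel_rate` field exists but values > 0
are rejected — the alignment and consensus model is deliberately gapless).
The rootstock gene space mirrors the scion's at substitution divergence
0.10, except five genes conserved verbatim.  Defaults place the conserved
bait on an unassembled scaffold present in the true scion genome but
absent from the published assembly.  This choice is what makes the
false-positive pathway *systematic*: with 150 bp reads, a 95% mapping
identity threshold and a 1% uniform error rate, the probability that
sequencing error alone unmaps a scion mate is ~2·10⁻⁴, far too small to
produce reproducible artifacts, whereas reference incompleteness — a real
and common source of unmapped reads — reliably routes the bait genes'
scion reads to their identical rootstock homologs in homografts and
heterografts alike.  Setting `n_unassembled_conserved=0` restores a fully
assembled reference (then the published genome plus the variant list
reproduces the true scion genome exactly, which the degenerate
identical-genomes configuration uses).

**Transcriptomes.**  Per-gene base weights are lognormal(0, 0.8), constant
across samples.  Eight scion genes carry a planted ±1.5 log₂ fold change
between WW and WS (alternating sign).  Mobile transcripts — five rootstock
genes drawn from the divergent (detectable) part of the gene space — are
present only in heterograft samples, at weight `0.05 × mean scion weight ×
condition multiplier (WW 1.0 / WS 2.0) × (1 + 2 × stress exposure)`, so
their abundance grows monotonically with drought severity.  Mobile
transcripts are deliberately low-abundance (a few tenths of a percent of
fragments), matching the regime where mobile mRNAs are observed.  The
per-sample abundance is the normalization of these weights to sum 1; the
planted fold change is exact on the unnormalized weights, while normalized
shares differ by the compensating library factor that the screening step's
normalization removes again.

**Reads.**  Paired 150 bp mates from 300 bp fragments (mate 2 on the
reverse strand), fragment counts multinomial over abundances at 50 000
fragments per RNA sample, DNA fragments uniform over the true scion genome
at 20× coverage, independent substitution errors at 1%/base.  Qualities
are constant 'I'; the pipeline ignores them.  One root seed; every
operation and sample uses a child stream keyed by SHA-256 of (seed, tag),
so adding a sample never shifts another sample's reads.

**What the generator does not model** — splicing, indels, PCR duplicates,
GC bias, position-dependent error profiles, expression dispersion between
biological replicates of the read-level samples (count-level replicates
are multinomial), and any physiology.  Passing tests therefore demonstrate
the correctness and calibration of the *procedure* under its stated model,
not performance on real libraries, where gapped alignment and quality-aware
mapping would be required.

## Alignment model and numerical choices

Both mapping stages are gapless, consistent with the substitution-only
genome model.

*Reference mapping* places a read end-to-end along a diagonal: identity =
matches / aligned span, with the span allowed to clip at contig ends down
to `min_aligned_fraction` of the read.  Seeds are exact k-mers (k = 21
nominal).  For the mapping thresholds the seed length is shrunk to
`read_length // (max_mismatches + 1)` (floor 11) so that disjoint seed
windows outnumber the maximum tolerated mismatches — by pigeonhole, every
qualifying placement then shares at least one exact seed and the seeded
search is exhaustive, which the brute-force sliding-window oracle tests
exploit.  Where the guarantee is unattainable (consensus pileup mapping at
identity 0.9) every k-mer start is probed instead, a best-effort standard
seed-and-extend.  Reads placing equally well at multiple locations are
discarded from the pileup; a tie at the consensus top base retains the
published base.  Defaults: pileup identity 0.9 over the full read;
consensus min_depth 3, min_majority 0.8.

*Rootstock rescue* finds the best gapless local segment (match +1,
mismatch −2, Kadane's scan per candidate diagonal) across rootstock gene
sequences, both strands, requiring identity ≥ 0.90 over ≥ 50 bp.  Each
mate yields at most one hit; a score tie between different genes yields
none, keeping candidate calls deterministic.  Like every seeded local
aligner, it only recovers alignments containing at least one exact k-mer.

*Pair rule*: a pair counts as mapped when either mate maps (default,
mirroring typical aligner behaviour); a stricter both-mates rule is
available.  Candidate genes need ≥ 2 supporting rescued mates, so a single
error-mangled read cannot nominate a gene.  The false-positive set is
condition-matched (homograft WS filters heterograft WS) — the stricter
reading of the pooling alternative, which remains available by passing a
pooled homograft batch.

## Expression, sets, enrichment, qPCR

The DEG screen reproduces the selection rule *P* < .05 and |log₂FC| > 1;
the underlying test is deliberately a two-sided Welch *t* on
log₂(normalized count + 1) with median-of-ratios size factors — a
documented stand-in that reproduces the screening rule, not any negative
binomial dispersion model.  The pseudocount (1) keeps fold changes defined
at zero counts.  Benjamini–Hochberg adjustment is implemented but off by
default because the screening criterion is a raw p-value.  Under the
count-level null simulation the pass rate is well below 5% (the fold
change filter attenuates the nominal type-I rate); with a planted
|log₂FC| = 1.5 at high depth, power exceeds 90% over three replicates per
group.

Venn regions are computed exactly from memberships; printed-cardinality
inputs are realized by constructing synthetic id sets with those
cardinalities.  Enrichment is the exact upper-tail hypergeometric
probability via `scipy.stats.hypergeom.sf`, checked against combinatorial
enumeration to 10⁻¹².  The ΔΔCt ratio assumes amplification efficiency 2;
the mobility rule confirms a gene when the heterograft mean ratio is at
least 10× the homograft mean, with the homograft mean floored at 10⁻³ so
the rule is defined when homografts show no signal.  The threshold is a
declared default for an inherently qualitative criterion ("high in
heterografts, absent or nearly absent in homografts").

## Problem sizes

Unit tests run a 12-gene, 3 000-fragment design; the end-to-end recovery
checks use the full default design (50 genes, 50 000 fragments per sample)
over five seeds, and the oracle-equivalence checks use 3-gene, 80 bp-read
instances where exhaustive alignment is exact and cheap.  These sizes were
chosen so the whole suite and the acceptance recomputation each complete
in well under their practical runtime on a single CPU while keeping every
statistical gate (binomial 3σ bounds, recovery rates) well-powered.

## Known limitations

Gapless alignment cannot represent indel divergence; the consensus step
calls substitutions only and emits a TSV rather than VCF.  Detection
operates gene-level (one qualifying homograft gene removes the whole
candidate gene), so a transcript both genuinely mobile *and* nominated by
homograft artifacts would be lost — the conservative direction.  The
simulator's conserved-bait mechanism models reference incompleteness; real
false positives also arise from paralogy and partial homology gradients
that a threshold-based matcher handles less cleanly than E-value-based
search.  Replicate handling for detection is single-library per condition;
union-with-support-sum across replicates is a thin loop away but not built
in.
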