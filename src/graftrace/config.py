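"""Simulation configuration.

One :class:`SimulationConfig` drives every synthetic input the pipeline
consumes: the published/true scion genome pair, the rootstock genome, the
per-sample transcript abundances and the read batches.  Defaults encode the
study conditions: a progressive drought schedule expressed as fractions of
field capacity (80% at stress onset down to 30% from day 5 onward), 150 bp
paired-end reads, and a small planted set of mobile rootstock transcripts
whose abundance grows with stress exposure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

#: Soil water content as a fraction of field capacity, per day after stress
#: onset.  Day 0 is the well-watered baseline; from day 5 the pots are held
#: at 30% of field capacity.
DEFAULT_STRESS_SCHEDULE: dict[int, float] = {
    0: 0.8, 1: 0.7, 2: 0.6, 3: 0.5, 4: 0.4,
    **{d: 0.3 for d in range(5, 12)},
}

CONDITIONS = ("WW", "WS")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 50
    gene_length_range: tuple[int, int] = (600, 1200)
    #: substitution rate between the published reference and the true scion
    scion_snp_rate: float = 0.005
    #: substitution rate between scion genes and their rootstock homologs
    rootstock_divergence: float = 0.10
    #: rootstock genes copied verbatim from the scion (false-positive bait)
    n_conserved_genes: int = 5
    n_mobile_genes: int = 5
    #: condition -> abundance multiplier for mobile transcripts
    mobile_condition_profile: dict[str, float] = field(
        default_factory=lambda: {"WW": 1.0, "WS": 2.0}
    )
    #: days-after-stress -> fraction of field capacity
    stress_schedule: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_STRESS_SCHEDULE)
    )
    read_length: int = 150
    sequencing_error_rate: float = 0.01
    #: RNA fragments (read pairs) per sample
    rna_depth: int = 50_000
    #: mean genome coverage of the scion DNA resequencing
    dna_depth: float = 20.0
    n_de_genes: int = 8
    de_log2fc: float = 1.5

    # --- engineering knobs (not part of the study design proper) ---
    #: indels between published reference and true scion; substitutions only
    #: are supported, the field exists so the limitation is explicit
    indel_rate: float = 0.0
    #: insert size; defaults to 2 * read_length (abutting mates)
    fragment_length: int | None = None
    intergenic_length: int = 200
    #: mobile transcript weight relative to the mean scion gene weight
    mobile_expression: float = 0.05
    #: slope of the mobile-abundance increase with stress exposure
    mobile_stress_gain: float = 2.0
    #: conserved bait genes absent from the published assembly
    #: (None -> all conserved genes; 0 -> fully assembled reference)
    n_unassembled_conserved: int | None = None
    n_replicates: int = 3

    def __post_init__(self) -> None:
        self.gene_length_range = tuple(self.gene_length_range)  # type: ignore[assignment]
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for name in ("scion_snp_rate", "rootstock_divergence",
                     "sequencing_error_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.indel_rate > 0:
            raise NotImplementedError(
                "indel_rate > 0: only substitution variants are supported "
                "(alignment and consensus are ungapped)"
            )
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_conserved_genes + self.n_mobile_genes > self.n_genes:
            raise ValueError(
                "n_conserved_genes + n_mobile_genes must not exceed n_genes"
            )
        if self.n_unassembled_conserved is not None and not (
            0 <= self.n_unassembled_conserved <= self.n_conserved_genes
        ):
            raise ValueError(
                "n_unassembled_conserved must lie in [0, n_conserved_genes]"
            )
        lo, hi = self.gene_length_range
        if lo > hi:
            raise ValueError("gene_length_range must be (low, high)")
        if lo < 2 * self.read_length:
            raise ValueError(
                f"gene_length_range lower bound {lo} is below twice the read "
                f"length ({2 * self.read_length}); read pairs could not be "
                "placed on the shortest transcripts"
            )
        das = sorted(self.stress_schedule)
        fcs = [self.stress_schedule[d] for d in das]
        if any(b > a for a, b in zip(fcs, fcs[1:])):
            raise ValueError(
                "stress_schedule field-capacity fractions must be "
                "non-increasing over days after stress"
            )
        if not all(0.0 <= v <= 1.0 for v in fcs):
            raise ValueError("stress_schedule values must lie in [0, 1]")
        for cond, mult in self.mobile_condition_profile.items():
            if mult < 0:
                raise ValueError(f"mobile multiplier for {cond} is negative")

    # ------------------------------------------------------------------
    @property
    def effective_fragment_length(self) -> int:
        return self.fragment_length or 2 * self.read_length

    @property
    def effective_n_unassembled(self) -> int:
        if self.n_unassembled_conserved is None:
            return self.n_conserved_genes
        return self.n_unassembled_conserved

    def field_capacity(self, das: int) -> float:
        """Fraction of field capacity at a given day after stress onset."""
        keys = [d for d in self.stress_schedule if d <= das]
        if not keys:
            return max(self.stress_schedule.values())
        return self.stress_schedule[max(keys)]

    def stress_exposure(self, condition: str, das: int) -> float:
        """Normalized cumulative stress severity in [0, 1].

        Zero for well-watered samples; for drought samples the soil-water
        deficit relative to the schedule's full range.
        """
        if condition != "WS":
            return 0.0
        fc0 = max(self.stress_schedule.values())
        fc_min = min(self.stress_schedule.values())
        span = fc0 - fc_min
        if span <= 0:
            return 0.0
        return (fc0 - self.field_capacity(das)) / span

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_length_range"] = list(self.gene_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "stress_schedule" in d:
            d["stress_schedule"] = {int(k): float(v)
                                    for k, v in d["stress_schedule"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
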