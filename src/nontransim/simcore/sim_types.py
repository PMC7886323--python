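"""Domain types for the serial-transfer host/virus evolution simulator."""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ViralVariant:
    """A variant of the intracellular killer virus.

    ``within_cell_advantage`` is the replication advantage per viral
    replication event (weight 1 + advantage when the intracellular pool is
    resampled at cell division).  A variant may be toxin-null yet still
    confer immunity, because immunity derives from the unprocessed
    preprotoxin; an internal-deletion variant encodes neither.
    """

    id: str
    toxin_functional: bool = True
    immunity_functional: bool = True
    within_cell_advantage: float = 0.0
    is_deletion: bool = False
    # optional substitution annotation (ref base, alt base) for spectrum stats
    change: tuple[str, str] | None = None

    def __post_init__(self):
        if self.within_cell_advantage < -1:
            raise ValueError("within_cell_advantage must be >= -1")
        if self.is_deletion and (self.toxin_functional or self.immunity_functional):
            raise ValueError("a deletion variant is toxin-null and immunity-null")


#: the founding full-function virus
WILDTYPE = ViralVariant("WT", True, True, 0.0)


@dataclass
class HostGenotype:
    """A host cell genotype: nuclear fitness plus its intracellular viral pool.

    ``viral_composition`` maps variant id -> copy count; counts sum to the
    viral copy number (all zero for a cured strain).
    """

    id: str
    nuclear_fitness_s: float = 0.0  # per generation, relative (Malthusian)
    label: str = "unlabeled"  # unlabeled | fluorescent
    viral_composition: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in ("unlabeled", "fluorescent"):
            raise ValueError("label must be 'unlabeled' or 'fluorescent'")
        if any(c < 0 for c in self.viral_composition.values()):
            raise ValueError("viral counts must be >= 0")

    @property
    def copy_number(self) -> int:
        return sum(self.viral_composition.values())

    @property
    def is_cured(self) -> bool:
        return self.copy_number == 0


@dataclass
class SerialTransferProtocol:
    """Daily 1:2^g dilution regime: g generations of regrowth per transfer."""

    dilution_factor: int = 1024
    generations_per_transfer: int | None = None  # = log2(dilution_factor)
    bottleneck_size: int = 100_000
    n_transfers: int = 100

    def __post_init__(self):
        g = int(round(math.log2(self.dilution_factor)))
        if 2**g != self.dilution_factor:
            raise ValueError("dilution_factor must be an exact power of 2")
        if self.generations_per_transfer is None:
            self.generations_per_transfer = g
        elif self.generations_per_transfer != g:
            raise ValueError("generations_per_transfer must equal log2(dilution_factor)")
        if self.bottleneck_size < 1:
            raise ValueError("bottleneck_size must be >= 1")


@dataclass
class ToxinModel:
    """Well-mixed, memoryless toxin kinetics.

    A susceptible (non-immune) cell dies in a generation with probability
    kill_coefficient * f_killer, where f_killer is the current frequency of
    toxin-producing cells; with ``saturating`` the probability is clamped
    at 1, otherwise exceeding 1 is an error.
    """

    kill_coefficient: float = 0.2
    saturating: bool = True

    def __post_init__(self):
        if self.kill_coefficient < 0:
            raise ValueError("kill_coefficient must be >= 0")

    def death_probability(self, f_killer: float) -> float:
        p = self.kill_coefficient * f_killer
        if p > 1.0:
            if not self.saturating:
                raise ValueError(
                    f"kill probability {p:.3f} > 1 with saturating=False"
                )
            p = 1.0
        return p


@dataclass
class EffectTable:
    """Distribution of phenotypic effects for de novo viral variants.

    Each row: (probability, toxin_functional, immunity_functional,
    advantage_low, advantage_high); the within-cell advantage is drawn
    uniformly from [advantage_low, advantage_high].
    """

    rows: tuple = (
        # most function-altering mutations knock out killing but keep immunity
        (0.6, False, True, 0.02, 0.15),
        # some abolish both (e.g. frameshift early in the preprotoxin)
        (0.2, False, False, 0.02, 0.15),
        # neutral/synonymous: no phenotype change, no advantage
        (0.2, True, True, 0.0, 0.0),
    )

    def __post_init__(self):
        total = sum(r[0] for r in self.rows)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("effect-table probabilities must sum to 1")


@dataclass
class SimConfig:
    """Configuration of the multilevel simulation.

    Defaults mirror the source evolution experiment: 1:2^10 daily dilution
    (10 generations per transfer) at a bottleneck of ~1e5 cells, ~100 viral
    copies per cell, and a transition-biased viral mutation spectrum
    (transition weight 6.4 per transversion class).  ``standing_variants``
    lists (variant, initial cell fraction) pairs present in the founding
    culture (heteroplasmic carriers); off by default.
    """

    protocol: SerialTransferProtocol = field(default_factory=SerialTransferProtocol)
    toxin: ToxinModel = field(default_factory=ToxinModel)
    viral_copy_number: int = 100
    viral_mutation_rate: float = 1e-6  # per copy per replication
    ts_tv_bias: float = 6.4
    seed: int = 0
    standing_variants: list[tuple[ViralVariant, float]] = field(default_factory=list)
    # fraction of viral copies that are the standing variant within a carrier cell
    standing_within_cell_freq: float = 0.1
    # nuclear beneficial-mutation supply driving periodic selective sweeps
    nuclear_mutation_rate: float = 4e-7  # per cell per generation
    nuclear_effect_mean: float = 0.04  # exponential mean of the fitness effect
    # phenotype thresholds: a cell produces toxin iff the functional-copy
    # fraction >= theta_K; it is immune iff the fraction >= theta_I (sparse
    # preprotoxin copies suffice for immunity)
    theta_K: float = 0.5
    theta_I: float = 0.05
    effect_table: EffectTable = field(default_factory=EffectTable)

    def __post_init__(self):
        if not (0.0 <= self.viral_mutation_rate <= 1.0):
            raise ValueError("viral_mutation_rate must be in [0, 1]")
        if self.viral_copy_number < 1:
            raise ValueError("viral_copy_number must be >= 1")
        for _, frac in self.standing_variants:
            if not (0.0 <= frac <= 1.0):
                raise ValueError("standing-variant fractions must be in [0, 1]")


@dataclass(frozen=True)
class Timepoint:
    generation: int
    count_a: float
    count_b: float
    sample_size: float


@dataclass
class CompetitionTimecourse:
    """Flow-cytometry-like counts from a pairwise competition.

    In stochastic mode counts are integer sampled events; in deterministic
    mode they are real-valued expectations (still summing to sample_size).
    """

    competitor_a: str
    competitor_b: str
    timepoints: list[Timepoint]

    def __post_init__(self):
        gens = [tp.generation for tp in self.timepoints]
        if gens and (gens[0] != 0 or any(b <= a for a, b in zip(gens, gens[1:]))):
            raise ValueError("generations must increase strictly from 0")
        for tp in self.timepoints:
            if tp.count_a < 0 or tp.count_b < 0:
                raise ValueError("counts must be >= 0")
            if abs(tp.count_a + tp.count_b - tp.sample_size) > 1e-6 * max(tp.sample_size, 1):
                raise ValueError("count_a + count_b must equal sample_size")


@dataclass(frozen=True)
class BottleneckRecord:
    bottleneck: int
    variant_freq: float
    killing: str
    immunity: str


@dataclass
class IntracellularTrajectory:
    line_id: str
    records: list[BottleneckRecord]

    def __post_init__(self):
        idx = [r.bottleneck for r in self.records]
        if idx != list(range(len(idx))):
            raise ValueError("bottleneck indices must be consecutive from 0")
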