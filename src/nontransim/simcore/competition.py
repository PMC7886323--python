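"""Pairwise competition under the serial-transfer regime.

Each generation a competitor's cell count grows by 2*exp(s) (one doubling
modulated by the Malthusian selection coefficient s), susceptible non-immune
cells then die with probability kill_coefficient * f_killer, and every
``generations_per_transfer`` generations the culture is diluted back to the
bottleneck size.  In deterministic mode every sampling step is replaced by
its expectation, so fitness examples have exact closed forms.
"""

from __future__ import annotations

import math

import numpy as np

from .phenotype import cell_phenotype
from .sim_types import (
    CompetitionTimecourse,
    HostGenotype,
    SimConfig,
    Timepoint,
    ViralVariant,
    WILDTYPE,
)


def _phenotypes(config: SimConfig, genotype: HostGenotype, variants):
    if genotype.is_cured:
        return False, False
    return cell_phenotype(genotype.viral_composition, variants, config)


def simulate_competition(
    config: SimConfig,
    genotype_a: HostGenotype,
    genotype_b: HostGenotype,
    start_freq_a: float,
    n_generations: int,
    sampling_interval: int,
    sample_size: int = 10_000,
    deterministic: bool = False,
    variants: dict[str, ViralVariant] | None = None,
) -> CompetitionTimecourse:
    """Compete two genotypes and emit flow-cytometry-like counts.

    The killer phenotype of each competitor is derived once from its viral
    composition (no viral evolution over a 50-generation competition).
    ``variants`` supplies the variant definitions referenced by the
    genotypes' compositions (the wild-type virus by default).
    """
    if not (0.0 < start_freq_a < 1.0):
        raise ValueError("start_freq_a must be in (0, 1)")
    if n_generations % sampling_interval != 0:
        raise ValueError("sampling_interval must divide n_generations")
    if variants is None:
        variants = {WILDTYPE.id: WILDTYPE}

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    nb = config.protocol.bottleneck_size
    g_per_transfer = config.protocol.generations_per_transfer

    kill_a, immune_a = _phenotypes(config, genotype_a, variants)
    kill_b, immune_b = _phenotypes(config, genotype_b, variants)
    grow_a = 2.0 * math.exp(genotype_a.nuclear_fitness_s)
    grow_b = 2.0 * math.exp(genotype_b.nuclear_fitness_s)

    n_a = start_freq_a * nb
    n_b = (1.0 - start_freq_a) * nb

    def record(gen: int) -> Timepoint:
        f_a = n_a / (n_a + n_b)
        if deterministic:
            return Timepoint(gen, sample_size * f_a, sample_size * (1 - f_a), sample_size)
        c_a = int(rng.binomial(sample_size, f_a))
        return Timepoint(gen, c_a, sample_size - c_a, sample_size)

    timepoints = [record(0)]
    for gen in range(1, n_generations + 1):
        n_a *= grow_a
        n_b *= grow_b
        total = n_a + n_b
        f_killer = (n_a * kill_a + n_b * kill_b) / total if total > 0 else 0.0
        if f_killer > 0:
            p = config.toxin.death_probability(f_killer)
            if not immune_a and n_a > 0:
                n_a = _survive(n_a, p, rng, deterministic)
            if not immune_b and n_b > 0:
                n_b = _survive(n_b, p, rng, deterministic)
        if gen % g_per_transfer == 0 and gen < n_generations:
            total = n_a + n_b
            if deterministic:
                scale = nb / total
                n_a *= scale
                n_b *= scale
            else:
                sampled_a = rng.binomial(nb, n_a / total)
                n_a, n_b = float(sampled_a), float(nb - sampled_a)
        if gen % sampling_interval == 0:
            timepoints.append(record(gen))

    return CompetitionTimecourse(genotype_a.id, genotype_b.id, timepoints)


def _survive(n: float, p: float, rng, deterministic: bool) -> float:
    if deterministic:
        return n * (1.0 - p)
    return float(rng.binomial(int(round(n)), 1.0 - p))
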