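"""Population-scale serial-transfer evolution with multilevel selection.

The simulation couples three levels: (1) among-host selection via nuclear
beneficial mutations that drive periodic selective sweeps, (2) within-host
selection among viral variants in each cell's intracellular pool, and
(3) toxin-mediated interference (non-immune cells are killed in proportion
to the frequency of toxin producers).  Viral variants spread through the
population mainly by hitchhiking on nuclear sweeps: a sweep founded in a
cell whose pool a toxin-null variant has already taken over carries that
pool to fixation, and the population loses killing ability.

The state is cohort-based: counts per (nuclear genotype, viral-pool
composition).  All cells in a cohort share one intracellular composition,
which is resampled once per generation (multinomial of the viral copy
number, weighted by 1 + within_cell_advantage).  Host-level growth and
toxin death are applied as expectations; demographic stochasticity enters
at the daily dilution bottleneck (multinomial to the bottleneck size) and
through Poisson mutation events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotype import cell_phenotype, grade_from_fraction
from .sim_types import EffectTable, SimConfig, ViralVariant, WILDTYPE

CompKey = tuple[tuple[str, int], ...]


def _comp_key(comp: dict[str, int]) -> CompKey:
    return tuple(sorted((k, v) for k, v in comp.items() if v > 0))


def _draw_substitution(rng, ts_tv_bias: float) -> tuple[str, str]:
    """Random base change with transitions weighted ts_tv_bias : 1 per
    transversion class."""
    ref = "ACGT"[rng.integers(4)]
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
    transversions = [b for b in "ACGT" if b != ref and b != transition]
    w = np.array([ts_tv_bias, 1.0, 1.0])
    pick = rng.choice(3, p=w / w.sum())
    alt = ([transition] + transversions)[pick]
    return ref, alt


def draw_de_novo_variant(rng, config: SimConfig, new_id: str) -> ViralVariant:
    """Draw a de novo viral variant's effects from the configured table."""
    probs = np.array([r[0] for r in config.effect_table.rows])
    row = config.effect_table.rows[rng.choice(len(probs), p=probs / probs.sum())]
    _, tox, imm, lo, hi = row
    adv = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return ViralVariant(
        new_id, tox, imm, adv, change=_draw_substitution(rng, config.ts_tv_bias)
    )


@dataclass
class _PopState:
    cohorts: dict  # (nuclear_id, comp_key) -> cell count
    nuclear_s: dict  # nuclear_id -> fitness
    variants: dict  # variant id -> ViralVariant

    def __post_init__(self):
        self._phen_cache: dict = {}

    def phenotype(self, comp: CompKey, config: SimConfig) -> tuple[bool, bool]:
        """Cached (produces_toxin, immune) for a composition key."""
        hit = self._phen_cache.get(comp)
        if hit is None:
            hit = cell_phenotype(dict(comp), self.variants, config)
            self._phen_cache[comp] = hit
        return hit


def _founding_state(config: SimConfig, rng) -> _PopState:
    nv = config.viral_copy_number
    variants = {WILDTYPE.id: WILDTYPE}
    nb = config.protocol.bottleneck_size
    cohorts: dict = {}
    carrier_cells = 0
    for variant, frac in config.standing_variants:
        variants[variant.id] = variant
        k = max(1, int(round(config.standing_within_cell_freq * nv)))
        comp = {WILDTYPE.id: nv - k, variant.id: k}
        n = int(round(frac * nb))
        if n > 0:
            cohorts[("anc", _comp_key(comp))] = cohorts.get(("anc", _comp_key(comp)), 0) + n
            carrier_cells += n
    if nb - carrier_cells > 0:
        key = ("anc", _comp_key({WILDTYPE.id: nv}))
        cohorts[key] = cohorts.get(key, 0) + (nb - carrier_cells)
    return _PopState(cohorts, {"anc": 0.0}, variants)


def _within_cell_step(state: _PopState, config: SimConfig, rng) -> None:
    nv = config.viral_copy_number
    updates = {}
    for key, n in state.cohorts.items():
        nuclear, comp = key
        if len(comp) <= 1:
            continue
        ids = [vid for vid, _ in comp]
        counts = np.array([c for _, c in comp], dtype=float)
        w = counts * np.array(
            [1.0 + state.variants[v].within_cell_advantage for v in ids]
        )
        new_counts = rng.multinomial(nv, w / w.sum())
        new_comp = _comp_key(dict(zip(ids, (int(c) for c in new_counts))))
        updates[key] = (nuclear, new_comp)
    for old_key, new_key in updates.items():
        n = state.cohorts.pop(old_key)
        state.cohorts[new_key] = state.cohorts.get(new_key, 0) + n


def _mutation_steps(state: _PopState, config: SimConfig, rng, counters) -> None:
    total = sum(state.cohorts.values())
    if total <= 0:
        return
    keys = list(state.cohorts.keys())
    weights = np.array([state.cohorts[k] for k in keys], dtype=float)
    probs = weights / weights.sum()
    nv = config.viral_copy_number

    # mutation supply evaluated at the effective (bottleneck) size: lineages
    # born in the transient excess above the bottleneck are almost surely
    # removed at the next dilution, so simulating them individually only
    # burns time without changing the dynamics
    n_eff = min(total, config.protocol.bottleneck_size)
    n_viral = rng.poisson(n_eff * nv * config.viral_mutation_rate)
    for _ in range(min(n_viral, 1000)):
        key = keys[rng.choice(len(keys), p=probs)]
        if state.cohorts.get(key, 0) < 1:
            continue
        nuclear, comp = key
        counters["viral"] += 1
        vid = f"dn{counters['viral']}"
        state.variants[vid] = draw_de_novo_variant(rng, config, vid)
        comp_d = dict(comp)
        ids = list(comp_d)
        src = ids[rng.choice(len(ids), p=np.array([comp_d[i] for i in ids]) / nv)]
        comp_d[src] -= 1
        comp_d[vid] = comp_d.get(vid, 0) + 1
        state.cohorts[key] -= 1
        if state.cohorts[key] <= 0:
            del state.cohorts[key]
        nk = (nuclear, _comp_key(comp_d))
        state.cohorts[nk] = state.cohorts.get(nk, 0) + 1

    n_nuclear = rng.poisson(n_eff * config.nuclear_mutation_rate)
    for _ in range(min(n_nuclear, 1000)):
        key = keys[rng.choice(len(keys), p=probs)]
        if state.cohorts.get(key, 0) < 1:
            continue
        nuclear, comp = key
        counters["nuclear"] += 1
        nid = f"n{counters['nuclear']}"
        state.nuclear_s[nid] = state.nuclear_s[nuclear] + float(
            rng.exponential(config.nuclear_effect_mean)
        )
        state.cohorts[key] -= 1
        if state.cohorts[key] <= 0:
            del state.cohorts[key]
        nk = (nid, comp)
        state.cohorts[nk] = state.cohorts.get(nk, 0) + 1


def _population_summary(state: _PopState, config: SimConfig):
    """(toxin-producing cell fraction, immune cell fraction, variant copy freqs)."""
    total = sum(state.cohorts.values())
    ktot = itot = 0.0
    copy_counts: dict[str, float] = {}
    for (nuclear, comp), n in state.cohorts.items():
        produces, immune = state.phenotype(comp, config)
        if produces:
            ktot += n
        if immune:
            itot += n
        for vid, c in comp:
            copy_counts[vid] = copy_counts.get(vid, 0.0) + n * c
    copy_total = sum(copy_counts.values())
    freqs = {v: c / copy_total for v, c in copy_counts.items()} if copy_total else {}
    return ktot / total, itot / total, freqs


def simulate_population_evolution(
    config: SimConfig,
    n_populations: int,
    n_generations: int,
    record_every: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evolve replicate populations and report phenotypes and viral dynamics.

    Returns (phenotypes, trajectories): ``phenotypes`` has one row per
    (population, recorded generation) with ordinal killing/immunity grades;
    ``trajectories`` is long-format (population, generation, variant_id,
    frequency) over pooled viral copies.
    """
    if n_populations < 1:
        raise ValueError("n_populations must be >= 1")
    record_gens = sorted(set(range(0, n_generations + 1, record_every)) | {n_generations})
    phen_rows, traj_rows = [], []
    for p in range(n_populations):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(p,))
        )
        state = _founding_state(config, rng)
        counters = {"viral": 0, "nuclear": 0}
        g_per = config.protocol.generations_per_transfer
        nb = config.protocol.bottleneck_size

        def record(gen: int):
            fk, fi, freqs = _population_summary(state, config)
            phen_rows.append(
                {
                    "population": f"P{p:03d}",
                    "generation": gen,
                    "killing": grade_from_fraction(fk),
                    "immunity": grade_from_fraction(fi),
                }
            )
            for vid, f in freqs.items():
                if f > 0:
                    traj_rows.append(
                        {
                            "population": f"P{p:03d}",
                            "generation": gen,
                            "variant_id": vid,
                            "frequency": f,
                        }
                    )

        record(0)
        for gen in range(1, n_generations + 1):
            # growth (expectation): one doubling modulated by nuclear fitness
            for key in list(state.cohorts):
                state.cohorts[key] *= 2.0 * math.exp(state.nuclear_s[key[0]])
            # toxin-mediated death of non-immune cells
            if config.toxin.kill_coefficient > 0:
                total = sum(state.cohorts.values())
                fk = (
                    sum(
                        n for key, n in state.cohorts.items()
                        if state.phenotype(key[1], config)[0]
                    )
                    / total
                )
            else:
                fk = 0.0
            if fk > 0 and config.toxin.kill_coefficient > 0:
                pdie = config.toxin.death_probability(fk)
                for key in list(state.cohorts):
                    _, immune = state.phenotype(key[1], config)
                    if not immune:
                        state.cohorts[key] *= 1.0 - pdie
                        if state.cohorts[key] < 1e-6:
                            del state.cohorts[key]
            _within_cell_step(state, config, rng)
            _mutation_steps(state, config, rng, counters)
            if gen % g_per == 0:
                keys = list(state.cohorts.keys())
                w = np.array([state.cohorts[k] for k in keys], dtype=float)
                sampled = rng.multinomial(nb, w / w.sum())
                state.cohorts = {
                    k: int(c) for k, c in zip(keys, sampled) if c > 0
                }
            if gen in record_gens:
                record(gen)

    return pd.DataFrame(phen_rows), pd.DataFrame(traj_rows)
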