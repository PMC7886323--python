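"""Heteroplasmic single-cell-bottleneck lines: within-cell viral competition.

A heteroplasmic diploid (two viral variants in one cell) is grown from a
single cell into a colony and a single cell is drawn uniformly to found the
next bottleneck, repeated for a fixed number of bottlenecks to minimise
among-cell selection.  Because an unstructured colony after g doublings is
a full binary tree, a uniformly drawn cell is equivalent to following a
uniformly random root-to-leaf path, so each line is simulated as a single
cell lineage: at every division the intracellular pool is doubled by
weighted sampling (with mutation) and the followed daughter receives half
the pool without replacement.
"""

from __future__ import annotations

import numpy as np

from .phenotype import functional_fractions, grade_from_fraction
from .population import draw_de_novo_variant
from .sim_types import (
    BottleneckRecord,
    IntracellularTrajectory,
    SimConfig,
    ViralVariant,
    WILDTYPE,
)


def _divide(comp: dict[str, int], variants, config: SimConfig, rng, counters) -> dict[str, int]:
    """One cell division: double the pool with selection+mutation, then split."""
    nv = config.viral_copy_number
    ids = list(comp)
    counts = np.array([comp[v] for v in ids], dtype=float)
    w = counts * np.array([1.0 + variants[v].within_cell_advantage for v in ids])
    doubled = rng.multinomial(2 * nv, w / w.sum())
    # per-copy mutation during replication
    n_mut = rng.binomial(2 * nv, config.viral_mutation_rate)
    for _ in range(n_mut):
        src_idx = rng.choice(len(ids), p=doubled / doubled.sum())
        if doubled[src_idx] == 0:
            continue
        doubled = doubled.copy()
        doubled[src_idx] -= 1
        counters["n"] += 1
        vid = f"dn{counters['n']}"
        variants[vid] = draw_de_novo_variant(rng, config, vid)
        ids.append(vid)
        doubled = np.append(doubled, 1)
    daughter = rng.multivariate_hypergeometric(doubled.astype(int), nv)
    return {v: int(c) for v, c in zip(ids, daughter) if c > 0}


def _deterministic_divide(comp, variants, config) -> dict[str, float]:
    w = {v: c * (1.0 + variants[v].within_cell_advantage) for v, c in comp.items()}
    total = sum(w.values())
    nv = config.viral_copy_number
    return {v: nv * x / total for v, x in w.items()}


def simulate_heteroplasmic_lines(
    config: SimConfig,
    variant: ViralVariant,
    initial_freq: float,
    n_lines: int,
    n_bottlenecks: int = 7,
    generations_per_bottleneck: int = 20,
    deterministic: bool = False,
) -> list[IntracellularTrajectory]:
    """Propagate heteroplasmic lines and record the variant's frequency.

    Records are indexed 0 (initial state) through ``n_bottlenecks``.  The
    killing / immunity grades are those of the sampled founder cell at each
    bottleneck, graded from its functional-copy fractions.
    """
    if not (0.0 <= initial_freq <= 1.0):
        raise ValueError("initial_freq must be in [0, 1]")
    if n_bottlenecks < 1:
        raise ValueError("n_bottlenecks must be >= 1")
    nv = config.viral_copy_number
    out = []
    for line in range(n_lines):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(line,))
        )
        variants = {WILDTYPE.id: WILDTYPE, variant.id: variant}
        counters = {"n": 0}
        k = int(round(initial_freq * nv))
        comp: dict = {}
        if nv - k > 0:
            comp[WILDTYPE.id] = nv - k
        if k > 0:
            comp[variant.id] = k

        def rec(idx: int) -> BottleneckRecord:
            f_tox, f_imm = functional_fractions(comp, variants)
            f_var = comp.get(variant.id, 0) / sum(comp.values())
            return BottleneckRecord(
                idx, f_var, grade_from_fraction(f_tox), grade_from_fraction(f_imm)
            )

        records = [rec(0)]
        for b in range(1, n_bottlenecks + 1):
            for _ in range(generations_per_bottleneck):
                if deterministic:
                    comp = _deterministic_divide(comp, variants, config)
                else:
                    comp = _divide(comp, variants, config, rng, counters)
            records.append(rec(b))
        out.append(IntracellularTrajectory(f"line{line}", records))
    return out
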