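"""Deriving killer phenotype from an intracellular viral composition."""

from __future__ import annotations

from .sim_types import SimConfig, ViralVariant


def functional_fractions(
    composition: dict[str, int], variants: dict[str, ViralVariant]
) -> tuple[float, float]:
    """(toxin-functional fraction, immunity-functional fraction) of the pool."""
    total = sum(composition.values())
    if total == 0:
        return 0.0, 0.0
    tox = sum(n for vid, n in composition.items() if variants[vid].toxin_functional)
    imm = sum(n for vid, n in composition.items() if variants[vid].immunity_functional)
    return tox / total, imm / total


def cell_phenotype(
    composition: dict[str, int], variants: dict[str, ViralVariant], config: SimConfig
) -> tuple[bool, bool]:
    """(produces_toxin, immune) for a cell with the given viral pool.

    Toxin production needs at least theta_K functional copies; immunity is
    conferred by sparse preprotoxin, so theta_I is low by default.
    """
    f_tox, f_imm = functional_fractions(composition, variants)
    return f_tox >= config.theta_K, f_imm >= config.theta_I


def grade_from_fraction(frac: float, full: float = 0.75, weak: float = 0.25) -> str:
    """Map a functional fraction to an ordinal halo-assay-like grade."""
    if frac >= full:
        return "full"
    if frac >= weak:
        return "weak"
    return "none"
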