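"""Reported study inputs and synthetic stand-in sequence data.

The numeric tables here are the published population-level summaries of the
killer-virus evolution experiment (mutation-presence contingency table,
recurrent ancestral-polymorphism fixation counts, clone fitness steps).
The K1 ORF reference and the full per-substitution spectrum are synthetic
stand-ins: the real reference and supplementary variant list are external
resources, so a random coding sequence is generated whose constrained
codons make the reported amino-acid changes (P47S, D106G, G131D, D253N,
I292M) consistent, and a spectrum table is reconstructed to match the
reported marginals (32 transitions : 5 transversions; 13/14/15 recurrent
fixations of the three ancestral polymorphisms).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .seqstats import ORFAnnotation, Variant

#: 2x2 table: rows = populations that lost / retained killing ability,
#: columns = viral mutations present / absent.  57 loss populations all
#: carried M1 mutations; of 10 controls a single (synonymous) mutation was
#: found in one.
M1_MUTATION_TABLE = [[57, 0], [1, 9]]

#: measured per-generation fitness gains along the focal lineage:
#: Intermediate vs Early, Late vs Intermediate
CLONE_FITNESS_STEPS = (0.038, 0.012)

#: Late vs virus-cured Early clone (frequency-independent)
CURED_LATE_FITNESS = 0.043

#: deterministic sweep-time benchmark: hexose-transporter amplification in
#: glucose-limited chemostats
CHEMOSTAT_SWEEP = {"s": 0.30, "N": 4e9}

# codons guaranteeing the reported amino-acid changes are consistent
_CONSTRAINED_CODONS = {47: "CCT", 106: "GAT", 131: "GGT", 253: "GAC", 292: "ATA"}

_CODON_POOL = [
    "GCT", "TGT", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT", "AAA", "TTA",
    "ATG", "AAT", "CCA", "CAA", "AGA", "TCT", "ACT", "GTT", "TGG", "TAC",
]


def synthetic_k1_orf(seed: int = 7, n_aa: int = 316) -> ORFAnnotation:
    """A synthetic stand-in for the K1 preprotoxin ORF (316 aa + stop).

    Random sense codons, ATG start and TAA stop, with codons fixed at the
    positions of the reported recurrent substitutions so those protein
    changes can be expressed on this reference.
    """
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [
        _CODON_POOL[i] for i in rng.integers(0, len(_CODON_POOL), size=n_aa - 1)
    ]
    for aa_pos, codon in _CONSTRAINED_CODONS.items():
        codons[aa_pos - 1] = codon
    codons.append("TAA")
    return ORFAnnotation("".join(codons))


def recurrent_snp_variants(orf: ORFAnnotation) -> pd.DataFrame:
    """The three recurrent ancestral polymorphisms with fixation counts.

    Positions are expressed on the synthetic reference; the amino-acid
    changes (D106G, D253N, I292M) and the recurrence counts (13, 14, 15)
    are the reported values.
    """
    rows = [
        # (aa change, codon offset of the substituted base, ref, alt, count)
        ("D106G", 106, 1, "A", "G", 13),  # GAT -> GGT
        ("D253N", 253, 0, "G", "A", 14),  # GAC -> AAC
        ("I292M", 292, 2, "A", "G", 15),  # ATA -> ATG
    ]
    out = []
    for change, aa, off, ref, alt, n in rows:
        pos = (aa - 1) * 3 + off
        assert orf.sequence[pos] == ref, "synthetic ORF inconsistent with table"
        out.append(
            {"protein_change": change, "position": pos, "ref": ref, "alt": alt,
             "n_populations": n}
        )
    return pd.DataFrame(out)


def spectrum_table() -> pd.DataFrame:
    """Synthetic reconstruction of the K1 substitution spectrum.

    Per-substitution rows (position, ref, alt, n_populations) drawn to match
    the reported marginals: 37 distinct point substitutions of which 32 are
    transitions and 5 transversions (R = 6.4), including the three recurrent
    ancestral polymorphisms.
    """
    path = resources.files("nontransim.data").joinpath("k1_spectrum_synthetic.csv")
    with resources.as_file(path) as f:
        return pd.read_csv(f)


def spectrum_variants(df: pd.DataFrame | None = None) -> tuple[list[Variant], list[int]]:
    """(variants, per-variant occurrence counts) from a spectrum table."""
    if df is None:
        df = spectrum_table()
    variants = [Variant(int(r.position), r.ref, r.alt) for r in df.itertuples()]
    weights = [int(r.n_populations) for r in df.itertuples()]
    return variants, weights
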