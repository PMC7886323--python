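"""Mutation-spectrum and selection statistics for a toxin-encoding ORF.

The killer toxin preprotoxin is a single short coding sequence organised in
four subunits (delta, alpha, gamma, beta).  This module classifies variants
on such an ORF (synonymous / missense / nonsense / frameshift), summarises
the substitution spectrum (transition:transversion ratio with a chi-squared
test against the 1:2 null expected under no mutational bias), computes
Nei-Gojobori (1986) proportion-based dN/dS, and evaluates the deterministic
logistic sweep time for a beneficial mutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Data import CodonTable
from scipy import stats

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
BASES = "ACGT"

# Preprotoxin subunit boundaries (1-based amino-acid intervals, inclusive),
# defaults from the K1 literature; configuration data, not hard claims.
DEFAULT_SUBUNITS = (
    ("delta", 1, 44),
    ("alpha", 45, 149),
    ("gamma", 150, 233),
    ("beta", 234, 316),
)


@dataclass(frozen=True)
class Variant:
    """A variant on an ORF, VCF-style: 0-based position, ref and alt strings."""

    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if not self.ref and not self.alt:
            raise ValueError("ref and alt cannot both be empty")
        for s in (self.ref, self.alt):
            if any(b not in BASES for b in s):
                raise ValueError(f"non-ACGT base in variant: {s!r}")

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snv"
        if len(self.alt) > len(self.ref):
            return "insertion"
        return "deletion"

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))


@dataclass
class ORFAnnotation:
    """A coding sequence starting at ATG with labelled subunit intervals."""

    sequence: str
    codon_table_id: int = 1
    subunits: tuple = DEFAULT_SUBUNITS

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if len(self.sequence) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if not self.sequence.startswith("ATG"):
            raise ValueError("ORF must start with ATG")
        self._table = CodonTable.unambiguous_dna_by_id[self.codon_table_id]

    def translate_codon(self, codon: str) -> str:
        if codon in self._table.stop_codons:
            return "*"
        return self._table.forward_table[codon]

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    def codon(self, i: int) -> str:
        return self.sequence[3 * i : 3 * i + 3]

    def subunit_of(self, aa_pos_1based: int) -> str | None:
        for name, lo, hi in self.subunits:
            if lo <= aa_pos_1based <= hi:
                return name
        return None


@dataclass
class VariantEffect:
    effect: str  # synonymous | missense | nonsense | frameshift | inframe_indel
    protein_change: str | None = None  # e.g. "D106G"
    subunit: str | None = None


@dataclass
class SpectrumStats:
    ts_count: int
    tv_count: int
    R: float | None
    chi2: float
    p: float


@dataclass
class DnDsResult:
    N_sites: float
    S_sites: float
    N_diff: float
    S_diff: float
    pN: float
    pS: float
    ratio: float | None
    note: str = ""


def classify_variant(orf: ORFAnnotation, v: Variant) -> VariantEffect:
    """Classify a variant's coding effect by codon comparison.

    Indels whose length is not a multiple of 3 are frameshifts; in-frame
    indels are reported without a protein change string.  SNVs are compared
    codon against codon; a change to a stop codon is nonsense.
    """
    if v.position < 0 or v.position >= len(orf.sequence):
        raise ValueError("variant position outside the ORF")
    if orf.sequence[v.position : v.position + len(v.ref)] != v.ref:
        raise ValueError(
            f"variant ref {v.ref!r} does not match ORF at position {v.position}"
        )
    aa_pos = v.position // 3 + 1
    subunit = orf.subunit_of(aa_pos)
    if v.kind != "snv":
        if v.indel_length % 3 != 0:
            return VariantEffect("frameshift", None, subunit)
        return VariantEffect("inframe_indel", None, subunit)
    if v.alt == v.ref:
        raise ValueError("alt equals ref: not a variant")
    codon_idx = v.position // 3
    offset = v.position % 3
    ref_codon = orf.codon(codon_idx)
    alt_codon = ref_codon[:offset] + v.alt + ref_codon[offset + 1 :]
    ref_aa = orf.translate_codon(ref_codon)
    alt_aa = orf.translate_codon(alt_codon)
    change = f"{ref_aa}{aa_pos}{alt_aa}"
    if alt_aa == ref_aa:
        return VariantEffect("synonymous", change, subunit)
    if alt_aa == "*":
        return VariantEffect("nonsense", change, subunit)
    return VariantEffect("missense", change, subunit)


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in TRANSITIONS


def ts_tv_stats(variants: list[Variant], weights: list[int] | None = None) -> SpectrumStats:
    """Transition:transversion summary with a chi-squared test vs the 1:2 null.

    Under no mutational bias one of the three possible changes per site is a
    transition, so the null expectation is ts:tv = 1:2.  ``weights`` gives a
    per-variant occurrence count (recurrent fixations counted per occurrence
    by default elsewhere).
    """
    snvs = [v for v in variants if v.kind == "snv"]
    if not snvs:
        raise ValueError("need at least one SNV")
    if weights is None:
        weights = [1] * len(snvs)
    ts = sum(w for v, w in zip(snvs, weights) if is_transition(v.ref, v.alt))
    tv = sum(weights) - ts
    n = ts + tv
    expected = [n / 3.0, 2.0 * n / 3.0]
    chi2, p = stats.chisquare([ts, tv], f_exp=expected)
    R = ts / tv if tv > 0 else None
    return SpectrumStats(ts_count=ts, tv_count=tv, R=R, chi2=float(chi2), p=float(p))


def _codon_site_counts(orf: ORFAnnotation, codon: str) -> tuple[float, float]:
    """NG86 expected (nonsynonymous, synonymous) site counts for one codon."""
    n_sites = 0.0
    for pos in range(3):
        ref_base = codon[pos]
        nonsyn = 0
        for b in BASES:
            if b == ref_base:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if orf.translate_codon(mutant) != orf.translate_codon(codon):
                nonsyn += 1
        n_sites += nonsyn / 3.0
    return n_sites, 3.0 - n_sites


def dnds(orf: ORFAnnotation, variants: list[Variant], weights: list[int] | None = None) -> DnDsResult:
    """Nei-Gojobori (1986) proportion dN/dS without multiple-hit correction.

    Expected site counts are summed over the reference codons; observed
    differences are the SNVs classified by coding effect (stop-gains count
    as nonsynonymous).  ``ratio`` is absent (None) when pS = 0.
    """
    for v in variants:
        if v.kind != "snv":
            raise ValueError("dnds accepts SNVs only")
    if weights is None:
        weights = [1] * len(variants)
    N_sites = S_sites = 0.0
    for i in range(orf.n_codons):
        n, s = _codon_site_counts(orf, orf.codon(i))
        N_sites += n
        S_sites += s
    N_diff = S_diff = 0.0
    for v, w in zip(variants, weights):
        eff = classify_variant(orf, v).effect
        if eff == "synonymous":
            S_diff += w
        else:
            N_diff += w
    pN = N_diff / N_sites if N_sites > 0 else 0.0
    pS = S_diff / S_sites if S_sites > 0 else 0.0
    if pS > 0:
        return DnDsResult(N_sites, S_sites, N_diff, S_diff, pN, pS, pN / pS)
    return DnDsResult(
        N_sites, S_sites, N_diff, S_diff, pN, pS, None,
        note="pS = 0: no synonymous differences, ratio undefined",
    )


@dataclass
class SweepTimeQuery:
    s: float  # selection coefficient per generation, > 0
    N: float  # census population size, > 1

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("s must be > 0")
        if self.N <= 1:
            raise ValueError("N must be > 1")


def sweep_time(q: SweepTimeQuery, f0: float | None = None, f_end: float | None = None) -> float:
    """Deterministic logistic sweep time from frequency f0 to f_end.

    t = (1/s) * ln[ f_end (1 - f0) / (f0 (1 - f_end)) ], with f0 = 1/N and
    f_end = 1 - 1/N by default, i.e. t ~ (2/s) ln N for large N.
    """
    if f0 is None:
        f0 = 1.0 / q.N
    if f_end is None:
        f_end = 1.0 - 1.0 / q.N
    if not (0.0 < f0 < f_end < 1.0):
        raise ValueError("need 0 < f0 < f_end < 1")
    return (1.0 / q.s) * math.log(f_end * (1.0 - f0) / (f0 * (1.0 - f_end)))
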