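"""Intracellular variant-frequency quantification from amplicon reads.

The counting rule is deliberately simple and auditable: a read supports the
ancestral (derived) allele when it contains the ancestral (derived) k-mer —
the allele flanked by five nucleotides on each side — or its reverse
complement as an exact substring.  Reads matching both probes are
ambiguous; reads matching neither (including reads with sequencing errors
inside the window) are unmatched, and both are reported.  Sanger
chromatogram peak heights provide an independent estimate of the same
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .seqstats import Variant
from .simcore.reads import apply_variant, revcomp


@dataclass
class AlleleProbe:
    variant: Variant
    ancestral_kmer: str
    derived_kmer: str
    ancestral_rc: str
    derived_rc: str


@dataclass
class ReadCountResult:
    n_ancestral: int = 0
    n_derived: int = 0
    n_ambiguous: int = 0
    n_unmatched: int = 0

    @property
    def n_reads(self) -> int:
        return self.n_ancestral + self.n_derived + self.n_ambiguous + self.n_unmatched


@dataclass
class FrequencyEstimate:
    f: float
    ci_low: float | None
    ci_high: float | None
    n_informative: int
    method: str  # read_count | sanger_peak


def build_allele_probes(reference: str, variant: Variant, flank: int = 5) -> AlleleProbe:
    """Ancestral and derived k-mers: the allele with ``flank`` nt each side.

    Near sequence ends the flanks truncate to the available bases; probes
    shorter than 6 nt in total are refused as uninformative.
    """
    reference = reference.upper()
    p = variant.position
    if not (0 <= p < len(reference)):
        raise ValueError("variant position outside reference")
    if variant.ref == variant.alt:
        raise ValueError("alt equals ref: degenerate variant")
    if reference[p : p + len(variant.ref)] != variant.ref:
        raise ValueError("variant ref inconsistent with the reference sequence")
    left = reference[max(0, p - flank) : p]
    right = reference[p + len(variant.ref) : p + len(variant.ref) + flank]
    anc = left + variant.ref + right
    der = left + variant.alt + right
    if min(len(anc), len(der)) < 6:
        raise ValueError("probe shorter than 6 nt: flanks too truncated")
    return AlleleProbe(variant, anc, der, revcomp(anc), revcomp(der))


def count_reads(reads, probe: AlleleProbe) -> ReadCountResult:
    """Classify reads by exact substring match to the allele probes.

    ``reads`` may be strings or Biopython SeqRecords.
    """
    res = ReadCountResult()
    for read in reads:
        seq = str(read.seq if hasattr(read, "seq") else read).upper()
        anc = probe.ancestral_kmer in seq or probe.ancestral_rc in seq
        der = probe.derived_kmer in seq or probe.derived_rc in seq
        if anc and der:
            res.n_ambiguous += 1
        elif anc:
            res.n_ancestral += 1
        elif der:
            res.n_derived += 1
        else:
            res.n_unmatched += 1
    return res


def variant_frequency(counts: ReadCountResult, ci_alpha: float = 0.05) -> FrequencyEstimate:
    """Derived-allele frequency with a Wilson score interval.

    Ambiguous and unmatched reads are excluded from the denominator (they
    remain reported in ``counts``).
    """
    n = counts.n_ancestral + counts.n_derived
    if n < 1:
        raise ValueError("no informative reads")
    f = counts.n_derived / n
    lo, hi = proportion_confint(counts.n_derived, n, alpha=ci_alpha, method="wilson")
    return FrequencyEstimate(f, float(lo), float(hi), n, "read_count")


def sanger_peak_frequency(peak_derived: float, peak_ancestral: float) -> FrequencyEstimate:
    """Derived-allele frequency from Sanger chromatogram peak heights."""
    if peak_derived < 0 or peak_ancestral < 0:
        raise ValueError("peak heights must be >= 0")
    total = peak_derived + peak_ancestral
    if total == 0:
        raise ValueError("both peaks are zero")
    return FrequencyEstimate(peak_derived / total, None, None, 0, "sanger_peak")


def trajectory_classify(
    freqs: list[FrequencyEstimate | float],
    fix_threshold: float = 0.95,
    loss_threshold: float = 0.05,
) -> str:
    """Classify a variant-frequency trajectory over bottlenecks.

    fixed: final frequency at or above ``fix_threshold``; lost: final at or
    below ``loss_threshold``; transient: rose near fixation then fell back
    near loss (thresholds relaxed by 0.25 on each side); else segregating.
    """
    if len(freqs) < 2:
        raise ValueError("need at least two timepoints")
    vals = [f.f if isinstance(f, FrequencyEstimate) else float(f) for f in freqs]
    final = vals[-1]
    if final >= fix_threshold:
        return "fixed"
    if final <= loss_threshold:
        if max(vals) >= fix_threshold - 0.25:
            return "transient"
        return "lost"
    if max(vals) >= fix_threshold - 0.25 and final <= loss_threshold + 0.25:
        return "transient"
    return "segregating"
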