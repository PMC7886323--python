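"""Flanked-allele read counting and frequency estimation."""

import math

import numpy as np
import pytest

from nontransim.datasets import synthetic_k1_orf
from nontransim.seqstats import Variant
from nontransim.simcore import emit_amplicon_reads, revcomp
from nontransim.simcore.reads import apply_variant
from nontransim.variant_freq import (
    build_allele_probes,
    count_reads,
    sanger_peak_frequency,
    trajectory_classify,
    variant_frequency,
)

REF = str(synthetic_k1_orf().sequence)
VAR = Variant(300, REF[300], "G" if REF[300] != "G" else "A")


class TestProbes:
    def test_interior_snv_probe_length_11(self):
        p = build_allele_probes(REF, VAR)
        assert len(p.ancestral_kmer) == 11
        assert p.ancestral_kmer[5] == VAR.ref
        assert p.derived_kmer[5] == VAR.alt
        assert p.ancestral_rc == revcomp(p.ancestral_kmer)

    def test_probes_differ_only_at_center(self):
        p = build_allele_probes(REF, VAR)
        diffs = [i for i, (a, b) in enumerate(zip(p.ancestral_kmer, p.derived_kmer)) if a != b]
        assert diffs == [5]

    def test_truncation_near_sequence_start(self):
        v = Variant(2, REF[2], "A" if REF[2] != "A" else "C")
        p = build_allele_probes(REF, v)
        assert len(p.ancestral_kmer) == 8  # 2 left + 1 + 5 right

    def test_degenerate_variant_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_allele_probes(REF, Variant(300, REF[300], REF[300]))

    def test_ref_mismatch_rejected(self):
        bad = "A" if REF[300] != "A" else "C"
        with pytest.raises(ValueError, match="inconsistent"):
            build_allele_probes(REF, Variant(300, bad, "G"))


class TestCountReads:
    def test_zero_reads(self):
        res = count_reads([], build_allele_probes(REF, VAR))
        assert res.n_reads == 0

    def test_known_mixture_counted_exactly(self):
        reads = emit_amplicon_reads(REF, VAR, 0.0, 700, error_rate=0.0, seed=1)
        derived_reads = emit_amplicon_reads(REF, VAR, 1.0, 300, error_rate=0.0, seed=2)
        res = count_reads(reads + derived_reads, build_allele_probes(REF, VAR))
        assert res.n_derived == 300
        assert res.n_ancestral == 700
        assert res.n_ambiguous == res.n_unmatched == 0

    def test_reverse_complement_read_counted_derived(self):
        derived = apply_variant(REF, VAR)
        read = revcomp(derived[280:330])
        res = count_reads([read], build_allele_probes(REF, VAR))
        assert res.n_derived == 1

    def test_strand_symmetry(self):
        reads = [str(r.seq) for r in emit_amplicon_reads(REF, VAR, 0.4, 500, seed=3)]
        probe = build_allele_probes(REF, VAR)
        fwd = count_reads(reads, probe)
        rc = count_reads([revcomp(r) for r in reads], probe)
        assert (fwd.n_ancestral, fwd.n_derived, fwd.n_ambiguous, fwd.n_unmatched) == (
            rc.n_ancestral, rc.n_derived, rc.n_ambiguous, rc.n_unmatched
        )

    def test_no_ambiguity_for_error_free_substitution_reads(self):
        reads = emit_amplicon_reads(REF, VAR, 0.5, 1000, error_rate=0.0, seed=4)
        res = count_reads(reads, build_allele_probes(REF, VAR))
        assert res.n_ambiguous == 0
        assert res.n_unmatched == 0


class TestFrequency:
    def test_absent_variant(self):
        reads = emit_amplicon_reads(REF, VAR, 0.0, 100, error_rate=0.0, seed=5)
        est = variant_frequency(count_reads(reads, build_allele_probes(REF, VAR)))
        assert est.f == 0.0

    def test_wilson_interval_closed_form(self):
        reads = emit_amplicon_reads(REF, VAR, 1.0, 300, error_rate=0.0, seed=6)
        reads += emit_amplicon_reads(REF, VAR, 0.0, 700, error_rate=0.0, seed=7)
        est = variant_frequency(count_reads(reads, build_allele_probes(REF, VAR)))
        assert est.f == pytest.approx(0.300)
        # Wilson score interval computed by hand
        z = 1.959963984540054
        n, ph = 1000, 0.3
        center = (ph + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * math.sqrt(ph * (1 - ph) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        assert est.ci_low == pytest.approx(center - half, abs=1e-9)
        assert est.ci_high == pytest.approx(center + half, abs=1e-9)

    def test_estimator_consistency_across_frequencies(self):
        probe = build_allele_probes(REF, VAR)
        for i, f in enumerate(np.arange(0.1, 0.95, 0.1)):
            reads = emit_amplicon_reads(REF, VAR, f, 5000, error_rate=0.001, seed=100 + i)
            est = variant_frequency(count_reads(reads, probe))
            assert abs(est.f - f) < 0.02

    def test_zero_informative_rejected(self):
        from nontransim.variant_freq import ReadCountResult

        with pytest.raises(ValueError):
            variant_frequency(ReadCountResult(0, 0, 5, 10))


class TestSanger:
    def test_equal_peaks(self):
        assert sanger_peak_frequency(100, 100).f == pytest.approx(0.5)

    def test_ratio_arithmetic(self):
        est = sanger_peak_frequency(750, 250)
        assert est.f == pytest.approx(0.75)
        assert est.method == "sanger_peak"
        assert est.ci_low is None

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            sanger_peak_frequency(0, 0)

    def test_agrees_with_read_counting_on_same_truth(self):
        """Co-simulated Sanger and amplicon estimates of one mixture."""
        true_f = 0.62
        reads = emit_amplicon_reads(REF, VAR, true_f, 4000, error_rate=0.001, seed=9)
        read_est = variant_frequency(count_reads(reads, build_allele_probes(REF, VAR)))
        rng = np.random.default_rng(10)
        peak_d = 1000 * true_f * rng.normal(1, 0.02)
        peak_a = 1000 * (1 - true_f) * rng.normal(1, 0.02)
        sanger_est = sanger_peak_frequency(peak_d, peak_a)
        assert abs(read_est.f - sanger_est.f) < 0.05


class TestTrajectoryClassify:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ([0.5, 0.7, 0.9, 0.99], "fixed"),
            ([0.4, 0.8, 0.3, 0.1], "transient"),
            ([0.0, 0.0, 0.0], "lost"),
            ([0.3, 0.45, 0.5, 0.55], "segregating"),
            ([0.5, 0.9, 0.02], "transient"),
        ],
    )
    def test_classification(self, freqs, expected):
        assert trajectory_classify(freqs) == expected

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            trajectory_classify([0.5])
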