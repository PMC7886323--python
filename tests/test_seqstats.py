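"""Variant effect classification, spectrum statistics, dN/dS, sweep times."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nontransim.seqstats import (
    DEFAULT_SUBUNITS,
    ORFAnnotation,
    SpectrumStats,
    SweepTimeQuery,
    Variant,
    classify_variant,
    dnds,
    sweep_time,
    ts_tv_stats,
)

CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
]
SENSE_CODONS = [c for c in CODONS if c not in ("TAA", "TAG", "TGA")]


def random_orf(rng, n_codons=20):
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    return ORFAnnotation("ATG" + "".join(body) + "TAA", subunits=(("alpha", 1, n_codons + 2),))


class TestClassifyVariant:
    def test_synonymous_third_position(self, toy_orf):
        # AAA -> AAG both lysine
        eff = classify_variant(toy_orf, Variant(5, "A", "G"))
        assert eff.effect == "synonymous"
        assert eff.protein_change == "K2K"

    def test_missense_and_nonsense(self, toy_orf):
        eff = classify_variant(toy_orf, Variant(3, "A", "G"))  # AAA -> GAA, K2E
        assert eff.effect == "missense"
        assert eff.protein_change == "K2E"
        eff = classify_variant(toy_orf, Variant(3, "A", "T"))  # AAA -> TAA stop
        assert eff.effect == "nonsense"
        assert eff.protein_change == "K2*"

    def test_single_base_deletion_is_frameshift(self, toy_orf):
        eff = classify_variant(toy_orf, Variant(3, "AA", "A"))
        assert eff.effect == "frameshift"

    def test_in_frame_deletion(self, toy_orf):
        eff = classify_variant(toy_orf, Variant(3, "AAAT", "T"))
        assert eff.effect == "inframe_indel"

    def test_ref_mismatch_raises(self, toy_orf):
        with pytest.raises(ValueError, match="does not match"):
            classify_variant(toy_orf, Variant(3, "C", "G"))

    def test_subunit_label(self):
        orf = ORFAnnotation("ATG" + "AAA" * 320 + "TAA")
        eff = classify_variant(orf, Variant(3 * 105, "A", "G"))  # aa position 106
        assert eff.subunit == "alpha"
        assert DEFAULT_SUBUNITS[1][0] == "alpha"

    def test_agrees_with_full_translation_comparison(self):
        """Brute-force oracle: translate the whole mutated ORF and compare."""
        rng = np.random.default_rng(11)
        for _ in range(300):
            orf = random_orf(rng)
            pos = int(rng.integers(0, len(orf.sequence)))
            ref = orf.sequence[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            eff = classify_variant(orf, Variant(pos, ref, alt))
            mutated = orf.sequence[:pos] + alt + orf.sequence[pos + 1 :]
            p_ref = "".join(orf.translate_codon(orf.sequence[i : i + 3])
                            for i in range(0, len(orf.sequence), 3))
            p_alt = "".join(orf.translate_codon(mutated[i : i + 3])
                            for i in range(0, len(mutated), 3))
            aa = pos // 3
            if p_ref == p_alt:
                expected = "synonymous"
            elif p_alt[aa] == "*" and p_ref[aa] != "*":
                expected = "nonsense"
            else:
                expected = "missense"
            assert eff.effect == expected, (orf.sequence, pos, ref, alt)


class TestTsTv:
    def test_all_transitions_r_undefined(self):
        stats = ts_tv_stats([Variant(i, "A", "G") for i in range(10)])
        assert stats.ts_count == 10 and stats.tv_count == 0
        assert stats.R is None

    def test_exact_null_proportions_give_zero(self):
        stats = ts_tv_stats(
            [Variant(0, "A", "G"), Variant(1, "A", "C"), Variant(2, "A", "T")]
        )
        assert stats.chi2 == pytest.approx(0.0)

    def test_reported_spectrum_marginals(self):
        variants = [Variant(i, "C", "T") for i in range(32)] + [
            Variant(40 + i, "C", "G") for i in range(5)
        ]
        stats = ts_tv_stats(variants)
        assert stats.R == pytest.approx(6.4)
        assert stats.chi2 == pytest.approx(47.0, abs=0.05)

    def test_weights_count_recurrent_fixations(self):
        stats = ts_tv_stats([Variant(0, "A", "G"), Variant(1, "A", "C")], weights=[3, 1])
        assert (stats.ts_count, stats.tv_count) == (3, 1)


class TestDnDs:
    def test_empty_variant_list_has_no_ratio(self, toy_orf):
        res = dnds(toy_orf, [])
        assert res.ratio is None and res.N_diff == 0

    def test_hand_computed_site_table(self, toy_orf):
        # ATG: 3 nonsyn sites; AAA: 8/3 N, 1/3 S; TAA: 7/3 N, 2/3 S
        res = dnds(toy_orf, [Variant(5, "A", "G"), Variant(3, "A", "C")])
        assert res.N_sites == pytest.approx(8.0)
        assert res.S_sites == pytest.approx(1.0)
        assert (res.N_diff, res.S_diff) == (1, 1)
        assert res.ratio == pytest.approx((1 / 8.0) / (1 / 1.0))

    def test_sites_partition_sequence_length(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            orf = random_orf(rng, n_codons=15)
            res = dnds(orf, [])
            assert res.N_sites + res.S_sites == pytest.approx(len(orf.sequence), abs=1e-9)

    def test_all_synonymous_set_has_zero_ndiff(self):
        orf = ORFAnnotation("ATG" + "CTA" * 5 + "TAA")
        # CTA -> CTG is leucine -> leucine
        variants = [Variant(3 + 3 * i + 2, "A", "G") for i in range(5)]
        res = dnds(orf, variants)
        assert res.N_diff == 0 and res.S_diff == 5


class TestSweepTime:
    def test_chemostat_benchmark(self):
        t = sweep_time(SweepTimeQuery(s=0.30, N=4e9))
        assert round(t, -1) == 150

    def test_doubling_s_halves_t(self):
        q1, q2 = SweepTimeQuery(0.1, 1e6), SweepTimeQuery(0.2, 1e6)
        assert sweep_time(q1) == pytest.approx(2 * sweep_time(q2))

    def test_closed_form_value(self):
        t = sweep_time(SweepTimeQuery(0.1, 1e6))
        assert t == pytest.approx(276.3, abs=0.05)

    @given(
        s=st.floats(0.01, 1.0), n=st.floats(10.0, 1e12),
        ds=st.floats(0.001, 0.5), dn=st.floats(1.0, 100.0),
    )
    def test_monotone_in_s_and_n(self, s, n, ds, dn):
        t = sweep_time(SweepTimeQuery(s, n))
        assert sweep_time(SweepTimeQuery(s + ds, n)) < t
        assert sweep_time(SweepTimeQuery(s, n * dn + 1)) > t

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            sweep_time(SweepTimeQuery(0.1, 100), f0=0.9, f_end=0.1)
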