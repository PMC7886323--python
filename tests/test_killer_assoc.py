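"""Phenotype bookkeeping and contingency statistics."""

import numpy as np
import pandas as pd
import pytest

from nontransim.killer_assoc import (
    chisq_sf,
    contingency_chisq,
    phenotype_trajectory,
    transition_audit,
)


def direct_chisq(table):
    """Independent oracle: direct sum of (O-E)^2/E."""
    t = np.asarray(table, dtype=float)
    rows, cols, n = t.sum(1), t.sum(0), t.sum()
    e = np.outer(rows, cols) / n
    return ((t - e) ** 2 / e).sum()


class TestContingency:
    def test_reported_association_statistic(self):
        chi2, df, p = contingency_chisq([[57, 0], [1, 9]], yates=False)
        assert round(chi2, 1) == 59.3
        assert df == 1

    def test_independent_table(self):
        chi2, _, p = contingency_chisq([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_small_table(self):
        chi2, _, _ = contingency_chisq([[5, 2], [3, 8]])
        assert chi2 == pytest.approx(3.378, abs=0.001)

    def test_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            t = rng.integers(1, 100, size=(2, 2))
            chi2, _, _ = contingency_chisq(t)
            assert chi2 == pytest.approx(direct_chisq(t), abs=1e-10)

    def test_invariant_under_transposition_and_swaps(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = rng.integers(1, 50, size=(2, 2))
            ref = contingency_chisq(t)[0]
            assert contingency_chisq(t.T)[0] == pytest.approx(ref)
            assert contingency_chisq(t[::-1])[0] == pytest.approx(ref)
            assert contingency_chisq(t[:, ::-1])[0] == pytest.approx(ref)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            contingency_chisq([[0, 0], [3, 4]])


class TestChisqSf:
    def test_at_zero(self):
        assert chisq_sf(0, 1) == 1.0

    def test_reported_gene_set_p(self):
        assert chisq_sf(18.4, 1) == pytest.approx(1.8e-5, rel=0.02)

    def test_normal_tail_identity(self):
        # chi2(1) upper tail at 1.96^2 equals the two-sided normal tail
        assert chisq_sf(3.84, 1) == pytest.approx(0.0500, abs=2e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chisq_sf(-1.0, 1)


def make_records(rows):
    return pd.DataFrame(rows, columns=["population", "generation", "killing", "immunity"])


class TestTrajectory:
    def test_full_retention(self):
        rec = make_records(
            [(p, g, "full", "full") for p in "AB" for g in (0, 100, 200)]
        )
        traj = phenotype_trajectory(rec)
        assert (traj.killing_retained == 1.0).all()
        assert (traj.immunity_retained == 1.0).all()

    def test_reported_generation_1000_fractions(self):
        """Half the populations weakened killing; 10% lost both axes."""
        rows = []
        for i in range(20):
            rows.append((f"P{i}", 0, "full", "full"))
            if i < 2:
                rows.append((f"P{i}", 1000, "none", "none"))
            elif i < 10:
                rows.append((f"P{i}", 1000, "weak", "full"))
            else:
                rows.append((f"P{i}", 1000, "full", "full"))
        traj = phenotype_trajectory(make_records(rows))
        final = traj[traj.generation == 1000].iloc[0]
        assert final.killing_retained == pytest.approx(0.5)
        assert final.immunity_retained == pytest.approx(0.9)

    def test_matches_direct_recount_on_random_tables(self):
        rng = np.random.default_rng(8)
        grades = np.array(["none", "weak", "full"])
        gens = [0, 50, 100]
        rows = [
            (f"P{i}", g, grades[rng.integers(3)], grades[rng.integers(3)])
            for i in range(15) for g in gens
        ]
        rec = make_records(rows)
        traj = phenotype_trajectory(rec, threshold="weak")
        for g in gens:
            sub = rec[rec.generation == g]
            expect = (sub.killing != "none").mean()
            got = traj.loc[traj.generation == g, "killing_retained"].iloc[0]
            assert got == pytest.approx(expect)

    def test_missing_at_zero_rejected(self):
        rec = make_records([("A", 0, "full", "full"), ("B", 100, "full", "full")])
        with pytest.raises(ValueError, match="generation 0"):
            phenotype_trajectory(rec)

    def test_forward_fill_of_missing_observations(self):
        rec = make_records(
            [("A", 0, "full", "full"), ("A", 100, "none", "full"),
             ("B", 0, "full", "full")]
        )
        traj = phenotype_trajectory(rec)
        assert traj.loc[traj.generation == 100, "killing_retained"].iloc[0] == 0.5


class TestAudit:
    def test_constant_phenotypes_clean(self):
        rec = make_records([("A", g, "full", "full") for g in (0, 100)])
        assert transition_audit(rec) == []

    def test_immunity_lost_before_killing_flagged(self):
        rec = make_records([("A", 0, "full", "full"), ("A", 100, "full", "none")])
        v = transition_audit(rec)
        assert any(x.kind == "immunity_lost_before_killing" for x in v)

    def test_simultaneous_loss_is_legal(self):
        rec = make_records([("A", 0, "full", "full"), ("A", 100, "none", "none")])
        assert transition_audit(rec) == []

    def test_grade_increase_flagged(self):
        rec = make_records(
            [("A", 0, "full", "full"), ("A", 100, "none", "full"),
             ("A", 200, "weak", "full")]
        )
        v = transition_audit(rec)
        assert any(x.kind == "grade_increase" for x in v)
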