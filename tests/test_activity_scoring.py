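import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import regulonsurv as rs
from regulonsurv.activity_scoring import SampleRanking, standardize_activities
from regulonsurv.regulon_builder import Regulon


def brute_force_recovery_auc(ordered_genes, targets, cutoff_fraction):
    """Oracle: explicitly build the step recovery curve y(x) and integrate it."""
    N = len(ordered_genes)
    x_max = math.ceil(cutoff_fraction * N)
    present = [g for g in targets if g in ordered_genes]
    m = len(present)
    if m == 0:
        return float("nan")
    raw = 0
    for x in range(1, x_max + 1):
        raw += sum(1 for g in present if ordered_genes.index(g) + 1 <= x)
    max_raw = sum(min(x, m) for x in range(1, x_max + 1))
    return raw / max_raw


def _expr(values_by_gene, sample="s1"):
    genes = list(values_by_gene)
    return rs.ExpressionMatrix(genes, [sample], np.array([[values_by_gene[g]] for g in genes]))


class TestRankGenes:
    def test_descending_by_expression(self):
        ranking = rs.rank_genes(_expr({"A": 5, "B": 3, "C": 9}), "s1")
        assert ranking.ordered_genes == ["C", "A", "B"]

    def test_ties_broken_by_symbol(self):
        ranking = rs.rank_genes(_expr({"B": 5, "A": 5}), "s1")
        assert ranking.ordered_genes == ["A", "B"]

    def test_monotone_transform_leaves_ordering(self):
        vals = {"A": 1.0, "B": -2.0, "C": 0.5, "D": 3.0}
        r1 = rs.rank_genes(_expr(vals), "s1")
        r2 = rs.rank_genes(_expr({g: np.exp(v) for g, v in vals.items()}), "s1")
        assert r1.ordered_genes == r2.ordered_genes

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            rs.rank_genes(_expr({"A": 1}), "nope")


class TestRecoveryAuc:
    def _ranking(self, n):
        return SampleRanking("s", [f"G{i:03d}" for i in range(1, n + 1)])

    def test_perfect_enrichment_scores_one(self):
        regulon = Regulon("R", {"G001", "G002"})
        assert rs.recovery_auc(self._ranking(10), regulon, 0.2) == 1.0

    def test_no_recovery_scores_zero(self):
        regulon = Regulon("R", {"G009", "G010"})
        assert rs.recovery_auc(self._ranking(10), regulon, 0.2) == 0.0

    def test_hand_enumerated_half_recovery(self):
        # N=10, cutoff 0.5 (x_max=5), targets at ranks 2, 4, 9:
        # y = (0,1,1,2,2) -> raw 6; max_raw = 1+2+3+3+3 = 12 -> 0.5
        regulon = Regulon("R", {"G002", "G004", "G009"})
        auc = rs.recovery_auc(self._ranking(10), regulon, 0.5)
        assert auc == 0.5
        assert auc == brute_force_recovery_auc(self._ranking(10).ordered_genes,
                                               regulon.targets, 0.5)

    def test_absent_regulon_is_missing_coded(self, caplog):
        regulon = Regulon("R", {"NOT_THERE"})
        with caplog.at_level("WARNING", logger="regulonsurv"):
            assert math.isnan(rs.recovery_auc(self._ranking(10), regulon, 0.2))

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(10, 200))
            m = int(rng.integers(1, min(20, N)))
            cutoff = float(rng.choice([0.1, 0.2, 0.5]))
            genes = [f"G{i:04d}" for i in range(N)]
            order = rng.permutation(N)
            ranking = SampleRanking("s", [genes[i] for i in order])
            targets = set(rng.choice(genes, size=m, replace=False).tolist())
            regulon = Regulon("R", targets)
            assert rs.recovery_auc(ranking, regulon, cutoff) == brute_force_recovery_auc(
                ranking.ordered_genes, targets, cutoff
            )

    @given(st.data())
    def test_promoting_a_target_never_decreases_auc(self, data):
        N = data.draw(st.integers(10, 60))
        m = data.draw(st.integers(1, 8))
        genes = [f"G{i:03d}" for i in range(N)]
        target_pos = sorted(data.draw(
            st.sets(st.integers(0, N - 1), min_size=m, max_size=m)))
        targets = {genes[i] for i in target_pos}
        ranking = SampleRanking("s", genes)
        worst = max(target_pos)
        better = data.draw(st.integers(0, worst))
        # move the worst-ranked target up to position `better`
        promoted = [g for g in genes if g != genes[worst]]
        promoted.insert(better, genes[worst])
        auc_before = rs.recovery_auc(ranking, Regulon("R", targets), 0.2)
        auc_after = rs.recovery_auc(SampleRanking("s", promoted), Regulon("R", targets), 0.2)
        assert auc_after >= auc_before

    def test_auc_one_iff_targets_occupy_top_ranks(self):
        ranking = self._ranking(20)  # x_max = 4 at cutoff 0.2
        assert rs.recovery_auc(ranking, Regulon("R", {"G001", "G002", "G003"}), 0.2) == 1.0
        assert rs.recovery_auc(ranking, Regulon("R", {"G001", "G002", "G004"}), 0.2) < 1.0


class TestScoreActivityMatrix:
    def test_single_cell_composition_reproduces_recovery_auc(self, small_cohort, small_regulons):
        _, expr, _, _, _ = small_cohort
        act = rs.score_activity_matrix(expr, small_regulons)
        regulon = small_regulons[0]
        sample = expr.sample_ids[7]
        expected = rs.recovery_auc(rs.rank_genes(expr, sample), regulon, act.cutoff_fraction)
        i = act.regulators.index(regulon.regulator)
        j = act.sample_ids.index(sample)
        assert act.scores[i, j] == expected

    def test_affine_transform_gives_bitwise_identical_scores(self, small_cohort, small_regulons):
        _, expr, _, _, _ = small_cohort
        act = rs.score_activity_matrix(expr, small_regulons)
        shifted = rs.apply_platform_transform(expr, "affine", {"slope": 3.0, "intercept": -2.0})
        act2 = rs.score_activity_matrix(shifted, small_regulons)
        np.testing.assert_array_equal(act.scores, act2.scores)

    def test_scores_bounded(self, small_activity):
        assert np.nanmin(small_activity.scores) >= 0.0
        assert np.nanmax(small_activity.scores) <= 1.0

    def test_estimated_activity_tracks_latent_truth(self, small_cohort, small_activity):
        _, _, _, _, truth = small_cohort
        for reg in small_activity.regulators:
            est = small_activity.row(reg)
            corr = np.corrcoef(est, truth.activity_of(reg))[0, 1]
            assert corr > 0.6

    def test_low_presence_regulon_dropped(self, small_cohort, caplog):
        _, expr, _, _, _ = small_cohort
        half_absent = Regulon("R", set(expr.gene_ids[:5]) | {f"MISSING{i}" for i in range(6)})
        ok = Regulon("OK", set(expr.gene_ids[5:20]))
        with caplog.at_level("WARNING", logger="regulonsurv"):
            act = rs.score_activity_matrix(expr, [half_absent, ok])
        assert act.regulators == ["OK"]

    def test_error_when_no_regulon_survives(self, small_cohort):
        _, expr, _, _, _ = small_cohort
        ghost = Regulon("R", {f"MISSING{i}" for i in range(10)})
        with pytest.raises(ValueError, match="presence filter"):
            rs.score_activity_matrix(expr, [ghost])


class TestStandardizeActivities:
    def _act(self, rows, regs=None):
        rows = np.asarray(rows, float)
        regs = regs or [f"R{i}" for i in range(rows.shape[0])]
        return rs.ActivityMatrix(regs, [f"s{j}" for j in range(rows.shape[1])], rows)

    def test_closed_form_row(self):
        z = standardize_activities(self._act([[0.2, 0.4, 0.6]]))
        np.testing.assert_allclose(
            z.to_numpy()[0], [-math.sqrt(1.5), 0.0, math.sqrt(1.5)], atol=1e-12
        )

    def test_constant_row_dropped(self, caplog):
        with caplog.at_level("WARNING", logger="regulonsurv"):
            z = standardize_activities(self._act([[0.5, 0.5, 0.5], [0.1, 0.2, 0.9]]))
        assert list(z.index) == ["R1"]

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        z = standardize_activities(self._act(rng.uniform(size=(4, 30))))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-12)


class TestRandomTieBreak:
    def test_seeded_random_tie_break_is_reproducible_and_valid(self):
        expr = _expr({"A": 5, "B": 5, "C": 5, "D": 9})
        r1 = rs.rank_genes(expr, "s1", tie_break="random", seed=3)
        r2 = rs.rank_genes(expr, "s1", tie_break="random", seed=3)
        assert r1.ordered_genes == r2.ordered_genes
        assert r1.ordered_genes[0] == "D"
        assert sorted(r1.ordered_genes) == ["A", "B", "C", "D"]

    def test_unknown_tie_break_rejected(self):
        with pytest.raises(ValueError, match="tie_break"):
            rs.rank_genes(_expr({"A": 1}), "s1", tie_break="coin")
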