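"""The fuzzy traversal algorithm, its crisp limit, and the fallback search."""

import numpy as np
import pandas as pd
import pytest

from fptree import (
    FPTError,
    PatientRecord,
    Statement,
    build_tree,
    conditional_probability,
    crisp_predict,
    crisp_variant,
    find_existing_conditions,
    fuzzy_predict,
    predict,
)

from conftest import (
    enumerate_fuzzy_prediction,
    random_full_table,
    random_patient,
)


def patient_statements(demo):
    return demo.patient.statements + [
        Statement("Age", demo.patient.raw_values["Age"]),
        Statement("NoduleDimensions", demo.patient.raw_values["NoduleDimensions"]),
    ]


class TestWorkedExample:
    def test_fuzzy_prediction_is_0427(self, demo):
        """The membership-weighted prediction of the demonstration patient:
        0.2*(0.2*1*0 + 0.8*1*0) + 0.8*(0.2*0.333*0 + 0.2*0.667*1
        + 0.8*0.5*0 + 0.8*0.5*1) = 0.427 (to the printed three decimals)."""
        value = fuzzy_predict(
            demo.tree, demo.tree.root, patient_statements(demo), "1",
            demo.fuzzy_config,
        )
        assert round(value, 3) == 0.427
        assert value == pytest.approx(0.42672, abs=1e-12)

    def test_crisp_prediction_is_benign_with_probability_one(self, demo):
        result = crisp_predict(
            demo.tree, demo.fuzzy_config, demo.crisp_cuts, demo.patient
        )
        assert result.prob_negative == 1.0
        assert result.prob_positive == 0.0
        assert result.label == "0"

    def test_probabilities_sum_to_one(self, demo):
        result = predict(demo.tree, demo.fuzzy_config, demo.patient)
        assert result.prob_positive + result.prob_negative == pytest.approx(
            1.0, abs=1e-9
        )
        assert result.prob_positive == pytest.approx(0.42672, abs=1e-12)


class TestTraversalCases:
    def test_degenerate_memberships_equal_conditional_probability(self, demo):
        """A patient at full membership everywhere follows one crisp path."""
        statements = demo.patient.statements + [
            Statement("Age", 70.0),              # mu(50Plus) = 1
            Statement("NoduleDimensions", 30.0),  # mu(Large) = 1
        ]
        crisp = demo.patient.statements + [
            Statement("Age", "50Plus"),
            Statement("NoduleDimensions", "Large Nodule"),
        ]
        fuzzy = fuzzy_predict(demo.tree, demo.tree.root, statements, "1",
                              demo.fuzzy_config)
        assert fuzzy == pytest.approx(
            conditional_probability(demo.tree, crisp, "1"), abs=1e-12
        )
        assert fuzzy == pytest.approx(0.5)

    def test_empty_statements_return_marginal(self, demo):
        prior = conditional_probability(demo.tree, [], "1")
        assert fuzzy_predict(demo.tree, demo.tree.root, [], "1",
                             demo.fuzzy_config) == pytest.approx(prior)

    def test_unseen_value_uses_theta_weighted_average(self, ten_rows):
        # drop (A=0, B=1): at the A=0 node, B=1 has no child
        subset = ten_rows[~((ten_rows.A == "0") & (ten_rows.B == "1"))]
        tree = build_tree(subset, ["A", "B"], "Y")
        got = fuzzy_predict(
            tree, tree.root, [Statement("A", "0"), Statement("B", "1")], "1"
        )
        # single remaining child (B=0, theta 1): equals its leaf fraction
        expected = conditional_probability(
            tree, [Statement("A", "0"), Statement("B", "0")], "1"
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_absent_variable_uses_uniform_average(self, ten_rows):
        tree = build_tree(ten_rows, ["A", "B"], "Y")
        got = fuzzy_predict(tree, tree.root, [Statement("B", "1")], "1")
        expected = 0.5 * conditional_probability(
            tree, [Statement("A", "0"), Statement("B", "1")], "1"
        ) + 0.5 * conditional_probability(
            tree, [Statement("A", "1"), Statement("B", "1")], "1"
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_foreign_node_and_unknown_class_rejected(self, demo, ten_rows):
        other = build_tree(ten_rows, ["A", "B"], "Y")
        with pytest.raises(FPTError):
            fuzzy_predict(demo.tree, other.root, [], "1", demo.fuzzy_config)
        with pytest.raises(FPTError):
            fuzzy_predict(demo.tree, demo.tree.root, [], "maybe",
                          demo.fuzzy_config)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_weighted_enumeration_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        _, tree, fuzzy_config, levels = random_full_table(
            rng, n_features=4, fuzzy_vars=int(rng.integers(0, 3))
        )
        for _ in range(4):
            statements = random_patient(rng, tree, fuzzy_config, levels)
            got = fuzzy_predict(tree, tree.root, statements, "1", fuzzy_config)
            expected = enumerate_fuzzy_prediction(
                tree, fuzzy_config, statements, "1"
            )
            assert got == pytest.approx(expected, abs=1e-10)
            assert 0.0 <= got <= 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_crisp_limit_identity(self, seed):
        """With step memberships at the cuts, fuzzy and crisp prediction
        coincide on every patient."""
        rng = np.random.default_rng(400 + seed)
        _, tree, fuzzy_config, levels = random_full_table(
            rng, n_features=4, fuzzy_vars=2
        )
        cuts = {
            name: float(np.mean([var.sets[0].knots[0][0],
                                 var.sets[0].knots[-1][0]]))
            for name, var in fuzzy_config.items()
        }
        step_config = {n: crisp_variant(v, cuts[n])
                       for n, v in fuzzy_config.items()}
        for _ in range(5):
            statements = random_patient(rng, tree, fuzzy_config, levels,
                                        p_skip=0.0)
            raw = {s.variable: s.value for s in statements
                   if s.variable in fuzzy_config}
            crisp_stmts = [s for s in statements
                           if s.variable not in fuzzy_config]
            patient = PatientRecord(statements=crisp_stmts, raw_values=raw)
            fuzzy_as_steps = predict(tree, step_config, patient)
            crisp = crisp_predict(tree, fuzzy_config, cuts, patient)
            assert fuzzy_as_steps.prob_positive == pytest.approx(
                crisp.prob_positive, abs=1e-12
            )

    def test_monotonicity_in_membership(self, demo):
        """Raising the nodule size moves the prediction toward the
        large-nodule subtree's value."""
        base = demo.patient.statements + [Statement("Age", 70.0)]
        probs = [
            fuzzy_predict(
                demo.tree, demo.tree.root,
                base + [Statement("NoduleDimensions", float(mm))],
                "1", demo.fuzzy_config,
            )
            for mm in (12, 14, 16, 18)
        ]
        # under 50Plus: small leaf has fraction 0.667, large 0.5 — so the
        # prediction must decrease as the large-nodule weight grows
        assert all(a > b for a, b in zip(probs, probs[1:]))


class TestThresholdRule:
    @pytest.mark.parametrize(
        "prob, threshold, expected",
        [(0.50, 0.50, "1"), (0.49, 0.50, "0"), (0.60, 0.80, "0"),
         (0.80, 0.80, "1")],
    )
    def test_inclusive_cutoff(self, prob, threshold, expected):
        # two-leaf tree with exactly the wanted positive fraction
        n = 100
        pos = int(round(prob * n))
        df = pd.DataFrame({"A": ["x"] * n,
                           "Y": ["1"] * pos + ["0"] * (n - pos)})
        tree = build_tree(df, ["A"], "Y")
        result = predict(tree, {}, PatientRecord([Statement("A", "x")]),
                         threshold=threshold)
        assert result.prob_positive == pytest.approx(prob)
        assert result.label == expected


class TestFindExistingConditions:
    def test_exact_match_returns_full_list(self, ten_rows):
        tree = build_tree(ten_rows, ["A", "B"], "Y")
        statements = [Statement("A", "1"), Statement("B", "0")]
        assert find_existing_conditions(tree, statements) == statements

    def test_unrepresented_combination_drops_minimum(self, ten_rows):
        subset = ten_rows[~((ten_rows.A == "0") & (ten_rows.B == "1"))]
        tree = build_tree(subset, ["A", "B"], "Y")
        statements = [Statement("A", "0"), Statement("B", "1")]
        kept = find_existing_conditions(tree, statements)
        assert len(kept) == 1  # one of the two must be dropped

    def test_empty_input_returns_empty(self, ten_rows):
        tree = build_tree(ten_rows, ["A", "B"], "Y")
        assert find_existing_conditions(tree, []) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_subset_search(self, seed):
        """The result is a represented subset of maximum size."""
        import itertools

        rng = np.random.default_rng(500 + seed)
        records, tree, _, levels = random_full_table(rng, n_features=3)
        # thin the table so unrepresented combinations exist
        thinned = records.sample(frac=0.3, random_state=seed)
        if thinned["Y"].nunique() < 2:
            thinned = records.sample(frac=0.5, random_state=seed)
        tree = build_tree(thinned, tree.feature_order, "Y")

        def represented(subset):
            df = thinned
            mask = pd.Series(True, index=df.index)
            for s in subset:
                mask &= df[s.variable] == s.value
            return bool(mask.any())

        for _ in range(5):
            statements = [
                Statement(v, str(rng.choice(levels[v])))
                for v in tree.feature_order
            ]
            kept = find_existing_conditions(tree, statements)
            assert represented(kept)
            best = max(
                (
                    sub
                    for k in range(len(statements) + 1)
                    for sub in itertools.combinations(statements, k)
                    if represented(sub)
                ),
                key=len,
            )
            assert len(kept) == len(best)


class TestPredictFallbacks:
    def test_unrepresented_patient_still_gets_probability(self, ten_rows):
        subset = ten_rows[~((ten_rows.A == "0") & (ten_rows.B == "1"))]
        tree = build_tree(subset, ["A", "B"], "Y")
        patient = PatientRecord(
            statements=[Statement("A", "0"), Statement("B", "1")]
        )
        result = predict(tree, {}, patient)
        assert 0.0 <= result.prob_positive <= 1.0

    def test_no_statements_returns_prior(self, ten_rows):
        tree = build_tree(ten_rows, ["A", "B"], "Y")
        result = predict(tree, {}, PatientRecord())
        assert result.prob_positive == pytest.approx(0.5)
        assert result.support == 10

    def test_duplicate_statement_rejected(self):
        with pytest.raises(FPTError, match="duplicate"):
            PatientRecord([Statement("A", "1"), Statement("A", "2")])
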