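"""Site-rate inference: pruning likelihood, gamma posterior, 1-9 grading."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

from surfcons.conservation import (
    GeneralReversibleModel,
    Msa,
    PhyloTree,
    PoissonModel,
    SiteRateModel,
    column_residue_variety,
    discretize_gamma,
    grade_rates,
    labels_for_grades,
    site_log_likelihood,
    site_log_likelihoods,
    site_rate_posterior_mean,
    site_rate_posterior_means,
)
from surfcons.errors import FormatError, LookupFailure, ParameterError
from surfcons.synthetic import SimAlignmentSpec, balanced_tree, simulate_alignment


def toy_4state_model(seed=0):
    rng = np.random.default_rng(seed)
    pi = np.array([0.1, 0.2, 0.3, 0.4])
    ex = np.abs(rng.normal(1.0, 0.3, (4, 4)))
    ex = (ex + ex.T) / 2
    q = ex * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return GeneralReversibleModel(q, pi)


class TestMsa:
    def test_valid_alignment(self):
        msa = Msa(list("abcd"), ["ACDEFGHIKL"] * 4)
        assert msa.length == 10 and msa.n_sequences == 4

    def test_ragged_alignment_names_row(self):
        with pytest.raises(FormatError, match="row 2"):
            Msa(["a", "b"], ["ACDEFGHIKL", "ACDEFGHIK"])

    def test_invalid_character_cites_position(self):
        with pytest.raises(FormatError, match="row 1.*column 3"):
            Msa(["a", "b"], ["ACB", "ACD"])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(FormatError, match="duplicate"):
            Msa(["a", "a"], ["AC", "AD"])

    def test_gaps_accepted(self):
        msa = Msa(["a", "b"], ["A-C", "ABC".replace("B", "-")])
        assert (msa.codes[:, 1] == -1).all()


class TestPruning:
    def test_rate_zero_identical_leaves_gives_log_pi(self):
        tree = PhyloTree.from_newick("(a:0.07,b:0.13);")
        ll = site_log_likelihood({"a": "L", "b": "L"}, tree, rate=0.0)
        assert ll == pytest.approx(np.log(1 / 20))

    def test_rate_zero_differing_leaves_is_impossible(self):
        tree = PhyloTree.from_newick("(a:0.07,b:0.13);")
        ll = site_log_likelihood({"a": "L", "b": "P"}, tree, rate=0.0)
        assert ll == -np.inf

    def test_two_leaf_closed_form(self):
        # 20-state equal-rates: P(same) = 1/20 + (19/20) exp(-20/19 t)
        tree = PhyloTree.from_newick("(a:0.07,b:0.13);")
        t = 0.2
        same = np.log((1 / 20) * (1 / 20 + (19 / 20) * np.exp(-20 / 19 * t)))
        diff = np.log((1 / 20) * (1 / 20 - (1 / 20) * np.exp(-20 / 19 * t)))
        assert site_log_likelihood({"a": "L", "b": "L"}, tree) == pytest.approx(same)
        assert site_log_likelihood({"a": "L", "b": "P"}, tree) == pytest.approx(diff)

    def test_pruning_equals_interior_state_enumeration(self):
        # 4-leaf tree, 4-state model: sum over all interior assignments
        tree = PhyloTree.from_newick("((a:0.1,b:0.3):0.2,(c:0.15,d:0.25):0.05);")
        model = toy_4state_model()
        msa = Msa(list("abcd"), ["A", "C", "D", "A"])  # codes 0,1,2,0
        p = {
            k: model.transition_matrix(t)
            for k, t in dict(a=0.1, b=0.3, c=0.15, d=0.25, x=0.2, y=0.05).items()
        }
        col = msa.codes[:, 0]
        lik = 0.0
        for root in range(4):
            for x in range(4):
                for y in range(4):
                    lik += (
                        model.freqs[root]
                        * p["x"][root, x] * p["y"][root, y]
                        * p["a"][x, col[0]] * p["b"][x, col[1]]
                        * p["c"][y, col[2]] * p["d"][y, col[3]]
                    )
        ours = site_log_likelihoods(msa, tree, model, 1.0)[0]
        assert ours == pytest.approx(np.log(lik), abs=1e-10)

    def test_log_additivity_over_columns(self):
        tree = balanced_tree(8, 0.3)
        msa, _ = simulate_alignment(SimAlignmentSpec(tree=tree, n_sites=20, seed=5))
        per_col = site_log_likelihoods(msa, tree)
        assert np.isfinite(per_col).all()
        assert (per_col <= 0).all()  # site likelihoods are probabilities

    def test_missing_leaf_in_alignment_errors(self):
        tree = PhyloTree.from_newick("(a:0.1,b:0.1,c:0.1);")
        msa = Msa(["a", "b"], ["A", "A"])
        with pytest.raises(LookupFailure, match="c"):
            site_log_likelihoods(msa, tree)


class TestGammaPosterior:
    def test_discretization_mean_is_one(self):
        for alpha in (0.3, 1.0, 2.5):
            rates = discretize_gamma(alpha, 8)
            assert rates.mean() == pytest.approx(1.0, abs=1e-8)
            assert (np.diff(rates) > 0).all()

    def test_conserved_column_below_prior_mean(self):
        tree = balanced_tree(8, 0.5)
        col = {label: "W" for label in tree.leaf_labels}
        assert site_rate_posterior_mean(col, tree) < 1.0

    def test_diverse_column_matches_bruteforce_category_sum(self):
        tree = balanced_tree(8, 0.5)
        residues = list("ACDEFGHI")
        col = {lab: r for lab, r in zip(tree.leaf_labels, residues)}
        post = site_rate_posterior_mean(col, tree)
        assert post > 1.0  # all-different leaves pull the rate up
        # brute force: explicit category sum on raw likelihoods
        rates = discretize_gamma(1.0, 8)
        msa = Msa(tree.leaf_labels, [col[l] for l in tree.leaf_labels])
        liks = np.array(
            [np.exp(site_log_likelihoods(msa, tree, rate=r)[0]) for r in rates]
        )
        brute = (rates * liks).sum() / liks.sum()
        assert post == pytest.approx(brute, rel=1e-10)

    def test_identical_columns_get_identical_rates(self):
        tree = balanced_tree(8, 0.4)
        seqs = ["AWA"] * 4 + ["CWC"] * 4
        msa = Msa(tree.leaf_labels, seqs)
        rates = site_rate_posterior_means(msa, tree)
        assert rates[0] == rates[2]  # function purity: same column, same rate

    def test_all_gap_column_is_nan(self):
        tree = balanced_tree(4, 0.4)
        msa = Msa(tree.leaf_labels, ["A-"] * 4)
        rates = site_rate_posterior_means(msa, tree)
        assert np.isnan(rates[1]) and np.isfinite(rates[0])


class TestGrading:
    def test_degenerate_equal_rates_all_grade_nine(self):
        grades = grade_rates(np.full(20, 0.7))
        assert (grades == 9).all()

    def test_max_rate_gets_grade_one_variable(self):
        rates = np.linspace(0.1, 3.0, 50)
        grades = grade_rates(rates)
        assert grades[np.argmax(rates)] == 1
        assert labels_for_grades([grades[np.argmax(rates)]]) == ["variable"]

    def test_grades_antimonotone_in_rate(self):
        rng = np.random.default_rng(0)
        rates = rng.gamma(1.0, 1.0, 200)
        grades = grade_rates(rates)
        order = np.argsort(rates)
        assert (np.diff(grades[order]) <= 0).all()

    def test_label_mapping(self):
        assert labels_for_grades([1, 4, 5, 6, 7, 9]) == [
            "variable", "variable", "intermediate", "intermediate",
            "conserved", "conserved",
        ]

    def test_few_columns_warns(self):
        with pytest.warns(UserWarning, match="gradable columns"):
            grade_rates(np.array([0.5, 1.0, 2.0]))

    def test_no_gradable_columns_errors(self):
        with pytest.raises(ParameterError):
            grade_rates(np.array([np.nan, np.nan]))

    def test_planted_two_rate_separation(self):
        tree = balanced_tree(32)
        rates = np.array([0.1] * 50 + [3.0] * 50)
        msa, _ = simulate_alignment(
            SimAlignmentSpec(tree=tree, n_sites=100, site_rates=rates, seed=3)
        )
        grades = SiteRateModel(msa, tree).fit().grades
        low, high = grades[:50], grades[50:]
        assert set(low) <= {7, 8, 9}
        assert high.max() < low.min()  # planted classes never overlap
        assert np.isin(high, [1, 2, 3]).mean() >= 0.8


class TestRecovery:
    def test_rank_correlation_on_simulated_rates(self):
        tree = balanced_tree(32)
        msa, true_rates = simulate_alignment(
            SimAlignmentSpec(tree=tree, n_sites=200, site_rates=("gamma", 1.0),
                             seed=11)
        )
        result = SiteRateModel(msa, tree).fit()
        rho = spearmanr(true_rates, result.rates).statistic
        assert rho >= 0.8


class TestVariety:
    def test_unique_sorted_residues(self):
        msa = Msa(list("abcd"), ["L", "P", "V", "L"])
        assert column_residue_variety(msa, 0) == ["L", "P", "V"]

    def test_all_gap_column_empty(self):
        msa = Msa(list("abc"), ["-", "-", "-"])
        assert column_residue_variety(msa, 0) == []

    def test_out_of_range_column(self):
        msa = Msa(list("abc"), ["A", "A", "A"])
        with pytest.raises(IndexError):
            column_residue_variety(msa, 5)

    def test_planted_variety_recovered(self):
        # 66 rows drawn from a fixed 14-letter repertoire, as in published
        # residue-variety reports for a polymorphic position
        repertoire = sorted("ADEGKLMNPQSTVY")
        rng = np.random.default_rng(7)
        draws = list(repertoire) + list(rng.choice(repertoire, 66 - len(repertoire)))
        msa = Msa([f"s{i}" for i in range(66)], [d for d in draws])
        assert column_residue_variety(msa, 0) == repertoire


class TestResultObject:
    def test_profile_and_summary(self):
        tree = balanced_tree(8, 0.4)
        msa, _ = simulate_alignment(SimAlignmentSpec(tree=tree, n_sites=30, seed=2))
        res = SiteRateModel(msa, tree).fit()
        prof = res.profile
        assert list(prof.columns) == ["column", "rate", "grade", "label", "variety"]
        assert len(prof) == 30
        text = res.summary()
        assert "grade" in text and "gamma" in text
        assert res.grade_at(1) == prof.grade.iloc[0]
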