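"""Classifier-judge committees: training, seating, voting, experiments."""

import warnings

import numpy as np
import pytest

import crowdcourt as cc
from crowdcourt.errors import InvalidParameterError, SeatingInfeasibleError
from crowdcourt.seeding import derive_seeds


class ConstantClassifier:
    """Always predicts one label; stands in for a maximally biased judge."""

    def __init__(self, label=1, seed=0, **_):
        self.label = label

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.label, dtype=int)


def constant_pool(L, H, label=1):
    judge = lambda role: cc.Judge(  # noqa: E731
        role=role, training_set_id="const", model=ConstantClassifier(label), train_seed=0
    )
    return cc.JudgePool([judge("independent") for _ in range(L)],
                        [judge("dependent") for _ in range(H)], spec=None)


TREE = cc.ClassifierSpec(kind="decision_tree")
TREE_FIXED = cc.ClassifierSpec(kind="decision_tree", train_seed_policy="fixed")
SVM = cc.ClassifierSpec(kind="rbf_svm")


# --- parameter and spec contracts ------------------------------------------

def test_params_validate_and_warn():
    p = cc.EnsembleParams(L=10, H=10, p=0.5, n_L=8, n_H=9, N=5, M=20, alpha=0.4)
    assert p.shared_n_H + (p.n_H - p.shared_n_H) == p.n_H
    with pytest.raises(SeatingInfeasibleError):
        cc.EnsembleParams(L=3, H=3, p=0.5, n_L=8, n_H=8, N=7, M=20)
    with pytest.warns(UserWarning, match="redrawn"):
        cc.EnsembleParams(L=10, H=3, p=0.5, n_L=8, n_H=8, N=7, M=20)


@pytest.mark.parametrize("alpha,n_H,expected_shared", [(1.0, 9, 9), (0.0, 9, 0),
                                                       (0.5, 9, 5), (0.25, 10, 3)])
def test_shared_portion_rounding(alpha, n_H, expected_shared):
    p = cc.EnsembleParams(L=5, H=5, p=0.5, n_L=4, n_H=n_H, N=3, M=10, alpha=alpha)
    assert p.shared_n_H == expected_shared


def test_classifier_spec_rejects_unknown_kind():
    with pytest.raises(InvalidParameterError):
        cc.ClassifierSpec(kind="nearest_centroid")
    with pytest.raises(InvalidParameterError):
        cc.ClassifierSpec(kind="custom")  # custom requires a constructor


# --- training ---------------------------------------------------------------

def test_balanced_bootstrap_draws_even_classes(circles_split):
    params = cc.EnsembleParams(L=12, H=6, p=0.5, n_L=10, n_H=9, N=5, M=50)
    pool = cc.train_judge_pool(circles_split.train, TREE, params, seed=5)
    labels = circles_split.train.labels
    for judge in pool.independents:
        drawn = labels[judge.train_indices]
        assert (drawn == 0).sum() == 5 and (drawn == 1).sum() == 5
    for judge in pool.dependents:  # odd n: floor to class 0, ceil to class 1
        drawn = labels[judge.train_indices]
        assert (drawn == 0).sum() == 4 and (drawn == 1).sum() == 5
    ids = {j.training_set_id for j in pool.independents}
    assert len(ids) == params.L


def test_fully_shared_deterministic_dependents_are_clones(circles_split):
    params = cc.EnsembleParams(L=2, H=8, p=0.5, n_L=10, n_H=20, N=2, M=50, alpha=1.0)
    pool = cc.train_judge_pool(circles_split.train, TREE_FIXED, params, seed=9)
    X = circles_split.test.features[:200]
    preds = [j.predict_batch(X) for j in pool.dependents]
    for other in preds[1:]:
        assert (preds[0] == other).all()
    assert len({j.training_set_id for j in pool.dependents}) == 1


def test_unshared_dependents_match_independents_statistically(circles_split):
    """With alpha=0 and n_H=n_L both arms are the same i.i.d. bootstrap."""
    params = cc.EnsembleParams(L=50, H=50, p=0.5, n_L=30, n_H=30, N=10, M=50, alpha=0.0)
    pool = cc.train_judge_pool(circles_split.train, TREE, params, seed=21)
    X, y = circles_split.test.features, circles_split.test.labels
    acc_i = np.array([(j.predict_batch(X) == y).mean() for j in pool.independents])
    acc_d = np.array([(j.predict_batch(X) == y).mean() for j in pool.dependents])
    pooled_se = np.sqrt(acc_i.var() / 50 + acc_d.var() / 50)
    assert abs(acc_i.mean() - acc_d.mean()) < 4 * pooled_se + 1e-9


def test_training_requires_both_classes():
    one_class = cc.LabeledDataset(np.random.default_rng(0).normal(size=(30, 2)),
                                  np.zeros(30, dtype=int))
    params = cc.EnsembleParams(L=3, H=3, p=0.5, n_L=6, n_H=6, N=2, M=10)
    with pytest.raises(cc.DegenerateDataError):
        cc.train_judge_pool(one_class, TREE, params, seed=0)


def test_pool_training_is_reproducible(circles_split):
    params = cc.EnsembleParams(L=4, H=3, p=0.5, n_L=12, n_H=12, N=3, M=50)
    a = cc.train_judge_pool(circles_split.train, TREE, params, seed=33)
    b = cc.train_judge_pool(circles_split.train, TREE, params, seed=33)
    for ja, jb in zip(a.independents + a.dependents, b.independents + b.dependents):
        assert (ja.train_indices == jb.train_indices).all()
        assert ja.train_seed == jb.train_seed


# --- seating ----------------------------------------------------------------

def test_extreme_seat_probabilities():
    pool = cc.make_stub_pool(20, 20, 0.7, 0.6)
    all_ind = cc.convene_hearing(pool, p=1.0, N=10, seed=1)
    assert all(role == "independent" for role, _ in all_ind)
    all_dep = cc.convene_hearing(pool, p=0.0, N=10, seed=1)
    assert all(role == "dependent" for role, _ in all_dep)
    # distinct individuals within each roster
    idx = [i for _, i in all_dep]
    assert len(set(idx)) == len(idx)


def test_seat_counts_follow_binomial_mean():
    pool = cc.make_stub_pool(60, 60, 0.7, 0.6)
    rng = np.random.default_rng(7)
    N, p, reps = 40, 0.75, 10_000
    counts = [
        sum(1 for role, _ in cc.convene_hearing(pool, p, N, rng) if role == "independent")
        for _ in range(reps)
    ]
    se = np.sqrt(N * p * (1 - p) / reps)
    assert abs(np.mean(counts) - N * p) < 3 * se


def test_infeasible_seating_raises():
    pool = cc.make_stub_pool(5, 3, 0.7, 0.6)
    with pytest.raises(SeatingInfeasibleError):
        cc.convene_hearing(pool, p=0.0, N=4, seed=0)  # all seats dependent, H=3
    with pytest.raises(SeatingInfeasibleError):
        cc.convene_hearing(pool, p=0.5, N=9, seed=0)  # N > L + H


# --- hearings ---------------------------------------------------------------

def test_constant_judges_score_chance_on_balanced_labels(balanced_test):
    pool = constant_pool(5, 5, label=1)
    counts, _ = cc.run_hearings(pool, balanced_test, p=0.5, N=3, seed=4,
                                return_records=False)
    assert counts.accuracy == 0.5
    assert counts.FN == 0 and counts.TN == 0


def test_oracle_judges_are_always_right(balanced_test):
    pool = cc.make_stub_pool(5, 5, r_L=1.0, r_H=1.0)
    counts, _ = cc.run_hearings(pool, balanced_test, p=0.5, N=3, seed=4,
                                return_records=False)
    assert counts.accuracy == 1.0 and counts.FP == 0 and counts.FN == 0


def test_single_independent_seat_recovers_roster_average(circles_split):
    params = cc.EnsembleParams(L=30, H=5, p=1.0, n_L=25, n_H=25, N=1, M=600)
    pool = cc.train_judge_pool(circles_split.train, TREE, params, seed=13)
    test = circles_split.test.subset(np.arange(600))
    X, y = test.features, test.labels
    roster_mean = np.mean([(j.predict_batch(X) == y).mean() for j in pool.independents])
    counts, _ = cc.run_hearings(pool, test, p=1.0, N=1, seed=17, return_records=False)
    se = np.sqrt(roster_mean * (1 - roster_mean) / 600)
    assert abs(counts.accuracy - roster_mean) < 3 * se + 0.01


def test_confusion_counts_consistent_with_records(circles_split):
    params = cc.EnsembleParams(L=8, H=8, p=0.6, n_L=12, n_H=12, N=5, M=100)
    pool = cc.train_judge_pool(circles_split.train, TREE, params, seed=3)
    test = circles_split.test.subset(np.arange(100))
    counts, records = cc.run_hearings(pool, test, p=0.6, N=5, seed=8)
    assert counts.total == len(records) == 100
    assert counts.accuracy == sum(r.verdict == r.truth for r in records) / 100
    for r in records:
        assert len(r.votes) == 5
        if not r.tie_broken:
            assert r.verdict == int(2 * sum(r.votes) > 5)


def test_hearing_records_round_trip_as_json_lines(circles_split, tmp_path):
    import json

    params = cc.EnsembleParams(L=5, H=5, p=0.5, n_L=10, n_H=10, N=3, M=20)
    pool = cc.train_judge_pool(circles_split.train, TREE, params, seed=1)
    test = circles_split.test.subset(np.arange(20))
    _, records = cc.run_hearings(pool, test, p=0.5, N=3, seed=2)
    path = tmp_path / "audit.jsonl"
    cc.dump_hearing_records(records, path)
    lines = [json.loads(line) for line in path.read_text().splitlines()]
    assert lines == [r.to_dict() for r in records]


def test_hearing_records_are_seed_deterministic(circles_split):
    params = cc.EnsembleParams(L=8, H=8, p=0.6, n_L=12, n_H=12, N=4, M=60)
    pool = cc.train_judge_pool(circles_split.train, TREE, params, seed=3)
    test = circles_split.test.subset(np.arange(60))
    _, rec1 = cc.run_hearings(pool, test, p=0.6, N=4, seed=42)
    _, rec2 = cc.run_hearings(pool, test, p=0.6, N=4, seed=42)
    assert [r.to_dict() for r in rec1] == [r.to_dict() for r in rec2]


def test_dimensionality_mismatch_rejected(circles_split):
    params = cc.EnsembleParams(L=3, H=3, p=0.5, n_L=10, n_H=10, N=2, M=10)
    pool = cc.train_judge_pool(circles_split.train, TREE, params, seed=1)
    bad = cc.LabeledDataset(np.zeros((10, 5)), np.tile([0, 1], 5))
    with pytest.raises(cc.InvalidInputError):
        cc.run_hearings(pool, bad, p=0.5, N=2, seed=0)


# --- bridge to the population model ----------------------------------------

def test_stub_hearings_reproduce_population_oracle(balanced_test):
    """Bernoulli stub judges turn the hearing machinery into the cue model."""
    configs = [(0.6, 0.7, 0.55, 9), (0.9, 0.6, 0.5, 25), (0.3, 0.8, 0.75, 12)]
    for p, r_L, r_H, N in configs:
        pool = cc.make_stub_pool(40, 40, r_L, r_H)
        counts, _ = cc.run_hearings(pool, balanced_test, p, N, seed=101,
                                    return_records=False)
        exact = cc.exact_accuracy(cc.SyntheticParams(p, r_L, r_H), N)
        se = np.sqrt(exact * (1 - exact) / len(balanced_test))
        assert abs(counts.accuracy - exact) <= 4 * se


# --- group-size experiments --------------------------------------------------

def test_cloned_dependents_give_flat_curve(circles_split):
    """p=0 with deterministic same-data judges: every committee is one judge."""
    params = cc.EnsembleParams(L=6, H=12, p=0.0, n_L=15, n_H=15, N=11, M=200)
    pool = cc.train_judge_pool(circles_split.train, TREE_FIXED, params, seed=2)
    test = circles_split.test.subset(np.arange(200))
    curve = cc.accuracy_vs_group_size(pool, test, p=0.0, group_sizes=[1, 3, 7, 11],
                                      runs=3, seed=6)
    assert np.allclose(curve.values, curve.values[0])


def test_independent_committees_improve_with_size(circles_split):
    params = cc.EnsembleParams(L=40, H=5, p=1.0, n_L=150, n_H=150, N=25, M=400)
    pool = cc.train_judge_pool(circles_split.train, SVM, params, seed=19)
    test = circles_split.test.subset(np.arange(400))
    curve = cc.accuracy_vs_group_size(pool, test, p=1.0, group_sizes=[1, 5, 25],
                                      runs=15, seed=23)
    v = curve.values
    assert v[1] >= v[0] - 0.01 and v[2] >= v[1] - 0.01
    # Condorcet cross-check: the population oracle at the measured
    # single-judge competence assumes votes i.i.d. across judges, which
    # ignores shared per-sample difficulty — it upper-bounds the committee
    X, y = test.features, test.labels
    r_L = np.mean([(j.predict_batch(X) == y).mean() for j in pool.independents])
    predicted = cc.exact_accuracy(cc.SyntheticParams(1.0, float(r_L), 0.5), 25)
    assert v[0] - 0.02 <= v[2] <= predicted + 0.02


def test_committee_of_one_matches_single_judge_distribution(circles_split):
    params = cc.EnsembleParams(L=15, H=15, p=0.5, n_L=20, n_H=20, N=1, M=300)
    pool = cc.train_judge_pool(circles_split.train, TREE, params, seed=4)
    test = circles_split.test.subset(np.arange(300))
    curve = cc.accuracy_vs_group_size(pool, test, p=0.5, group_sizes=[1],
                                      runs=10, seed=5)
    assert 0.4 < curve.values[0] < 0.9


# --- decorrelation -----------------------------------------------------------

def test_full_sharing_reproduces_base_experiment(circles_split):
    params = cc.EnsembleParams(L=10, H=8, p=0.6, n_L=15, n_H=16, N=7, M=150)
    test = circles_split.test.subset(np.arange(150))
    curves = cc.decorrelation_experiment(
        circles_split.train, test, TREE, params, alphas=[1.0],
        group_sizes=[1, 3, 7], runs=4, seed=55,
    )
    pool_seed, hearing_seed = derive_seeds(55, 2)
    pool = cc.train_judge_pool(circles_split.train, TREE, params, seed=pool_seed)
    base = cc.accuracy_vs_group_size(pool, test, 0.6, [1, 3, 7], runs=4,
                                     seed=hearing_seed)
    assert curves[1.0].values.tolist() == base.values.tolist()


def test_dependent_agreement_decreases_with_alpha(circles_split):
    test_X = circles_split.test.features[:300]
    agreements = []
    for alpha in (1.0, 0.5, 0.0):
        params = cc.EnsembleParams(L=2, H=25, p=0.5, n_L=20, n_H=20, N=2, M=50,
                                   alpha=alpha)
        pool = cc.train_judge_pool(circles_split.train, TREE_FIXED, params, seed=77)
        agreements.append(cc.mean_pairwise_agreement(pool.dependents, test_X))
    assert agreements[0] >= agreements[1] - 0.02 >= agreements[2] - 0.04
    assert agreements[0] == 1.0  # deterministic clones agree everywhere


# --- phase maps --------------------------------------------------------------

def test_phase_map_shapes_and_degenerate_cell(circles_split):
    test = circles_split.test.subset(np.arange(120))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        diagram = cc.ensemble_phase_map(
            circles_split.train, test, TREE_FIXED,
            n_L_grid=[10, 30], p_grid=[0.0, 0.6], n_H=12, N_max=9,
            runs=2, seed=31, L=12, H=12, group_sizes=[1, 3, 9],
        )
    assert diagram.optimal_N.shape == (2, 2)
    assert ((diagram.optimal_N >= 1) & (diagram.optimal_N <= 9)).all()
    assert ((diagram.max_accuracy >= 0) & (diagram.max_accuracy <= 1)).all()
    # p=0 with cloned dependents: flat curve, smallest-N tie-break
    assert diagram.optimal_N[0, 0] == 1 and diagram.optimal_N[0, 1] == 1


def test_boundary_sweep_reduces_to_phase_map(circles_split):
    test = circles_split.test.subset(np.arange(120))
    sweep = cc.boundary_vs_nH(
        circles_split.train, test, TREE_FIXED,
        n_L_grid=[10, 30], p_grid=[0.3, 0.8], n_H_list=[12],
        N_max=9, runs=2, seed=13, L=12, H=12, group_sizes=[1, 3, 9],
    )
    assert len(sweep) == 1
    item = sweep[0]
    assert item.mask.shape == (2, 2)
    assert item.area == int(item.mask.sum())
    assert (item.mask == item.diagram.breakdown_mask()).all()
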