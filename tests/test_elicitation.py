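import numpy as np
import pytest

from afe.data import PoolMembershipError, SyntheticSpec, generate
from afe.divergences import DivergenceSpec, get_divergence
from afe.elicitation import (
    AFEConfig,
    ActiveFeatureElicitation,
    DivergenceSelection,
    ElicitationTrace,
    EmptyPoolError,
    IterationRecord,
    ModelPair,
    acquire,
    get_top_n,
    has_converged,
    mean_divergence,
    pairwise_divergence,
    run_afe,
    score_unobserved,
    update_batch_size,
)
from conftest import StubClassifier, make_split_dataset

ALL_DIVS = ["kl", "hellinger", "total_variation", "neyman_chi2"]


def _stub_pair(mu_map, mo_map, default_u=(0.5, 0.5), default_o=(0.5, 0.5)):
    return ModelPair(
        m_u=StubClassifier(mapping=mu_map, default=default_u),
        m_o=StubClassifier(mapping=mo_map, default=default_o),
    )


def test_pairwise_divergence_identity_and_direction():
    dataset, _ = make_split_dataset(n=6, n_fo=2)
    i, j = int(dataset.e_u[0]), int(dataset.e_o[0])
    same = _stub_pair({i: [0.6, 0.4]}, {j: [0.6, 0.4]})
    assert pairwise_divergence(i, j, dataset, same, DivergenceSpec("kl")) == 0.0

    pair = _stub_pair({i: [0.9, 0.1]}, {j: [0.1, 0.9]})
    tv = pairwise_divergence(i, j, dataset, pair, DivergenceSpec("total_variation"))
    assert tv == pytest.approx(0.8)
    # the printed argument order matters for asymmetric divergences
    skew = _stub_pair({i: [0.9, 0.1]}, {j: [0.6, 0.4]})
    fwd = pairwise_divergence(i, j, dataset, skew, DivergenceSpec("kl"))
    swapped = _stub_pair({i: [0.6, 0.4]}, {j: [0.9, 0.1]})
    bwd = pairwise_divergence(i, j, dataset, swapped, DivergenceSpec("kl"))
    assert fwd != pytest.approx(bwd)


def test_pairwise_divergence_pool_membership():
    dataset, _ = make_split_dataset(n=6, n_fo=2)
    pair = _stub_pair({}, {})
    with pytest.raises(PoolMembershipError):
        pairwise_divergence(int(dataset.e_o[0]), int(dataset.e_o[1]), dataset, pair, DivergenceSpec())
    with pytest.raises(PoolMembershipError):
        pairwise_divergence(int(dataset.e_u[0]), int(dataset.e_u[1]), dataset, pair, DivergenceSpec())


def test_mean_divergence_is_the_two_term_mean():
    dataset, _ = make_split_dataset(n=6, n_fo=2)
    i = int(dataset.e_u[0])
    # TV from [1,0] to [0.8,0.2] is 0.2; to [0.6,0.4] is 0.4 -> mean 0.3
    pair = _stub_pair({i: [1.0, 0.0]}, {0: [0.8, 0.2], 1: [0.6, 0.4]})
    md = mean_divergence(i, dataset, pair, DivergenceSpec("total_variation"))
    assert md == pytest.approx(0.3)


@pytest.mark.parametrize("name", ALL_DIVS)
def test_scores_match_naive_double_loop(name):
    dataset, _ = make_split_dataset(n=20, n_fo=10, seed=2)
    rng = np.random.default_rng(7)
    mu_map = {float(i): rng.dirichlet([2, 2]) for i in dataset.e_u}
    mo_map = {float(j): rng.dirichlet([2, 2]) for j in dataset.e_o}
    pair = _stub_pair(mu_map, mo_map)
    spec = DivergenceSpec(name)
    scores = score_unobserved(dataset, pair, spec)
    fn = get_divergence(name)
    for i in dataset.e_u:
        ref = np.mean([fn(mu_map[float(i)], mo_map[float(j)]) for j in dataset.e_o])
        assert scores[int(i)] == pytest.approx(ref, abs=1e-12)
        assert scores[int(i)] == pytest.approx(
            mean_divergence(int(i), dataset, pair, spec), abs=1e-12
        )


def test_score_unobserved_empty_pool_errors():
    dataset, _ = make_split_dataset(n=6, n_fo=2)
    pair = _stub_pair({}, {})
    empty_u = dataset.with_acquired(dataset.e_u, np.zeros((dataset.e_u.size, dataset.d_u)))
    with pytest.raises(EmptyPoolError):
        score_unobserved(empty_u, pair, DivergenceSpec())


def test_get_top_n_ordering_ties_and_exhaustion():
    assert get_top_n({0: 0.1, 1: 0.9, 2: 0.5}, 2) == [1, 2]
    assert get_top_n({0: 0.5, 1: 0.5}, 1) == [0]  # ties -> ascending index
    assert get_top_n({0: 0.1, 1: 0.9, 2: 0.5}, 10) == [1, 2, 0]
    with pytest.raises(EmptyPoolError):
        get_top_n({}, 1)


def test_ranking_is_scale_free():
    rng = np.random.default_rng(0)
    scores = {i: float(v) for i, v in enumerate(rng.random(20))}
    scaled = {i: 7.3 * v for i, v in scores.items()}
    assert get_top_n(scores, 6) == get_top_n(scaled, 6)


def test_acquire_accounting():
    dataset, oracle, _ = generate(SyntheticSpec(n_examples=60, seed=0))
    picks = [int(i) for i in dataset.e_u[:5]]
    updated = acquire(dataset, picks, oracle)
    assert updated.e_o.size == dataset.e_o.size + 5
    assert updated.e_u.size == dataset.e_u.size - 5
    assert acquire(dataset, [], oracle) is dataset


def test_update_batch_size_schedules():
    assert update_batch_size(5, 1.0, "fixed") == 5
    assert update_batch_size(5, 1.0, "literal") == pytest.approx(5 / 6)
    assert update_batch_size(5, 1.0, "literal") < 1  # terminates the loop


def _trace_with_lls(lls):
    trace = ElicitationTrace()
    for t, ll in enumerate(lls):
        trace.append(
            IterationRecord(t, (100 + t,), 10 + t, 50 - t, ll, 0.5, 0.5, 0.5)
        )
    return trace


def test_has_converged_on_ll_differences():
    assert not has_converged(_trace_with_lls([-0.69]), 0.01)
    assert not has_converged(_trace_with_lls([-0.69, -0.50]), 0.01)
    assert has_converged(_trace_with_lls([-0.500, -0.4995]), 0.01)


def test_has_converged_on_pool_exhaustion():
    trace = ElicitationTrace()
    trace.append(IterationRecord(0, (1,), 10, 0, -5.0, 0, 0, 0))
    assert has_converged(trace, 1e-9)


def test_trace_invariants_enforced():
    trace = _trace_with_lls([-0.7])
    with pytest.raises(ValueError):
        trace.append(IterationRecord(1, (100,), 11, 49, -0.6, 0, 0, 0))  # reselected
    with pytest.raises(ValueError):
        trace.append(IterationRecord(1, (200,), 10, 49, -0.6, 0, 0, 0))  # |E_o| flat


@pytest.mark.parametrize("name", ALL_DIVS)
def test_planted_cluster_is_selected_first(name):
    """Examples engineered to be maximally divergent from every fully
    observed posterior must form the entire first batch."""
    dataset, _ = make_split_dataset(n=25, n_fo=5, seed=3)
    planted = [7, 11, 12, 19, 23]
    mu_map = {float(i): [0.9, 0.1] for i in planted}
    pair = ModelPair(
        m_u=StubClassifier(mapping=mu_map, default=(0.12, 0.88)),
        m_o=StubClassifier(default=(0.1, 0.9)),
    )
    cfg = AFEConfig(divergence=DivergenceSpec(name))
    selected, scores = DivergenceSelection().select(dataset, pair, 5, cfg, 0)
    assert sorted(selected) == planted
    assert set(scores) == {int(i) for i in dataset.e_u}


def test_direction_fidelity_changes_selection():
    """Ranking under Div(p_i || q) differs from Div(q || p_i) on this
    3-class instance, so silently symmetrising (or swapping) the argument
    order would change which example is selected."""
    dataset, _ = make_split_dataset(n=8, n_fo=1, seed=0)
    a, b = [0.05, 0.9, 0.05], [0.02, 0.49, 0.49]
    q = [0.6, 0.2, 0.2]
    mu_map = {5.0: a, 6.0: b}
    pair = _stub_pair(mu_map, {0.0: q}, default_u=(1 / 3, 1 / 3, 1 / 3))
    fwd = score_unobserved(dataset, pair, DivergenceSpec("kl"))
    fn = get_divergence("kl")
    bwd = {
        int(i): fn(q, mu_map.get(float(i), (1 / 3, 1 / 3, 1 / 3)))
        for i in dataset.e_u
    }
    assert get_top_n(fwd, 1) == [5]  # a is farther from q reading forward
    assert get_top_n(bwd, 1) == [6]  # b is farther reading backward


# ---------------------------------------------------------------------------
# full loop with real classifiers


def test_run_afe_no_op_with_zero_iterations(fast_gb):
    dataset, oracle, test = generate(SyntheticSpec(n_examples=80, seed=1))
    cfg = AFEConfig(max_iterations=0, classifier=fast_gb, seed=1)
    model, trace = run_afe(dataset, oracle, cfg, test)
    assert len(trace) == 0
    assert model.n_features == dataset.d_o + dataset.d_u


def test_run_afe_accounting_identity(fast_gb):
    dataset, oracle, test = generate(SyntheticSpec(n_examples=120, seed=2))
    cfg = AFEConfig(batch_size=5, max_iterations=4, epsilon=None, classifier=fast_gb, seed=2)
    res = ActiveFeatureElicitation(dataset, oracle, config=cfg, test_set=test).fit()
    n0 = dataset.e_o.size
    for t, rec in enumerate(res.trace.records, start=1):
        assert rec.n_observed == n0 + 5 * t
        assert rec.n_observed + rec.n_unobserved == dataset.n


def test_run_afe_budget_caps_acquisitions(fast_gb):
    dataset, oracle, test = generate(SyntheticSpec(n_examples=120, seed=2))
    cfg = AFEConfig(
        batch_size=5, budget=7, max_iterations=10, epsilon=None, classifier=fast_gb, seed=2
    )
    res = ActiveFeatureElicitation(dataset, oracle, config=cfg, test_set=test).fit()
    assert res.n_acquired == 7  # 5 then the remaining 2


def test_run_afe_literal_schedule_stops_after_one_batch(fast_gb):
    dataset, oracle, test = generate(SyntheticSpec(n_examples=120, seed=2))
    cfg = AFEConfig(
        batch_size=5, schedule="literal", delta=1.0, max_iterations=10,
        epsilon=None, classifier=fast_gb, seed=2,
    )
    res = ActiveFeatureElicitation(dataset, oracle, config=cfg, test_set=test).fit()
    assert res.n_iterations == 1  # n drops to 5/6 < 1 after the first batch


def test_run_afe_deterministic_given_seed(fast_gb):
    dataset, oracle, test = generate(SyntheticSpec(n_examples=120, seed=4))
    cfg = AFEConfig(batch_size=5, max_iterations=3, epsilon=None, classifier=fast_gb, seed=4)
    r1 = ActiveFeatureElicitation(dataset, oracle, config=cfg, test_set=test).fit()
    r2 = ActiveFeatureElicitation(dataset, oracle, config=cfg, test_set=test).fit()
    for a, b in zip(r1.trace.records, r2.trace.records):
        assert a == b


def test_observed_model_is_frozen_across_iterations(fast_gb):
    dataset, oracle, test = generate(SyntheticSpec(n_examples=120, seed=5))
    probe = dataset.observed[:10]
    seen = []

    class Spy(DivergenceSelection):
        def select(self, ds, pair, n, config, iteration):
            seen.append(pair.m_u.predict_proba(probe).copy())
            return super().select(ds, pair, n, config, iteration)

    cfg = AFEConfig(batch_size=5, max_iterations=4, epsilon=None, classifier=fast_gb, seed=5)
    ActiveFeatureElicitation(dataset, oracle, config=cfg, test_set=test, strategy=Spy()).fit()
    assert len(seen) >= 2
    for later in seen[1:]:
        np.testing.assert_array_equal(seen[0], later)


def test_summary_renders(fast_gb):
    dataset, oracle, test = generate(SyntheticSpec(n_examples=80, seed=1))
    cfg = AFEConfig(batch_size=5, max_iterations=2, epsilon=None, classifier=fast_gb, seed=1)
    res = ActiveFeatureElicitation(dataset, oracle, config=cfg, test_set=test).fit()
    text = res.summary()
    assert "gradient_boosting" in text and "test recall" in text
    frame = res.trace.to_frame()
    assert list(frame.columns) == [
        "iteration", "selected_indices", "n_observed", "train_ll", "recall", "f1", "gmean",
    ]
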