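"""Comparison harness: AUC oracles, split arithmetic, structural and
reproducibility properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corrbin.compare import auc, default_model_configs, make_splits, run_comparison


def _brute_auc(y, s):
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


def test_auc_hand_case():
    assert auc(np.array([1, 0, 1, 0]), np.array([0.9, 0.8, 0.7, 0.1])) == pytest.approx(0.75)


def test_auc_perfect_and_constant():
    y = np.array([0, 0, 1, 1])
    assert auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
    assert auc(y, np.full(4, 0.3)) == 0.5


def test_auc_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(99)
    for _ in range(200):
        n = rng.integers(10, 500)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.random(n), 2)  # coarse scores force ties
        assert auc(y, s) == pytest.approx(_brute_auc(y, s), abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 1), st.integers(0, 64)),
        min_size=4,
        max_size=60,
    )
)
def test_auc_invariances(pairs):
    """AUC is invariant under strictly increasing score transforms and flips
    to 1 - AUC when the class labels are inverted.  Scores live on a coarse
    exact grid so the float transform stays injective."""
    y = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs]) / 64.0
    if y.min() == y.max():
        y[0] = 1 - y[0]
    a = auc(y, s)
    assert auc(y, np.exp(3.0 * s)) == pytest.approx(a, abs=1e-12)
    assert auc(1 - y, s) == pytest.approx(1.0 - a, abs=1e-12)


def test_auc_agrees_with_sklearn_reference():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(17)
    for _ in range(20):
        n = int(rng.integers(20, 300))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = rng.random(n)
        assert auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


@pytest.mark.parametrize("missing", [0, 1])
def test_auc_requires_both_classes(missing):
    y = np.full(10, missing)
    with pytest.raises(ValueError, match="positive" if missing == 0 else "negative"):
        auc(y, np.random.default_rng(0).random(10))


def test_make_splits_partitions_rows():
    plan = make_splits(8, seed=1)
    assert sorted(len(f) for f in plan.folds) == [2, 2, 2, 2]
    assert sorted(np.concatenate(plan.folds).tolist()) == list(range(8))


def test_make_splits_fold_sizes_at_survey_scale():
    plan = make_splits(4484, seed=0)
    assert [len(f) for f in plan.folds] == [1121, 1121, 1121, 1121]


def test_make_splits_deterministic():
    p1, p2 = make_splits(100, seed=7), make_splits(100, seed=7)
    for a, b in zip(p1.folds, p2.folds):
        assert np.array_equal(a, b)


def test_report_has_32_cells_and_is_reproducible(tiny_cohort):
    cfgs = default_model_configs(tiny_cohort, fast=True)
    cfgs["hier-bayes"].update(iters=600, burn_in=200, thin=2)
    r1 = run_comparison(tiny_cohort, configs=cfgs, seed=4, fit_full=False)
    assert len(r1.auc_table) == 4 * 4 * 2
    assert not r1.auc_table["failed"].any()
    assert r1.auc_table["auc"].between(0, 1).all()
    r2 = run_comparison(tiny_cohort, configs=cfgs, seed=4, fit_full=False)
    np.testing.assert_allclose(
        r1.auc_table["auc"].to_numpy(), r2.auc_table["auc"].to_numpy(), atol=0
    )


def test_training_auc_exceeds_validation_on_average(small_cohort):
    # optimism of in-sample scoring, averaged over split seeds
    diffs = []
    for seed in range(10):
        rep = run_comparison(
            small_cohort,
            configs=default_model_configs(small_cohort),
            seed=seed,
            models=("joint-glm",),
            fit_full=False,
        )
        t = rep.auc_table
        diffs.append(
            t[t.partition == "training"].auc.mean()
            - t[t.partition == "validation"].auc.mean()
        )
    assert np.mean(diffs) > 0


def test_unknown_model_listed(tiny_cohort):
    with pytest.raises(ValueError, match="hier-freq"):
        run_comparison(tiny_cohort, models=("nope",))
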