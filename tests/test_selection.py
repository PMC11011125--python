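"""Per-gene rank statistics, BH adjustment, and stability selection."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import gvhd_gmb as g
from gvhd_gmb.exceptions import DomainError
from conftest import pair_enumeration_auc


# ---------------------------------------------------------------------------
# per-gene AUC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "values, labels, expected",
    [
        ([5, 6, 1, 2], [1, 1, 0, 0], 1.0),       # perfect separation
        ([3, 3, 3, 3], [1, 1, 0, 0], 0.5),       # all ties
        ([3, 5, 1, 4], [1, 1, 0, 0], 0.75),      # 3 of 4 pairs concordant
        ([1, 2, 5, 6], [1, 1, 0, 0], 1.0),       # folded: fully down-regulated
    ],
)
def test_per_gene_auc_examples(values, labels, expected):
    assert g.per_gene_auc(values, labels) == pytest.approx(expected)


@given(
    st.lists(st.integers(0, 5), min_size=2, max_size=12),
    st.data(),
)
def test_per_gene_auc_matches_pair_enumeration(values, data):
    n = len(values)
    labels = data.draw(
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda y: 0 < sum(y) < n
        )
    )
    unfolded = g.per_gene_auc(values, labels, fold=False)
    oracle = pair_enumeration_auc(values, labels)
    assert unfolded == pytest.approx(oracle, abs=1e-12)
    assert g.per_gene_auc(values, labels) == pytest.approx(
        max(oracle, 1 - oracle), abs=1e-12
    )


def test_per_gene_auc_requires_both_classes():
    with pytest.raises(DomainError):
        g.per_gene_auc([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def test_rank_sum_exact_small_sample():
    """Cases strictly above controls with n=3+3: the exact two-sided tail is
    2/20 over the 20 equally likely label assignments."""
    values = [10, 12, 14, 1, 2, 3]
    labels = [1, 1, 1, 0, 0, 0]
    # independent enumeration oracle
    stat = pair_enumeration_auc(values, labels)
    count_as_extreme = 0
    for combo in itertools.combinations(range(6), 3):
        y = [1 if i in combo else 0 for i in range(6)]
        a = pair_enumeration_auc(values, y)
        if abs(a - 0.5) >= abs(stat - 0.5) - 1e-12:
            count_as_extreme += 1
    exact_p = count_as_extreme / 20
    assert g.rank_sum_pvalue(values, labels) == pytest.approx(exact_p)
    assert exact_p == pytest.approx(0.1)


def test_rank_sum_constant_gene_has_p_one():
    assert g.rank_sum_pvalue([7.0] * 8, [1, 1, 1, 1, 0, 0, 0, 0]) == 1.0


def test_rank_sum_null_uniformity_under_permutation():
    rng = np.random.default_rng(3)
    values = rng.normal(size=60)
    y = np.array([1] * 30 + [0] * 30)
    pvals = []
    for _ in range(400):
        rng.shuffle(y)
        pvals.append(g.rank_sum_pvalue(values, y))
    # continuous null: p-values roughly uniform
    assert abs(np.mean(pvals) - 0.5) < 0.06
    assert np.percentile(pvals, 10) < 0.2


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_worked_examples():
    assert g.adjust_pvalues([0.2]) == pytest.approx([0.2])
    np.testing.assert_allclose(
        g.adjust_pvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(g.adjust_pvalues([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    with pytest.raises(DomainError):
        g.adjust_pvalues([0.0, 0.5])


@given(st.lists(st.floats(1e-10, 1.0, exclude_min=False), min_size=1, max_size=60))
def test_bh_matches_statsmodels_and_is_monotone(pvals):
    ours = g.adjust_pvalues(pvals)
    theirs = multipletests(pvals, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, theirs, atol=1e-12)
    assert (ours >= np.asarray(pvals) - 1e-15).all()


# ---------------------------------------------------------------------------
# stability frequencies
# ---------------------------------------------------------------------------

def test_stability_single_full_replicate_equals_selection_flag():
    rng = np.random.default_rng(4)
    x = rng.gamma(2, 10, size=(50, 40))
    y = np.array([1] * 20 + [0] * 20)
    x[:5, y == 1] *= 8  # strong planted signal in 5 genes
    cfg = g.SelectionConfig(n_resamples=1, subsample_fraction=1.0, seed=0)
    freq = g.stability_frequencies(x, y, cfg)
    assert set(np.unique(freq)) <= {0.0, 1.0}
    from gvhd_gmb.selection import matrix_rank_stats

    _, p = matrix_rank_stats(x, y)
    flag = (g.adjust_pvalues(p) <= cfg.alpha).astype(float)
    np.testing.assert_array_equal(freq, flag)


def test_stability_planted_vs_null_genes(planted_cohort):
    matrix, labels, truth = planted_cohort
    y = labels.endpoint("agvhd").to_numpy()
    cfg = g.SelectionConfig(n_resamples=50, seed=5)
    freq = g.stability_frequencies(matrix, y, cfg)
    genes = matrix.gene_ids
    planted = np.array([gid in truth.informative_genes for gid in genes])
    assert freq[planted].min() == 1.0          # log2FC=2 at n=160: always kept
    assert freq[~planted].mean() <= cfg.alpha  # null genes rarely pass
    # granularity: exact multiples of 1/B
    assert np.allclose(freq * cfg.n_resamples, np.round(freq * cfg.n_resamples))


# ---------------------------------------------------------------------------
# select_genes
# ---------------------------------------------------------------------------

def test_select_recovers_planted_genes(planted_cohort):
    matrix, labels, truth = planted_cohort
    y = labels.endpoint("agvhd").to_numpy()
    report = g.select_genes(matrix, y, g.SelectionConfig(seed=3))
    selected = set(report.selected_genes)
    recovered = len(selected & truth.informative_genes) / len(truth.informative_genes)
    assert recovered >= 0.8
    # report invariant: selected implies significant AND stable
    tab = report.table
    sel = tab[tab["selected"]]
    assert (sel["p_adjusted"] <= report.config.alpha).all()
    assert (sel["stability_frequency"] >= report.config.stability_threshold).all()


def test_select_is_invariant_to_monotone_transforms(small_cohort, fast_selection):
    matrix, labels, _ = small_cohort
    y = labels.endpoint("agvhd").to_numpy()
    r1 = g.select_genes(matrix, y, fast_selection)
    transformed = g.ExpressionMatrix(np.sqrt(matrix.data * 3.0) + 1.0)
    r2 = g.select_genes(transformed, y, fast_selection)
    assert r1.selected_genes == r2.selected_genes
    np.testing.assert_allclose(r1.table["p_value"], r2.table["p_value"])
    np.testing.assert_allclose(r1.table["cv_auc"], r2.table["cv_auc"])


def test_select_null_cohort_selects_almost_nothing(fast_selection):
    fractions = []
    for seed in (21, 22, 23):
        cfg = g.SyntheticConfig(n_samples=120, n_genes=400, n_informative=0, seed=seed)
        matrix, labels, _ = g.generate_cohort(cfg)
        rep = g.select_genes(
            matrix, labels.endpoint("agvhd").to_numpy(),
            g.SelectionConfig(n_resamples=25, seed=seed),
        )
        fractions.append(len(rep.selected_genes) / matrix.n_genes)
    assert np.mean(fractions) <= 0.01


def test_max_genes_truncates_deterministically(planted_cohort):
    matrix, labels, _ = planted_cohort
    y = labels.endpoint("agvhd").to_numpy()
    cfg = g.SelectionConfig(seed=3, max_genes=10)
    r1 = g.select_genes(matrix, y, cfg)
    r2 = g.select_genes(matrix, y, cfg)
    assert len(r1.selected_genes) <= 10
    assert r1.selected_genes == r2.selected_genes
    aucs = r1.table.loc[r1.selected_genes, "cv_auc"].to_numpy()
    assert (np.diff(aucs) <= 1e-12).all()  # ordered by cv_auc descending


def test_empty_selection_is_warning_not_error():
    rng = np.random.default_rng(0)
    x = rng.gamma(2, 10, size=(30, 24))
    y = np.array([1] * 12 + [0] * 12)
    rep = g.select_genes(
        g.ExpressionMatrix(_frame(x)), y, g.SelectionConfig(n_resamples=10, seed=1)
    )
    assert rep.selected_genes == []
    assert rep.warning is not None


def _frame(x):
    import pandas as pd

    return pd.DataFrame(
        x,
        index=[f"G{i}" for i in range(x.shape[0])],
        columns=[f"S{j}" for j in range(x.shape[1])],
    )
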