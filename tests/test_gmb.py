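"""Geometric-mean naive Bayes: fitting, scoring, and cross-validation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import gvhd_gmb as g
from gvhd_gmb.exceptions import ConfigurationError, FittingError, ScoringError
from gvhd_gmb.gmb import log_fpkm


def _matrix(x, genes=None, samples=None):
    genes = genes or [f"G{i}" for i in range(x.shape[0])]
    samples = samples or [f"S{j}" for j in range(x.shape[1])]
    return g.ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples))


def _toy_model(mu0=0.0, mu1=2.0, var=1.0, priors=(0.5, 0.5), n_genes=1):
    return g.GMBModel(
        genes=[f"G{i}" for i in range(n_genes)],
        means=np.array([[mu0] * n_genes, [mu1] * n_genes]),
        variances=np.array([[var] * n_genes, [var] * n_genes]),
        class_priors=np.array(priors),
        variance_floor=1e-3,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_moments_match_manual_computation():
    x = np.array([[1.0, 3.0, 7.0, 15.0, 0.0, 1.0]])  # log2(x+1): 1,2,3,4,0,1
    y = np.array([1, 1, 1, 1, 0, 0])
    model = g.fit_gmb(_matrix(x), y)
    assert model.means[1, 0] == pytest.approx(2.5)   # mean of 1,2,3,4
    assert model.means[0, 0] == pytest.approx(0.5)   # mean of 0,1
    assert model.variances[1, 0] == pytest.approx(np.var([1, 2, 3, 4], ddof=1))
    assert model.class_priors[1] == pytest.approx(4 / 6)


def test_fit_dual_implementation_oracle(small_cohort):
    """Fitted moments equal an independent re-computation of the same
    formulas with python's statistics module."""
    import statistics

    matrix, labels, _ = small_cohort
    y = labels.endpoint("agvhd").to_numpy()
    sub = matrix.subset_genes(matrix.gene_ids[:5])
    model = g.fit_gmb(sub, y)
    logx = np.log2(sub.values + 1.0)
    for gi in range(5):
        for c in (0, 1):
            vals = [float(v) for v in logx[gi, y == c]]
            assert model.means[c, gi] == pytest.approx(statistics.fmean(vals))
            assert model.variances[c, gi] == pytest.approx(
                max(statistics.variance(vals), model.variance_floor)
            )


def test_constant_gene_hits_variance_floor():
    x = np.array([[2.0, 2.0, 2.0, 2.0]])
    y = np.array([1, 1, 0, 0])
    model = g.fit_gmb(_matrix(x), y, variance_floor=1e-3)
    assert (model.variances == 1e-3).all()


def test_fit_requires_two_samples_per_class():
    x = np.ones((3, 3))
    with pytest.raises(FittingError):
        g.fit_gmb(_matrix(x), np.array([1, 0, 0]))


def test_equal_priors_option():
    x = np.random.default_rng(0).gamma(2, 5, size=(4, 10))
    y = np.array([1] * 7 + [0] * 3)
    model = g.fit_gmb(_matrix(x), y, priors="equal")
    np.testing.assert_array_equal(model.class_priors, [0.5, 0.5])


def test_model_json_round_trip(tmp_path, small_cohort):
    matrix, labels, _ = small_cohort
    y = labels.endpoint("agvhd").to_numpy()
    model = g.fit_gmb(matrix.subset_genes(matrix.gene_ids[:8]), y)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = g.GMBModel.from_json(path)
    assert back.genes == model.genes
    np.testing.assert_allclose(back.means, model.means)
    np.testing.assert_allclose(back.variances, model.variances)
    np.testing.assert_allclose(back.class_priors, model.class_priors)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def test_single_gene_closed_form_score():
    """One gene, equal priors, class 1 ~ N(2,1), class 0 ~ N(0,1), observed
    transformed value 2: the posterior equals the normal-density ratio,
    ~0.881."""
    model = _toy_model()
    fpkm = 2.0**2 - 1.0  # log2(FPKM+1) == 2
    score = g.gmb_score(model, np.array([fpkm]))
    f1 = norm.pdf(2.0, 2.0, 1.0)
    f0 = norm.pdf(2.0, 0.0, 1.0)
    direct = f1 / (f1 + f0)
    assert score == pytest.approx(direct, abs=1e-12)
    assert score == pytest.approx(0.881, abs=1e-3)


def test_symmetric_sample_scores_half():
    model = _toy_model()
    fpkm = 2.0**1 - 1.0  # transformed value 1, equidistant from 0 and 2
    assert g.gmb_score(model, np.array([fpkm])) == pytest.approx(0.5)


def test_duplication_invariance_distinguishes_gmb_from_product_nb():
    rng = np.random.default_rng(1)
    x = rng.gamma(2, 8, size=(6, 20))
    y = np.array([1] * 11 + [0] * 9)
    model = g.fit_gmb(_matrix(x), y)
    sample = x[:, 0]

    doubled = g.GMBModel(
        genes=model.genes + [s + "_dup" for s in model.genes],
        means=np.tile(model.means, 2),
        variances=np.tile(model.variances, 2),
        class_priors=model.class_priors,
        variance_floor=model.variance_floor,
    )
    dup_sample = np.concatenate([sample, sample])

    gmb_once = g.gmb_score(model, sample)
    gmb_twice = g.gmb_score(doubled, dup_sample)
    assert gmb_twice == pytest.approx(gmb_once, abs=1e-12)

    nb_once = g.gmb_score(model, sample, combine="product")
    nb_twice = g.gmb_score(doubled, dup_sample, combine="product")
    assert nb_twice != pytest.approx(nb_once, abs=1e-9)
    # the product score is strictly more extreme after duplication
    assert abs(nb_twice - 0.5) > abs(nb_once - 0.5)


def test_no_underflow_at_thousand_genes():
    """With 1000 genes each contributing a density around 1e-300, the
    geometric-mean score stays finite and strictly inside (0, 1), while the
    plain product saturates."""
    n = 1000
    up, down = 502, 498  # genes favouring class 1 vs class 0, nearly balanced
    means = np.zeros((2, n))
    means[1, :up] = 2.0   # class-1 mean higher for the first group
    means[0, up:] = 2.0   # class-0 mean higher for the second group
    model = g.GMBModel(
        genes=[f"G{i}" for i in range(n)],
        means=means,
        variances=np.ones((2, n)),
        class_priors=np.array([0.5, 0.5]),
    )
    fpkm = np.full(n, 2.0**38.0 - 1.0)  # transformed value 38 for every gene
    assert norm.pdf(38.0, 2.0, 1.0) < 1e-280  # every per-gene density underflows
    score = g.gmb_score(model, fpkm)
    assert np.isfinite(score)
    assert 0.0 < score < 1.0
    assert score != pytest.approx(0.5)  # the slight imbalance is resolved
    product = g.gmb_score(model, fpkm, combine="product")
    assert product in (0.0, 1.0)  # the non-geometric combination saturates


def test_monotone_coupling_toward_case_mean():
    model = _toy_model(mu0=0.0, mu1=3.0, var=1.0, n_genes=3)
    base = np.array([1.0, 5.0, 2.0])
    grid = np.linspace(0.0, 3.0, 25)  # transformed value of gene 0 rises to mu1
    scores = []
    for v in grid:
        sample = base.copy()
        sample[0] = 2.0**v - 1.0
        scores.append(g.gmb_score(model, sample))
    assert (np.diff(scores) >= -1e-12).all()


def test_missing_gene_value_raises():
    model = _toy_model(n_genes=2)
    with pytest.raises(ScoringError):
        g.gmb_score(model, np.array([1.0]))
    with pytest.raises(ScoringError, match="G1"):
        g.gmb_score(model, np.array([1.0, np.nan]))


def test_parameter_recovery_rate(small_cohort):
    """Fitted class means approach the generating means as n grows."""
    rng = np.random.default_rng(8)
    true_mu = np.array([[5.0, 7.0], [6.0, 8.0]])  # class x gene, transformed
    errs = []
    for n in (50, 200, 800):
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        z = np.empty((2, n))
        for gi in range(2):
            z[gi] = np.where(y == 1, true_mu[1, gi], true_mu[0, gi]) + rng.normal(
                0, 1, size=n
            )
        z = np.maximum(z, 0.0)  # FPKM cannot be negative
        model = g.fit_gmb(_matrix(2.0**z - 1.0), y)
        errs.append(np.abs(model.means - true_mu[[0, 1]][:, :]).mean())
    assert errs[2] < errs[0]
    assert errs[2] < 2.0 / np.sqrt(800)


# ---------------------------------------------------------------------------
# cross-validation and external application
# ---------------------------------------------------------------------------

def test_cv_partition_and_determinism(small_cohort, fast_selection):
    matrix, labels, _ = small_cohort
    y = labels.endpoint("agvhd").to_numpy()
    ss1 = g.cross_validated_scores(matrix, y, fast_selection, k=6, seed=2)
    ss2 = g.cross_validated_scores(matrix, y, fast_selection, k=6, seed=2)
    assert ss1.data.equals(ss2.data)
    assert sorted(ss1.data.index) == sorted(matrix.sample_ids)
    assert set(ss1.data["fold"]) == set(range(1, 7))
    np.testing.assert_array_equal(ss1.labels, y)


def test_cv_k_exceeding_class_count_is_config_error(small_cohort, fast_selection):
    matrix, labels, _ = small_cohort
    y = labels.endpoint("agvhd").to_numpy()
    with pytest.raises(ConfigurationError, match="k"):
        g.cross_validated_scores(matrix, y, fast_selection, k=len(y))


def test_apply_model_prototype_and_empty(small_cohort):
    matrix, labels, _ = small_cohort
    y = labels.endpoint("agvhd").to_numpy()
    genes = matrix.gene_ids[:10]
    model = g.fit_gmb(matrix.subset_genes(genes), y, priors="equal")
    # prototype sample at the class-1 means scores above 1/2
    proto = 2.0 ** model.means[1] - 1.0
    assert g.gmb_score(model, proto) > 0.5

    empty = g.ExpressionMatrix(
        pd.DataFrame(np.empty((10, 0)), index=genes, columns=[])
    )
    out = g.apply_model(model, empty)
    assert len(out.data) == 0

    missing = g.ExpressionMatrix(
        pd.DataFrame(np.ones((2, 2)), index=genes[:2], columns=["V1", "V2"])
    )
    with pytest.raises(ScoringError, match=genes[3]):
        g.apply_model(model, missing)


def test_paper_mode_leaks_and_nested_does_not(planted_cohort):
    """On a planted cohort both modes separate well; the study-style shared
    selection can only raise (never lower) apparent training performance."""
    matrix, labels, _ = planted_cohort
    y = labels.endpoint("agvhd").to_numpy()
    cfg = g.SelectionConfig(n_resamples=25, seed=1)
    sub = matrix.subset_samples(matrix.sample_ids[:100])
    ysub = y[:100]
    nested = g.cross_validated_scores(sub, ysub, cfg, k=6, mode="nested", seed=3)
    paper = g.cross_validated_scores(sub, ysub, cfg, k=6, mode="paper", seed=3)
    auc_nested = g.roc_curve(nested.scores, nested.labels).auc
    auc_paper = g.roc_curve(paper.scores, paper.labels).auc
    assert auc_paper >= auc_nested - 0.05
    assert auc_paper > 0.8
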