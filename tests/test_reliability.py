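"""ICC / SEM / MDC estimation against brute-force and library oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcfat.phantom import VarianceComponents, simulate_ratings
from rcfat.reliability import (
    DegenerateVarianceError,
    IncompleteDesignError,
    ReliabilityModel,
    SampleSizeSpec,
    classify_icc,
    concurrent_validity,
    icc,
    mdc,
    sample_size_icc,
    sem,
)

from oracles import brute_icc, reject_low_reliability


def components_for_icc(rho, mu=12.0, sigma_subject=3.0, sigma_rater=0.2):
    """Variance components hitting a target population ICC.

    Between-subject SD ~3 %fat and a small rater bias reflect the reliability
    setting this package targets (trained raters, ICCs near 1)."""
    err_var = sigma_subject**2 * (1 - rho) / rho
    sigma_error = math.sqrt(err_var - sigma_rater**2)
    return VarianceComponents(mu, sigma_subject, sigma_rater, sigma_error)


def test_identical_raters_give_icc_one():
    rng = np.random.default_rng(0)
    col = rng.normal(12, 3, 10)
    res = icc(np.column_stack([col, col]))
    assert res.icc == pytest.approx(1.0)
    assert res.ci_low == res.ci_high == 1.0
    assert res.sem == pytest.approx(0.0)
    assert res.mdc == pytest.approx(0.0)


@pytest.mark.parametrize(
    "model,absolute",
    [("two_way_random_absolute_single", True), ("two_way_mixed_consistency_single", False)],
)
def test_icc_matches_brute_force_oracle(model, absolute):
    """100 random small designs, both forms, agreement to 1e-10."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(2, 9))
        k = int(rng.integers(2, 4))
        data = rng.normal(10, 2, (n, k)) + rng.normal(0, 2, (n, 1))
        expected = brute_icc(data.tolist(), absolute_agreement=absolute)
        got = ReliabilityModel(data).fit(model=model).icc
        assert got == pytest.approx(expected, abs=1e-10)


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    data = rng.normal(10, 2, (12, 3)) + rng.normal(0, 2, (12, 1))
    df = pd.DataFrame(
        {
            "subject": np.repeat(range(12), 3),
            "rater": list(range(3)) * 12,
            "score": data.ravel(),
        }
    )
    tbl = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    ci_col = tbl.columns[-1]
    # rows: single-measure one-way, absolute-agreement, consistency, then k-forms
    row_abs, row_con = tbl.iloc[1], tbl.iloc[2]
    res_a = ReliabilityModel(data).fit()
    res_c = ReliabilityModel(data).fit(model="two_way_mixed_consistency_single")
    assert res_a.icc == pytest.approx(row_abs["ICC"], abs=1e-9)
    assert res_c.icc == pytest.approx(row_con["ICC"], abs=1e-9)
    lo, hi = row_abs[ci_col]
    assert res_a.ci_low == pytest.approx(lo, abs=5e-3)
    assert res_a.ci_high == pytest.approx(hi, abs=5e-3)


def test_icc_ci_brackets_estimate():
    rng = np.random.default_rng(9)
    for _ in range(20):
        data = rng.normal(0, 1, (6, 2)) + rng.normal(0, 1.5, (6, 1))
        res = ReliabilityModel(data).fit()
        assert res.ci_low <= res.icc <= res.ci_high


def test_parameter_recovery_single_seed():
    for rho in (0.5, 0.8, 0.95):
        vc = components_for_icc(rho)
        res = icc(simulate_ratings(vc, 2000, 2, seed=1))
        assert res.icc == pytest.approx(vc.true_icc, abs=0.02)


def test_parameter_recovery_spec_components():
    # sigma_rater = 0.5 with k = 2: the realized rater-pair draw shifts the
    # large-n limit by O(sigma_rater^2), so the band is wider here
    vc = VarianceComponents(12.0, 3.0, 0.5, 0.5)
    res = icc(simulate_ratings(vc, 2000, 2, seed=7))
    assert res.icc == pytest.approx(vc.true_icc, abs=0.03)


@pytest.mark.parametrize(
    "value,band",
    [(0.0, "poor"), (-0.5, "poor"), (0.3, "fair"), (0.5, "moderate"),
     (0.78, "good"), (0.93, "very_good"), (1.0, "very_good"),
     (0.205, "fair"), (0.2049, "poor")],
)
def test_classify_icc_bands(value, band):
    assert classify_icc(value) == band


def test_classify_icc_monotone():
    grid = np.linspace(-0.9, 1.0, 200)
    order = ["poor", "fair", "moderate", "good", "very_good"]
    ranks = [order.index(classify_icc(v)) for v in grid]
    assert ranks == sorted(ranks)


def test_sem_closed_forms():
    # data rescaled so the pooled SD is exactly 4; ICC = 0.75 -> SEM = 2
    raw = np.array([[1.0, 7.0], [3.0, 5.0]])
    data = 4.0 + (raw - raw.mean()) * (4.0 / raw.std(ddof=1))
    assert data.std(ddof=1) == pytest.approx(4.0, abs=1e-12)
    assert sem(data, 0.75) == pytest.approx(2.0)
    assert sem(data, 1.0) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        sem(data, 1.5)


def test_sem_anova_error_recovers_error_sd():
    vc = VarianceComponents(12.0, 3.0, 0.0, 1.0)
    df = simulate_ratings(vc, 1000, 2, seed=4)
    m = ReliabilityModel.from_dataframe(df)
    assert sem(m, 0.0, method="anova_error") == pytest.approx(1.0, abs=0.05)


# SEM -> MDC cells where the printed values round self-consistently
TABLE_CELLS = [
    (1.74, 2.46), (0.55, 0.78), (0.61, 0.86), (0.96, 1.36),
    (1.54, 2.18), (2.95, 4.17), (1.10, 1.56), (0.75, 1.06),
]


@pytest.mark.parametrize("sem_val,expected_mdc", TABLE_CELLS)
def test_mdc_reproduces_reported_cells(sem_val, expected_mdc):
    assert round(mdc(sem_val), 2) == pytest.approx(expected_mdc)


def test_mdc_volume_cell_one_decimal():
    assert round(mdc(2.9), 1) == pytest.approx(4.1)


def test_mdc_edge_cases():
    assert mdc(0.0) == 0.0
    with pytest.raises(ValueError):
        mdc(-1.0)
    # conventional MDC95 via the z argument
    assert mdc(1.0, z=1.96) == pytest.approx(1.96 * math.sqrt(2))


@settings(max_examples=50, deadline=None)
@given(s=st.floats(1e-6, 1e6))
def test_mdc_sem_ratio_is_sqrt2(s):
    assert mdc(s) / s == pytest.approx(math.sqrt(2), rel=1e-12)


def test_concurrent_validity_identity_and_offset():
    rng = np.random.default_rng(5)
    a = rng.normal(12, 3, 10)
    assert concurrent_validity(a, a.copy()).icc == pytest.approx(1.0)
    # fixed offset of one SD: absolute agreement strictly below consistency
    b = a + a.std(ddof=1)
    res_abs = concurrent_validity(a, b)
    res_con = concurrent_validity(a, b, model="two_way_mixed_consistency_single")
    assert res_abs.icc < res_con.icc
    assert res_con.icc == pytest.approx(1.0)
    # brute-force oracle agreement on the same toy table
    table = np.column_stack([a, b]).tolist()
    assert res_abs.icc == pytest.approx(brute_icc(table, True), abs=1e-10)


def test_concurrent_validity_independent_noise_near_zero():
    rng = np.random.default_rng(6)
    a = rng.normal(12, 3, 50)
    b = rng.normal(12, 3, 50)
    assert abs(concurrent_validity(a, b).icc) < 0.3


def test_concurrent_validity_unpaired_raises():
    with pytest.raises(IncompleteDesignError):
        concurrent_validity(np.arange(5.0), np.arange(6.0))
    s1 = pd.Series([1.0, 2.0], index=["a", "b"])
    s2 = pd.Series([1.0, 2.0], index=["a", "c"])
    with pytest.raises(IncompleteDesignError):
        concurrent_validity(s1, s2)


def test_incomplete_design_rejected():
    df = pd.DataFrame(
        {"subject_id": ["a", "a", "b"], "rater_id": ["r1", "r2", "r1"],
         "value": [1.0, 2.0, 3.0]}
    )
    with pytest.raises(IncompleteDesignError):
        ReliabilityModel.from_dataframe(df)


def test_zero_variance_degenerate():
    with pytest.raises(DegenerateVarianceError):
        ReliabilityModel(np.full((5, 2), 7.0)).fit()


def test_sample_size_matches_reported_design():
    """rho0=0.75, rho1=0.95, one-sided alpha=0.05, power=0.80, k=2."""
    n = sample_size_icc(SampleSizeSpec(rho0=0.75, rho1=0.95))
    assert n in (10, 11)


def test_sample_size_monte_carlo_power():
    """Simulated power at the returned n reaches the requested 80%."""
    spec = SampleSizeSpec(rho0=0.75, rho1=0.95)
    n = sample_size_icc(spec)
    rng = np.random.default_rng(11)
    ss, se = math.sqrt(spec.rho1), math.sqrt(1 - spec.rho1)
    hits = sum(
        reject_low_reliability(
            (rng.normal(0, ss, (n, 1)) + rng.normal(0, se, (n, 2))).tolist(),
            spec.rho0,
            spec.alpha,
        )
        for _ in range(1500)
    )
    assert hits / 1500 >= spec.power - 0.03  # simulation error margin


def test_sample_size_monotonicity():
    base = sample_size_icc(SampleSizeSpec(rho0=0.75, rho1=0.95))
    closer = sample_size_icc(SampleSizeSpec(rho0=0.85, rho1=0.95))
    assert closer > base
    stricter = sample_size_icc(
        SampleSizeSpec(rho0=0.75, rho1=0.95, alpha=0.01, power=0.9)
    )
    assert stricter > base
    with pytest.raises(ValueError):
        SampleSizeSpec(rho0=0.95, rho1=0.75)


def test_summary_renders():
    rng = np.random.default_rng(8)
    res = icc(rng.normal(10, 2, (8, 2)) + rng.normal(0, 3, (8, 1)))
    text = res.summary()
    assert "ICC" in text and "SEM" in text and "MDC" in text
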