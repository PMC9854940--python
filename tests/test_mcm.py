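import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecgmcm as e
from conftest import M, SEED


# -- minimum sample count -----------------------------------------------------


@pytest.mark.parametrize("p, expected", [(0.95, 200_000), (0.99, 1_000_000),
                                         (0.90, 100_000)])
def test_required_samples(p, expected):
    assert e.required_samples(p) == expected


@given(st.floats(0.01, 0.989), st.floats(0.001, 0.01))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_required_samples_strictly_increasing(p, dp):
    assert e.required_samples(p + dp) > e.required_samples(p)


def test_required_samples_rejects_bad_p():
    for p in (0.0, 1.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            e.required_samples(p)


# -- expanded uncertainty -----------------------------------------------------


def test_expanded_uncertainty_coverage_factor():
    assert e.expanded_uncertainty(1.0, 0.95) == pytest.approx(1.96)
    assert e.expanded_uncertainty(0.0, 0.95) == 0.0
    assert e.expanded_uncertainty(56.98, 0.95) == pytest.approx(111.68, abs=0.01)
    # other coverages via the normal quantile
    assert e.expanded_uncertainty(1.0, 0.99) == pytest.approx(2.5758, abs=1e-3)
    with pytest.raises(ValueError):
        e.expanded_uncertainty(-1.0, 0.95)


# -- full propagation ---------------------------------------------------------


def test_full_run_headline_statistics(full_run):
    """All-sources propagation: mean ~2596 mV, sd ~57 mV, U95 ~112 mV (4.3%)."""
    assert full_run.m == M and full_run.seed == SEED
    # small positive bias (~0.2 mV) from E[1/R] > 1/E[R] is real; allow it
    assert full_run.mean == pytest.approx(2596.4, abs=1.0)
    assert e.round_mv(full_run.sd) == 57
    assert e.round_mv(full_run.U95) == 112
    assert full_run.U95 == pytest.approx(1.96 * full_run.sd, rel=1e-12)
    assert abs(full_run.U95_percent - 4.32) <= 0.01
    lo, hi = full_run.coverage_interval
    assert lo < full_run.mean < hi
    # for this near-normal output the percentile interval sits within a few
    # mV of mean +/- U95 (residual skew ~0.04 accounts for the offset)
    assert lo == pytest.approx(full_run.mean - full_run.U95, abs=3.0)
    assert hi == pytest.approx(full_run.mean + full_run.U95, abs=3.0)


def test_same_seed_is_bit_identical(ecg_sys, full_run):
    again = e.run_full(ecg_sys, m=M, seed=SEED)
    assert np.array_equal(again.samples, full_run.samples)
    assert again.mean == full_run.mean and again.sd == full_run.sd


def test_different_seed_changes_samples_not_summary(ecg_sys, full_run):
    other = e.run_full(ecg_sys, m=M, seed=SEED + 1)
    assert not np.array_equal(other.samples, full_run.samples)
    # summary statistics are seed-stable to within Monte Carlo error
    assert other.sd == pytest.approx(full_run.sd, rel=0.01)


def test_near_degenerate_pdfs_collapse_output(ecg_sys):
    tiny = {q.name: e.PDFSpec.normal(q.nominal, 1e-12) for q in ecg_sys.active}
    res = e.run_full(ecg_sys.replace_pdfs(tiny), m=1000, seed=0)
    assert res.mean == pytest.approx(2596.374, abs=1e-6)
    assert res.sd < 1e-6


def test_run_rejects_tiny_m(ecg_sys):
    with pytest.raises(ValueError):
        e.run_full(ecg_sys, m=10, seed=0)


# -- per-source propagation ---------------------------------------------------


def test_run_sources_reuses_full_run_columns(ecg_sys, full_run):
    """Varying every source through run_sources reproduces run_full exactly."""
    res = e.run_sources(ecg_sys, ecg_sys.active_names, m=M, seed=SEED)
    assert np.array_equal(res.samples, full_run.samples)


def test_run_sources_mean_invariance(ecg_sys, full_run):
    """Each subset run stays centred on the nominal output (within MC error)."""
    for subset in (["vin_plus", "vin_minus"], ["baseline"], ["R8", "R11"]):
        res = e.run_sources(ecg_sys, subset, m=M, seed=SEED)
        assert abs(res.mean - full_run.mean) < 3 * full_run.sd / math.sqrt(M)


def test_run_sources_argument_validation(ecg_sys):
    with pytest.raises(ValueError):
        e.run_sources(ecg_sys, [], m=M, seed=SEED)
    with pytest.raises(ValueError):
        e.run_sources(ecg_sys, ["not_a_quantity"], m=M, seed=SEED)
    with pytest.raises(ValueError):
        e.run_sources(ecg_sys, ["C1"], m=M, seed=SEED)  # frequency-only


def test_variance_quadrature_over_disjoint_blocks(ecg_sys, default_budget):
    """Per-source variances of the five disjoint rows add to the full-run
    variance within 3% (the model is close to linear)."""
    total_var = default_budget.total.sd ** 2
    sum_var = sum(r.sd ** 2 for r in default_budget.rows)
    assert sum_var == pytest.approx(total_var, rel=0.03)


def test_tightening_a_source_never_raises_total_sd(ecg_sys, full_run):
    tightened = ecg_sys.with_tolerance(["R1", "R5"], 0.001)
    res = e.run_full(tightened, m=M, seed=SEED)
    mc_noise = 4 * full_run.sd / math.sqrt(2 * M)
    assert res.sd <= full_run.sd + mc_noise


# -- budget assembly ----------------------------------------------------------


def test_budget_layout_and_rounding(default_budget):
    assert [r.source for r in default_budget.rows] == [
        "vin", "Baseline", "Preamplifier", "Final stage", "Noise"]
    assert [r.group for r in default_budget.rows] == [
        "measurand", "measurand", "measuring_system", "measuring_system",
        "environment"]
    assert default_budget.total.source == "All sources"
    df = default_budget.to_frame(rounded=True)
    assert list(df.columns) == ["source", "group", "mean_mV", "sd_mV",
                                "U95_mV", "U95_pct"]
    assert df["mean_mV"].between(2596, 2597).all()


def test_budget_empty_grouping_has_only_total(ecg_sys):
    bud = e.budget(ecg_sys, {}, m=1000, seed=0)
    assert bud.rows == ()
    assert bud.total.sd > 0


def test_budget_overlapping_subsets_warn(ecg_sys, caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="ecgmcm.mcm"):
        e.budget(ecg_sys, {"a": ["R1", "R2"], "b": ["R2"]}, m=1000, seed=0)
    assert any("overlap" in rec.message for rec in caplog.records)


def test_budget_json_round_trip(default_budget):
    again = e.UncertaintyBudget.from_json_dict(default_budget.to_json_dict())
    assert again.rows == default_budget.rows
    assert again.total == default_budget.total
    assert (again.m, again.seed, again.p) == (M, SEED, 0.95)


def test_report_rounding_convention():
    assert e.round_mv(111.68) == 112
    assert e.round_mv(44.5) == 45
    assert e.round_mv(-2.5) == -3
    assert e.round_pct(2.0649) == 2.06
    assert e.round_pct(0.5939) == 0.59
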