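import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dcflow import (compensate, fold_change, net_mfi, paired_t_test,
                    phenotype_cohort, simulate_fmo, unpaired_t_test)
from dcflow.events import EventMatrix
from dcflow.gating import (apply_gate_tree, build_dc_gate_tree,
                           derive_gating_thresholds, transform_for_gating)
from dcflow.panel import default_panel
from dcflow.phenotyping import (MFIRecord, condition_contrasts,
                                subset_contrasts, summarize)

SEED = 11
PANEL = default_panel()
CHANNELS = ["FSC-A", "FSC-H", "SSC-A"] + list(PANEL.detectors)
MARKERS = ["FSC-A", "FSC-H", "SSC-A"] + list(PANEL.marker_names)


def constant_events(marker, value, n=10, condition="basal",
                    control="full_stain"):
    values = np.full((n, len(MARKERS)), 100.0)
    values[:, MARKERS.index(marker)] = value
    return EventMatrix(values=values, channels=CHANNELS, markers=MARKERS,
                       metadata={"compensated": True, "transformed": False,
                                 "donor": 0, "condition": condition,
                                 "control_type": control})


def labels(n, subset="pDC"):
    return np.repeat(subset, n)


# ---------------------------------------------------------------------------
# net MFI
# ---------------------------------------------------------------------------

def test_net_mfi_is_sample_minus_fmo():
    sample = constant_events("CD86", 850.0)
    fmo = constant_events("CD86", 120.0, control="FMO:CD86")
    rec = net_mfi(sample, labels(10), fmo, labels(10), "pDC", "CD86")
    assert rec.net_mfi == 730.0
    assert rec.sample_mfi == 850.0 and rec.fmo_mfi == 120.0


def test_fmo_against_itself_gives_zero():
    fmo = constant_events("CD86", 312.5, control="FMO:CD86")
    rec = net_mfi(fmo, labels(10), fmo, labels(10), "pDC", "CD86")
    assert rec.net_mfi == 0.0


def test_net_mfi_requires_matching_fmo_and_events():
    sample = constant_events("CD86", 850.0)
    wrong = constant_events("CD86", 120.0, control="FMO:CD40")
    with pytest.raises(ValueError, match="does not match"):
        net_mfi(sample, labels(10), wrong, labels(10), "pDC", "CD86")
    fmo = constant_events("CD86", 120.0, control="FMO:CD86")
    with pytest.raises(ValueError, match="no events"):
        net_mfi(sample, labels(10, "cDC1"), fmo, labels(10), "pDC", "CD86")


def test_net_mfi_recovers_generator_expectation(boosted_config):
    from dcflow import SpilloverMatrix, simulate_sample
    from dcflow.pipeline import process_sample

    spill = SpilloverMatrix(boosted_config.spillover,
                            list(boosted_config.panel.detectors))
    sample = simulate_sample(boosted_config, 0, "basal", seed=SEED,
                             n_events=40_000)
    proc = process_sample(sample, spill)
    fmo = simulate_fmo(boosted_config, 0, "basal", "CD86", seed=SEED,
                       n_events=20_000)
    fmo_lin = compensate(fmo, spill)
    fmo_tr = transform_for_gating(fmo_lin)
    fmo_res = apply_gate_tree(
        build_dc_gate_tree(derive_gating_thresholds(fmo_tr)), fmo_tr)
    rec = net_mfi(proc.linear, proc.result, fmo_lin, fmo_res,
                  "cDC2", "CD86")
    assert rec.n_events >= 2000
    expected = (boosted_config.on_state_mean(0, "basal", "cDC2", "CD86")
                - boosted_config.background[0])
    assert rec.net_mfi == pytest.approx(expected, rel=0.05)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.floats(0.1, 100.0))
def test_net_mfi_linearity_under_intensity_scaling(c):
    sample = constant_events("CD86", 850.0)
    fmo = constant_events("CD86", 120.0, control="FMO:CD86")
    base = net_mfi(sample, labels(10), fmo, labels(10), "pDC", "CD86")
    scaled = net_mfi(
        sample.with_values(sample.values * c), labels(10),
        fmo.with_values(fmo.values * c), labels(10), "pDC", "CD86")
    assert scaled.net_mfi == pytest.approx(c * base.net_mfi, rel=1e-12)


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

def _rec(net, condition="LPS", **kw):
    defaults = dict(donor=0, condition=condition, subset="cDC2",
                    marker="CD86", sample_mfi=net + 120.0, fmo_mfi=120.0,
                    n_events=100, n_fmo_events=100)
    defaults.update(kw)
    return MFIRecord(**defaults)


def test_fold_change_basics():
    basal = _rec(500.0, condition="basal")
    assert fold_change(basal, basal) == 1.0
    assert fold_change(_rec(1500.0), basal) == pytest.approx(3.0)
    assert np.isnan(fold_change(_rec(1500.0), _rec(-5.0, "basal")))
    with pytest.raises(ValueError, match="differ"):
        fold_change(_rec(1500.0, marker="CD40"), basal)


def test_fold_change_recovers_generator_multiplier(boosted_config):
    records = phenotype_cohort(
        boosted_config, seed=SEED, n_events=20_000, n_fmo_events=8_000,
        conditions=["basal", "LPS"], subsets=("cDC2",), markers=("CD86",),
        donors=2)
    got = records[(records.condition == "LPS")].fold_change.mean()
    bg = boosted_config.background[0]
    loc = boosted_config.population("cDC2").expression["CD86"]
    mult = boosted_config.condition("LPS").multiplier("cDC2", "CD86")
    expected = (loc * mult - bg) / (loc - bg)
    assert got == pytest.approx(expected, rel=0.10)
    assert (records[records.condition == "LPS"].fold_change > 1).all()


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

def test_paired_t_matches_hand_computation():
    x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
    d = x - y
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
    res = paired_t_test(x, y)
    assert res.statistic == pytest.approx(t_hand, abs=1e-12)
    assert res.df == 2
    ref = sps.ttest_rel(x, y)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_unpaired_t_matches_reference(rng):
    x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1.3, 9)
    res = unpaired_t_test(x, y)
    ref = sps.ttest_ind(x, y, equal_var=True)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
    assert res.df == 19


def test_degenerate_and_invalid_inputs():
    res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.degenerate and np.isnan(res.statistic)
    with pytest.raises(ValueError):
        paired_t_test([1.0], [2.0])
    with pytest.raises(ValueError):
        unpaired_t_test([1.0], [2.0, 3.0])
    with pytest.raises(ValueError, match="equal length"):
        paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])


def test_null_type_one_error_rate(rng):
    rejections = 0
    reps = 2000
    for _ in range(reps):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        if unpaired_t_test(x, y).p_value < 0.05:
            rejections += 1
    assert 0.035 <= rejections / reps <= 0.065


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.floats(-1e4, 1e4))
def test_paired_t_invariant_to_constant_shift(c):
    x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
    y = np.array([2.0, 2.5, 3.0, 0.5, 4.0])
    a, b = paired_t_test(x, y), paired_t_test(x + c, y + c)
    assert a.statistic == pytest.approx(b.statistic, rel=1e-9)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def _toy_records():
    rows = []
    rng = np.random.default_rng(5)
    for donor in range(4):
        for cond in ("basal", "LPS", "IMQ", "IL10", "LPS+IL10",
                     "IMQ+IL10"):
            for subset in ("pDC", "cDC2"):
                rows.append({"cohort": "healthy", "donor": donor,
                             "condition": cond, "subset": subset,
                             "marker": "CD86",
                             "net_mfi": float(rng.normal(1000, 100)),
                             "fold_change": 1.0})
    return pd.DataFrame(rows)


def test_summarize_mean_and_sem():
    df = pd.DataFrame({"cohort": "h", "subset": "pDC", "marker": "CD86",
                       "condition": "basal", "net_mfi": [2.0, 4.0, 6.0]})
    out = summarize(df)
    assert out["mean"].iloc[0] == pytest.approx(4.0)
    assert out["sem"].iloc[0] == pytest.approx(2.0 / np.sqrt(3))
    same = df.assign(net_mfi=7.0)
    assert summarize(same)["sem"].iloc[0] == 0.0


def test_condition_contrasts_cover_the_design():
    out = condition_contrasts(_toy_records())
    contrasts = set(out.contrast)
    for cond in ("LPS", "IMQ", "IL10", "LPS+IL10", "IMQ+IL10"):
        assert f"pDC/CD86: {cond} vs basal" in contrasts
    assert "pDC/CD86: LPS+IL10 vs LPS" in contrasts
    assert "pDC/CD86: IMQ+IL10 vs IMQ" in contrasts
    assert out.paired.all()


def test_subset_contrasts_are_paired_within_donor():
    out = subset_contrasts(_toy_records())
    assert "CD86 @ basal: pDC vs cDC2" in set(out.contrast)
    assert (out.n_a == 4).all()
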