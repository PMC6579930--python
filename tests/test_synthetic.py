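import numpy as np
import pytest
from scipy import stats as sps

from dcflow import (build_default_healthy_config, build_default_mds_config,
                    simulate_bead_controls, simulate_fmo, simulate_sample)
from dcflow.synthetic import (BACKGROUND, DC_POPULATIONS, PopulationSpec,
                              StimulationCondition, default_spillover)

SEED = 11


def test_default_healthy_config_encodes_reported_frequencies():
    cfg = build_default_healthy_config()
    assert cfg.n_donors == 16
    assert cfg.base_frequency("pDC") == pytest.approx(0.0044)
    assert cfg.base_frequency("cDC1") == pytest.approx(0.0002)
    assert cfg.base_frequency("cDC2") == pytest.approx(0.0049)
    assert cfg.base_frequency("slanDC") == pytest.approx(0.0007)
    # moDCs are near-undetectable; the double-negative cDC remainder fills
    # the total-cDC gate to 0.79%
    assert cfg.base_frequency("moDC") <= 1e-4
    total_cdc = sum(cfg.base_frequency(s)
                    for s in ("cDC1", "cDC2", "cDC_other"))
    assert total_cdc == pytest.approx(0.0079)
    assert sum(p.frequency for p in cfg.populations) == pytest.approx(1.0)
    names = {c.name for c in cfg.conditions}
    assert names == {"basal", "LPS", "IMQ", "IL10", "LPS+IL10", "IMQ+IL10"}


def test_donor_frequency_spread_matches_configured_cv():
    cfg = build_default_healthy_config()
    per_donor = np.array([cfg.donor_frequencies(d)["pDC"]
                          for d in range(cfg.n_donors)])
    # quantile-balanced draw: cohort mean equals the configured truth and
    # the spread tracks the configured CV
    assert per_donor.mean() == pytest.approx(0.0044, rel=0.02)
    cv = per_donor.std(ddof=1) / per_donor.mean()
    assert 0.3 < cv < 0.7


def test_simulation_is_deterministic():
    cfg = build_default_healthy_config(seed=SEED)
    a = simulate_sample(cfg, 0, "basal", seed=1, n_events=4000)
    b = simulate_sample(cfg, 0, "basal", seed=1, n_events=4000)
    assert np.array_equal(a.values, b.values)
    assert (a.truth_labels == b.truth_labels).all()
    c = simulate_sample(cfg, 0, "basal", seed=2, n_events=4000)
    assert not np.array_equal(a.values, c.values)


def test_unknown_condition_and_bad_donor_rejected():
    cfg = build_default_healthy_config(seed=SEED)
    with pytest.raises(ValueError, match="condition"):
        simulate_sample(cfg, 0, "TNF", seed=1, n_events=1000)
    with pytest.raises(ValueError, match="donor"):
        simulate_sample(cfg, 99, "basal", seed=1, n_events=1000)


def test_lps_raises_true_cd86_signal_on_cdc2(boosted_config):
    basal = simulate_sample(boosted_config, 0, "basal", seed=SEED)
    lps = simulate_sample(boosted_config, 0, "LPS", seed=SEED)
    col = basal.column("CD86")
    for ev in (basal, lps):
        assert ev.true_signal is not None
    m_basal = basal.true_signal[basal.truth_labels == "cDC2", col].mean()
    m_lps = lps.true_signal[lps.truth_labels == "cDC2", col].mean()
    assert m_lps > 2 * m_basal


def test_pdc_fraction_matches_binomial_expectation(boosted_config,
                                                   boosted_sample):
    mono_pops = {p.name for p in boosted_config.populations}
    mono = np.isin(boosted_sample.truth_labels, list(mono_pops))
    n = int(mono.sum())
    k = int((boosted_sample.truth_labels == "pDC").sum())
    p = boosted_config.donor_frequencies(0)["pDC"]
    sd = np.sqrt(n * p * (1 - p))
    assert abs(k - n * p) <= 3 * sd


def test_fmo_replaces_only_the_omitted_marker(boosted_config):
    full = simulate_sample(boosted_config, 0, "basal", seed=SEED,
                           n_events=8000)
    fmo = simulate_fmo(boosted_config, 0, "basal", "CD86", seed=SEED,
                       n_events=8000)
    assert fmo.metadata["control_type"] == "FMO:CD86"
    col = full.column("CD86")
    other = [i for i in range(full.values.shape[1]) if i != col]
    assert np.array_equal(full.true_signal[:, other],
                          fmo.true_signal[:, other])
    assert not np.array_equal(full.true_signal[:, col],
                              fmo.true_signal[:, col])


def test_fmo_channel_is_pure_autofluorescence(boosted_config):
    fmo = simulate_fmo(boosted_config, 0, "LPS", "PD-L1", seed=SEED,
                       n_events=20_000)
    col = fmo.column("PD-L1")
    sig = fmo.true_signal[fmo.truth_labels == "cDC2", col]
    ref = np.random.default_rng(0).normal(*BACKGROUND, size=10_000)
    # two-sample location test must fail to reject at alpha = 0.01
    _, p = sps.ttest_ind(sig, ref, equal_var=False)
    assert p > 0.01


def test_fmo_for_gating_marker_rejected(boosted_config):
    with pytest.raises(ValueError, match="gating marker"):
        simulate_fmo(boosted_config, 0, "basal", "CD123", seed=SEED)


def test_population_composition_multinomial(boosted_config):
    # pooled counts over repeated seeds follow the configured multinomial
    pops = [p.name for p in boosted_config.populations]
    expected = boosted_config.donor_frequencies(0)
    counts = np.zeros(len(pops))
    total = 0
    for seed in range(5):
        ev = simulate_sample(boosted_config, 0, "basal", seed=seed,
                             n_events=20_000)
        mono = np.isin(ev.truth_labels, pops)
        total += int(mono.sum())
        for i, name in enumerate(pops):
            counts[i] += int((ev.truth_labels == name).sum())
    exp = np.array([expected[name] * total for name in pops])
    chi2 = ((counts - exp) ** 2 / exp).sum()
    p = sps.chi2.sf(chi2, df=len(pops) - 1)
    assert p > 0.01


def test_contaminant_fractions_present(boosted_sample):
    labels = boosted_sample.truth_labels
    n = len(labels)
    for kind, frac in (("dead", 0.05), ("doublet", 0.02),
                       ("granulocyte", 0.01), ("debris", 0.02)):
        assert (labels == kind).sum() == pytest.approx(frac * n, rel=0.05)


def test_bead_controls_cover_all_channels_and_spillover():
    panel_channels = 18
    ident = np.eye(panel_channels)
    beads = simulate_bead_controls(ident, n_events=4000, seed=SEED)
    assert len(beads) == panel_channels
    # identity spillover: off-channel medians of bright and negative beads
    # agree within noise
    b0 = beads[0]
    fluor = b0.values[:, b0.fluorescence_columns]
    bright = fluor[:, 0] > 10_000
    off = np.abs(np.median(fluor[bright, 1:], axis=0)
                 - np.median(fluor[~bright, 1:], axis=0))
    assert off.max() < 5.0

    spill = np.eye(panel_channels)
    spill[2, 7] = 0.15
    beads = simulate_bead_controls(spill, n_events=8000, seed=SEED)
    b2 = beads[2]
    fluor = b2.values[:, b2.fluorescence_columns]
    bright = fluor[:, 2] > 10_000
    ratio = ((np.median(fluor[bright, 7]) - np.median(fluor[~bright, 7]))
             / (np.median(fluor[bright, 2]) - np.median(fluor[~bright, 2])))
    assert ratio == pytest.approx(0.15, abs=0.005)

    with pytest.raises(ValueError, match="square"):
        simulate_bead_controls(np.ones((3, 4)), n_events=100, seed=0)


def test_mds_mode_directions_on_generator_parameters():
    h = build_default_healthy_config(seed=SEED)
    m = build_default_mds_config(seed=SEED)
    for subset in DC_POPULATIONS:
        assert m.base_frequency(subset) < h.base_frequency(subset)
    # subverted cDC1 checkpoint repertoire
    assert (m.on_state_mean(0, "basal", "cDC1", "ILT2")
            > 3 * h.on_state_mean(0, "basal", "cDC1", "ILT2"))
    assert (m.on_state_mean(0, "basal", "cDC1", "TIM-3")
            < h.on_state_mean(0, "basal", "cDC1", "TIM-3"))
    # TLR hyporesponsiveness: attenuated multipliers
    h_fold = (h.on_state_mean(0, "LPS", "cDC2", "CD86")
              / h.on_state_mean(0, "basal", "cDC2", "CD86"))
    m_fold = (m.on_state_mean(0, "LPS", "cDC2", "CD86")
              / m.on_state_mean(0, "basal", "cDC2", "CD86"))
    assert m_fold < h_fold


def test_population_spec_and_condition_invariants():
    with pytest.raises(ValueError, match="background"):
        PopulationSpec("x", 0.1, ((1, 1), (1, 1)), {"CD40": 10.0})
    with pytest.raises(ValueError, match="positive"):
        StimulationCondition("LPS", {"pDC": {"CD40": -1.0}})
    with pytest.raises(ValueError, match="basal"):
        StimulationCondition("basal", {"pDC": {"CD40": 2.0}})


def test_default_spillover_is_well_conditioned():
    S = default_spillover(18, seed=5)
    assert np.allclose(np.diag(S), 1.0)
    off = S - np.eye(18)
    assert off.min() >= 0 and off.max() <= 0.2
    assert np.linalg.cond(S) < 100
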