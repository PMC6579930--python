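import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcflow import (apply_gate_tree, build_dc_gate_tree,
                    derive_threshold, transform_for_gating, tree_from_text,
                    tree_to_text)
from dcflow.events import EventMatrix
from dcflow.gating import (DC_LABELS, GATING_MARKERS, inverse_transform,
                           internal_negatives)
from dcflow.panel import default_panel

PANEL = default_panel()
CHANNELS = ["FSC-A", "FSC-H", "SSC-A"] + list(PANEL.detectors)
MARKERS = ["FSC-A", "FSC-H", "SSC-A"] + list(PANEL.marker_names)

#: handcrafted thresholds on the transformed scale
THRESHOLDS = {m: 1.5 for m in GATING_MARKERS}
THRESHOLDS.update({"Viability": 1.5, "CD45": 1.5})

NEG, POS = 0.5, 5.0


def make_events(rows):
    """Handcrafted transformed events: each row is a dict of positive
    markers (value POS unless given); everything else sits at background.
    Scatter defaults land inside the mononuclear gate."""
    values = []
    for row in rows:
        rec = {"FSC-A": 60_000.0, "FSC-H": 57_000.0, "SSC-A": 15_000.0}
        rec.update({m: NEG for m in PANEL.marker_names})
        for k, v in row.items():
            rec[k] = POS if v is True else v
        values.append([rec[m] for m in MARKERS])
    return EventMatrix(values=np.array(values), channels=CHANNELS,
                       markers=MARKERS,
                       metadata={"compensated": True, "transformed": True})


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------

def test_transform_zero_maps_to_zero(boosted_sample):
    tr = transform_for_gating(boosted_sample)
    assert np.arcsinh(0.0) == 0.0
    assert tr.metadata["transformed"]
    # scatter untouched
    assert np.array_equal(tr.values[:, :3], boosted_sample.values[:, :3])


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.floats(-1e5, 1e5), st.floats(-1e5, 1e5))
def test_transform_is_strictly_monotone(x, y):
    if x == y:
        return
    lo, hi = sorted((x, y))
    assert np.arcsinh(lo / 150.0) < np.arcsinh(hi / 150.0)


def test_transform_round_trip(boosted_sample):
    tr = transform_for_gating(boosted_sample, cofactor=150)
    back = inverse_transform(tr)
    rel = (np.abs(back.values - boosted_sample.values)
           / np.maximum(np.abs(boosted_sample.values), 1.0))
    assert rel.max() < 1e-9


def test_non_positive_cofactor_rejected(boosted_sample):
    with pytest.raises(ValueError, match="cofactor"):
        transform_for_gating(boosted_sample, cofactor=0)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def test_threshold_of_constant_control_is_the_constant():
    ev = make_events([{"CD40": 2.25} for _ in range(600)])
    assert derive_threshold(ev, "CD40", 99.5) == pytest.approx(2.25)


def test_threshold_percentile_monotonicity(rng):
    ev = make_events([{"CD40": float(v)}
                      for v in rng.normal(1.0, 0.3, size=800)])
    assert (derive_threshold(ev, "CD40", 100.0)
            >= derive_threshold(ev, "CD40", 99.5))


def test_negative_population_exceedance_matches_percentile(rng):
    n = 20_000
    ev = make_events([{"CD40": float(v)}
                      for v in rng.normal(0.8, 0.3, size=n)])
    thr = derive_threshold(ev, "CD40", 99.5)
    exceed = (ev.get("CD40") > thr).mean()
    tol = 3 * np.sqrt(0.005 * 0.995 / n)
    assert exceed <= 0.005 + tol


def test_too_few_control_events_rejected():
    ev = make_events([{"CD40": 1.0} for _ in range(100)])
    with pytest.raises(ValueError, match="too few"):
        derive_threshold(ev, "CD40", 99.5)


def test_internal_negatives_split(rng):
    neg = rng.normal(0.7, 0.3, size=5000)
    pos = rng.normal(5.5, 0.4, size=500)
    ev = make_events([{"CD123": float(v)}
                      for v in np.concatenate([neg, pos])])
    mask = internal_negatives(ev, "CD123")
    assert mask.sum() == pytest.approx(5000, abs=5)
    # unimodal channel: everything is treated as negative
    ev2 = make_events([{"CD123": float(v)} for v in neg])
    assert internal_negatives(ev2, "CD123").all()


# ---------------------------------------------------------------------------
# tree structure and special cases
# ---------------------------------------------------------------------------

def test_tree_has_exactly_five_terminal_dc_labels():
    tree = build_dc_gate_tree(THRESHOLDS)
    assert sorted(tree.terminal_labels) == sorted(DC_LABELS)


def test_missing_threshold_rejected():
    partial = {k: v for k, v in THRESHOLDS.items() if k != "CD123"}
    with pytest.raises(ValueError, match="CD123"):
        build_dc_gate_tree(partial)


def test_lineage_positive_event_gets_no_dc_label():
    tree = build_dc_gate_tree(THRESHOLDS)
    ev = make_events([{"Lineage": True, "HLA-DR": True, "CD11c": True,
                       "M-DC8": True, "CD123": True}])
    res = apply_gate_tree(tree, ev)
    assert res.labels[0] == ""


def test_cd14_positive_slandc_found_via_inflammatory_branch():
    # CD14+ HLA-DR+ CD11c+ M-DC8+ is excluded from DC-lineage but still
    # labelled slanDC: inflammatory DCs may be CD14/CD16 positive
    tree = build_dc_gate_tree(THRESHOLDS)
    ev = make_events([{"CD14": True, "HLA-DR": True, "CD11c": True,
                       "M-DC8": True}])
    res = apply_gate_tree(tree, ev)
    assert not res.mask("dc_lineage")[0]
    assert res.labels[0] == "slanDC"


def test_cd141_cd1c_double_positive_is_cdc1():
    tree = build_dc_gate_tree(THRESHOLDS)
    ev = make_events([{"HLA-DR": True, "CD11c": True, "CD141": True,
                       "CD1c": True}])
    assert apply_gate_tree(tree, ev).labels[0] == "cDC1"


def test_empty_modc_class_reports_zero_frequency():
    tree = build_dc_gate_tree(THRESHOLDS)
    ev = make_events([{"HLA-DR": True, "CD11c": True, "CD1c": True}
                      for _ in range(20)])
    res = apply_gate_tree(tree, ev)
    assert res.percent("moDC") == 0.0


# ---------------------------------------------------------------------------
# full-sample behaviour
# ---------------------------------------------------------------------------

def test_gated_labels_agree_with_generator_truth(boosted_sample, processed):
    truth = boosted_sample.truth_labels
    labels = processed.result.labels
    for subset in ("pDC", "cDC2", "slanDC"):
        is_truth = truth == subset
        recall = (labels[is_truth] == subset).mean()
        precision = (truth[labels == subset] == subset).mean()
        assert recall >= 0.99, subset
        assert precision >= 0.99, subset


def test_partition_of_mononuclear_events(processed):
    m = processed.result.memberships
    mono = m["mononuclear"]
    pdc, cdc, infl = m["pDC"], m["cDC"], m["inflammatory"]
    infl_only = infl & ~(pdc | cdc)
    unlabeled = mono & ~(pdc | cdc | infl)
    assert not (pdc & cdc).any()
    assert (pdc.sum() + cdc.sum() + infl_only.sum() + unlabeled.sum()
            == mono.sum())


def test_hierarchy_consistency_by_reevaluation(processed, boosted_sample):
    res = processed.result
    tree = build_dc_gate_tree(processed.thresholds)
    path = ["singlets", "live", "mononuclear", "dc_lineage", "cDC", "cDC1"]
    is_cdc1 = res.labels == "cDC1"
    assert is_cdc1.any()
    for name in path:
        node = tree.node(name)
        if node.predicate is not None:
            mask = node.predicate.evaluate(processed.transformed)
            assert mask[is_cdc1].all(), name


def test_frequencies_invariant_to_excluded_scatter_events(processed):
    tr = processed.transformed
    tree = build_dc_gate_tree(processed.thresholds)
    base = apply_gate_tree(tree, tr)
    # append granulocyte-like (high SSC) and debris-like (low FSC) events
    # far outside the mononuclear scatter rectangle
    extra = np.tile(tr.values[:1], (500, 1))
    extra[:250, tr.column("SSC-A")] = 150_000.0
    extra[250:, tr.column("FSC-A")] = 2_000.0
    spiked = EventMatrix(values=np.vstack([tr.values, extra]),
                         channels=list(tr.channels),
                         markers=list(tr.markers),
                         metadata=dict(tr.metadata))
    res = apply_gate_tree(tree, spiked)
    assert res.denominator == base.denominator
    assert np.allclose(res.frequencies.percent, base.frequencies.percent)


def test_tree_text_round_trip(processed):
    tree = build_dc_gate_tree(processed.thresholds)
    text = tree_to_text(tree)
    back = tree_from_text(text)
    assert [n.name for n in back.walk()] == [n.name for n in tree.walk()]
    a = apply_gate_tree(tree, processed.transformed)
    b = apply_gate_tree(back, processed.transformed)
    assert (a.labels == b.labels).all()
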