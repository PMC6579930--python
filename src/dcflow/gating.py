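"""Hierarchical gating of dendritic-cell subsets.

Implements the five-subset gating tree as a declarative hierarchy of
predicates over asinh-transformed, compensated fluorescence channels:

    all -> singlets -> live -> mononuclear (FSC/SSC rectangle)
      +- DC-lineage:  lin- CD14- CD16- HLA-DR+
      |    +- pDC:  CD123+ CD11c-
      |    +- cDC:  CD123- CD11c+
      |         +- cDC1: CD141+
      |         +- cDC2: CD1c+ CD141-
      +- inflammatory: lin- HLA-DR+ CD11c+  (CD14/CD16 unconstrained)
           +- slanDC: M-DC8+
           +- moDC:  CD1a+ M-DC8-

Thresholds are data-derived: a percentile of the internal negative
population of each channel (the lower mode of a 1-D 2-means split on the
transformed scale). Subset frequencies are reported as percentages of the
mononuclear (live, singlet, lymphocyte+monocyte scatter) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .events import EventMatrix

DEFAULT_COFACTOR = 150.0
#: raw-scatter mononuclear rectangle, calibrated to the generator's
#: lymphocyte + monocyte clusters ((FSC-A lo, hi), (SSC-A lo, hi))
MONONUCLEAR_GATE = ((25_000.0, 120_000.0), (1_000.0, 60_000.0))
#: FSC-H / FSC-A ratio below which an event is called an aggregate
SINGLET_RATIO = 0.75
#: identity-marker thresholds use a high percentile of the internal
#: negatives so rare-subset gates are not swamped by false positives from
#: abundant parents (0.05% of ~18% monocytes vs a 0.07% slanDC gate)
IDENTITY_PERCENTILE = 99.95

#: channels whose thresholds the tree needs
GATING_MARKERS = ("Lineage", "CD14", "CD16", "HLA-DR", "CD123", "CD11c",
                  "CD141", "CD1c", "M-DC8", "CD1a")
DC_LABELS = ("pDC", "cDC1", "cDC2", "slanDC", "moDC")


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------

def transform_for_gating(events: EventMatrix,
                         cofactor: float = DEFAULT_COFACTOR) -> EventMatrix:
    """Inverse-hyperbolic-sine transform of the fluorescence channels
    (scatter untouched). Order-preserving and invertible."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    values = events.values.copy()
    cols = events.fluorescence_columns
    values[:, cols] = np.arcsinh(values[:, cols] / cofactor)
    return events.with_values(values, transformed=True, cofactor=cofactor)


def inverse_transform(events: EventMatrix) -> EventMatrix:
    cofactor = events.metadata.get("cofactor", DEFAULT_COFACTOR)
    values = events.values.copy()
    cols = events.fluorescence_columns
    values[:, cols] = np.sinh(values[:, cols]) * cofactor
    return events.with_values(values, transformed=False)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def two_means_split(x: np.ndarray, max_iter: int = 100) -> tuple:
    """Deterministic 1-D 2-means. Returns (mask_of_upper_cluster,
    lower_center, upper_center)."""
    c1, c2 = float(np.min(x)), float(np.max(x))
    upper = np.abs(x - c2) < np.abs(x - c1)
    for _ in range(max_iter):
        if upper.all() or not upper.any():
            break
        n1, n2 = float(np.mean(x[~upper])), float(np.mean(x[upper]))
        if (n1, n2) == (c1, c2):
            break
        c1, c2 = n1, n2
        upper = np.abs(x - c2) < np.abs(x - c1)
    return upper, c1, c2


def internal_negatives(events: EventMatrix, marker: str,
                       min_separation: float = 2.0) -> np.ndarray:
    """Mask of the channel's internal negative population: the lower
    2-means cluster if the channel is genuinely bimodal (cluster centers
    more than ``min_separation`` transformed units apart), else all
    events."""
    x = events.get(marker)
    upper, c1, c2 = two_means_split(x)
    if c2 - c1 < min_separation or not upper.any() or upper.all():
        return np.ones(events.n_events, dtype=bool)
    return ~upper


def derive_threshold(control_events: EventMatrix, channel: str,
                     percentile: float = 99.5,
                     min_events: int = 500) -> float:
    """Positivity threshold: the stated percentile of the (transformed)
    control/negative distribution. Deterministic for fixed input."""
    x = control_events.get(channel)
    if x.shape[0] < min_events:
        raise ValueError(
            f"too few control events for {channel} threshold "
            f"({x.shape[0]} < {min_events})")
    return float(np.percentile(x, percentile))


def derive_gating_thresholds(events: EventMatrix,
                             percentile: float = IDENTITY_PERCENTILE,
                             min_events: int = 100) -> dict:
    """Derive all thresholds the gating tree needs from a compensated,
    transformed sample itself.

    The viability and CD45 thresholds come from internal negatives among
    singlets (debris provides CD45 negatives); identity-marker thresholds
    come from internal negatives among live single mononuclear events.
    """
    if not events.metadata.get("transformed"):
        raise ValueError("thresholds are derived on the transformed scale")
    thresholds = {}
    ratio = np.divide(events.get("FSC-H"),
                      np.maximum(events.get("FSC-A"), 1e-9))
    singlets = events.subset(ratio >= SINGLET_RATIO)

    for marker in ("Viability", "CD45"):
        neg = singlets.subset(internal_negatives(singlets, marker))
        thresholds[marker] = derive_threshold(neg, marker, percentile,
                                              min_events)

    (fl, fh), (sl, sh) = MONONUCLEAR_GATE
    live = singlets.get("Viability") < thresholds["Viability"]
    mono = (live
            & (singlets.get("FSC-A") >= fl) & (singlets.get("FSC-A") <= fh)
            & (singlets.get("SSC-A") >= sl) & (singlets.get("SSC-A") <= sh))
    parent = singlets.subset(mono)
    for marker in GATING_MARKERS:
        neg = parent.subset(internal_negatives(parent, marker))
        thresholds[marker] = derive_threshold(neg, marker, percentile,
                                              min_events)
    return thresholds


# ---------------------------------------------------------------------------
# gate tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gate:
    """1-D threshold (side '+' keeps >= value, '-' keeps < value)."""
    marker: str
    side: str
    value: float

    def evaluate(self, events: EventMatrix) -> np.ndarray:
        x = events.get(self.marker)
        return x >= self.value if self.side == "+" else x < self.value


@dataclass(frozen=True)
class RectGate:
    """2-D rectangle over two (raw-scale) channels."""
    x_marker: str
    y_marker: str
    x_range: tuple
    y_range: tuple

    def evaluate(self, events: EventMatrix) -> np.ndarray:
        x, y = events.get(self.x_marker), events.get(self.y_marker)
        return ((x >= self.x_range[0]) & (x <= self.x_range[1])
                & (y >= self.y_range[0]) & (y <= self.y_range[1]))


@dataclass(frozen=True)
class RatioGate:
    """Keeps events with numerator/denominator >= min_ratio (singlet
    surrogate on the scatter area/height pair)."""
    numerator: str
    denominator: str
    min_ratio: float

    def evaluate(self, events: EventMatrix) -> np.ndarray:
        den = np.maximum(events.get(self.denominator), 1e-9)
        return events.get(self.numerator) / den >= self.min_ratio


@dataclass(frozen=True)
class AllOf:
    gates: tuple

    def evaluate(self, events: EventMatrix) -> np.ndarray:
        mask = np.ones(events.n_events, dtype=bool)
        for g in self.gates:
            mask &= g.evaluate(events)
        return mask


@dataclass
class GateNode:
    name: str
    predicate: object | None = None       # None = pass-through (root)
    label: str | None = None              # terminal subset label
    children: list = field(default_factory=list)

    def add(self, child: "GateNode") -> "GateNode":
        self.children.append(child)
        return child


@dataclass
class GateTree:
    root: GateNode

    def __post_init__(self):
        names, labels = [], []
        for node in self.walk():
            names.append(node.name)
            if node.label:
                labels.append(node.label)
        if len(set(names)) != len(names):
            raise ValueError("gate node names must be unique")
        if len(set(labels)) != len(labels):
            raise ValueError("terminal subset labels must be unique")

    def walk(self):
        stack = [self.root]
        while stack:
            node = stack.pop(0)
            yield node
            stack.extend(node.children)

    @property
    def terminal_labels(self) -> list:
        return [n.label for n in self.walk() if n.label]

    def node(self, name: str) -> GateNode:
        for n in self.walk():
            if n.name == name:
                return n
        raise KeyError(name)


def build_dc_gate_tree(thresholds: dict,
                          scatter_gate: tuple = MONONUCLEAR_GATE,
                          singlet_ratio: float = SINGLET_RATIO) -> GateTree:
    """Build the five-subset DC gating tree from a threshold dict
    (transformed scale; keys per :data:`GATING_MARKERS` plus
    ``Viability``).

    Tie-breaks: inside the cDC gate an event positive for both CD141 and
    CD1c is called cDC1 (bright CD141 defines cDC1s; cDC2s may express
    low CD141), and inside the inflammatory branch M-DC8 takes precedence
    over CD1a. DC-lineage labels take precedence over inflammatory ones.
    """
    needed = set(GATING_MARKERS) | {"Viability"}
    missing = sorted(needed - set(thresholds))
    if missing:
        raise ValueError(f"missing threshold(s) for: {missing}")
    t = thresholds

    root = GateNode("all")
    singlets = root.add(GateNode(
        "singlets", RatioGate("FSC-H", "FSC-A", singlet_ratio)))
    live = singlets.add(GateNode(
        "live", Gate("Viability", "-", t["Viability"])))
    mono = live.add(GateNode(
        "mononuclear", RectGate("FSC-A", "SSC-A", *scatter_gate)))

    dc_lin = mono.add(GateNode("dc_lineage", AllOf((
        Gate("Lineage", "-", t["Lineage"]), Gate("CD14", "-", t["CD14"]),
        Gate("CD16", "-", t["CD16"]), Gate("HLA-DR", "+", t["HLA-DR"])))))
    dc_lin.add(GateNode("pDC", AllOf((
        Gate("CD123", "+", t["CD123"]), Gate("CD11c", "-", t["CD11c"]))),
        label="pDC"))
    cdc = dc_lin.add(GateNode("cDC", AllOf((
        Gate("CD123", "-", t["CD123"]), Gate("CD11c", "+", t["CD11c"])))))
    cdc.add(GateNode("cDC1", Gate("CD141", "+", t["CD141"]), label="cDC1"))
    cdc.add(GateNode("cDC2", AllOf((
        Gate("CD1c", "+", t["CD1c"]), Gate("CD141", "-", t["CD141"]))),
        label="cDC2"))

    infl = mono.add(GateNode("inflammatory", AllOf((
        Gate("Lineage", "-", t["Lineage"]), Gate("HLA-DR", "+", t["HLA-DR"]),
        Gate("CD11c", "+", t["CD11c"])))))
    infl.add(GateNode("slanDC", Gate("M-DC8", "+", t["M-DC8"]),
                      label="slanDC"))
    infl.add(GateNode("moDC", AllOf((
        Gate("CD1a", "+", t["CD1a"]), Gate("M-DC8", "-", t["M-DC8"]))),
        label="moDC"))
    return GateTree(root)


@dataclass
class GatingResult:
    """Per-event membership and subset frequencies of one sample."""

    labels: np.ndarray            # terminal DC label per event ('' = none)
    memberships: dict             # node name -> boolean event mask
    frequencies: pd.DataFrame     # subset, count, percent (of mononuclear)
    denominator: int              # mononuclear event count
    metadata: dict = field(default_factory=dict)

    def mask(self, node: str) -> np.ndarray:
        return self.memberships[node]

    def percent(self, subset: str) -> float:
        row = self.frequencies.loc[self.frequencies.subset == subset]
        if row.empty:
            raise KeyError(subset)
        return float(row.percent.iloc[0])


def apply_gate_tree(tree: GateTree, events: EventMatrix) -> GatingResult:
    """Assign each event its deepest satisfied gate path and compute
    subset frequencies on the mononuclear denominator. Terminal labels
    follow the precedence pDC, cDC1, cDC2, slanDC, moDC (first wins)."""
    if not events.metadata.get("transformed"):
        raise ValueError("apply_gate_tree expects transformed events")

    memberships = {}

    def _evaluate(node: GateNode, parent_mask: np.ndarray):
        own = (parent_mask if node.predicate is None
               else parent_mask & node.predicate.evaluate(events))
        memberships[node.name] = own
        for child in node.children:
            _evaluate(child, own)

    _evaluate(tree.root, np.ones(events.n_events, dtype=bool))

    labels = np.full(events.n_events, "", dtype=object)
    label_order = [lb for lb in DC_LABELS if lb in tree.terminal_labels]
    label_order += [lb for lb in tree.terminal_labels
                    if lb not in label_order]
    for lb in label_order:
        node = next(n for n in tree.walk() if n.label == lb)
        mask = memberships[node.name] & (labels == "")
        labels[mask] = lb

    denom = int(memberships["mononuclear"].sum())
    rows = []
    report = list(label_order)
    if "cDC" in memberships:
        report.insert(report.index("cDC1") if "cDC1" in report else 0, "cDC")
    for name in report:
        count = (int((labels == name).sum()) if name != "cDC"
                 else int(memberships["cDC"].sum()))
        rows.append({"subset": name, "count": count,
                     "percent": 100.0 * count / denom if denom else np.nan})
    freq = pd.DataFrame(rows)
    return GatingResult(labels=np.asarray(labels, dtype=str),
                        memberships=memberships, frequencies=freq,
                        denominator=denom,
                        metadata=dict(events.metadata))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_GATE_TYPES = {"Gate": Gate, "RectGate": RectGate, "RatioGate": RatioGate}


def _predicate_to_dict(p):
    if p is None:
        return None
    if isinstance(p, AllOf):
        return {"type": "AllOf",
                "gates": [_predicate_to_dict(g) for g in p.gates]}
    d = {"type": type(p).__name__}
    d.update({k: (list(v) if isinstance(v, tuple) else v)
              for k, v in p.__dict__.items()})
    return d


def _predicate_from_dict(d):
    if d is None:
        return None
    kind = d.pop("type")
    if kind == "AllOf":
        return AllOf(tuple(_predicate_from_dict(g) for g in d["gates"]))
    cls = _GATE_TYPES[kind]
    kwargs = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in d.items()}
    return cls(**kwargs)


def tree_to_text(tree: GateTree) -> str:
    """Serialize a gate tree to a structured text (YAML) document: one
    record per node with name, parent, optional label and predicate."""
    records = []

    def _walk(node, parent):
        records.append({"name": node.name, "parent": parent,
                        "label": node.label,
                        "predicate": _predicate_to_dict(node.predicate)})
        for c in node.children:
            _walk(c, node.name)

    _walk(tree.root, None)
    return yaml.safe_dump(records, sort_keys=False)


def tree_from_text(text: str) -> GateTree:
    records = yaml.safe_load(text)
    nodes = {}
    root = None
    for rec in records:
        node = GateNode(rec["name"],
                        _predicate_from_dict(rec.get("predicate")),
                        label=rec.get("label"))
        nodes[node.name] = node
        parent = rec.get("parent")
        if parent is None:
            root = node
        else:
            nodes[parent].add(node)
    if root is None:
        raise ValueError("gate tree text has no root node")
    return GateTree(root)


def frequencies_to_csv(results: list, path) -> None:
    """Export per-sample subset frequencies as long-format CSV
    (sample metadata + subset, count, percent)."""
    frames = []
    for res in results:
        df = res.frequencies.copy()
        df.insert(0, "donor", res.metadata.get("donor"))
        df.insert(1, "condition", res.metadata.get("condition"))
        df.insert(2, "cohort", res.metadata.get("cohort"))
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
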