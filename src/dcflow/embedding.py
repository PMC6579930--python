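"""Barcoded-concatenation t-SNE analysis of gated cytometry events.

Events gated live/CD45+/lineage-/HLA-DR+ from multiple samples are
barcoded, concatenated and embedded in 2-D with Barnes-Hut t-SNE
(defaults: 800 iterations, perplexity 20, theta 0.5, learning rate 200,
deterministic PCA initialization) on the asinh-transformed, per-marker
standardized intensities of the 15 identity + read-out markers. A
quantitative region-shift statistic (centroid displacement plus a
chance-normalized cross-group k-NN mixing score) makes the visual
"same/different t-SNE region" comparison reproducible; it is an artifact
addition to the visual analysis and is labelled as such in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .events import EventMatrix
from .panel import EMBED_MARKERS


@dataclass(frozen=True)
class TSNEParams:
    """Hyperparameters of the t-SNE run, stored verbatim in results."""

    iterations: int = 800
    perplexity: float = 20.0
    theta: float = 0.5
    eta: float = 200.0
    init: str = "deterministic"   # PCA initialization
    random_state: int = 0


@dataclass
class EventBundle:
    """Concatenated, filtered events with per-event sample barcode and
    carried labels/metadata."""

    events: EventMatrix
    barcode: np.ndarray
    labels: np.ndarray
    condition: np.ndarray
    cohort: np.ndarray

    @property
    def n_events(self) -> int:
        return self.events.n_events

    def take(self, idx: np.ndarray) -> "EventBundle":
        return EventBundle(self.events.subset(idx), self.barcode[idx],
                           self.labels[idx], self.condition[idx],
                           self.cohort[idx])


def barcode_concatenate(samples: list, results: list, thresholds: list,
                        cap: int | None = None, seed: int = 0) -> EventBundle:
    """Filter each gated sample to live, singlet, CD45+, lineage-,
    HLA-DR+ events, assign a unique sample barcode and concatenate.

    ``samples`` are the transformed event matrices the gating ran on;
    ``results`` the matching gating results; ``thresholds`` the matching
    threshold dicts (CD45/Lineage/HLA-DR are pre-filters, not tree
    gates). ``cap`` optionally down-samples each sample uniformly
    (seeded) before concatenation.
    """
    if not (len(samples) == len(results) == len(thresholds)):
        raise ValueError("samples, results and thresholds must align")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    parts = []
    for code, (ev, res, thr) in enumerate(zip(samples, results, thresholds)):
        if "CD45" not in thr:
            raise ValueError("CD45 threshold required for the embedding "
                             "pre-filter")
        mask = (res.mask("live")
                & (ev.get("CD45") >= thr["CD45"])
                & (ev.get("Lineage") < thr["Lineage"])
                & (ev.get("HLA-DR") >= thr["HLA-DR"]))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            warnings.warn(f"sample {code}: no events pass the embedding "
                          "filter; skipped")
            continue
        if cap is not None and idx.size > cap:
            idx = np.sort(rng.choice(idx, size=cap, replace=False))
        parts.append((code, ev, res, idx))
    if not parts:
        raise ValueError("no events pass the embedding filter")

    events = EventMatrix(
        values=np.vstack([ev.values[idx] for _, ev, _, idx in parts]),
        channels=list(parts[0][1].channels),
        markers=list(parts[0][1].markers),
        metadata={**parts[0][1].metadata, "concatenated": True})
    barcode = np.concatenate([np.repeat(code, idx.size)
                              for code, _, _, idx in parts])
    labels = np.concatenate([res.labels[idx] for _, _, res, idx in parts])
    condition = np.concatenate(
        [np.repeat(str(ev.metadata.get("condition", "")), idx.size)
         for _, ev, _, idx in parts])
    cohort = np.concatenate(
        [np.repeat(str(ev.metadata.get("cohort", "")), idx.size)
         for _, ev, _, idx in parts])
    return EventBundle(events, barcode, labels, condition, cohort)


def stratified_downsample(bundle: EventBundle, total: int,
                          seed: int = 0) -> EventBundle:
    """Down-sample to ``total`` events, stratified by gated label: rare
    subsets are retained in full, abundant classes share the remaining
    quota equally (classic balanced allocation). Keeps enough events of
    rare DC subsets for neighbor statistics at desk scale."""
    if bundle.n_events <= total:
        return bundle
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    classes, counts = np.unique(bundle.labels, return_counts=True)
    order = np.argsort(counts, kind="stable")
    quota = {}
    remaining, slots = total, len(classes)
    for i in order:
        share = remaining // slots
        take = min(int(counts[i]), share)
        quota[classes[i]] = take
        remaining -= take
        slots -= 1
    # distribute any leftover to the largest class
    quota[classes[order[-1]]] += remaining
    keep = []
    for cls, q in quota.items():
        idx = np.flatnonzero(bundle.labels == cls)
        if idx.size > q:
            idx = rng.choice(idx, size=q, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return bundle.take(keep)


@dataclass
class EmbeddingResult:
    """2-D embedding coordinates with carried metadata and the verbatim
    hyperparameter record."""

    coordinates: np.ndarray
    barcode: np.ndarray
    labels: np.ndarray
    condition: np.ndarray
    cohort: np.ndarray
    params: dict
    marker_set: tuple

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "event": np.arange(len(self.barcode)),
            "barcode": self.barcode, "subset": self.labels,
            "condition": self.condition, "cohort": self.cohort,
            "tsne_1": self.coordinates[:, 0],
            "tsne_2": self.coordinates[:, 1]})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def embed(bundle: EventBundle, marker_set=EMBED_MARKERS,
          params: TSNEParams = TSNEParams(),
          standardize: bool = True) -> EmbeddingResult:
    """t-SNE embedding of the bundle on the given marker set.

    Features are the transformed intensities, standardized per marker.
    Scatter and viability channels never enter the feature set. With the
    default deterministic (PCA) initialization a fixed input reproduces
    identical coordinates. ``theta == 0`` selects the exact method.
    """
    if not bundle.events.metadata.get("transformed"):
        raise ValueError("embedding expects transformed intensities")
    forbidden = {"FSC-A", "FSC-H", "SSC-A", "Viability"}
    if forbidden & set(marker_set):
        raise ValueError("scatter and viability channels may not enter "
                         "the embedding feature set")
    try:
        cols = [bundle.events.column(m) for m in marker_set]
    except KeyError as exc:
        raise ValueError(f"unknown marker in marker_set: {exc}") from exc
    n = bundle.n_events
    if n < 3 * params.perplexity:
        raise ValueError(f"too few events ({n}) for perplexity "
                         f"{params.perplexity} (need >= 3x)")

    X = bundle.events.values[:, cols]
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    tsne = TSNE(
        n_components=2, perplexity=params.perplexity,
        learning_rate=params.eta, max_iter=params.iterations,
        angle=params.theta,
        method="exact" if params.theta == 0 else "barnes_hut",
        init="pca" if params.init == "deterministic" else params.init,
        random_state=params.random_state)
    coords = np.asarray(tsne.fit_transform(X), dtype=float)
    return EmbeddingResult(coordinates=coords, barcode=bundle.barcode,
                           labels=bundle.labels, condition=bundle.condition,
                           cohort=bundle.cohort, params=asdict(params),
                           marker_set=tuple(marker_set))


# ---------------------------------------------------------------------------
# neighbor statistics
# ---------------------------------------------------------------------------

def knn_label_purity(result: EmbeddingResult, subsets, k: int = 15) -> dict:
    """Leave-one-out k-NN majority-vote accuracy per subset in embedding
    space (non-DC events vote with their own background label), a purity
    measure robust to the extreme rarity of some DC subsets."""
    coords = result.coordinates
    labels = np.where(result.labels == "", "other", result.labels)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh = labels[idx[:, 1:]]  # drop self
    out = {}
    for subset in subsets:
        rows = np.flatnonzero(labels == subset)
        if rows.size == 0:
            out[subset] = float("nan")
            continue
        correct = 0
        for r in rows:
            vals, counts = np.unique(neigh[r], return_counts=True)
            if vals[np.argmax(counts)] == subset:
                correct += 1
        out[subset] = correct / rows.size
    return out


@dataclass(frozen=True)
class ShiftReport:
    """Region-shift statistic between two groups of one subset's events:
    normalized centroid displacement and chance-normalized cross-group
    k-NN mixing (1 = perfectly mixed, 0 = disjoint regions)."""

    subset: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    centroid_shift: float
    mixing: float
    shifted: bool


def region_shift(result: EmbeddingResult, subset: str,
                 group_a: str, group_b: str, group_by: str = "cohort",
                 k: int = 15, min_events: int = 50,
                 mixing_cutoff: float = 0.5) -> ShiftReport:
    """Quantify whether a subset occupies different embedding regions in
    two groups (cohorts or conditions).

    Reports (i) centroid displacement normalized by the pooled
    within-group spread and (ii) the mean fraction of each event's k
    nearest same-subset neighbors that belong to the other group,
    normalized by its expectation under exchangeability. The subset is
    flagged ``shifted`` when mixing falls below ``mixing_cutoff``. The
    statistic is symmetric in the two groups.
    """
    groups = getattr(result, group_by if group_by != "condition"
                     else "condition")
    if group_by == "cohort":
        groups = result.cohort
    elif group_by == "condition":
        groups = result.condition
    elif group_by == "barcode":
        groups = result.barcode.astype(str)
    else:
        raise ValueError(f"unknown grouping {group_by!r}")

    sel = (result.labels == subset) & np.isin(groups, [group_a, group_b])
    coords = result.coordinates[sel]
    is_b = groups[sel] == group_b
    n_a, n_b = int((~is_b).sum()), int(is_b.sum())
    if n_a < min_events or n_b < min_events:
        raise ValueError(
            f"{subset}: need >= {min_events} events per group "
            f"(got {group_a}: {n_a}, {group_b}: {n_b})")

    n = n_a + n_b
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh_b = is_b[idx[:, 1:]]
    frac_other = np.where(is_b, (~neigh_b).mean(axis=1),
                          neigh_b.mean(axis=1))
    chance = np.where(is_b, n_a / (n - 1), n_b / (n - 1))
    mixing = float(np.mean(frac_other / chance))

    ca, cb = coords[~is_b].mean(axis=0), coords[is_b].mean(axis=0)
    spread = np.sqrt(0.5 * (coords[~is_b].var(axis=0).sum()
                            + coords[is_b].var(axis=0).sum()))
    shift = float(np.linalg.norm(ca - cb) / max(spread, 1e-12))
    return ShiftReport(subset=subset, group_a=str(group_a),
                       group_b=str(group_b), n_a=n_a, n_b=n_b,
                       centroid_shift=shift, mixing=mixing,
                       shifted=bool(mixing < mixing_cutoff))
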