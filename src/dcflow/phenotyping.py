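"""Net-MFI read-outs, fold changes and cohort statistics.

Expression of the six read-outs (CD40, CD80, CD86, PD-L1, ILT2, TIM-3) on
a gated subset is summarized as net MFI: the arithmetic mean fluorescence
intensity over subset events on the compensated linear scale, minus the
MFI of the matched fluorescence-minus-one (FMO) control on the same
subset. Treatment effects are expressed as fold change of the net MFI
normalized on the untreated (basal) sample. Cohort comparisons use
classical Student t statistics implemented from their closed forms:
paired tests for within-donor contrasts (between subsets, or treatment
vs basal), unpaired tests for patient-vs-healthy contrasts. No
multiple-testing correction is applied (two-sided p-values are reported
raw); this mirrors the analysis design and is a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import READOUT_MARKERS
from . import gating as _gating
from .compensation import SpilloverMatrix, compensate
from .synthetic import CohortConfig, simulate_fmo, simulate_sample

#: subsets whose phenotype the analysis reports (moDCs are near-absent)
MEASURED_SUBSETS = ("pDC", "cDC1", "cDC2", "slanDC")
#: records with fewer gated events than this are flagged unreliable
MIN_RELIABLE_EVENTS = 30


# ---------------------------------------------------------------------------
# net MFI and fold change
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MFIRecord:
    donor: int
    condition: str
    subset: str
    marker: str
    sample_mfi: float
    fmo_mfi: float
    n_events: int
    n_fmo_events: int
    cohort: str = ""

    @property
    def net_mfi(self) -> float:
        return self.sample_mfi - self.fmo_mfi

    @property
    def reliable(self) -> bool:
        return (self.n_events >= MIN_RELIABLE_EVENTS
                and self.n_fmo_events >= MIN_RELIABLE_EVENTS)


def _labels_of(result) -> np.ndarray:
    return result.labels if hasattr(result, "labels") else np.asarray(result)


def net_mfi(sample_events, sample_result, fmo_events, fmo_result,
            subset: str, marker: str, statistic: str = "mean") -> MFIRecord:
    """Net MFI of ``marker`` on ``subset``: subset-mean intensity in the
    stained sample minus the same statistic in the matched FMO control.

    Intensities must be compensated and on the linear scale; negative net
    MFI is retained. ``statistic`` may be ``mean`` (default, matching the
    "mean fluorescence intensity" read-out) or ``median``.
    """
    for ev in (sample_events, fmo_events):
        if ev.metadata.get("transformed"):
            raise ValueError("net MFI is computed on the linear scale")
        if not ev.metadata.get("compensated"):
            raise ValueError("net MFI requires compensated events")
    fmo_type = fmo_events.metadata.get("control_type", "")
    if fmo_type != f"FMO:{marker}":
        raise ValueError(f"FMO control {fmo_type!r} does not match "
                         f"marker {marker!r}")
    if marker not in READOUT_MARKERS:
        raise ValueError(f"{marker!r} is not a read-out marker")
    stat = {"mean": np.mean, "median": np.median}[statistic]

    masks = []
    for ev, res in ((sample_events, sample_result), (fmo_events, fmo_result)):
        mask = _labels_of(res) == subset
        if not mask.any():
            raise ValueError(f"no events gated as {subset!r}")
        masks.append(mask)

    return MFIRecord(
        donor=sample_events.metadata.get("donor", -1),
        condition=sample_events.metadata.get("condition", ""),
        cohort=sample_events.metadata.get("cohort", ""),
        subset=subset, marker=marker,
        sample_mfi=float(stat(sample_events.get(marker)[masks[0]])),
        fmo_mfi=float(stat(fmo_events.get(marker)[masks[1]])),
        n_events=int(masks[0].sum()), n_fmo_events=int(masks[1].sum()))


def fold_change(record_condition: MFIRecord, record_basal: MFIRecord,
                floor: float = 0.0) -> float:
    """Fold change of the net MFI normalized on the untreated sample.

    Returns NaN (flagged undefined) when the basal net MFI is at or below
    the positivity ``floor``; callers exclude undefined ratios listwise.
    """
    for attr in ("donor", "subset", "marker"):
        if getattr(record_condition, attr) != getattr(record_basal, attr):
            raise ValueError(f"records differ in {attr}")
    if record_basal.net_mfi <= floor:
        return float("nan")
    return record_condition.net_mfi / record_basal.net_mfi


# ---------------------------------------------------------------------------
# t statistics (closed forms)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    contrast: str
    statistic: float
    df: float
    p_value: float
    paired: bool
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int
    degenerate: bool = False


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan


def paired_t_test(x, y, contrast: str = "") -> ComparisonResult:
    """Two-sided paired Student t test: t = mean(d) / (sd(d)/sqrt(n)),
    d = x - y, df = n - 1. Zero-variance differences yield an undefined
    statistic flagged ``degenerate`` rather than a silent p of 1."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("paired t test needs n >= 2 pairs")
    d = x - y
    sd = np.std(d, ddof=1)
    base = dict(contrast=contrast, paired=True, df=float(n - 1),
                mean_a=float(np.mean(x)), sem_a=_sem(x),
                mean_b=float(np.mean(y)), sem_b=_sem(y), n_a=n, n_b=n)
    if sd == 0:
        return ComparisonResult(statistic=np.nan, p_value=np.nan,
                                degenerate=True, **base)
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return ComparisonResult(statistic=t, p_value=p, **base)


def unpaired_t_test(x, y, contrast: str = "") -> ComparisonResult:
    """Two-sided unpaired Student t test with pooled variance,
    df = n_x + n_y - 2."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("unpaired t test needs >= 2 observations per group")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    df = nx + ny - 2
    pooled = ((nx - 1) * vx + (ny - 1) * vy) / df
    base = dict(contrast=contrast, paired=False, df=float(df),
                mean_a=float(np.mean(x)), sem_a=_sem(x),
                mean_b=float(np.mean(y)), sem_b=_sem(y), n_a=nx, n_b=ny)
    if pooled == 0:
        return ComparisonResult(statistic=np.nan, p_value=np.nan,
                                degenerate=True, **base)
    t = float((np.mean(x) - np.mean(y))
              / np.sqrt(pooled * (1.0 / nx + 1.0 / ny)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return ComparisonResult(statistic=t, p_value=p, **base)


def _comparison_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def summarize(records: pd.DataFrame,
              value: str = "net_mfi",
              grouping=("cohort", "subset", "marker", "condition")
              ) -> pd.DataFrame:
    """Mean +/- SEM per grouping cell."""
    grouping = [g for g in grouping if g in records.columns]
    out = (records.groupby(grouping, sort=False)[value]
           .agg(mean="mean", sem=lambda x: _sem(np.asarray(x)), n="count")
           .reset_index())
    if out["n"].min() == 0:
        raise ValueError("empty grouping cell")
    return out


def _paired_vectors(records, subset, marker, cond_a, cond_b,
                    value="net_mfi"):
    sel = records[(records.subset == subset) & (records.marker == marker)]
    a = sel[sel.condition == cond_a].set_index("donor")[value]
    b = sel[sel.condition == cond_b].set_index("donor")[value]
    donors = a.index.intersection(b.index)
    pair = pd.DataFrame({"a": a.loc[donors], "b": b.loc[donors]}).dropna()
    return pair["a"].to_numpy(), pair["b"].to_numpy()


def condition_contrasts(records: pd.DataFrame,
                        value: str = "net_mfi") -> pd.DataFrame:
    """Paired within-donor contrasts: every condition vs basal, and each
    TLR ligand vs its TLR+IL-10 combination."""
    pairs = [(c, "basal") for c in records.condition.unique()
             if c != "basal"]
    for tlr in ("LPS", "IMQ"):
        combo = f"{tlr}+IL10"
        if {tlr, combo} <= set(records.condition.unique()):
            pairs.append((combo, tlr))
    out = []
    for subset in records.subset.unique():
        for marker in records.marker.unique():
            for ca, cb in pairs:
                x, y = _paired_vectors(records, subset, marker, ca, cb,
                                       value)
                if len(x) >= 2:
                    out.append(paired_t_test(
                        x, y, contrast=f"{subset}/{marker}: {ca} vs {cb}"))
    return _comparison_frame(out)


def subset_contrasts(records: pd.DataFrame, condition: str = "basal",
                     value: str = "net_mfi") -> pd.DataFrame:
    """Paired between-subset contrasts of each marker at one condition."""
    sel = records[records.condition == condition]
    subsets = [s for s in MEASURED_SUBSETS if s in set(sel.subset)]
    out = []
    for marker in sel.marker.unique():
        for i, sa in enumerate(subsets):
            for sb in subsets[i + 1:]:
                a = sel[(sel.subset == sa) & (sel.marker == marker)]
                b = sel[(sel.subset == sb) & (sel.marker == marker)]
                pair = pd.merge(a[["donor", value]], b[["donor", value]],
                                on="donor", suffixes=("_a", "_b")).dropna()
                if len(pair) >= 2:
                    out.append(paired_t_test(
                        pair[f"{value}_a"], pair[f"{value}_b"],
                        contrast=f"{marker} @ {condition}: {sa} vs {sb}"))
    return _comparison_frame(out)


def cohort_contrasts(records_a: pd.DataFrame, records_b: pd.DataFrame,
                     value: str = "net_mfi") -> pd.DataFrame:
    """Unpaired contrasts between two cohorts per subset x marker x
    condition (e.g. MDS patients vs healthy donors). Undefined values
    (NaN fold changes) are excluded listwise per donor."""
    keys = ["subset", "marker", "condition"]
    out = []
    for key, sel_a in records_a.groupby(keys, sort=False):
        sel_b = records_b
        for k, v in zip(keys, key):
            sel_b = sel_b[sel_b[k] == v]
        x = sel_a[value].dropna().to_numpy()
        y = sel_b[value].dropna().to_numpy()
        if len(x) >= 2 and len(y) >= 2:
            out.append(unpaired_t_test(
                x, y, contrast="/".join(map(str, key))
                + f" ({records_a.cohort.iloc[0]} vs "
                  f"{records_b.cohort.iloc[0]})"))
    return _comparison_frame(out)


def cohort_summary(records: pd.DataFrame,
                   other_cohort: pd.DataFrame | None = None) -> dict:
    """The full analysis table set for one cohort (optionally contrasted
    against a second cohort): mean +/- SEM summaries plus the paired
    vs-basal / TLR-vs-TLR+IL-10 / between-subset contrasts, and unpaired
    cohort contrasts on both net MFI and fold change when a second cohort
    is given."""
    out = {
        "summary": summarize(records),
        "condition_contrasts": condition_contrasts(records),
        "subset_contrasts": subset_contrasts(records),
    }
    if other_cohort is not None:
        out["cohort_contrasts_net_mfi"] = cohort_contrasts(
            records, other_cohort, value="net_mfi")
        fc_a = records[records.condition != "basal"]
        fc_b = other_cohort[other_cohort.condition != "basal"]
        out["cohort_contrasts_fold_change"] = cohort_contrasts(
            fc_a, fc_b, value="fold_change")
    return out


# ---------------------------------------------------------------------------
# cohort driver
# ---------------------------------------------------------------------------

def phenotype_cohort(config: CohortConfig, seed: int,
                     n_events: int | None = None,
                     n_fmo_events: int = 20_000,
                     conditions=None,
                     subsets=MEASURED_SUBSETS,
                     markers=READOUT_MARKERS,
                     spillover: SpilloverMatrix | None = None,
                     donors: int | None = None) -> pd.DataFrame:
    """Simulate, compensate and gate a whole cohort and return the long-
    format net-MFI / fold-change record table.

    FMO controls are simulated once per donor and read-out marker (the
    omitted marker's background does not depend on the stimulation), and
    evaluated with their own data-derived gating thresholds. If no
    spillover matrix is given the config's ground truth is used.
    """
    spill = spillover or SpilloverMatrix(config.spillover,
                                         list(config.panel.detectors))
    cond_names = conditions or [c.name for c in config.conditions]
    rows = []
    for donor in range(min(donors or config.n_donors, config.n_donors)):
        fmos = {}
        for marker in markers:
            ev = simulate_fmo(config, donor, "basal", marker,
                              seed=seed, n_events=n_fmo_events)
            ev = compensate(ev, spill)
            tr = _gating.transform_for_gating(ev)
            res = _gating.apply_gate_tree(
                _gating.build_dc_gate_tree(
                    _gating.derive_gating_thresholds(tr)), tr)
            fmos[marker] = (ev, res)
        per_condition = {}
        for cond in cond_names:
            ev = simulate_sample(config, donor, cond, seed=seed,
                                 n_events=n_events)
            ev = compensate(ev, spill)
            tr = _gating.transform_for_gating(ev)
            res = _gating.apply_gate_tree(
                _gating.build_dc_gate_tree(
                    _gating.derive_gating_thresholds(tr)), tr)
            per_condition[cond] = (ev, res)
        for subset in subsets:
            for marker in markers:
                recs = {}
                for cond in cond_names:
                    ev, res = per_condition[cond]
                    fmo_ev, fmo_res = fmos[marker]
                    try:
                        recs[cond] = net_mfi(ev, res, fmo_ev, fmo_res,
                                             subset, marker)
                    except ValueError:
                        recs[cond] = None
                basal = recs.get("basal")
                for cond, rec in recs.items():
                    if rec is None:
                        continue
                    fc = (1.0 if cond == "basal" else
                          (fold_change(rec, basal)
                           if basal is not None else float("nan")))
                    rows.append({
                        "cohort": config.cohort, "donor": donor,
                        "condition": cond, "subset": subset,
                        "marker": marker, "sample_mfi": rec.sample_mfi,
                        "fmo_mfi": rec.fmo_mfi, "net_mfi": rec.net_mfi,
                        "n_events": rec.n_events,
                        "reliable": rec.reliable, "fold_change": fc})
    return pd.DataFrame(rows)
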