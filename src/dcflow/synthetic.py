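"""Synthetic whole-blood cytometry sample generator with known ground truth.

Emulates erythrocyte-lysed whole blood acquired on an 18-fluorescence-
parameter panel: T/B/NK cells, monocytes, residual granulocytes, debris,
dead cells, doublets, and six dendritic-cell populations (pDC, cDC1, cDC2,
a CD141-/CD1c- "double-negative" cDC remainder, slanDC, moDC) at the
frequencies reported for healthy mononuclear cells. Marker expression is a
two-state model: an "off" state drawn from a normal autofluorescence
background and an "on" state drawn from a log-normal with configurable
mean (the true MFI) and CV. True signals are mixed through a ground-truth
spillover matrix to produce raw detector values.

Stimulation conditions (LPS, IMQ, IL-10 and combinations) act as
multiplicative shifts on the on-state means of the costimulatory and
checkpoint read-outs; an MDS cohort mode reduces DC frequencies, applies
the disease's basal phenotype shifts and attenuates TLR responses.

All draws are reproducible from ``(config, donor, condition, seed)``;
every (population-block, channel) pair uses its own RNG stream so that an
FMO sample differs from its paired full-stain sample only in the omitted
marker's pre-mixing signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .events import EventMatrix
from .panel import (PanelDefinition, READOUT_MARKERS, SCATTER_CHANNELS,
                    default_panel)

# ---------------------------------------------------------------------------
# defaults: composition, phenotypes, stimulation effects
# ---------------------------------------------------------------------------

DC_SUBSETS = ("pDC", "cDC1", "cDC2", "slanDC", "moDC")
#: DC populations carried by the generator (cDC_other fills the gap between
#: total cDC and cDC1+cDC2 in the total-cDC gate)
DC_POPULATIONS = ("pDC", "cDC1", "cDC2", "cDC_other", "slanDC", "moDC")

#: fractions of live single mononuclear events (healthy cohort means)
HEALTHY_FREQUENCIES = {
    "T": 0.60, "B": 0.10, "NK": 0.09, "monocyte": 0.18, "other": 0.01699,
    "pDC": 0.0044, "cDC1": 0.0002, "cDC2": 0.0049, "cDC_other": 0.0028,
    "slanDC": 0.0007, "moDC": 0.00001,
}

#: between-donor CV of the population frequencies; DC spreads chosen so a
#: 16-donor cohort SEM has the order of magnitude of the reported +/- values
DONOR_FREQUENCY_CV = {
    "T": 0.10, "B": 0.10, "NK": 0.10, "monocyte": 0.10, "other": 0.10,
    "pDC": 0.50, "cDC1": 0.80, "cDC2": 0.25, "cDC_other": 0.40,
    "slanDC": 0.80, "moDC": 0.50,
}

#: fractions of total acquired events
CONTAMINANTS = {"dead": 0.05, "doublet": 0.02,
                "granulocyte": 0.01, "debris": 0.02}

BACKGROUND = (120.0, 55.0)      # autofluorescence off-state (mean, sd)
ON_STATE_CV = 0.5               # log-normal CV of on-state expression
DONOR_EXPRESSION_CV = 0.20      # between-donor CV of read-out on-state means
VIABILITY_ON = 15000.0          # dead-cell viability-stain intensity

#: ((FSC-A mean, sd), (SSC-A mean, sd)) per population class
_SCATTER = {
    "lymphoid": ((50000, 8000), (12000, 4000)),
    "dc": ((75000, 8000), (18000, 5000)),
    "monocyte": ((80000, 10000), (35000, 8000)),
    "granulocyte": ((70000, 10000), (100000, 10000)),
    "debris": ((10000, 4000), (4000, 2000)),
}

#: identity / lineage marker on-state means per population (off if absent)
_IDENTITY = {
    "T": {"CD45": 20000, "Lineage": 25000},
    "B": {"CD45": 20000, "Lineage": 25000, "HLA-DR": 6000},
    "NK": {"CD45": 20000, "Lineage": 18000, "CD16": 12000},
    "monocyte": {"CD45": 25000, "CD14": 30000, "HLA-DR": 8000,
                 "CD11c": 15000},
    "other": {"CD45": 15000},
    "granulocyte": {"CD45": 8000, "CD16": 20000},
    "debris": {},
    "pDC": {"CD45": 20000, "HLA-DR": 20000, "CD123": 20000},
    "cDC1": {"CD45": 20000, "HLA-DR": 20000, "CD11c": 15000,
             "CD141": 15000},
    "cDC2": {"CD45": 20000, "HLA-DR": 20000, "CD11c": 15000, "CD1c": 15000},
    "cDC_other": {"CD45": 20000, "HLA-DR": 20000, "CD11c": 15000},
    "slanDC": {"CD45": 20000, "HLA-DR": 15000, "CD11c": 15000,
               "CD16": 8000, "M-DC8": 12000},
    "moDC": {"CD45": 20000, "HLA-DR": 15000, "CD11c": 15000, "CD14": 10000,
             "CD1a": 12000},
}

_SCATTER_CLASS = {
    "T": "lymphoid", "B": "lymphoid", "NK": "lymphoid", "other": "lymphoid",
    "monocyte": "monocyte", "granulocyte": "granulocyte", "debris": "debris",
    **{p: "dc" for p in DC_POPULATIONS},
}

#: basal on-state means of the six read-outs per DC population. Absolute
#: scales are free parameters (the source figures print none); orderings
#: follow the reported subset comparisons: CD40/CD86 lowest on pDCs,
#: CD40 higher and CD86 lower on cDC1s than cDC2s, slanDCs above cDC2s;
#: CD80 negligible everywhere; PD-L1 low on slanDCs and negligible
#: elsewhere; ILT2 absent on cDC1s, highest on slanDCs; TIM-3 highest on
#: cDC1s and lowest on pDCs.
BASAL_READOUT = {
    "pDC": {"CD40": 300, "CD80": 250, "CD86": 400,
            "PD-L1": 200, "ILT2": 800, "TIM-3": 300},
    "cDC1": {"CD40": 1500, "CD80": 250, "CD86": 700,
             "PD-L1": 200, "ILT2": 170, "TIM-3": 3000},
    "cDC2": {"CD40": 800, "CD80": 250, "CD86": 1500,
             "PD-L1": 200, "ILT2": 900, "TIM-3": 1000},
    "cDC_other": {"CD40": 800, "CD80": 250, "CD86": 1200,
                  "PD-L1": 200, "ILT2": 900, "TIM-3": 1000},
    "slanDC": {"CD40": 1600, "CD80": 250, "CD86": 2500,
               "PD-L1": 500, "ILT2": 1800, "TIM-3": 900},
    "moDC": {"CD40": 800, "CD80": 250, "CD86": 1500,
             "PD-L1": 200, "ILT2": 900, "TIM-3": 1000},
}

CONDITION_NAMES = ("basal", "LPS", "IMQ", "IL10", "LPS+IL10", "IMQ+IL10")

#: TLR-ligand effect maps: multiplicative shifts of the on-state means.
#: Directions follow the reported responses: LPS fully activates cDCs and
#: slanDCs with only marginal pDC activation; IMQ induces its highest CD40
#: upregulation on pDCs; CD80/CD86 upregulation is higher on cDC2s than
#: cDC1s; PD-L1 rises on all subsets (highest slanDC, lowest cDC1); ILT2
#: rises on cDC2s but not cDC1s; TIM-3 is unaffected.
_LPS = {
    "pDC": {"CD40": 1.3, "CD80": 1.2, "CD86": 1.3,
            "PD-L1": 3.0, "ILT2": 2.0, "TIM-3": 1.0},
    "cDC1": {"CD40": 2.5, "CD80": 4.0, "CD86": 3.0,
             "PD-L1": 2.0, "ILT2": 1.0, "TIM-3": 1.0},
    "cDC2": {"CD40": 3.0, "CD80": 8.0, "CD86": 6.0,
             "PD-L1": 6.0, "ILT2": 2.5, "TIM-3": 1.0},
    "slanDC": {"CD40": 2.5, "CD80": 5.0, "CD86": 4.0,
               "PD-L1": 8.0, "ILT2": 2.0, "TIM-3": 1.0},
}
_IMQ = {
    "pDC": {"CD40": 5.0, "CD80": 2.0, "CD86": 2.5,
            "PD-L1": 4.0, "ILT2": 2.2, "TIM-3": 1.0},
    "cDC1": {"CD40": 2.0, "CD80": 3.0, "CD86": 2.5,
             "PD-L1": 1.8, "ILT2": 1.0, "TIM-3": 1.0},
    "cDC2": {"CD40": 2.5, "CD80": 6.0, "CD86": 5.0,
             "PD-L1": 5.0, "ILT2": 2.2, "TIM-3": 1.0},
    "slanDC": {"CD40": 2.0, "CD80": 4.0, "CD86": 3.5,
               "PD-L1": 7.0, "ILT2": 1.8, "TIM-3": 1.0},
}
#: IL-10 alone scarcely affects costimulatory molecules; mildly raises
#: the checkpoints
_IL10 = {s: {"CD40": 1.0, "CD80": 1.0, "CD86": 1.0,
             "PD-L1": 1.2, "ILT2": 1.1, "TIM-3": 1.0}
         for s in ("pDC", "cDC1", "cDC2", "slanDC")}

#: MDS basal phenotype: activated cDC2s (CD86, ILT2 up) and a subverted
#: cDC1 checkpoint repertoire (ILT2 hugely up, TIM-3 down to cDC2-like
#: levels, CD141/CD86 up)
MDS_BASAL_OVERRIDES = {
    ("cDC2", "CD86"): 1.6, ("cDC2", "ILT2"): 1.5, ("cDC2", "CD40"): 1.2,
    ("pDC", "CD86"): 1.2,
    ("cDC1", "ILT2"): 10.0, ("cDC1", "TIM-3"): 1.0 / 3.0,
    ("cDC1", "CD141"): 1.6, ("cDC1", "CD86"): 2.0,
}
MDS_FREQUENCY_FACTOR = 0.35      # DC reduction in MDS blood
MDS_RESPONSE_ATTENUATION = 0.45  # TLR hyporesponsiveness: m -> 1+0.45(m-1)


def _expand(effect: dict) -> dict:
    """Extend a four-subset effect map to cDC_other/moDC (cDC2-like)."""
    out = {k: dict(v) for k, v in effect.items()}
    out["cDC_other"] = dict(effect["cDC2"])
    out["moDC"] = dict(effect["cDC2"])
    return out


def _combine_with_il10(tlr: dict) -> dict:
    """TLR + IL-10: costimulatory upregulation partially reverted
    (half-way back to basal), checkpoint upregulation further enhanced."""
    out = {}
    for subset, mm in tlr.items():
        out[subset] = {}
        for marker, m in mm.items():
            if marker in ("CD40", "CD80", "CD86"):
                out[subset][marker] = 1.0 + 0.5 * (m - 1.0)
            elif marker in ("PD-L1", "ILT2"):
                out[subset][marker] = m * 1.5
            else:
                out[subset][marker] = m
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulationCondition:
    """A whole-blood stimulation condition and its per-(subset, marker)
    multiplicative shifts of on-state read-out means."""

    name: str
    effect_map: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name == "basal" and any(
                m != 1.0 for mm in self.effect_map.values()
                for m in mm.values()):
            raise ValueError("basal condition must have all multipliers 1")
        for mm in self.effect_map.values():
            for m in mm.values():
                if not m > 0:
                    raise ValueError("multipliers must be positive")

    def multiplier(self, population: str, marker: str) -> float:
        return self.effect_map.get(population, {}).get(marker, 1.0)


def default_conditions() -> list:
    lps, imq, il10 = _expand(_LPS), _expand(_IMQ), _expand(_IL10)
    return [
        StimulationCondition("basal", {}),
        StimulationCondition("LPS", lps),
        StimulationCondition("IMQ", imq),
        StimulationCondition("IL10", il10),
        StimulationCondition("LPS+IL10", _combine_with_il10(lps)),
        StimulationCondition("IMQ+IL10", _combine_with_il10(imq)),
    ]


@dataclass(frozen=True)
class PopulationSpec:
    """One cell population: its frequency among live single mononuclear
    events, bivariate scatter model and per-marker two-state expression
    model (``expression[marker]`` = on-state mean, or absent = off)."""

    name: str
    frequency: float
    scatter_model: tuple
    expression: dict

    def __post_init__(self):
        if not 0 <= self.frequency <= 1:
            raise ValueError("frequency must be in [0, 1]")
        for marker, loc in self.expression.items():
            if loc is not None and loc <= BACKGROUND[0]:
                raise ValueError(
                    f"{self.name}/{marker}: on-state mean must exceed the "
                    "autofluorescence background")


@dataclass(frozen=True)
class CohortConfig:
    """Generative configuration of a donor cohort."""

    cohort: str                      # "healthy" | "MDS"
    n_donors: int
    populations: tuple               # mononuclear PopulationSpecs, sum to 1
    conditions: tuple
    seed: int
    panel: PanelDefinition = field(default_factory=default_panel)
    contaminants: dict = field(default_factory=lambda: dict(CONTAMINANTS))
    donor_frequency_cv: dict = field(
        default_factory=lambda: dict(DONOR_FREQUENCY_CV))
    donor_expression_cv: float = DONOR_EXPRESSION_CV
    on_cv: float = ON_STATE_CV
    background: tuple = BACKGROUND
    basal_overrides: dict = field(default_factory=dict)
    response_attenuation: float = 1.0
    n_events: int = 200_000
    spillover: np.ndarray | None = None

    def __post_init__(self):
        total = sum(p.frequency for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population frequencies sum to {total}, not 1")
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if self.spillover is None:
            object.__setattr__(
                self, "spillover",
                default_spillover(self.panel.n_fluorescence, self.seed))

    # -- lookups ---------------------------------------------------------
    @property
    def population_names(self) -> list:
        return [p.name for p in self.populations]

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def condition(self, name: str):
        for c in self.conditions:
            if c.name == name:
                return c
        raise ValueError(f"unknown condition {name!r}; "
                         f"known: {[c.name for c in self.conditions]}")

    def base_frequency(self, name: str) -> float:
        return self.population(name).frequency

    # -- per-donor ground-truth parameters -------------------------------
    def donor_frequencies(self, donor: int) -> dict:
        """True population frequencies of one donor (sum to 1).

        Donor factors are a quantile-balanced log-normal sample: the
        ``n_donors`` factors per population are the permuted quantile
        midpoints of the configured log-normal spread, normalized to unit
        mean, so the cohort is representative of the configured
        distribution (cohort SD matches the CV; cohort-mean truth equals
        the configured frequency up to renormalization).
        """
        self._check_donor(donor)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.seed), 101]))
        freqs = {}
        for i, pop in enumerate(self.populations):
            cv = self.donor_frequency_cv.get(pop.name, 0.1)
            sigma = np.sqrt(np.log1p(cv ** 2))
            perm = rng.permutation(self.n_donors)
            q = (perm + 0.5) / self.n_donors
            factors = np.exp(-0.5 * sigma ** 2 + sigma * sps.norm.ppf(q))
            factors /= factors.mean()
            freqs[pop.name] = pop.frequency * factors[donor]
        total = sum(freqs.values())
        return {k: v / total for k, v in freqs.items()}

    def donor_expression_factor(self, donor: int, population: str,
                                marker: str) -> float:
        """Between-donor multiplicative factor on a read-out on-state mean
        (shared across conditions, so fold changes cancel it)."""
        self._check_donor(donor)
        if marker not in READOUT_MARKERS:
            return 1.0
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(self.seed), 202, int(donor)]))
        cv = self.donor_expression_cv
        sigma = np.sqrt(np.log1p(cv ** 2))
        factor = 1.0
        for pop in DC_POPULATIONS:
            for m in READOUT_MARKERS:
                f = float(np.exp(rng.normal(-0.5 * sigma ** 2, sigma)))
                if pop == population and m == marker:
                    factor = f
        return factor

    def on_state_mean(self, donor: int, condition, population: str,
                      marker: str) -> float:
        """Ground-truth on-state mean for (donor, condition, population,
        marker), including disease overrides, donor factor and the
        (possibly attenuated) stimulation multiplier."""
        if isinstance(condition, str):
            condition = self.condition(condition)
        pop = self.population(population)
        loc = pop.expression.get(marker)
        if loc is None:
            raise KeyError(f"{population} does not express {marker}")
        loc = float(loc) * self.basal_overrides.get((population, marker), 1.0)
        mult = condition.multiplier(population, marker)
        mult = 1.0 + self.response_attenuation * (mult - 1.0)
        return loc * mult * self.donor_expression_factor(
            donor, population, marker)

    def _check_donor(self, donor: int) -> None:
        if not 0 <= donor < self.n_donors:
            raise ValueError(f"donor index {donor} out of range "
                             f"(n_donors={self.n_donors})")


# ---------------------------------------------------------------------------
# config constructors
# ---------------------------------------------------------------------------

def default_spillover(n_channels: int, seed: int) -> np.ndarray:
    """Ground-truth spillover: identity plus sparse off-diagonals in
    [0, 0.2] (Bernoulli(0.3) occupancy, seeded); per-row off-diagonal sums
    capped at 0.8 to keep the matrix well-conditioned."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 777]))
    mask = rng.random((n_channels, n_channels)) < 0.3
    mag = rng.uniform(0.0, 0.2, size=(n_channels, n_channels))
    spill = np.where(mask, mag, 0.0)
    np.fill_diagonal(spill, 0.0)
    row_sums = spill.sum(axis=1)
    over = row_sums > 0.8
    spill[over] *= (0.8 / row_sums[over])[:, None]
    np.fill_diagonal(spill, 1.0)
    return spill


def _build_populations(frequencies: dict,
                       basal_readout: dict) -> tuple:
    pops = []
    for name, freq in frequencies.items():
        expr = dict(_IDENTITY[name])
        if name in DC_POPULATIONS:
            expr.update(basal_readout[name])
        pops.append(PopulationSpec(
            name=name, frequency=freq,
            scatter_model=_SCATTER[_SCATTER_CLASS[name]],
            expression=expr))
    return tuple(pops)


def build_default_healthy_config(seed: int = 0,
                                 n_events: int = 200_000) -> CohortConfig:
    """Default 16-donor healthy cohort whose ground-truth mononuclear
    composition encodes the reported cohort means: pDC 0.44%, total cDC
    0.79% (cDC1 0.02% + cDC2 0.49% + 0.28% double-negative cDCs), slanDC
    0.07%, moDC ~0 ("almost undetectable")."""
    return CohortConfig(
        cohort="healthy", n_donors=16,
        populations=_build_populations(HEALTHY_FREQUENCIES, BASAL_READOUT),
        conditions=tuple(default_conditions()),
        seed=int(seed), n_events=int(n_events))


def build_default_mds_config(seed: int = 0,
                             n_events: int = 200_000) -> CohortConfig:
    """Default 10-patient MDS cohort: DC frequencies reduced, cDC2
    basally activated (CD86/ILT2 up), cDC1 checkpoint repertoire subverted
    (ILT2 up, TIM-3 down), TLR responses attenuated."""
    freqs = dict(HEALTHY_FREQUENCIES)
    moved = 0.0
    for name in DC_POPULATIONS:
        reduced = freqs[name] * MDS_FREQUENCY_FACTOR
        moved += freqs[name] - reduced
        freqs[name] = reduced
    freqs["T"] += moved  # keep the composition normalized
    return CohortConfig(
        cohort="MDS", n_donors=10,
        populations=_build_populations(freqs, BASAL_READOUT),
        conditions=tuple(default_conditions()),
        seed=int(seed), n_events=int(n_events),
        basal_overrides=dict(MDS_BASAL_OVERRIDES),
        response_attenuation=MDS_RESPONSE_ATTENUATION)


def with_population_frequencies(config: CohortConfig,
                                overrides: dict,
                                filler: str = "T") -> CohortConfig:
    """Return a config with selected population frequencies replaced; the
    difference is absorbed by the ``filler`` population. Convenience for
    studies needing enriched rare subsets."""
    freqs = {p.name: p.frequency for p in config.populations}
    for name, f in overrides.items():
        if name not in freqs:
            raise KeyError(name)
        freqs[name] = f
    freqs[filler] = 1.0 - sum(v for k, v in freqs.items() if k != filler)
    if freqs[filler] < 0:
        raise ValueError("override frequencies exceed 1")
    pops = tuple(replace(config.population(n), frequency=f)
                 for n, f in freqs.items())
    return replace(config, populations=pops)


# ---------------------------------------------------------------------------
# event generation
# ---------------------------------------------------------------------------

def _lognormal(rng, mean: float, cv: float, size: int) -> np.ndarray:
    sigma = np.sqrt(np.log1p(cv ** 2))
    mu = np.log(mean) - 0.5 * sigma ** 2
    return rng.lognormal(mu, sigma, size=size)


def _draw_block(config: CohortConfig, pop: PopulationSpec, n: int,
                donor: int, condition: StimulationCondition,
                key: list, omit: str | None,
                force_dead: bool) -> tuple:
    """Draw true (pre-mixing) fluorescence and scatter for ``n`` events of
    one population. ``key`` is the RNG stream prefix; each channel gets an
    independent substream so omitting one marker (FMO) leaves every other
    channel's draw bit-identical."""
    markers = config.panel.marker_names
    bg_mean, bg_sd = config.background
    fluor = np.empty((n, len(markers)))
    for j, marker in enumerate(markers):
        rng = np.random.default_rng(np.random.SeedSequence(key + [j]))
        loc = pop.expression.get(marker)
        on = loc is not None and marker != omit
        if marker == "Viability":
            on = force_dead
            loc = VIABILITY_ON
        if on:
            if marker == "Viability":
                mean = VIABILITY_ON
            elif pop.name in config.population_names:
                mean = config.on_state_mean(donor, condition,
                                            pop.name, marker)
            else:  # contaminant populations (granulocyte, debris)
                mean = float(loc)
            fluor[:, j] = _lognormal(rng, mean, config.on_cv, n)
        else:
            fluor[:, j] = rng.normal(bg_mean, bg_sd, size=n)

    (fm, fs), (sm, ss) = pop.scatter_model
    rng = np.random.default_rng(np.random.SeedSequence(key + [900]))
    fsc_a = np.clip(rng.normal(fm, fs, size=n), 0, None)
    rng = np.random.default_rng(np.random.SeedSequence(key + [901]))
    ssc_a = np.clip(rng.normal(sm, ss, size=n), 0, None)
    rng = np.random.default_rng(np.random.SeedSequence(key + [902]))
    fsc_h = np.clip(fsc_a * rng.normal(0.95, 0.02, size=n), 0, None)
    scatter = np.column_stack([fsc_a, fsc_h, ssc_a])
    return fluor, scatter


def _simulate(config: CohortConfig, donor: int, condition, seed: int,
              omit: str | None = None,
              n_events: int | None = None) -> EventMatrix:
    if isinstance(condition, str):
        condition = config.condition(condition)
    elif condition not in config.conditions:
        raise ValueError(f"unknown condition {condition.name!r}")
    config._check_donor(donor)
    cond_idx = [c.name for c in config.conditions].index(condition.name)
    n = int(n_events or config.n_events)

    n_dead = int(round(config.contaminants["dead"] * n))
    n_doub = int(round(config.contaminants["doublet"] * n))
    n_gran = int(round(config.contaminants["granulocyte"] * n))
    n_debris = int(round(config.contaminants["debris"] * n))
    n_mono = n - n_dead - n_doub - n_gran - n_debris

    freqs = config.donor_frequencies(donor)
    names = config.population_names
    p = np.array([freqs[nm] for nm in names])
    base = [int(seed), int(donor), cond_idx]
    rng_counts = np.random.default_rng(np.random.SeedSequence(base + [0]))
    counts_live = rng_counts.multinomial(n_mono, p)
    counts_dead = rng_counts.multinomial(n_dead, p)
    counts_comp = rng_counts.multinomial(2 * n_doub, p)

    blocks, labels = [], []

    def add(fluor, scatter, label):
        blocks.append((fluor, scatter))
        labels.append(np.repeat(label, fluor.shape[0]))

    for i, nm in enumerate(names):
        if counts_live[i]:
            f, s = _draw_block(config, config.population(nm), counts_live[i],
                               donor, condition, base + [1, i], omit, False)
            add(f, s, nm)
    for i, nm in enumerate(names):
        if counts_dead[i]:
            f, s = _draw_block(config, config.population(nm), counts_dead[i],
                               donor, condition, base + [2, i], omit, True)
            add(f, s, "dead")

    # doublets: sum two random singlets (areas add; height is the larger)
    if n_doub:
        comp_f, comp_s = [], []
        for i, nm in enumerate(names):
            if counts_comp[i]:
                f, s = _draw_block(config, config.population(nm),
                                   counts_comp[i], donor, condition,
                                   base + [3, i], omit, False)
                comp_f.append(f)
                comp_s.append(s)
        comp_f = np.vstack(comp_f)
        comp_s = np.vstack(comp_s)
        rng_pair = np.random.default_rng(np.random.SeedSequence(base + [4]))
        order = rng_pair.permutation(comp_f.shape[0])[: 2 * n_doub]
        a, b = order[:n_doub], order[n_doub:]
        fluor = comp_f[a] + comp_f[b]
        scatter = np.column_stack([
            comp_s[a][:, 0] + comp_s[b][:, 0],
            np.maximum(comp_s[a][:, 1], comp_s[b][:, 1]),
            comp_s[a][:, 2] + comp_s[b][:, 2]])
        add(fluor, scatter, "doublet")

    for nm, cnt, bid in (("granulocyte", n_gran, 5), ("debris", n_debris, 6)):
        if cnt:
            spec = PopulationSpec(
                name=nm, frequency=0.0,
                scatter_model=_SCATTER[_SCATTER_CLASS[nm]],
                expression=dict(_IDENTITY[nm]))
            f, s = _draw_block(config, spec, cnt, donor, condition,
                               base + [bid, 0], omit, False)
            add(f, s, nm)

    true_fluor = np.vstack([f for f, _ in blocks])
    scatter = np.vstack([s for _, s in blocks])
    truth = np.concatenate(labels)

    rng_perm = np.random.default_rng(np.random.SeedSequence(base + [9999]))
    order = rng_perm.permutation(true_fluor.shape[0])
    true_fluor, scatter, truth = (true_fluor[order], scatter[order],
                                  truth[order])

    observed = true_fluor @ config.spillover
    values = np.column_stack([scatter, observed])
    channels = list(SCATTER_CHANNELS) + list(config.panel.detectors)
    markers = list(SCATTER_CHANNELS) + list(config.panel.marker_names)
    control = "full_stain" if omit is None else f"FMO:{omit}"
    return EventMatrix(
        values=values, channels=channels, markers=markers,
        truth_labels=truth,
        metadata={"donor": int(donor), "condition": condition.name,
                  "cohort": config.cohort, "control_type": control,
                  "compensated": False, "transformed": False,
                  "config_seed": int(config.seed)},
        true_signal=np.column_stack([scatter, true_fluor]))


def simulate_sample(config: CohortConfig, donor: int, condition,
                    seed: int, n_events: int | None = None) -> EventMatrix:
    """Simulate one fully stained whole-blood sample.

    Deterministic in ``(config, donor, condition, seed)``. Events include
    the configured fractions of dead cells, doublets, residual
    granulocytes and debris; true signals are mixed through the config's
    ground-truth spillover matrix."""
    return _simulate(config, donor, condition, seed, omit=None,
                     n_events=n_events)


def simulate_fmo(config: CohortConfig, donor: int, condition,
                 omitted_marker: str, seed: int,
                 n_events: int | None = None) -> EventMatrix:
    """Simulate a fluorescence-minus-one control: identical generative
    process except the omitted read-out marker is replaced by its
    autofluorescence off-state in every population."""
    if omitted_marker not in READOUT_MARKERS:
        raise ValueError(
            f"FMO controls exist only for the read-out markers "
            f"{READOUT_MARKERS}; cannot omit gating marker "
            f"{omitted_marker!r}")
    return _simulate(config, donor, condition, seed, omit=omitted_marker,
                     n_events=n_events)


def simulate_bead_controls(spillover: np.ndarray, n_events: int = 20_000,
                           seed: int = 0,
                           panel: PanelDefinition | None = None) -> list:
    """Simulate one single-stained antibody-capture bead file per
    fluorescence channel, each with a negative and a bright population
    mixed through the supplied spillover matrix."""
    spillover = np.asarray(spillover, dtype=float)
    if spillover.ndim != 2 or spillover.shape[0] != spillover.shape[1]:
        raise ValueError("spillover matrix must be square")
    if not np.allclose(np.diag(spillover), 1.0):
        raise ValueError("spillover diagonal must be 1")
    panel = panel or default_panel()
    if spillover.shape[0] != panel.n_fluorescence:
        raise ValueError("spillover size must match the panel")

    channels = list(SCATTER_CHANNELS) + list(panel.detectors)
    markers = list(SCATTER_CHANNELS) + list(panel.marker_names)
    out = []
    for i, det in enumerate(panel.detectors):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        n_pos = n_events // 2
        n_neg = n_events - n_pos
        true = rng.normal(100.0, 40.0,
                          size=(n_events, panel.n_fluorescence))
        true[n_neg:, i] = _lognormal(rng, 50_000.0, 0.10, n_pos)
        observed = true @ spillover
        fsc = np.clip(rng.normal(60_000, 5_000, size=n_events), 0, None)
        ssc = np.clip(rng.normal(10_000, 2_000, size=n_events), 0, None)
        values = np.column_stack(
            [fsc, fsc * rng.normal(0.95, 0.02, size=n_events), ssc,
             observed])
        out.append(EventMatrix(
            values=values, channels=channels, markers=markers,
            metadata={"control_type": f"bead:{det}",
                      "stained_marker": panel.marker_names[i],
                      "compensated": False, "transformed": False}))
    return out
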