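"""Spillover estimation from single-stained bead controls and
fluorescence compensation.

The observed detector values of an event are modelled as
``observed = true @ S`` with ``S`` the row-stochastic-like spillover
matrix (``S[i, j]`` = fraction of channel-i signal bleeding into detector
j, diagonal 1). Compensation right-multiplies by ``S^-1``. Spillover
coefficients are estimated per bead file from the robust (median)
positive-minus-negative signal ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventMatrix
from .panel import SCATTER_CHANNELS


@dataclass
class SpilloverMatrix:
    """Square channel-by-channel spillover coefficients, diagonal 1."""

    coefficients: np.ndarray
    channels: list

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("spillover matrix must be square")
        if c.shape[0] != len(self.channels):
            raise ValueError("channel list must match matrix size")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("spillover diagonal must be exactly 1")
        if np.any(c < 0):
            raise ValueError("spillover entries must be >= 0")
        self.coefficients = c

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.coefficients))

    # -- CSV round-trip (rows = stained source channel, cols = detector) --
    def to_csv(self, path) -> None:
        pd.DataFrame(self.coefficients, index=self.channels,
                     columns=self.channels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("spillover CSV row/column channels must match")
        return cls(df.to_numpy(float), list(df.columns))


def _split_positive(values: np.ndarray, asinh_cofactor: float = 150.0,
                    max_iter: int = 100) -> np.ndarray:
    """Boolean mask of the positive (bright) population via 1-D 2-means
    on the asinh scale. Deterministic."""
    x = np.arcsinh(values / asinh_cofactor)
    c1, c2 = np.min(x), np.max(x)
    for _ in range(max_iter):
        assign = np.abs(x - c2) < np.abs(x - c1)
        if assign.all() or not assign.any():
            break
        n1, n2 = np.mean(x[~assign]), np.mean(x[assign])
        if n1 == c1 and n2 == c2:
            break
        c1, c2 = n1, n2
    return np.abs(x - c2) < np.abs(x - c1)


def estimate_spillover(bead_files: list, min_snr: float = 10.0) -> SpilloverMatrix:
    """Estimate the spillover matrix from one single-stained bead file per
    fluorescence channel.

    Per file, positive and negative bead populations are split by a
    bimodality threshold on the stained channel;
    ``S[i, j] = (median_j(pos) - median_j(neg)) /
    (median_i(pos) - median_i(neg))``. The diagonal is normalized to 1 and
    negative estimates are clamped to 0.
    """
    if not bead_files:
        raise ValueError("no bead files supplied")
    channels = [c for c in bead_files[0].channels
                if c not in SCATTER_CHANNELS]
    stained = {}
    for beads in bead_files:
        ctype = beads.metadata.get("control_type", "")
        if not ctype.startswith("bead:"):
            raise ValueError(f"not a bead control: {ctype!r}")
        stained[ctype.split(":", 1)[1]] = beads
    missing = [c for c in channels if c not in stained]
    if missing:
        raise ValueError(f"missing bead file(s) for channel(s): {missing}")

    n = len(channels)
    S = np.zeros((n, n))
    for i, ch in enumerate(channels):
        beads = stained[ch]
        fluor = beads.values[:, [beads.column(c) for c in channels]]
        pos = _split_positive(fluor[:, i])
        if pos.all() or not pos.any():
            raise ValueError(f"bead file {ch}: cannot separate positive "
                             "and negative populations")
        med_pos = np.median(fluor[pos], axis=0)
        med_neg = np.median(fluor[~pos], axis=0)
        signal = med_pos[i] - med_neg[i]
        noise = np.median(np.abs(fluor[~pos, i] - med_neg[i])) * 1.4826
        if noise > 0 and signal / noise < min_snr:
            raise ValueError(f"bead file {ch}: positive/negative "
                             f"separation below signal-to-background "
                             f"minimum ({signal / noise:.1f} < {min_snr})")
        S[i] = (med_pos - med_neg) / signal
    S = np.clip(S, 0.0, None)
    np.fill_diagonal(S, 1.0)
    return SpilloverMatrix(S, channels)


def compensate(events: EventMatrix, spillover: SpilloverMatrix) -> EventMatrix:
    """Apply fluorescence compensation (``observed @ S^-1``) to the
    fluorescence columns; scatter columns are untouched. Compensated
    values may be negative and are retained."""
    if events.metadata.get("compensated"):
        raise ValueError("events are already compensated")
    cols = events.fluorescence_columns
    order = [events.channels[i] for i in cols]
    if order != list(spillover.channels):
        raise ValueError("channel order mismatch between events and "
                         "spillover matrix")
    cond = spillover.condition_number
    if not np.isfinite(cond) or cond > 1e8:
        raise ValueError(f"spillover matrix is singular or ill-conditioned "
                         f"(condition number {cond:.3g})")
    observed = events.values[:, cols]
    true = np.linalg.solve(spillover.coefficients.T, observed.T).T
    values = events.values.copy()
    values[:, cols] = true
    return events.with_values(values, compensated=True,
                              spillover_condition_number=cond)
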