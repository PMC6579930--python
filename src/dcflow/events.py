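"""Event-level data container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .panel import SCATTER_CHANNELS


@dataclass
class EventMatrix:
    """Per-event table of scatter + fluorescence intensities (linear scale).

    Attributes
    ----------
    values : (n_events, n_channels) float array
        Raw or compensated intensities; first columns are scatter.
    channels : list of str
        Detector identifiers, e.g. ``FSC-A`` or ``PE-A``.
    markers : list of str
        Marker names aligned with ``channels`` (scatter channels repeat
        their own name).
    truth_labels : optional (n_events,) array of str
        Ground-truth population label per event (synthetic samples only).
    metadata : dict
        Sample-level metadata: donor, condition, cohort, control_type
        (``full_stain`` / ``FMO:<marker>`` / ``bead:<channel>``) and
        processing flags (``compensated``, ``transformed``).
    true_signal : optional array
        Pre-spillover true fluorescence signals (in-memory only; used by
        round-trip checks, never serialized).
    """

    values: np.ndarray
    channels: list
    markers: list
    truth_labels: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)
    true_signal: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x channels array")
        if self.values.shape[1] != len(self.channels):
            raise ValueError("column count must equal channel count")
        if len(self.markers) != len(self.channels):
            raise ValueError("markers and channels must align")
        scatter_cols = [i for i, c in enumerate(self.channels)
                        if c in SCATTER_CHANNELS]
        if scatter_cols and self.values.size and np.any(
                self.values[:, scatter_cols] < 0):
            raise ValueError("scatter values must be non-negative")
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels)
            if self.truth_labels.shape[0] != self.values.shape[0]:
                raise ValueError("truth_labels must have one entry per event")

    # -- accessors -------------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, marker: str) -> int:
        """Column index of a marker (or detector) name."""
        if marker in self.markers:
            return self.markers.index(marker)
        if marker in self.channels:
            return self.channels.index(marker)
        raise KeyError(f"channel {marker!r} missing from events")

    def get(self, marker: str) -> np.ndarray:
        return self.values[:, self.column(marker)]

    @property
    def fluorescence_columns(self) -> list:
        return [i for i, c in enumerate(self.channels)
                if c not in SCATTER_CHANNELS]

    @property
    def fluorescence_markers(self) -> list:
        return [self.markers[i] for i in self.fluorescence_columns]

    def subset(self, mask: np.ndarray) -> "EventMatrix":
        """Row-subset preserving metadata alignment."""
        return EventMatrix(
            values=self.values[mask],
            channels=list(self.channels),
            markers=list(self.markers),
            truth_labels=None if self.truth_labels is None
            else self.truth_labels[mask],
            metadata=dict(self.metadata),
            true_signal=None if self.true_signal is None
            else self.true_signal[mask],
        )

    def with_values(self, values: np.ndarray, **meta) -> "EventMatrix":
        new = replace(self, values=values)
        new.metadata = {**self.metadata, **meta}
        return new

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.markers)
        if self.truth_labels is not None:
            df["truth_label"] = self.truth_labels
        return df
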