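"""Trial-aligned spike-count container and TSV round-tripping.

Counts are accumulated over a fixed analysis epoch (default 3.35 s, from the
presentation of the first option to just before feedback). Optionally a
table also carries counts for the three 400-ms presentation epochs in which
each option appeared alone, used by the stimulus/choice tuning analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REGIONS: tuple[str, ...] = ("OFC", "VS", "DS")

SPIKES_COLUMNS = ("neuron_id", "region", "session_id", "trial_index", "spike_count")


@dataclass
class SpikeCountTable:
    """trials x neurons spike counts over the analysis epoch.

    Attributes
    ----------
    counts : (T, N) array of non-negative counts (floats allowed for
        noiseless expected-count fixtures).
    neuron_ids : length-N labels.
    regions : length-N region tag per neuron (OFC/VS/DS).
    epoch_duration : analysis-epoch length in seconds.
    epoch_counts : optional (T, N, 3) counts for the three 400-ms
        presentation epochs, ordered by presentation slot.
    """

    counts: np.ndarray
    neuron_ids: np.ndarray
    regions: np.ndarray
    trial_index: np.ndarray
    session_id: str = "synthetic"
    epoch_duration: float = 3.35
    epoch_counts: np.ndarray | None = None
    presentation_epoch_duration: float = 0.4

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be trials x neurons")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.epoch_duration <= 0:
            raise ValueError("epoch_duration must be positive")
        n = self.counts.shape[1]
        if len(self.neuron_ids) != n or len(self.regions) != n:
            raise ValueError("neuron metadata length mismatch")
        if len(self.trial_index) != self.counts.shape[0]:
            raise ValueError("trial_index length mismatch")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    @property
    def rates(self) -> np.ndarray:
        """Firing rates in spikes/s over the analysis epoch."""
        return self.counts / self.epoch_duration

    def select_neurons(self, mask: np.ndarray) -> "SpikeCountTable":
        return SpikeCountTable(
            counts=self.counts[:, mask],
            neuron_ids=np.asarray(self.neuron_ids)[mask],
            regions=np.asarray(self.regions)[mask],
            trial_index=self.trial_index,
            session_id=self.session_id,
            epoch_duration=self.epoch_duration,
            epoch_counts=None if self.epoch_counts is None else self.epoch_counts[:, mask, :],
            presentation_epoch_duration=self.presentation_epoch_duration,
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format table: neuron_id, region, session_id, trial_index, spike_count."""
        t, n = self.counts.shape
        return pd.DataFrame({
            "neuron_id": np.repeat(self.neuron_ids, t),
            "region": np.repeat(self.regions, t),
            "session_id": self.session_id,
            "trial_index": np.tile(self.trial_index, n),
            "spike_count": self.counts.T.ravel(),
        })

    def write(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame, epoch_duration: float = 3.35) -> "SpikeCountTable":
        wide = df.pivot_table(index="trial_index", columns="neuron_id",
                              values="spike_count", sort=True)
        meta = df.drop_duplicates("neuron_id").set_index("neuron_id")
        neuron_ids = wide.columns.to_numpy()
        return cls(
            counts=wide.to_numpy(),
            neuron_ids=neuron_ids,
            regions=meta.loc[neuron_ids, "region"].to_numpy(),
            trial_index=wide.index.to_numpy(),
            session_id=str(df["session_id"].iloc[0]),
            epoch_duration=epoch_duration,
        )

    @classmethod
    def read(cls, path, epoch_duration: float = 3.35) -> "SpikeCountTable":
        return cls.from_long(pd.read_csv(path, sep="\t"), epoch_duration=epoch_duration)
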