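"""The Trial container shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trial:
    """One stimulus presentation: multichannel EEG plus its dB envelope.

    ``eeg`` is channels × samples and ``envelope`` the dB envelope resampled
    to the EEG rate, aligned sample-for-sample with the recording.
    """

    eeg: np.ndarray
    envelope: np.ndarray
    rate: float
    label: str = ""
    channel_names: list[str] | None = None
    beat_times: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        self.envelope = np.asarray(self.envelope, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.eeg)):
            raise ValueError("EEG contains non-finite values")
        if not np.all(np.isfinite(self.envelope)):
            raise ValueError("envelope contains non-finite values")
        if self.envelope.ndim != 1 or self.envelope.size != self.eeg.shape[1]:
            raise ValueError(
                "envelope must be 1-D and sample-aligned with the EEG"
            )
        if self.channel_names is not None and len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"got {len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )
        if self.beat_times is not None:
            self.beat_times = np.asarray(self.beat_times, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate
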