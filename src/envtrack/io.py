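"""HDF5 trial container and result serialization.

A dataset is a single hierarchical array file: one group per trial holding
the EEG array (channels × samples), the dB envelope, the sampling rate,
channel labels, the stimulus class and optional beat times.  Channels
flagged as reference channels (e.g. mastoids) are averaged, subtracted
from every other channel and dropped at read time.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .trials import Trial

__all__ = ["write_trialset", "read_trialset", "write_manifest"]


def write_trialset(path, trials: list[Trial], reference_channels=()) -> None:
    """Write trials to an HDF5 container (lossless round-trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["n_trials"] = len(trials)
        f.attrs["reference_channels"] = json.dumps(list(reference_channels))
        for i, t in enumerate(trials):
            g = f.create_group(f"trial_{i:03d}")
            g.create_dataset("eeg", data=t.eeg)
            g.create_dataset("envelope", data=t.envelope)
            g.attrs["rate"] = t.rate
            g.attrs["label"] = t.label
            names = t.channel_names or [f"ch{c}" for c in range(t.n_channels)]
            g.attrs["channel_names"] = json.dumps(names)
            if t.beat_times is not None:
                g.create_dataset("beat_times", data=t.beat_times)


def read_trialset(path) -> list[Trial]:
    """Read and validate a trial container, applying re-referencing.

    If the file flags reference channels, their average is subtracted from
    every channel and the reference channels are dropped.  Missing fields
    and non-finite data are rejected with the offending field named.
    """
    trials = []
    with h5py.File(path, "r") as f:
        refs = json.loads(f.attrs.get("reference_channels", "[]"))
        for key in sorted(k for k in f.keys() if k.startswith("trial_")):
            g = f[key]
            for required in ("eeg", "envelope"):
                if required not in g:
                    raise ValueError(f"{key}: missing dataset '{required}'")
            for attr in ("rate", "channel_names"):
                if attr not in g.attrs:
                    raise ValueError(f"{key}: missing attribute '{attr}'")
            eeg = np.asarray(g["eeg"])
            env = np.asarray(g["envelope"])
            if not np.all(np.isfinite(eeg)):
                raise ValueError(f"{key}: eeg contains non-finite values")
            if not np.all(np.isfinite(env)):
                raise ValueError(f"{key}: envelope contains non-finite values")
            names = json.loads(g.attrs["channel_names"])
            if len(names) != eeg.shape[0]:
                raise ValueError(
                    f"{key}: {len(names)} channel names for {eeg.shape[0]} channels"
                )
            if refs:
                ref_idx = [names.index(r) for r in refs if r in names]
                if ref_idx:
                    eeg = eeg - eeg[ref_idx].mean(axis=0)
                    keep = [c for c in range(eeg.shape[0]) if c not in ref_idx]
                    eeg = eeg[keep]
                    names = [names[c] for c in keep]
            beats = np.asarray(g["beat_times"]) if "beat_times" in g else None
            trials.append(
                Trial(
                    eeg=eeg,
                    envelope=env,
                    rate=float(g.attrs["rate"]),
                    label=str(g.attrs["label"]),
                    channel_names=names,
                    beat_times=beats,
                )
            )
    return trials


def write_manifest(path, config: dict) -> None:
    """Write a JSON manifest sufficient to reproduce a run exactly."""
    from . import __version__

    manifest = {"envtrack_version": __version__, **config}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
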