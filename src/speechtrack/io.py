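"""HDF5 array-container I/O for epochs, envelopes and source maps.

Datasets are written with ``track_times=False`` so identical inputs
produce byte-identical files (the pipeline manifest hashes artifacts).
"""

from __future__ import annotations

import numpy as np
import h5py

from .envelope import EnvelopeSignal
from .preprocess import EpochSet


def _write(g: h5py.Group, name: str, data) -> None:
    g.create_dataset(name, data=data, track_times=False)


def save_epochs(path, e: EpochSet) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        _write(f, "epochs", e.epochs)
        f.attrs["rate"] = e.rate
        f.attrs["epoch_len_s"] = e.epoch_len_s
        f.attrs["subject_id"] = e.subject_id
        f.attrs["group"] = e.group
        if e.condition_labels is not None:
            _write(f, "condition_labels", np.array(e.condition_labels, dtype="S"))
        if e.envelope_epochs is not None:
            _write(f, "envelope_epochs", e.envelope_epochs)
        if e.channel_ids is not None:
            _write(f, "channel_ids", np.array(e.channel_ids, dtype="S"))


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        labels = None
        if "condition_labels" in f:
            labels = [s.decode() for s in f["condition_labels"][()]]
        chans = None
        if "channel_ids" in f:
            chans = [s.decode() for s in f["channel_ids"][()]]
        return EpochSet(
            epochs=f["epochs"][()],
            rate=float(f.attrs["rate"]),
            epoch_len_s=float(f.attrs["epoch_len_s"]),
            condition_labels=labels,
            subject_id=str(f.attrs.get("subject_id", "")),
            group=str(f.attrs.get("group", "")),
            envelope_epochs=f["envelope_epochs"][()] if "envelope_epochs" in f else None,
            channel_ids=chans)


def save_envelope(path, e: EnvelopeSignal, **meta) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        _write(f, "samples", e.samples)
        f.attrs["rate"] = e.rate
        f.attrs["normalized"] = bool(e.normalized)
        for k, v in meta.items():
            f.attrs[k] = v


def load_envelope(path) -> EnvelopeSignal:
    with h5py.File(path, "r") as f:
        return EnvelopeSignal(samples=f["samples"][()], rate=float(f.attrs["rate"]),
                              normalized=bool(f.attrs["normalized"]))


def save_array(path, **arrays) -> None:
    """Write named arrays (and scalar attrs prefixed 'attr_') to HDF5."""
    with h5py.File(path, "w", track_order=True) as f:
        for k, v in arrays.items():
            if np.isscalar(v):
                f.attrs[k] = v
            else:
                _write(f, k, np.asarray(v))


def load_array(path) -> dict:
    with h5py.File(path, "r") as f:
        out = {k: f[k][()] for k in f}
        out.update({k: f.attrs[k] for k in f.attrs})
        return out
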