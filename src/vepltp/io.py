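"""HDF5 persistence for recordings, epochs and evoked responses.

Container layout for a Recording:
  /data                channels x samples float64 (uV)
  /markers/sample      int64
  /markers/orientation int8 codes (attrs carry the code table)
  /markers/block       int8 codes
  /meta                attrs: sampling_rate, channel_labels, positions
"""

from __future__ import annotations

import numpy as np
import h5py

from .simulate import Recording, EventMarker, ORIENTATIONS, BLOCKS
from .preprocess import Epochs, Evoked


def save_recording(recording: Recording, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data, compression="gzip",
                         compression_opts=4)
        grp = f.create_group("markers")
        grp.create_dataset("sample", data=np.array(
            [m.sample_index for m in recording.markers], dtype=np.int64))
        grp.create_dataset("orientation", data=np.array(
            [ORIENTATIONS.index(m.orientation) for m in recording.markers],
            dtype=np.int8))
        grp.create_dataset("block", data=np.array(
            [BLOCKS.index(m.block) for m in recording.markers],
            dtype=np.int8))
        grp.attrs["orientation_codes"] = list(ORIENTATIONS)
        grp.attrs["block_codes"] = list(BLOCKS)
        meta = f.create_group("meta")
        meta.attrs["sampling_rate"] = recording.sampling_rate
        meta.attrs["channel_labels"] = recording.channel_labels
        meta.create_dataset("channel_positions",
                            data=recording.channel_positions)


def load_recording(path: str) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        samples = f["markers/sample"][()]
        orient = f["markers/orientation"][()]
        block = f["markers/block"][()]
        markers = [EventMarker(int(s), ORIENTATIONS[int(o)], BLOCKS[int(b)])
                   for s, o, b in zip(samples, orient, block)]
        rec = Recording(
            data=data,
            sampling_rate=float(f["meta"].attrs["sampling_rate"]),
            channel_labels=[str(x) for x in f["meta"].attrs["channel_labels"]],
            channel_positions=f["meta/channel_positions"][()],
            markers=markers)
    rec.validate()
    return rec


def save_evokeds(evokeds: dict[tuple[str, str], Evoked], path: str) -> None:
    with h5py.File(path, "w") as f:
        for (block, cond), ev in evokeds.items():
            grp = f.create_group(f"{block}/{cond}")
            grp.create_dataset("data", data=ev.data)
            grp.create_dataset("times", data=ev.times)
            grp.attrs["sampling_rate"] = ev.sampling_rate
            grp.attrs["n_epochs_averaged"] = ev.n_epochs_averaged
            grp.attrs["channel_labels"] = ev.channel_labels
            grp.create_dataset("channel_positions",
                               data=ev.channel_positions)


def load_evokeds(path: str) -> dict[tuple[str, str], Evoked]:
    out = {}
    with h5py.File(path, "r") as f:
        for block in f:
            for cond in f[block]:
                grp = f[block][cond]
                out[(block, cond)] = Evoked(
                    data=grp["data"][()], times=grp["times"][()],
                    sampling_rate=float(grp.attrs["sampling_rate"]),
                    block=block, condition=cond,
                    n_epochs_averaged=int(grp.attrs["n_epochs_averaged"]),
                    channel_labels=[str(x)
                                    for x in grp.attrs["channel_labels"]],
                    channel_positions=grp["channel_positions"][()])
    return out


def save_epochs(epochs: Epochs, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip",
                         compression_opts=4)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("kept", data=epochs.kept)
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["block"] = epochs.block
        f.attrs["condition"] = epochs.condition
        f.attrs["channel_labels"] = epochs.channel_labels
        f.create_dataset("channel_positions", data=epochs.channel_positions)


def load_epochs(path: str) -> Epochs:
    with h5py.File(path, "r") as f:
        return Epochs(
            data=f["data"][()], times=f["times"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            block=str(f.attrs["block"]), condition=str(f.attrs["condition"]),
            kept=f["kept"][()].astype(bool),
            channel_labels=[str(x) for x in f.attrs["channel_labels"]],
            channel_positions=f["channel_positions"][()])
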