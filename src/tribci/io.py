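"""Reading and writing the dataset container schema.

Recordings are stored as HDF5 files whose top-level groups are named structs
(e.g. ``EEG_MI_train``), each holding the seven canonical fields:

``x``        continuous signal, samples x channels, microvolts
``t``        0-based stimulus-onset sample index per trial
``fs``       sampling rate (Hz, scalar)
``y_dec``    1-based integer class code per trial
``y_logic``  one-hot logical matrix, classes x trials
``y_class``  class-name strings
``chan``     channel-name strings

MAT v7.3 files are HDF5 underneath, so files written by MATLAB with this
struct layout are readable through the same code path; only the HDF5 layer
is used, never the legacy MAT binary dialects.  Two auxiliary datasets
(``event_code``, ``chan_kind``) and a ``meta`` attribute block carry marker
codes, the EEG/EMG flag per channel, and free-form metadata; they are
optional on read.
"""

from __future__ import annotations

import os

import h5py
import numpy as np

from .containers import ContinuousEEG, LabelBlock, SchemaError

__all__ = ["REQUIRED_FIELDS", "read_recording", "write_recording"]

REQUIRED_FIELDS = ("x", "t", "fs", "y_dec", "y_logic", "y_class", "chan")

_STR = h5py.string_dtype(encoding="utf-8")


def _decode_strings(ds) -> list[str]:
    out = []
    for v in np.asarray(ds[()]).ravel():
        out.append(v.decode("utf-8") if isinstance(v, bytes) else str(v))
    return out


def write_recording(rec: ContinuousEEG, labels: LabelBlock | None, path, struct_name: str = "EEG"):
    """Write a recording (and optional labels) as one named struct.

    An existing struct of the same name in the file is replaced; other
    structs (e.g. the train/test sibling) are preserved.
    """
    if labels is None:
        labels = LabelBlock.from_y_dec([], [])
    if len(labels) and len(labels) != rec.markers.shape[0]:
        raise SchemaError("label count must equal marker count")
    try:
        f = h5py.File(path, "a")
    except OSError as e:
        raise IOError(f"cannot open {path!r} for writing: {e}") from e
    with f:
        if struct_name in f:
            del f[struct_name]
        g = f.create_group(struct_name)
        g.create_dataset("x", data=rec.signal)
        g.create_dataset("t", data=rec.marker_samples.astype(np.int64))
        g.create_dataset("event_code", data=rec.marker_codes.astype(np.int64))
        g.create_dataset("fs", data=float(rec.fs))
        g.create_dataset("y_dec", data=labels.y_dec.astype(np.int64))
        g.create_dataset("y_logic", data=labels.y_logic.astype(np.uint8))
        g.create_dataset("y_class", data=np.array(labels.y_class, dtype=_STR))
        g.create_dataset("chan", data=np.array(rec.channel_names, dtype=_STR))
        g.create_dataset("chan_kind", data=np.array(rec.channel_kinds, dtype=_STR))
        meta = g.create_group("meta")
        for k, v in rec.meta.items():
            try:
                meta.attrs[k] = v
            except TypeError:
                meta.attrs[k] = str(v)
    return path


def read_recording(path, struct_name: str) -> tuple[ContinuousEEG, LabelBlock]:
    """Read one named struct back into a recording + label block.

    Raises
    ------
    SchemaError
        If the struct or one of the seven required fields is missing, or an
        invariant of the stored fields is violated.
    IOError
        If the file cannot be opened as HDF5.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path!r}")
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise IOError(f"cannot read {path!r} as HDF5: {e}") from e
    with f:
        if struct_name not in f:
            raise SchemaError(
                f"struct {struct_name!r} not found in {path!r}; available: {list(f)}"
            )
        g = f[struct_name]
        for field in REQUIRED_FIELDS:
            if field not in g:
                raise SchemaError(f"required field {field!r} missing from struct {struct_name!r}")
        x = np.asarray(g["x"][()], dtype=np.float64)
        if x.ndim != 2:
            raise SchemaError("field 'x' must be 2-D (samples x channels)")
        t = np.asarray(g["t"][()], dtype=np.int64).ravel()
        fs = float(np.asarray(g["fs"][()]).ravel()[0])
        y_dec = np.asarray(g["y_dec"][()], dtype=np.int64).ravel()
        y_logic = np.asarray(g["y_logic"][()]).astype(bool)
        y_class = _decode_strings(g["y_class"])
        chan = _decode_strings(g["chan"])
        if "event_code" in g:
            codes = np.asarray(g["event_code"][()], dtype=np.int64).ravel()
        else:
            codes = y_dec if y_dec.size == t.size else np.zeros(t.size, dtype=np.int64)
        kinds = _decode_strings(g["chan_kind"]) if "chan_kind" in g else ["EEG"] * len(chan)
        meta = {}
        if "meta" in g:
            for k, v in g["meta"].attrs.items():
                meta[k] = v

    if len(chan) != x.shape[1]:
        raise SchemaError("field 'chan' length must equal the channel count of 'x'")
    if codes.size != t.size:
        raise SchemaError("event_code length must equal marker count")
    labels = LabelBlock(y_dec=y_dec, y_logic=y_logic, y_class=y_class)
    if len(labels) and len(labels) != t.size:
        raise SchemaError("label count must equal marker count (field 't')")
    rec = ContinuousEEG(
        signal=x,
        fs=fs,
        markers=np.column_stack([t, codes]) if t.size else np.empty((0, 2), dtype=np.int64),
        channel_names=chan,
        channel_kinds=kinds,
        meta=meta,
    )
    return rec, labels
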