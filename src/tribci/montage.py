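"""Channel montage: the 62 EEG + 4 EMG recording layout and paradigm presets.

The EEG montage follows the International 10-20 (extended 10-10) system at
62 scalp sites; four EMG electrodes record from the forearm flexors.  The
paradigm-specific subsets mirror standard practice: a broad 32-channel set
for ERP analysis, a 20-channel sensorimotor strip (FC/C/CP rows) for motor
imagery, and a 10-channel occipito-parietal set for SSVEP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EEG_CHANNELS",
    "EMG_CHANNELS",
    "PRESETS",
    "MontagePreset",
    "get_preset",
    "channel_positions",
]

EEG_CHANNELS: list[str] = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "FC3", "FC4", "C5", "C1", "C2", "C6", "CP3", "CPz", "CP4",
    "P1", "P2", "POz", "FT9", "FTT9h", "TTP7h", "TP7", "TPP9h",
    "FT10", "FTT10h", "TTP8h", "TP8", "TPP10h",
    "F9", "F10", "AF7", "AF3", "AF4", "AF8", "PO3", "PO4",
]

EMG_CHANNELS: list[str] = ["EMG1", "EMG2", "EMG3", "EMG4"]


@dataclass(frozen=True)
class MontagePreset:
    """Named ordered channel subset used by one decoding pipeline."""

    name: str
    channels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.channels)


_ERP32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "T8", "C3", "Cz", "C4",
    "TP9", "TP10", "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "PO10", "O1", "Oz", "O2",
)
_MI20 = (
    "FC5", "FC3", "FC1", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
)
_SSVEP10 = ("P7", "P3", "Pz", "P4", "P8", "PO9", "PO10", "O1", "Oz", "O2")

PRESETS: dict[str, MontagePreset] = {
    "ERP32": MontagePreset("ERP32", _ERP32),
    "MI20": MontagePreset("MI20", _MI20),
    "SSVEP10": MontagePreset("SSVEP10", _SSVEP10),
    "ALL62": MontagePreset("ALL62", tuple(EEG_CHANNELS)),
}

assert len(_ERP32) == 32 and len(_MI20) == 20 and len(_SSVEP10) == 10
assert len(EEG_CHANNELS) == 62


def get_preset(name: str) -> MontagePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown montage preset {name!r}; choose from {sorted(PRESETS)}")


_ROW_Y = {
    "Fp": 1.0, "AF": 0.82, "F": 0.62, "FT": 0.38, "FC": 0.35, "FTT": 0.2,
    "T": 0.0, "C": 0.0, "TTP": -0.12, "TP": -0.38, "CP": -0.35, "TPP": -0.48,
    "P": -0.62, "PO": -0.82, "O": -1.0,
}
_NUM_X = {0: 0.0, 1: 0.22, 2: 0.22, 3: 0.45, 4: 0.45, 5: 0.68, 6: 0.68,
          7: 0.92, 8: 0.92, 9: 1.1, 10: 1.1}


def _parse_label(label: str) -> tuple[float, float]:
    name = label[:-1] if label.endswith("h") else label
    i = 0
    while i < len(name) and name[i].isalpha() and name[i] != "z":
        i += 1
    prefix, suffix = name[:i], name[i:]
    if suffix in ("z", ""):
        num = 0
    else:
        num = int(suffix)
    y = _ROW_Y.get(prefix, 0.0)
    x = _NUM_X.get(num, 1.0)
    if num % 2 == 1:  # odd = left hemisphere
        x = -x
    return x, y


def channel_positions(channels: list[str] | tuple[str, ...] = None) -> np.ndarray:
    """Schematic 2-D electrode coordinates (x: left-to-right, y: front-to-back).

    The layout is a flattened top view used only to give simulated sources a
    spatially smooth projection; it makes no anatomical claims.  EMG channels
    are placed far outside the scalp disc so they share no spread with EEG.
    """
    if channels is None:
        channels = EEG_CHANNELS
    pos = np.zeros((len(channels), 2))
    for i, ch in enumerate(channels):
        if ch.upper().startswith("EMG"):
            pos[i] = (3.0 + i * 0.5, -3.0)
        else:
            pos[i] = _parse_label(ch)
    return pos
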