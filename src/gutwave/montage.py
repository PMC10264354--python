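"""Channel layout of the 31-channel 10-20 EEG cap used by the protocol.

One electrode of the 32-channel cap records ECG from the back, leaving 31
scalp channels including the mastoids TP9/TP10 (the reference pair) and the
posterior midline group where the gastric evoked potential is maximal.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["EEG_CHANNELS", "MASTOIDS", "POSTERIOR_CHANNELS", "standard_positions"]

EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "POz", "O1", "Oz", "O2",
)

MASTOIDS: tuple[str, str] = ("TP9", "TP10")

#: Parieto-occipital channels carrying the late positive gastric evoked potential.
POSTERIOR_CHANNELS: tuple[str, ...] = ("Cz", "CP1", "CP2", "Pz", "POz", "O1", "Oz", "O2")


def standard_positions(labels=EEG_CHANNELS, normalize: bool = True) -> dict[str, np.ndarray]:
    """3-D electrode positions from the standard 10-20 montage.

    With ``normalize=True`` coordinates are divided by the median scalp
    radius, so inter-electrode distances are in units of head radius (the
    scale on which the default adjacency threshold is expressed).
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mon = mne.channels.make_standard_montage("standard_1020")
    pos = mon.get_positions()["ch_pos"]
    missing = [c for c in labels if c not in pos]
    if missing:
        raise KeyError(f"channels absent from standard montage: {missing}")
    pts = {c: np.asarray(pos[c], dtype=float) for c in labels}
    if normalize:
        r = float(np.median([np.linalg.norm(p) for p in pts.values()]))
        pts = {c: p / r for c, p in pts.items()}
    return pts
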