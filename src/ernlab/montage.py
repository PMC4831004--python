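"""Electrode montages: builtin 10-20 sets, contralateral pairing, neighbours.

Coordinates live on the unit sphere.  The builtin montages are derived at run
time from the standard 10-20 template positions shipped with MNE-Python and
re-projected onto the unit sphere; they contain scalp channels only (no eye
channels).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: 60-channel extended 10-20 scalp set (the default simulated cap).
LABELS_60 = [
    "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
]

#: 32-channel subset used for desk-scale EEG simulations.
LABELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "POz", "PO4", "O1", "O2",
]

_LATERAL_RE = re.compile(r"^([A-Za-z]+?)(\d+)$")


class MontageError(ValueError):
    pass


@dataclass
class Montage:
    labels: list
    positions: np.ndarray  # (n, 3), unit sphere

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise MontageError("positions must be (n_labels, 3)")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self):
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise MontageError(f"electrode {label!r} not in montage") from None

    def contralateral(self, label: str) -> str:
        """10-20 contralateral partner: odd<->even trailing digit, midline
        ('z') electrodes pair with themselves."""
        self.index(label)
        m = _LATERAL_RE.match(label)
        if m is None:  # midline labels end in 'z'
            return label
        stem, num = m.group(1), int(m.group(2))
        partner = f"{stem}{num + 1 if num % 2 == 1 else num - 1}"
        if partner not in self._index:
            raise MontageError(
                f"contralateral partner {partner!r} of {label!r} missing"
            )
        return partner

    def neighbors(self, label: str, k: int = 7) -> list:
        """The k nearest other electrodes by Euclidean distance."""
        i = self.index(label)
        d = np.linalg.norm(self.positions - self.positions[i], axis=1)
        order = np.argsort(d, kind="stable")
        out = [self.labels[j] for j in order if j != i][:k]
        if len(out) < k:
            raise MontageError(f"montage too small for {k} neighbours")
        return out

    def spatial_profile(self, center: str, width: float) -> np.ndarray:
        """Gaussian scalp topography, 1.0 at `center`, width on the sphere."""
        c = self.positions[self.index(center)]
        d = np.linalg.norm(self.positions - c, axis=1)
        return np.exp(-0.5 * (d / width) ** 2)

    def subset(self, labels) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(list(labels), self.positions[idx])


def _template_positions() -> dict:
    import mne

    for name in ("standard_1020", "colin27_1020"):
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mon = mne.channels.make_standard_montage(name)
            return mon.get_positions()["ch_pos"]
        except Exception:
            continue
    raise MontageError("no standard 10-20 template available")


def make_builtin(name: str = "standard-60") -> Montage:
    """Builtin montages: 'standard-60' and 'standard-32'."""
    labels = {"standard-60": LABELS_60, "standard-32": LABELS_32}.get(name)
    if labels is None:
        raise MontageError(f"unknown builtin montage {name!r}")
    ch_pos = _template_positions()
    pos = np.array([ch_pos[l] for l in labels], dtype=float)
    pos = pos - pos.mean(axis=0)  # approximate sphere centre
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(list(labels), pos)


def load_montage(spec: str) -> Montage:
    """Resolve a montage reference: builtin name or path to a TSV file."""
    if str(spec).startswith("standard-"):
        return make_builtin(str(spec))
    if not Path(spec).exists():
        raise MontageError(f"montage file not found: {spec}")
    return read_montage(spec)


def write_montage(montage: Montage, path) -> None:
    df = pd.DataFrame(montage.positions, columns=["x", "y", "z"])
    df.insert(0, "label", montage.labels)
    df.to_csv(path, sep="\t", index=False)


def read_montage(path) -> Montage:
    df = pd.read_csv(path, sep="\t")
    missing = {"label", "x", "y", "z"} - set(df.columns)
    if missing:
        raise MontageError(f"montage file missing columns: {sorted(missing)}")
    return Montage(df["label"].tolist(), df[["x", "y", "z"]].to_numpy(float))
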