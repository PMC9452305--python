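"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RoiMask:
    """One detected nucleus: a pixel set on a single plane."""

    roi_id: int
    plane: int
    pixels: np.ndarray  # (k, 2) int array of (row, col)
    centroid_um: tuple[float, float, float]  # (x, y, z)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.size == 0:
            raise ValueError(f"ROI {self.roi_id}: empty pixel set")
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError(f"ROI {self.roi_id}: pixels must be (k, 2)")


@dataclass
class NeuronSet:
    """ROI centroids in um (3D) with optional pixel masks and genetic labels."""

    ids: np.ndarray  # (n,) int
    centroids_um: np.ndarray  # (n, 3) float, columns x, y, z
    masks: list[RoiMask] | None = None
    labels: pd.DataFrame | None = None  # optional per-neuron annotations

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.centroids_um = np.asarray(self.centroids_um, dtype=float)
        if self.centroids_um.shape != (len(self.ids), 3):
            raise ValueError("centroids_um must be (n_neurons, 3)")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("neuron ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "neuron_id": self.ids,
                "x_um": self.centroids_um[:, 0],
                "y_um": self.centroids_um[:, 1],
                "z_um": self.centroids_um[:, 2],
            }
        )
        if self.labels is not None:
            df = df.join(self.labels.reset_index(drop=True))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NeuronSet":
        df = pd.read_csv(path)
        extra = [c for c in df.columns if c not in ("neuron_id", "x_um", "y_um", "z_um")]
        return cls(
            ids=df["neuron_id"].to_numpy(),
            centroids_um=df[["x_um", "y_um", "z_um"]].to_numpy(),
            labels=df[extra] if extra else None,
        )


@dataclass
class FluorescenceMatrix:
    """Raw per-ROI fluorescence F_t (arbitrary units), neurons x frames."""

    F: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValueError("F must be 2D (neurons x frames)")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("F contains non-finite values")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]
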