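"""Stimulus protocols: ordered organ stimulation events on the imaging clock.

A protocol is an ordered list of :class:`StimulusEvent`, each tagged with the
organ it targets, the modality (balloon ``stretch`` or ``chemical`` perfusion),
a scalar intensity (microlitres for stretch; bolus volume or a nominal
concentration value for chemicals, with an optional ``chemical`` label), and a
half-open frame window ``[onset_frame, offset_frame)`` in volume indices.

Simultaneous stimulation of two organs (the "mix" condition of the paired
stomach--duodenum experiments) is represented by two events sharing the same
frame window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

STRETCH = "stretch"
CHEMICAL = "chemical"
_MODALITIES = (STRETCH, CHEMICAL)


@dataclass(frozen=True)
class StimulusEvent:
    organ: str
    modality: str
    intensity: float
    onset_frame: int
    offset_frame: int
    chemical: str | None = None

    def __post_init__(self) -> None:
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not 0 <= self.onset_frame < self.offset_frame:
            raise ValueError(
                f"invalid frame window [{self.onset_frame}, {self.offset_frame})"
            )

    @property
    def n_frames(self) -> int:
        return self.offset_frame - self.onset_frame

    def overlaps(self, other: "StimulusEvent") -> bool:
        return self.onset_frame < other.offset_frame and other.onset_frame < self.offset_frame


@dataclass
class StimulusProtocol:
    """Ordered stimulus events plus the total recording length in frames."""

    events: list[StimulusEvent]
    n_frames: int

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.offset_frame > self.n_frames:
                raise ValueError(
                    f"event {ev.organ}/{ev.modality} ends at frame {ev.offset_frame} "
                    f"beyond recording length {self.n_frames}"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[StimulusEvent]:
        return iter(self.events)

    def __getitem__(self, i: int) -> StimulusEvent:
        return self.events[i]

    @property
    def organs(self) -> list[str]:
        seen: list[str] = []
        for ev in self.events:
            if ev.organ not in seen:
                seen.append(ev.organ)
        return seen

    def stimulus_mask(self) -> "pd.Series":
        """Boolean per-frame mask, True inside any stimulus window."""
        import numpy as np

        mask = np.zeros(self.n_frames, dtype=bool)
        for ev in self.events:
            mask[ev.onset_frame : ev.offset_frame] = True
        return mask

    def simultaneous_partners(self, index: int) -> list[StimulusEvent]:
        """Events of *other* organs overlapping event ``index`` in time."""
        ev = self.events[index]
        return [
            o
            for j, o in enumerate(self.events)
            if j != index and o.organ != ev.organ and ev.overlaps(o)
        ]

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "organ": [e.organ for e in self.events],
                "modality": [e.modality for e in self.events],
                "intensity": [e.intensity for e in self.events],
                "onset_frame": [e.onset_frame for e in self.events],
                "offset_frame": [e.offset_frame for e in self.events],
                "chemical": [e.chemical for e in self.events],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.insert(0, "n_frames", self.n_frames)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StimulusProtocol":
        df = pd.read_csv(path)
        required = {"organ", "modality", "intensity", "onset_frame", "offset_frame"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"protocol file {path} missing columns {sorted(missing)}")
        events = []
        for row_idx, row in df.iterrows():
            if row["onset_frame"] >= row["offset_frame"]:
                raise ValueError(
                    f"protocol row {row_idx}: onset_frame >= offset_frame"
                )
            chem = row.get("chemical")
            if pd.isna(chem):
                chem = None
            events.append(
                StimulusEvent(
                    organ=str(row["organ"]),
                    modality=str(row["modality"]),
                    intensity=float(row["intensity"]),
                    onset_frame=int(row["onset_frame"]),
                    offset_frame=int(row["offset_frame"]),
                    chemical=chem,
                )
            )
        if "n_frames" in df.columns:
            n_frames = int(df["n_frames"].iloc[0])
        else:
            n_frames = max(e.offset_frame for e in events)
        return cls(events=events, n_frames=n_frames)


def build_protocol(
    blocks: Sequence[tuple[str, str, float]],
    *,
    stim_frames: int = 50,
    gap_frames: int = 40,
    pre_frames: int = 40,
    post_frames: int = 40,
    chemical_labels: dict[str, str] | None = None,
) -> StimulusProtocol:
    """Lay out one event per ``(organ, modality, intensity)`` block in series.

    Defaults mirror the study design at 1.25 volumes/s: 40-s stimuli
    (50 frames), 32-s inter-stimulus gaps and a 32-s pre-roll, long enough for
    the 24-s pre-stimulus baseline window of every event.
    """
    events = []
    t = pre_frames
    chemical_labels = chemical_labels or {}
    for organ, modality, intensity in blocks:
        events.append(
            StimulusEvent(
                organ=organ,
                modality=modality,
                intensity=float(intensity),
                onset_frame=t,
                offset_frame=t + stim_frames,
                chemical=chemical_labels.get(organ),
            )
        )
        t += stim_frames + gap_frames
    return StimulusProtocol(events=events, n_frames=t - gap_frames + post_frames)


def default_protocol(**kwargs) -> StimulusProtocol:
    """The graded multi-organ series: stomach 150/300/600/900 ul, duodenum
    90/115/140 ul balloon stretches and a laryngeal water perfusion."""
    blocks = [
        ("stomach", STRETCH, 150),
        ("stomach", STRETCH, 300),
        ("stomach", STRETCH, 600),
        ("stomach", STRETCH, 900),
        ("duodenum", STRETCH, 90),
        ("duodenum", STRETCH, 115),
        ("duodenum", STRETCH, 140),
        ("larynx", CHEMICAL, 100),
    ]
    kwargs.setdefault("chemical_labels", {"larynx": "water"})
    return build_protocol(blocks, **kwargs)


def paired_pulse_protocol(
    *,
    suppressed_organ: str = "duodenum",
    suppressor_organ: str = "stomach",
    suppressed_intensity: float = 115,
    suppressor_intensity: float = 600,
    stim_frames: int = 50,
    gap_frames: int = 80,
    pre_frames: int = 40,
) -> tuple[StimulusProtocol, dict[str, int]]:
    """Cross-inhibition series S1, D1, M1, S2, D2, M2 (mix = both balloons).

    Inter-stimulus gaps default to 64 s so responses decay fully before the
    next pre-stimulus baseline window. Returns the protocol plus a map from
    the six measurement names (``d_S1`` .. ``d_M2``) to the protocol index
    whose window they are measured in (for the mix, the suppressed organ's
    event).
    """
    events: list[StimulusEvent] = []
    index: dict[str, int] = {}
    t = pre_frames

    def _add(organ: str, intensity: float) -> int:
        events.append(
            StimulusEvent(organ, STRETCH, float(intensity), t, t + stim_frames)
        )
        return len(events) - 1

    for rep in (1, 2):
        index[f"d_S{rep}"] = _add(suppressor_organ, suppressor_intensity)
        t += stim_frames + gap_frames
        index[f"d_D{rep}"] = _add(suppressed_organ, suppressed_intensity)
        t += stim_frames + gap_frames
        _add(suppressor_organ, suppressor_intensity)
        index[f"d_M{rep}"] = _add(suppressed_organ, suppressed_intensity)
        t += stim_frames + gap_frames
    return (
        StimulusProtocol(events=events, n_frames=t),
        index,
    )
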