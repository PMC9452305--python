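"""Raw fluorescence to detrended dF/F and per-stimulus baseline statistics.

dF/F is (F_t - F0) / F0 with F0 the mean over a pre-stimulus baseline window.
Traces are then detrended (linear fit on non-stimulus frames by default) to
remove non-stationary effects such as photobleaching — except for recordings
flagged for exclusion (duodenal chemical perfusion runs), which pass through
unchanged.

Because thresholds are compared against the dF/F trace itself, the
per-stimulus baseline statistics (F0, s0 and theta = F0 + 2.5 * s0) are
computed on the detrended dF/F trace, so theta is in dF/F units and F0 is
close to zero. This is the only dimensionally coherent reading of comparing
"dF/F during the stimulation period" with a threshold built from baseline
fluorescence statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import FluorescenceMatrix
from .protocol import StimulusEvent, StimulusProtocol

logger = logging.getLogger(__name__)

THETA_SD_MULTIPLIER = 2.5
BASELINE_S = 24.0  # pre-stimulus baseline window, seconds
MECH_PRE_FRAMES = 7  # local pre-onset window for the mechanical criterion
CHEM_PRE_FRAMES = 25  # local pre-onset window for the chemical criterion


@dataclass
class BaselineStats:
    """Per neuron x stimulus baseline statistics on the dF/F trace."""

    F0: float  # mean over the 24-s pre-stimulus window
    s0: float  # sample SD over that window
    theta: float  # response threshold F0 + 2.5 * s0
    F0_m: float  # mean of the 7 pre-onset frames (mechanical criterion)
    s0_m: float
    F0_c: float  # mean of the 25 pre-onset frames (chemical criterion)
    s0_c: float


@dataclass
class DffMatrix:
    """Per-neuron, per-frame dF/F plus lazily computed baseline statistics."""

    dff: np.ndarray
    frame_rate_hz: float
    detrended: bool = False
    baseline: dict[tuple[int, int], BaselineStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2:
            raise ValueError("dff must be 2D (neurons x frames)")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


def compute_dff(
    F: FluorescenceMatrix, baseline_window: tuple[int, int]
) -> DffMatrix:
    """dF/F = (F_t - F0) / F0 with F0 averaged over ``baseline_window``
    (half-open frame range). Raises if any neuron's F0 is non-positive."""
    start, stop = baseline_window
    if not 0 <= start < stop <= F.n_frames:
        raise ValueError(f"invalid baseline window [{start}, {stop})")
    F0 = F.F[:, start:stop].mean(axis=1)
    bad = np.flatnonzero(F0 <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive baseline F0 for neuron(s) {bad[:10].tolist()}; "
            "dF/F undefined"
        )
    dff = (F.F - F0[:, None]) / F0[:, None]
    return DffMatrix(dff=dff, frame_rate_hz=F.frame_rate_hz)


def detrend_trace(
    trace: np.ndarray,
    stimulus_mask: np.ndarray | None = None,
    exclude: bool = False,
    method: str = "linear",
    percentile: float = 20.0,
    window_frames: int = 75,
) -> np.ndarray:
    """Remove a slow trend estimated on non-stimulus frames.

    ``exclude=True`` returns the trace unchanged (used for duodenal chemical
    perfusion runs). ``method`` is ``"linear"`` (default) or
    ``"percentile"`` (running-percentile baseline subtraction).

    Photobleaching scales fluorescence multiplicatively, so the linear
    method removes the fitted trend by division on the (1 + dF/F) scale:
    out = (1 + trace) / (1 + trend) - 1. This restores late-recording
    response amplitudes instead of merely re-zeroing the baseline.
    """
    trace = np.asarray(trace, dtype=float)
    if exclude:
        return trace.copy()
    n = trace.size
    if stimulus_mask is None:
        fit_idx = np.arange(n)
    else:
        fit_idx = np.flatnonzero(~np.asarray(stimulus_mask, dtype=bool))
        if fit_idx.size < 2:
            logger.warning(
                "all frames inside stimuli; falling back to whole-trace fit"
            )
            fit_idx = np.arange(n)
    if method == "linear":
        coef = np.polyfit(fit_idx, trace[fit_idx], 1)
        trend = np.polyval(coef, np.arange(n))
        if np.any(1.0 + trend < 0.05):
            logger.warning(
                "fitted trend approaches -1; subtracting instead of dividing"
            )
            return trace - trend
        return (1.0 + trace) / (1.0 + trend) - 1.0
    if method == "percentile":
        half = max(1, window_frames // 2)
        base = np.array(
            [
                np.percentile(trace[max(0, i - half) : min(n, i + half + 1)], percentile)
                for i in range(n)
            ]
        )
        return trace - base
    raise ValueError(f"unknown detrend method {method!r}")


def detrend_matrix(
    dff: DffMatrix,
    protocol: StimulusProtocol,
    exclude: bool = False,
    method: str = "linear",
    tail_frames: int = 10,
) -> DffMatrix:
    """Detrend every row against the protocol's non-stimulus frames.

    ``tail_frames`` extra frames after each stimulus offset are also excluded
    from the fit so indicator decay tails do not bias the trend estimate.
    """
    if exclude or dff.n_neurons == 0:
        return DffMatrix(dff.dff.copy(), dff.frame_rate_hz, detrended=False)
    mask = np.asarray(protocol.stimulus_mask())
    for ev in protocol:
        mask[ev.offset_frame : ev.offset_frame + tail_frames] = True
    out = np.vstack(
        [detrend_trace(row, mask, method=method) for row in dff.dff]
    )
    return DffMatrix(out, dff.frame_rate_hz, detrended=True)


def baseline_stats(
    dff_row: np.ndarray,
    stimulus: StimulusEvent,
    frame_rate_hz: float,
    protocol: StimulusProtocol | None = None,
) -> BaselineStats:
    """Baseline statistics in the windows preceding ``stimulus`` onset.

    The long window spans 24 s (30 frames at 1.25 Hz); the local mechanical
    and chemical windows span the 7 and 25 frames before onset. Raises when
    the long window does not fit before the onset. Overlap of the long window
    with a preceding stimulus is allowed with a logged warning.
    """
    dff_row = np.asarray(dff_row, dtype=float)
    n_long = int(round(BASELINE_S * frame_rate_hz))
    onset = stimulus.onset_frame
    if onset < n_long:
        raise ValueError(
            f"insufficient pre-stimulus frames for {stimulus.organ}/"
            f"{stimulus.modality} at frame {onset}: need {n_long}"
        )
    if protocol is not None:
        for ev in protocol:
            if ev is not stimulus and ev.offset_frame > onset - n_long and ev.onset_frame < onset:
                logger.warning(
                    "baseline window of %s@%d overlaps preceding %s event",
                    stimulus.organ,
                    onset,
                    ev.organ,
                )
                break

    long_win = dff_row[onset - n_long : onset]
    F0 = float(long_win.mean())
    s0 = float(long_win.std(ddof=1)) if n_long > 1 else 0.0

    mech = dff_row[onset - MECH_PRE_FRAMES : onset]
    F0_m = float(mech.mean())
    s0_m = float(mech.std(ddof=1)) if mech.size > 1 else 0.0

    if onset >= CHEM_PRE_FRAMES:
        chem = dff_row[onset - CHEM_PRE_FRAMES : onset]
        F0_c = float(chem.mean())
        s0_c = float(chem.std(ddof=1))
    else:
        F0_c = s0_c = float("nan")

    return BaselineStats(
        F0=F0,
        s0=s0,
        theta=F0 + THETA_SD_MULTIPLIER * s0,
        F0_m=F0_m,
        s0_m=s0_m,
        F0_c=F0_c,
        s0_c=s0_c,
    )


def compute_baselines(dff: DffMatrix, protocol: StimulusProtocol) -> DffMatrix:
    """Fill ``dff.baseline`` with stats for every neuron x stimulus pair.

    Vectorized across neurons; window semantics identical to
    :func:`baseline_stats` (which validates window fit once per stimulus).
    """
    for j, ev in enumerate(protocol):
        # validates the windows and emits any overlap warning once
        baseline_stats(dff.dff[0], ev, dff.frame_rate_hz, protocol)
        onset = ev.onset_frame
        n_long = int(round(BASELINE_S * dff.frame_rate_hz))
        long_win = dff.dff[:, onset - n_long : onset]
        F0 = long_win.mean(axis=1)
        s0 = long_win.std(axis=1, ddof=1) if n_long > 1 else np.zeros(dff.n_neurons)
        mech = dff.dff[:, onset - MECH_PRE_FRAMES : onset]
        F0_m = mech.mean(axis=1)
        s0_m = mech.std(axis=1, ddof=1) if mech.shape[1] > 1 else np.zeros(dff.n_neurons)
        if onset >= CHEM_PRE_FRAMES:
            chem = dff.dff[:, onset - CHEM_PRE_FRAMES : onset]
            F0_c = chem.mean(axis=1)
            s0_c = chem.std(axis=1, ddof=1)
        else:
            F0_c = s0_c = np.full(dff.n_neurons, np.nan)
        for i in range(dff.n_neurons):
            dff.baseline[(i, j)] = BaselineStats(
                F0=float(F0[i]),
                s0=float(s0[i]),
                theta=float(F0[i] + THETA_SD_MULTIPLIER * s0[i]),
                F0_m=float(F0_m[i]),
                s0_m=float(s0_m[i]),
                F0_c=float(F0_c[i]),
                s0_c=float(s0_c[i]),
            )
    return dff
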