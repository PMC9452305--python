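"""Response calling, magnitudes, kinetic classes and FOV inclusion filters.

A neuron responds to a mechanical stimulus when, during the stimulation
period, its dF/F (1) exceeds theta for more than three continuous frames
(i.e. at least four) and (2) exceeds both the local 7-frame pre-onset bound
F0' + 2*s0' and theta for at least two continuous frames. The chemical
criterion evaluates the stimulation period plus the 20 frames after offset,
requires more than four continuous frames above theta, and uses the
25-frame pre-onset bound F0'' + 2*s0''. Response magnitude is the maximum of
the 5-frame moving-averaged dF/F in the matching window, minus theta
(negative values are kept; reporting clips at zero).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .protocol import CHEMICAL, StimulusEvent, StimulusProtocol
from .traces import BaselineStats, DffMatrix

logger = logging.getLogger(__name__)

MECH_MIN_RUN = 4  # "more than three continuous frames"
CHEM_MIN_RUN = 5  # "more than four continuous frames"
LOCAL_MIN_RUN = 2  # "for at least two continuous frames"
CHEM_POST_FRAMES = 20
SMOOTH_FRAMES = 5

RAPID = "rapid"
SLOW = "slow"
NONE = "none"


def longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return 0
    padded = np.concatenate(([False], mask, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max()) if starts.size else 0


def _call(
    dff_row: np.ndarray,
    stats: BaselineStats,
    window: tuple[int, int],
    local_bound: float,
    min_run: int,
) -> tuple[bool, dict]:
    seg = np.asarray(dff_row)[window[0] : window[1]]
    run_theta = longest_run(seg > stats.theta)
    bound = max(local_bound, stats.theta)
    run_local = longest_run(seg > bound)
    responsive = run_theta >= min_run and run_local >= LOCAL_MIN_RUN
    return responsive, {
        "n_theta_frames": run_theta,
        "n_local_frames": run_local,
        "window": window,
    }


def call_mechanical_response(
    dff_row: np.ndarray, stats: BaselineStats, stimulus: StimulusEvent
) -> tuple[bool, dict]:
    """Mechanical criterion over [onset, offset)."""
    if stimulus.n_frames < MECH_MIN_RUN:
        logger.warning(
            "stimulus window of %d frames cannot satisfy the %d-frame criterion",
            stimulus.n_frames,
            MECH_MIN_RUN,
        )
        return False, {"n_theta_frames": 0, "n_local_frames": 0, "window": None}
    local = stats.F0_m + 2.0 * stats.s0_m
    return _call(
        dff_row,
        stats,
        (stimulus.onset_frame, stimulus.offset_frame),
        local,
        MECH_MIN_RUN,
    )


def call_chemical_response(
    dff_row: np.ndarray, stats: BaselineStats, stimulus: StimulusEvent
) -> tuple[bool, dict]:
    """Chemical criterion over [onset, offset + 20 frames)."""
    if not np.isfinite(stats.F0_c):
        raise ValueError(
            f"chemical baseline window unavailable before frame {stimulus.onset_frame}"
        )
    n = len(dff_row)
    stop = stimulus.offset_frame + CHEM_POST_FRAMES
    if stop > n:
        logger.warning("chemical window truncated at recording end (%d > %d)", stop, n)
        stop = n
    if stop - stimulus.onset_frame < CHEM_MIN_RUN:
        logger.warning("chemical window too short for the %d-frame criterion", CHEM_MIN_RUN)
        return False, {"n_theta_frames": 0, "n_local_frames": 0, "window": None}
    local = stats.F0_c + 2.0 * stats.s0_c
    return _call(dff_row, stats, (stimulus.onset_frame, stop), local, CHEM_MIN_RUN)


def smooth_trace(trace: np.ndarray, window: int = SMOOTH_FRAMES) -> np.ndarray:
    """Centered moving average, window shrinking at the trace edges."""
    return (
        pd.Series(np.asarray(trace, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def response_magnitude(
    dff_row: np.ndarray,
    stats: BaselineStats,
    stimulus: StimulusEvent,
    modality: str | None = None,
) -> float:
    """Max of the 5-frame smoothed dF/F in the criterion window, minus theta."""
    modality = modality or stimulus.modality
    start = stimulus.onset_frame
    stop = stimulus.offset_frame
    if modality == CHEMICAL:
        stop = min(stop + CHEM_POST_FRAMES, len(dff_row))
    if stop <= start:
        raise ValueError("empty response window")
    smoothed = smooth_trace(dff_row)
    return float(smoothed[start:stop].max() - stats.theta)


# --------------------------------------------------------------- full tables


def call_responses(
    dff: DffMatrix,
    protocol: StimulusProtocol,
    seed: int = 0,
    fov_id: int = 0,
) -> pd.DataFrame:
    """Apply the matching criterion to every neuron x stimulus pair.

    Requires ``dff.baseline`` to be populated (see
    :func:`viscmap.traces.compute_baselines`). Returns a tidy table with one
    row per neuron x stimulus, plus a per-neuron kinetic class from k-means
    clustering of the onset-aligned responsive traces.
    """
    # smooth all rows once (same centered shrinking-window average as
    # smooth_trace)
    smoothed = (
        pd.DataFrame(dff.dff.T)
        .rolling(SMOOTH_FRAMES, center=True, min_periods=1)
        .mean()
        .to_numpy()
        .T
    )
    rows = []
    for j, ev in enumerate(protocol):
        start = ev.onset_frame
        stop = ev.offset_frame
        if ev.modality == CHEMICAL:
            stop = min(stop + CHEM_POST_FRAMES, dff.n_frames)
        for i in range(dff.n_neurons):
            stats = dff.baseline[(i, j)]
            if ev.modality == CHEMICAL:
                responsive, diag = call_chemical_response(dff.dff[i], stats, ev)
            else:
                responsive, diag = call_mechanical_response(dff.dff[i], stats, ev)
            mag = float(smoothed[i, start:stop].max() - stats.theta)
            rows.append(
                {
                    "fov_id": fov_id,
                    "neuron_id": i,
                    "stim_index": j,
                    "organ": ev.organ,
                    "modality": ev.modality,
                    "intensity": ev.intensity,
                    "responsive": bool(responsive),
                    "magnitude": mag,
                    "n_criteria_frames": diag["n_theta_frames"],
                }
            )
    table = pd.DataFrame(rows)
    table["kinetic_class"] = assign_kinetics(table, dff, protocol, seed=seed)
    return table


def assign_kinetics(
    table: pd.DataFrame,
    dff: DffMatrix,
    protocol: StimulusProtocol,
    seed: int = 0,
) -> pd.Series:
    """Per-row kinetic class: each responsive neuron is classified once from
    the onset-aligned window of its strongest responsive stimulus."""
    resp = table[table["responsive"]]
    classes = pd.Series(NONE, index=table.index, dtype=object)
    if resp.empty:
        return classes
    best = resp.loc[resp.groupby("neuron_id")["magnitude"].idxmax()]
    width = min(ev.n_frames for ev in protocol)
    traces = np.vstack(
        [
            dff.dff[int(r.neuron_id)][
                protocol[int(r.stim_index)].onset_frame : protocol[
                    int(r.stim_index)
                ].onset_frame
                + width
            ]
            for r in best.itertuples()
        ]
    )
    labels, _ = classify_kinetics(traces, seed=seed)
    per_neuron = dict(zip(best["neuron_id"], labels))
    mask = table["responsive"].to_numpy()
    classes[mask] = table.loc[mask, "neuron_id"].map(per_neuron).to_numpy()
    return classes


def classify_kinetics(
    traces: np.ndarray, k: int = 2, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, dict]:
    """k-means (k=2) on peak-normalized onset-aligned traces.

    The cluster whose mean trace sustains more of its early activity into the
    late window (larger late/early ratio) is labelled ``slow``; the other
    ``rapid``. Fewer than two traces cannot be clustered and are labelled
    ``none``; an effectively single cluster (all traces identical) is
    labelled ``slow``.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n, w = traces.shape
    if n < 2:
        return np.array([NONE] * n, dtype=object), {"n_clusters": 0}
    peaks = traces.max(axis=1)
    normed = np.where(peaks[:, None] > 0, traces / np.maximum(peaks, 1e-300)[:, None], traces)
    if np.allclose(normed, normed[0], atol=1e-12):
        return np.array([SLOW] * n, dtype=object), {"n_clusters": 1}
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    idx = km.fit_predict(normed)
    third = max(1, w // 3)

    def late_early_ratio(mean_trace: np.ndarray) -> float:
        early = float(mean_trace[:third].mean())
        late = float(mean_trace[-third:].mean())
        return late / (abs(early) + 1e-12)

    ratios = [late_early_ratio(normed[idx == c].mean(axis=0)) for c in range(k)]
    slow_cluster = int(np.argmax(ratios))
    labels = np.where(idx == slow_cluster, SLOW, RAPID).astype(object)
    return labels, {"n_clusters": k, "ratios": ratios}


# ------------------------------------------------------------- FOV filtering

GLUCOSE_MIN_RESPONDERS = 5
STANDARD_MIN_RESPONDERS = 2
SPATIAL_MIN_SELECTIVE = 2


def filter_fovs(
    tables: dict,
    mode: str,
    stimuli: list | None = None,
    selective_counts: dict | None = None,
    pair: tuple | None = None,
) -> set:
    """FOV inclusion filters.

    ``glucose``: keep FOVs with >= 5 neurons responsive to every stimulus.
    ``standard``: keep FOVs with >= 2 neurons responsive to every analysed
    stimulus. ``spatial_pairs``: keep FOVs with >= 2 selectively tuned
    neurons per stimulus of ``pair`` (requires ``selective_counts``:
    fov_id -> {stimulus/organ label: count}).
    """
    if mode == "spatial_pairs":
        if selective_counts is None or pair is None:
            raise ValueError("spatial_pairs mode needs selective_counts and pair")
        return {
            fov
            for fov, counts in selective_counts.items()
            if all(counts.get(s, 0) >= SPATIAL_MIN_SELECTIVE for s in pair)
        }
    if mode not in ("glucose", "standard"):
        raise ValueError(f"unknown FOV filter mode {mode!r}")
    need = GLUCOSE_MIN_RESPONDERS if mode == "glucose" else STANDARD_MIN_RESPONDERS
    kept = set()
    for fov, table in tables.items():
        use = table if stimuli is None else table[table["stim_index"].isin(stimuli)]
        counts = use.groupby("stim_index")["responsive"].sum()
        if len(counts) and (counts >= need).all():
            kept.add(fov)
    return kept
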