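"""Cross-inhibition by paired-organ stimulation.

In the paired series — stomach (d_S1), duodenum (d_D1), mix (d_M1), then a
repeat (d_S2, d_D2, d_M2) — a neuron's response to the target organ is
classified as suppressed by the mixture only if all three strict
inequalities hold (duodenum target):

    (1) d_M1 < d_D1,  (2) d_M2 < d_D2,  (3) (d_M1 + d_M2) / 2 < d_D2

and symmetrically with d_S for the stomach target. Criterion (3) compares
the mix average against the *second* single-stimulus trial, exactly as the
criteria are stated; ties fail (strict inequalities).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .protocol import StimulusProtocol
from .responses import response_magnitude
from .traces import DffMatrix

logger = logging.getLogger(__name__)

DUODENUM_TARGET = "duodenum_response"
STOMACH_TARGET = "stomach_response"


@dataclass
class SuppressionSeries:
    """The six response magnitudes of the ordered paired-stimulus series."""

    d_S1: float
    d_D1: float
    d_M1: float
    d_S2: float
    d_D2: float
    d_M2: float

    def __post_init__(self) -> None:
        vals = [self.d_S1, self.d_D1, self.d_M1, self.d_S2, self.d_D2, self.d_M2]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all six magnitudes must be finite")


@dataclass
class SuppressionCall:
    target: str  # duodenum_response or stomach_response
    suppressed: bool  # mix < single vs mix ~ single


def classify_suppression(s: SuppressionSeries, target: str) -> SuppressionCall:
    """Apply the three strict criteria for the requested target organ."""
    if target == DUODENUM_TARGET:
        single1, single2 = s.d_D1, s.d_D2
    elif target == STOMACH_TARGET:
        single1, single2 = s.d_S1, s.d_S2
    else:
        raise ValueError(f"unknown suppression target {target!r}")
    suppressed = (
        s.d_M1 < single1
        and s.d_M2 < single2
        and (s.d_M1 + s.d_M2) / 2.0 < single2
    )
    return SuppressionCall(target=target, suppressed=suppressed)


def measure_suppression_series(
    dff: DffMatrix,
    protocol: StimulusProtocol,
    series_index: dict[str, int],
    neuron: int,
) -> SuppressionSeries:
    """Measure the six magnitudes for one neuron from a paired protocol.

    ``series_index`` maps the six measurement names to protocol event
    indices (see :func:`viscmap.protocol.paired_pulse_protocol`). The mix
    magnitudes are measured in the mix windows of the corresponding event.
    """
    required = ("d_S1", "d_D1", "d_M1", "d_S2", "d_D2", "d_M2")
    missing = [k for k in required if k not in series_index]
    if missing:
        raise ValueError(f"series index missing measurements {missing}")
    vals = {}
    for name in required:
        j = series_index[name]
        vals[name] = response_magnitude(
            dff.dff[neuron], dff.baseline[(neuron, j)], protocol[j]
        )
    return SuppressionSeries(**vals)


def suppression_table(
    dff: DffMatrix,
    protocol: StimulusProtocol,
    series_index: dict[str, int],
    responses: pd.DataFrame,
    target: str,
    fov_id: int = 0,
    mouse_id: int = 0,
) -> pd.DataFrame:
    """Classify every eligible neuron of one FOV.

    Eligible neurons selectively detected the target organ: they were called
    responsive to both single-stimulus trials of the target and to neither
    single trial of the paired organ. Neurons missing a trial are excluded
    with a log note.
    """
    if target == DUODENUM_TARGET:
        singles = (series_index["d_D1"], series_index["d_D2"])
        others = (series_index["d_S1"], series_index["d_S2"])
    elif target == STOMACH_TARGET:
        singles = (series_index["d_S1"], series_index["d_S2"])
        others = (series_index["d_D1"], series_index["d_D2"])
    else:
        raise ValueError(f"unknown suppression target {target!r}")
    resp = responses.set_index(["neuron_id", "stim_index"])["responsive"]
    rows = []
    for i in range(dff.n_neurons):
        try:
            eligible = all(bool(resp.loc[(i, j)]) for j in singles) and not any(
                bool(resp.loc[(i, j)]) for j in others
            )
        except KeyError:
            logger.warning("neuron %d missing a trial; excluded", i)
            continue
        if not eligible:
            continue
        series = measure_suppression_series(dff, protocol, series_index, i)
        call = classify_suppression(series, target)
        rows.append(
            {
                "mouse_id": mouse_id,
                "fov_id": fov_id,
                "neuron_id": i,
                "target": target,
                "suppressed": call.suppressed,
                **series.__dict__,
            }
        )
    return pd.DataFrame(rows)


def suppression_summary(calls: pd.DataFrame) -> dict:
    """Fractions suppressed per target: pooled and per mouse.

    Per-mouse analysis includes only animals in which both response types
    (suppressed and non-suppressed) were observed.
    """
    if calls.empty:
        return {}
    out: dict = {}
    for target, grp in calls.groupby("target"):
        per_mouse = {}
        for mouse, mg in grp.groupby("mouse_id"):
            n_sup = int(mg["suppressed"].sum())
            if 0 < n_sup < len(mg):  # both response types present
                per_mouse[mouse] = n_sup / len(mg)
        out[target] = {
            "n_eligible": int(len(grp)),
            "n_suppressed": int(grp["suppressed"].sum()),
            "fraction_suppressed": float(grp["suppressed"].mean()),
            "per_mouse": per_mouse,
        }
    return out


def dose_series_table(
    dff: DffMatrix,
    protocol: StimulusProtocol,
    target_organ: str,
    co_organ: str,
    neurons: list[int] | None = None,
) -> pd.DataFrame:
    """Response magnitude of target-organ events against the intensity of the
    simultaneously applied co-stimulus (0 when presented alone)."""
    rows = []
    ids = range(dff.n_neurons) if neurons is None else neurons
    for j, ev in enumerate(protocol):
        if ev.organ != target_organ:
            continue
        partners = [p for p in protocol.simultaneous_partners(j) if p.organ == co_organ]
        co_intensity = max((p.intensity for p in partners), default=0.0)
        for i in ids:
            rows.append(
                {
                    "neuron_id": i,
                    "stim_index": j,
                    "target_intensity": ev.intensity,
                    "co_intensity": co_intensity,
                    "magnitude": response_magnitude(
                        dff.dff[i], dff.baseline[(i, j)], ev
                    ),
                }
            )
    return pd.DataFrame(rows)
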