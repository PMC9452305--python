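"""Per-neuron tuning profiles, selectivity and stimulus-pair correlations.

A neuron's organ set contains every organ with at least one positively called
stimulus; tuning is ``selective`` (one organ), ``multi_organ`` (two or more)
or ``none``. Stimulus-pair Pearson correlations are computed across all
neurons responsive to at least one stimulus of the analysed set, using raw
magnitudes (possibly non-positive for non-called stimuli).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SELECTIVE = "selective"
MULTI = "multi_organ"
NONE = "none"


@dataclass
class TuningProfile:
    neuron_id: int
    magnitudes: dict[int, float]  # stim_index -> max smoothed dF/F - theta
    responsive_set: frozenset[int]  # stim indices with positive calls
    organ_set: frozenset[str]
    selectivity: str
    dominant_organ: str | None


def build_tuning_profiles(
    responses: pd.DataFrame,
    organ_order: list[str] | None = None,
) -> list[TuningProfile]:
    """One profile per neuron from a tidy response table.

    The table must map each stimulus to exactly one organ (its ``organ``
    column). The dominant organ is the organ of the maximal-magnitude
    responsive stimulus; ties are broken by ``organ_order`` (defaults to
    first-appearance order) with a logged note.
    """
    stim_norgans = responses.groupby("stim_index")["organ"].nunique()
    multi_mapped = stim_norgans[stim_norgans > 1]
    if len(multi_mapped):
        raise ValueError(
            f"stimuli mapped to multiple organs: {multi_mapped.index.tolist()}"
        )
    if organ_order is None:
        organ_order = list(dict.fromkeys(responses["organ"]))
    rank = {o: i for i, o in enumerate(organ_order)}
    unmapped = set(responses["organ"]) - set(rank)
    if unmapped:
        raise ValueError(f"organs missing from organ_order: {sorted(unmapped)}")

    profiles = []
    for nid, grp in responses.groupby("neuron_id"):
        mags = dict(zip(grp["stim_index"], grp["magnitude"]))
        resp = grp[grp["responsive"]]
        responsive_set = frozenset(resp["stim_index"])
        organ_set = frozenset(resp["organ"])
        if not organ_set:
            selectivity, dominant = NONE, None
        else:
            selectivity = SELECTIVE if len(organ_set) == 1 else MULTI
            best = resp["magnitude"].max()
            at_best = resp[resp["magnitude"] == best]
            if len(at_best) > 1 and at_best["organ"].nunique() > 1:
                logger.info("neuron %s: dominant-organ tie broken by organ order", nid)
            dominant = min(at_best["organ"], key=lambda o: rank[o])
        profiles.append(
            TuningProfile(
                neuron_id=int(nid),
                magnitudes=mags,
                responsive_set=responsive_set,
                organ_set=organ_set,
                selectivity=selectivity,
                dominant_organ=dominant,
            )
        )
    return profiles


def profiles_frame(profiles: list[TuningProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "neuron_id": [p.neuron_id for p in profiles],
            "selectivity": [p.selectivity for p in profiles],
            "dominant_organ": [p.dominant_organ for p in profiles],
            "organ_set": ["+".join(sorted(p.organ_set)) for p in profiles],
            "n_responsive_stimuli": [len(p.responsive_set) for p in profiles],
        }
    )


def stimulus_correlation_matrix(
    responses: pd.DataFrame,
    stim_indices: list[int] | None = None,
) -> pd.DataFrame:
    """Pearson R between stimulus magnitude vectors.

    Neurons responsive to at least one stimulus of the set are included; each
    stimulus contributes its raw magnitude for those neurons. Zero-variance
    columns yield missing (NaN) entries with a logged warning.
    """
    use = (
        responses
        if stim_indices is None
        else responses[responses["stim_index"].isin(stim_indices)]
    )
    mags = use.pivot(index="neuron_id", columns="stim_index", values="magnitude")
    resp = use.pivot(index="neuron_id", columns="stim_index", values="responsive")
    include = resp.fillna(False).any(axis=1)
    mags = mags[include]
    if len(mags) < 3:
        raise ValueError(
            f"need >= 3 neurons responsive to the stimulus set, got {len(mags)}"
        )
    X = mags.to_numpy(dtype=float)
    sd = X.std(axis=0)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        logger.warning(
            "zero-variance magnitude column(s) %s: correlations undefined",
            mags.columns[zero_var].tolist(),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R[zero_var, :] = np.nan
    R[:, zero_var] = np.nan
    ok = np.setdiff1d(np.arange(X.shape[1]), zero_var)
    R[ok, ok] = 1.0
    return pd.DataFrame(R, index=mags.columns, columns=mags.columns)


def convergence_summary(
    responses: pd.DataFrame,
    stim_a,
    stim_b,
    by: str = "stim_index",
) -> dict:
    """Responder-set overlap between two stimuli (or organs, ``by='organ'``).

    Returns ``frac_a_in_b`` = \\|A∩B\\|/\\|A\\|, ``frac_b_in_a`` = \\|A∩B\\|/\\|B\\|
    and ``relative_likelihood`` = P(respond B | respond A) / P(respond B)
    over all neurons in the table. Empty responder sets yield None fractions
    with a logged warning.
    """
    for s in (stim_a, stim_b):
        if s not in set(responses[by]):
            raise ValueError(f"{by} {s!r} not present in responses")
    resp = responses[responses["responsive"]]
    set_a = set(resp.loc[resp[by] == stim_a, "neuron_id"])
    set_b = set(resp.loc[resp[by] == stim_b, "neuron_id"])
    n_total = responses["neuron_id"].nunique()
    inter = len(set_a & set_b)
    if not set_a or not set_b:
        logger.warning("empty responder set for %r or %r", stim_a, stim_b)
        return {
            "n_a": len(set_a),
            "n_b": len(set_b),
            "n_intersection": inter,
            "frac_a_in_b": None,
            "frac_b_in_a": None,
            "relative_likelihood": None,
        }
    p_b = len(set_b) / n_total
    p_b_given_a = inter / len(set_a)
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_intersection": inter,
        "frac_a_in_b": inter / len(set_a),
        "frac_b_in_a": inter / len(set_b),
        "relative_likelihood": p_b_given_a / p_b if p_b > 0 else None,
    }
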