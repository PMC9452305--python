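"""Synthetic volumetric calcium-imaging experiments with known ground truth.

Emulates the study preparation end to end: ~2,800 nuclear-labelled neurons in
a 509.12 x 509.12 x 320 um field imaged as 5 planes at 1.25 volumes/s.
Responders are tuned to organs (mostly single-organ), occupy Gaussian spatial
domains offset by tens of micrometres, show rapidly or slowly adapting
kinetics, and a configurable fraction are cross-inhibited during simultaneous
paired-organ stimulation. Raw fluorescence combines a per-neuron baseline,
slow photobleaching drift, the stimulus-driven dF/F and Gaussian noise:

    F_i(t) = B_i * (1 + drift(t)) * (1 + dFF_i(t)) + B_i * noise_sd * eps(t)

Everything is deterministic for a fixed ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .containers import FluorescenceMatrix, NeuronSet
from .protocol import StimulusProtocol

RAPID = "rapid"
SLOW = "slow"
NONE = "none"


@dataclass
class GroundTruth:
    """Sidecar truth for parameter-recovery tests.

    ``amplitudes`` holds the *effective* noiseless response amplitude of each
    neuron to each protocol event (dose scaling and cross-inhibition already
    applied); a neuron is truly responsive to an event iff its entry is > 0.
    """

    tuning: list[frozenset[str]]  # per neuron, organs in the tuning set
    dominant_organ: list[str | None]
    amplitudes: np.ndarray  # (n_neurons, n_events) dF/F
    kinetic_class: np.ndarray  # (n,) str: rapid / slow / none
    positions_um: np.ndarray  # (n, 3)
    suppression_flags: dict[tuple[str, str], np.ndarray]  # (suppressed, suppressor)

    @property
    def n_neurons(self) -> int:
        return len(self.tuning)

    @property
    def responsive(self) -> np.ndarray:
        return self.amplitudes.max(axis=1) > 0

    def organ_responsive(self, organ: str, protocol: StimulusProtocol) -> np.ndarray:
        cols = [j for j, ev in enumerate(protocol) if ev.organ == organ]
        if not cols:
            return np.zeros(self.n_neurons, dtype=bool)
        return self.amplitudes[:, cols].max(axis=1) > 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "neuron_id": np.arange(self.n_neurons),
                "tuning": ["+".join(sorted(t)) for t in self.tuning],
                "dominant_organ": [d if d is not None else "" for d in self.dominant_organ],
                "kinetic_class": self.kinetic_class,
                "x_um": self.positions_um[:, 0],
                "y_um": self.positions_um[:, 1],
                "z_um": self.positions_um[:, 2],
            }
        )
        for (a, b), flags in self.suppression_flags.items():
            df[f"suppressed_{a}_by_{b}"] = flags
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------- traces


def _dose_factor(intensity: float, ec50: float, hill_n: float) -> float:
    if intensity <= 0:
        return 0.0
    return intensity**hill_n / (intensity**hill_n + ec50**hill_n)


def _event_templates(
    protocol: StimulusProtocol, config: SimConfig, kinetic_class: str
) -> np.ndarray:
    """Unit-amplitude noiseless dF/F template per event, (n_events, n_frames).

    Slow class: saturating rise (tau ``kernel_rise_s``) to a sustained plateau
    for the stimulus duration, then exponential decay (``kernel_decay_s``).
    Rapid class: same rise multiplied by exponential relaxation toward
    baseline during the stimulus (``adapt_tau_s``).
    """
    if kinetic_class not in (RAPID, SLOW):
        raise ValueError(f"unknown kinetic class {kinetic_class!r}")
    fr = config.frame_rate_hz
    t = np.arange(protocol.n_frames) / fr
    out = np.zeros((len(protocol), protocol.n_frames))
    for j, ev in enumerate(protocol):
        t_on = ev.onset_frame / fr
        t_off = ev.offset_frame / fr
        during = (t >= t_on) & (t < t_off)
        rel = t[during] - t_on
        rise = 1.0 - np.exp(-rel / config.kernel_rise_s)
        if kinetic_class == RAPID:
            shape = rise * np.exp(-rel / config.adapt_tau_s)
        else:
            shape = rise
        out[j, during] = shape
        # decay from the value the response would reach at stimulus offset
        rel_off = t_off - t_on
        v_off = 1.0 - np.exp(-rel_off / config.kernel_rise_s)
        if kinetic_class == RAPID:
            v_off *= np.exp(-rel_off / config.adapt_tau_s)
        after = t >= t_off
        out[j, after] = v_off * np.exp(-(t[after] - t_off) / config.kernel_decay_s)
    # responses are exactly zero outside stimulus-driven transients: clip the
    # asymptotic decay tail once it falls below a negligible level
    out[out < 1e-6] = 0.0
    return out


def synthesize_trace(
    amplitudes: np.ndarray,
    kinetic_class: str,
    protocol: StimulusProtocol,
    config: SimConfig,
) -> np.ndarray:
    """Noiseless per-frame dF/F of one neuron given per-event amplitudes."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (len(protocol),):
        raise ValueError("need one amplitude per protocol event")
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be non-negative")
    if kinetic_class == NONE or not np.any(amplitudes > 0):
        return np.zeros(protocol.n_frames)
    templates = _event_templates(protocol, config, kinetic_class)
    return amplitudes @ templates


# ----------------------------------------------------------------- experiment


def _draw_tuning(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[frozenset[str]], list[str | None], np.ndarray]:
    """Tuning set, dominant organ and (n, n_organs) base amplitudes."""
    n = config.n_neurons
    organs = [o.label for o in config.organs]
    weights = np.array([o.weight for o in config.organs], dtype=float)
    weights = weights / weights.sum()

    responsive = rng.random(n) < config.frac_responsive
    multi = responsive & (rng.random(n) < config.frac_multi)
    dominant_idx = rng.choice(len(organs), size=n, p=weights)
    base_amp = np.zeros((n, len(organs)))
    amp = np.exp(rng.normal(np.log(config.amplitude_median), config.amplitude_sigma, n))

    tuning: list[frozenset[str]] = []
    dominant: list[str | None] = []
    lo, hi = config.multi_secondary_range
    for i in range(n):
        if not responsive[i]:
            tuning.append(frozenset())
            dominant.append(None)
            continue
        d = dominant_idx[i]
        members = {d}
        base_amp[i, d] = amp[i]
        if multi[i] and len(organs) >= 2:
            others = [k for k in range(len(organs)) if k != d]
            w = weights[others] / weights[others].sum()
            s = int(rng.choice(others, p=w))
            members.add(s)
            base_amp[i, s] = amp[i] * rng.uniform(lo, hi)
        tuning.append(frozenset(organs[k] for k in members))
        dominant.append(organs[d])
    return tuning, dominant, base_amp


def _draw_positions(
    config: SimConfig,
    dominant: list[str | None],
    rng: np.random.Generator,
) -> np.ndarray:
    n = config.n_neurons
    fx, fy, fz = config.fov_um
    organ_map = config.organ_map()
    pos = np.empty((n, 3))
    pos[:, 0] = rng.uniform(0, fx, n)
    pos[:, 1] = rng.uniform(0, fy, n)
    pos[:, 2] = rng.uniform(0, fz, n)
    for i, d in enumerate(dominant):
        if d is None:
            continue
        spec = organ_map[d]
        pos[i, 0] = spec.centroid_um[0] + rng.normal(0, spec.spread_um)
        pos[i, 1] = spec.centroid_um[1] + rng.normal(0, spec.spread_um)
    eps = 1e-6
    pos[:, 0] = np.clip(pos[:, 0], 0, fx - eps)
    pos[:, 1] = np.clip(pos[:, 1], 0, fy - eps)
    return pos


def _effective_amplitudes(
    config: SimConfig,
    protocol: StimulusProtocol,
    tuning: list[frozenset[str]],
    base_amp: np.ndarray,
    suppression_flags: dict[tuple[str, str], np.ndarray],
) -> np.ndarray:
    organs = [o.label for o in config.organs]
    organ_map = config.organ_map()
    # per-organ EC50 defaults to the median intensity of that organ's events;
    # the dose curve is normalized to its value at the organ's strongest
    # protocol intensity so a neuron's drawn amplitude is its peak-dose dF/F
    ec50: dict[str, float] = {}
    top: dict[str, float] = {}
    for label, spec in organ_map.items():
        ints = [ev.intensity for ev in protocol if ev.organ == label]
        if spec.ec50 is not None:
            ec50[label] = spec.ec50
        else:
            ec50[label] = float(np.median(ints)) if ints else 1.0
        top[label] = max(ints) if ints else 1.0

    def dose(organ: str, intensity: float) -> float:
        spec = organ_map[organ]
        ref = _dose_factor(top[organ], ec50[organ], spec.hill_n)
        if ref == 0:
            return 0.0
        return _dose_factor(intensity, ec50[organ], spec.hill_n) / ref

    n = base_amp.shape[0]
    amps = np.zeros((n, len(protocol)))
    for j, ev in enumerate(protocol):
        col = organs.index(ev.organ)
        amps[:, j] = base_amp[:, col] * dose(ev.organ, ev.intensity)
        # cross-inhibition from simultaneously presented other-organ events
        for partner in protocol.simultaneous_partners(j):
            for sup in config.suppression:
                if sup.suppressed_organ != ev.organ:
                    continue
                if sup.suppressor_organ != partner.organ:
                    continue
                flags = suppression_flags[(sup.suppressed_organ, sup.suppressor_organ)]
                amps[flags, j] *= 1.0 - sup.strength * dose(
                    partner.organ, partner.intensity
                )
    return amps


def generate_experiment(
    config: SimConfig, protocol: StimulusProtocol
) -> tuple[NeuronSet, GroundTruth, FluorescenceMatrix]:
    """Draw one complete synthetic FOV: geometry, tuning, traces.

    Deterministic for a fixed ``config.seed``. Raises ``ValueError`` when the
    protocol references an organ absent from the config or no neurons are
    requested.
    """
    if config.n_neurons == 0:
        raise ValueError("zero neurons requested")
    known = {o.label for o in config.organs}
    unknown = [ev.organ for ev in protocol if ev.organ not in known]
    if unknown:
        raise ValueError(f"protocol organs not in config: {sorted(set(unknown))}")

    rng = np.random.default_rng(config.seed)
    tuning, dominant, base_amp = _draw_tuning(config, rng)
    positions = _draw_positions(config, dominant, rng)

    suppression_flags: dict[tuple[str, str], np.ndarray] = {}
    for sup in config.suppression:
        eligible = np.array([sup.suppressed_organ in t for t in tuning])
        flags = eligible & (rng.random(config.n_neurons) < sup.fraction)
        suppression_flags[(sup.suppressed_organ, sup.suppressor_organ)] = flags

    amps = _effective_amplitudes(config, protocol, tuning, base_amp, suppression_flags)

    kinetic = np.full(config.n_neurons, NONE, dtype=object)
    responders = amps.max(axis=1) > 0
    is_rapid = rng.random(config.n_neurons) < config.frac_rapid
    kinetic[responders & is_rapid] = RAPID
    kinetic[responders & ~is_rapid] = SLOW

    # noiseless dF/F: one matrix product per kinetic class
    dff_true = np.zeros((config.n_neurons, protocol.n_frames))
    for klass in (RAPID, SLOW):
        idx = np.flatnonzero(kinetic == klass)
        if idx.size:
            templates = _event_templates(protocol, config, klass)
            dff_true[idx] = amps[idx] @ templates

    # raw fluorescence with baseline, bleaching drift and noise
    t_min = np.arange(protocol.n_frames) / config.frame_rate_hz / 60.0
    drift = 1.0 - config.drift_rate * t_min
    baseline = rng.uniform(*config.baseline_au, config.n_neurons)
    F = baseline[:, None] * drift[None, :] * (1.0 + dff_true)
    F = F + baseline[:, None] * config.noise_sd * rng.standard_normal(F.shape)

    neurons = NeuronSet(
        ids=np.arange(config.n_neurons),
        centroids_um=positions,
        labels=pd.DataFrame(
            {
                "dominant_organ": [d if d is not None else "" for d in dominant],
                "kinetic_class": kinetic.astype(str),
            }
        ),
    )
    truth = GroundTruth(
        tuning=tuning,
        dominant_organ=dominant,
        amplitudes=amps,
        kinetic_class=kinetic.astype(str),
        positions_um=positions,
        suppression_flags=suppression_flags,
    )
    fluor = FluorescenceMatrix(F=F, frame_rate_hz=config.frame_rate_hz)
    return neurons, truth, fluor


# ------------------------------------------------------------------ rendering


def render_movie(
    neurons: NeuronSet,
    F: FluorescenceMatrix,
    config: SimConfig,
    seed: int | None = None,
) -> np.ndarray:
    """Render (frames, planes, H, W) float32 frames of Gaussian nuclei.

    Each neuron is drawn on its nearest plane as a 2D Gaussian spot whose
    peak tracks its raw fluorescence; frames carry a constant background and
    additive Gaussian pixel noise. No axial blur is modelled.
    """
    if len(neurons) != F.n_neurons:
        raise ValueError("neuron count and fluorescence rows disagree")
    H, W = config.image_shape
    px_x, px_y = config.pixel_size_um
    fx, fy, fz = config.fov_um
    pos = neurons.centroids_um
    if np.any((pos[:, 0] < 0) | (pos[:, 0] >= fx) | (pos[:, 1] < 0) | (pos[:, 1] >= fy)):
        raise ValueError("neuron position outside the field of view")
    if np.any((pos[:, 2] < 0) | (pos[:, 2] > fz)):
        raise ValueError("neuron z outside the imaged volume")

    rng = np.random.default_rng(config.seed + 1000 if seed is None else seed)
    T = F.n_frames
    movie = np.full((T, config.n_planes, H, W), config.background_au, dtype=np.float32)

    sigma = config.nucleus_sigma_px
    rad = max(1, int(np.ceil(3 * sigma)))
    yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    kernel = np.exp(-(xx**2 + yy**2) / (2 * sigma**2)).astype(np.float32)

    plane_idx = np.clip(
        np.round(pos[:, 2] / config.plane_spacing_um).astype(int), 0, config.n_planes - 1
    )
    rows = np.clip(np.round(pos[:, 1] / px_y).astype(int), 0, H - 1)
    cols = np.clip(np.round(pos[:, 0] / px_x).astype(int), 0, W - 1)

    for i in range(len(neurons)):
        r, c, p = rows[i], cols[i], plane_idx[i]
        r0, r1 = max(0, r - rad), min(H, r + rad + 1)
        c0, c1 = max(0, c - rad), min(W, c + rad + 1)
        sub = kernel[r0 - (r - rad) : r1 - (r - rad), c0 - (c - rad) : c1 - (c - rad)]
        movie[:, p, r0:r1, c0:c1] += F.F[i][:, None, None].astype(np.float32) * sub
    movie += config.pixel_noise_sd * rng.standard_normal(movie.shape, dtype=np.float32)
    return movie


def write_movie_tiff(movie: np.ndarray, path: str | Path) -> None:
    """Write a (frames, planes, H, W) stack as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(movie, dtype=np.float32))


def read_movie_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))
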