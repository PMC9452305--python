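"""End-to-end orchestration: simulate -> (render/extract) -> call -> map ->
suppress, with every artifact written to a run directory plus a manifest
recording the seed, config hash, inputs and outputs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import SimConfig
from .protocol import StimulusProtocol, default_protocol, paired_pulse_protocol
from .responses import call_responses
from .roi import detect_nuclei_stack, extract_fluorescence
from .spatial import segregation_index
from .suppression import (
    DUODENUM_TARGET,
    STOMACH_TARGET,
    suppression_summary,
    suppression_table,
)
from .synth import generate_experiment, render_movie, write_movie_tiff
from .traces import BASELINE_S, compute_baselines, compute_dff, detrend_matrix
from .tuning import build_tuning_profiles, profiles_frame, stimulus_correlation_matrix

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "call", "map", "suppress", "report")
RESPONSE_COLUMNS = [
    "fov_id",
    "neuron_id",
    "stim_index",
    "organ",
    "modality",
    "intensity",
    "responsive",
    "magnitude",
    "n_criteria_frames",
    "kinetic_class",
]


def config_hash(config: SimConfig) -> str:
    return hashlib.sha256(
        yaml.safe_dump(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


# ------------------------------------------------------------------ table I/O


def write_responses(table: pd.DataFrame, path: str | Path) -> None:
    table[RESPONSE_COLUMNS].to_csv(path, index=False)


def read_responses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"response table {path} missing columns {sorted(missing)}")
    bad = df.index[~np.isfinite(df["magnitude"])]
    if len(bad):
        raise ValueError(f"response table {path}: non-finite magnitude at row {bad[0]}")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ------------------------------------------------------------------- pipeline


def process_experiment(
    fluor, protocol: StimulusProtocol, seed: int = 0, fov_id: int = 0, detrend: bool = True
):
    """Shared dF/F -> detrend -> baselines -> response-calling path.

    ``detrend=False`` skips trend removal, e.g. for drift-free synthetic
    recordings; duodenal chemical perfusion runs skip it automatically.
    """
    first_onset = min(ev.onset_frame for ev in protocol)
    n_base = int(round(BASELINE_S * fluor.frame_rate_hz))
    dff = compute_dff(fluor, (max(0, first_onset - n_base), first_onset))
    from .protocol import CHEMICAL

    has_duodenal_chem = any(
        ev.organ == "duodenum" and ev.modality == CHEMICAL for ev in protocol
    )
    dff = detrend_matrix(dff, protocol, exclude=has_duodenal_chem or not detrend)
    compute_baselines(dff, protocol)
    table = call_responses(dff, protocol, seed=seed, fov_id=fov_id)
    return dff, table


def run_pipeline(
    config: SimConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    mode: str = "all",
    protocol: StimulusProtocol | None = None,
) -> dict:
    """Execute the requested stage and its dependencies; returns the manifest.

    ``mode``: simulate | extract | call | map | suppress | report | all.
    ``extract`` runs the rendered-movie path (render -> detect nuclei ->
    extract fluorescence); other modes analyse the simulated traces directly.
    All randomness derives from a single root seed.
    """
    if mode not in STAGES + ("all",):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(config, (str, Path)):
        if not Path(config).exists():
            raise FileNotFoundError(f"config file not found: {config}")
        config = SimConfig.from_yaml(config)
    if seed is not None:
        config.seed = seed
    root_seed = config.seed

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "mode": mode,
        "seed": root_seed,
        "config_hash": config_hash(config),
        "version": __version__,
        "inputs": [],
        "outputs": {},
    }

    def _write(name: str, path: Path) -> None:
        manifest["outputs"][name] = path.name

    def _fail(stage: str, err: Exception) -> None:
        manifest["failed_stage"] = stage
        write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # ---- simulate -----------------------------------------------------
    try:
        proto = protocol if protocol is not None else default_protocol()
        neurons, truth, fluor = generate_experiment(config, proto)
        config.to_yaml(out / "config.yaml")
        proto.to_csv(out / "protocol.csv")
        neurons.to_csv(out / "neurons.csv")
        truth.to_csv(out / "ground_truth.csv")
        for name in ("config.yaml", "protocol.csv", "neurons.csv", "ground_truth.csv"):
            _write(name.split(".")[0], out / name)
    except Exception as err:  # noqa: BLE001 - abort names the stage
        _fail("simulate", err)
    if mode == "simulate":
        write_json(manifest, out / "manifest.json")
        return manifest

    # ---- extract (rendered-movie path) --------------------------------
    if mode == "extract":
        try:
            H, W = config.image_shape
            est_gb = fluor.n_frames * config.n_planes * H * W * 4 / 1e9
            if est_gb > 1.0:
                raise ValueError(
                    f"rendered movie would need ~{est_gb:.1f} GB; use a config "
                    "with a smaller image_shape / n_planes / protocol for the "
                    "rendered-movie path"
                )
            movie = render_movie(neurons, fluor, config, seed=root_seed + 1)
            write_movie_tiff(movie, out / "movie.tif")
            rois = detect_nuclei_stack(
                movie.mean(axis=0),
                pixel_size_um=config.pixel_size_um,
                plane_spacing_um=config.plane_spacing_um,
                min_area_px=5,
            )
            if not rois:
                raise ValueError("no nuclei detected in the rendered movie")
            fluor = extract_fluorescence(movie, rois, config.frame_rate_hz)
            pd.DataFrame(
                {
                    "roi_id": [r.roi_id for r in rois],
                    "x_um": [r.centroid_um[0] for r in rois],
                    "y_um": [r.centroid_um[1] for r in rois],
                    "z_um": [r.centroid_um[2] for r in rois],
                }
            ).to_csv(out / "rois.csv", index=False)
            _write("movie", out / "movie.tif")
            _write("rois", out / "rois.csv")
        except Exception as err:  # noqa: BLE001
            _fail("extract", err)

    # ---- call ----------------------------------------------------------
    try:
        dff, table = process_experiment(fluor, proto, seed=root_seed)
        write_responses(table, out / "responses.csv")
        _write("responses", out / "responses.csv")
    except Exception as err:  # noqa: BLE001
        _fail("call", err)
    if mode in ("extract", "call"):
        write_json(manifest, out / "manifest.json")
        return manifest

    # ---- map: tuning + spatial segregation -----------------------------
    try:
        organ_order = [o.label for o in config.organs]
        profiles = build_tuning_profiles(table, organ_order)
        profiles_frame(profiles).to_csv(out / "tuning_profiles.csv", index=False)
        _write("tuning_profiles", out / "tuning_profiles.csv")
        corr = stimulus_correlation_matrix(table)
        corr.to_csv(out / "stimulus_correlation.csv")
        _write("stimulus_correlation", out / "stimulus_correlation.csv")

        sel = {
            p.neuron_id: next(iter(p.organ_set))
            for p in profiles
            if p.selectivity == "selective"
        }
        si_results = {}
        for a, b in zip(organ_order, organ_order[1:]):
            Xa = neurons.centroids_um[
                [i for i, o in sel.items() if o == a], :2
            ]
            Xb = neurons.centroids_um[
                [i for i, o in sel.items() if o == b], :2
            ]
            if len(Xa) >= 2 and len(Xb) >= 2:
                r = segregation_index(Xa, Xb, seed=root_seed + 2)
                si_results[f"{a}_vs_{b}"] = r.to_dict()
        write_json(si_results, out / "segregation.json")
        _write("segregation", out / "segregation.json")
    except Exception as err:  # noqa: BLE001
        _fail("map", err)
    if mode == "map":
        write_json(manifest, out / "manifest.json")
        return manifest

    # ---- suppress: paired-stimulus series ------------------------------
    try:
        paired, series_index = paired_pulse_protocol()
        from dataclasses import replace

        sup_config = replace(config, seed=root_seed + 3)
        _, sup_truth, sup_fluor = generate_experiment(sup_config, paired)
        sup_dff, sup_table = process_experiment(sup_fluor, paired, seed=root_seed + 3)
        calls = pd.concat(
            [
                suppression_table(
                    sup_dff, paired, series_index, sup_table, DUODENUM_TARGET
                ),
                suppression_table(
                    sup_dff, paired, series_index, sup_table, STOMACH_TARGET
                ),
            ],
            ignore_index=True,
        )
        calls.to_csv(out / "suppression_calls.csv", index=False)
        write_json(suppression_summary(calls), out / "suppression_summary.json")
        _write("suppression_calls", out / "suppression_calls.csv")
        _write("suppression_summary", out / "suppression_summary.json")
    except Exception as err:  # noqa: BLE001
        _fail("suppress", err)

    write_json(manifest, out / "manifest.json")
    return manifest
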