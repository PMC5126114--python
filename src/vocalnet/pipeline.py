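"""End-to-end orchestration: one config in, a directory of session outputs out.

Stages: load (or simulate) audio -> per-channel detection -> caller
attribution -> noise filtering (optional, needs a trained model) ->
activity/burst metrics -> cross-correlation and turn-taking networks.
Given a pre-attributed event table instead of audio, the audio stages are
skipped.  Every run writes a manifest with the config, package version and
seed; CSV outputs are serialized at fixed precision so identical configs
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import session_activity
from .attribution import attribute_session
from .detection import detect_session
from .networks import build_cc_network, build_transition_network
from .noise_classifier import filter_events, load_model
from .session_io import (
    EventTable,
    GroupLayout,
    load_session,
    read_event_table,
    write_event_table,
    write_network,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ConfigError, StageError):
                raise
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run all applicable stages and write the session artifacts.

    Outputs (CSV unless noted): attributed_events, burst_metrics,
    per_bird_counts, cc_network, transition_counts + transition_probs,
    max_transition_network, and ``run_manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    session_block = config.get("session", {})
    has_audio = "audio" in session_block
    has_table = "event_table" in session_block
    if has_audio == has_table:
        raise ConfigError("session block must set exactly one of 'audio' or 'event_table'")

    if has_audio:
        table, duration_s, bird_ids = _audio_stages(config, out_dir)
        write_event_table(table, out_dir / "attributed_events.csv")
    else:
        table = read_event_table(session_block["event_table"])
        duration_s = float(session_block.get("duration_s") or table.df["end_s"].max())
        bird_ids = session_block.get("bird_ids") or sorted(table.df["bird_id"].unique())
    _analysis_stages(config, table, duration_s, bird_ids, out_dir)

    manifest = {
        "vocalnet_version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.get("seed"),
        "n_events": len(table),
        "duration_s": duration_s,
        "input_mode": "audio" if has_audio else "event_table",
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out_dir


@_stage("audio")
def _load_audio(config: dict):
    session_block = config["session"]
    layout_cfg = session_block.get("layout")
    if isinstance(layout_cfg, str):
        layout = GroupLayout.from_yaml(layout_cfg)
    elif isinstance(layout_cfg, dict):
        layout = GroupLayout.from_config(layout_cfg)
    else:
        layout = GroupLayout.default_square(tuple(session_block["audio"].keys()))
    return load_session(session_block["audio"], layout)


def _audio_stages(config: dict, out_dir: Path):
    session = _load_audio(config)
    det_cfg = config.get("detection", {})

    @_stage("detection")
    def _detect():
        threshold = det_cfg.get("threshold")
        threshold = None if threshold in (None, "auto") else float(threshold)
        kwargs = {}
        if "fft_size" in det_cfg:
            kwargs["fft_size"] = int(det_cfg["fft_size"])
        if "envelope_rate_hz" in det_cfg:
            kwargs["frame_rate"] = float(det_cfg["envelope_rate_hz"])
        if "highpass_cutoff_hz" in det_cfg:
            kwargs["cutoff"] = float(det_cfg["highpass_cutoff_hz"])
        return detect_session(session, threshold=threshold,
                              auto_k=float(det_cfg.get("auto_k", 8.0)), **kwargs)

    events = _detect()
    logger.info("detection: %s events", {b: len(v) for b, v in events.items()})

    @_stage("attribution")
    def _attribute():
        att_cfg = config.get("attribution", {})
        return attribute_session(events, session.layout,
                                 onset_tol_s=float(att_cfg.get("onset_tolerance_s", 0.015)))

    table = _attribute()

    cls_cfg = config.get("classifier", {})
    if cls_cfg.get("model"):

        @_stage("noise_filter")
        def _filter():
            model = load_model(cls_cfg["model"])
            return filter_events(table, session, model)

        table = _filter()

    return table, session.duration_s, list(session.layout.bird_ids)


def _analysis_stages(config: dict, table: EventTable, duration_s: float, bird_ids, out_dir: Path):
    act_cfg = config.get("activity", {})
    net_cfg = config.get("network", {})

    @_stage("activity")
    def _activity():
        metrics, counts = session_activity(
            table,
            duration_s,
            window_length_s=float(act_cfg.get("window_length_s", 60.0)),
            step_s=float(act_cfg.get("step_s", 30.0)),
            burst_factor=float(act_cfg.get("burst_factor", 1.10)),
        )
        metrics.to_frame().round(6).to_csv(out_dir / "burst_metrics.csv", index=False)
        pd.DataFrame(
            [{"bird_id": b, "n_vocalizations": counts.get(b, 0)} for b in bird_ids]
        ).to_csv(out_dir / "per_bird_counts.csv", index=False)

    _activity()

    @_stage("networks")
    def _networks():
        cc = build_cc_network(
            table,
            bird_ids,
            duration_s,
            bin_width_s=float(net_cfg.get("bin_width_s", 0.5)),
            onset_only=bool(net_cfg.get("onset_only", False)),
        )
        write_network(cc, out_dir / "cc_network.csv", graphml=bool(net_cfg.get("graphml", False)))
        matrix, max_net = build_transition_network(table, bird_ids)
        counts_df, probs_df = matrix.to_frames()
        counts_df.to_csv(out_dir / "transition_counts.csv")
        probs_df.round(9).to_csv(out_dir / "transition_probs.csv")
        write_network(max_net, out_dir / "max_transition_network.csv",
                      graphml=bool(net_cfg.get("graphml", False)))

    _networks()
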