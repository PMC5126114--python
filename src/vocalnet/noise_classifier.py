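"""Supervised removal of non-vocal noise (cage knocks, wing flutter).

Each detected event is summarized as a fixed-size feature vector: the
log-magnitude spectrogram of the clip restricted to the 500 Hz - 6 kHz band
over a 50 ms span.  Clips longer than 50 ms contribute their central 50 ms;
shorter clips are centered in the 50 ms span with exactly-zero flanks, so
every clip yields a vector of identical length.  A random-forest classifier
trained on a labeled corpus then separates "vocalization" from
"non-vocalization" clips, and events predicted as noise are dropped from
the attributed event table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

LABEL_VOC = "vocalization"
LABEL_NOISE = "non-vocalization"


@dataclass(frozen=True)
class FeatureConfig:
    """Spectrogram-feature geometry; must match between training and prediction."""

    sample_rate: int = 44100
    fft_size: int = 256
    hop: int = 128
    fmin_hz: float = 500.0
    fmax_hz: float = 6000.0
    clip_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.sample_rate < 2 * self.fmax_hz:
            raise ValueError(
                f"sample rate {self.sample_rate} puts Nyquist below fmax {self.fmax_hz}"
            )

    @property
    def clip_samples(self) -> int:
        return int(round(self.clip_ms / 1000.0 * self.sample_rate))

    @property
    def n_time_frames(self) -> int:
        return int(round(self.clip_samples / self.hop))

    @property
    def band_bins(self) -> np.ndarray:
        freqs = np.fft.rfftfreq(self.fft_size, 1.0 / self.sample_rate)
        return np.flatnonzero((freqs >= self.fmin_hz) & (freqs <= self.fmax_hz))

    @property
    def n_freq_bins(self) -> int:
        return len(self.band_bins)

    @property
    def n_features(self) -> int:
        return self.n_freq_bins * self.n_time_frames


def _spectrogram(clip: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Hann-windowed log1p-magnitude spectrogram, band-restricted; (freq, time)."""
    x = np.asarray(clip, dtype=np.float64)
    if len(x) < cfg.fft_size:  # pad symmetrically up to one window
        deficit = cfg.fft_size - len(x)
        x = np.pad(x, (deficit // 2, deficit - deficit // 2))
    n_frames = 1 + (len(x) - cfg.fft_size) // cfg.hop
    frames = np.lib.stride_tricks.sliding_window_view(x, cfg.fft_size)[:: cfg.hop][:n_frames]
    spec = np.abs(np.fft.rfft(frames * np.hanning(cfg.fft_size), axis=1))
    return np.log1p(spec[:, cfg.band_bins]).T


def featurize_clip(
    clip: np.ndarray,
    sample_rate: int,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Flattened fixed-size band-limited spectrogram of one clip.

    Long clips are cropped to their central 50 ms in the waveform domain
    (so the feature depends only on that central content); short clips are
    centered among all-zero spectrogram columns.
    """
    if config is None:
        config = FeatureConfig(sample_rate=sample_rate)
    elif sample_rate != config.sample_rate:
        raise ValueError(f"clip sample rate {sample_rate} != feature config {config.sample_rate}")
    clip = np.asarray(clip, dtype=np.float64)
    if len(clip) == 0:
        raise ValueError("empty clip")

    target = config.clip_samples
    if len(clip) > target:
        off = (len(clip) - target) // 2
        clip = clip[off : off + target]
    sg = _spectrogram(clip, config)  # (n_freq_bins, m)
    m = sg.shape[1]
    out = np.zeros((config.n_freq_bins, config.n_time_frames))
    if m >= config.n_time_frames:
        off = (m - config.n_time_frames) // 2
        out[:] = sg[:, off : off + config.n_time_frames]
    else:
        off = (config.n_time_frames - m) // 2
        out[:, off : off + m] = sg
    return out.ravel()


@dataclass
class ClassifierModel:
    """Fitted vocalization/noise forest plus the feature geometry it expects."""

    forest: RandomForestClassifier
    feature_config: FeatureConfig
    n_trees: int
    seed: int
    labels: tuple[str, str] = (LABEL_VOC, LABEL_NOISE)
    training_report: dict = field(default_factory=dict)

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        if features.shape[1] != self.feature_config.n_features:
            raise ValueError(
                f"feature length {features.shape[1]} != model's "
                f"{self.feature_config.n_features}; feature configs differ"
            )
        return self.forest.predict(features)


def train_classifier(
    labeled_clips: list[tuple[np.ndarray, str]],
    n_trees: int = 100,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
    eval_set: list[tuple[np.ndarray, str]] | None = None,
) -> ClassifierModel:
    """Fit the random forest on (feature_vector, label) pairs.

    Requires both classes and at least 20 examples.  If ``eval_set`` is
    given, the held-out misclassification fraction is stored in the
    training report.  Training is deterministic given ``seed``.
    """
    if len(labeled_clips) < 20:
        raise ValueError(f"need at least 20 labeled clips, got {len(labeled_clips)}")
    X = np.vstack([np.asarray(f, dtype=np.float64) for f, _ in labeled_clips])
    y = np.array([lab for _, lab in labeled_clips])
    classes = set(y)
    if len(classes) < 2:
        raise ValueError(f"training set holds a single class {classes}; need both")
    unknown = classes - {LABEL_VOC, LABEL_NOISE}
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")

    if feature_config is None:
        feature_config = FeatureConfig()
    if X.shape[1] != feature_config.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} != config's {feature_config.n_features}"
        )

    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    report: dict = {"n_train": len(y)}
    if eval_set:
        Xe = np.vstack([np.asarray(f, dtype=np.float64) for f, _ in eval_set])
        ye = np.array([lab for _, lab in eval_set])
        report["n_eval"] = len(ye)
        report["holdout_error"] = float(np.mean(forest.predict(Xe) != ye))
    model = ClassifierModel(
        forest=forest, feature_config=feature_config, n_trees=n_trees, seed=seed,
        training_report=report,
    )
    logger.info("trained forest: %s", report)
    return model


def filter_events(table, session, model: ClassifierModel):
    """Drop attributed events the classifier labels as noise.

    Each event's audio is cut from its owner's channel, featurized and
    classified; kept rows get ``label='vocalization'``.  Row order and all
    non-label fields of kept rows are preserved.
    """
    from .session_io import EventTable

    if len(table) == 0:
        return EventTable.empty()
    sr = session.sample_rate
    if sr != model.feature_config.sample_rate:
        raise ValueError(
            f"session sample rate {sr} != model feature config "
            f"{model.feature_config.sample_rate}"
        )
    features = []
    for idx, row in table.df.iterrows():
        lo = int(round(row["start_s"] * sr))
        hi = int(round(row["end_s"] * sr))
        channel = session.channel(row["bird_id"])
        if lo < 0 or hi > len(channel) or hi <= lo:
            raise ValueError(f"event at row {idx} lies outside the audio extent")
        features.append(featurize_clip(channel[lo:hi], sr, model.feature_config))
    preds = model.predict(np.vstack(features))
    keep = preds == LABEL_VOC
    df = table.df.loc[keep].copy()
    df["label"] = LABEL_VOC
    logger.info("noise filter: kept %d / %d events (%d dropped)",
                int(keep.sum()), len(keep), int((~keep).sum()))
    return EventTable(df)


# ---------------------------------------------------------------------------
# Persistence: joblib payload + JSON sidecar with the feature geometry
# ---------------------------------------------------------------------------


def save_model(model: ClassifierModel, path: str | Path) -> Path:
    path = Path(path)
    joblib.dump(model.forest, path)
    sidecar = {
        "format_version": 1,
        "feature_config": asdict(model.feature_config),
        "n_trees": model.n_trees,
        "seed": model.seed,
        "labels": list(model.labels),
        "training_report": model.training_report,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_model(path: str | Path) -> ClassifierModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if sidecar.get("format_version") != 1:
        raise ValueError(f"unsupported model format {sidecar.get('format_version')}")
    return ClassifierModel(
        forest=joblib.load(path),
        feature_config=FeatureConfig(**sidecar["feature_config"]),
        n_trees=sidecar["n_trees"],
        seed=sidecar["seed"],
        labels=tuple(sidecar["labels"]),
        training_report=sidecar["training_report"],
    )
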