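"""I/O for synchronized multichannel recordings, event tables and acoustic networks.

A recording session is a set of single-channel WAV files — one overhead
microphone per caged bird — that share a common start time and sample rate,
plus a :class:`GroupLayout` describing who sits where.  Detected and
attributed vocalizations travel through the pipeline as :class:`EventTable`
objects (thin wrappers over a pandas DataFrame) and the final dyadic
networks are written as undirected weighted edge lists.

Time convention: seconds from session start; every interval is half-open
``[start_s, end_s)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

SPEED_OF_SOUND_MPS = 343.0

#: columns of a serialized event table, in order
EVENT_COLUMNS = ["bird_id", "start_s", "end_s", "duration_s", "peak_energy", "label"]
VALID_LABELS = ("vocalization", "noise", "unlabeled")

#: default geometry: unit square of cages, one microphone above each bird.
#: The mic z-offset is measured relative to the bird's (perch) height.
DEFAULT_SIDE_M = 1.0
DEFAULT_MIC_HEIGHT_M = 0.25


class SessionError(ValueError):
    """Raised on invalid session inputs (mismatched channels, bad layout...)."""


@dataclass(frozen=True)
class GroupLayout:
    """Spatial layout of a recorded group.

    Parameters
    ----------
    bird_ids
        Ordered identifiers, one per bird/cage/microphone.
    positions
        ``bird_id -> (x, y)`` cage position in meters.  The sound source is
        taken at ``(x, y, 0)``; microphone heights are relative to it.
    mic_positions
        ``bird_id -> (x, y, z)`` microphone position in meters.
    speed_of_sound
        Propagation speed in m/s used for delay predictions.
    """

    bird_ids: tuple[str, ...]
    positions: dict[str, tuple[float, float]]
    mic_positions: dict[str, tuple[float, float, float]]
    speed_of_sound: float = SPEED_OF_SOUND_MPS

    def __post_init__(self) -> None:
        if len(self.bird_ids) != len(set(self.bird_ids)):
            raise SessionError("duplicate bird ids in layout")
        for bird in self.bird_ids:
            if bird not in self.positions:
                raise SessionError(f"bird {bird!r} has no cage position")
            if bird not in self.mic_positions:
                raise SessionError(f"bird {bird!r} has no microphone position")
        for a, b in itertools.combinations(self.bird_ids, 2):
            if math.dist(self.positions[a], self.positions[b]) <= 0:
                raise SessionError(f"cages of {a!r} and {b!r} coincide")
        if self.speed_of_sound <= 0:
            raise SessionError("speed of sound must be positive")

    @classmethod
    def default_square(
        cls,
        bird_ids: Sequence[str] = ("bird1", "bird2", "bird3", "bird4"),
        side_m: float = DEFAULT_SIDE_M,
        mic_height_m: float = DEFAULT_MIC_HEIGHT_M,
        speed_of_sound: float = SPEED_OF_SOUND_MPS,
    ) -> "GroupLayout":
        """Birds at the corners of a square, one overhead mic per cage."""
        corners = [(0.0, 0.0), (side_m, 0.0), (side_m, side_m), (0.0, side_m)]
        if len(bird_ids) > len(corners):
            raise SessionError("default square layout supports at most 4 birds")
        positions = {b: corners[i] for i, b in enumerate(bird_ids)}
        mics = {b: (positions[b][0], positions[b][1], mic_height_m) for b in bird_ids}
        return cls(tuple(bird_ids), positions, mics, speed_of_sound)

    # -- geometry helpers -------------------------------------------------

    def source_position(self, bird_id: str) -> np.ndarray:
        x, y = self.positions[bird_id]
        return np.array([x, y, 0.0])

    def mic_position(self, bird_id: str) -> np.ndarray:
        return np.asarray(self.mic_positions[bird_id], dtype=float)

    def distance_m(self, emitter: str, mic_bird: str) -> float:
        """Distance from ``emitter``'s source point to ``mic_bird``'s microphone."""
        return float(np.linalg.norm(self.source_position(emitter) - self.mic_position(mic_bird)))

    def propagation_delay_s(self, emitter: str, mic_bird: str) -> float:
        return self.distance_m(emitter, mic_bird) / self.speed_of_sound

    def max_mic_delay_s(self) -> float:
        """Largest possible arrival-time difference between two microphones."""
        dists = [
            float(np.linalg.norm(self.mic_position(a) - self.mic_position(b)))
            for a, b in itertools.combinations(self.bird_ids, 2)
        ]
        return max(dists) / self.speed_of_sound if dists else 0.0

    # -- config -----------------------------------------------------------

    @classmethod
    def from_config(cls, config: Mapping) -> "GroupLayout":
        """Build a layout from a parsed config mapping.

        The ``birds`` block maps each bird id to optional ``position`` and
        ``mic`` coordinates; omitted coordinates fall back to the default
        square geometry in declaration order.
        """
        birds_block = config.get("birds")
        if not birds_block:
            raise SessionError("layout config has no 'birds' block")
        bird_ids = tuple(birds_block.keys())
        default = cls.default_square(
            bird_ids,
            side_m=float(config.get("side_m", DEFAULT_SIDE_M)),
            mic_height_m=float(config.get("mic_height_m", DEFAULT_MIC_HEIGHT_M)),
            speed_of_sound=float(config.get("speed_of_sound", SPEED_OF_SOUND_MPS)),
        )
        positions = dict(default.positions)
        mics = dict(default.mic_positions)
        for bird, block in birds_block.items():
            block = block or {}
            if "position" in block:
                x, y = block["position"]
                positions[bird] = (float(x), float(y))
                if "mic" not in block:
                    mics[bird] = (float(x), float(y), default.mic_positions[bird][2])
            if "mic" in block:
                mx, my, mz = block["mic"]
                mics[bird] = (float(mx), float(my), float(mz))
        return cls(bird_ids, positions, mics, default.speed_of_sound)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroupLayout":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


@dataclass
class RecordingSession:
    """Synchronized per-bird audio channels plus the group layout."""

    channels: dict[str, np.ndarray]
    sample_rate: int
    layout: GroupLayout
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.channels) != set(self.layout.bird_ids):
            raise SessionError(
                f"channel keys {sorted(self.channels)} do not match layout birds "
                f"{sorted(self.layout.bird_ids)}"
            )
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise SessionError(f"channels differ in length: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, bird_id: str) -> np.ndarray:
        return self.channels[bird_id]


def _read_wav_mono(path: str | Path) -> tuple[int, np.ndarray]:
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise SessionError(f"{path}: expected a single-channel file, got shape {data.shape}")
    if data.dtype == np.int16:
        data = data.astype(np.float32) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float32) / 2147483648.0
    else:
        data = data.astype(np.float32)
    return int(rate), data


def load_session(
    audio_paths: Mapping[str, str | Path],
    layout: GroupLayout | Mapping | str | Path,
    max_length_mismatch_s: float = 0.1,
    meta: dict | None = None,
) -> RecordingSession:
    """Load one WAV file per bird into a validated session.

    Channels may disagree in trailing length by at most
    ``max_length_mismatch_s`` seconds; all channels are truncated to the
    shortest.  Mismatched sample rates or a bird missing an audio file are
    hard errors.
    """
    if isinstance(layout, (str, Path)):
        layout = GroupLayout.from_yaml(layout)
    elif isinstance(layout, Mapping):
        layout = GroupLayout.from_config(layout)
    missing = set(layout.bird_ids) - set(audio_paths)
    if missing:
        raise SessionError(f"no audio file for bird(s): {sorted(missing)}")

    rates: dict[str, int] = {}
    data: dict[str, np.ndarray] = {}
    for bird in layout.bird_ids:
        rates[bird], data[bird] = _read_wav_mono(audio_paths[bird])
    if len(set(rates.values())) > 1:
        raise SessionError(f"sample rates differ across channels: {rates}")
    rate = next(iter(rates.values()))

    lengths = {b: len(v) for b, v in data.items()}
    shortest, longest = min(lengths.values()), max(lengths.values())
    if (longest - shortest) / rate > max_length_mismatch_s:
        raise SessionError(
            f"channel lengths differ by {(longest - shortest) / rate:.3f} s "
            f"(> {max_length_mismatch_s} s): {lengths}"
        )
    channels = {b: v[:shortest] for b, v in data.items()}
    return RecordingSession(channels, rate, layout, meta=dict(meta or {}))


def write_session(session: RecordingSession, out_dir: str | Path) -> dict[str, Path]:
    """Write one float32 WAV per channel; returns the per-bird paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for bird, samples in session.channels.items():
        p = out_dir / f"{bird}.wav"
        wavfile.write(p, session.sample_rate, samples.astype(np.float32))
        paths[bird] = p
    return paths


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------


class EventTable:
    """Table of sound events: ``(bird_id, start_s, end_s, duration_s, peak_energy, label)``.

    Rows are kept sorted ascending by ``start_s`` (ties: ``end_s`` then
    ``bird_id``).  Extra columns (e.g. a generator's ``call_type``) are
    preserved.
    """

    def __init__(self, df: pd.DataFrame, duration_s: float | None = None):
        df = df.copy()
        if "bird_id" not in df.columns or "start_s" not in df.columns or "end_s" not in df.columns:
            raise ValueError("event table needs at least bird_id, start_s, end_s columns")
        df["bird_id"] = df["bird_id"].astype(str)
        df["start_s"] = df["start_s"].astype(float)
        df["end_s"] = df["end_s"].astype(float)
        df["duration_s"] = df["end_s"] - df["start_s"]
        if "peak_energy" not in df.columns:
            df["peak_energy"] = np.nan
        if "label" not in df.columns:
            df["label"] = "unlabeled"
        bad = df.index[df["end_s"] <= df["start_s"]]
        if len(bad):
            raise ValueError(f"non-positive duration at row index {bad[0]}")
        if (df["start_s"] < 0).any():
            raise ValueError("negative start_s in event table")
        if duration_s is not None and (df["end_s"] > duration_s + 1e-9).any():
            raise ValueError("event end_s beyond session duration")
        unknown = set(df["label"].unique()) - set(VALID_LABELS)
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}")
        extra = [c for c in df.columns if c not in EVENT_COLUMNS]
        df = df[EVENT_COLUMNS + extra]
        df = df.sort_values(["start_s", "end_s", "bird_id"], kind="stable").reset_index(drop=True)
        self.df = df

    @classmethod
    def from_records(cls, records: Iterable[Mapping], duration_s: float | None = None) -> "EventTable":
        return cls(pd.DataFrame(list(records)), duration_s=duration_s)

    @classmethod
    def empty(cls) -> "EventTable":
        return cls(pd.DataFrame(columns=EVENT_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"EventTable({len(self)} events, {self.df['bird_id'].nunique()} birds)"

    def for_bird(self, bird_id: str) -> "EventTable":
        return EventTable(self.df[self.df["bird_id"] == bird_id])


def read_event_table(path: str | Path) -> EventTable:
    """Read a CSV event table; rows are re-sorted by onset on read."""
    df = pd.read_csv(path)
    try:
        return EventTable(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_event_table(table: EventTable, path: str | Path) -> Path:
    """Write an event table as CSV; times at µs precision, energies at 6 significant digits."""
    path = Path(path)
    df = table.df.copy()
    for col in ("start_s", "end_s", "duration_s"):
        df[col] = df[col].map(lambda v: f"{v:.6f}")
    df["peak_energy"] = df["peak_energy"].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def write_network(network, path: str | Path, graphml: bool = False) -> Path:
    """Write an acoustic network as an undirected edge list CSV.

    One row per unordered dyad: ``source,target,weight,weight_type``.
    Undefined edge weights are written as empty fields.  With
    ``graphml=True`` an additional ``.graphml`` file is written next to the
    CSV (undefined edges omitted there).
    """
    path = Path(path)
    if len(network.nodes) < 2:
        raise ValueError("network must have at least 2 nodes")
    rows = []
    for (a, b), w in sorted(network.weights.items()):
        rows.append(
            {
                "source": a,
                "target": b,
                "weight": "" if (w is None or (isinstance(w, float) and math.isnan(w))) else f"{w:.12g}",
                "weight_type": network.weight_type,
            }
        )
    pd.DataFrame(rows, columns=["source", "target", "weight", "weight_type"]).to_csv(path, index=False)
    if graphml:
        import networkx as nx

        g = network.to_networkx(drop_undefined=True)
        nx.write_graphml(g, path.with_suffix(".graphml"))
    return path


def read_network(path: str | Path):
    """Read an edge-list CSV written by :func:`write_network`."""
    from .networks import AcousticNetwork

    df = pd.read_csv(path)
    nodes: list[str] = []
    weights: dict[tuple[str, str], float] = {}
    wtype = str(df["weight_type"].iloc[0]) if len(df) else "cross_correlation"
    for _, row in df.iterrows():
        a, b = str(row["source"]), str(row["target"])
        for n in (a, b):
            if n not in nodes:
                nodes.append(n)
        w = row["weight"]
        weights[tuple(sorted((a, b)))] = float(w) if pd.notna(w) and w != "" else float("nan")
    return AcousticNetwork(nodes=nodes, weights=weights, weight_type=wtype)
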