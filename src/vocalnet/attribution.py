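"""Caller attribution: collapse cross-microphone copies of one call to its emitter.

A call produced by one bird is recorded by its own overhead microphone and,
attenuated and delayed, by every other microphone in the room.  Because
each bird's own microphone is by far the closest, the emitter's channel
receives the highest energy and the earliest onset.  Attribution exploits
this: events are clustered across channels greedily in decreasing
peak-energy order — the loudest unassigned event anchors a cluster and
absorbs, on every other channel, the overlapping copy whose onset lies
within the physically possible propagation delay (plus a tolerance) and
whose energy does not exceed the anchor's.  Each cluster becomes one
vocalization attributed to the anchor channel's bird.

Simultaneous calls by two birds survive as two clusters: each emitter's
channel holds the locally loudest copy, and the onset gate (a few ms for a
1 m cage square) keeps genuinely asynchronous events apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .detection import SoundEvent
from .session_io import EventTable, GroupLayout

logger = logging.getLogger(__name__)

DEFAULT_ONSET_TOL_S = 0.015  # >> max geometric delay (~4 ms) + envelope-frame quantization
_REL_ENERGY_TIE = 1e-9


@dataclass
class CrossChannelCluster:
    """Copies of one physical call across channels; the anchor is the loudest."""

    members: list[SoundEvent]
    anchor: SoundEvent

    def __post_init__(self) -> None:
        channels = [m.channel_bird_id for m in self.members]
        if len(channels) != len(set(channels)):
            raise ValueError("cluster holds more than one event per channel")
        if self.anchor not in self.members:
            raise ValueError("anchor must be a cluster member")

    def __len__(self) -> int:
        return len(self.members)


def _sort_key(ev: SoundEvent):
    # loudest first; energy ties (< 1e-9 relative) resolved by onset then bird id
    return (-ev.peak_energy, ev.start_s, ev.channel_bird_id)


def cluster_events(
    per_channel_events: dict[str, list[SoundEvent]],
    layout: GroupLayout,
    onset_tol_s: float = DEFAULT_ONSET_TOL_S,
) -> list[CrossChannelCluster]:
    """Greedy loudest-first clustering of per-channel detections.

    Every input event ends up in exactly one cluster.  An anchor absorbs at
    most one event per other channel: among unassigned events on that
    channel that overlap the anchor in time, have onset within
    ``max_mic_delay + onset_tol_s`` of the anchor onset, and peak energy
    not above the anchor's, the one with the closest onset is taken.
    """
    gate = layout.max_mic_delay_s() + onset_tol_s
    all_events: list[SoundEvent] = []
    for bird, events in per_channel_events.items():
        for ev in events:
            if ev.channel_bird_id != bird:
                raise ValueError(f"event on channel {bird!r} labeled {ev.channel_bird_id!r}")
            all_events.append(ev)
    ordered = sorted(all_events, key=_sort_key)
    assigned: set[int] = set()
    clusters: list[CrossChannelCluster] = []

    for ev in ordered:
        if id(ev) in assigned:
            continue
        assigned.add(id(ev))
        members = [ev]
        max_absorbable = ev.peak_energy * (1.0 + _REL_ENERGY_TIE)
        for other_bird, others in per_channel_events.items():
            if other_bird == ev.channel_bird_id:
                continue
            candidates = [
                o
                for o in others
                if id(o) not in assigned
                and o.overlaps(ev)
                and abs(o.start_s - ev.start_s) <= gate
                and o.peak_energy <= max_absorbable
            ]
            if candidates:
                best = min(candidates, key=lambda o: (abs(o.start_s - ev.start_s), o.start_s))
                assigned.add(id(best))
                members.append(best)
        clusters.append(CrossChannelCluster(members=members, anchor=ev))

    n_removed = len(all_events) - len(clusters)
    logger.info("clustered %d events into %d calls (%d cross-channel copies removed)",
                len(all_events), len(clusters), n_removed)
    return clusters


def attribute(clusters: list[CrossChannelCluster]) -> EventTable:
    """One vocalization per cluster, owned by the anchor channel's bird.

    Times and peak energy are taken from the anchor (emitter-channel)
    event; the output table is sorted by onset.
    """
    if not clusters:
        return EventTable.empty()
    rows = [
        {
            "bird_id": c.anchor.channel_bird_id,
            "start_s": c.anchor.start_s,
            "end_s": c.anchor.end_s,
            "peak_energy": c.anchor.peak_energy,
            "label": "unlabeled",
        }
        for c in clusters
    ]
    return EventTable(pd.DataFrame(rows))


def delay_consistency_score(
    cluster: CrossChannelCluster,
    layout: GroupLayout,
    onset_tol_s: float = DEFAULT_ONSET_TOL_S,
) -> float:
    """Fraction of members whose onset lag matches the geometric prediction.

    Under the hypothesis that the anchor channel's bird emitted the call,
    each other microphone should receive it later by
    ``(d_member - d_anchor) / c`` where ``d`` are source-to-mic distances.
    Diagnostic only; singleton clusters are undefined (returns NaN).
    """
    if len(cluster) < 2:
        logger.warning("delay consistency undefined for singleton cluster")
        return float("nan")
    emitter = cluster.anchor.channel_bird_id
    d_anchor = layout.distance_m(emitter, emitter)
    n_ok = 0
    others = [m for m in cluster.members if m is not cluster.anchor]
    for m in others:
        predicted = (layout.distance_m(emitter, m.channel_bird_id) - d_anchor) / layout.speed_of_sound
        observed = m.start_s - cluster.anchor.start_s
        if abs(observed - predicted) <= onset_tol_s:
            n_ok += 1
    return n_ok / len(others)


def attribute_session(
    per_channel_events: dict[str, list[SoundEvent]],
    layout: GroupLayout,
    onset_tol_s: float = DEFAULT_ONSET_TOL_S,
) -> EventTable:
    """Cluster and attribute in one call."""
    return attribute(cluster_events(per_channel_events, layout, onset_tol_s=onset_tol_s))
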