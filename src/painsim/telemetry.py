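"""Append-only event log and the after-action-review timeline.

A day of play is recorded as a :class:`TelemetryLog` holding two kinds of
information: the sampled pain trajectory and every discrete action (doses,
activities, side-effect onsets, consults, refusals, monologue bubbles).
The after-action review projects the log onto a pain curve plus classified
nodes: doses, pain-relieving activities and pain-impairing activities, with
an outline flag on nodes that fall inside an active side-effect interval.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Optional

from .errors import IntegrityError, UsageError

#: Legal event kinds, in no particular order.
ENTRY_KINDS = frozenset(
    {
        "pain_sample",
        "dose",
        "activity",
        "side_effect_onset",
        "side_effect_end",
        "consult",
        "event_trigger",
        "refusal",
        "monologue",
    }
)

REVIEW_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class LogEntry:
    """One timestamped event. ``payload`` is kind-specific."""

    time: int
    kind: str
    payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ENTRY_KINDS:
            raise IntegrityError(f"unknown log entry kind {self.kind!r}")


class TelemetryLog:
    """Append-only, time-ordered event record for one (or more) days.

    Entries must be appended in non-decreasing time order; simultaneous
    events (a dose and the side effect it triggers) share a timestamp and
    keep insertion order.
    """

    def __init__(self, entries: Optional[Iterable[LogEntry]] = None):
        self._entries: list[LogEntry] = []
        if entries is not None:
            for e in entries:
                self.append(e)

    def append(self, entry: LogEntry) -> None:
        if self._entries and entry.time < self._entries[-1].time:
            raise IntegrityError(
                f"out-of-order append: {entry.time} < {self._entries[-1].time}"
            )
        self._entries.append(entry)

    def add(self, time: int, kind: str, **payload: Any) -> None:
        self.append(LogEntry(time=time, kind=kind, payload=payload))

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[LogEntry]:
        return iter(self._entries)

    def __getitem__(self, i):
        return self._entries[i]

    def of_kind(self, *kinds: str) -> list[LogEntry]:
        return [e for e in self._entries if e.kind in kinds]

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        payload = [
            {"time": e.time, "kind": e.kind, "payload": e.payload}
            for e in self._entries
        ]
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TelemetryLog":
        raw = json.loads(text)
        return cls(
            LogEntry(time=r["time"], kind=r["kind"], payload=r.get("payload", {}))
            for r in raw
        )


@dataclass(frozen=True)
class TimelineNode:
    """A classified marker on the after-action-review graph."""

    time: int
    node_class: str  # one of {"impairing", "dose", "relieving"}
    side_effect_outline: bool
    label: str


@dataclass
class Timeline:
    """Pain curve plus classified nodes for one day."""

    pain_curve: list[tuple[int, float]]
    nodes: list[TimelineNode]


def _side_effect_intervals(log: TelemetryLog) -> list[tuple[str, int, float]]:
    """Closed-open [onset, end) intervals; open-ended if the day ends first."""
    intervals: list[tuple[str, int, float]] = []
    open_idx: dict[str, int] = {}
    for e in log:
        if e.kind == "side_effect_onset":
            open_idx[e.payload["effect_id"]] = len(intervals)
            intervals.append((e.payload["effect_id"], e.time, float("inf")))
        elif e.kind == "side_effect_end":
            eid = e.payload["effect_id"]
            if eid in open_idx:
                i = open_idx.pop(eid)
                intervals[i] = (intervals[i][0], intervals[i][1], e.time)
    return intervals


def build_timeline(day_log: TelemetryLog) -> Timeline:
    """Project a complete day log onto (pain curve, classified nodes).

    Doses map to class ``dose``; activities with a negative pain effect to
    ``relieving``, positive to ``impairing``. Neutral (zero-effect)
    activities produce no node. A node gets ``side_effect_outline`` when
    its time falls inside any active side-effect interval.
    """
    prev_t = None
    for e in day_log:
        if prev_t is not None and e.time < prev_t:
            raise IntegrityError("telemetry log is not time-ordered")
        prev_t = e.time

    curve = [
        (e.time, float(e.payload["pain"])) for e in day_log.of_kind("pain_sample")
    ]
    intervals = _side_effect_intervals(day_log)

    def outlined(t: int) -> bool:
        return any(a <= t < b for (_, a, b) in intervals)

    nodes: list[TimelineNode] = []
    for e in day_log:
        if e.kind == "dose":
            label = f"{e.payload['med_id']} x{e.payload['tablets']}"
            nodes.append(TimelineNode(e.time, "dose", outlined(e.time), label))
        elif e.kind == "activity":
            effect = float(e.payload.get("pain_effect", 0.0))
            if effect == 0.0:
                continue
            cls = "relieving" if effect < 0 else "impairing"
            nodes.append(
                TimelineNode(e.time, cls, outlined(e.time), str(e.payload["id"]))
            )
    return Timeline(pain_curve=curve, nodes=nodes)


# -- export ------------------------------------------------------------


def timeline_to_dict(timeline: Timeline) -> dict[str, Any]:
    return {
        "version": REVIEW_SCHEMA_VERSION,
        "pain_curve": [{"time": t, "pain": p} for (t, p) in timeline.pain_curve],
        "nodes": [
            {
                "time": n.time,
                "node_class": n.node_class,
                "side_effect_outline": n.side_effect_outline,
                "label": n.label,
            }
            for n in timeline.nodes
        ],
    }


def timeline_from_dict(d: dict[str, Any]) -> Timeline:
    return Timeline(
        pain_curve=[(int(r["time"]), float(r["pain"])) for r in d["pain_curve"]],
        nodes=[
            TimelineNode(
                time=int(r["time"]),
                node_class=r["node_class"],
                side_effect_outline=bool(r["side_effect_outline"]),
                label=r["label"],
            )
            for r in d["nodes"]
        ],
    )


def export_review(timeline: Timeline, path: str, format: str = "json") -> None:
    """Write the review to ``path`` as canonical JSON or flat CSV.

    The CSV has one row per curve sample (``row_kind=sample``) and one per
    node (``row_kind=node``), so row count = samples + nodes.
    """
    if format == "json":
        with open(path, "w") as fh:
            json.dump(timeline_to_dict(timeline), fh, sort_keys=True, indent=2)
            fh.write("\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["row_kind", "time", "pain", "node_class", "side_effect_outline", "label"]
            )
            for (t, p) in timeline.pain_curve:
                w.writerow(["sample", t, p, "", "", ""])
            for n in timeline.nodes:
                w.writerow(
                    ["node", n.time, "", n.node_class, int(n.side_effect_outline), n.label]
                )
    else:
        raise UsageError(f"unknown review format {format!r} (expected json or csv)")


def load_review(path: str) -> Timeline:
    with open(path) as fh:
        return timeline_from_dict(json.load(fh))


def render_review_plot(timeline: Timeline, path: str) -> None:
    """Optional PNG rendering of the review overlay (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"impairing": "tab:red", "dose": "tab:orange", "relieving": "tab:green"}
    fig, ax = plt.subplots(figsize=(10, 4))
    if timeline.pain_curve:
        ts, ps = zip(*timeline.pain_curve)
        ax.plot(ts, ps, color="black", lw=1.2, label="pain")
        pain_at = dict(timeline.pain_curve)
    else:
        pain_at = {}
    for n in timeline.nodes:
        y = pain_at.get(n.time, 0.0)
        edge = "gold" if n.side_effect_outline else "none"
        ax.scatter(
            [n.time], [y], s=60, color=colors[n.node_class],
            edgecolors=edge, linewidths=2, zorder=3,
        )
    ax.set_xlabel("in-game minutes")
    ax.set_ylabel("pain (NRS)")
    ax.set_ylim(-0.5, 10.5)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
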