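"""Frame-to-frame islet matching, so each physical islet is counted once.

Islets transit the field of view along the channel axis; between consecutive
frames each detection is linked to an existing track by a weighted L2 cost on
(x, y, area):

    J = w_x |x1 - x2| / min(r1, r2)
      + w_y |y1 - y2| / min(r1, r2)
      + w_area |a1 - a2| / min(a1, a2)

with r the equivalent radius sqrt(area / pi). The default weights (1, 0.5, 1)
reflect the flow geometry: displacement is mostly along x, so cross-channel
(y) deviation is down-weighted. Pairs with J above a cutoff are never linked;
unmatched detections start new tracks, and a track that goes unmatched for
more than ``max_missed`` consecutive frames is retired (the islet left the
field of view).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import Detection

__all__ = [
    "CostWeights",
    "IsletTracker",
    "Track",
    "finalize",
    "match_frame",
    "pair_cost",
]


@dataclass(frozen=True)
class CostWeights:
    """Dimensionless weights of the matching cost; defaults (1, 0.5, 1)."""

    w_x: float = 1.0
    w_y: float = 0.5
    w_area: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_x, self.w_y, self.w_area) < 0:
            raise ValueError("cost weights must be >= 0")


@dataclass
class Track:
    """One physical islet: its detections across consecutive frames."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)
    active: bool = True
    missed_frames: int = 0

    @property
    def last(self) -> Detection:
        return self.detections[-1]

    def __len__(self) -> int:
        return len(self.detections)


def pair_cost(a: Detection, b: Detection, weights: CostWeights = CostWeights()) -> float:
    """Weighted L2 linking cost between two detections."""
    if a.degenerate or b.degenerate:
        raise ValueError("pair_cost requires non-degenerate detections")
    if a.area_px <= 0 or b.area_px <= 0:
        raise ValueError("pair_cost requires positive areas")
    r_min = min(a.equivalent_radius_px, b.equivalent_radius_px)
    a_min = min(a.area_px, b.area_px)
    return (
        weights.w_x * abs(a.centroid_x - b.centroid_x) / r_min
        + weights.w_y * abs(a.centroid_y - b.centroid_y) / r_min
        + weights.w_area * abs(a.area_px - b.area_px) / a_min
    )


def match_frame(
    active_tracks: list[Track],
    detections: list[Detection],
    weights: CostWeights = CostWeights(),
    j_max: float = 2.0,
    solver: str = "greedy",
    next_track_id: int = 0,
) -> tuple[list[tuple[Track, Detection]], list[Track]]:
    """Assign one frame's detections to active tracks.

    Greedy matching (default): all (track, detection) pairs with J <= j_max
    are sorted by ascending cost and consumed in order, each track and each
    detection used at most once. The alternative ``solver="optimal"`` solves
    the same gated problem as a minimum-total-cost assignment.

    Matched tracks gain the detection and reset their miss counter; unmatched
    tracks increment it; unmatched detections found new tracks numbered from
    ``next_track_id``. Returns (assignments, new_tracks).
    """
    detections = [d for d in detections if not d.degenerate]
    assignments: list[tuple[Track, Detection]] = []
    matched_tracks: set[int] = set()
    matched_dets: set[int] = set()

    if active_tracks and detections:
        cost = np.array(
            [[pair_cost(t.last, d, weights) for d in detections] for t in active_tracks]
        )
        if solver == "greedy":
            order = np.dstack(np.unravel_index(np.argsort(cost, axis=None), cost.shape))[0]
            for ti, di in order:
                if cost[ti, di] > j_max:
                    break
                if ti in matched_tracks or di in matched_dets:
                    continue
                matched_tracks.add(int(ti))
                matched_dets.add(int(di))
                assignments.append((active_tracks[ti], detections[di]))
        elif solver == "optimal":
            from scipy.optimize import linear_sum_assignment

            big = j_max + 1e6
            gated = np.where(cost <= j_max, cost, big)
            rows, cols = linear_sum_assignment(gated)
            for ti, di in zip(rows, cols):
                if cost[ti, di] <= j_max:
                    matched_tracks.add(int(ti))
                    matched_dets.add(int(di))
                    assignments.append((active_tracks[ti], detections[di]))
        else:
            raise ValueError(f"unknown solver {solver!r}")

    for track, det in assignments:
        track.detections.append(det)
        track.missed_frames = 0

    for i, track in enumerate(active_tracks):
        if i not in matched_tracks:
            track.missed_frames += 1

    new_tracks = [
        Track(track_id=next_track_id + k, detections=[d])
        for k, d in enumerate(d for i, d in enumerate(detections) if i not in matched_dets)
    ]
    return assignments, new_tracks


def finalize(tracks: list[Track], min_track_length: int = 2) -> list[Track]:
    """Keep tracks that represent real islets; their number is the count.

    A finalized track has at least ``min_track_length`` detections and at
    least one detection fully inside the frame (tracks seen only touching the
    border are entry/exit artifacts, not countable islets).
    """
    kept = []
    for t in tracks:
        valid = [d for d in t.detections if not d.degenerate]
        if len(valid) >= min_track_length and any(not d.touches_edge for d in valid):
            kept.append(t)
    return kept


class IsletTracker:
    """Stateful per-frame tracker orchestrating :func:`match_frame`.

    Feed each frame's detections in temporal order with :meth:`step`; call
    :meth:`finalize` when the video is exhausted.
    """

    def __init__(
        self,
        weights: CostWeights = CostWeights(),
        j_max: float = 2.0,
        max_missed: int = 2,
        min_track_length: int = 2,
        solver: str = "greedy",
    ) -> None:
        if j_max <= 0:
            raise ValueError("j_max must be > 0")
        self.weights = weights
        self.j_max = j_max
        self.max_missed = max_missed
        self.min_track_length = min_track_length
        self.solver = solver
        self.tracks: list[Track] = []
        self._next_id = 0

    @property
    def active_tracks(self) -> list[Track]:
        return [t for t in self.tracks if t.active]

    def step(self, detections: list[Detection]) -> None:
        active = self.active_tracks
        _, new = match_frame(
            active,
            detections,
            weights=self.weights,
            j_max=self.j_max,
            solver=self.solver,
            next_track_id=self._next_id,
        )
        self._next_id += len(new)
        self.tracks.extend(new)
        for t in active:
            if t.missed_frames > self.max_missed:
                t.active = False

    def finalize(self) -> list[Track]:
        return finalize(self.tracks, self.min_track_length)
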