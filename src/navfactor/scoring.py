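"""Scoring of raw navigation-task data into the nine indicators.

Sign convention: error-type scores (pointing errors, route-efficiency
ratios) are reverse scored — multiplied by -1 — so that higher always means
better, matching the other measures.  Map accuracy is a bidimensional
regression R^2 in [0, 1]; questionnaire scores keep their native scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PointingTrial",
    "CategoricalPointingTrial",
    "ProtractorTrial",
    "MapPlacementSet",
    "PathTrace",
    "fold_angular_difference",
    "chirality_correct",
    "score_temple_pointing",
    "score_silcton_pointing",
    "score_squaretown_pointing",
    "bidimensional_regression",
    "bidimensional_regression_r2",
    "trace_length",
    "score_squaretown_efficiency",
    "score_temple_efficiency",
    "score_sbsod",
    "score_nsq",
    "score_mrt",
    "score_ptta",
    "reverse_score",
    "SBSOD_POSITIVE_ITEMS",
]


class ScoringError(ValueError):
    """Raised for invalid raw trial data."""


# ---------------------------------------------------------------------------
# trial containers


@dataclass
class PointingTrial:
    """One pointing judgment from a station to a named target building."""

    station_id: str
    target_id: str
    station_route: str
    target_route: str
    true_bearing: float
    indicated_bearing: float

    def __post_init__(self) -> None:
        if self.station_id == self.target_id:
            raise ScoringError("station and target must differ")
        for b in (self.true_bearing, self.indicated_bearing):
            if not 0 <= b < 360:
                raise ScoringError(f"bearing {b} outside [0, 360)")


@dataclass
class CategoricalPointingTrial:
    """Forward / left-right / backward judgment; both lateral responses code 90."""

    true_egocentric: int
    response: int

    def __post_init__(self) -> None:
        for v in (self.true_egocentric, self.response):
            if v not in (0, 90, 180):
                raise ScoringError(f"categorical response {v} not in {{0, 90, 180}}")


@dataclass
class ProtractorTrial:
    """Protractor pointing trial with recorded turn direction."""

    indicated_angle: float
    turn_direction: str
    actual_angle: float

    def __post_init__(self) -> None:
        if self.turn_direction not in ("left", "right"):
            raise ScoringError(f"unknown turn direction {self.turn_direction!r}")


@dataclass
class MapPlacementSet:
    """Drag-and-drop map reconstruction: placed vs. true 2-D coordinates."""

    object_ids: list[str]
    placed_xy: np.ndarray
    true_xy: np.ndarray

    def __post_init__(self) -> None:
        self.placed_xy = np.asarray(self.placed_xy, dtype=float)
        self.true_xy = np.asarray(self.true_xy, dtype=float)
        if len(self.object_ids) != len(set(self.object_ids)):
            raise ScoringError("duplicated object ids")
        if self.placed_xy.shape != self.true_xy.shape or self.placed_xy.shape[1] != 2:
            raise ScoringError("placed and true coordinate sets must be n x 2 and congruent")


@dataclass
class PathTrace:
    """5-Hz position trace of one route-retrieval trial."""

    route_id: str
    block: int
    xy: np.ndarray
    shortest_distance: float
    sample_hz: float = 5.0

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[0] < 2 or self.xy.shape[1] != 2:
            raise ScoringError("trace needs at least two 2-D samples")
        if self.shortest_distance <= 0:
            raise ScoringError("shortest_distance must be positive")


# ---------------------------------------------------------------------------
# angular scoring


def fold_angular_difference(a: float, b: float) -> float:
    """Smallest angular difference between two bearings, in [0, 180].

    Takes ``|a - b|`` and, when that exceeds 180, subtracts it from 360 —
    e.g. ``|100 - 295| = 195``, folded to ``360 - 195 = 165``.
    """
    if not (0 <= a < 360 and 0 <= b < 360):
        raise ScoringError(f"angles ({a}, {b}) outside [0, 360)")
    d = abs(a - b)
    return 360.0 - d if d > 180.0 else d


def chirality_correct(indicated: float, turn: str) -> float:
    """Express a protractor reading as its rightward-equivalent bearing.

    A leftward turn of the protractor mirrors the angle, so a leftward
    reading is subtracted from 360 (a leftward 315 is a rightward 45);
    rightward readings are unchanged.
    """
    if not 0 <= indicated < 360:
        raise ScoringError(f"indicated angle {indicated} outside [0, 360)")
    if turn == "right":
        return float(indicated)
    if turn == "left":
        return float((360.0 - indicated) % 360.0)
    raise ScoringError(f"unknown turn direction {turn!r}")


def score_temple_pointing(trials: Sequence[ProtractorTrial]) -> float:
    """Reverse-scored mean absolute angular error of the protractor task."""
    if not trials:
        raise ScoringError("no protractor trials")
    errs = [
        fold_angular_difference(chirality_correct(t.indicated_angle, t.turn_direction), t.actual_angle)
        for t in trials
    ]
    return -float(np.mean(errs))


def score_silcton_pointing(trials: Sequence[PointingTrial]) -> tuple[float, float]:
    """Reverse-scored mean angular error, split into (within, between) route.

    Within-route trials point to a target on the station's own route;
    between-route trials point across routes.  The 8-station x 7-target
    design yields 24 within and 32 between judgments.
    """
    within = [
        fold_angular_difference(t.indicated_bearing, t.true_bearing)
        for t in trials
        if t.station_route == t.target_route
    ]
    between = [
        fold_angular_difference(t.indicated_bearing, t.true_bearing)
        for t in trials
        if t.station_route != t.target_route
    ]
    if not within:
        raise ScoringError("no within-route pointing trials")
    if not between:
        raise ScoringError("no between-route pointing trials")
    return -float(np.mean(within)), -float(np.mean(between))


def score_squaretown_pointing(trials: Sequence[CategoricalPointingTrial]) -> float:
    """Reverse-scored mean |response - true| over categorical pointing trials."""
    if not trials:
        raise ScoringError("no categorical pointing trials")
    errs = [abs(t.response - t.true_egocentric) for t in trials]
    return -float(np.mean(errs))


# ---------------------------------------------------------------------------
# map accuracy


def bidimensional_regression(
    placed: np.ndarray, true: np.ndarray, model: str = "euclidean"
) -> dict[str, float | np.ndarray]:
    """Least-squares planar transform from placed onto true coordinates.

    The Euclidean (similarity) model fits translation, rotation and a
    single scale: ``x' = a1 + b1 x - b2 y``, ``y' = a2 + b2 x + b1 y``.
    The affine model frees all four linear coefficients.  R^2 is
    ``1 - SSE / SST`` with SST taken about the true configuration's
    centroid, pooling both coordinates, i.e. the share of variance in the
    correct map explained by the participant's map.
    """
    placed = np.asarray(placed, dtype=float)
    true = np.asarray(true, dtype=float)
    n = placed.shape[0]
    if n < 3:
        raise ScoringError("bidimensional regression needs >= 3 point pairs")
    if np.allclose(placed.var(axis=0).sum(), 0.0):
        raise ScoringError("degenerate placed configuration (zero variance)")
    x, y = placed[:, 0], placed[:, 1]
    if model == "euclidean":
        # stacked design: rows (x'_i; y'_i), parameters (a1, a2, b1, b2)
        design = np.zeros((2 * n, 4))
        design[:n, 0] = 1.0
        design[:n, 2] = x
        design[:n, 3] = -y
        design[n:, 1] = 1.0
        design[n:, 2] = y
        design[n:, 3] = x
    elif model == "affine":
        design = np.zeros((2 * n, 6))
        design[:n, 0] = 1.0
        design[:n, 2] = x
        design[:n, 3] = y
        design[n:, 1] = 1.0
        design[n:, 4] = x
        design[n:, 5] = y
    else:
        raise ValueError(f"unknown model {model!r}")
    target = np.concatenate([true[:, 0], true[:, 1]])
    coefs, *_ = np.linalg.lstsq(design, target, rcond=None)
    fitted = design @ coefs
    sse = float(np.sum((target - fitted) ** 2))
    centroid = true.mean(axis=0)
    sst = float(np.sum((true - centroid) ** 2))
    if sst == 0.0:
        raise ScoringError("degenerate true configuration (zero variance)")
    r2 = max(0.0, min(1.0, 1.0 - sse / sst))
    return {"r2": r2, "coefs": coefs, "sse": sse, "sst": sst}


def bidimensional_regression_r2(placements: MapPlacementSet, model: str = "euclidean") -> float:
    """R^2 of the similarity bidimensional regression of true on placed maps."""
    return float(bidimensional_regression(placements.placed_xy, placements.true_xy, model)["r2"])


# ---------------------------------------------------------------------------
# route efficiency


def trace_length(trace: PathTrace) -> float:
    """Traveled distance: sum of Euclidean segment lengths along the trace."""
    return float(np.sum(np.linalg.norm(np.diff(trace.xy, axis=0), axis=1)))


def score_squaretown_efficiency(
    traces: Iterable[PathTrace], literal_sum: bool = False
) -> float:
    """Reverse-scored route-efficiency ratio for the gridded virtual town.

    Per route, traveled distance is averaged across retrieval blocks; the
    participant's ratio is the mean of those route means divided by the
    mean shortest distance, so a navigator reproducing every shortest path
    scores exactly 1 before reversal.  Corner-cutting can push the ratio
    below 1.  ``literal_sum=True`` instead divides the *sum* of route
    means by the mean shortest distance (in which case a perfect navigator
    scores the number of routes).
    """
    per_route: dict[str, list[float]] = {}
    shortest: dict[str, float] = {}
    for t in traces:
        per_route.setdefault(t.route_id, []).append(trace_length(t))
        shortest[t.route_id] = t.shortest_distance
    if not per_route:
        raise ScoringError("no traces")
    route_means = np.array([np.mean(v) for v in per_route.values()])
    mean_shortest = float(np.mean([shortest[r] for r in per_route]))
    numerator = route_means.sum() if literal_sum else route_means.mean()
    return -float(numerator / mean_shortest)


def score_temple_efficiency(routes: Sequence[tuple[int, int]]) -> float:
    """Reverse-scored objects-passed ratio for the real-world tour.

    ``routes`` holds (objects_passed, min_objects) per sequential leg; the
    score is total passed over total minimum.  Shortcuts are impossible,
    so the ratio is >= 1 before reversal.
    """
    if not routes:
        raise ScoringError("no route legs")
    passed = 0
    minimum = 0
    for p, m in routes:
        if p < m:
            raise ScoringError(f"objects_passed {p} < min_objects {m}")
        passed += p
        minimum += m
    return -passed / minimum


# ---------------------------------------------------------------------------
# questionnaires and visuospatial tests

#: default 1-based indices of positively phrased sense-of-direction items
#: (reverse-scored so that high always means a better reported sense of
#: direction); configurable because phrasing is a property of the form used
SBSOD_POSITIVE_ITEMS: tuple[int, ...] = (1, 3, 4, 5, 7, 9, 14)


def score_sbsod(
    items: Sequence[int], positive_items: Sequence[int] = SBSOD_POSITIVE_ITEMS
) -> float:
    """Mean sense-of-direction score in [1, 7] after reversing positive items."""
    if len(items) != 15:
        raise ScoringError(f"expected 15 items, got {len(items)}")
    pos = set(positive_items)
    vals = []
    for i, r in enumerate(items, start=1):
        if not 1 <= r <= 7:
            raise ScoringError(f"item {i} response {r} outside 1-7")
        vals.append(8 - r if i in pos else r)
    return float(np.mean(vals))


def score_nsq(item_categories: Sequence[str]) -> int:
    """Map-based minus scene-based response counts; alternatives uncoded."""
    n_map = sum(1 for c in item_categories if c == "map")
    n_scene = sum(1 for c in item_categories if c == "scene")
    return n_map - n_scene


def score_mrt(
    responses: Sequence[tuple[Sequence[int], Sequence[int]]]
) -> int:
    """Mental-rotation score with guessing correction.

    ``responses`` holds, per problem, (chosen option indices, keyed correct
    option indices).  Each correct chosen option earns +2, each incorrect
    chosen option -2; unattempted options score nothing, so one right and
    one wrong pick nets zero.
    """
    total = 0
    for prob, (chosen, key) in enumerate(responses):
        if len(chosen) > 2:
            raise ScoringError(f"problem {prob}: more than two selections")
        keyset = set(key)
        for c in chosen:
            total += 2 if c in keyset else -2
    return total


def score_ptta(points: int, start_time: float, end_time: float) -> float:
    """Perspective-taking points per minute; times are in seconds."""
    elapsed = end_time - start_time
    if elapsed <= 0:
        raise ScoringError("nonpositive elapsed time")
    return points / (elapsed / 60.0)


def reverse_score(x: float) -> float:
    """Negate an error-type score so that higher means better."""
    return -x
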