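"""Classification and kinetic quantification of single-particle tracks.

Implements the manual kymograph-scoring conventions of reconstituted
microtubule motility assays as deterministic, parameterised rules:

* a track is a **binding event** only if it lasts at least ``min_frames``
  frames / ``min_duration`` seconds (event duration counts one frame interval
  per frame, so 3 frames at 2 frames/s = 1.5 s);
* a binding event is **processive** if it achieves predominantly minus-end
  displacement beyond ``processive_min_net`` (net displacement at least that
  magnitude toward the minus end, with a net/path directionality ratio of at
  least ``directionality_min``); **static** if it never strays more than
  ``static_max_excursion`` from its mean position; **diffusive** otherwise;
* velocities are measured on constant-velocity segments found by penalised
  piecewise-linear changepoint detection;
* run lengths are total displacements, pauses included, with the censoring
  rule that only fully observed runs or runs starting more than 5 um from the
  minus end enter run-length statistics;
* the run-length distribution is summarised by a least-squares one-phase
  exponential fit to the empirical 1 - CDF (survival) curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from ._types import MicrotubuleRef, MotilityEvent, Track, VelocitySegment

__all__ = [
    "ClassifyParams",
    "DecayFit",
    "TrackClassifier",
    "VelocitySegmenter",
    "ExponentialDecayModel",
    "classify_track",
    "classify_trackset",
    "segment_velocities",
    "extract_run_lengths",
    "fit_decay",
    "count_events",
    "colocalize",
    "motility_fractions",
]


@dataclass
class ClassifyParams:
    """Thresholds of the event-scoring rules (um / s units).

    ``static_max_excursion`` defaults to roughly 2*sqrt(2) times a 50-nm
    localisation sigma; widen it for noisier data.  ``changepoint_penalty``
    multiplies the per-changepoint cost (noise-variance * log n) of the
    piecewise-linear segmentation; ``pause_velocity`` is the |v| below which a
    segment counts as a pause and is excluded from velocity statistics.
    """

    min_frames: int = 3
    min_duration: float = 1.5
    processive_min_net: float = 0.5
    directionality_min: float = 0.7
    static_max_excursion: float = 0.15
    changepoint_penalty: float = 10.0
    min_segment_frames: int = 3
    velocity_merge_tol: float = 0.1
    pause_velocity: float = 0.05
    fully_observed_margin: float = 0.2
    min_start_distance: float = 5.0

    def __post_init__(self) -> None:
        for name in ("min_duration", "processive_min_net", "static_max_excursion",
                     "velocity_merge_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.directionality_min <= 1.0):
            raise ValueError("directionality_min must lie in [0, 1]")
        if self.min_frames < 2:
            raise ValueError("min_frames must be >= 2")


@dataclass
class DecayFit:
    """One-phase exponential fit of the run-length survival curve."""

    scale: float           # um; the mean of the fitted exponential
    n_runs: int
    fit_domain: tuple[float, float]
    poorly_conditioned: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError("fitted scale must be finite and > 0")

    def survival(self, x: np.ndarray) -> np.ndarray:
        return np.exp(-np.asarray(x, dtype=float) / self.scale)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _frame_interval(times: np.ndarray) -> float:
    return float(np.median(np.diff(times))) if times.size > 1 else 0.5


def _median3(x: np.ndarray) -> np.ndarray:
    """3-point running median (suppresses single-frame localisation outliers)."""
    if x.size < 3:
        return x.copy()
    m = x.copy()
    m[1:-1] = np.median(np.stack([x[:-2], x[1:-1], x[2:]]), axis=0)
    return m


def _trim_stationary_tails(times: np.ndarray, positions: np.ndarray,
                           tol: float) -> tuple[int, int]:
    """Indices [start, stop) of the motile portion of a track.

    Leading and trailing plateaus — stretches that never escape ``tol`` of the
    track's first/last level (attachment wait, minus-end arrest dwell) — are
    trimmed so that localisation noise accumulated while stationary does not
    inflate the path length.  Plateau escape is judged on a 3-point median
    filter, so single noisy frames neither end nor extend a plateau.  One
    plateau point is kept on each side (the departure / arrival sample).
    """
    n = positions.size
    if n < 4:
        return 0, n
    xs = _median3(positions)
    head_level = np.median(xs[: min(5, n)])
    tail_level = np.median(xs[max(n - 5, 0):])
    escapes_head = np.abs(xs - head_level) > tol
    escapes_tail = np.abs(xs - tail_level) > tol
    if not escapes_head.any() or not escapes_tail.any():
        return 0, n  # never leaves a plateau: effectively stationary
    i0 = max(int(np.argmax(escapes_head)) - 1, 0)
    last_escape = n - 1 - int(np.argmax(escapes_tail[::-1]))
    i1 = min(last_escape + 2, n)
    if i1 - i0 < 2:
        return 0, n
    return i0, i1


def _ols_slope(times: np.ndarray, positions: np.ndarray) -> float:
    t = times - times.mean()
    denom = float(np.dot(t, t))
    if denom == 0.0:
        return 0.0
    return float(np.dot(t, positions - positions.mean()) / denom)


# ---------------------------------------------------------------------------
# changepoint segmentation
# ---------------------------------------------------------------------------

def _segment_costs(times: np.ndarray, positions: np.ndarray,
                   min_len: int) -> np.ndarray:
    """cost[i, j] = RSS of an OLS line on samples i..j-1 (inf below min_len)."""
    n = times.size
    # cumulative sums give O(1) per-interval OLS residuals
    c_t = np.concatenate([[0.0], np.cumsum(times)])
    c_x = np.concatenate([[0.0], np.cumsum(positions)])
    c_tt = np.concatenate([[0.0], np.cumsum(times * times)])
    c_tx = np.concatenate([[0.0], np.cumsum(times * positions)])
    c_xx = np.concatenate([[0.0], np.cumsum(positions * positions)])
    cost = np.full((n + 1, n + 1), np.inf)
    for i in range(n):
        for j in range(i + min_len, n + 1):
            m = j - i
            st = c_t[j] - c_t[i]
            sx = c_x[j] - c_x[i]
            stt = c_tt[j] - c_tt[i]
            stx = c_tx[j] - c_tx[i]
            sxx = c_xx[j] - c_xx[i]
            var_t = stt - st * st / m
            cov_tx = stx - st * sx / m
            var_x = sxx - sx * sx / m
            rss = var_x - (cov_tx * cov_tx / var_t if var_t > 1e-300 else 0.0)
            cost[i, j] = max(rss, 0.0)
    return cost


def _noise_scale(positions: np.ndarray) -> float:
    """Robust localisation-noise sigma from second differences.

    For a piecewise-linear signal the second difference is pure noise with
    variance 6 sigma^2 (away from changepoints); the MAD makes the estimate
    insensitive to the few changepoint-straddling terms.
    """
    if positions.size < 4:
        return 0.0
    d2 = np.diff(positions, n=2)
    mad = np.median(np.abs(d2 - np.median(d2)))
    return float(1.4826 * mad / math.sqrt(6.0))


class VelocitySegmenter(BaseEstimator):
    """Piecewise-linear changepoint segmentation of a processive run.

    Optimal partitioning by dynamic programming: segment cost is the residual
    sum of squares of an OLS line, each changepoint pays a penalty of
    ``changepoint_penalty * sigma^2 * log(n)`` with sigma estimated robustly
    from second differences (a small floor keeps noiseless tracks from being
    oversegmented, where any partition has zero cost).  Adjacent segments
    whose slopes differ by less than ``velocity_merge_tol`` are merged.

    Fitted attributes: ``segments_`` (list of :class:`VelocitySegment`),
    ``changepoints_`` (sample indices where new segments start).
    """

    def __init__(self, changepoint_penalty: float = 10.0, min_segment_frames: int = 3,
                 velocity_merge_tol: float = 0.1):
        self.changepoint_penalty = changepoint_penalty
        self.min_segment_frames = min_segment_frames
        self.velocity_merge_tol = velocity_merge_tol

    def fit(self, X: Track, y=None) -> "VelocitySegmenter":
        times = np.asarray(X.times, dtype=float)
        positions = np.asarray(X.positions, dtype=float)
        n = times.size
        min_len = self.min_segment_frames
        if n < 2 * min_len:
            # too short to split: single-segment fallback
            self.changepoints_ = []
            self.segments_ = [self._make_segment(times, positions, 0, n)]
            return self

        cost = _segment_costs(times, positions, min_len)
        sigma = _noise_scale(positions)
        penalty = max(self.changepoint_penalty * sigma * sigma * math.log(n), 1e-12)

        # DP over segment ends: best[j] = min cost of segmenting samples [0, j)
        best = np.full(n + 1, np.inf)
        prev = np.zeros(n + 1, dtype=int)
        best[0] = -penalty  # cancels the penalty charged for the first segment
        for j in range(min_len, n + 1):
            cand = best[: j - min_len + 1] + cost[: j - min_len + 1, j] + penalty
            i = int(np.argmin(cand))
            best[j] = cand[i]
            prev[j] = i
        bounds = [n]
        while bounds[-1] > 0:
            bounds.append(int(prev[bounds[-1]]))
        bounds = bounds[::-1]

        segments = [(i, j) for i, j in zip(bounds[:-1], bounds[1:])]
        segments = self._merge(times, positions, segments)
        self.changepoints_ = [i for i, _ in segments[1:]]
        self.segments_ = [self._make_segment(times, positions, i, j) for i, j in segments]
        return self

    def transform(self, tracks: Iterable[Track]) -> list[list[VelocitySegment]]:
        return [VelocitySegmenter(**self.get_params()).fit(tr).segments_ for tr in tracks]

    def _merge(self, times, positions, segments):
        merged = [segments[0]]
        for i, j in segments[1:]:
            pi, pj = merged[-1]
            v_prev = _ols_slope(times[pi:pj], positions[pi:pj])
            v_next = _ols_slope(times[i:j], positions[i:j])
            if abs(v_prev - v_next) < self.velocity_merge_tol:
                merged[-1] = (pi, j)
            else:
                merged.append((i, j))
        return merged

    @staticmethod
    def _make_segment(times, positions, i, j) -> VelocitySegment:
        dt = _frame_interval(times)
        # half-open segment intervals tile the run without overlap
        t_end = times[j - 1] + dt if j == times.size else times[j]
        return VelocitySegment(t_start=float(times[i]), t_end=float(t_end),
                               velocity=_ols_slope(times[i:j], positions[i:j]))


def segment_velocities(track: Track, params: Optional[ClassifyParams] = None) -> list[VelocitySegment]:
    """Constant-velocity segments of a (processive) track."""
    params = params or ClassifyParams()
    seg = VelocitySegmenter(changepoint_penalty=params.changepoint_penalty,
                            min_segment_frames=params.min_segment_frames,
                            velocity_merge_tol=params.velocity_merge_tol)
    return seg.fit(track).segments_


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TrackClassifier(BaseEstimator):
    """Static / diffusive / processive classifier for microtubule-bound tracks.

    Stateless rule-based classifier (``fit`` is a no-op kept for pipeline
    compatibility).  ``predict`` returns one label per track, with
    ``"rejected"`` for tracks too short to count as binding events;
    ``events`` returns full :class:`MotilityEvent` records for accepted
    tracks, including velocity segments and censoring flags.
    """

    def __init__(self, params: Optional[ClassifyParams] = None,
                 movie_start: float = 0.0, movie_end: Optional[float] = None):
        self.params = params
        self.movie_start = movie_start
        self.movie_end = movie_end

    def fit(self, X=None, y=None) -> "TrackClassifier":
        return self

    def _params(self) -> ClassifyParams:
        return self.params if self.params is not None else ClassifyParams()

    def classify(self, track: Track, mt: MicrotubuleRef) -> Optional[MotilityEvent]:
        """Classify one track; returns None for rejected (non-binding) tracks."""
        p = self._params()
        times, positions = track.times, track.positions
        if track.mt_id != mt.mt_id:
            raise ValueError(f"track {track.track_id!r} is not on microtubule {mt.mt_id!r}")
        n = times.size
        dt = _frame_interval(times)
        duration = n * dt  # each frame represents one sampling interval
        if n < p.min_frames or duration < p.min_duration - 1e-9:
            return None

        # static: never strays far from its mean position
        excursion = float(np.max(np.abs(positions - positions.mean())))
        is_static = excursion <= p.static_max_excursion

        # trim stationary attachment/arrest tails before measuring motility
        i0, i1 = _trim_stationary_tails(times, positions, p.static_max_excursion)
        core_t, core_x = times[i0:i1], positions[i0:i1]
        net = float(core_x[-1] - core_x[0])
        path = float(np.sum(np.abs(np.diff(core_x))))
        directionality = abs(net) / path if path > 0 else 0.0

        if (not is_static and net <= -p.processive_min_net
                and directionality >= p.directionality_min):
            category = "processive"
        elif is_static:
            category = "static"
        else:
            category = "diffusive"

        segments: list[VelocitySegment] = []
        run_length: Optional[float] = None
        if category == "processive":
            segments = segment_velocities(Track(track.mt_id, track.track_id, track.channel,
                                                core_t, core_x), p)
            run_length = abs(net)  # total displacement, pauses included

        movie_end = self.movie_end
        starts_at_movie_start = times[0] - dt < self.movie_start + 1e-9
        ends_at_movie_end = (movie_end is not None) and (times[-1] + dt > movie_end - 1e-9)
        at_minus_end = float(positions[-1]) - mt.minus_end_position < p.fully_observed_margin
        fully_observed = not (starts_at_movie_start or ends_at_movie_end or at_minus_end)
        censored = not fully_observed
        start_distance = float(positions[i0]) - mt.minus_end_position
        eligible = (category == "processive"
                    and (fully_observed or start_distance > p.min_start_distance))

        return MotilityEvent(
            track_id=track.track_id, mt_id=track.mt_id, channel=track.channel,
            category=category, duration=duration, n_frames=n,
            start_time=float(times[0]), end_time=float(times[-1]),
            start_position=float(positions[i0]), end_position=float(positions[i1 - 1]),
            net_displacement=net, path_length=max(path, abs(net)),
            segments=segments, run_length=run_length,
            censored=censored, fully_observed=fully_observed,
            eligible_for_run_stats=eligible,
        )

    def predict(self, tracks: Sequence[Track],
                microtubules: Optional[Sequence[MicrotubuleRef]] = None) -> np.ndarray:
        """Labels for a sequence of tracks ('rejected' for non-binding tracks)."""
        mt_map = {mt.mt_id: mt for mt in microtubules} if microtubules else {}
        labels = []
        for tr in tracks:
            mt = mt_map.get(tr.mt_id, MicrotubuleRef(tr.mt_id, length=max(1.0, tr.positions.max() + 1.0)))
            ev = self.classify(tr, mt)
            labels.append(ev.category if ev is not None else "rejected")
        return np.asarray(labels, dtype=object)

    def events(self, tracks: Sequence[Track],
               microtubules: Sequence[MicrotubuleRef]) -> list[MotilityEvent]:
        mt_map = {mt.mt_id: mt for mt in microtubules}
        out = []
        for tr in tracks:
            ev = self.classify(tr, mt_map[tr.mt_id])
            if ev is not None:
                out.append(ev)
        return out


def classify_track(track: Track, mt: MicrotubuleRef,
                   params: Optional[ClassifyParams] = None,
                   movie_end: Optional[float] = None) -> Optional[MotilityEvent]:
    """Classify a single track (None = rejected: not a binding event)."""
    return TrackClassifier(params=params, movie_end=movie_end).classify(track, mt)


def classify_trackset(trackset, params: Optional[ClassifyParams] = None) -> list[MotilityEvent]:
    """Classify every track of a :class:`TrackSet`, dropping rejected tracks."""
    clf = TrackClassifier(params=params, movie_end=trackset.movie_duration)
    return clf.events(trackset.tracks, trackset.microtubules)


# ---------------------------------------------------------------------------
# run-length statistics
# ---------------------------------------------------------------------------

def extract_run_lengths(events: Iterable[MotilityEvent], mt: Optional[MicrotubuleRef] = None,
                        min_start_distance: float = 5.0) -> list[float]:
    """Run lengths of events eligible for run statistics.

    An event contributes its run length iff it is processive and either its
    entire run was observed or it started more than ``min_start_distance``
    from the minus end (so the microtubule end cannot have cut the run short).
    """
    minus_end = mt.minus_end_position if mt is not None else 0.0
    out = []
    for ev in events:
        if ev.category != "processive" or ev.run_length is None:
            continue
        if ev.fully_observed or (ev.start_position - minus_end) > min_start_distance:
            out.append(float(ev.run_length))
    return out


class ExponentialDecayModel(BaseEstimator):
    """Least-squares one-phase exponential fit of the run-length 1 - CDF.

    Fits ``S(x) = exp(-x / scale)`` to the empirical survival fractions of the
    observed run lengths.  ``fit`` requires at least ``min_runs`` values;
    group comparisons should use the raw run lengths, not the fitted scale.
    """

    def __init__(self, min_runs: int = 10):
        self.min_runs = min_runs

    def fit(self, X: Sequence[float], y=None) -> "ExponentialDecayModel":
        runs = np.sort(np.asarray(list(X), dtype=float))
        if runs.size < self.min_runs:
            raise ValueError(f"need >= {self.min_runs} runs to fit a decay, got {runs.size}")
        if np.any(runs < 0):
            raise ValueError("run lengths must be nonnegative")
        n = runs.size
        # empirical survival just below each sorted value: S(x_i) = 1 - i/n
        surv = 1.0 - np.arange(n) / n
        poorly_conditioned = np.unique(runs).size < 3
        p0 = max(float(runs.mean()), 1e-9)
        if poorly_conditioned:
            scale = p0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(lambda x, s: np.exp(-x / s), runs, surv,
                                    p0=[p0], maxfev=10000)
            scale = float(abs(popt[0]))
        self.fit_ = DecayFit(scale=max(scale, 1e-12), n_runs=int(n),
                             fit_domain=(float(runs[0]), float(runs[-1])),
                             poorly_conditioned=bool(poorly_conditioned))
        self.scale_ = self.fit_.scale
        self.n_runs_ = n
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.fit_.survival(x)


def fit_decay(run_lengths: Sequence[float], min_runs: int = 10) -> DecayFit:
    """Fit ``1 - CDF = exp(-x/scale)`` to run lengths; see :class:`ExponentialDecayModel`."""
    return ExponentialDecayModel(min_runs=min_runs).fit(run_lengths).fit_


# ---------------------------------------------------------------------------
# event counting with background correction
# ---------------------------------------------------------------------------

def count_events(events: Iterable[MotilityEvent],
                 mt_lengths: dict[str, float],
                 background_counts: Optional[Sequence[float]] = None,
                 background_region_length: Optional[float] = None) -> "pd.DataFrame":
    """Per-microtubule binding/processive counts with background correction.

    ``background_counts`` are event tallies from microtubule-free regions of
    the coverslip, each of length ``background_region_length`` (the median
    microtubule length by the sampling convention).  The mean background is
    scaled linearly to each microtubule's length and subtracted; corrected
    counts are floored at 0.  Without background regions the correction is
    skipped with a warning.
    """
    import pandas as pd

    raw: dict[str, dict[str, float]] = {mt: {"n_binding": 0, "n_processive": 0}
                                        for mt in mt_lengths}
    for ev in events:
        if ev.mt_id not in raw:
            raise KeyError(f"event on unknown microtubule {ev.mt_id!r}")
        raw[ev.mt_id]["n_binding"] += 1
        if ev.category == "processive":
            raw[ev.mt_id]["n_processive"] += 1

    if background_counts is None or len(background_counts) == 0:
        warnings.warn("no background regions supplied; skipping background correction")
        bg_per_um = 0.0
    else:
        if background_region_length is None:
            background_region_length = float(np.median(list(mt_lengths.values())))
        bg_per_um = float(np.mean(background_counts)) / background_region_length

    rows = []
    for mt_id, counts in raw.items():
        length = mt_lengths[mt_id]
        expected_bg = bg_per_um * length
        rows.append({
            "mt_id": mt_id, "length_um": length,
            "n_binding": counts["n_binding"], "n_processive": counts["n_processive"],
            "background_expected": expected_bg,
            "n_binding_corrected": max(counts["n_binding"] - expected_bg, 0.0),
            "n_processive_corrected": max(counts["n_processive"] - expected_bg, 0.0),
        })
    return pd.DataFrame(rows).sort_values("mt_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# co-localisation
# ---------------------------------------------------------------------------

def colocalize(tracks_A: Sequence[Track], tracks_B: Sequence[Track],
               max_gap: float = 0.21, min_overlap_fraction: float = 0.5
               ) -> tuple[list[tuple[str, str]], "pd.DataFrame"]:
    """Two-channel co-transport detection.

    Tracks a (channel A) and b (channel B) on the same microtubule are
    co-localised when, over the frames where both exist, their positions agree
    within ``max_gap`` (um, default 2 pixels) for at least
    ``min_overlap_fraction`` of the shorter track's frames.  Each track is
    matched at most once (greedy, best-overlap-first).

    Returns the matched (track_A_id, track_B_id) pairs and a per-microtubule
    table with the co-localised fraction of each channel's tracks.
    """
    import pandas as pd

    channels_a = {tr.channel for tr in tracks_A}
    channels_b = {tr.channel for tr in tracks_B}
    if channels_a and channels_a == channels_b:
        raise ValueError(f"both inputs carry the same channel label {channels_a}")

    candidates = []
    for a in tracks_A:
        ta = np.round(a.times, 6)
        for b in tracks_B:
            if a.mt_id != b.mt_id:
                continue
            tb = np.round(b.times, 6)
            common, ia, ib = np.intersect1d(ta, tb, return_indices=True)
            if common.size == 0:
                continue
            agree = np.abs(a.positions[ia] - b.positions[ib]) <= max_gap
            shorter = min(a.n_frames, b.n_frames)
            score = float(np.sum(agree)) / shorter
            if score >= min_overlap_fraction:
                candidates.append((score, a.track_id, b.track_id, a.mt_id))

    pairs: list[tuple[str, str]] = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    pair_mts = []
    for score, aid, bid, mt_id in sorted(candidates, reverse=True):
        if aid in used_a or bid in used_b:
            continue
        used_a.add(aid)
        used_b.add(bid)
        pairs.append((aid, bid))
        pair_mts.append(mt_id)

    mt_ids = sorted({tr.mt_id for tr in list(tracks_A) + list(tracks_B)})
    rows = []
    for mt_id in mt_ids:
        n_a = sum(tr.mt_id == mt_id for tr in tracks_A)
        n_b = sum(tr.mt_id == mt_id for tr in tracks_B)
        n_pairs = pair_mts.count(mt_id)
        rows.append({
            "mt_id": mt_id, "n_tracks_A": n_a, "n_tracks_B": n_b, "n_pairs": n_pairs,
            "fraction_A_coloc": n_pairs / n_a if n_a else np.nan,
            "fraction_B_coloc": n_pairs / n_b if n_b else np.nan,
        })
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# motility fractions
# ---------------------------------------------------------------------------

def motility_fractions(events: Sequence[MotilityEvent]) -> "pd.DataFrame":
    """Per-microtubule and pooled (processive, static, diffusive) fractions.

    Microtubules without accepted events do not appear (the fraction is
    undefined, not zero).  The pooled row aggregates all events.
    """
    import pandas as pd

    if not events:
        return pd.DataFrame(columns=["mt_id", "n_events", "fraction_processive",
                                     "fraction_static", "fraction_diffusive"])
    rows = []
    by_mt: dict[str, list[MotilityEvent]] = {}
    for ev in events:
        by_mt.setdefault(ev.mt_id, []).append(ev)
    groups = [(mt_id, evs) for mt_id, evs in sorted(by_mt.items())]
    groups.append(("pooled", list(events)))
    for mt_id, evs in groups:
        n = len(evs)
        counts = {c: sum(ev.category == c for ev in evs)
                  for c in ("processive", "static", "diffusive")}
        rows.append({"mt_id": mt_id, "n_events": n,
                     **{f"fraction_{c}": counts[c] / n for c in counts}})
    return pd.DataFrame(rows)
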