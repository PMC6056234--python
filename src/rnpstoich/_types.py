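"""Core record types shared across the simulation, motility and stoichiometry layers.

Units are fixed package-wide: positions and lengths in micrometres, times in
seconds, velocities in um/s.  The microtubule minus end sits at coordinate 0
and positions increase toward the plus end, so minus-end-directed (dynein)
transport corresponds to *decreasing* position and negative velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Track",
    "MicrotubuleRef",
    "TrackSet",
    "VelocitySegment",
    "MotilityEvent",
    "DualColourCounts",
    "CopyNumberEstimate",
]


@dataclass(frozen=True)
class MicrotubuleRef:
    """One microtubule selected for analysis.

    ``minus_end_position`` is 0 by convention; ``length`` is the plus-end
    coordinate in um.
    """

    mt_id: str
    length: float
    minus_end_position: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.length) or self.length <= 0:
            raise ValueError(f"microtubule {self.mt_id!r}: length must be > 0, got {self.length}")


@dataclass
class Track:
    """One particle's sampled positions along one microtubule, one channel.

    ``times`` are strictly increasing sample times (s); ``positions`` are the
    matching coordinates along the microtubule axis (um).
    """

    mt_id: str
    track_id: str
    channel: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.positions.shape:
            raise ValueError(f"track {self.track_id!r}: times and positions must be matching 1-D arrays")
        if self.times.size < 1:
            raise ValueError(f"track {self.track_id!r}: needs at least one sample")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"track {self.track_id!r}: times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError(f"track {self.track_id!r}: positions must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def duration_span(self) -> float:
        """Time between first and last sample (s)."""
        return float(self.times[-1] - self.times[0])


@dataclass
class TrackSet:
    """A collection of tracks plus the microtubules they live on.

    ``ground_truth`` (optional, present for simulated data) maps track_id to a
    dict with keys ``class`` ("static" | "diffusive" | "processive"),
    ``run_length`` (um, processive only), ``segment_velocities`` (list of um/s,
    signed), ``reached_minus_end`` and ``censored_by_movie_end`` flags.
    """

    tracks: list[Track]
    microtubules: list[MicrotubuleRef]
    ground_truth: Optional[dict[str, dict]] = None
    frame_interval: Optional[float] = None
    movie_duration: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        known = {mt.mt_id for mt in self.microtubules}
        for tr in self.tracks:
            if tr.mt_id not in known:
                raise ValueError(f"track {tr.track_id!r} references unknown microtubule {tr.mt_id!r}")

    def microtubule(self, mt_id: str) -> MicrotubuleRef:
        for mt in self.microtubules:
            if mt.mt_id == mt_id:
                return mt
        raise KeyError(f"unknown microtubule id {mt_id!r}")

    def __len__(self) -> int:
        return len(self.tracks)


@dataclass(frozen=True)
class VelocitySegment:
    """A constant-velocity stretch of a processive run (half-open [t_start, t_end))."""

    t_start: float
    t_end: float
    velocity: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("segment must have t_end > t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class MotilityEvent:
    """A classified binding event.

    ``net_displacement`` is signed (negative = toward the minus end);
    ``run_length`` is the magnitude of the total displacement of the motile
    portion, pauses and velocity changes included, and is present only for
    processive events.  ``censored`` marks runs whose full extent was not
    observed (movie-boundary truncation or minus-end arrest);
    ``eligible_for_run_stats`` applies the censoring rule: the entire run was
    observed, or it began more than ``min_start_distance`` from the minus end.
    """

    track_id: str
    mt_id: str
    channel: str
    category: str  # "static" | "diffusive" | "processive"
    duration: float
    n_frames: int
    start_time: float
    end_time: float
    start_position: float
    end_position: float
    net_displacement: float
    path_length: float
    segments: list[VelocitySegment] = field(default_factory=list)
    run_length: Optional[float] = None
    censored: bool = False
    fully_observed: bool = False
    eligible_for_run_stats: bool = False


@dataclass
class DualColourCounts:
    """Tallies of dual / single-colour / undetected complexes for one condition.

    ``n_undetected`` is unobservable in the real assay (a complex with no dye
    produces no spot) and is retained only for simulated data.
    Observed fractions are conditioned on detection.
    """

    n_dual: int
    n_A_only: int
    n_B_only: int
    n_undetected: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        for name in ("n_dual", "n_A_only", "n_B_only", "n_undetected"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_detected(self) -> int:
        return self.n_dual + self.n_A_only + self.n_B_only

    @property
    def n_total(self) -> int:
        return self.n_detected + self.n_undetected

    @property
    def dual_fraction(self) -> float:
        """Dual-colour fraction among detected complexes."""
        if self.n_detected == 0:
            return float("nan")
        return self.n_dual / self.n_detected

    def fractions(self) -> tuple[float, float, float]:
        """(dual, A-only, B-only) fractions among detected complexes."""
        n = self.n_detected
        if n == 0:
            return (float("nan"),) * 3
        return (self.n_dual / n, self.n_A_only / n, self.n_B_only / n)


@dataclass
class CopyNumberEstimate:
    """Inferred 1-copy / 2-copy mixture with an interval on the 2-copy weight."""

    two_copy_fraction: float
    one_copy_fraction: float
    ci_low: float
    ci_high: float
    observed_dual_fraction: float
    n_detected: int
    out_of_model: bool = False
    model: str = ""

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.two_copy_fraction <= 1 + 1e-9):
            raise ValueError("two_copy_fraction outside [0, 1]")
        if abs(self.two_copy_fraction + self.one_copy_fraction - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")
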