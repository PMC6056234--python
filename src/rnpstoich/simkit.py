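"""Synthetic single-molecule trajectory and labelling-outcome generator.

Emulates the statistical structure of particle tracks observed by TIRF
microscopy on surface-immobilised microtubules: a mixture of static,
diffusive and processive (minus-end-directed) particles sampled at ~2 frames
per second with Gaussian localisation noise at the 105-nm pixel scale, plus
the stochastic dye-assignment process of dual-colour labelling experiments
(binomial SNAP labelling of polypeptides, Poisson body-labelling of RNA).

Every simulation is driven by a single seeded ``numpy.random.Generator`` and
records per-track ground truth, so downstream classification, kinetics and
copy-number inference can be tested against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._types import DualColourCounts, MicrotubuleRef, Track, TrackSet

__all__ = [
    "SimConfig",
    "LabelingModel",
    "simulate_trackset",
    "simulate_dual_labels",
    "simulate_rna_labels",
    "render_kymograph",
    "save_kymograph",
]

CLASS_NAMES = ("static", "diffusive", "processive")


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


@dataclass
class SimConfig:
    """Parameters of a synthetic motility experiment.

    Lengths in um, times in s.  The minus end of every microtubule is at
    coordinate 0; processive particles move toward it (decreasing position).

    Defaults describe the reconstituted mRNA-transport assay: ~15-um
    microtubules, 500 frames at 2 frames/s, 105-nm pixels, ~1 um/s
    minus-end-directed runs with exponential ~5-um run lengths, and mostly
    processive particles.
    """

    n_microtubules: int = 10
    mt_length_mean: float = 15.0
    mt_length_sd: float = 3.0
    tracks_per_mt_mean: float = 30.0
    n_tracks: Optional[int] = None  # exact total; overrides the Poisson draw
    class_probs: tuple[float, float, float] = (0.1, 0.1, 0.8)
    velocity_mean: float = 1.0
    velocity_sd: float = 0.3
    segment_switch_rate: float = 0.1
    run_length_mean: float = 5.0
    diffusion_coeff: float = 0.05
    attach_duration_mean: float = 10.0
    minus_end_dwell: Optional[float] = None  # None: arrested until movie end
    frame_interval: float = 0.5
    pixel_size: float = 0.105
    localisation_sd: float = 0.05
    movie_duration: float = 250.0
    channel: str = "ch0"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.class_probs, dtype=float)
        _require(probs.size == 3 and np.all(probs >= 0),
                 "class_probs must be 3 nonnegative probabilities (static, diffusive, processive)")
        _require(abs(probs.sum() - 1.0) <= 1e-12, "class_probs must sum to 1")
        for name in ("mt_length_mean", "tracks_per_mt_mean", "velocity_mean",
                     "segment_switch_rate", "run_length_mean", "attach_duration_mean",
                     "frame_interval", "pixel_size", "movie_duration"):
            value = getattr(self, name)
            _require(np.isfinite(value) and value > 0, f"{name} must be finite and > 0, got {value}")
        for name in ("mt_length_sd", "velocity_sd", "diffusion_coeff", "localisation_sd"):
            value = getattr(self, name)
            _require(np.isfinite(value) and value >= 0, f"{name} must be finite and >= 0, got {value}")
        _require(self.n_microtubules >= 1, "n_microtubules must be >= 1")


@dataclass
class LabelingModel:
    """Parameters of the stochastic dye-assignment process.

    ``binomial_snap`` mode: each polypeptide carries a dye with probability
    ``p_label``; a labelled polypeptide is dye A with probability ``q_dyeA``
    else dye B.  ``poisson_body`` mode: each RNA comes from the colour-A
    preparation with probability ``colourA_fraction`` and carries
    Poisson(``poisson_mean``) dyes of that colour.
    """

    mode: str = "binomial_snap"
    p_label: float = 0.9
    q_dyeA: float = 0.5
    poisson_mean: float = 3.0
    colourA_fraction: float = 0.5

    def __post_init__(self) -> None:
        _require(self.mode in ("binomial_snap", "poisson_body"),
                 f"mode must be 'binomial_snap' or 'poisson_body', got {self.mode!r}")
        for name in ("p_label", "q_dyeA", "colourA_fraction"):
            _require(0.0 <= getattr(self, name) <= 1.0, f"{name} must lie in [0, 1]")
        _require(self.poisson_mean >= 0, "poisson_mean must be >= 0")


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _truncated_normal_speed(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw a nonnegative speed; resampling implements the >=0 truncation."""
    if sd == 0:
        return max(mean, 0.0)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= 0:
            return v
    return 0.0


def _processive_path(rng: np.random.Generator, cfg: SimConfig, x0: float,
                     t_grid: np.ndarray) -> tuple[np.ndarray, dict]:
    """Noise-free minus-end-directed path with piecewise-constant speed.

    The particle consumes an exponential total run length; it arrests on
    reaching the minus end (coordinate 0) and then dwells there.  Returns the
    positions on ``t_grid`` (relative times from attachment) and ground truth.
    """
    run_length = rng.exponential(cfg.run_length_mean)
    # build piecewise-constant speed profile until the run budget is spent
    seg_velocities: list[float] = []
    seg_durations: list[float] = []
    remaining = run_length
    while remaining > 1e-12:
        speed = _truncated_normal_speed(rng, cfg.velocity_mean, cfg.velocity_sd)
        duration = rng.exponential(1.0 / cfg.segment_switch_rate)
        if speed <= 1e-9:
            # a pause segment: consumes time, not run length
            seg_velocities.append(0.0)
            seg_durations.append(duration)
            continue
        travel = speed * duration
        if travel >= remaining:
            duration = remaining / speed
            travel = remaining
        seg_velocities.append(-speed)  # minus-end-directed
        seg_durations.append(duration)
        remaining -= travel
    if not seg_durations:  # zero-length run
        seg_velocities, seg_durations = [0.0], [cfg.frame_interval]

    # integrate the piecewise path, stopping at the minus end
    breaks = np.concatenate([[0.0], np.cumsum(seg_durations)])
    x = np.empty_like(t_grid)
    reached_minus_end = False
    for i, t in enumerate(t_grid):
        # position at relative time t
        xt = x0
        for v, t_a, t_b in zip(seg_velocities, breaks[:-1], breaks[1:]):
            if t <= t_a:
                break
            xt += v * (min(t, t_b) - t_a)
        if xt <= 0.0:
            reached_minus_end = True
            xt = 0.0
        x[i] = xt
    truth = {
        "class": "processive",
        "run_length": run_length,
        "segment_velocities": list(seg_velocities),
        "segment_durations": list(seg_durations),
        "reached_minus_end": reached_minus_end,
    }
    return x, truth


def simulate_trackset(config: SimConfig) -> TrackSet:
    """Simulate a full track set with recorded ground truth.

    Tracks attach at uniform random times and positions, persist for an
    exponential attachment duration (processive tracks: until the run length
    is consumed, the minus end is reached, or the movie ends), and are sampled
    on the global frame grid with Gaussian localisation noise added to every
    position.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval
    n_frames_movie = int(math.floor(config.movie_duration / dt)) + 1

    microtubules = []
    for m in range(config.n_microtubules):
        length = max(rng.normal(config.mt_length_mean, config.mt_length_sd), 1.0)
        microtubules.append(MicrotubuleRef(mt_id=f"mt{m:03d}", length=length))

    if config.n_tracks is not None:
        # exact total, assigned to microtubules uniformly at random
        mt_index = rng.integers(0, config.n_microtubules, size=config.n_tracks)
        per_mt = [int(np.sum(mt_index == m)) for m in range(config.n_microtubules)]
    else:
        per_mt = [int(rng.poisson(config.tracks_per_mt_mean)) for _ in range(config.n_microtubules)]

    tracks: list[Track] = []
    ground_truth: dict[str, dict] = {}
    track_counter = 0
    for mt, n_tracks in zip(microtubules, per_mt):
        for _ in range(n_tracks):
            track_id = f"tr{track_counter:05d}"
            track_counter += 1
            cls = CLASS_NAMES[rng.choice(3, p=np.asarray(config.class_probs, dtype=float))]
            t_attach = rng.uniform(0.0, config.movie_duration)
            x0 = rng.uniform(0.0, mt.length)

            # frame grid covering the attachment window
            first_frame = int(math.ceil(t_attach / dt))
            if cls == "processive":
                # duration is set by the run itself (plus any minus-end dwell)
                t_grid_full = np.arange(first_frame, n_frames_movie) * dt
                if t_grid_full.size == 0:
                    continue
                rel = t_grid_full - t_attach
                x, truth = _processive_path(rng, config, x0, rel)
                run_time = sum(truth["segment_durations"])
                if truth["reached_minus_end"]:
                    dwell = (config.movie_duration - t_attach
                             if config.minus_end_dwell is None else config.minus_end_dwell)
                    arrest_rel = rel[np.nonzero(x <= 0.0)[0][0]] if np.any(x <= 0.0) else run_time
                    t_detach_rel = arrest_rel + dwell
                else:
                    t_detach_rel = run_time
                keep = rel <= t_detach_rel + 1e-9
                times, positions = t_grid_full[keep], x[keep]
                truth["censored_by_movie_end"] = bool(
                    times.size and times[-1] + dt > config.movie_duration - 1e-9)
            else:
                duration = rng.exponential(config.attach_duration_mean)
                t_detach = min(t_attach + duration, config.movie_duration)
                last_frame = int(math.floor(t_detach / dt))
                times = np.arange(first_frame, min(last_frame + 1, n_frames_movie)) * dt
                if times.size == 0:
                    continue
                rel = times - t_attach
                if cls == "static":
                    positions = np.full(rel.shape, x0)
                else:  # diffusive: unbiased Gaussian random walk
                    steps = rng.normal(0.0, math.sqrt(2.0 * config.diffusion_coeff * dt),
                                       size=rel.size)
                    steps[0] = 0.0
                    positions = x0 + np.cumsum(steps)
                truth = {"class": cls, "run_length": None, "segment_velocities": [],
                         "reached_minus_end": False,
                         "censored_by_movie_end": bool(t_attach + duration > config.movie_duration)}
            if times.size == 0:
                continue
            noisy = positions + rng.normal(0.0, config.localisation_sd, size=positions.size)
            noisy = np.clip(noisy, 0.0, mt.length)
            truth["attach_time"] = t_attach
            truth["start_position"] = x0
            tracks.append(Track(mt_id=mt.mt_id, track_id=track_id,
                                channel=config.channel, times=times, positions=noisy))
            ground_truth[track_id] = truth

    return TrackSet(tracks=tracks, microtubules=microtubules, ground_truth=ground_truth,
                    frame_interval=dt, movie_duration=config.movie_duration, seed=config.seed)


# ---------------------------------------------------------------------------
# labelling simulations
# ---------------------------------------------------------------------------

def simulate_dual_labels(n_complexes: int, two_copy_fraction: float,
                         model: LabelingModel, seed: int) -> DualColourCounts:
    """Monte-Carlo dual-colour outcome of binomially labelled 1/2-copy complexes.

    Each complex holds two polypeptides with probability ``two_copy_fraction``
    (else one); each polypeptide is independently labelled with probability
    ``p_label`` and, if labelled, carries dye A with probability ``q_dyeA``.
    """
    if model.mode != "binomial_snap":
        raise ValueError(f"simulate_dual_labels requires a binomial_snap model, got {model.mode!r}")
    _require(0.0 <= two_copy_fraction <= 1.0, "two_copy_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    copies = 1 + (rng.random(n_complexes) < two_copy_fraction).astype(int)
    n_dual = n_a = n_b = n_none = 0
    for k in copies:
        labelled = rng.random(k) < model.p_label
        is_a = rng.random(k) < model.q_dyeA
        has_a = bool(np.any(labelled & is_a))
        has_b = bool(np.any(labelled & ~is_a))
        if has_a and has_b:
            n_dual += 1
        elif has_a:
            n_a += 1
        elif has_b:
            n_b += 1
        else:
            n_none += 1
    return DualColourCounts(n_dual=n_dual, n_A_only=n_a, n_B_only=n_b,
                            n_undetected=n_none, condition="simulated_snap")


def simulate_rna_labels(n_rnps: int, two_rna_fraction: float,
                        model: LabelingModel, seed: int) -> DualColourCounts:
    """Monte-Carlo dual-colour outcome of Poisson body-labelled 1/2-RNA particles.

    Each RNP holds two RNAs with probability ``two_rna_fraction`` (else one);
    each RNA comes from the colour-A preparation with probability
    ``colourA_fraction`` and carries Poisson(``poisson_mean``) dyes of that
    colour; it is detected iff it carries at least one dye.
    """
    if model.mode != "poisson_body":
        raise ValueError(f"simulate_rna_labels requires a poisson_body model, got {model.mode!r}")
    _require(0.0 <= two_rna_fraction <= 1.0, "two_rna_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_rna = 1 + (rng.random(n_rnps) < two_rna_fraction).astype(int)
    n_dual = n_a = n_b = n_none = 0
    for k in n_rna:
        is_a = rng.random(k) < model.colourA_fraction
        dyes = rng.poisson(model.poisson_mean, size=k)
        detected = dyes >= 1
        has_a = bool(np.any(detected & is_a))
        has_b = bool(np.any(detected & ~is_a))
        if has_a and has_b:
            n_dual += 1
        elif has_a:
            n_a += 1
        elif has_b:
            n_b += 1
        else:
            n_none += 1
    return DualColourCounts(n_dual=n_dual, n_A_only=n_a, n_B_only=n_b,
                            n_undetected=n_none, condition="simulated_rna")


# ---------------------------------------------------------------------------
# kymograph rendering
# ---------------------------------------------------------------------------

def render_kymograph(trackset: TrackSet, mt_id: str,
                     amplitude: float = 100.0, background: float = 10.0,
                     psf_sigma: float = 0.13, clip_max: float = 255.0) -> np.ndarray:
    """Render a time-by-position kymograph image for one microtubule.

    Each track sample contributes a 1-D Gaussian spot of width ``psf_sigma``
    (um) centred at its position; rows are frames, columns are pixels of size
    ``trackset``'s pixel scale (0.105 um).  Values are background + signal,
    clipped to [0, clip_max].
    """
    mt = trackset.microtubule(mt_id)  # raises KeyError for unknown ids
    dt = trackset.frame_interval or 0.5
    duration = trackset.movie_duration
    if duration is None:
        duration = max((tr.times[-1] for tr in trackset.tracks), default=0.0)
    pixel = 0.105
    n_rows = int(math.floor(duration / dt)) + 1
    n_cols = max(int(math.ceil(mt.length / pixel)), 1)
    img = np.full((n_rows, n_cols), background, dtype=float)
    cols = (np.arange(n_cols) + 0.5) * pixel
    for tr in trackset.tracks:
        if tr.mt_id != mt_id:
            continue
        rows = np.rint(tr.times / dt).astype(int)
        ok = (rows >= 0) & (rows < n_rows)
        for row, x in zip(rows[ok], tr.positions[ok]):
            img[row] += amplitude * np.exp(-0.5 * ((cols - x) / psf_sigma) ** 2)
    return np.clip(img, 0.0, clip_max)


def save_kymograph(trackset: TrackSet, mt_id: str, path, **render_kwargs) -> None:
    """Render one microtubule's kymograph and write it as single-channel TIFF."""
    import tifffile

    img = render_kymograph(trackset, mt_id, **render_kwargs)
    tifffile.imwrite(str(path), img.astype(np.float32))
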