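"""End-to-end orchestration: simulate -> classify -> kinetics -> coloc -> stoich.

A :class:`RunConfig` selects stages and sources; :func:`run_pipeline` executes
them in order, writes every intermediate table under the output directory and
returns a :class:`Report` whose provenance block (config hash, seed, package
version) makes the run reproducible.  All randomness flows from the single
configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from ._types import DualColourCounts, MotilityEvent
from .io import read_counts, read_tracks, write_counts, write_tracks
from .motility import (ClassifyParams, classify_trackset, colocalize,
                       count_events, extract_run_lengths, fit_decay,
                       motility_fractions)
from .simkit import LabelingModel, SimConfig, simulate_dual_labels, simulate_trackset
from .stoichiometry import infer_rna_mixture, infer_two_copy_fraction

__all__ = ["RunConfig", "Report", "run_pipeline", "compare_conditions"]

logger = logging.getLogger("rnpstoich")


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Exactly one input source per stage: the classify/kinetics stages read
    ``tracks_path`` unless ``sim`` is given (then tracks are simulated); the
    stoichiometry stage reads ``counts_path`` unless ``labeling`` plus
    simulated counts are requested via ``simulate_counts``.
    """

    out_dir: str = "rnpstoich_out"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "classify", "kinetics", "coloc", "stoich")
    sim: Optional[SimConfig] = None
    tracks_path: Optional[str] = None
    tracks_path_B: Optional[str] = None  # second channel for coloc
    counts_path: Optional[str] = None
    labeling: LabelingModel = field(default_factory=LabelingModel)
    simulate_counts: Optional[dict] = None  # {"n_complexes": int, "two_copy_fraction": float}
    classify_params: ClassifyParams = field(default_factory=ClassifyParams)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        if "sim" in doc and doc["sim"] is not None and not isinstance(doc["sim"], SimConfig):
            doc["sim"] = SimConfig(**doc["sim"])
        if "labeling" in doc and not isinstance(doc["labeling"], LabelingModel):
            doc["labeling"] = LabelingModel(**doc["labeling"])
        if "classify_params" in doc and not isinstance(doc["classify_params"], ClassifyParams):
            doc["classify_params"] = ClassifyParams(**doc["classify_params"])
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)


@dataclass
class Report:
    """Structured pipeline output: one table per stage plus provenance."""

    tables: dict[str, pd.DataFrame]
    provenance: dict

    def to_json(self) -> str:
        body = {name: df.to_dict(orient="records") for name, df in sorted(self.tables.items())}
        return json.dumps({"tables": body, "provenance": self.provenance},
                          indent=1, sort_keys=True, default=float)


def _config_hash(config: RunConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            # out_dir is where results land, not an analysis input
            return {f.name: encode(getattr(obj, f.name))
                    for f in dataclasses.fields(obj) if f.name != "out_dir"}
        if isinstance(obj, (tuple, list)):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        return obj
    blob = json.dumps(encode(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _events_table(events: Sequence[MotilityEvent]) -> pd.DataFrame:
    rows = [{k: v for k, v in dataclasses.asdict(ev).items() if k != "segments"}
            | {"n_segments": len(ev.segments)} for ev in events]
    return pd.DataFrame(rows)


def _segments_table(events: Sequence[MotilityEvent], pause_velocity: float) -> pd.DataFrame:
    rows = []
    for ev in events:
        for seg in ev.segments:
            rows.append({"track_id": ev.track_id, "mt_id": ev.mt_id,
                         "t_start": seg.t_start, "t_end": seg.t_end,
                         "velocity_um_s": seg.velocity,
                         "is_pause": abs(seg.velocity) < pause_velocity})
    return pd.DataFrame(rows, columns=["track_id", "mt_id", "t_start", "t_end",
                                       "velocity_um_s", "is_pause"])


def run_pipeline(config: RunConfig) -> Report:
    """Execute the configured stages; see module docstring.

    A stage failure raises with the stage named; tables produced by earlier
    stages are already on disk and are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    stage = "setup"
    try:
        trackset = None
        if "simulate" in config.stages and config.sim is not None:
            stage = "simulate"
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            trackset = simulate_trackset(sim_cfg)
            write_tracks(trackset, out / "tracks.tsv")
            logger.info("simulate: %d tracks on %d microtubules",
                        len(trackset), len(trackset.microtubules))
        elif config.tracks_path is not None:
            stage = "load"
            trackset = read_tracks(config.tracks_path)
            logger.info("load: %d tracks in", len(trackset))

        events: list[MotilityEvent] = []
        if "classify" in config.stages and trackset is not None:
            stage = "classify"
            events = classify_trackset(trackset, config.classify_params)
            tables["events"] = _events_table(events)
            tables["events"].to_csv(out / "events.tsv", sep="\t", index=False)
            tables["motility_fractions"] = motility_fractions(events)
            tables["motility_fractions"].to_csv(out / "motility_fractions.tsv",
                                                sep="\t", index=False)
            logger.info("classify: %d tracks in, %d binding events out",
                        len(trackset), len(events))

        if "kinetics" in config.stages and events:
            stage = "kinetics"
            p = config.classify_params
            tables["segments"] = _segments_table(events, p.pause_velocity)
            tables["segments"].to_csv(out / "segments.tsv", sep="\t", index=False)
            runs = extract_run_lengths(events, min_start_distance=p.min_start_distance)
            summary: dict[str, float] = {"n_eligible_runs": len(runs)}
            if len(runs) >= 10:
                decay = fit_decay(runs)
                summary |= {"run_length_scale_um": decay.scale,
                            "run_length_mean_um": float(np.mean(runs))}
            moving = tables["segments"].query("~is_pause")["velocity_um_s"]
            if len(moving):
                summary |= {"segment_velocity_mean_um_s": float(moving.mean()),
                            "segment_velocity_sd_um_s": float(moving.std(ddof=1))
                            if len(moving) > 1 else 0.0}
            tables["kinetics_summary"] = pd.DataFrame([summary])
            tables["kinetics_summary"].to_csv(out / "kinetics_summary.tsv",
                                              sep="\t", index=False)
            mt_lengths = {m.mt_id: m.length for m in trackset.microtubules}
            tables["event_counts"] = count_events(events, mt_lengths, background_counts=[0.0])
            tables["event_counts"].to_csv(out / "event_counts.tsv", sep="\t", index=False)
            logger.info("kinetics: %d events in, %d eligible runs out", len(events), len(runs))

        if "coloc" in config.stages and trackset is not None and config.tracks_path_B:
            stage = "coloc"
            other = read_tracks(config.tracks_path_B)
            _, coloc_df = colocalize(trackset.tracks, other.tracks)
            tables["colocalization"] = coloc_df
            coloc_df.to_csv(out / "colocalization.tsv", sep="\t", index=False)
            logger.info("coloc: %d + %d tracks in, %d pairs out",
                        len(trackset), len(other), int(coloc_df["n_pairs"].sum()))

        if "stoich" in config.stages:
            stage = "stoich"
            counts_list: list[DualColourCounts] = []
            if config.counts_path is not None:
                counts_list = read_counts(config.counts_path)
            elif config.simulate_counts is not None:
                sc = config.simulate_counts
                counts_list = [simulate_dual_labels(
                    n_complexes=int(sc["n_complexes"]),
                    two_copy_fraction=float(sc["two_copy_fraction"]),
                    model=config.labeling, seed=config.seed)]
                write_counts(counts_list, out / "counts.tsv")
            rows = []
            for counts in counts_list:
                if config.labeling.mode == "binomial_snap":
                    est = infer_two_copy_fraction(counts, config.labeling.p_label,
                                                  config.labeling.q_dyeA,
                                                  random_state=config.seed)
                else:
                    est = infer_rna_mixture(counts, config.labeling.poisson_mean,
                                            config.labeling.colourA_fraction,
                                            random_state=config.seed)
                rows.append({"condition": counts.condition, "n_detected": est.n_detected,
                             "observed_dual_fraction": est.observed_dual_fraction,
                             "two_copy_fraction": est.two_copy_fraction,
                             "one_copy_fraction": est.one_copy_fraction,
                             "ci_low": est.ci_low, "ci_high": est.ci_high,
                             "out_of_model": est.out_of_model, "model": est.model})
            if rows:
                tables["copy_number"] = pd.DataFrame(rows)
                tables["copy_number"].to_csv(out / "copy_number.tsv", sep="\t", index=False)
                logger.info("stoich: %d conditions in, %d estimates out", len(rows), len(rows))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    provenance = {"config_hash": _config_hash(config), "seed": config.seed,
                  "package": "rnpstoich", "version": __version__,
                  "stages_run": sorted(tables)}
    report = Report(tables=tables, provenance=provenance)
    (out / "report.json").write_text(report.to_json())
    return report


def compare_conditions(groupA: Sequence[float], groupB: Sequence[float],
                       test: str = "welch") -> dict:
    """Two-sample comparison mirroring standard motility-paper choices.

    ``test``: "student" (equal-variance t), "welch" (unequal variance) or
    "mannwhitney" (rank-based).  Returns statistic, p-value, group means and
    mean difference; raises for groups smaller than 2.
    """
    a = np.asarray(list(groupA), dtype=float)
    b = np.asarray(list(groupB), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if test == "student":
        res = stats.ttest_ind(a, b, equal_var=True)
    elif test == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"test": test, "statistic": float(res.statistic), "p_value": float(res.pvalue),
            "mean_A": float(a.mean()), "mean_B": float(b.mean()),
            "difference": float(a.mean() - b.mean())}
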