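"""End-to-end pipeline: run every analysis stage, write tidy CSVs and a
machine-readable manifest.

All randomness (generator, rewiring nulls) flows from one master seed,
split deterministically per stage, so a single integer reproduces the
whole bundle; outputs carry no wall-clock state, making reruns
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity_metrics import (daily_counts, interposting_ecdf, periodogram,
                               superuser_set, weekly_active_superusers)
from .ego_analysis import triads_vs_contribution
from .errors import InsufficientDataError, ParameterError, ThreadnetError
from .expertise import z_score_table
from .forum_io import read_post_log, write_post_log
from .model import PostLog
from .network_build import build_reply_network, undirected_projection, weekly_cumulative_networks
from .report import summarize
from .structure_metrics import (largest_component_fraction_series,
                                normalized_rich_club_curve, targeted_removal_curve)
from .synthetic_forum import generate_forum, preset_config

ALL_STAGES = (
    "summary",
    "components",
    "removal",
    "richclub",
    "periodicity",
    "interposting",
    "superusers",
    "zscore",
    "ego",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a posts CSV/JSONL, with optional
    ``users_path`` sidecar) or ``preset`` (synthetic community generated
    on the fly) must be given.
    """

    out_dir: str | Path
    input_path: str | Path | None = None
    users_path: str | Path | None = None
    input_format: str = "csv"
    preset: str | None = None
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    superuser_percent: float = 1.0
    interposting_top_percent: float = 5.0
    ego_top_percent: float = 5.0
    richclub_nulls: int = 20
    removal_fractions: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.26, 0.01), 2))

    def validate(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ParameterError("give exactly one of input_path or preset")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ParameterError(f"unknown stage(s): {', '.join(sorted(unknown))}")


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest.

    Writes one tidy CSV per stage under ``out_dir`` plus ``manifest.json``
    recording version, seeds, parameters and the input checksum. A stage
    that cannot run on the given data (e.g. too few usable egos) is
    recorded as failed in the manifest without aborting the rest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.preset is not None:
        cfg = preset_config(config.preset, seed=_stage_seed(config.seed, "simulate"))
        log = generate_forum(cfg)
        posts_file = out / "forum.csv"
        write_post_log(log, posts_file, "csv", users_sink=out / "users.csv")
        input_bytes = posts_file.read_bytes()
        source = {"preset": config.preset, "generator_config": cfg.to_dict()}
    else:
        input_bytes = Path(config.input_path).read_bytes()
        log = read_post_log(config.input_path, config.input_format,
                            users_source=config.users_path)
        source = {"input_path": str(config.input_path)}

    manifest: dict = {
        "threadnet_version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in ("simulate", "richclub")},
        "source": source,
        "input_sha256": hashlib.sha256(input_bytes).hexdigest(),
        "parameters": {
            "superuser_percent": config.superuser_percent,
            "interposting_top_percent": config.interposting_top_percent,
            "ego_top_percent": config.ego_top_percent,
            "richclub_nulls": config.richclub_nulls,
            "removal_fractions": list(config.removal_fractions),
        },
        "stages": {},
        "outputs": {},
    }

    view = None

    def need_view():
        nonlocal view
        if view is None:
            view = undirected_projection(build_reply_network(log))
        return view

    def emit(stage: str, filename: str, frame: pd.DataFrame) -> None:
        path = out / filename
        frame.to_csv(path, index=False)
        manifest["outputs"][stage] = filename

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            if stage == "summary":
                rep = summarize(log).to_dict()
                emit(stage, "summary.csv",
                     pd.DataFrame({"metric": list(rep), "value": list(rep.values())}))
            elif stage == "components":
                snaps = weekly_cumulative_networks(log)
                emit(stage, "largest_component_series.csv",
                     largest_component_fraction_series(log, snaps))
            elif stage == "removal":
                curve = targeted_removal_curve(need_view(), list(config.removal_fractions))
                emit(stage, "removal_curve.csv", curve.to_frame())
            elif stage == "richclub":
                curve = normalized_rich_club_curve(
                    need_view(), n_nulls=config.richclub_nulls,
                    seed=_stage_seed(config.seed, "richclub"))
                emit(stage, "richclub_curve.csv", curve.to_frame())
            elif stage == "periodicity":
                spec = periodogram(daily_counts(log))
                emit(stage, "spectrum.csv", spec.to_frame())
            elif stage == "interposting":
                ecdf = interposting_ecdf(
                    log, set(superuser_set(log, "top_percent_posts",
                                           config.interposting_top_percent).members))
                emit(stage, "interposting_ecdf.csv",
                     pd.DataFrame({"gap_days": ecdf.gaps, "cum_fraction": ecdf.cum_fraction}))
            elif stage == "superusers":
                su = superuser_set(log, "top_percent_posts", config.superuser_percent)
                emit(stage, "weekly_superusers.csv", weekly_active_superusers(log, su))
            elif stage == "zscore":
                zt = z_score_table(log)
                emit(stage, "zscore.csv", zt.table)
            elif stage == "ego":
                cohort = superuser_set(log, "top_percent_posts", config.ego_top_percent)
                summary = triads_vs_contribution(log, cohort)
                emit(stage, "ego_triads.csv", summary.table)
                manifest["stages"].setdefault("ego_stats", {})
                manifest["stages"]["ego_stats"] = {
                    "r": None if np.isnan(summary.r) else summary.r,
                    "p_value": None if np.isnan(summary.p_value) else summary.p_value,
                    "n": summary.n,
                }
            manifest["stages"][stage] = "ok"
        except (ThreadnetError, InsufficientDataError) as exc:
            manifest["stages"][stage] = f"failed: {exc}"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def load_log(config: RunConfig) -> PostLog:
    """Materialize the run's input log (synthetic or from disk)."""
    config.validate()
    if config.preset is not None:
        return generate_forum(
            preset_config(config.preset, seed=_stage_seed(config.seed, "simulate")))
    return read_post_log(config.input_path, config.input_format,
                         users_source=config.users_path)
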