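"""End-to-end study orchestration: simulate → metrics → maps → scores → fits.

A :class:`StudyConfig` describes a 2×2 cohort (sex × treatment, reference
cell F.PBO), the three task environments, and the analysis options; all
randomness is funneled through a single master seed via
``numpy.random.SeedSequence`` spawning, so a rerun with the same config is
bit-identical for every deterministic stage.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as tm
from . import scoring
from .config import ArenaConfig, NavigatorParams, TownConfig, YMazeConfig
from .density import build_density, difference_map, gi_star, hex_crossings, hex_tessellate
from .records import events_to_frame
from .simulate import simulate_arena_session, simulate_town, simulate_ymaze
from .stats import (compare_models, design_matrix, dispersion_check,
                    fit_beta_regression, fit_hurdle_negbin, squeeze_proportions)

__all__ = ["StudyConfig", "CellParams", "run_study", "simulate_cohort"]

CELLS = ("F.PBO", "F.E2V", "M.PBO", "M.E2V")


@dataclass(frozen=True)
class CellParams:
    """Per-cell navigator behavior and town-task error parameters."""

    nav: NavigatorParams = NavigatorParams()
    town_turn_error_prob: float = 0.12
    town_pointing_noise_sd: float = 25.0


def _default_cells() -> dict:
    # planted cohort differences in the directions reported for real
    # navigators: women more thigmotactic/peripheral (attractor ring in the
    # outer half of the arena requires bias > 0.5), with slower and less
    # precise drop-offs; estradiol slows F drop-offs and raises route errors
    return {
        "F.PBO": CellParams(NavigatorParams(strategy="mixed", thigmotaxis_bias=0.65,
                                            memory_noise_sd=900, speed=600),
                            town_turn_error_prob=0.12, town_pointing_noise_sd=30.0),
        "F.E2V": CellParams(NavigatorParams(strategy="mixed", thigmotaxis_bias=0.65,
                                            memory_noise_sd=900, speed=520),
                            town_turn_error_prob=0.18, town_pointing_noise_sd=30.0),
        "M.PBO": CellParams(NavigatorParams(strategy="mixed", thigmotaxis_bias=0.30,
                                            memory_noise_sd=650, speed=650),
                            town_turn_error_prob=0.12, town_pointing_noise_sd=20.0),
        "M.E2V": CellParams(NavigatorParams(strategy="mixed", thigmotaxis_bias=0.30,
                                            memory_noise_sd=650, speed=650),
                            town_turn_error_prob=0.12, town_pointing_noise_sd=20.0),
    }


@dataclass(frozen=True)
class StudyConfig:
    """Full specification of one synthetic 2×2 navigation study."""

    n_per_cell: int = 12
    cells: dict = field(default_factory=_default_cells)
    arena: ArenaConfig = ArenaConfig()
    ymaze: YMazeConfig = YMazeConfig()
    town: TownConfig = TownConfig()
    periphery_boundary: str = "half"    # 'half' | 'equal_area'
    hex_cell_size: float = 700.0
    k_neighbors: int = 6
    gi_p_threshold: float = 0.10
    density_bins: int = 101
    density_smoothing_sd: float = 5.0
    master_seed: int = 0

    def __post_init__(self):
        if set(self.cells) != set(CELLS):
            raise ValueError(f"cells must be exactly {CELLS}")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")

    def participant_seeds(self) -> dict:
        """Deterministic per-participant seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.master_seed)
        children = ss.spawn(len(CELLS) * self.n_per_cell)
        seeds, i = {}, 0
        for cell in CELLS:
            for j in range(self.n_per_cell):
                seeds[(cell, j)] = int(children[i].generate_state(1)[0] % (2 ** 31))
                i += 1
        return seeds


def _log(stage: str, t0: float) -> None:
    print(f"[navscape] {stage}: {time.time() - t0:.1f}s", file=sys.stderr)


def simulate_cohort(cfg: StudyConfig):
    """Simulate every participant of every cell across all three tasks.

    Returns (trajectories, drop events, ymaze records, town records), each a
    dict keyed by (cell, participant index).
    """
    seeds = cfg.participant_seeds()
    trajs, drops, ymazes, towns = {}, {}, {}, {}
    for (cell, j), seed in seeds.items():
        sex, treatment = cell.split(".")
        nav = dataclasses.replace(cfg.cells[cell].nav, seed=seed)
        traj, events = simulate_arena_session(cfg.arena, nav)
        traj.participant = f"{cell}.{j:03d}"
        traj.sex, traj.treatment = sex, treatment
        trajs[(cell, j)] = traj
        drops[(cell, j)] = events
        ymazes[(cell, j)] = simulate_ymaze(cfg.ymaze, nav)
        towns[(cell, j)] = simulate_town(
            cfg.town, cfg.cells[cell].town_turn_error_prob,
            cfg.cells[cell].town_pointing_noise_sd, seed=seed + 1)
    return trajs, drops, ymazes, towns


def metrics_tables(cfg: StudyConfig, trajs: dict, drops: dict
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant summary table and per-trial path-metric table."""
    part_rows, trial_frames = [], []
    for (cell, j), traj in trajs.items():
        sex, treatment = cell.split(".")
        events = drops[(cell, j)]
        nav_speed = cfg.cells[cell].nav.speed
        eps = 0.01 * nav_speed
        row = {
            "participant": traj.participant, "cell": cell,
            "sex": sex, "treatment": treatment,
            "n_dropoffs": len(events),
            "periphery_preference": tm.periphery_preference(
                traj, cfg.arena.radius, boundary=cfg.periphery_boundary),
            "idle_time": tm.idle_time(traj, eps),
        }
        try:
            row["periphery_preference_retrieval"] = tm.periphery_preference(
                traj, cfg.arena.radius, boundary=cfg.periphery_boundary,
                phase="retrieval")
        except ValueError:
            row["periphery_preference_retrieval"] = np.nan
        if len(events) >= 2:
            sa = tm.speed_accuracy(events)
            row["auc"] = sa.auc
            row["mean_lisas"] = float(sa.lisas.mean())
            row["mean_drop_error"] = float(np.mean([e.drop_error for e in events]))
            row["mean_navigation_duration"] = float(
                np.mean([e.navigation_duration for e in events]))
        part_rows.append(row)

        paths = tm.trial_paths(traj, events, idle_speed_eps=eps)
        if len(paths):
            paths.insert(0, "participant", traj.participant)
            paths.insert(1, "cell", cell)
            trial_frames.append(paths)
    trials = (pd.concat(trial_frames, ignore_index=True)
              if trial_frames else pd.DataFrame())
    return pd.DataFrame(part_rows), trials


def score_tables(ymazes: dict, towns: dict) -> pd.DataFrame:
    """Task scores (Y-maze label, town route and pointing) per participant."""
    rows = []
    for (cell, j), rec in ymazes.items():
        sex, treatment = cell.split(".")
        out = scoring.classify_ymaze(rec)
        route = scoring.score_town_route(towns[(cell, j)])
        pointing = scoring.score_pointing(towns[(cell, j)])
        rows.append({
            "participant": f"{cell}.{j:03d}", "cell": cell,
            "sex": sex, "treatment": treatment,
            "ymaze_label": out.label,
            "rounds_to_criterion": route.rounds_to_criterion,
            "route_errors": route.cumulative_errors,
            "mean_pointing_error": float(pointing["pointing_error"].mean()),
            "mean_pointing_rt": float(pointing["rt"].mean()),
        })
    return pd.DataFrame(rows)


def map_analysis(cfg: StudyConfig, trajs: dict) -> dict:
    """Sex-difference density map and Gi* on the hex-tiled crossing difference."""
    f_trajs = [t for (c, _), t in trajs.items() if c.startswith("F")]
    m_trajs = [t for (c, _), t in trajs.items() if c.startswith("M")]
    dm_f = build_density(f_trajs, radius=cfg.arena.radius, bins=cfg.density_bins,
                         smoothing_sd=cfg.density_smoothing_sd)
    dm_m = build_density(m_trajs, radius=cfg.arena.radius, bins=cfg.density_bins,
                         smoothing_sd=cfg.density_smoothing_sd)
    diff = difference_map(dm_f, dm_m)
    grid = hex_tessellate(cfg.arena.radius, cfg.hex_cell_size, cfg.k_neighbors)
    x_diff = (hex_crossings(grid, f_trajs) - hex_crossings(grid, m_trajs))
    gmap = gi_star(x_diff, grid, p_threshold=cfg.gi_p_threshold)
    return {"density_F": dm_f, "density_M": dm_m, "difference": diff,
            "grid": grid, "gi": gmap}


def fit_models(cfg: StudyConfig, participants: pd.DataFrame, scores: pd.DataFrame) -> dict:
    """The group-comparison models on the cohort tables."""
    X_full = design_matrix(participants["sex"], participants["treatment"])
    X_sex = X_full[["const", "sex_M"]]
    X_null = X_full[["const"]]
    y_periph = squeeze_proportions(participants["periphery_preference"].to_numpy())

    beta_full = fit_beta_regression(y_periph, X_full)
    beta_sex = fit_beta_regression(y_periph, X_sex)
    beta_null = fit_beta_regression(y_periph, X_null)

    Xs = design_matrix(scores["sex"], scores["treatment"])
    errs = scores["route_errors"].to_numpy()
    out = {
        "periphery_beta_full": beta_full,
        "periphery_beta_sex": beta_sex,
        "periphery_beta_null": beta_null,
        "comparison_full_vs_sex": compare_models(beta_full, beta_sex),
        "comparison_sex_vs_null": compare_models(beta_sex, beta_null),
    }
    ratio, chi2 = dispersion_check(errs, Xs)
    out["route_errors_dispersion"] = {"ratio": ratio, "pearson_chi2": chi2}
    # the zero-hurdle needs both outcomes in enough cells; on small cohorts
    # the full interaction design can separate, so back off to sex-only
    if (errs > 0).any() and (errs == 0).any():
        for design in (Xs, Xs[["const", "sex_M"]]):
            try:
                out["route_errors_hurdle"] = fit_hurdle_negbin(errs, design)
                break
            except (ValueError, RuntimeError, np.linalg.LinAlgError):
                continue
        else:
            out["route_errors_hurdle"] = {
                "error": "hurdle fit degenerate on this cohort "
                         "(separation or too few zero counts)"}
    return out


def run_study(cfg: StudyConfig, outdir) -> dict:
    """Run the full study pipeline, writing tables and a summary to outdir.

    Stages: simulate cohorts, movement/memory metric tables, density maps
    and the Gi* hex map, task scores, group models, and a summary document
    with the provenance of every statistic.  Any stage failure is re-raised
    with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    t0 = time.time()
    try:
        trajs, drops, ymazes, towns = simulate_cohort(cfg)
    except Exception as e:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e
    _log("simulate", t0)

    def stage(name, fn):
        t = time.time()
        try:
            out = fn()
        except Exception as e:
            raise RuntimeError(f"stage '{name}' failed: {e}") from e
        _log(name, t)
        return out

    participants, trials = stage("metrics", lambda: metrics_tables(cfg, trajs, drops))
    scores = stage("score", lambda: score_tables(ymazes, towns))
    maps = stage("maps", lambda: map_analysis(cfg, trajs))
    fits = stage("fit", lambda: fit_models(cfg, participants, scores))

    # ---------------- outputs
    events = pd.concat(
        [events_to_frame(ev, trajs[key].participant) for key, ev in drops.items()],
        ignore_index=True)
    participants.to_csv(outdir / "participants.csv", index=False)
    trials.to_csv(outdir / "path_metrics.csv", index=False)
    events.to_csv(outdir / "drop_events.csv", index=False)
    scores.to_csv(outdir / "task_scores.csv", index=False)

    gi = maps["gi"]
    pd.DataFrame({
        "tile_x": gi.grid.centroids[:, 0], "tile_y": gi.grid.centroids[:, 1],
        "crossing_diff": gi.x, "gi_z": gi.z, "gi_p": gi.p, "flagged": gi.mask,
    }).to_csv(outdir / "gi_star_map.csv", index=False)

    fits_json = {}
    for name, obj in fits.items():
        if hasattr(obj, "to_dict"):
            fits_json[name] = obj.to_dict()
        elif dataclasses.is_dataclass(obj):
            fits_json[name] = dataclasses.asdict(obj)
        else:
            fits_json[name] = obj
    with open(outdir / "model_fits.json", "w") as fh:
        json.dump(fits_json, fh, indent=2, default=float)

    with open(outdir / "study_config.yaml", "w") as fh:
        yaml.safe_dump({"master_seed": cfg.master_seed,
                        "n_per_cell": cfg.n_per_cell,
                        "periphery_boundary": cfg.periphery_boundary,
                        "hex_cell_size": cfg.hex_cell_size,
                        "k_neighbors": cfg.k_neighbors}, fh)

    _write_summary(outdir, cfg, participants, scores, fits, gi)
    results.update(participants=participants, trials=trials, events=events,
                   scores=scores, maps=maps, fits=fits)
    return results


_PROVENANCE = [
    ("periphery_preference", "metrics.periphery_preference"),
    ("idle_time", "metrics.idle_time"),
    ("path metrics (distance, sinuosity, deviation, flips)", "metrics.path_metrics"),
    ("auc / lisas", "metrics.auc_speed_accuracy, metrics.lisas"),
    ("drop_error", "records.DropEvent.drop_error (metrics.drop_error)"),
    ("ymaze_label", "scoring.classify_ymaze"),
    ("rounds_to_criterion / route_errors", "scoring.score_town_route"),
    ("mean_pointing_error", "scoring.pointing_error"),
    ("density / difference maps", "density.build_density, density.difference_map"),
    ("gi_z / gi_p", "density.gi_star on density.hex_tessellate grid"),
    ("beta-regression fits", "stats.fit_beta_regression"),
    ("hurdle-NB fit", "stats.fit_hurdle_negbin"),
    ("dispersion check", "stats.dispersion_check"),
    ("model comparisons", "stats.compare_models"),
]


def _write_summary(outdir: Path, cfg: StudyConfig, participants, scores, fits, gi
                   ) -> None:
    lines = ["# Study summary", "",
             f"master seed: {cfg.master_seed}; n per cell: {cfg.n_per_cell}", ""]
    lines.append("## Group means")
    lines.append(participants.groupby("cell")[
        [c for c in ("periphery_preference", "mean_drop_error", "mean_lisas",
                     "auc", "idle_time", "n_dropoffs") if c in participants]
    ].mean().round(3).to_string())
    lines.append("")
    lines.append("## Task scores")
    lines.append(scores.groupby("cell")[["rounds_to_criterion", "route_errors",
                                         "mean_pointing_error"]]
                 .mean().round(2).to_string())
    lines.append("")
    beta = fits["periphery_beta_full"]
    lines.append("## Periphery-preference beta regression (probit)")
    lines.append(beta.coefficients.round(4).to_string())
    lines.append(f"precision phi = {beta.precision:.2f}, "
                 f"pseudo-R2 = {beta.pseudo_r2:.3f}")
    lines.append("")
    lines.append(f"## Gi* map: {int(gi.mask.sum())}/{gi.grid.n} tiles flagged "
                 f"at p < {gi.p_threshold}")
    lines.append("")
    lines.append("## Statistic provenance")
    for stat, op in _PROVENANCE:
        lines.append(f"- {stat}: `{op}`")
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
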