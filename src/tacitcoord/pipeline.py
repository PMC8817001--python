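"""End-to-end analysis pipeline with machine-readable reports.

Stages: simulate (or load) a cohort -> rule-profile the boards -> score
players (CI per game, iCA, strategy rates) -> characterize the ability
distribution (dip test, mixture fit, k selection) -> fit the PCA +
regression ability model -> validate on an independently simulated cohort.
Identical config and seed give byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .boards import ResponseMatrix, read_board, read_responses
from .distribution import dip_test, select_k
from .model import fit_ability_model, fit_pca, predict_ica, retained_variance, validate
from .simulate import default_population, simulate_population
from .stats import ica_scores, per_game_summary, strategic_profiles

log = logging.getLogger("tacitcoord")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    out_dir: str | Path = "tacitcoord_run"
    seed: int = 0
    validation_seed: Optional[int] = None  # default: seed + 1
    n_agents: int = 93
    n_validation_agents: int = 33
    board_paths: list[str] = field(default_factory=list)
    responses_path: Optional[str] = None
    n_predefined: Optional[int] = None
    bins: int = 20
    elbow_threshold: float = 0.10
    k_range: tuple[int, int] = (1, 10)
    dip_boot: int = 2000

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.validation_seed is None:
            self.validation_seed = self.seed + 1


class StageError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _load_matrix(config: RunConfig) -> ResponseMatrix:
    boards = []
    for p in config.board_paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"board file not found: {p}")
        boards.append(read_board(p))
    if config.responses_path is None:
        raise ValueError("files mode requires responses_path")
    if not Path(config.responses_path).exists():
        raise FileNotFoundError(f"responses file not found: {config.responses_path}")
    return read_responses(
        config.responses_path, boards, n_predefined=config.n_predefined
    )


def score_cohort(matrix: ResponseMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-player scores (iCA + strategy rates) and the per-game summary."""
    scores = strategic_profiles(matrix)
    scores.insert(0, "ica", ica_scores(matrix))
    return scores, per_game_summary(matrix)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; write reports under ``config.out_dir``; return a bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    stage = "input"
    try:
        if config.mode == "synthetic":
            spec = default_population(n_agents=config.n_agents, seed=config.seed)
            matrix = simulate_population(spec)
        else:
            matrix = _load_matrix(config)
        log.info(
            "cohort: %d players x %d boards (%d predefined)",
            matrix.n_players, len(matrix.boards), matrix.n_predefined,
        )

        stage = "scoring"
        scores, per_game = score_cohort(matrix)
        scores.to_csv(out / "scores.csv")
        per_game.to_csv(out / "per_game.csv")
        bundle["scores"] = scores
        bundle["per_game"] = per_game

        stage = "distribution"
        ica = scores["ica"].to_numpy()
        dip = dip_test(ica, n_boot=config.dip_boot, seed=config.seed)
        sel = select_k(
            ica,
            k_range=config.k_range,
            bins=config.bins,
            seed=config.seed,
            elbow_threshold=config.elbow_threshold,
        )
        best = sel.fits[sel.k]
        dist_report = {
            "dip": dip.dip,
            "dip_p_value": dip.p_value,
            "n_boot": dip.n_boot,
            "k_rss": sel.k_rss,
            "k_silhouette": sel.k_silhouette,
            "rss_by_k": {str(k): v for k, v in sel.rss_by_k.items()},
            "silhouette_by_k": {str(k): v for k, v in sel.silhouette_by_k.items()},
            "components": [list(c) for c in best.components],
            "rss": best.rss,
            "bins": config.bins,
        }
        (out / "distribution.json").write_text(json.dumps(dist_report, indent=1))
        bundle["distribution"] = dist_report

        stage = "model"
        complete = scores.dropna()
        profiles = complete[["sr_closeness", "sr_equality", "sr_accession"]]
        pca = fit_pca(profiles)
        compressed = pca.project(profiles)[:, :2]
        ability = fit_ability_model(compressed, complete["ica"].to_numpy())
        model_report = {
            "center": pca.center.tolist(),
            "scale": pca.scale.tolist(),
            "components": pca.components.tolist(),
            "eigenvalues": pca.eigenvalues.tolist(),
            "retained_variance_pct": [
                retained_variance(profiles, pca, m) for m in (1, 2, 3)
            ],
            "intercept": ability.intercept,
            "coef_s1": ability.coef_s1,
            "coef_s2": ability.coef_s2,
            "r_squared": ability.r_squared,
            "f_stat": ability.f_stat,
            "f_pvalue": ability.f_pvalue,
            "var_error": ability.var_error,
            "n_players": int(len(complete)),
        }
        (out / "model.json").write_text(json.dumps(model_report, indent=1))
        bundle["pca"] = pca
        bundle["ability_model"] = ability
        bundle["model"] = model_report

        stage = "validation"
        if config.mode == "synthetic":
            vspec = default_population(
                n_agents=config.n_validation_agents, seed=config.validation_seed
            )
            vmatrix = simulate_population(vspec)
            vscores, _ = score_cohort(vmatrix)
            vcomplete = vscores.dropna()
            vprofiles = vcomplete[["sr_closeness", "sr_equality", "sr_accession"]]
            predictions = predict_ica(vprofiles, pca, ability)
            report = validate(predictions, vcomplete["ica"].to_numpy())
            val_report = report.as_dict()
            val_report["seed"] = config.validation_seed
            (out / "validation.json").write_text(json.dumps(val_report, indent=1))
            bundle["validation"] = val_report

        stage = "log"
        run_log = {
            "tacitcoord": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": config.seed,
            "validation_seed": config.validation_seed,
            "mode": config.mode,
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
        bundle["run_log"] = run_log
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    return bundle
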