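"""Multi-repetition experiment orchestration.

One *repetition* draws a fresh pseudo signal panel from the real parameter
panel, generates a phs or poc dataset to 30-per-year replication, builds
fresh initial prefs and runs the constructor to its fixpoint.  Experiments
repeat this under deterministically derived per-repetition seeds (spawned
from one root seed, so results are identical regardless of execution order)
and aggregate the repetition summaries.  Completed repetitions are
persisted as JSON and skipped on re-run, making interrupted experiments
resumable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constructor import ConstructorConfig, make_initial_prefs, run_constructor
from .detrend import ParamPanel
from .evaluate import (ContrastMap, MultiRepSummary, RepetitionSummary,
                       summarize_repetition, summarize_repetitions)
from .io import SeriesLengthPool
from .simulate import build_phs_dataset, build_poc_dataset, simulate_signal_panel
from .util import spawn_seedseqs

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class ExperimentConfig:
    """Full specification of one simulation setting."""

    approach: str = "poc"          # "phs" or "poc"
    t_threshold: float = 15.0
    osr: float = 1.0
    n_repetitions: int = 50
    n_years: int = 1000
    target_replication: int = 30
    initial_n_series: int = 30
    initial_length: int = 150
    min_overlap: int = 50
    seed: int = 0
    panel_path: str | None = None
    pool_path: str | None = None
    meta_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.approach not in ("phs", "poc"):
            raise ValueError("approach must be 'phs' or 'poc'")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")

    @property
    def name(self) -> str:
        if self.approach == "phs":
            return f"phs_t{self.t_threshold:g}"
        return f"poc_t{self.t_threshold:g}_{self.osr:g}"

    def constructor_config(self) -> ConstructorConfig:
        return ConstructorConfig(
            t_threshold=self.t_threshold, min_overlap=self.min_overlap,
            initial_n_series=self.initial_n_series,
            initial_length=self.initial_length)

    def content_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_single_repetition(param_panel: ParamPanel, pool: SeriesLengthPool,
                          config: ExperimentConfig, seed,
                          contrast_map: ContrastMap | None = None
                          ) -> RepetitionSummary:
    """One repetition: fresh panel -> dataset -> initial prefs -> constructor."""
    seqs = spawn_seedseqs(seed, 3) if not isinstance(seed, list) else seed
    panel = simulate_signal_panel(param_panel, config.n_years, seqs[0])
    if config.approach == "phs":
        dataset = build_phs_dataset(panel, pool, config.target_replication, seqs[1])
    else:
        dataset = build_poc_dataset(panel, pool, config.osr,
                                    target_replication=config.target_replication,
                                    seed=seqs[1])
    cc = config.constructor_config()
    prefs = make_initial_prefs(panel, cc, seqs[2])
    prefs, logs = run_constructor(dataset, prefs, cc, keep_assignments=False)
    return summarize_repetition(dataset, prefs, logs, contrast_map)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _summary_to_dict(s: RepetitionSummary) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "pct_generated_classified": s.pct_generated_classified,
        "pct_classified_correct": s.pct_classified_correct,
        "n_runs_executed": s.n_runs_executed,
        "n_series_generated": s.n_series_generated,
        "pref_ids": s.pref_ids,
        "final_lengths": s.final_lengths,
        "final_mean_replication": s.final_mean_replication,
        "final_n_members": s.final_n_members,
        "full_length": s.full_length,
        "final_contamination": s.final_contamination,
        "run_contamination": {k: v.tolist() for k, v in s.run_contamination.items()},
        "run_lengths": s.run_lengths.tolist(),
        "run_mean_replication": s.run_mean_replication.tolist(),
    }


def _summary_from_dict(d: dict) -> RepetitionSummary:
    if d.get("schema_version", 0) != SCHEMA_VERSION:
        logger.warning("repetition file has schema %s, current is %s",
                       d.get("schema_version"), SCHEMA_VERSION)
    n_prefs = len(d["pref_ids"])
    return RepetitionSummary(
        pct_generated_classified=d["pct_generated_classified"],
        pct_classified_correct=d["pct_classified_correct"],
        n_runs_executed=d["n_runs_executed"],
        n_series_generated=d["n_series_generated"],
        pref_ids=d["pref_ids"],
        final_lengths=d["final_lengths"],
        final_mean_replication=d["final_mean_replication"],
        final_n_members=d["final_n_members"],
        full_length=d["full_length"],
        final_contamination=d["final_contamination"],
        run_contamination={k: np.array(v).reshape(-1, n_prefs)
                           for k, v in d["run_contamination"].items()},
        run_lengths=np.array(d["run_lengths"], dtype=int).reshape(-1, n_prefs),
        run_mean_replication=np.array(d["run_mean_replication"]).reshape(-1, n_prefs),
    )


def run_experiment(config: ExperimentConfig,
                   param_panel: ParamPanel | None = None,
                   pool: SeriesLengthPool | None = None,
                   contrast_map: ContrastMap | None = None) -> MultiRepSummary:
    """Run (or resume) all repetitions of one setting and aggregate them."""
    if param_panel is None:
        if config.panel_path is None:
            raise ValueError("need param_panel or config.panel_path")
        param_panel = ParamPanel.from_csv(config.panel_path)
    if pool is None:
        if config.pool_path is None:
            raise ValueError("need pool or config.pool_path")
        from .io import read_length_pool
        pool = read_length_pool(config.pool_path)
    if contrast_map is None and config.meta_path is not None:
        from .io import read_site_metadata
        contrast_map = ContrastMap.from_meta(read_site_metadata(config.meta_path))

    out_dir = None
    if config.out_dir is not None:
        out_dir = Path(config.out_dir) / config.content_hash()
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {"schema_version": SCHEMA_VERSION, "config": asdict(config),
                    "panel_fingerprint": param_panel.fingerprint()}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    seed_seqs = spawn_seedseqs(config.seed, config.n_repetitions)
    summaries: list[RepetitionSummary] = []
    for i, seq in enumerate(seed_seqs):
        rep_file = out_dir / f"rep{i:04d}.json" if out_dir else None
        if rep_file is not None and rep_file.exists():
            summaries.append(_summary_from_dict(json.loads(rep_file.read_text())))
            continue
        s = run_single_repetition(param_panel, pool, config, seq, contrast_map)
        summaries.append(s)
        if rep_file is not None:
            rep_file.write_text(json.dumps(_summary_to_dict(s)))
        logger.info("%s: repetition %d/%d done (%d runs, %.1f%% classified)",
                    config.name, i + 1, config.n_repetitions,
                    s.n_runs_executed, s.pct_generated_classified)
    return summarize_repetitions(summaries)


def compare_settings(configs: list[ExperimentConfig],
                     param_panel: ParamPanel,
                     pool: SeriesLengthPool,
                     contrast_map: ContrastMap | None = None) -> pd.DataFrame:
    """One summary row per setting (min/median/max of the headline fields).

    All settings must run against the same input panel.
    """
    keys = {(c.panel_path, c.pool_path) for c in configs}
    if len(keys) > 1:
        raise ValueError("settings reference different input panels")
    rows = []
    for c in configs:
        summary = run_experiment(c, param_panel, pool, contrast_map)
        row = {"approach": c.name}
        for fieldname in ("pct_generated_classified", "pct_classified_correct",
                          "n_runs_executed", "n_series_generated"):
            for stat in ("min", "median", "max"):
                row[f"{fieldname}_{stat}"] = summary.table1.loc[stat, fieldname]
        rows.append(row)
    return pd.DataFrame(rows)
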