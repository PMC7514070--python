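"""Stability metrics, contamination under contrasts, multi-repetition tables.

Two families of diagnostics:

* **Signal stability** — the between-site correlation matrix of the
  generated pseudo means (pmv) must reproduce that of the real means (rmv)
  in every repetition (delta at machine precision), and the sample pseudo
  mean chronologies (spmv: per-site yearwise means of the phs under a
  perfect classification) must reproduce it up to sampling error.

* **Pref composition** — the share of generated series classified, the
  share of those classified correctly, and the contamination of each pref:
  the percentage of its members originating from a site (or contrast group
  — elevation band, coarse elevation, watershed) other than the group of
  the pref's initializing signal.

Multi-repetition summaries follow the convention that per-run statistics
(95th-percentile contamination, median length, median mean replication)
are computed only over runs executed in *every* repetition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .constructor import Pref, RunLog
from .simulate import PseudoDataset, PseudoSignalPanel

CONTRASTS = ("site", "elevation", "elevation_coarse", "watershed")

LENGTH_BINS = ("0", "1-333", "334-667", "668-999", "1000")
ATTRACTOR_BINS = ("0-100", "101-500", "501-1000", ">1000")


@dataclass
class ContrastMap:
    """Site -> contrast-group assignments (elevation band, watershed)."""

    elevation: dict[str, str]
    watershed: dict[str, str]

    def __post_init__(self) -> None:
        valid = {"low", "medium", "high"}
        bad = {b for b in self.elevation.values()} - valid
        if bad:
            raise ValueError(f"unknown elevation bands: {sorted(bad)}")

    @classmethod
    def from_meta(cls, meta: dict[str, dict]) -> "ContrastMap":
        return cls({s: m["elevation_band"] for s, m in meta.items()},
                   {s: m["watershed"] for s, m in meta.items()})

    def group(self, site: str, contrast: str) -> str:
        if contrast == "site":
            return site
        if contrast == "elevation":
            return self._lookup(self.elevation, site)
        if contrast == "elevation_coarse":
            band = self._lookup(self.elevation, site)
            return "high" if band == "high" else "medium_low"
        if contrast == "watershed":
            return self._lookup(self.watershed, site)
        raise ValueError(f"unknown contrast {contrast!r}; use one of {CONTRASTS}")

    @staticmethod
    def _lookup(mapping: dict[str, str], site: str) -> str:
        try:
            return mapping[site]
        except KeyError:
            raise ValueError(f"site {site!r} is not mapped in the contrast") from None


class ContaminationResult(NamedTuple):
    percent: float
    n_members: int
    empty: bool


def contamination(pref: Pref, contrast: str = "site",
                  contrast_map: ContrastMap | None = None) -> ContaminationResult:
    """Percentage of a pref's members from outside its own contrast group.

    An empty pref is reported as 0% with the ``empty`` flag set, keeping
    per-run tables rectangular.
    """
    if contrast != "site" and contrast_map is None:
        raise ValueError("contrast_map required for non-site contrasts")
    if not pref.members:
        return ContaminationResult(0.0, 0, True)
    if contrast == "site":
        own = pref.init_site
        off = sum(s != own for s in pref.member_sites)
    else:
        own = contrast_map.group(pref.init_site, contrast)
        off = sum(contrast_map.group(s, contrast) != own
                  for s in pref.member_sites)
    return ContaminationResult(100.0 * off / len(pref.members),
                               len(pref.members), False)


# ---------------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------------

def _corr_columns(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    if np.any(m.std(axis=0) == 0):
        raise ValueError("zero-variance column")
    return np.corrcoef(m, rowvar=False)


def delta_corr(matrix_a: np.ndarray, matrix_b: np.ndarray) -> tuple[float, float]:
    """(min, max) of the elementwise difference corr(A) - corr(B)."""
    ca = _corr_columns(matrix_a)
    cb = _corr_columns(matrix_b)
    if ca.shape != cb.shape:
        raise ValueError("matrices must have equal column counts")
    d = ca - cb
    return float(d.min()), float(d.max())


def spmv_from_perfect_classification(dataset: PseudoDataset,
                                     panel: PseudoSignalPanel) -> np.ndarray:
    """Per-site yearwise means of the phs under a perfect classification."""
    n, s = panel.n_years, panel.n_sites
    total = np.zeros((n, s))
    count = np.zeros((n, s), dtype=int)
    idx = {site: j for j, site in enumerate(panel.site_ids)}
    for r in dataset.records:
        j = idx[r.source_site]
        i0 = r.start_year - 1
        total[i0:i0 + len(r), j] += r.values
        count[i0:i0 + len(r), j] += 1
    if np.any(count == 0):
        bad = np.argwhere(count == 0)[0]
        raise ValueError(
            f"no coverage at year {bad[0] + 1}, site {panel.site_ids[bad[1]]!r}")
    return total / count


@dataclass
class StabilityReport:
    """Per-repetition and overall ranges of the correlation-matrix deltas."""

    delta_pmv_rmv: list[tuple[float, float]]
    delta_spmv_rmv: list[tuple[float, float]]

    @property
    def pmv_range(self) -> tuple[float, float]:
        return (min(d[0] for d in self.delta_pmv_rmv),
                max(d[1] for d in self.delta_pmv_rmv))

    @property
    def spmv_range(self) -> tuple[float, float]:
        return (min(d[0] for d in self.delta_spmv_rmv),
                max(d[1] for d in self.delta_spmv_rmv))


def assess_stability(param_panel, pool=None, n_reps: int = 10,
                     n_years: int = 1000, replication: int = 30,
                     seed=None) -> StabilityReport:
    """Signal-stability diagnostics across fresh simulation repetitions.

    Per repetition, a new pseudo signal panel is generated and the range of
    corr(pmv) - corr(rmv) recorded.  If a length ``pool`` is given, a phs
    dataset is additionally sampled to 30-per-year replication and the
    corr(spmv) - corr(rmv) range of the perfectly classified mean
    chronologies recorded (the sampling-noise floor of the simulation).
    """
    from .simulate import build_phs_dataset, simulate_signal_panel
    from .util import spawn_seedseqs

    d_pmv: list[tuple[float, float]] = []
    d_spmv: list[tuple[float, float]] = []
    for seq in spawn_seedseqs(seed, n_reps):
        a, b = seq.spawn(2)
        panel = simulate_signal_panel(param_panel, n_years, a)
        d_pmv.append(delta_corr(panel.pmv, param_panel.rmv))
        if pool is not None:
            dset = build_phs_dataset(panel, pool, replication, b)
            spmv = spmv_from_perfect_classification(dset, panel)
            d_spmv.append(delta_corr(spmv, param_panel.rmv))
    return StabilityReport(d_pmv, d_spmv)


# ---------------------------------------------------------------------------
# Repetition summaries
# ---------------------------------------------------------------------------

@dataclass
class RepetitionSummary:
    """Headline statistics of one simulation repetition."""

    pct_generated_classified: float
    pct_classified_correct: float
    n_runs_executed: int
    n_series_generated: int
    pref_ids: list[int]
    final_lengths: list[int]
    final_mean_replication: list[float]
    final_n_members: list[int]
    full_length: int  # timeline length, for the "1000" length category
    # contamination[contrast] = per-pref final %
    final_contamination: dict[str, list[float]] = field(default_factory=dict)
    # trajectories[contrast] = (n_runs x S) cumulative per-run contamination %
    run_contamination: dict[str, np.ndarray] = field(default_factory=dict)
    run_lengths: np.ndarray | None = None          # n_runs x S
    run_mean_replication: np.ndarray | None = None  # n_runs x S


def _run_trajectories(prefs: list[Pref], logs: list[RunLog],
                      contrast: str, contrast_map: ContrastMap | None
                      ) -> np.ndarray:
    """Cumulative per-run off-group contamination % (n_runs x n_prefs)."""
    n_runs = len(logs)
    out = np.zeros((n_runs, len(prefs)))
    for j, pref in enumerate(prefs):
        if contrast == "site":
            own = pref.init_site
            is_off = [s != own for s in pref.member_sites]
        else:
            own = contrast_map.group(pref.init_site, contrast)
            is_off = [contrast_map.group(s, contrast) != own
                      for s in pref.member_sites]
        runs = np.array([ri for _, ri in pref.members], dtype=int)
        offs = np.array(is_off, dtype=float)
        for k in range(1, n_runs + 1):
            sel = runs <= k
            n = int(sel.sum())
            out[k - 1, j] = 100.0 * offs[sel].sum() / n if n else 0.0
    return out


def summarize_repetition(dataset: PseudoDataset, prefs: list[Pref],
                         logs: list[RunLog],
                         contrast_map: ContrastMap | None = None
                         ) -> RepetitionSummary:
    """Collapse one constructor run into Table-1-style statistics."""
    n_generated = len(dataset.records)
    n_classified = sum(len(p.members) for p in prefs)
    n_correct = sum(sum(s == p.init_site for s in p.member_sites) for p in prefs)
    pct_classified = 100.0 * n_classified / n_generated if n_generated else 0.0
    pct_correct = 100.0 * n_correct / n_classified if n_classified else 0.0

    contrasts = ["site"]
    if contrast_map is not None:
        contrasts += ["elevation", "elevation_coarse", "watershed"]
    final_cont = {c: [contamination(p, c, contrast_map).percent for p in prefs]
                  for c in contrasts}
    run_cont = {c: _run_trajectories(prefs, logs, c, contrast_map)
                for c in contrasts}
    return RepetitionSummary(
        pct_generated_classified=pct_classified,
        pct_classified_correct=pct_correct,
        n_runs_executed=len(logs),
        n_series_generated=n_generated,
        pref_ids=[p.pref_id for p in prefs],
        final_lengths=[p.length for p in prefs],
        final_mean_replication=[p.mean_replication for p in prefs],
        final_n_members=[len(p.members) for p in prefs],
        full_length=dataset.n_years,
        final_contamination=final_cont,
        run_contamination=run_cont,
        run_lengths=np.array([log.lengths for log in logs], dtype=int).reshape(
            len(logs), len(prefs)),
        run_mean_replication=np.array(
            [log.mean_replication for log in logs]).reshape(len(logs), len(prefs)),
    )


def _length_category(length: int, n_members: int, full: int) -> str:
    if n_members == 0:
        return "0"
    if length >= full:
        return "1000"
    if length <= 333:
        return "1-333"
    if length <= 667:
        return "334-667"
    return "668-999"


def _attractor_category(n_members: int) -> str:
    if n_members <= 100:
        return "0-100"
    if n_members <= 500:
        return "101-500"
    if n_members <= 1000:
        return "501-1000"
    return ">1000"


@dataclass
class MultiRepSummary:
    """Aggregate of many repetitions of one simulation setting."""

    table1: pd.DataFrame                 # min/median/max of the 4 headline fields
    n_full_runs: int                     # runs executed in every repetition
    per_run_contamination_q95: pd.DataFrame  # runs x prefs (site contrast)
    per_run_median_length: pd.DataFrame
    per_run_median_replication: pd.DataFrame
    length_categories: pd.Series         # mean pref count per category
    attractor_categories: pd.Series
    final_contamination: dict[str, np.ndarray]  # contrast -> reps x prefs
    pref_ids: list[int]
    n_repetitions: int

    def contaminated_fraction(self, threshold_pct: float = 20.0,
                              contrast: str = "site") -> np.ndarray:
        return flag_contaminated(self.final_contamination[contrast], threshold_pct)


def flag_contaminated(final_contamination: np.ndarray,
                      threshold_pct: float = 20.0) -> np.ndarray:
    """Per-pref share of repetitions with contamination above the threshold."""
    arr = np.asarray(final_contamination, dtype=float)
    return (arr > threshold_pct).mean(axis=0)


def summarize_repetitions(reps: list[RepetitionSummary],
                          quantile: float = 0.95) -> MultiRepSummary:
    """Aggregate repetition summaries into the standard report.

    Per-run statistics cover only the fully replicated runs (those executed
    in every repetition); the 95th percentile uses linear interpolation
    between order statistics.
    """
    if not reps:
        raise ValueError("need at least one repetition")
    pref_ids = reps[0].pref_ids
    s = len(pref_ids)

    fields = {
        "pct_generated_classified": [r.pct_generated_classified for r in reps],
        "pct_classified_correct": [r.pct_classified_correct for r in reps],
        "n_runs_executed": [r.n_runs_executed for r in reps],
        "n_series_generated": [r.n_series_generated for r in reps],
    }
    table1 = pd.DataFrame(
        {k: [np.min(v), np.median(v), np.max(v)] for k, v in fields.items()},
        index=["min", "median", "max"])

    n_full = min(r.n_runs_executed for r in reps)
    cols = [f"pref{p}" for p in pref_ids]
    idx = [f"run{k}" for k in range(1, n_full + 1)]
    if n_full > 0:
        cont = np.stack([r.run_contamination["site"][:n_full] for r in reps])
        lens = np.stack([r.run_lengths[:n_full] for r in reps])
        repl = np.stack([r.run_mean_replication[:n_full] for r in reps])
        q95 = np.quantile(cont, quantile, axis=0)
        med_len = np.median(lens, axis=0)
        med_repl = np.median(repl, axis=0)
    else:
        q95 = med_len = med_repl = np.empty((0, s))
    per_run = {
        "q95": pd.DataFrame(q95, index=idx, columns=cols),
        "len": pd.DataFrame(med_len, index=idx, columns=cols),
        "repl": pd.DataFrame(med_repl, index=idx, columns=cols),
    }

    len_counts = np.zeros((len(reps), len(LENGTH_BINS)))
    att_counts = np.zeros((len(reps), len(ATTRACTOR_BINS)))
    for i, r in enumerate(reps):
        for length, n_mem in zip(r.final_lengths, r.final_n_members):
            len_counts[i, LENGTH_BINS.index(
                _length_category(length, n_mem, r.full_length))] += 1
            att_counts[i, ATTRACTOR_BINS.index(_attractor_category(n_mem))] += 1

    final_cont = {
        c: np.array([r.final_contamination[c] for r in reps])
        for c in reps[0].final_contamination
    }
    return MultiRepSummary(
        table1=table1,
        n_full_runs=n_full,
        per_run_contamination_q95=per_run["q95"],
        per_run_median_length=per_run["len"],
        per_run_median_replication=per_run["repl"],
        length_categories=pd.Series(len_counts.mean(axis=0), index=LENGTH_BINS),
        attractor_categories=pd.Series(att_counts.mean(axis=0),
                                       index=ATTRACTOR_BINS),
        final_contamination=final_cont,
        pref_ids=pref_ids,
        n_repetitions=len(reps),
    )
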