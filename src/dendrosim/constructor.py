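"""The PREF-Constructor: iterative best-match reference-chronology building.

Mimics how a dendrochronologist extends living-tree site chronologies with
historical series: 15 initial pseudo reference chronologies (prefs), each a
150-year mean of 30 freshly drawn pseudo series, are grown by repeatedly
classifying candidate series (phs or poc) to their best-matching pref.  A
candidate matches a pref when their overlap is at least ``min_overlap``
years and the t-value of the Pearson correlation at the candidate's fixed
calendar position (cross-dating is assumed correct, so no offset search)
meets the threshold; among qualifying prefs the highest t wins.  Runs are
batch-synchronous: within a run every unclassified candidate is scored
against the prefs as of the run's start, and all accepted candidates are
added simultaneously at the run's end.  The algorithm stops when a run
classifies nothing or no candidates remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import PseudoDataset, PseudoSeriesRecord, PseudoSignalPanel
from .util import spawn_rngs


@dataclass
class ConstructorConfig:
    """Matching thresholds and initial-chronology geometry."""

    t_threshold: float = 15.0
    min_overlap: int = 50
    initial_n_series: int = 30
    initial_length: int = 150
    t_cap: float = 1e6

    def __post_init__(self) -> None:
        if self.min_overlap < 3:
            raise ValueError("min_overlap must be >= 3 (t-value undefined)")
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be > 0")


class Pref:
    """A growing pseudo reference chronology.

    The initial chronology counts as ONE contributor (weight 1) in the
    per-year mean and replication; each classified member adds one more on
    the years it covers.  Years are 1-based on the pseudo timeline.
    """

    def __init__(self, pref_id: int, init_site: str, init_start_year: int,
                 init_values: np.ndarray, n_years: int):
        self.pref_id = pref_id
        self.init_site = init_site
        self.n_years = n_years
        init_values = np.asarray(init_values, dtype=float)
        self._init = np.zeros(n_years)
        self._init_mask = np.zeros(n_years, dtype=bool)
        i0 = init_start_year - 1
        self._init[i0:i0 + len(init_values)] = init_values
        self._init_mask[i0:i0 + len(init_values)] = True
        self._member_sum = np.zeros(n_years)
        self._member_count = np.zeros(n_years, dtype=int)
        self.members: list[tuple[str, int]] = []  # (record_id, run_index)
        self.member_sites: list[str] = []

    # -- aggregate state ---------------------------------------------------

    def replication(self) -> np.ndarray:
        return self._init_mask.astype(int) + self._member_count

    def values(self) -> np.ndarray:
        """Per-year mean of available contributors; NaN where uncovered."""
        repl = self.replication()
        with np.errstate(invalid="ignore"):
            v = (np.where(self._init_mask, self._init, 0.0) + self._member_sum) \
                / np.where(repl > 0, repl, np.nan)
        return v

    @property
    def length(self) -> int:
        """Number of covered years."""
        return int(np.count_nonzero(self.replication() > 0))

    @property
    def mean_replication(self) -> float:
        repl = self.replication()
        covered = repl[repl > 0]
        return float(covered.mean()) if covered.size else 0.0

    def contamination(self) -> float:
        """% of classified members whose source is not the init site."""
        if not self.members:
            return 0.0
        off = sum(s != self.init_site for s in self.member_sites)
        return 100.0 * off / len(self.members)

    # -- growth ------------------------------------------------------------

    def add_member(self, record: PseudoSeriesRecord, run_index: int) -> None:
        if any(rid == record.record_id for rid, _ in self.members):
            raise ValueError(f"duplicate member {record.record_id!r}")
        i0 = record.start_year - 1
        self._member_sum[i0:i0 + len(record)] += record.values
        self._member_count[i0:i0 + len(record)] += 1
        self.members.append((record.record_id, run_index))
        self.member_sites.append(record.source_site)


def update_pref(pref: Pref, new_members: list[tuple[PseudoSeriesRecord, int]]) -> Pref:
    """Add (record, run_index) pairs to a pref; empty list is a no-op."""
    for record, run_index in new_members:
        pref.add_member(record, run_index)
    return pref


@dataclass
class RunLog:
    """Per-run snapshot of the constructor state, taken after the run."""

    run_index: int
    n_classified: int
    n_remaining: int
    contamination: list[float]      # per pref, % off-site members
    lengths: list[int]              # per pref, covered years
    mean_replication: list[float]   # per pref
    assignments: list[dict] = field(default_factory=list)
    # assignment dicts: record_id, pref_id, t, r, overlap


def make_initial_prefs(panel: PseudoSignalPanel, config: ConstructorConfig,
                       seed=None) -> list[Pref]:
    """One initial pref per site: the 150-year mean of 30 fresh ps.

    The initial window occupies the most recent ``initial_length`` years of
    the pseudo timeline, mimicking living-tree chronologies that are
    extended backward in time.
    """
    if config.initial_length > panel.n_years:
        raise ValueError("initial_length exceeds the pseudo timeline")
    start = panel.n_years - config.initial_length + 1
    sl = slice(start - 1, panel.n_years)
    rngs = spawn_rngs(seed, panel.n_sites)
    prefs = []
    for pid, (site, rng) in enumerate(zip(panel.site_ids, rngs), start=1):
        j = panel.site_index(site)
        noise = rng.standard_normal((config.initial_length,
                                     config.initial_n_series))
        draws = panel.pmv[sl, j][:, None] + panel.psd[sl, j][:, None] * noise
        prefs.append(Pref(pid, site, start, draws.mean(axis=1), panel.n_years))
    return prefs


def t_value(r: float, n: int, t_cap: float = 1e6) -> float:
    """t statistic of a Pearson correlation over an n-year overlap.

    t = r * sqrt(n-2) / sqrt(1-r^2); at |r| -> 1 the value is capped at
    +/- t_cap to keep the ordering finite.
    """
    if n < 3:
        raise ValueError("t-value needs n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")
    denom = 1.0 - r * r
    if denom <= 0.0:
        return t_cap if r > 0 else -t_cap
    t = r * np.sqrt(n - 2) / np.sqrt(denom)
    return float(np.clip(t, -t_cap, t_cap))


def match_candidate(candidate: PseudoSeriesRecord,
                    prefs: list[Pref],
                    config: ConstructorConfig,
                    pref_values: list[np.ndarray] | None = None,
                    ) -> tuple[Pref | None, float, float, int]:
    """Best-matching pref for a candidate at its fixed calendar position.

    Returns (pref or None, t, r, overlap).  ``pref_values`` may supply
    frozen per-pref value arrays (NaN = uncovered) for batch semantics;
    otherwise current values are used.  Prefs with overlap below
    ``min_overlap`` or zero variance on the overlap are skipped.  Ties on t
    go to the lowest pref index.
    """
    if pref_values is None:
        pref_values = [p.values() for p in prefs]
    i0 = candidate.start_year - 1
    i1 = i0 + len(candidate)
    x_full = candidate.values
    best: tuple[Pref | None, float, float, int] = (None, -np.inf, 0.0, 0)
    for pref, vals in zip(prefs, pref_values):
        y = vals[i0:i1]
        mask = ~np.isnan(y)
        n = int(mask.sum())
        if n < config.min_overlap:
            continue
        x = x_full[mask]
        yv = y[mask]
        xd = x - x.mean()
        yd = yv - yv.mean()
        sx = np.dot(xd, xd)
        sy = np.dot(yd, yd)
        if sx <= 0.0 or sy <= 0.0:
            continue
        r = float(np.dot(xd, yd) / np.sqrt(sx * sy))
        r = min(1.0, max(-1.0, r))
        t = t_value(r, n, config.t_cap)
        if t >= config.t_threshold and t > best[1]:
            best = (pref, t, r, n)
    if best[0] is None:
        return (None, float("nan"), float("nan"), 0)
    return best


def run_constructor(dataset: PseudoDataset, prefs: list[Pref],
                    config: ConstructorConfig,
                    keep_assignments: bool = True,
                    ) -> tuple[list[Pref], list[RunLog]]:
    """Run batch classification to the fixpoint.

    Only runs that classify at least one candidate are logged; the final
    fruitless scan terminates the loop silently.
    """
    unclassified = list(dataset.records)
    logs: list[RunLog] = []
    run_index = 0
    while unclassified:
        run_index += 1
        snapshot = [p.values() for p in prefs]
        accepted: list[tuple[PseudoSeriesRecord, Pref, float, float, int]] = []
        remaining: list[PseudoSeriesRecord] = []
        for rec in unclassified:
            pref, t, r, n = match_candidate(rec, prefs, config, snapshot)
            if pref is None:
                remaining.append(rec)
            else:
                accepted.append((rec, pref, t, r, n))
        if not accepted:
            break
        for rec, pref, _, _, _ in accepted:
            pref.add_member(rec, run_index)
        unclassified = remaining
        log = RunLog(
            run_index=run_index,
            n_classified=len(accepted),
            n_remaining=len(remaining),
            contamination=[p.contamination() for p in prefs],
            lengths=[p.length for p in prefs],
            mean_replication=[p.mean_replication for p in prefs],
        )
        if keep_assignments:
            log.assignments = [
                {"record_id": rec.record_id, "pref_id": pref.pref_id,
                 "t": t, "r": r, "overlap": n}
                for rec, pref, t, r, n in accepted]
        logs.append(log)
    return prefs, logs
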