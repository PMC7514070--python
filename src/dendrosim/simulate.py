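"""Covariance-preserving pseudo site signals and pseudo series sampling.

The simulation extends a short, real parameter panel (yearly means rmv and
SDs rsd of AR residual site chronologies) to an arbitrarily long pseudo
timeline.  The joint matrix [rmv | ln(rsd)] is treated as multivariate
normal: its sample covariance is eigendecomposed and used to colour a
standard-normal draw matrix, yielding pseudo means (pmv) and pseudo SDs
(psd) whose columns reproduce the between-site covariance of the real data.
The draw matrix is empirically standardized (centered, orthogonalized,
unit sample variance) before colouring, so the *sample* covariance of the
generated panel equals the source covariance exactly, up to rounding —
every simulation repetition then realizes the same set of site signals.

Pseudo series (ps) are sampled year-by-year from Normal(pmv, psd); pseudo
historical series (phs) are >= 50-year partitions of a ps, cut to lengths
drawn from an empirical pool; pseudo object chronologies (poc) average six
ps (of which a configurable on-site ratio originates from the nominal site)
before partitioning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detrend import ParamPanel, log_rsd
from .io import MIN_SERIES_LENGTH, SeriesLengthPool
from .util import as_rng, spawn_rngs

#: admissible on-site ratios for six-series object chronologies
DEFAULT_OSR_VALUES = (1.0, 5 / 6, 4 / 6)


@dataclass
class PseudoSignalPanel:
    """The generated matrix P: yearly pmv and psd per pseudo site signal.

    Years are the pseudo timeline 1..n_years.
    """

    site_ids: list[str]
    pmv: np.ndarray
    psd: np.ndarray
    source_panel_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.pmv = np.asarray(self.pmv, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.pmv.shape != self.psd.shape:
            raise ValueError("pmv and psd shapes differ")
        if self.pmv.shape[1] != len(self.site_ids):
            raise ValueError("column count does not match site_ids")
        if np.any(self.psd <= 0):
            raise ValueError("psd must be positive everywhere")

    @property
    def n_years(self) -> int:
        return self.pmv.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def site_index(self, site: str) -> int:
        try:
            return self.site_ids.index(site)
        except ValueError:
            raise KeyError(f"unknown site {site!r}") from None

    def to_csv(self, path) -> None:
        cols = {f"pmv_{s}": self.pmv[:, j] for j, s in enumerate(self.site_ids)}
        cols.update({f"psd_{s}": self.psd[:, j] for j, s in enumerate(self.site_ids)})
        idx = pd.Index(np.arange(1, self.n_years + 1), name="year")
        pd.DataFrame(cols, index=idx).to_csv(path, float_format="%.17g")
        meta = {"site_ids": self.site_ids,
                "source_panel_fingerprint": self.source_panel_fingerprint}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "PseudoSignalPanel":
        df = pd.read_csv(path, index_col="year", float_precision="round_trip")
        site_ids = [c[4:] for c in df.columns if c.startswith("pmv_")]
        pmv = df[[f"pmv_{s}" for s in site_ids]].to_numpy()
        psd = df[[f"psd_{s}" for s in site_ids]].to_numpy()
        fp = ""
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            fp = json.loads(sidecar.read_text()).get("source_panel_fingerprint", "")
        return cls(site_ids, pmv, psd, fp)


@dataclass
class PseudoSeriesRecord:
    """One simulated series (or partition) with its true source label.

    ``start_year`` is 1-based on the pseudo timeline; ``values[i]`` belongs
    to year ``start_year + i``.  For object chronologies (kind="poc"),
    ``members`` lists the source sites of the six constituent ps and ``osr``
    is the on-site fraction among them.
    """

    record_id: str
    source_site: str
    kind: str  # ps | phs | poc | initial_ps
    start_year: int
    values: np.ndarray
    members: list[str] | None = None
    osr: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind in ("phs", "poc") and len(self.values) < MIN_SERIES_LENGTH:
            raise ValueError(
                f"{self.record_id}: {self.kind} length {len(self.values)} "
                f"< {MIN_SERIES_LENGTH}")
        if self.kind == "poc":
            if self.members is None:
                raise ValueError(f"{self.record_id}: poc without members")
            on = sum(m == self.source_site for m in self.members)
            self.osr = on / len(self.members)

    @property
    def end_year(self) -> int:
        """Last covered year (inclusive)."""
        return self.start_year + len(self.values) - 1

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PseudoDataset:
    """A generated pool of phs or poc records over one pseudo signal panel."""

    records: list[PseudoSeriesRecord]
    site_ids: list[str]
    n_years: int
    kind: str = "phs"
    osr: float | None = None
    panel_fingerprint: str = ""
    _coverage: np.ndarray | None = field(default=None, repr=False)

    @property
    def coverage(self) -> np.ndarray:
        """S x n_years matrix: records of each site covering each year."""
        if self._coverage is None:
            cov = np.zeros((len(self.site_ids), self.n_years), dtype=int)
            idx = {s: i for i, s in enumerate(self.site_ids)}
            for r in self.records:
                # year y sits at index y-1; end_year is inclusive
                cov[idx[r.source_site], r.start_year - 1:r.end_year] += 1
            self._coverage = cov
        return self._coverage

    def min_coverage(self) -> int:
        return int(self.coverage.min())

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        rows = []
        for r in self.records:
            rows.append({
                "record_id": r.record_id, "source_site": r.source_site,
                "kind": r.kind, "start_year": r.start_year,
                "values": ";".join(f"{v:.10g}" for v in r.values),
                "members": ";".join(r.members) if r.members else "",
            })
        pd.DataFrame(rows).to_csv(path, index=False)
        meta = {"site_ids": self.site_ids, "n_years": self.n_years,
                "kind": self.kind, "osr": self.osr,
                "panel_fingerprint": self.panel_fingerprint}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "PseudoDataset":
        df = pd.read_csv(path, keep_default_na=False)
        meta = json.loads(Path(str(path) + ".json").read_text())
        records = []
        for _, row in df.iterrows():
            members = row["members"].split(";") if row["members"] else None
            records.append(PseudoSeriesRecord(
                row["record_id"], row["source_site"], row["kind"],
                int(row["start_year"]),
                np.array([float(v) for v in row["values"].split(";")]),
                members))
        return cls(records, meta["site_ids"], meta["n_years"], meta["kind"],
                   meta["osr"], meta["panel_fingerprint"])


# ---------------------------------------------------------------------------
# Signal panel generation
# ---------------------------------------------------------------------------

def sample_mvn_eig(mu: np.ndarray, cov: np.ndarray, n: int, rng,
                   empirical: bool = True,
                   psd_rtol: float = 1e-8) -> np.ndarray:
    """Draw n rows from N(mu, cov) via the eigendecomposition square root.

    With ``empirical=True`` the standard-normal draw matrix is centered,
    orthogonalized (SVD rotation) and scaled to unit sample variance before
    colouring, so the returned sample has *sample* covariance exactly
    ``cov`` (requires n > dim).  Eigenvalues below ``-psd_rtol * max`` are
    rejected; tiny negatives are clamped to zero.
    """
    rng = as_rng(rng)
    mu = np.asarray(mu, dtype=float)
    cov = np.asarray(cov, dtype=float)
    p = len(mu)
    if n < 1:
        raise ValueError("n must be >= 1")
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals < -psd_rtol * max(evals.max(), 0.0)):
        raise ValueError("covariance matrix is not positive semi-definite")
    evals = np.clip(evals, 0.0, None)
    z = rng.standard_normal((n, p))
    if empirical:
        if n <= p:
            raise ValueError(f"empirical standardization needs n > dim ({n} <= {p})")
        z = z - z.mean(axis=0)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        z = z @ vt.T
        z = z / z.std(axis=0, ddof=1)
    return mu + z @ (evecs * np.sqrt(evals)).T


def simulate_signal_panel(param_panel: ParamPanel, n_years: int = 1000,
                          seed=None, empirical: bool = True) -> PseudoSignalPanel:
    """Generate the pmv/psd panel preserving the [rmv | ln(rsd)] covariance."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    m = log_rsd(param_panel)  # Y x 2S
    mu = m.mean(axis=0)
    cov = np.cov(m, rowvar=False, ddof=1)
    x = sample_mvn_eig(mu, cov, n_years, seed, empirical=empirical)
    s = param_panel.n_sites
    pmv = x[:, :s]
    psd = np.exp(x[:, s:])
    return PseudoSignalPanel(list(param_panel.site_ids), pmv, psd,
                             param_panel.fingerprint())


# ---------------------------------------------------------------------------
# Series sampling
# ---------------------------------------------------------------------------

def draw_pseudo_series(panel: PseudoSignalPanel, site: str, seed=None,
                       record_id: str | None = None,
                       kind: str = "ps") -> PseudoSeriesRecord:
    """Draw one full-length pseudo series: value_t ~ N(pmv[t], psd[t])."""
    rng = as_rng(seed)
    j = panel.site_index(site)
    values = panel.pmv[:, j] + panel.psd[:, j] * rng.standard_normal(panel.n_years)
    return PseudoSeriesRecord(record_id or f"{site}_ps", site, kind, 1, values)


def _object_mean_values(panel: PseudoSignalPanel, site: str, osr: float,
                        n_per_object: int, rng,
                        osr_values=DEFAULT_OSR_VALUES) -> tuple[np.ndarray, list[str]]:
    """Yearwise mean of n_per_object ps; returns (values, member site labels)."""
    if not any(np.isclose(osr, v) for v in osr_values):
        raise ValueError(f"osr {osr} not in allowed set {tuple(osr_values)}")
    n_on = int(round(osr * n_per_object))
    if not np.isclose(n_on, osr * n_per_object):
        raise ValueError(f"osr {osr} is not an integral fraction of {n_per_object}")
    others = [s for s in panel.site_ids if s != site]
    members = [site] * n_on
    # off-site donors drawn uniformly and independently (repeats allowed)
    members += [others[k] for k in rng.integers(0, len(others),
                                                size=n_per_object - n_on)]
    cols = np.empty((panel.n_years, n_per_object))
    for i, m in enumerate(members):
        j = panel.site_index(m)
        cols[:, i] = panel.pmv[:, j] + panel.psd[:, j] * rng.standard_normal(panel.n_years)
    return cols.mean(axis=1), members


def draw_object_series(panel: PseudoSignalPanel, site: str, osr: float = 1.0,
                       n_per_object: int = 6, seed=None) -> PseudoSeriesRecord:
    """Draw one full-length pseudo object chronology (mean of six ps)."""
    rng = as_rng(seed)
    values, members = _object_mean_values(panel, site, osr, n_per_object, rng)
    rec = PseudoSeriesRecord(f"{site}_poc", site, "ps", 1, values)
    rec.members = members
    return rec


def draw_partition_lengths(pool: SeriesLengthPool, total: int, rng) -> np.ndarray:
    """Draw lengths with replacement until their sum reaches ``total``."""
    lengths: list[int] = []
    s = 0
    while s < total:
        ln = int(rng.choice(pool.lengths))
        lengths.append(ln)
        s += ln
    return np.array(lengths, dtype=int)


def partition_series(ps: PseudoSeriesRecord, pool: SeriesLengthPool, seed=None,
                     kind: str = "phs",
                     min_length: int = MIN_SERIES_LENGTH) -> list[PseudoSeriesRecord]:
    """Cut a full-length ps into consecutive partitions of pooled lengths.

    Lengths are drawn with replacement until they sum to >= the series
    length; the series is cut forward from year 1, the final partition being
    truncated to the remaining years and discarded if shorter than
    ``min_length``.  Kept partitions (plus any discarded tail) tile the full
    timeline disjointly.
    """
    rng = as_rng(seed)
    n = len(ps.values)
    lengths = draw_partition_lengths(pool, n, rng)
    out: list[PseudoSeriesRecord] = []
    pos = 0
    for i, ln in enumerate(lengths):
        take = min(int(ln), n - pos)
        if take >= min_length:
            rec = PseudoSeriesRecord(
                f"{ps.record_id}_p{i}", ps.source_site, kind,
                ps.start_year + pos, ps.values[pos:pos + take],
                list(ps.members) if ps.members else None)
            out.append(rec)
        pos += take
        if pos >= n:
            break
    return out


def _build_dataset(panel: PseudoSignalPanel, pool: SeriesLengthPool,
                   draw_full, kind: str, target_replication: int,
                   seed, osr: float | None,
                   max_draws_per_site: int = 100_000) -> PseudoDataset:
    site_rngs = spawn_rngs(seed, panel.n_sites)
    records: list[PseudoSeriesRecord] = []
    for site, rng in zip(panel.site_ids, site_rngs):
        coverage = np.zeros(panel.n_years, dtype=int)
        i = 0
        while coverage.min() < target_replication:
            if i >= max_draws_per_site:
                raise RuntimeError(
                    f"site {site!r}: coverage {coverage.min()} < "
                    f"{target_replication} after {i} draws; the length pool "
                    "cannot tile the timeline (tail years unreachable)")
            full = draw_full(site, rng, i)
            parts = partition_series(full, pool, rng, kind=kind)
            for r in parts:
                coverage[r.start_year - 1:r.end_year] += 1
            records.extend(parts)
            i += 1
    ds = PseudoDataset(records, list(panel.site_ids), panel.n_years, kind,
                       osr, panel.source_panel_fingerprint)
    return ds


def build_phs_dataset(panel: PseudoSignalPanel, pool: SeriesLengthPool,
                      target_replication: int = 30, seed=None) -> PseudoDataset:
    """Draw-and-partition per site until every year has >= 30 phs."""

    def draw_full(site, rng, i):
        return draw_pseudo_series(panel, site, rng, record_id=f"{site}_ps{i}")

    return _build_dataset(panel, pool, draw_full, "phs", target_replication,
                          seed, None)


def build_poc_dataset(panel: PseudoSignalPanel, pool: SeriesLengthPool,
                      osr: float = 1.0, n_per_object: int = 6,
                      target_replication: int = 30, seed=None) -> PseudoDataset:
    """Like phs, but each full series is the mean of six ps at the given osr."""

    def draw_full(site, rng, i):
        values, members = _object_mean_values(panel, site, osr, n_per_object, rng)
        rec = PseudoSeriesRecord(f"{site}_poc{i}", site, "ps", 1, values)
        rec.members = members
        return rec

    return _build_dataset(panel, pool, draw_full, "poc", target_replication,
                          seed, osr)
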