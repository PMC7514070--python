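"""AR prewhitening of ring-width series and the rmv/rsd parameter panel.

Raw ring-width series carry medium- and low-frequency growth trends that are
irrelevant (and harmful) for provenance matching.  Fitting an autoregressive
model and keeping the innovations isolates the year-to-year (high-frequency)
variability.  Stacking the residual series of all trees of a site and taking
per-year sample means (rmv) and standard deviations (rsd) over the common,
well-replicated period yields the parameter panel that seeds the simulation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.regression.linear_model import yule_walker

from .io import RingWidthSeries, SiteDataset


@dataclass
class ResidualSeries:
    """AR residuals of one ring-width series, re-centered on the raw mean."""

    series_id: str
    site_id: str
    first_year: int
    residuals: np.ndarray
    ar_order: int

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.residuals))

    def __len__(self) -> int:
        return len(self.residuals)


@dataclass
class ParamPanel:
    """Per-site yearly means (rmv) and SDs (rsd) over the common period.

    ``rmv`` and ``rsd`` are Y x S arrays; row i is calendar year ``years[i]``,
    column j is site ``site_ids[j]``.  Every rsd entry is positive.
    """

    years: np.ndarray
    site_ids: list[str]
    rmv: np.ndarray
    rsd: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.rmv = np.asarray(self.rmv, dtype=float)
        self.rsd = np.asarray(self.rsd, dtype=float)
        y, s = len(self.years), len(self.site_ids)
        if self.rmv.shape != (y, s) or self.rsd.shape != (y, s):
            raise ValueError("rmv/rsd shape does not match years x sites")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("panel years must be consecutive")
        if np.any(self.rsd <= 0):
            raise ValueError("all rsd entries must be > 0")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.rmv).tobytes())
        h.update(np.ascontiguousarray(self.rsd).tobytes())
        h.update(",".join(self.site_ids).encode())
        return h.hexdigest()[:16]

    def to_csv(self, path) -> None:
        cols = {f"rmv_{s}": self.rmv[:, j] for j, s in enumerate(self.site_ids)}
        cols.update({f"rsd_{s}": self.rsd[:, j] for j, s in enumerate(self.site_ids)})
        pd.DataFrame(cols, index=pd.Index(self.years, name="year")).to_csv(
            path, float_format="%.17g")  # round-trip exact for float64

    @classmethod
    def from_csv(cls, path) -> "ParamPanel":
        df = pd.read_csv(path, index_col="year", float_precision="round_trip")
        site_ids = [c[4:] for c in df.columns if c.startswith("rmv_")]
        rmv = df[[f"rmv_{s}" for s in site_ids]].to_numpy()
        rsd = df[[f"rsd_{s}" for s in site_ids]].to_numpy()
        return cls(df.index.to_numpy(), site_ids, rmv, rsd)


def default_max_order(n: int) -> int:
    """AR order-search ceiling: min(floor(10*log10(n)), n-1)."""
    return min(int(np.floor(10.0 * np.log10(n))), n - 1)


def ar_residuals(series: RingWidthSeries, max_order: int | None = None) -> ResidualSeries:
    """Prewhiten one series: AIC-selected Yule-Walker AR fit, innovations kept.

    Candidate orders p = 0..max_order are fit by Yule-Walker (divisor-n
    autocovariances on the demeaned series); AIC(p) = n*log(sigma2_p) + 2p
    selects the order.  The one-step-ahead innovations (defined from index p
    onward) are re-centered so their mean equals the raw-series mean, the
    residual-chronology convention that keeps series on a comparable level.
    """
    x = np.asarray(series.widths, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError(f"series {series.series_id!r}: length {n} < 10")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"series {series.series_id!r}: non-finite widths")

    raw_mean = float(np.mean(x))
    xc = x - raw_mean

    if np.allclose(xc, 0.0):
        # constant series: order 0, zero-variance residuals at the mean level
        return ResidualSeries(series.series_id, series.site_id,
                              series.first_year, np.full(n, raw_mean), 0)

    if max_order is None:
        max_order = default_max_order(n)
    max_order = max(0, min(max_order, n - 1))

    sigma2_0 = float(np.mean(xc ** 2))
    best_order, best_aic = 0, n * np.log(sigma2_0)
    best_rho = np.empty(0)
    for p in range(1, max_order + 1):
        rho, sigma = yule_walker(x, order=p, method="mle")
        sigma2 = float(sigma) ** 2
        if sigma2 <= 0:
            break
        aic = n * np.log(sigma2) + 2 * p
        if aic < best_aic:
            best_aic, best_order, best_rho = aic, p, rho

    p = best_order
    if p == 0:
        resid = xc.copy()
    else:
        pred = np.zeros(n - p)
        for i, c in enumerate(best_rho, start=1):
            pred += c * xc[p - i:n - i]
        resid = xc[p:] - pred
    resid = resid - resid.mean() + raw_mean
    return ResidualSeries(series.series_id, series.site_id,
                          series.first_year + p, resid, p)


def _site_residual_frame(site: SiteDataset,
                         max_order: int | None = None) -> pd.DataFrame:
    """Year x series frame of AR residuals for one site (NaN = no ring)."""
    cols = {}
    for s in site.series:
        r = ar_residuals(s, max_order=max_order)
        cols[r.series_id] = pd.Series(r.residuals, index=r.years)
    df = pd.DataFrame(cols)
    df.index.name = "year"
    return df.sort_index()


def build_param_panel(site_datasets: list[SiteDataset],
                      min_replication: int = 15,
                      max_order: int | None = None) -> ParamPanel:
    """Estimate the rmv/rsd panel over the common well-replicated period.

    The common period is the maximal consecutive year range in which every
    site has at least ``min_replication`` residual values per year; a hole
    inside a site's qualifying range is an error (gap-free data assumed).
    SDs use the n-1 denominator.
    """
    if not site_datasets:
        raise ValueError("no site datasets given")
    frames = {d.site_id: _site_residual_frame(d, max_order) for d in site_datasets}

    ranges: dict[str, tuple[int, int]] = {}
    for site, df in frames.items():
        counts = df.notna().sum(axis=1)
        ok = counts[counts >= min_replication].index.to_numpy()
        if ok.size == 0:
            cov = {s: int(frames[s].notna().sum(axis=1).max())
                   for s in frames}
            raise ValueError(
                f"site {site!r} never reaches replication {min_replication}; "
                f"max per-year coverage per site: {cov}")
        if np.any(np.diff(ok) != 1):
            raise ValueError(
                f"site {site!r}: replication >= {min_replication} range has holes")
        ranges[site] = (int(ok[0]), int(ok[-1]))

    lo = max(a for a, _ in ranges.values())
    hi = min(b for _, b in ranges.values())
    if lo > hi:
        detail = ", ".join(f"{s}: {a}-{b}" for s, (a, b) in ranges.items())
        raise ValueError(f"empty common period; per-site coverage: {detail}")

    years = np.arange(lo, hi + 1)
    site_ids = sorted(frames)
    rmv = np.empty((len(years), len(site_ids)))
    rsd = np.empty_like(rmv)
    for j, site in enumerate(site_ids):
        block = frames[site].loc[lo:hi]
        rmv[:, j] = block.mean(axis=1, skipna=True).to_numpy()
        rsd[:, j] = block.std(axis=1, ddof=1, skipna=True).to_numpy()
    return ParamPanel(years, site_ids, rmv, rsd)


def log_rsd(panel: ParamPanel) -> np.ndarray:
    """Return the Y x 2S matrix [rmv | ln(rsd)] used for the covariance step."""
    if np.any(panel.rsd <= 0):
        raise ValueError("rsd must be > 0 to take logs")
    return np.hstack([panel.rmv, np.log(panel.rsd)])
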