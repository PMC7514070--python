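"""Synthetic stand-ins for the deposited ring-width data.

The real inputs are a 15-site Norway-spruce ring-width collection and an
empirical pool of historical series lengths.  This module emulates both so
the full pipeline builds and tests without any download: correlated site
signals with a block (elevation-band) correlation design, lognormal
positive ring widths with AR(1) persistence for the prewhitening step to
remove, block-assigned elevation/watershed metadata, and a truncated
lognormal length pool.  All outputs are labelled synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detrend import ParamPanel
from .io import RingWidthSeries, SeriesLengthPool, SiteDataset
from .simulate import sample_mvn_eig
from .util import as_rng, spawn_rngs

_BANDS = ("low", "medium", "high")


@dataclass
class FixtureSpec:
    """Knobs of the synthetic dataset generator.

    The defaults emulate the real collection: 15 sites in 3 elevation
    blocks, 15-32 series per site, signals correlated ~0.6 within a block
    and ~0.25 across blocks, moderate tree-level noise and AR(1)
    persistence in the raw widths.
    """

    n_sites: int = 15
    series_per_site: tuple[int, int] = (15, 32)
    n_years_raw: int = 100
    first_year: int = 1915
    n_blocks: int = 3
    r_within: float = 0.6
    r_between: float = 0.25
    target_corr: np.ndarray | None = None
    within_site_corr: float = 0.5
    ar_coef: float = 0.5
    width_scale: float = 0.25
    width_base: float = 1.0  # mm
    pool_median: float = 70.0
    pool_sigma: float = 0.45
    pool_max: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_within < 1.0 or not 0.0 <= self.r_between < 1.0:
            raise ValueError("block correlations must be in [0, 1)")
        if not 0.0 <= self.within_site_corr <= 1.0:
            raise ValueError("within_site_corr must be in [0, 1]")

    @property
    def site_ids(self) -> list[str]:
        return [f"site{i + 1:02d}" for i in range(self.n_sites)]

    def blocks(self) -> np.ndarray:
        """Block index per site (contiguous, roughly equal blocks)."""
        return (np.arange(self.n_sites) * self.n_blocks) // self.n_sites

    def signal_corr(self) -> np.ndarray:
        """The S x S target correlation matrix of the site signals."""
        if self.target_corr is not None:
            c = np.asarray(self.target_corr, dtype=float)
            if c.shape != (self.n_sites, self.n_sites):
                raise ValueError("target_corr must be S x S")
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("target_corr must be symmetric with unit diagonal")
            return c
        b = self.blocks()
        same = b[:, None] == b[None, :]
        c = np.where(same, self.r_within, self.r_between)
        np.fill_diagonal(c, 1.0)
        return c

    def site_metadata(self) -> dict[str, dict]:
        """Elevation band per block; watersheds cut across blocks."""
        blocks = self.blocks()
        n_ws = min(3, self.n_sites)
        return {
            site: {
                "elevation_band": _BANDS[blocks[i] % len(_BANDS)],
                "watershed": f"ws{i % n_ws + 1}",
            }
            for i, site in enumerate(self.site_ids)
        }


def make_site_signals(spec: FixtureSpec, n_years: int | None = None,
                      seed=None) -> np.ndarray:
    """n_years x S standard-normal signals with the target correlation."""
    rng = as_rng(spec.seed if seed is None else seed)
    n = n_years or spec.n_years_raw
    corr = spec.signal_corr()
    return sample_mvn_eig(np.zeros(spec.n_sites), corr, n, rng, empirical=False)


def make_raw_dataset(spec: FixtureSpec, seed=None) -> list[SiteDataset]:
    """Synthetic per-site raw ring-width datasets.

    Tree series mix the site signal with tree-level noise at the requested
    within-site correlation, pass through an AR(1) filter (persistence for
    the prewhitening step to remove) and map to positive widths via
    ``base * exp(scale * value)`` — the standard lognormal width assumption.
    """
    root = as_rng(spec.seed if seed is None else seed)
    sig_rng, tree_rng, count_rng = spawn_rngs(root, 3)
    signals = make_site_signals(spec, spec.n_years_raw, sig_rng)
    w = spec.within_site_corr
    a, b = np.sqrt(w), np.sqrt(1.0 - w)
    lo, hi = spec.series_per_site
    meta = spec.site_metadata()

    datasets = []
    for j, site in enumerate(spec.site_ids):
        n_trees = int(count_rng.integers(lo, hi + 1))
        series = []
        for k in range(n_trees):
            noise = tree_rng.standard_normal(spec.n_years_raw)
            x = a * signals[:, j] + b * noise
            y = np.empty_like(x)
            y[0] = x[0]
            for t in range(1, len(x)):
                y[t] = spec.ar_coef * y[t - 1] + x[t]
            widths = spec.width_base * np.exp(spec.width_scale * y)
            series.append(RingWidthSeries(f"{site}t{k + 1:02d}", site,
                                          spec.first_year, widths))
        datasets.append(SiteDataset(site, series, dict(meta[site])))
    return datasets


def make_length_pool(spec: FixtureSpec, size: int = 1000,
                     seed=None) -> SeriesLengthPool:
    """Truncated lognormal series-length pool (min 50, median ~spec value)."""
    rng = as_rng(spec.seed if seed is None else seed)
    out = np.empty(size, dtype=int)
    mu = np.log(spec.pool_median)
    filled = 0
    while filled < size:
        draws = np.rint(np.exp(mu + spec.pool_sigma *
                               rng.standard_normal(size))).astype(int)
        ok = draws[(draws >= 50) & (draws <= spec.pool_max)]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return SeriesLengthPool(out)


def make_param_panel(n_sites: int = 15, n_years: int = 63,
                     target_corr: np.ndarray | None = None,
                     r_within: float = 0.6, r_between: float = 0.25,
                     n_blocks: int = 3,
                     mean_level: float = 1.0, mean_scale: float = 0.1,
                     sd_level: float = 0.2, sd_jitter: float = 0.1,
                     first_year: int = 1951, seed=None) -> ParamPanel:
    """A synthetic rmv/rsd panel built directly, bypassing raw widths.

    Handy for exercising the simulator and constructor at controlled
    between-site correlation: rmv columns are correlated signals around
    ``mean_level``; rsd columns are lognormal around ``sd_level``.
    """
    spec = FixtureSpec(n_sites=n_sites, r_within=r_within,
                       r_between=r_between, n_blocks=n_blocks,
                       target_corr=target_corr, seed=0)
    rng = as_rng(seed)
    sig_rng, sd_rng = spawn_rngs(rng, 2)
    signals = make_site_signals(spec, n_years, sig_rng)
    rmv = mean_level + mean_scale * signals
    rsd = sd_level * np.exp(sd_jitter * sd_rng.standard_normal((n_years, n_sites)))
    years = np.arange(first_year, first_year + n_years)
    return ParamPanel(years, spec.site_ids, rmv, rsd)
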