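# dendrosim

Simulation framework for assessing the **contamination risk of reference
chronologies in dendro-provenancing** — the practice of approximating the
geographic origin of wood from the similarity of its ring-width pattern to
regional reference chronologies.

Reference chronologies are typically seeded from living-tree site
chronologies and extended backward in time by attaching best-matching
ring-width series from historical buildings and objects. Because the true
provenance of historical wood is unknown, series from other regions can be
absorbed, progressively diluting the local growth signal — and this
contamination cannot be measured on real data. `dendrosim` measures it by
simulation: it generates pseudo site signals that preserve the statistical
structure of a real multi-site dataset, samples pseudo "historical" series
whose provenance is known by construction, rebuilds reference chronologies
with the same best-match procedure a laboratory would use, and reports how
much foreign signal the references absorb.

Intended users are dendrochronologists and quantitative-archaeology
researchers planning or auditing provenance studies for a specific region.

## The model

1. **Parameter estimation.** Each ring-width series is prewhitened with an
   AIC-selected Yule–Walker autoregressive model; the innovations isolate
   the year-to-year (high-frequency) signal used for provenancing. Over the
   common period in which every site has ≥ 15 residual values per year, the
   per-site yearly sample means **rmv** and standard deviations **rsd** are
   estimated, giving a `Y × 2S` matrix `[rmv | ln(rsd)]` (SDs are treated
   as log-normal).

2. **Pseudo signal generation.** The sample covariance `Σ` of
   `[rmv | ln(rsd)]` is eigendecomposed, `Σ = EΛEᵀ`, and used to colour an
   empirically standardized standard-normal matrix `Z` (n years × 2S):
   `X = μ + Z(EΛ^{1/2})ᵀ`. The first S columns are the pseudo means
   **pmv**, the exponentiated last S columns the pseudo SDs **psd**. By
   construction the *sample* covariance of `X` equals `Σ` exactly, so every
   simulation repetition realizes the same set of site signals (correlation
   deltas at the 10⁻¹⁵ level).

3. **Pseudo series.** A pseudo series (ps) draws year *t* from
   `N(pmv_t, psd_t)`. Pseudo historical series (**phs**) are ≥ 50-year
   partitions of a ps, with lengths drawn from an empirical pool of real
   historical series lengths (sub-50-year tails are discarded). Pseudo
   object chronologies (**poc**) average 6 ps before partitioning; the
   on-site ratio (osr ∈ {1, 5/6, 4/6}) controls how many of the 6
   originate from the nominal site. Generation repeats until every year is
   covered by 30 phs/poc per site.

4. **PREF-Constructor.** Each site's initial pseudo reference (pref) is
   the 150-year mean of 30 fresh ps on the most recent years of the
   timeline. In synchronous runs, every unclassified candidate is compared
   with every pref at its fixed calendar position (correct cross-dating is
   assumed); with overlap `n ≥ 50` years and Pearson correlation `r`, the
   match statistic is

   `t = r·√(n−2) / √(1−r²)`,

   and a candidate joins the pref with the highest `t ≥ t_threshold`
   (thresholds 5, 10, 15, 20). Runs repeat until nothing more classifies.

5. **Evaluation.** Per pref, *contamination* is the percentage of members
   originating from a different site — or a different elevation band or
   watershed, via configurable contrast groups. Multi-repetition summaries
   report classified/correct percentages, per-run 95th-percentile
   contamination, and length/attractor category tables, computed over the
   runs executed in every repetition.

A synthetic fixture module emulates the real inputs (correlated multi-site
ring-width data with block structure, metadata, length pool), so the whole
pipeline runs with no external data.

## Worked example

```python
import dendrosim as ds

# synthetic 6-site raw dataset -> rmv/rsd parameter panel
spec = ds.FixtureSpec(n_sites=6, n_years_raw=80, seed=3)
raw = ds.make_raw_dataset(spec)
panel = ds.build_param_panel(raw, min_replication=15)

# 500-year pseudo signals preserving the panel covariance
sig = ds.simulate_signal_panel(panel, n_years=500, seed=1)
lo, hi = ds.delta_corr(sig.pmv, panel.rmv)
print(f"pmv-rmv correlation delta range: ({lo:.2e}, {hi:.2e})")

# pseudo historical series, 5 per year and site
pool = ds.make_length_pool(spec, 500, seed=5)
dset = ds.build_phs_dataset(sig, pool, target_replication=5, seed=7)

# build pseudo references at t >= 5
cfg = ds.ConstructorConfig(t_threshold=5.0)
prefs = ds.make_initial_prefs(sig, cfg, seed=11)
prefs, logs = ds.run_constructor(dset, prefs, cfg)

cmap = ds.ContrastMap.from_meta(spec.site_metadata())
rep = ds.summarize_repetition(dset, prefs, logs, cmap)
print(f"{rep.n_series_generated} series generated, "
      f"{rep.pct_generated_classified:.1f}% classified, "
      f"{rep.pct_classified_correct:.1f}% of those correctly, "
      f"{rep.n_runs_executed} constructor runs")
for p in prefs[:3]:
    print(f"pref{p.pref_id} ({p.init_site}): length {p.length}, "
          f"mean replication {p.mean_replication:.1f}, "
          f"off-site contamination {p.contamination():.1f}%")
```

prints

```
pmv-rmv correlation delta range: (-8.33e-16, 4.44e-16)
329 series generated, 66.9% classified, 90.9% of those correctly, 8 constructor runs
pref1 (site01): length 231, mean replication 6.4, off-site contamination 0.0%
pref2 (site02): length 313, mean replication 9.3, off-site contamination 0.0%
pref3 (site03): length 435, mean replication 7.1, off-site contamination 0.0%
```

The delta range shows the covariance transfer is exact up to rounding; two
thirds of the simulated historical series were attached to a reference, 91%
of them to the right one, and the first three references grew from their
150-year initial chronologies to 231–435 years without absorbing any
off-site series (the fixture's site signals are well separated at this
threshold).

A command-line interface wraps the same pipeline:

```sh
dendrosim fixture --out data/ --seed 4         # synthetic RWL + pool + metadata
dendrosim panel --rwl-dir data/ --out panel.csv
dendrosim construct --panel panel.csv --pool data/length_pool.csv \
    --meta data/sites.csv --mode poc --threshold 15 --osr 1.0 \
    --seed 1 --out rep.json
dendrosim run --config experiment.yaml          # multi-repetition experiment
dendrosim evaluate --experiment-dir out/<hash> --contrast elevation
```

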