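import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dendrosim as ds
from dendrosim.simulate import draw_partition_lengths, sample_mvn_eig


class TestSignalPanel:
    def test_correlation_preserved_to_machine_precision(self, param_panel):
        """The generated pmv columns reproduce the rmv correlation exactly."""
        panel = ds.simulate_signal_panel(param_panel, n_years=400, seed=7)
        lo, hi = ds.delta_corr(panel.pmv, param_panel.rmv)
        assert max(abs(lo), abs(hi)) < 1e-12

    def test_full_covariance_preserved(self, param_panel):
        panel = ds.simulate_signal_panel(param_panel, n_years=400, seed=7)
        m = ds.log_rsd(param_panel)
        x = np.hstack([panel.pmv, np.log(panel.psd)])
        d = np.cov(x, rowvar=False) - np.cov(m, rowvar=False)
        assert np.abs(d).max() < 1e-12

    def test_diagonal_covariance_gives_independent_columns(self, rng):
        n, p = 2000, 6
        x = sample_mvn_eig(np.zeros(p), np.eye(p), n, rng, empirical=False)
        corr = np.corrcoef(x, rowvar=False)
        off = np.abs(corr[~np.eye(p, dtype=bool)])
        assert off.mean() <= 3 / np.sqrt(n)

    def test_non_psd_covariance_rejected(self, rng):
        cov = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="positive semi-definite"):
            sample_mvn_eig(np.zeros(2), cov, 100, rng)

    def test_semi_definite_covariance_tolerated(self, rng):
        cov = np.ones((3, 3))  # rank 1, PSD
        x = sample_mvn_eig(np.zeros(3), cov, 50, rng, empirical=False)
        np.testing.assert_allclose(x[:, 0], x[:, 1], atol=1e-10)

    def test_nonempirical_covariance_converges(self, rng):
        """Plain (non-standardized) sampling converges in distribution."""
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        n = 100_000
        x = sample_mvn_eig(np.array([1.0, -1.0]), cov, n, rng, empirical=False)
        # bootstrap-free SE bound: Var(s_ij) ~ (cov_ii*cov_jj + cov_ij^2)/n
        d = np.cov(x, rowvar=False) - cov
        se = np.sqrt((np.outer(np.diag(cov), np.diag(cov)) + cov ** 2) / n)
        assert np.all(np.abs(d) <= 5 * se)
        assert np.all(np.abs(x.mean(axis=0) - [1.0, -1.0])
                      <= 5 * np.sqrt(np.diag(cov) / n))

    def test_bad_sizes_rejected(self, param_panel):
        with pytest.raises(ValueError, match="n_years"):
            ds.simulate_signal_panel(param_panel, n_years=0, seed=0)
        with pytest.raises(ValueError, match="empirical"):
            # empirical standardization needs n_years > 2S
            ds.simulate_signal_panel(param_panel, n_years=5, seed=0)

    def test_fingerprint_recorded(self, param_panel, signal_panel):
        assert signal_panel.source_panel_fingerprint == param_panel.fingerprint()

    def test_csv_round_trip(self, tmp_path, signal_panel):
        path = tmp_path / "panel.csv"
        signal_panel.to_csv(path)
        back = ds.PseudoSignalPanel.from_csv(path)
        assert back.site_ids == signal_panel.site_ids
        np.testing.assert_allclose(back.pmv, signal_panel.pmv, atol=1e-9)
        assert back.source_panel_fingerprint == signal_panel.source_panel_fingerprint


class TestDrawPseudoSeries:
    def test_moments_at_fixed_year(self, signal_panel):
        rngs = np.random.default_rng(0).spawn(3000)
        year_idx, site = 10, signal_panel.site_ids[0]
        vals = np.array([
            ds.draw_pseudo_series(signal_panel, site, r).values[year_idx]
            for r in rngs])
        mu = signal_panel.pmv[year_idx, 0]
        sd = signal_panel.psd[year_idx, 0]
        n = len(vals)
        assert abs(vals.mean() - mu) <= 4 * sd / np.sqrt(n)
        assert abs(vals.std(ddof=1) - sd) <= 4 * sd / np.sqrt(2 * n)

    def test_degenerate_psd_returns_pmv(self, signal_panel):
        panel = ds.PseudoSignalPanel(signal_panel.site_ids, signal_panel.pmv,
                                     np.full_like(signal_panel.psd, 1e-12))
        ps = ds.draw_pseudo_series(panel, panel.site_ids[2], seed=0)
        np.testing.assert_allclose(ps.values, panel.pmv[:, 2], atol=1e-9)

    def test_seed_determinism(self, signal_panel):
        a = ds.draw_pseudo_series(signal_panel, "site01", seed=42)
        b = ds.draw_pseudo_series(signal_panel, "site01", seed=42)
        c = ds.draw_pseudo_series(signal_panel, "site01", seed=43)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_unknown_site_rejected(self, signal_panel):
        with pytest.raises(KeyError):
            ds.draw_pseudo_series(signal_panel, "nowhere", seed=0)


def _full_ps(n=1000, site="siteA"):
    return ds.PseudoSeriesRecord("ps0", site, "ps", 1,
                                 np.linspace(0.0, 1.0, n))


class TestPartitioning:
    @pytest.mark.parametrize("pool_lengths,n,expected", [
        ([1000], 1000, [1000]),        # single full-length partition
        ([100], 1000, [100] * 10),     # exact tiling
        ([600], 1000, [600, 400]),     # truncated tail of 400 kept (>= 50)
        ([970], 1000, [970]),          # 30-year tail discarded
    ])
    def test_cutting_rule(self, pool_lengths, n, expected):
        pool = ds.SeriesLengthPool(np.array(pool_lengths))
        parts = ds.partition_series(_full_ps(n), pool, seed=0)
        assert [len(p) for p in parts] == expected
        # forward, consecutive from year 1
        assert parts[0].start_year == 1
        for a, b in zip(parts, parts[1:]):
            assert b.start_year == a.end_year + 1

    def test_partition_values_slice_the_parent(self):
        ps = _full_ps(1000)
        pool = ds.SeriesLengthPool(np.array([600]))
        parts = ds.partition_series(ps, pool, seed=0)
        np.testing.assert_array_equal(parts[1].values, ps.values[600:])
        assert all(p.source_site == ps.source_site for p in parts)

    @given(lengths=st.lists(st.integers(min_value=50, max_value=400),
                            min_size=1, max_size=8),
           seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_tiling_property(self, lengths, seed):
        """Partitions tile years 1..N disjointly; tails < 50 are discarded."""
        n = 1000
        pool = ds.SeriesLengthPool(np.array(lengths))
        parts = ds.partition_series(_full_ps(n), pool, seed=seed)
        assert parts, "at least the first >= 50-year partition is kept"
        covered = np.zeros(n, dtype=int)
        for p in parts:
            assert len(p) >= 50
            covered[p.start_year - 1:p.end_year] += 1
        assert covered.max() <= 1
        # coverage is a prefix: only a tail < 50 may be missing
        n_covered = covered.sum()
        assert np.all(covered[:n_covered] == 1)
        assert n - n_covered < 50 or n_covered == n

    def test_length_draw_accounting(self, rng):
        pool = ds.SeriesLengthPool(np.array([70, 120, 300]))
        lengths = draw_partition_lengths(pool, 1000, rng)
        assert lengths.sum() >= 1000
        assert lengths[:-1].sum() < 1000


class TestDatasets:
    def test_single_record_per_site_limit(self, signal_panel):
        pool = ds.SeriesLengthPool(np.array([1000]))
        dset = ds.build_phs_dataset(signal_panel, pool,
                                    target_replication=1, seed=0)
        assert len(dset) == signal_panel.n_sites
        assert dset.min_coverage() == 1

    def test_coverage_invariant(self, signal_panel, length_pool):
        dset = ds.build_phs_dataset(signal_panel, length_pool,
                                    target_replication=4, seed=2)
        assert dset.min_coverage() >= 4
        assert all(r.kind == "phs" for r in dset.records)
        assert all(len(r) >= 50 for r in dset.records)

    def test_record_count_accounting(self, signal_panel, length_pool):
        """Record-years at least cover S * replication * N; overshoot bounded.

        The lower bound is exact (every site-year must reach the target
        coverage); the upper bound is loose because late years are covered
        only by draws whose final partition survives the tail discard.
        """
        rep = 4
        dset = ds.build_phs_dataset(signal_panel, length_pool,
                                    target_replication=rep, seed=2)
        record_years = sum(len(r) for r in dset.records)
        floor = signal_panel.n_sites * rep * signal_panel.n_years
        assert record_years >= floor
        assert record_years <= 4 * floor

    def test_dataset_determinism(self, signal_panel, length_pool):
        a = ds.build_phs_dataset(signal_panel, length_pool, 2, seed=9)
        b = ds.build_phs_dataset(signal_panel, length_pool, 2, seed=9)
        assert len(a) == len(b)
        for ra, rb in zip(a.records, b.records):
            assert ra.record_id == rb.record_id
            np.testing.assert_array_equal(ra.values, rb.values)

    def test_csv_round_trip(self, tmp_path, signal_panel, length_pool):
        dset = ds.build_poc_dataset(signal_panel, length_pool, osr=5 / 6,
                                    target_replication=1, seed=3)
        path = tmp_path / "dset.csv"
        dset.to_csv(path)
        back = ds.PseudoDataset.from_csv(path)
        assert len(back) == len(dset)
        assert back.kind == "poc" and back.osr == dset.osr
        for ra, rb in zip(dset.records, back.records):
            assert ra.members == rb.members
            np.testing.assert_allclose(ra.values, rb.values, rtol=1e-9)


class TestObjectChronologies:
    @pytest.mark.parametrize("osr,n_off", [(1.0, 0), (5 / 6, 1), (4 / 6, 2)])
    def test_member_composition(self, signal_panel, osr, n_off):
        rec = ds.draw_object_series(signal_panel, "site02", osr=osr, seed=1)
        assert len(rec.members) == 6
        assert sum(m != "site02" for m in rec.members) == n_off
        assert all(m in signal_panel.site_ids for m in rec.members)

    def test_invalid_osr_rejected(self, signal_panel):
        with pytest.raises(ValueError, match="osr"):
            ds.draw_object_series(signal_panel, "site01", osr=0.5, seed=0)

    def test_poc_records_report_osr(self, signal_panel, length_pool):
        dset = ds.build_poc_dataset(signal_panel, length_pool, osr=5 / 6,
                                    target_replication=1, seed=4)
        assert all(r.kind == "poc" for r in dset.records)
        assert all(r.osr == pytest.approx(5 / 6) for r in dset.records)

    def test_variance_law(self, signal_panel):
        """At osr=1 a poc value is a mean of 6 iid draws: SD = psd/sqrt(6)."""
        year_idx, site = 5, signal_panel.site_ids[0]
        rngs = np.random.default_rng(11).spawn(3000)
        vals = np.array([
            ds.draw_object_series(signal_panel, site, 1.0, seed=r).values[year_idx]
            for r in rngs])
        expected = signal_panel.psd[year_idx, 0] / np.sqrt(6)
        n = len(vals)
        assert abs(vals.std(ddof=1) - expected) <= 4 * expected / np.sqrt(2 * n)
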