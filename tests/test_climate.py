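"""Window assembly, bootstrap/moving/partial correlations and surrogate
significance."""

import numpy as np
import pandas as pd
import pytest

from dendrobomb.climate import (
    MonthKey,
    assemble_window,
    bootstrap_correlation,
    circulant_significance,
    circulant_surrogates,
    gridded_correlation,
    month_keys,
    moving_correlation,
    partial_correlation,
    seasonal_aggregate,
)
from dendrobomb.types import Chronology, ClimateSeries


def labelled_climate(y0=1948, y1=2018):
    """Climate whose values encode (year, month) for index auditing."""
    rows = [
        {"year": y, "month": m, "precip_mm": y * 100.0 + m, "tmax_c": y + m / 100.0}
        for y in range(y0, y1 + 1)
        for m in range(1, 13)
    ]
    return ClimateSeries(pd.DataFrame(rows))


def ar1_series(rng, n=56, phi=0.5):
    x = np.zeros(n)
    e = rng.standard_normal(n)
    for i in range(n):
        x[i] = phi * (x[i - 1] if i else 0.0) + e[i]
    return x


class TestAssembleWindow:
    def test_24_columns_jul_to_jun(self):
        w = assemble_window(labelled_climate(), [2000], "precip_mm")
        assert w.shape == (1, 24)
        assert w.columns[0] == "Jul (prev)"
        assert w.columns[-1] == "Jun (curr)"
        assert w.iloc[0, 0] == 1999 * 100 + 7  # Jul 1999
        assert w.iloc[0, -1] == 2001 * 100 + 6  # Jun 2001

    def test_missing_month_error_names_it(self):
        clim = labelled_climate(1999, 2000)  # Jun 2001 absent
        with pytest.raises(ValueError, match=r"\(2001, 6\)"):
            assemble_window(clim, [2000], "precip_mm")

    def test_previous_december_column_audit(self):
        years = list(range(1960, 2010))
        w = assemble_window(labelled_climate(), years, "precip_mm")
        expect = [(t - 1) * 100 + 12 for t in years]
        assert w["Dec (prev)"].tolist() == expect

    def test_every_month_used_once(self):
        # exhaustive audit: the 24 encoded (year, month) values per ring
        # year are distinct and form the exact Jul(t-1)..Jun(t+1) span
        w = assemble_window(labelled_climate(), [1980, 1981], "precip_mm")
        for t, row in zip([1980, 1981], w.to_numpy()):
            ym = sorted((int(v) // 100, int(v) % 100) for v in row)
            start = (t - 1) * 12 + 6  # Jul(t-1), zero-based month index
            expect = sorted(
                ((start + i) // 12, (start + i) % 12 + 1) for i in range(24)
            )
            assert ym == expect

    def test_month_key_calendar_years(self):
        assert MonthKey("prev", 12).calendar_year(2000) == 1999
        assert MonthKey("prev", 3).calendar_year(2000) == 2000
        assert MonthKey("curr", 11).calendar_year(2000) == 2000
        assert MonthKey("curr", 4).calendar_year(2000) == 2001
        assert len(month_keys()) == 24


class TestBootstrapCorrelation:
    def test_identical_series_degenerate_ci(self, rng):
        x = rng.standard_normal(56)
        res = bootstrap_correlation(x, x, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)
        assert res.significant

    def test_seeded_reproducibility(self, rng):
        x, y = rng.standard_normal((2, 56))
        a = bootstrap_correlation(x, y, seed=42)
        b = bootstrap_correlation(x, y, seed=42)
        assert (a.r, a.ci_low, a.ci_high) == (b.r, b.ci_low, b.ci_high)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            bootstrap_correlation(np.ones(30), np.arange(30.0))

    def test_size_on_independent_noise(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x, y = rng.standard_normal((2, 56))
            res = bootstrap_correlation(x, y, n_boot=300, seed=rng)
            hits += res.significant
        assert hits / n_rep <= 0.10

    def test_power_when_correlated(self):
        rng = np.random.default_rng(8)
        covered = signif = 0
        n_rep = 100
        for _ in range(n_rep):
            x = rng.standard_normal(56)
            y = 0.75 * x + rng.standard_normal(56)  # population r = 0.6
            res = bootstrap_correlation(x, y, n_boot=300, seed=rng)
            covered += res.ci_low <= res.r <= res.ci_high
            signif += res.significant
        assert covered == n_rep
        assert signif / n_rep >= 0.90


class TestMovingCorrelation:
    def test_window_count_56yr_35win(self, rng):
        x, y = rng.standard_normal((2, 56))
        out = moving_correlation(x, y, np.arange(1960, 2016), n_boot=50)
        assert len(out) == 22
        assert out[0].key == "1960-1994"
        assert out[-1].key == "1981-2015"

    def test_full_span_window_equals_plain_correlation(self, rng):
        x, y = rng.standard_normal((2, 40))
        (res,) = moving_correlation(x, y, np.arange(1960, 2000), window=40, n_boot=50)
        assert res.r == pytest.approx(bootstrap_correlation(x, y, n_boot=10).r)

    def test_stationary_relationship_stable(self):
        # under a constant population r = 0.5, window estimates fluctuate
        # around 0.5; in >= 95% of replicates no window strays beyond 0.35
        rng = np.random.default_rng(9)
        n_rep, all_within = 20, 0
        for _ in range(n_rep):
            x = rng.standard_normal(56)
            y = 0.577 * x + rng.standard_normal(56)  # population r = 0.5
            rs = np.array(
                [w.r for w in moving_correlation(x, y, np.arange(56), n_boot=10, seed=rng)]
            )
            all_within += np.all(np.abs(rs - 0.5) <= 0.35)
        assert all_within / n_rep >= 0.95

    def test_short_overlap_rejected(self, rng):
        x, y = rng.standard_normal((2, 30))
        with pytest.raises(ValueError, match="window"):
            moving_correlation(x, y, np.arange(30), window=35)


class TestSeasonalAggregate:
    def test_block_values_and_count(self):
        w = assemble_window(labelled_climate(), [1980, 1981], "precip_mm")
        sums = seasonal_aggregate(w, mode="sum")
        means = seasonal_aggregate(w, mode="mean")
        assert sums.shape[1] == 24 + 23 + 22
        assert means.shape[1] == 69
        aug, sep = w["Aug (prev)"], w["Sep (prev)"]
        np.testing.assert_allclose(sums["Aug-Sep (prev)"], aug + sep)
        oct_, nov, dec = w["Oct (prev)"], w["Nov (prev)"], w["Dec (prev)"]
        np.testing.assert_allclose(
            means["Oct-Dec (prev)"], (oct_ + nov + dec) / 3.0
        )

    def test_simple_blocks(self):
        df = pd.DataFrame({"Aug (prev)": [10.0], "Sep (prev)": [20.0], "Oct (prev)": [30.0]})
        assert seasonal_aggregate(df, lengths=(2,), mode="sum")["Aug-Sep (prev)"].iloc[0] == 30.0
        assert seasonal_aggregate(df, lengths=(3,), mode="mean")["Aug-Oct (prev)"].iloc[0] == 20.0


class TestPartialCorrelation:
    def test_reduces_to_simple_when_climate_uncorrelated(self):
        # construct T exactly orthogonal to P
        rng = np.random.default_rng(3)
        p = rng.standard_normal(200)
        t = rng.standard_normal(200)
        p -= p.mean()
        t -= t.mean()
        t -= p * (t @ p) / (p @ p)  # centred and exactly orthogonal to p
        c = rng.standard_normal(200)
        r_pc_t, _, r_tp = partial_correlation(p, t, c)
        assert abs(r_tp) < 1e-12
        simple_pc = np.corrcoef(p, c)[0, 1]
        simple_tc = np.corrcoef(t, c)[0, 1]
        # with r_TP = 0 the formula reduces to r_PC / sqrt(1 - r_TC^2)
        assert r_pc_t == pytest.approx(simple_pc / np.sqrt(1 - simple_tc**2), abs=1e-12)

    def test_residual_regression_oracle(self):
        # the formula must equal the correlation of the residuals of
        # Cr ~ T and P ~ T, computed via an independent lstsq route
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = rng.integers(25, 80)
            p, t, c = rng.standard_normal((3, n))
            c = c + 0.5 * t
            p = p + 0.6 * t
            r_pc_t, r_tc_p, _ = partial_correlation(p, t, c)

            def resid(y, x):
                X = np.column_stack([np.ones(len(x)), x])
                return y - X @ np.linalg.lstsq(X, y, rcond=None)[0]

            oracle_p = np.corrcoef(resid(p, t), resid(c, t))[0, 1]
            oracle_t = np.corrcoef(resid(t, p), resid(c, p))[0, 1]
            assert r_pc_t == pytest.approx(oracle_p, abs=1e-10)
            assert r_tc_p == pytest.approx(oracle_t, abs=1e-10)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        p, t, c = rng.standard_normal((3, 60))
        c = c - 0.4 * t + 0.3 * p
        df = pd.DataFrame({"p": p, "t": t, "c": c})
        r_pc_t, r_tc_p, _ = partial_correlation(p, t, c)
        ref_p = pingouin.partial_corr(df, x="p", y="c", covar="t")["r"].iloc[0]
        ref_t = pingouin.partial_corr(df, x="t", y="c", covar="p")["r"].iloc[0]
        assert r_pc_t == pytest.approx(ref_p, abs=1e-9)
        assert r_tc_p == pytest.approx(ref_t, abs=1e-9)

    def test_pure_covariance_signal_vanishes(self):
        # Cr = -0.5 T + e and P = 0.6 T + u: P's apparent correlation with
        # Cr is pure covariance, the partial must be ~0
        rng = np.random.default_rng(6)
        n = 5000
        t = rng.standard_normal(n)
        c = -0.5 * t + rng.standard_normal(n)
        p = 0.6 * t + rng.standard_normal(n)
        r_pc_t, _, _ = partial_correlation(p, t, c)
        assert abs(np.corrcoef(p, c)[0, 1]) > 0.15  # simple r is clearly non-zero
        assert abs(r_pc_t) < 0.05

    def test_collinear_climate_rejected(self):
        x = np.arange(30.0)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, 2 * x + 1, np.random.default_rng(0).standard_normal(30))


class TestCirculantSignificance:
    def test_self_correlation_minimum_p(self, rng):
        x = ar1_series(rng)
        p = circulant_significance(x, x, n_surrogates=1000, seed=1)
        assert p == pytest.approx(1.0 / 1001.0)

    def test_seeded_reproducibility(self, rng):
        x = ar1_series(rng)
        y = rng.standard_normal(56)
        assert circulant_significance(x, y, seed=3) == circulant_significance(
            x, y, seed=3
        )

    def test_surrogates_preserve_lag1_autocorrelation(self, rng):
        x = ar1_series(rng, n=120, phi=0.6)
        sur = circulant_surrogates(x, 400, np.random.default_rng(2))

        def lag1(v):
            v = v - v.mean(axis=-1, keepdims=True)
            num = (v[..., 1:] * v[..., :-1]).sum(axis=-1)
            den = (v**2).sum(axis=-1)
            return num / den

        assert np.mean(lag1(sur)) == pytest.approx(lag1(x), abs=0.1)

    def test_size_under_autocorrelation(self):
        # independent predictor vs an AR(1) chronology: rejection rate
        # must stay near the nominal 5% despite the autocorrelation
        rng = np.random.default_rng(11)
        rej = 0
        n_rep = 200
        for _ in range(n_rep):
            x = ar1_series(rng, phi=0.5)
            y = rng.standard_normal(56)
            rej += circulant_significance(x, y, n_surrogates=400, seed=rng) < 0.05
        assert rej / n_rep <= 0.07


class TestGriddedCorrelation:
    def _chron(self, rng, n=40):
        idx = rng.standard_normal(n) * 0.1 + 1.0
        return Chronology(
            years=np.arange(1970, 1970 + n),
            index=idx,
            raw_mean=np.ones(n),
            sample_depth=np.full(n, 5),
            rbar=0.4,
            eps=0.8,
            sss=np.ones(n),
        ), idx

    def _grid(self, chron_idx, rng, cells):
        rows = []
        for cid, (lat, lon, values) in cells.items():
            for i, y in enumerate(range(1969, 1969 + len(chron_idx) + 2)):
                for m in range(1, 13):
                    v = values[i] if m == 12 else rng.standard_normal()
                    rows.append(
                        {"cell_id": cid, "lat": lat, "lon": lon, "year": y,
                         "month": m, "value": v}
                    )
        return pd.DataFrame(rows)

    def test_matching_cell_identified(self, rng):
        chron, idx = self._chron(rng)
        pad = np.concatenate([[0.0], idx, [0.0, 0.0]])
        cells = {
            "hit": (-20.0, -64.0, np.roll(pad, -1)),  # Dec(prev) equals index
            "noise": (-21.0, -65.0, rng.standard_normal(len(pad))),
        }
        grid = self._grid(idx, rng, cells)
        out = gridded_correlation(
            chron, grid, months=[("prev", 12)], n_boot=100, seed=0
        )
        hit = out[out.cell_id == "hit"].iloc[0]
        noise = out[out.cell_id == "noise"].iloc[0]
        assert hit.r == pytest.approx(1.0, abs=1e-9)
        assert hit.significant
        assert abs(noise.r) < 0.5

    def test_constant_field_rejected(self, rng):
        chron, idx = self._chron(rng)
        cells = {"flat": (-20.0, -64.0, np.zeros(len(idx) + 3))}
        grid = self._grid(idx, rng, cells)
        grid["value"] = 1.0
        with pytest.raises(ValueError, match="variance"):
            gridded_correlation(chron, grid, months=[("prev", 12)], n_boot=50)

    def test_span_mismatch_rejected(self, rng):
        chron, idx = self._chron(rng)
        cells = {"short": (-20.0, -64.0, rng.standard_normal(len(idx) + 3))}
        grid = self._grid(idx, rng, cells)
        grid = grid[grid.year >= 1975]
        with pytest.raises(ValueError, match="cover"):
            gridded_correlation(chron, grid, months=[("prev", 12)], n_boot=50)
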