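import numpy as np
import pandas as pd
import pytest

import cordmap as cm
from cordmap.birthdating import (
    CumulativeBirthModel,
    logistic_4pl,
    logistic_5pl,
)
from cordmap.synthetic import BirthWaveModel, WaveParams, labeling_probability


def _panel_from_fractions(frac_by_day_litter, family="f", n=1000):
    """Build an embryo-level panel realizing exact litter fractions."""
    rows = []
    for (day, litter), frac in frac_by_day_litter.items():
        rows.append((litter, f"{litter}_E1", day, family, int(round(frac * n)), n))
    return pd.DataFrame(
        rows, columns=["litter", "embryo", "pulse_day", "family", "n_colabeled", "n_total"]
    )


class TestFractionsAndLitterPoints:
    @pytest.mark.parametrize(
        "co,total,expected", [(5, 20, 0.25), (0, 17, 0.0), (17, 17, 1.0)]
    )
    def test_colabel_fraction(self, co, total, expected):
        assert cm.colabel_fraction(co, total) == expected

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            cm.colabel_fraction(0, 0)

    def test_litter_mean_of_embryos(self):
        panel = pd.DataFrame(
            {
                "litter": ["L1", "L1", "L2"],
                "embryo": ["L1_E1", "L1_E2", "L2_E1"],
                "pulse_day": [11.0, 11.0, 11.0],
                "family": ["f", "f", "f"],
                "n_colabeled": [20, 40, 30],
                "n_total": [100, 100, 100],
            }
        )
        pts = cm.litter_points(panel)
        got = pts.set_index("litter")["fraction"]
        assert got["L1"] == pytest.approx(0.3)  # mean of 0.2, 0.4
        assert got["L2"] == pytest.approx(0.3)  # single embryo

    def test_litter_points_match_brute_force_groupby(self, pulse_panel):
        pts = cm.litter_points(pulse_panel)
        df = pulse_panel.assign(f=pulse_panel.n_colabeled / pulse_panel.n_total)
        for row in pts.sample(25, random_state=0).itertuples():
            sub = df[
                (df.family == row.family)
                & (df.pulse_day == row.pulse_day)
                & (df.litter == row.litter)
            ]
            assert row.fraction == pytest.approx(sub.f.mean())

    def test_zero_total_embryo_dropped_with_warning(self):
        panel = _panel_from_fractions({(11.0, "L1"): 0.5, (12.0, "L2"): 0.9})
        panel.loc[len(panel)] = ["L3", "L3_E1", 11.0, "f", 0, 0]
        with pytest.warns(UserWarning, match="n_total=0"):
            pts = cm.litter_points(panel)
        assert "L3" not in set(pts["litter"])


class TestBirthWavePercentages:
    def test_normalization_example(self):
        panel = _panel_from_fractions(
            {(11.0, "L1"): 0.1, (11.5, "L2"): 0.3, (12.0, "L3"): 0.1}
        )
        p = cm.birth_wave_percentages(cm.litter_points(panel), "f")
        assert np.allclose(p.to_numpy(), [20, 60, 20])
        assert p.sum() == pytest.approx(100.0)

    def test_single_nonzero_timepoint(self):
        panel = _panel_from_fractions({(11.0, "L1"): 0.0, (12.0, "L2"): 0.4})
        p = cm.birth_wave_percentages(cm.litter_points(panel), "f")
        assert p[12.0] == pytest.approx(100.0)

    def test_all_zero_rejected(self):
        panel = _panel_from_fractions({(11.0, "L1"): 0.0, (12.0, "L2"): 0.0})
        with pytest.raises(ValueError, match="all-zero"):
            cm.birth_wave_percentages(cm.litter_points(panel), "f")

    def test_matches_closed_form_wave_profile(self):
        """Large-count simulated percentages track the Gaussian interval
        probabilities normalized to 100."""
        wave = WaveParams(mean=11.5, sd=0.25)
        model = BirthWaveModel(
            families={"f": wave}, embryos_per_litter=3, neurons_per_embryo=20000
        )
        days = list(cm.synthetic.DEFAULT_PULSE_DAYS)
        panel = cm.simulate_pulse_panel(model, days, n_litters_per_time=4, seed=2)
        p = cm.birth_wave_percentages(cm.litter_points(panel), "f")
        probs = np.array([labeling_probability(wave, t, 0.5) for t in days])
        oracle = 100 * probs / probs.sum()
        assert np.max(np.abs(p.to_numpy() - oracle)) < 3.0


class TestCumulativeCurve:
    def test_identical_litters_running_sum(self):
        panel = _panel_from_fractions(
            {
                (11.0, "L1"): 0.2, (11.0, "L2"): 0.2,
                (12.0, "L3"): 0.6, (12.0, "L4"): 0.6,
                (13.0, "L5"): 0.2, (13.0, "L6"): 0.2,
            }
        )
        curve = cm.cumulative_curve(cm.litter_points(panel), "f")
        assert np.allclose(curve.means, [20.0, 80.0, 100.0])
        assert np.allclose(curve.sds, 0.0)

    def test_final_timepoint_mean_is_100(self, pulse_panel):
        lt = cm.litter_points(pulse_panel)
        for family in pulse_panel["family"].unique():
            curve = cm.cumulative_curve(lt, family)
            assert curve.means[-1] == pytest.approx(100.0, abs=1e-9)

    def test_cumulative_means_non_decreasing(self, pulse_panel):
        lt = cm.litter_points(pulse_panel)
        for family in pulse_panel["family"].unique():
            curve = cm.cumulative_curve(lt, family)
            assert (np.diff(curve.means) >= -1e-9).all()

    def test_per_timepoint_sd_from_current_litters_only(self):
        """The prior-timepoint addend is a constant, so the cumulative sd at t
        equals the sd of the normalized litter values at t."""
        rng = np.random.default_rng(4)
        fracs = {}
        for day in (11.0, 11.5, 12.0, 12.5):
            for i in range(4):
                fracs[(day, f"L{day}_{i}")] = float(rng.uniform(0.05, 0.5))
        panel = _panel_from_fractions(fracs, n=10000)
        lt = cm.litter_points(panel)
        curve = cm.cumulative_curve(lt, "f")
        means = lt.groupby("pulse_day")["fraction"].mean()
        total = means.sum()
        for k, day in enumerate(curve.pulse_days):
            vals = 100 * lt.loc[lt.pulse_day == day, "fraction"] / total
            assert curve.sds[k] == pytest.approx(vals.std(ddof=1))

    def test_scale_invariance(self, pulse_panel):
        scaled = pulse_panel.copy()
        scaled["n_colabeled"] *= 7
        scaled["n_total"] *= 7
        c1 = cm.cumulative_curve(cm.litter_points(pulse_panel), "dILB2")
        c2 = cm.cumulative_curve(cm.litter_points(scaled), "dILB2")
        assert np.allclose(c1.means, c2.means)
        assert np.allclose(
            c1.litter_values["cumulative_pct"], c2.litter_values["cumulative_pct"]
        )


def _noiseless_curve_from_4pl(bottom, top, ec50, hill, days):
    rows = []
    for i, d in enumerate(days):
        for lit in ("L1", "L2"):
            rows.append(
                {"litter": f"{lit}@{d}", "pulse_day": d, "family": "f",
                 "cumulative_pct": logistic_4pl(np.array([d]), bottom, top, ec50, hill)[0]}
            )
    df = pd.DataFrame(rows)
    days_arr = np.asarray(days, dtype=float)
    stats = df.groupby("pulse_day")["cumulative_pct"].agg(["mean", "std"])
    return cm.CumulativeCurve(
        family="f",
        pulse_days=days_arr,
        litter_values=df[["litter", "pulse_day", "cumulative_pct"]],
        means=stats["mean"].to_numpy(),
        sds=stats["std"].fillna(0).to_numpy(),
        percentages=np.zeros(len(days_arr)),
    )


class TestSigmoidFits:
    days = (10.5, 11.0, 11.5, 12.0, 12.5, 13.0, 13.5)

    def test_4pl_exact_recovery_on_noiseless_data(self):
        curve = _noiseless_curve_from_4pl(0.0, 100.0, 11.75, 20.0, self.days)
        res = cm.fit_4pl(curve)
        assert res.params["EC50"] == pytest.approx(11.75, abs=1e-4)
        assert res.half_birthdate == pytest.approx(11.75, abs=1e-4)

    def test_flat_curve_flagged_degenerate(self):
        rows = [
            {"litter": f"L{d}", "pulse_day": d, "family": "f", "cumulative_pct": 100.0}
            for d in self.days
        ]
        df = pd.DataFrame(rows)
        curve = cm.CumulativeCurve(
            family="f", pulse_days=np.array(self.days),
            litter_values=df, means=np.full(len(self.days), 100.0),
            sds=np.zeros(len(self.days)), percentages=np.zeros(len(self.days)),
        )
        with pytest.warns(UserWarning, match="degenerate"):
            res = cm.fit_4pl(curve)
        assert res.degenerate

    def test_5pl_reduces_to_4pl_when_symmetric(self):
        curve = _noiseless_curve_from_4pl(0.0, 100.0, 11.9, 12.0, self.days)
        res4 = cm.fit_4pl(curve)
        res5 = cm.fit_5pl(curve)
        assert res5.half_birthdate == pytest.approx(res4.half_birthdate, abs=1e-3)

    def test_5pl_half_birthdate_matches_root_of_generator(self):
        bottom, top, xb, hill, s = 0.0, 100.0, 11.6, 15.0, 2.0
        rows = []
        for d in self.days:
            y = logistic_5pl(np.array([d]), bottom, top, xb, hill, s)[0]
            for lit in ("L1", "L2"):
                rows.append({"litter": f"{lit}@{d}", "pulse_day": d, "family": "f",
                             "cumulative_pct": y})
        df = pd.DataFrame(rows)
        stats = df.groupby("pulse_day")["cumulative_pct"].agg(["mean", "std"])
        curve = cm.CumulativeCurve(
            family="f", pulse_days=np.array(self.days), litter_values=df,
            means=stats["mean"].to_numpy(), sds=stats["std"].fillna(0).to_numpy(),
            percentages=np.zeros(len(self.days)),
        )
        res = cm.fit_5pl(curve)
        # independent root of the generating curve at half-span
        from scipy.optimize import brentq

        root = brentq(
            lambda x: logistic_5pl(np.array([x]), bottom, top, xb, hill, s)[0] - 50.0,
            10.0, 14.0, xtol=1e-12,
        )
        assert res.half_birthdate == pytest.approx(root, abs=1e-4)

    def test_auto_selects_5pl_for_early_rise(self):
        """A curve nearly complete by the second timepoint (negligible
        slow-growth phase) triggers the asymmetric fallback."""
        rng = np.random.default_rng(0)
        rows = []
        for d in self.days:
            y = logistic_5pl(np.array([d]), 0.0, 100.0, 6.35, 9.0, 15.0)[0]
            for lit in ("L1", "L2", "L3"):
                rows.append(
                    {"litter": f"{lit}@{d}", "embryo": f"{lit}@{d}_E1",
                     "pulse_day": d, "family": "f",
                     "n_colabeled": 0, "n_total": 1,
                     "cumulative_pct": y + rng.normal(0, 0.5)}
                )
        df = pd.DataFrame(rows)
        assert df[df.pulse_day == self.days[1]]["cumulative_pct"].mean() >= 88
        stats = df.groupby("pulse_day")["cumulative_pct"].agg(["mean", "std"])
        curve = cm.CumulativeCurve(
            family="f", pulse_days=np.array(self.days),
            litter_values=df[["litter", "pulse_day", "cumulative_pct"]],
            means=stats["mean"].to_numpy(), sds=stats["std"].to_numpy(),
            percentages=np.zeros(len(self.days)),
        )
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", UserWarning)  # 4PL EC50 pins at the bound
            fit4, fit5 = cm.fit_4pl(curve), cm.fit_5pl(curve)
        from cordmap.birthdating import _prefer_5pl

        assert _prefer_5pl(fit4, fit5, curve.pulse_days)


class TestHalfBirthdates:
    def test_order_recovery_and_identical_panels(self):
        waves = {"early": WaveParams(11.5, 0.3), "late": WaveParams(12.5, 0.3)}
        model = BirthWaveModel(families=waves)
        panel = cm.simulate_pulse_panel(model, seed=8)
        table = cm.half_birthdates(panel).set_index("family")
        assert table.loc["early", "half_birthdate"] < table.loc["late", "half_birthdate"]
        # duplicating a family's records under a new name gives the same fit
        dup = panel[panel.family == "early"].assign(family="early_copy")
        table2 = cm.half_birthdates(pd.concat([panel, dup])).set_index("family")
        assert table2.loc["early", "half_birthdate"] == pytest.approx(
            table2.loc["early_copy", "half_birthdate"], abs=1e-9
        )

    def test_missing_timepoint_still_fits(self, pulse_panel):
        reduced = pulse_panel[pulse_panel.pulse_day != 12.0]
        table = cm.half_birthdates(reduced)
        assert (table["error"] == "").all()

    def test_model_object_front_door(self, pulse_panel):
        res = CumulativeBirthModel(pulse_panel, "dILB2").fit()
        assert res.model in ("4pl", "5pl")
        assert "half-birthdate" in res.summary()
        assert np.isfinite(res.half_birthdate)
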