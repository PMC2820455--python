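"""Normalization and replicate t-statistics, including the published-row audit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tauscreen.published import published_hit_rows
from tauscreen.stats import (
    NoControlWellsError,
    normalize_plate,
    normalize_screen,
    p_two_tailed_df2,
    recompute_table_pvalues,
    summarize_sirna,
    t_test_vs_control,
)


def make_plate(values, roles, plate_id="P01r1", total=None):
    n = len(values)
    return pd.DataFrame(
        {
            "plate_id": plate_id,
            "well": [f"A{i + 1:02d}" for i in range(n)],
            "replicate": 1,
            "role": roles,
            "gene": ["NS" if r == "non_silencing" else f"G{i}" for i, r in enumerate(roles)],
            "sirna_id": ["NS" if r == "non_silencing" else f"G{i}_s1" for i, r in enumerate(roles)],
            "cell_count": 100,
            "phospho_mean": values,
            "total_mean": total if total is not None else values,
        }
    )


class TestNormalization:
    def test_ns_wells_average_to_one_exactly(self):
        plate = make_plate([90.0, 100.0, 110.0, 55.0], ["non_silencing"] * 3 + ["target"])
        norm = normalize_plate(plate)
        ns = norm[norm["role"] == "non_silencing"]
        assert abs(ns["phospho_norm"].mean() - 1.0) < 1e-12
        assert abs(ns["total_norm"].mean() - 1.0) < 1e-12

    def test_simple_arithmetic(self):
        plate = make_plate(
            [100.0, 100.0, 100.0, 100.0],
            ["non_silencing"] * 3 + ["target"],
            total=[200.0, 200.0, 200.0, 100.0],
        )
        row = normalize_plate(plate).iloc[-1]
        assert row["phospho_norm"] == pytest.approx(1.0)
        assert row["total_norm"] == pytest.approx(0.5)
        assert row["ratio"] == pytest.approx(2.0)

    def test_no_controls_rejected(self):
        plate = make_plate([1.0, 2.0], ["target", "target"])
        with pytest.raises(NoControlWellsError):
            normalize_plate(plate)

    def test_scale_invariance(self):
        plate = make_plate(
            [90.0, 100.0, 110.0, 55.0, 70.0], ["non_silencing"] * 3 + ["target"] * 2
        )
        base = normalize_plate(plate)
        for k in (0.001, 7.3, 1e6):
            scaled = plate.copy()
            scaled["phospho_mean"] *= k
            scaled["total_mean"] *= k
            out = normalize_plate(scaled)
            for col in ("phospho_norm", "total_norm", "ratio"):
                assert np.allclose(out[col], base[col], rtol=1e-12)

    def test_idempotence(self):
        # feeding normalized readouts back through changes nothing
        plate = make_plate([90.0, 100.0, 110.0, 55.0], ["non_silencing"] * 3 + ["target"])
        once = normalize_plate(plate)
        again = once.drop(columns=["phospho_norm", "total_norm", "ratio"]).assign(
            phospho_mean=once["phospho_norm"], total_mean=once["total_norm"]
        )
        twice = normalize_plate(again)
        assert np.allclose(twice["phospho_norm"], once["phospho_norm"], rtol=1e-12)
        assert np.allclose(twice["total_norm"], once["total_norm"], rtol=1e-12)

    def test_min_cells_floor_drops_wells(self):
        plate = make_plate([90.0, 100.0, 110.0, 55.0], ["non_silencing"] * 3 + ["target"])
        plate.loc[3, "cell_count"] = 5
        norm = normalize_plate(plate, min_cells=10)
        assert (norm["role"] == "target").sum() == 0

    def test_normalize_screen_is_per_plate(self):
        p1 = make_plate([100.0] * 3 + [50.0], ["non_silencing"] * 3 + ["target"], "P01r1")
        p2 = make_plate([400.0] * 3 + [200.0], ["non_silencing"] * 3 + ["target"], "P01r2")
        out = normalize_screen(pd.concat([p1, p2], ignore_index=True))
        targets = out[out["role"] == "target"]
        assert np.allclose(targets["phospho_norm"], 0.5)


class TestTTest:
    @pytest.mark.parametrize(
        "avg,sd,p_published",
        [
            (0.672, 0.044, 0.006),  # strong phospho knockdown
            (1.424, 0.024, 0.001),  # strong ratio increase
            (0.848, 0.104, 0.127),  # non-significant total-tau change
        ],
    )
    def test_reproduces_published_pvalues(self, avg, sd, p_published):
        assert t_test_vs_control(avg, sd, 3) == pytest.approx(p_published, abs=5e-4)

    def test_null_average_gives_p_one(self):
        assert t_test_vs_control(1.0, 0.123, 3) == 1.0

    def test_zero_sd_nonnull_gives_smallest_positive(self):
        p = t_test_vs_control(0.672, 0.0, 3)
        assert 0 < p < 1e-300

    def test_too_few_replicates_error(self):
        with pytest.raises(ValueError):
            t_test_vs_control(0.9, 0.1, 1)

    def test_closed_form_agrees_with_t_distribution(self):
        t = np.linspace(-30, 30, 1201)
        general = 2 * sps.t.sf(np.abs(t), df=2)
        assert np.max(np.abs(p_two_tailed_df2(t) - general)) < 1e-12

    @given(d=st.floats(1e-6, 5), sd=st.floats(1e-6, 2))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_p_symmetric_in_effect_direction(self, d, sd):
        assert t_test_vs_control(1 + d, sd, 3) == pytest.approx(
            t_test_vs_control(1 - d, sd, 3), rel=1e-9
        )

    @given(st.tuples(st.floats(0.001, 2), st.floats(0.001, 2)), st.floats(0.01, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_p_monotone_in_effect_size(self, deltas, sd):
        lo, hi = sorted(deltas)
        if hi - lo < 1e-9:
            return
        assert t_test_vs_control(1 + hi, sd, 3) < t_test_vs_control(1 + lo, sd, 3)


class TestSummaries:
    def make_norm(self, phospho, total=None, ratio=None):
        phospho = list(phospho)
        total = list(total) if total is not None else phospho
        return pd.DataFrame(
            {
                "gene": "G",
                "sirna_id": "G_s1",
                "cell_count": [100] * len(phospho),
                "phospho_norm": phospho,
                "total_norm": total,
                "ratio": ratio if ratio is not None else np.array(phospho) / np.array(total),
            }
        )

    def test_hand_arithmetic(self):
        rec = summarize_sirna(self.make_norm([0.9, 1.0, 1.1]))
        assert rec["phospho_avg"] == pytest.approx(1.0)
        assert rec["phospho_sd"] == pytest.approx(0.1)

    def test_degenerate_replicates(self):
        rec = summarize_sirna(self.make_norm([0.672, 0.672, 0.672]))
        assert rec["phospho_sd"] == 0.0
        assert rec["phospho_p"] < 1e-300

    def test_single_replicate_gives_missing_p(self):
        rec = summarize_sirna(self.make_norm([0.9]))
        assert rec["phospho_n"] == 1
        assert np.isnan(rec["phospho_p"]) and np.isnan(rec["phospho_sd"])

    def test_triplicate_sd_tracks_well_cv(self):
        # Monte Carlo: with multiplicative well CV 0.05, the mean sample SD
        # of triplicates is c4 * 0.05 * avg (normal-order correction ~0.886)
        rng = np.random.default_rng(99)
        sds = []
        for _ in range(1000):
            vals = rng.lognormal(mean=0.0, sigma=0.05, size=3)
            sds.append(summarize_sirna(self.make_norm(vals))["phospho_sd"])
        assert np.mean(sds) == pytest.approx(0.886 * 0.05, rel=0.05)


class TestPublishedRowAudit:
    def test_all_rows_reproduce_within_rounding(self):
        audit = recompute_table_pvalues(published_hit_rows())
        ok = audit[~audit["degenerate"]]
        assert len(ok) == 27 * 3
        # printed p-values come back within what 3-decimal input rounding allows
        assert ok["dev_beyond_rounding"].max() <= 0.002
        # and the vast majority agree to better than 0.002 outright
        assert (ok["abs_dev"] <= 0.002).mean() > 0.97
        assert ok["abs_dev"].max() < 0.0035

    def test_specific_row_values(self):
        audit = recompute_table_pvalues(published_hit_rows())
        dyrk1a_total = audit[(audit["gene"] == "DYRK1A") & (audit["readout"] == "total")]
        assert dyrk1a_total["p_recomputed"].iloc[0] == pytest.approx(0.127, abs=5e-4)

    def test_zero_sd_rows_flagged_and_excluded(self):
        row = pd.DataFrame(
            [
                {
                    "gene": "X",
                    "phospho_avg": 0.9,
                    "phospho_sd": 0.0,
                    "phospho_p": 0.01,
                    "total_avg": 1.0,
                    "total_sd": 0.1,
                    "total_p": 1.0,
                    "ratio_avg": 0.9,
                    "ratio_sd": 0.1,
                    "ratio_p": 0.2,
                }
            ]
        )
        audit = recompute_table_pvalues(row)
        assert audit.loc[audit["readout"] == "phospho", "degenerate"].iloc[0]
        assert np.isnan(audit.loc[audit["readout"] == "phospho", "abs_dev"].iloc[0])
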