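"""Panel chain: calibration, imputation, detection filter, ΔΔCt calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirbayes import (
    PanelSpec,
    calibrate_interplate,
    call_enrichment,
    enrichment_pipeline,
    filter_detected,
    global_mean_normalize,
    impute_undetected,
    simulate_panels,
)
from mirbayes.tables import CtTable

from conftest import make_ct_table


class TestCalibration:
    def test_hand_example_two_plates(self):
        # IPC means 20.0 and 21.0 -> grand mean 20.5, plate2 factor -0.5
        table = make_ct_table(
            [
                ("s1", "UniSp3", "p1", 20.0, True),
                ("s1", "m1", "p1", 25.0, True),
                ("s2", "UniSp3", "p2", 21.0, True),
                ("s2", "m1", "p2", 30.0, True),
            ]
        )
        out = calibrate_interplate(table)
        ct = out.data.set_index(["sample_id", "mirna_id"])["ct"]
        assert ct[("s2", "m1")] == pytest.approx(29.5, abs=1e-12)
        assert ct[("s1", "m1")] == pytest.approx(25.5, abs=1e-12)
        ipc = out.data[out.data["mirna_id"] == "UniSp3"]
        assert ipc.groupby("plate_id")["ct"].mean().nunique() == 1

    def test_equal_ipc_means_no_change(self):
        table = make_ct_table(
            [
                ("s1", "UniSp3", "p1", 20.0, True),
                ("s1", "m1", "p1", 25.0, True),
                ("s2", "UniSp3", "p2", 20.0, True),
                ("s2", "m1", "p2", 30.0, True),
            ]
        )
        out = calibrate_interplate(table)
        pd.testing.assert_series_equal(out.data["ct"], table.data["ct"])

    def test_single_plate_unchanged(self):
        table = make_ct_table(
            [("s1", "UniSp3", "p1", 20.0, True), ("s1", "m1", "p1", 25.0, True)]
        )
        out = calibrate_interplate(table)
        pd.testing.assert_series_equal(out.data["ct"], table.data["ct"])

    def test_plate_without_ipc_named_in_error(self):
        table = make_ct_table(
            [
                ("s1", "UniSp3", "p1", 20.0, True),
                ("s2", "m1", "bad_plate", 30.0, True),
            ]
        )
        with pytest.raises(ValueError, match="bad_plate"):
            calibrate_interplate(table)


class TestImputeAndFilter:
    def test_undetected_becomes_ceiling(self):
        table = make_ct_table(
            [("s1", "m1", "p1", np.nan, False), ("s1", "m2", "p1", 35.0, True)]
        )
        out = impute_undetected(table)
        df = out.data.set_index("mirna_id")
        assert df.loc["m1", "ct"] == 40.0 and df.loc["m1", "imputed"]
        assert df.loc["m2", "ct"] == 35.0 and not df.loc["m2", "imputed"]

    def test_detection_fraction_boundary(self):
        rows = []
        for i in range(6):
            rows.append((f"s{i}", "keep", "p1", 30.0 if i < 4 else np.nan, i < 4))
            rows.append((f"s{i}", "drop", "p1", 30.0 if i < 3 else np.nan, i < 3))
        out = filter_detected(make_ct_table(rows))
        assert list(out.mirnas) == ["keep"]  # 4/6 = 0.667 kept, 3/6 = 0.5 dropped

    def test_per_sample_variant_drops_incomplete_samples(self):
        rows = [("good", f"m{i}", "p1", 30.0, True) for i in range(3)]
        rows += [("bad", f"m{i}", "p1", np.nan, False) for i in range(3)]
        out = filter_detected(make_ct_table(rows), per_sample=True)
        assert list(out.samples) == ["good"]

    def test_empty_table_rejected(self):
        table = make_ct_table([("s1", "UniSp3", "p1", 20.0, True)])
        with pytest.raises(ValueError, match="empty"):
            filter_detected(table)


class TestNormalization:
    def test_hand_example(self):
        table = make_ct_table(
            [("s1", m, "p1", ct, True) for m, ct in [("a", 30.0), ("b", 32.0), ("c", 34.0)]]
        )
        dct = global_mean_normalize(table)
        assert list(dct.loc["s1"]) == [-2.0, 0.0, 2.0]

    def test_constant_sample_all_zero(self):
        table = make_ct_table(
            [("s1", m, "p1", 28.0, True) for m in ("a", "b", "c")]
        )
        assert (global_mean_normalize(table) == 0).all().all()

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        cts = rng.uniform(25, 35, 5)
        t1 = make_ct_table(
            [("s1", f"m{i}", "p1", ct, True) for i, ct in enumerate(cts)]
        )
        t2 = make_ct_table(
            [("s1", f"m{i}", "p1", ct + 3.7, True) for i, ct in enumerate(cts)]
        )
        pd.testing.assert_frame_equal(
            global_mean_normalize(t1), global_mean_normalize(t2)
        )


class TestEnrichmentCall:
    def test_hand_example_with_welch_oracle(self):
        cap = pd.DataFrame({"m1": [-0.9, -1.0, -1.1]})
        scr = pd.DataFrame({"m1": [0.1, 0.0, -0.1]})
        res = call_enrichment(cap, scr).iloc[0]
        assert res["ddct"] == pytest.approx(-1.0, abs=1e-12)
        assert res["fold_change"] == pytest.approx(2.0, abs=1e-12)
        # independent Welch computation from first principles
        va, vb = cap["m1"].var(ddof=1), scr["m1"].var(ddof=1)
        se = np.sqrt(va / 3 + vb / 3)
        t = (cap["m1"].mean() - scr["m1"].mean()) / se
        df = (va / 3 + vb / 3) ** 2 / (
            (va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2
        )
        p = 2 * stats.t.sf(abs(t), df)
        assert res["p_value"] == pytest.approx(p, abs=1e-12)
        assert res["enriched"]

    def test_identical_arms_not_enriched(self):
        arm = pd.DataFrame({"m1": [0.5, 0.6, 0.4]})
        res = call_enrichment(arm, arm.copy()).iloc[0]
        assert res["fold_change"] == pytest.approx(1.0)
        assert not res["enriched"]

    def test_zero_variance_degenerate_cases(self):
        same = pd.DataFrame({"m1": [1.0, 1.0, 1.0]})
        other = pd.DataFrame({"m1": [0.0, 0.0, 0.0]})
        res_eq = call_enrichment(same, same.copy()).iloc[0]
        assert res_eq["p_value"] == 1.0
        res_ne = call_enrichment(other, same).iloc[0]
        assert res_ne["p_value"] == 0.0 and res_ne["zero_variance_warning"]

    def test_fold_change_two_routes_agree(self, rng):
        cap = pd.DataFrame(rng.normal(0, 1, (3, 8)), columns=[f"m{i}" for i in range(8)])
        scr = pd.DataFrame(rng.normal(1, 1, (3, 8)), columns=cap.columns)
        res = call_enrichment(cap, scr).set_index("mirna_id")
        # route 2: ratio of per-arm geometric means of 2^-ΔCt
        geo = lambda df: np.exp2(-df.mean(axis=0))
        alt = geo(cap) / geo(scr)
        assert np.allclose(res["fold_change"], alt[res.index], atol=1e-10, rtol=0)

    def test_sorted_by_fold_change(self, rng):
        cap = pd.DataFrame(rng.normal(0, 1, (3, 6)), columns=list("abcdef"))
        scr = pd.DataFrame(rng.normal(0, 1, (3, 6)), columns=list("abcdef"))
        fc = call_enrichment(cap, scr)["fold_change"].to_numpy()
        assert (np.diff(fc) <= 0).all()


class TestPipeline:
    def test_plate_shift_invariance_end_to_end(self, small_panels):
        """Adding a constant to one plate's wells and its IPC must not change
        the final enrichment results once calibration is applied."""
        spec, capture, scramble = small_panels
        shifted = capture.copy()
        plate = shifted.data["plate_id"].iloc[0]
        on = (shifted.data["plate_id"] == plate) & shifted.data["detected"]
        shifted.data.loc[on, "ct"] += 2.5
        base = enrichment_pipeline(capture, scramble).results
        moved = enrichment_pipeline(shifted, scramble).results
        pd.testing.assert_frame_equal(base, moved, atol=1e-9, rtol=0)

    def test_spikes_recovered(self, small_panels):
        spec, capture, scramble = small_panels
        summary = enrichment_pipeline(capture, scramble)
        res = summary.results.set_index("mirna_id")
        for m in spec.enriched_set:
            assert res.loc[m, "enriched"], m
        null = res.drop(index=list(spec.enriched_set))
        assert (~null["enriched"]).mean() >= 0.95

    def test_single_spike_fold_change_band(self):
        """One 3-cycle spike must come out near 8-fold (within noise band)."""
        spec = PanelSpec(n_mirnas=300, present_fraction=0.9, noise_sd=0.1, seed=21)
        spec.enriched_set = {"hsa-miR-s0005": 3.0}
        capture, scramble = simulate_panels(spec)
        res = enrichment_pipeline(capture, scramble).results.set_index("mirna_id")
        assert 6.0 <= res.loc["hsa-miR-s0005", "fold_change"] <= 10.7
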