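"""Normalization, dispersion, NB Wald fit (vs. grid-search oracle), BH, gating."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import barsense as bs
from barsense.design import SampleSheet
from barsense.diff import (
    Contrast,
    DiffError,
    ResponseModel,
    adjust_bh,
    dose_response_table,
    estimate_dispersion,
    gate_significance,
    heatmap_matrix,
    normalize,
    size_factors,
    wald_test,
)
from barsense.quantify import CountMatrix, collapse_to_sensors
from barsense.simulate import Effect, EffectSpec, simulate_counts


def single_tag_panel(n_sensors=8, seed=0):
    """Panel variant with one tag per sensor (and a 4-tag control), so the
    simulated tag dispersion IS the sensor-level dispersion."""
    from barsense.panel import BarcodeTag, Sensor, SensorPanel, generate_tag_set

    rng = np.random.default_rng(seed)
    seqs = generate_tag_set(n_sensors + 4, 10, rng)
    sensors = [
        Sensor(f"S{i}", "MAPK & IEG response", "synthetic TFBS",
               [BarcodeTag(f"S{i}_bc1", seqs[i], f"S{i}")])
        for i in range(n_sensors)
    ]
    ctrl = Sensor("MLPmin", "control", "control",
                  [BarcodeTag(f"MLPmin_bc{j+1}", seqs[n_sensors + j], "MLPmin") for j in range(4)])
    return SensorPanel(tag_length=10, flank_5p="ACGTACGATCGT", flank_3p="TCAGGCATTAGC",
                       sensors=sensors + [ctrl])


class TestSizeFactors:
    def test_identical_wells_give_unity(self):
        tab = pd.DataFrame({"w1": [100, 200, 150, 120], "w2": [100, 200, 150, 120]})
        s = size_factors(tab)
        assert np.allclose(s.values, 1.0)

    def test_two_well_arithmetic(self):
        # geometric means 100 and 400 -> grand geomean 200 -> s = (0.5, 2.0)
        tab = pd.DataFrame({"w1": [100, 100, 100, 100], "w2": [400, 400, 400, 400]})
        s = size_factors(tab)
        assert s.values["w1"] == pytest.approx(0.5)
        assert s.values["w2"] == pytest.approx(2.0)

    def test_anchoring_invariant(self, default_panel, small_design):
        cm, _ = simulate_counts(default_panel, small_design, EffectSpec(), seed=41)
        _, ctrl = collapse_to_sensors(cm, default_panel)
        s = size_factors(ctrl)
        assert np.exp(np.log(s.values).mean()) == pytest.approx(1.0)

    def test_all_zero_well_is_error(self):
        tab = pd.DataFrame({"w1": [100, 100, 100, 100], "w2": [0, 0, 0, 0]})
        with pytest.raises(DiffError, match="w2"):
            size_factors(tab)

    def test_recovery_at_high_depth(self, default_panel):
        """Counting-noise-limited regime: estimated s_j within 5% RMS of truth."""
        sheet = bs.build_design(genotypes=("control",), treatments=(), doses=(),
                                timepoints=(4,), n_replicates=16, seed=42)
        cm, truth = simulate_counts(
            default_panel, sheet, EffectSpec(), seed=43,
            baselines=100_000 / 23.0, dispersion=0.001,
        )
        assert cm.counts.sum(axis=0).mean() > 5e4  # depth ~1e5 per well
        _, ctrl = collapse_to_sensors(cm, default_panel)
        s = size_factors(ctrl)
        rel = s.values / truth.size_factors - 1.0
        assert np.sqrt((rel**2).mean()) < 0.05


class TestNormalize:
    def test_identity_and_scaling(self):
        df = pd.DataFrame({"w1": [10, 20], "w2": [10, 40]}, index=["a", "b"])
        s = pd.Series({"w1": 1.0, "w2": 2.0})
        out = normalize(df, s)
        assert out["w1"].tolist() == [10, 20]
        assert out["w2"].tolist() == [5, 20]

    def test_zero_column_stays_zero(self):
        df = pd.DataFrame({"w1": [0, 0]}, index=["a", "b"])
        out = normalize(df, pd.Series({"w1": 3.0}))
        assert (out == 0).all().all()

    def test_missing_well_is_error(self):
        df = pd.DataFrame({"w1": [1]}, index=["a"])
        with pytest.raises(DiffError, match="w1"):
            normalize(df, pd.Series({"other": 1.0}))


class TestDispersion:
    def test_poisson_truth_gives_negligible_estimates(self, recovery_design):
        panel = single_tag_panel(12)
        cm, _ = simulate_counts(panel, recovery_design, EffectSpec(), seed=44,
                                baselines=500.0, dispersion=0.0,
                                size_factors={w: 1.0 for w in recovery_design.well_ids})
        scm, _ = collapse_to_sensors(cm, panel)
        # known unit size factors: isolates the estimator from control noise
        s = pd.Series(1.0, index=recovery_design.well_ids)
        disp = estimate_dispersion(scm, s, recovery_design)
        # moments estimates center at 0: many floored, none materially positive
        assert (disp.values <= 0.01).mean() >= 0.9
        assert (disp.values == disp.floor).mean() >= 0.3

    def test_recovery_of_true_dispersion(self, recovery_design):
        panel = single_tag_panel(12)
        medians = []
        for seed in range(20):
            cm, _ = simulate_counts(panel, recovery_design, EffectSpec(), seed=100 + seed,
                                    baselines=500.0, dispersion=0.1)
            scm, ctrl = collapse_to_sensors(cm, panel)
            s = size_factors(ctrl)
            disp = estimate_dispersion(scm, s, recovery_design)
            medians.append(disp.values.drop("MLPmin").median())
        assert 0.05 <= np.median(medians) <= 0.2

    def test_constant_counts_floored(self, small_design):
        panel = single_tag_panel(3)
        idx = [s.sensor_id for s in panel.sensors]
        df = pd.DataFrame(200, index=idx, columns=small_design.well_ids)
        s = pd.Series(1.0, index=small_design.well_ids)
        disp = estimate_dispersion(df, s, small_design)
        assert (disp.values == disp.floor).all()

    def test_zero_mean_sensor_warns_and_floors(self, small_design):
        panel = single_tag_panel(3)
        idx = [s.sensor_id for s in panel.sensors]
        df = pd.DataFrame(100, index=idx, columns=small_design.well_ids)
        df.loc["S0"] = 0
        s = pd.Series(1.0, index=small_design.well_ids)
        with pytest.warns(UserWarning, match="S0"):
            disp = estimate_dispersion(df, s, small_design)
        assert disp.values["S0"] == disp.floor


from oracles import grid_search_mle, textbook_bh


def two_group_sheet(n_num, n_den):
    rows = []
    for i in range(n_den):
        rows.append((f"d{i}", f"IDX{i}", "control", "vehicle", 0.0, "uM", 4, i + 1))
    for i in range(n_num):
        rows.append((f"n{i}", f"JDX{i}", "control", "AMPA", 10.0, "uM", 4, i + 1))
    return SampleSheet(pd.DataFrame(
        rows, columns=["well_id", "sample_index", "genotype", "treatment",
                       "dose", "dose_units", "timepoint_h", "replicate"]))


AMPA_VS_VEH = Contrast("ampa", {"treatment": "AMPA"}, {"treatment": "vehicle"})


class TestWald:
    # small fixed instances: (den counts, num counts, size factors den, num, alpha)
    FIXTURES = [
        ([5, 9, 7], [21, 30, 26], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0], 0.05),
        ([50, 80, 65], [12, 9, 16], [0.8, 1.0, 1.25], [0.9, 1.1, 1.0], 0.1),
        ([200, 230, 180], [210, 190, 250], [1.0, 1.2, 0.9], [1.1, 0.8, 1.0], 0.02),
        ([0, 1, 2], [9, 14, 11], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0], 0.15),
        ([400, 500], [40, 60], [1.0, 1.0], [1.0, 1.0], 0.05),
    ]

    @pytest.mark.parametrize("kd,kn,sd,sn,alpha", FIXTURES)
    def test_mle_matches_grid_search(self, kd, kn, sd, sn, alpha):
        """Iterative MLE equals exhaustive grid search to 3 decimals."""
        sheet = two_group_sheet(len(kn), len(kd))
        idx = ["S1"]
        df = pd.DataFrame([kd + kn], index=idx,
                          columns=[f"d{i}" for i in range(len(kd))] + [f"n{i}" for i in range(len(kn))])
        s = pd.Series(sd + sn, index=df.columns)
        a = pd.Series([alpha], index=idx)
        res = wald_test(df, s, a, AMPA_VS_VEH, sheet)
        _, l_grid = grid_search_mle(np.array(kn, float), np.array(kd, float),
                                    np.array(sn), np.array(sd), alpha)
        assert res["log2fc"].iloc[0] == pytest.approx(l_grid, abs=1e-3)

    def test_identical_groups_null(self):
        sheet = two_group_sheet(3, 3)
        df = pd.DataFrame([[30, 40, 50, 30, 40, 50]], index=["S1"],
                          columns=["d0", "d1", "d2", "n0", "n1", "n2"])
        s = pd.Series(1.0, index=df.columns)
        res = wald_test(df, s, pd.Series([0.05], index=["S1"]), AMPA_VS_VEH, sheet)
        assert res["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert res["p_raw"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_group_pseudocount(self):
        sheet = two_group_sheet(3, 3)
        df = pd.DataFrame([[0, 0, 0, 10, 12, 8]], index=["S1"],
                          columns=["d0", "d1", "d2", "n0", "n1", "n2"])
        s = pd.Series(1.0, index=df.columns)
        res = wald_test(df, s, pd.Series([0.05], index=["S1"]), AMPA_VS_VEH, sheet)
        assert res["zero_pseudocount"].iloc[0]
        assert np.isfinite(res["log2fc"].iloc[0]) and res["log2fc"].iloc[0] > 2

    def test_overlapping_contrast_rejected(self):
        sheet = two_group_sheet(3, 3)
        with pytest.raises(DiffError, match="both groups"):
            Contrast("bad", {}, {"treatment": "vehicle"}).wells(sheet)

    def test_ci_coverage_at_small_n(self, lfc_recovery_run):
        """95% Wald CI covers the true LFC in >= 90% of seeded replicates."""
        assert lfc_recovery_run["covered"].mean() >= 0.90

    def test_median_recovery_error(self, lfc_recovery_run):
        assert np.median(lfc_recovery_run["errors"]) <= 0.15

    def test_normalization_invariance(self, default_panel, small_design):
        """Scaling one well's counts (incl. controls) leaves log2FC nearly
        unchanged; exact in the Poisson limit, O(alpha) shift under NB."""
        effects = EffectSpec([Effect("EGR1p", "AMPA", lmax=2.0, ec50=1.0)])
        cm, _ = simulate_counts(default_panel, small_design, effects, seed=45, baselines=300.0)
        scaled = cm.counts.copy()
        well = small_design.well_ids[0]
        scaled[well] = scaled[well] * 3

        def run(counts):
            scm, ctrl = collapse_to_sensors(CountMatrix(counts=counts, level="tag"), default_panel)
            s = size_factors(ctrl)
            disp = estimate_dispersion(scm, s, small_design)
            return wald_test(scm, s, disp, AMPA_VS_VEH, small_design).set_index("sensor_id")["log2fc"]

        base, mod = run(cm.counts), run(scaled)
        assert np.nanmax(np.abs(base - mod)) < 0.02

    def test_bh_false_discovery_rate_under_global_null(self, default_panel):
        """With every LFC = 0, the per-panel probability of any BH rejection
        at 0.05 stays near the nominal level.  The plug-in moments dispersion
        gives the Wald statistic slightly heavy tails (t-like with the pooled
        residual df), which inflates the far-tail p values that drive BH's
        smallest-rank rejections, so the realized rate sits somewhat above
        0.05 (~0.09 at these settings) rather than at it."""
        design = bs.build_design(genotypes=("control", "cKO"),
                                 treatments=("AMPA", "forskolin"), doses=(10.0,),
                                 timepoints=(4, 24), n_replicates=4, seed=7)
        contrast = Contrast(
            "null", {"treatment": "AMPA", "genotype": "control", "timepoint_h": 4},
            {"treatment": "vehicle", "genotype": "control", "timepoint_h": 4})
        rng = np.random.default_rng(99)
        hits = 0
        n = 200
        for _ in range(n):
            cm, _ = simulate_counts(default_panel, design, EffectSpec(),
                                    seed=int(rng.integers(2**31)),
                                    baselines=500.0, dispersion=0.05)
            scm, ctrl = collapse_to_sensors(cm, default_panel)
            s = size_factors(ctrl)
            disp = estimate_dispersion(scm, s, design)
            res = wald_test(scm, s, disp, contrast, design)
            hits += int((adjust_bh(res["p_raw"]) <= 0.05).any())
        assert hits / n <= 0.13

    def test_rescaling_shift_vanishes_with_overdispersion(self):
        """Rescaling a well (counts and size factor together) changes the
        MLE only through the NB weights mu/(1 + alpha*mu): in the Poisson
        limit the fit is the depth-weighted ratio estimator and legitimately
        moves with a well's depth, while as alpha*mu grows the weights
        saturate at 1/alpha and the estimate becomes scaling-invariant."""
        sheet = two_group_sheet(3, 3)
        df = pd.DataFrame([[30, 44, 52, 61, 70, 83]], index=["S1"],
                          columns=["d0", "d1", "d2", "n0", "n1", "n2"])
        s = pd.Series(1.0, index=df.columns)
        shifts = []
        for alpha in (1e-8, 0.05, 1.0, 5.0):
            a = pd.Series([alpha], index=["S1"])
            base = wald_test(df, s, a, AMPA_VS_VEH, sheet)["log2fc"].iloc[0]
            df2, s2 = df.copy(), s.copy()
            df2["d1"] *= 5
            s2["d1"] *= 5
            mod = wald_test(df2, s2, a, AMPA_VS_VEH, sheet)["log2fc"].iloc[0]
            shifts.append(abs(mod - base))
        assert shifts == sorted(shifts, reverse=True)
        assert shifts[-1] < 1e-3


class TestBH:
    @pytest.mark.parametrize(
        "pvec",
        [
            [0.01, 0.02, 0.03, 0.04],
            [0.5],
            [0.04, 0.001, 0.04, 0.2, 0.9],
            [0.05, 0.05, 0.05],
            [1.0, 0.0001, 0.3, 0.3, 0.3, 0.02],
        ],
    )
    def test_matches_textbook_arithmetic(self, pvec):
        got = adjust_bh(pd.Series(pvec))
        assert np.allclose(got.to_numpy(), textbook_bh(pvec))

    def test_four_equal_spaced_example(self):
        got = adjust_bh(pd.Series([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(got.to_numpy(), 0.04)

    def test_families_adjusted_separately(self):
        p = pd.Series([0.01, 0.02, 0.01, 0.02])
        fam = pd.Series(["a", "a", "b", "b"])
        got = adjust_bh(p, fam)
        assert np.allclose(got.to_numpy(), [0.02, 0.02, 0.02, 0.02])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_adjusted_never_below_raw(self, pvec):
        got = adjust_bh(pd.Series(pvec))
        assert (got.to_numpy() >= np.asarray(pvec) - 1e-12).all()

    def test_nan_passthrough(self):
        got = adjust_bh(pd.Series([0.01, np.nan, 0.03]))
        assert np.isnan(got.iloc[1]) and np.isfinite(got.iloc[0])


class TestGating:
    def make(self, lfc, p_adj):
        return pd.DataFrame({"log2fc": lfc, "p_adj": p_adj})

    def test_below_gate_never_annotated(self):
        out = gate_significance(self.make([1.2], [1e-6]))
        assert out["gated_label"].iloc[0] == ""

    def test_above_gate_star_levels(self):
        out = gate_significance(self.make([2.0, 2.0, -2.0, 1.6], [0.0005, 0.03, 5e-5, 0.2]))
        assert list(out["gated_label"]) == ["***", "*", "****", ""]

    def test_gate_zero_defers_to_p(self):
        out = gate_significance(self.make([0.1], [0.004]), gate=0.0)
        assert out["gated_label"].iloc[0] == "**"

    def test_no_annotation_at_or_below_gate_property(self):
        rng = np.random.default_rng(0)
        out = gate_significance(self.make(rng.normal(0, 2, 200), rng.uniform(0, 0.1, 200)))
        annotated = out[out["gated_label"] != ""]
        assert (annotated["log2fc"].abs() > 1.5).all()


@pytest.fixture(scope="module")
def fitted(default_panel, small_design):
    effects = EffectSpec([Effect("EGR1p", "AMPA", lmax=3.0, ec50=1.0)])
    cm, truth = simulate_counts(default_panel, small_design, effects, seed=46)
    model = ResponseModel.from_quantification(cm, default_panel, small_design)
    res = model.fit([AMPA_VS_VEH])
    return model, res, truth


class TestSummaries:
    def test_dose_response_vehicle_is_one(self, fitted):
        model, _, _ = fitted
        tab = dose_response_table(model.normalized(), model.samples)
        veh = tab[tab["treatment"] == "vehicle"]
        assert np.allclose(veh["mean_response"].dropna(), 1.0)

    def test_dose_response_n_is_replicates(self, fitted):
        model, _, _ = fitted
        tab = dose_response_table(model.normalized(), model.samples)
        assert (tab["n"] == 4).all()

    def test_dose_response_monotone_under_hill(self, default_panel):
        sheet = bs.build_design(genotypes=("control",), treatments=("AMPA",),
                                doses=(0.1, 1.0, 10.0, 100.0), timepoints=(4,), seed=47)
        effects = EffectSpec([Effect(s.sensor_id, "AMPA", lmax=3.0, ec50=1.0)
                              for s in default_panel.pathway_sensors])
        hits = 0
        total = 0
        # moderate technical noise: near-saturating doses differ by little, so
        # strict monotonicity of noisy means needs dispersion well below the
        # plateau gaps (see docs/methods.md)
        for seed in range(30):
            cm, _ = simulate_counts(default_panel, sheet, effects, seed=300 + seed,
                                    dispersion=0.01)
            model = ResponseModel.from_quantification(cm, default_panel, sheet)
            tab = dose_response_table(model.normalized(), sheet)
            amp = tab[(tab["treatment"] == "AMPA") & (tab["sensor_id"] != "IL6p")
                      & (tab["sensor_id"] != "MLPmin")]
            for sid, grp in amp.groupby("sensor_id"):
                vals = grp.sort_values("dose")["mean_response"].to_numpy()
                total += 1
                hits += bool((np.diff(vals) > -1e-9).all())
        assert hits / total >= 0.95

    def test_heatmap_round_trip(self, fitted, tmp_path):
        _, res, _ = fitted
        mat = res.heatmap_matrix()
        assert mat.shape[0] == len(res.table["sensor_id"].unique())
        path = tmp_path / "heat.tsv"
        mat.to_csv(path, sep="\t")
        back = pd.read_csv(path, sep="\t", index_col=0)
        np.testing.assert_allclose(back["ampa"].to_numpy(),
                                   mat["ampa"].to_numpy(), rtol=1e-12)

    def test_heatmap_duplicate_cell_rejected(self, fitted):
        _, res, _ = fitted
        dup = pd.concat([res.table, res.table.iloc[:1]], ignore_index=True)
        with pytest.raises(DiffError, match="duplicate"):
            heatmap_matrix(dup)

    def test_summary_mentions_gate_and_counts(self, fitted):
        _, res, _ = fitted
        text = res.summary()
        assert "|log2FC| > 1.5" in text
        assert "sensors: 23" in text

    def test_estimated_lfc_tracks_truth(self, fitted):
        _, res, truth = fitted
        t = res.table.set_index("sensor_id")
        true_val = truth.lfc_for("EGR1p", "control", "AMPA", 10.0, 4)
        assert t.loc["EGR1p", "log2fc"] == pytest.approx(true_val, abs=0.8)
        assert t.loc["MLPmin", "log2fc"] == pytest.approx(0.0, abs=0.8)
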