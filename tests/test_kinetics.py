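"""Rate fitting, background subtraction and per-plate normalization."""

import dataclasses

import numpy as np
import pytest

from mutscape import kinetics as kin, quantify as q, synthdata as sd
from mutscape.core import Variant

SPEC = sd.MICHAEL_ADDITION_ASSAY


def _expr(conc, below=False):
    return q.ExpressionRecord(variant_id="V", conc_mg_ml=conc, below_lod=below)


class TestInitialRate:
    @pytest.mark.parametrize("rate", [0.1, 1.0, 3.5, 12.0])
    def test_noise_free_exact_recovery(self, rate):
        tr = sd.simulate_trace(SPEC, rate, 0.0, noise_sd=0.0)
        est = kin.initial_rate(tr, SPEC)
        assert est.rate_uM_min == pytest.approx(rate, rel=1e-9)
        assert est.fit_r_squared == pytest.approx(1.0)

    def test_constant_trace_rate_zero(self):
        tr = sd.simulate_trace(SPEC, 0.0, 0.0, noise_sd=0.0)
        est = kin.initial_rate(tr, SPEC)
        assert est.rate_uM_min == 0.0
        assert est.fit_r_squared == 0.0

    def test_window_confined_to_linear_phase(self):
        # substrate exhausted mid-run: the fitted span must end before the plateau
        rate = 25.0   # 500 uM gone in 20 min of the 40 min run
        tr = sd.simulate_trace(SPEC, rate, 0.0, noise_sd=0.0)
        est = kin.initial_rate(tr, SPEC)
        plateau_start = int(np.argmax(tr.absorbance == 0.0))
        assert est.window[1] <= plateau_start
        assert est.rate_uM_min == pytest.approx(rate, rel=1e-9)

    def test_sliding_window_mode_matches_default_on_linear_trace(self):
        tr = sd.simulate_trace(SPEC, 2.0, 0.0, noise_sd=0.0)
        full = kin.initial_rate(tr, SPEC)
        slid = kin.initial_rate(tr, SPEC, window_points=8)
        assert slid.window == (0, 8)          # earliest window wins the R2 tie
        assert slid.rate_uM_min == pytest.approx(full.rate_uM_min, rel=1e-9)

    def test_too_short_trace(self):
        tr = kin.KineticTrace([0.0, 1.0], [1.0, 0.9], 320.0)
        with pytest.raises(ValueError, match="points"):
            kin.initial_rate(tr, SPEC, min_points=8)


class TestBackground:
    def test_mean_of_ev_rates(self):
        evs = [sd.simulate_trace(SPEC, 0.0, b, noise_sd=0.0) for b in (1.0, 3.0)]
        assert kin.background_rate(evs, SPEC) == pytest.approx(2.0, rel=1e-9)

    def test_no_ev_wells_is_an_error(self):
        with pytest.raises(ValueError, match="empty-vector"):
            kin.background_rate([], SPEC)


class TestSpecificActivity:
    def test_rate_equal_to_background_is_zero_activity(self):
        rec = kin.specific_activity(2.0, 2.0, _expr(5.0), SPEC)
        assert rec.state == "zero_activity"
        assert rec.specific_activity == 0.0

    def test_below_lod_wins_regardless_of_rate(self):
        rec = kin.specific_activity(50.0, 0.0, _expr(0.3, below=True), SPEC)
        assert rec.state == "below_lod"
        assert rec.specific_activity is None

    def test_known_specific_activity_recovered(self):
        conc = 4.0
        s_true = 0.002    # U per mg
        rate = sd.well_rate_uM_min(conc, 1.0, s_true, SPEC)
        rec = kin.specific_activity(rate, 0.0, _expr(conc), SPEC)
        assert rec.specific_activity == pytest.approx(s_true, rel=1e-6)


class TestRelativeActivity:
    def test_explicit_division_oracle_on_toy_plate(self, reference):
        # hand-computed: each relative is specific / mean(WT specifics)
        variants = sd.make_collection(reference, 15, 1000, seed=1)[:3]
        truth = sd.TruthTable({
            v.variant_id: sd.VariantTruth(5.0, r)
            for v, r in zip(variants, (0.5, 1.0, 3.5))
        })
        plate = sd.simulate_plate(variants, truth, n_wt_wells=2, n_ev_wells=2,
                                  noise_sd=0.0, seed=0)
        exprs = {v.variant_id: _expr(5.0) for v in variants}
        records = kin.analyze_plate(plate, exprs, wt_conc_mg_ml=5.0)

        spec = plate.spec
        bg = kin.background_rate([t for t in plate.traces if t.role == "ev"], spec)
        wt_specs = []
        for t in plate.traces:
            if t.role == "wt":
                est = kin.initial_rate(t, spec)
                wt_specs.append(kin.specific_activity(
                    est.rate_uM_min, bg, _expr(5.0), spec).specific_activity)
        ref_value = np.mean(wt_specs)
        for rec in records:
            traces = [t for t in plate.traces
                      if t.role == "variant" and t.variant_id == rec.variant_id]
            est = kin.initial_rate(kin.average_traces(traces), spec)
            manual = kin.specific_activity(
                est.rate_uM_min, bg, _expr(5.0), spec).specific_activity / ref_value
            assert rec.relative == pytest.approx(manual, rel=1e-12)

    def test_truth_recovered_noise_free(self, reference):
        variants = sd.make_collection(reference, 15, 1000, seed=1)[:4]
        ratios = (0.5, 1.0, 2.0, 3.5)
        truth = sd.TruthTable({
            v.variant_id: sd.VariantTruth(5.0, r) for v, r in zip(variants, ratios)
        })
        plate = sd.simulate_plate(variants, truth, noise_sd=0.0, seed=0)
        exprs = {v.variant_id: _expr(5.0) for v in variants}
        records = {r.variant_id: r for r in
                   kin.analyze_plate(plate, exprs, wt_conc_mg_ml=5.0)}
        for v, r in zip(variants, ratios):
            if r == 0.0:
                assert records[v.variant_id].state == "zero_activity"
            else:
                assert records[v.variant_id].relative == pytest.approx(r, rel=1e-9)

    def test_no_wild_type_record_fails(self):
        rec = kin.ActivityRecord("V", "P", 1.0, 1.0, "value")
        with pytest.raises(ValueError, match="wild-type"):
            kin.relative_activity([rec], [])

    def test_wt_variant_is_unity(self, reference):
        variants = sd.make_collection(reference, 15, 1000, seed=1)[:1]
        truth = sd.TruthTable({variants[0].variant_id: sd.VariantTruth(5.0, 1.0)})
        plate = sd.simulate_plate(variants, truth, noise_sd=0.0, seed=0)
        exprs = {variants[0].variant_id: _expr(5.0)}
        rec = kin.analyze_plate(plate, exprs, wt_conc_mg_ml=5.0)[0]
        assert rec.relative == pytest.approx(1.0, rel=1e-9)


class TestInvariances:
    def test_extinction_and_path_invariance(self, reference):
        # the AU->concentration conversion cancels in the WT ratio exactly
        variants = sd.make_collection(reference, 15, 1000, seed=2)[:3]
        truth = sd.TruthTable({
            v.variant_id: sd.VariantTruth(5.0, r)
            for v, r in zip(variants, (0.7, 1.3, 2.5))
        })
        exprs = {v.variant_id: _expr(5.0) for v in variants}
        results = []
        for eps, path in ((10.0, 0.29), (3.2, 1.0), (77.7, 0.05)):
            spec = dataclasses.replace(SPEC, extinction_mM_cm=eps, path_length_cm=path)
            plate = sd.simulate_plate(variants, truth, spec=spec, noise_sd=0.0, seed=4)
            recs = kin.analyze_plate(plate, exprs, wt_conc_mg_ml=5.0)
            results.append(sorted((r.variant_id, r.relative) for r in recs))
        for other in results[1:]:
            for (vid_a, rel_a), (vid_b, rel_b) in zip(results[0], other):
                assert vid_a == vid_b
                assert rel_b == pytest.approx(rel_a, rel=1e-12)

    def test_plate_isolation(self, reference):
        # analysing plates in any order yields identical per-record relatives
        variants = sd.make_collection(reference, 15, 1000, seed=2)[:6]
        truth = sd.TruthTable.uniform(variants)
        exprs = {v.variant_id: _expr(5.0) for v in variants}
        p1 = sd.simulate_plate(variants[:3], truth, seed=5, plate_id="P1")
        p2 = sd.simulate_plate(variants[3:], truth, seed=6, plate_id="P2",
                               wt_rate_uM_min=6.0)
        ab = {r.variant_id: r.relative
              for p in (p1, p2) for r in kin.analyze_plate(p, exprs, 5.0)}
        ba = {r.variant_id: r.relative
              for p in (p2, p1) for r in kin.analyze_plate(p, exprs, 5.0)}
        assert ab == ba

    def test_recovery_sweep_median_within_ten_percent(self, reference):
        # the screen's quantitative range: fivefold down to fivefold up
        ratios = (0.2, 0.5, 1.0, 2.0, 3.5, 5.0)
        variants = sd.make_collection(reference, 15, 1000, seed=3)[:len(ratios)]
        recovered = {r: [] for r in ratios}
        for seed in range(5):
            truth = sd.TruthTable({
                v.variant_id: sd.VariantTruth(5.0, r)
                for v, r in zip(variants, ratios)
            })
            plate = sd.simulate_plate(variants, truth, seed=seed)
            exprs = {v.variant_id: _expr(5.0) for v in variants}
            recs = {r.variant_id: r for r in kin.analyze_plate(plate, exprs, 5.0)}
            for v, r in zip(variants, ratios):
                recovered[r].append(recs[v.variant_id].relative)
        for r, vals in recovered.items():
            assert np.median(vals) == pytest.approx(r, rel=0.10)


def test_average_traces_requires_shared_time_base():
    a = kin.KineticTrace(np.arange(10.0), np.ones(10), 320.0)
    b = kin.KineticTrace(np.arange(9.0), np.ones(9), 320.0)
    with pytest.raises(ValueError, match="time base"):
        kin.average_traces([a, b])
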