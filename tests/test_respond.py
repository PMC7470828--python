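"""Dual responder criterion, K+ exclusion and population summaries."""

import numpy as np
import pandas as pd
import pytest

import trpscope as t
from trpscope.core import StimulusProtocol, StimWindow
from trpscope.respond import (
    ResponseTable,
    apply_k_exclusion,
    call_response,
    classify_responses,
    coexpression_classes,
    coexpression_frequencies,
    normalize_to_k,
    responder_fraction,
    responsive_area,
)
from trpscope.roi import RoiSet


def _protocol_mk():
    return StimulusProtocol(
        windows=[StimWindow("M3", 20, 30), StimWindow("K", 45, 55)],
        pre_frames=10,
    )


def _roiset(traces: dict[int, np.ndarray], labels_shape=(64, 64)):
    labels = np.zeros(labels_shape, np.int32)
    for k, rid in enumerate(traces):
        labels[2 * k, :5] = rid
    rs = RoiSet(labels=labels)
    rs.traces = {rid: np.asarray(tr, float) for rid, tr in traces.items()}
    return rs


def _step_trace(T=60, onset=20, amp=10.0, sigma=1.0, seed=0, onset2=45, amp2=10.0):
    rng = np.random.default_rng(seed)
    tr = rng.normal(0, sigma, T)
    tt = np.arange(T, dtype=float)
    tr += amp * np.where(tt >= onset, np.exp(-(tt - onset) / 8), 0)
    if amp2:
        tr += amp2 * np.where(tt >= onset2, np.exp(-(tt - onset2) / 8), 0)
    return tr


class TestCallResponse:
    def test_step_is_responder_with_expected_peak(self):
        tr = _step_trace(amp=10.0, sigma=1.0, seed=1, amp2=0.0)
        call = call_response(tr, (20, 30), (10, 20))
        assert call.is_responder
        assert call.peak_dff == pytest.approx(10.0, rel=0.10)

    def test_null_false_positive_rate_controlled(self):
        """Monte-Carlo under the null: dual criterion fires < 5%."""
        traces = t.gen_traces(1000, 0.0, 30, 60, seed=42)
        hits = sum(
            call_response(tr, (30, 40), (20, 30)).is_responder for tr in traces
        )
        assert hits / 1000 < 0.05

    def test_slow_ramp_rejected_by_derivative_criterion(self):
        """A drift crossing 5 SD with per-frame increments below the
        pre-stimulus dF/dt SD must not be called a responder."""
        rng = np.random.default_rng(7)
        T = 120
        tr = np.empty(T)
        tr[:60] = rng.normal(0, 1.0, 60)
        d_sd = np.diff(tr[:60]).std(ddof=1)
        # deterministic ramp from the last baseline value, small increments
        tr[60:] = tr[59] + np.cumsum(np.full(60, 0.3 * d_sd))
        call = call_response(tr, (60, 120), (20, 60))
        assert call.peak_margin > 0  # the peak criterion alone would fire
        assert call.deriv_margin <= 0
        assert not call.is_responder

    def test_window_validation(self):
        tr = np.zeros(50)
        with pytest.raises(ValueError, match=">= 3 frames"):
            call_response(tr, (20, 22), (10, 20))
        with pytest.raises(ValueError, match="precede"):
            call_response(tr, (10, 20), (15, 25))
        with pytest.raises(ValueError, match="beyond"):
            call_response(tr, (45, 55), (30, 40))

    def test_degenerate_flat_baseline_flagged(self):
        tr = np.zeros(40)
        tr[20:30] = 5.0
        call = call_response(tr, (20, 30), (10, 20))
        assert call.degenerate
        assert call.is_responder  # any step beats an epsilon SD

    def test_threshold_monotonicity(self):
        """Raising the peak multiplier never converts a non-responder into
        a responder."""
        traces = t.gen_traces(200, 6.0, 30, 60, seed=9)
        for tr in traces:
            c5 = call_response(tr, (30, 40), (20, 30), peak_mult=5.0)
            c6 = call_response(tr, (30, 40), (20, 30), peak_mult=6.0)
            if not c5.is_responder:
                assert not c6.is_responder

    def test_parameter_recovery_sensitivity_specificity(self):
        """Default synthetic trace population (amplitudes 0 or 10 SD):
        sensitivity and specificity both >= 0.95."""
        null = t.gen_traces(100, 0.0, 30, 60, seed=10)
        sig = t.gen_traces(100, 10.0, 30, 60, seed=11)
        fp = sum(call_response(x, (30, 40), (20, 30)).is_responder for x in null)
        tp = sum(call_response(x, (30, 40), (20, 30)).is_responder for x in sig)
        assert tp / 100 >= 0.95
        assert 1 - fp / 100 >= 0.95


class TestKExclusionAndNormalization:
    def _table(self, k_amps):
        protocol = _protocol_mk()
        traces = {
            rid + 1: _step_trace(amp=8.0, seed=rid, amp2=k_amp)
            for rid, k_amp in enumerate(k_amps)
        }
        rs = _roiset(traces)
        return classify_responses(rs, protocol), protocol

    def test_all_k_responsive_unchanged(self):
        table, _ = self._table([10.0] * 5)
        apply_k_exclusion(table)
        assert not table.rois["excluded"].any()
        assert len(table.included_ids()) == 5

    def test_k_negative_rois_excluded_everywhere(self):
        table, _ = self._table([10.0] * 7 + [0.0] * 3)
        apply_k_exclusion(table)
        assert table.rois["excluded"].sum() == 3
        assert len(table.included_ids()) == 7
        fr = responder_fraction(table)
        assert (fr["n_rois"] == 7).all()

    def test_exclusion_concordance_with_truth(self, soma_dataset):
        res = t.analyze_drg_movie(
            soma_dataset["movie"],
            soma_dataset["protocol"],
            cell_masks=soma_dataset["labels"],
            register=False,
        )
        truth = soma_dataset["truth"]
        got = ~res["table"].rois.sort_values("roi_id")["excluded"].to_numpy()
        np.testing.assert_array_equal(got, truth.k_responsive)

    def test_missing_k_stimulus_rejected(self):
        protocol = StimulusProtocol(windows=[StimWindow("M3", 20, 30)])
        rs = _roiset({1: _step_trace(amp2=0.0)})
        table = classify_responses(rs, protocol)
        with pytest.raises(ValueError, match="high-K"):
            apply_k_exclusion(table)

    def test_normalize_to_k_ratios(self):
        table, _ = self._table([10.0, 10.0, 10.0])
        apply_k_exclusion(table)
        normalize_to_k(table)
        calls = table.calls.set_index(["roi_id", "stimulus"])
        for rid in (1, 2, 3):
            m3 = calls.loc[(rid, "M3")]
            k = calls.loc[(rid, "K")]
            assert m3["peak_dff_norm"] == pytest.approx(
                m3["peak_dff"] / k["peak_dff"]
            )
            assert k["peak_dff_norm"] == pytest.approx(1.0)

    def test_normalization_requires_exclusion_first(self):
        table, _ = self._table([10.0])
        with pytest.raises(ValueError, match="apply_k_exclusion"):
            normalize_to_k(table)

    def test_excluded_rois_get_nan_norm(self):
        table, _ = self._table([10.0, 0.0])
        apply_k_exclusion(table)
        normalize_to_k(table)
        sub = table.calls[table.calls["roi_id"] == 2]
        assert sub["peak_dff_norm"].isna().all()


class TestCoexpression:
    def _mixed_table(self):
        protocol = t.default_protocol()
        rng = np.random.default_rng(3)
        T = protocol.last_end + 10
        traces = {}
        classes = {1: {"M3", "V1"}, 2: set(), 3: {"M3", "A1", "V1"}, 4: {"A1"}}
        for rid, cls in classes.items():
            tr = rng.normal(0, 0.02, T)
            tt = np.arange(T, dtype=float)
            for lab in list(cls) + ["K"]:
                w = protocol.window(lab)
                tr += 1.0 * np.where(
                    tt >= w.start_frame,
                    np.exp(-(tt - w.start_frame) / 8),
                    0,
                )
            traces[rid] = tr
        table = classify_responses(_roiset(traces), protocol)
        apply_k_exclusion(table)
        return table, classes

    def test_classes_match_construction(self):
        table, classes = self._mixed_table()
        coexpression_classes(table)
        got = dict(zip(table.rois["roi_id"], table.rois["coexpression_class"]))
        assert got[1] == "M3+V1"
        assert got[2] == "none"
        assert got[3] == "M3+A1+V1"
        assert got[4] == "A1"

    def test_frequencies_sum_to_one(self):
        table, _ = self._mixed_table()
        coexpression_classes(table)
        freqs = coexpression_frequencies(table)
        assert freqs["frequency"].sum() == pytest.approx(1.0)

    def test_programmed_mixture_recovered(self, protocol):
        """A generated population with a programmed expression mixture is
        recovered within binomial bounds (end-to-end, import-mask mode)."""
        p_m3 = 0.4
        truth = t.make_soma_truth(
            (160, 160), n_cells=24, p_expressed={"M3": p_m3, "A1": 0.0, "V1": 0.0},
            seed=51,
        )
        shape = (protocol.last_end + 10, 160, 160)
        movie, _, truth = t.gen_soma_movie(truth, protocol, shape, seed=52)
        res = t.analyze_drg_movie(
            movie, protocol,
            cell_masks=t.synthgen.soma_label_image(truth, (160, 160)),
            register=False,
        )
        fr = res["fractions"]
        m3 = fr[fr["stimulus"] == "M3"]["fraction"].iloc[0]
        n = fr[fr["stimulus"] == "M3"]["n_rois"].iloc[0]
        true_frac = np.mean([("M3" in e) for e in truth.expressed])
        # binomial 95% bound around the realised truth fraction
        assert abs(m3 - true_frac) <= 1.96 * np.sqrt(true_frac * (1 - true_frac) / n) + 1e-9


class TestFractionsAndAreas:
    def test_responder_fraction_arithmetic(self):
        protocol = _protocol_mk()
        traces = {
            rid: _step_trace(amp=(10.0 if rid <= 5 else 0.0), seed=rid)
            for rid in range(1, 21)
        }
        table = classify_responses(_roiset(traces), protocol)
        apply_k_exclusion(table)
        fr = responder_fraction(table)
        m3 = fr[fr["stimulus"] == "M3"].iloc[0]
        assert m3["n_responders"] == 5
        assert m3["fraction"] == pytest.approx(0.25)

    def test_zero_responders_fraction_zero(self):
        protocol = _protocol_mk()
        traces = {rid: _step_trace(amp=0.0, seed=rid) for rid in range(1, 6)}
        table = classify_responses(_roiset(traces), protocol)
        apply_k_exclusion(table)
        fr = responder_fraction(table)
        assert (fr[fr["stimulus"] == "M3"]["fraction"] == 0).all()

    def test_per_group_breakdown(self):
        protocol = _protocol_mk()
        traces = {rid: _step_trace(amp=10.0, seed=rid) for rid in range(1, 7)}
        table = classify_responses(_roiset(traces), protocol)
        apply_k_exclusion(table)
        grouping = pd.Series({rid: ("A" if rid <= 3 else "B") for rid in range(1, 7)})
        fr = responder_fraction(table, grouping)
        assert set(fr["group"]) == {"A", "B"}
        assert (fr[fr["stimulus"] == "M3"]["n_rois"] == 3).all()

    def test_responsive_area_arithmetic(self):
        """One responding ROI of 500 px in a 50,000 px field: 1%."""
        protocol = _protocol_mk()
        labels = np.zeros((250, 200), np.int32)
        labels[:25, :20] = 1  # 500 px
        rs = RoiSet(labels=labels)
        rs.traces = {1: _step_trace(amp=10.0, seed=1)}
        table = classify_responses(rs, protocol)
        areas = responsive_area(rs, table, imaged_area_px=50_000, per_class=False)
        m3 = areas[(areas["kind"] == "stimulus") & (areas["key"] == "M3")]
        assert m3["fraction"].iloc[0] == pytest.approx(0.01)

    def test_area_classes_sum_to_any_agonist_area(self, skin_dataset):
        res = t.analyze_skin_movie(skin_dataset["movie"], skin_dataset["protocol"])
        areas = res["areas"]
        cls = areas[(areas["kind"] == "class") & (areas["key"] != "none")]
        per_stim = areas[areas["kind"] == "stimulus"]
        any_resp_area = cls["area_px"].sum()
        # every class area belongs to some agonist; union = sum of exact classes
        assert any_resp_area >= per_stim[per_stim["key"] != "K"]["area_px"].max()

    def test_no_k_exclusion_in_skin_mode(self, skin_dataset):
        """Branches failing the K+ criterion still count toward areas."""
        res = t.analyze_skin_movie(skin_dataset["movie"], skin_dataset["protocol"])
        assert not res["table"].rois["excluded"].any()
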