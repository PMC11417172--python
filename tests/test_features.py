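import logging
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import simpson

from astroroa import (
    EpochSpec,
    LabeledMap,
    Signal,
    TraceTable,
    align_roa_cell,
    analyze_signal,
    cell_analysis,
    composite_simpson,
    generate_synthetic_traces,
    iterative_baseline,
    roa_analysis,
)
from astroroa.features import FEATURE_COLUMNS


def dff_table(values, frame_rate=1.0):
    return TraceTable(np.atleast_2d(np.asarray(values, dtype=float)), "dff", frame_rate)


def triangle_trace():
    """20 s triangular pulse at 1 Hz between low-noise baseline stretches."""
    baseline = np.array([0.1, -0.1, 0.2, 0.0, -0.2])
    rise = np.linspace(0.0, 1.0, 11)       # frames 5..15
    fall = np.linspace(0.9, 0.0, 10)       # frames 16..25
    tail = np.array([0.2, -0.1, 0.1, -0.2, 0.0])
    return np.concatenate([baseline, rise, fall, tail])


class TestCompositeSimpson:
    def test_unit_hat(self):
        assert composite_simpson(np.array([0.0, 1.0, 0.0]), 1.0) == pytest.approx(4 / 3)

    def test_even_intervals_match_scipy(self, rng):
        y = rng.random(11)
        assert composite_simpson(y, 0.5) == pytest.approx(
            simpson(y, dx=0.5), abs=1e-12
        )

    def test_odd_intervals_simpson_plus_trapezoid(self, rng):
        y = rng.random(12)
        expected = simpson(y[:-1], dx=0.5) + 0.5 * (y[-2] + y[-1]) / 2
        assert composite_simpson(y, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_matches_fine_trapezoid_on_piecewise_linear(self, rng):
        # knots on even sample indices so both quadratures are exact
        for _ in range(20):
            n_knots = int(rng.integers(3, 20))
            knots = rng.random(n_knots) * 2
            coarse = np.interp(
                np.arange(2 * (n_knots - 1) + 1) / 2.0, np.arange(n_knots), knots
            )
            fine_x = np.linspace(0, len(coarse) - 1, (len(coarse) - 1) * 100 + 1)
            fine = np.interp(fine_x, np.arange(len(coarse)), coarse)
            auc = composite_simpson(coarse, 1.0)
            ref = np.trapezoid(fine, dx=fine_x[1] - fine_x[0])
            assert auc == pytest.approx(ref, abs=1e-9)


class TestAnalyzeSignal:
    def test_triangle_feature_values(self):
        dff = dff_table(triangle_trace())
        sig = [[Signal(start=5, peak=15, end=25)]]
        feats = analyze_signal(dff, sig)
        row = feats.iloc[0]
        assert row["amplitude"] == pytest.approx(1.0)
        assert row["rise_time"] == pytest.approx(8.0)
        assert row["decay_time"] == pytest.approx(8.0)
        assert row["half_width"] == pytest.approx(10.0)
        assert row["duration"] == pytest.approx(20.0)
        assert row["AUC"] == pytest.approx(10.0)
        assert row["signal_to_noise"] == pytest.approx(5.0)
        assert row["peak_frame"] == 15
        assert np.isnan(row["inter_event_interval"])

    def test_schema_matches_feature_dictionary(self):
        feats = analyze_signal(dff_table(triangle_trace()), [[Signal(5, 15, 25)]])
        assert list(feats.columns) == FEATURE_COLUMNS

    def test_interpolated_crossings_between_samples(self):
        # rise jumps 0 -> 1 in one 1 s step: 10% and 90% crossings land
        # inside that interval, 0.8 s apart
        dff = np.array([-0.05, 0.0, 1.0, 0.5, 0.0, -0.05])
        feats = analyze_signal(dff_table(dff), [[Signal(1, 2, 4)]])
        assert feats.iloc[0]["rise_time"] == pytest.approx(0.8)

    def test_inter_event_interval(self):
        dff = np.zeros(100)
        dff -= 0.001
        dff[10:30] = 1.0   # ends (crossing) at frame 30
        dff[50:70] = 1.0   # starts (crossing) at frame 49
        tt = dff_table(dff)
        sigs = [[Signal(9, 10, 30), Signal(49, 50, 70)]]
        feats = analyze_signal(tt, sigs)
        assert np.isnan(feats.iloc[0]["inter_event_interval"])
        assert feats.iloc[1]["inter_event_interval"] == pytest.approx(49.0 - 30.0)

    def test_epoch_split_at_drug_frame(self):
        dff = np.zeros(40) - 0.001
        dff[5:10] = 1.0
        dff[20:25] = 1.0
        sigs = [[Signal(4, 5, 10), Signal(19, 20, 25)]]
        feats = analyze_signal(dff_table(dff), sigs, drug_frame=20)
        assert feats.iloc[0]["epoch"] == "baseline"
        assert feats.iloc[1]["epoch"] == "drug"  # peak exactly at drug_frame

    def test_truncated_rows_have_partial_features(self):
        dff = np.zeros(30) - 0.001
        dff[20:] = np.linspace(0, 2.0, 10)
        trunc = [[Signal(20, 29, 29, has_end=False)]]
        feats = analyze_signal(
            dff_table(dff), [[]], trunc, include_incomplete=True
        )
        row = feats.iloc[0]
        assert row["amplitude"] == pytest.approx(2.0)
        assert np.isfinite(row["rise_time"])
        assert np.isnan(row["AUC"]) and np.isnan(row["duration"])
        excluded = analyze_signal(dff_table(dff), [[]], trunc, include_incomplete=False)
        assert excluded.empty


class TestAlignRoaCell:
    @staticmethod
    def _maps():
        roa = np.zeros((20, 20), dtype=int)
        roa[2:4, 2:4] = 1    # inside cell 2
        roa[10:14, 0:10] = 2  # straddles cells 1 and 2
        roa[17:19, 17:19] = 3  # outside all cells
        cells = np.zeros((20, 20), dtype=int)
        cells[8:16, 0:8] = 1
        cells[0:6, 0:20] = 2
        cells[10:14, 8:10] = 2
        return LabeledMap(roa, 3), LabeledMap(cells, 2, kind="cell")

    def test_assignment_by_max_overlap(self):
        roa_map, cell_map = self._maps()
        info = align_roa_cell(roa_map, cell_map, spatial_resolution=0.5)
        assert info.loc[info.ROA_ID == 1, "cell_ID"].item() == 2
        # ROA 2: 32 px in cell 1 vs 8 px in cell 2
        assert info.loc[info.ROA_ID == 2, "cell_ID"].item() == 1
        assert info.loc[info.ROA_ID == 3, "cell_ID"].item() == 0
        assert info.loc[info.ROA_ID == 2, "size_um2"].item() == pytest.approx(40 * 0.25)

    def test_overlap_against_brute_count(self):
        roa_map, cell_map = self._maps()
        info = align_roa_cell(roa_map, cell_map, 1.0)
        for roa_id in (1, 2, 3):
            counts = {}
            for y in range(20):
                for x in range(20):
                    if roa_map.labels[y, x] == roa_id and cell_map.labels[y, x] > 0:
                        counts[cell_map.labels[y, x]] = counts.get(cell_map.labels[y, x], 0) + 1
            expected = max(counts, key=counts.get) if counts else 0
            assert info.loc[info.ROA_ID == roa_id, "cell_ID"].item() == expected

    def test_tie_goes_to_smaller_cell_with_warning(self, caplog):
        roa = np.zeros((10, 10), dtype=int)
        roa[4:6, 4:6] = 1
        cells = np.zeros((10, 10), dtype=int)
        cells[4:6, 4] = 1
        cells[4:6, 5] = 2
        with caplog.at_level(logging.WARNING):
            info = align_roa_cell(LabeledMap(roa, 1), LabeledMap(cells, 2, kind="cell"), 1.0)
        assert info.loc[0, "cell_ID"] == 1
        assert any("equally" in r.message for r in caplog.records)

    def test_canvas_mismatch_rejected(self):
        roa = LabeledMap(np.ones((4, 4), dtype=int), 1)
        cell = LabeledMap(np.ones((6, 6), dtype=int), 1, kind="cell")
        with pytest.raises(ValueError, match="canvas mismatch"):
            align_roa_cell(roa, cell, 1.0)


def features_fixture():
    """Hand-built feature table: ROA 1 active in both epochs, ROA 2 baseline
    only, ROA 3 drug only, ROA 4 silent."""
    rows = []
    for roa, epoch, amp in [
        (1, "baseline", 1.0), (1, "drug", 2.0),
        (2, "baseline", 3.0),
        (3, "drug", 0.5), (3, "drug", 1.5),
    ]:
        rows.append(
            {"ROA_ID": roa, "epoch": epoch, "amplitude": amp, "AUC": amp * 2,
             "signal_to_noise": 5.0, "rise_time": 2.0, "decay_time": 4.0,
             "half_width": 3.0, "duration": 8.0, "inter_event_interval": np.nan}
        )
    return pd.DataFrame(rows)


def info_fixture(with_cells=True):
    info = pd.DataFrame({"ROA_ID": [1, 2, 3, 4], "size_um2": [10.0, 20.0, 30.0, 5.0]})
    if with_cells:
        info["cell_ID"] = [1, 1, 2, 0]
    return info


class TestRoaAnalysis:
    def test_roa_types_follow_epoch_activity(self):
        epochs = EpochSpec(frame_count=600, frame_rate=1.0, drug_frame=300)
        roa_based, census = roa_analysis(features_fixture(), info_fixture(), epochs)
        types = roa_based.drop_duplicates("ROA_ID").set_index("ROA_ID")["ROA_type"]
        assert types[1] == "stable"
        assert types[2] == "off"
        assert types[3] == "on"
        assert types[4] == "inactive"
        assert census.set_index("ROA_type")["count"].sum() == 4

    def test_frequency_per_minute(self):
        epochs = EpochSpec(frame_count=240, frame_rate=1.0, drug_frame=120)
        feats = features_fixture()
        feats = pd.concat([feats] + [feats[(feats.ROA_ID == 3)]] * 2, ignore_index=True)
        # ROA 3 now has 6 drug-epoch signals in a 120 s epoch
        roa_based, _ = roa_analysis(feats, info_fixture(), epochs)
        row = roa_based[(roa_based.ROA_ID == 3) & (roa_based.epoch == "drug")]
        assert row["signal_count"].item() == 6
        assert row["frequency_permin"].item() == pytest.approx(3.0)

    def test_unweighted_epoch_means(self):
        epochs = EpochSpec(600, 1.0, 300)
        roa_based, _ = roa_analysis(features_fixture(), info_fixture(), epochs)
        row = roa_based[(roa_based.ROA_ID == 3) & (roa_based.epoch == "drug")]
        assert row["mean_amplitude"].item() == pytest.approx(1.0)

    def test_no_drug_frame_single_epoch(self):
        epochs = EpochSpec(600, 1.0, None)
        feats = features_fixture().assign(epoch=pd.NA)
        roa_based, census = roa_analysis(feats, info_fixture(), epochs)
        assert len(roa_based) == 4  # one row per ROA
        assert roa_based["ROA_type"].isna().all()
        assert census.empty
        row = roa_based[roa_based.ROA_ID == 1]
        assert row["frequency_permin"].item() == pytest.approx(2 / 10.0)

    def test_census_partition(self):
        epochs = EpochSpec(600, 1.0, 300)
        _, census = roa_analysis(features_fixture(), info_fixture(), epochs)
        counts = census.set_index("ROA_type")["count"]
        assert counts.to_dict() == {"stable": 1, "on": 1, "off": 1, "inactive": 1}


class TestCellAnalysis:
    def test_unweighted_mean_across_roas(self):
        epochs = EpochSpec(600, 1.0, 300)
        roa_based, _ = roa_analysis(features_fixture(), info_fixture(), epochs)
        cells = cell_analysis(roa_based)
        row = cells[(cells.cell_ID == 1) & (cells.epoch == "baseline")]
        # cell 1 holds ROAs 1 (mean amp 1.0) and 2 (mean amp 3.0)
        assert row["mean_amplitude"].item() == pytest.approx(2.0)
        assert row["ROA_count"].item() == 2
        assert row["signal_count"].item() == 2

    def test_inactive_cell_has_no_feature_means(self):
        epochs = EpochSpec(600, 1.0, 300)
        info = pd.DataFrame(
            {"ROA_ID": [1], "size_um2": [5.0], "cell_ID": [3]}
        )
        feats = features_fixture().iloc[0:0]
        roa_based, _ = roa_analysis(feats, info, epochs)
        cells = cell_analysis(roa_based)
        assert (cells["signal_count"] == 0).all()
        assert cells["mean_amplitude"].isna().all()

    def test_cell0_isolated_from_real_cells(self):
        epochs = EpochSpec(600, 1.0, 300)
        info = info_fixture()
        feats = features_fixture()
        # make the unassigned ROA 4 active with a huge amplitude
        extra = feats.iloc[[0]].assign(ROA_ID=4, amplitude=100.0)
        roa_based, _ = roa_analysis(pd.concat([feats, extra], ignore_index=True), info, epochs)
        cells = cell_analysis(roa_based)
        real = cells[cells.cell_ID > 0]
        assert (real["mean_amplitude"].dropna() < 50).all()
        assert 0 in cells["cell_ID"].values

    def test_requires_cell_assignment(self):
        epochs = EpochSpec(600, 1.0, 300)
        roa_based, _ = roa_analysis(
            features_fixture(), info_fixture(with_cells=False), epochs
        )
        with pytest.raises(ValueError, match="cell-assigned"):
            cell_analysis(roa_based)


class TestParameterRecovery:
    def test_amplitude_and_duration_recovered_at_high_snr(self, rng):
        # one isolated event per trace; a zero-noise twin provides the
        # expected signal duration under the crossing-bound definition
        n = 40
        events = [
            [(float(rng.uniform(40, 120)), float(rng.uniform(1.0, 2.0)))]
            for _ in range(n)
        ]
        kwargs = dict(n_traces=n, frame_count=300, frame_rate=1.0, events=events)
        noisy, truth = generate_synthetic_traces(noise_sd=0.05, seed=42, **kwargs)
        res = iterative_baseline(noisy, threshold_k=3.0, n_iterations=10)
        feats = analyze_signal(res.dff, res.signals, res.truncated)
        amp_errors = []
        for r in range(n):
            true_amp = truth.events.loc[truth.events.trace_id == r, "amplitude"].item()
            got = feats[feats.ROA_ID == r + 1]
            if len(got):
                main = got.loc[got.amplitude.idxmax()]
                amp_errors.append(abs(main.amplitude - true_amp) / true_amp)
        assert len(amp_errors) >= 0.9 * n
        assert np.median(amp_errors) <= 0.10

    def test_duration_recovered_on_sharp_transients(self, rng):
        # triangular transients have exactly known crossing-bound durations;
        # recovered duration should land within 2 frames of the truth
        n, frames = 40, 200
        f0 = 100.0
        dur_errors = []
        raw = np.empty((n, frames))
        true_dur = []
        for r in range(n):
            start = int(rng.integers(40, 100))
            half = int(rng.integers(5, 12))
            amp = float(rng.uniform(1.0, 2.0))
            dff_true = np.zeros(frames)
            dff_true[start:start + half + 1] = np.linspace(0, amp, half + 1)
            dff_true[start + half:start + 2 * half + 1] = np.linspace(amp, 0, half + 1)
            true_dur.append(2 * half)
            raw[r] = f0 * (1 + dff_true) + f0 * 0.05 * rng.standard_normal(frames)
        res = iterative_baseline(
            TraceTable(raw, "raw", 1.0), threshold_k=3.0, n_iterations=10
        )
        feats = analyze_signal(res.dff, res.signals, res.truncated)
        for r in range(n):
            got = feats[feats.ROA_ID == r + 1]
            if len(got):
                main = got.loc[got.amplitude.idxmax()]
                dur_errors.append(abs(main.duration - true_dur[r]))
        assert len(dur_errors) >= 0.9 * n
        assert np.median(dur_errors) <= 2.0
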