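"""Transport-index computation and transport-efficiency classification."""

import numpy as np
import pytest

from conftest import split_channels
from secrflux import simulate, transport
from secrflux.errors import DegenerateHistogramError, InputError
from secrflux.stack import CellROI, ImageStack


class TestGolgiMask:
    def test_disc_marker_mask_geometry(self, transport_series):
        stack, truth, roi, _ = transport_series
        mask = transport.compute_golgi_mask(
            stack.data[0, 1], roi, background_radius_px=25
        )
        planted = truth.golgi_mask_true == 1
        assert (mask <= roi.mask).all()
        # two erosions can shrink the footprint but the mask stays inside
        # the marker staining and overlaps the planted Golgi strongly
        iou = (mask & planted).sum() / (mask | planted).sum()
        assert iou >= 0.9

    def test_zero_marker_raises(self):
        roi = CellROI(1, np.ones((64, 64), bool))
        with pytest.raises(DegenerateHistogramError):
            transport.compute_golgi_mask(np.zeros((64, 64)), roi, 10)

    def test_mask_area_non_increasing_with_erosions(self, transport_series):
        stack, truth, roi, _ = transport_series
        areas = [
            transport.compute_golgi_mask(
                stack.data[0, 1], roi, background_radius_px=25, erosions=k
            ).sum()
            for k in range(3)
        ]
        assert areas[0] >= areas[1] >= areas[2] > 0


class TestTransportIndex:
    def test_static_cargo_gives_flat_ti(self):
        scene = simulate.SceneParams(seed=3)
        kinetics = simulate.TransportKinetics()  # constant small fraction
        stack, truth = simulate.generate_transport_series(scene, kinetics)
        roi = CellROI(1, truth.cell_masks_true == 1, "ground_truth")
        cargo, marker = split_channels(stack)
        traj = transport.compute_transport_index(
            cargo, marker, roi, background_radius_px=25
        )
        assert np.allclose(traj.ti, 1.0, atol=1e-9)

    def test_hand_computed_8x8_example(self):
        """ROI = whole frame, Golgi mask = fixed 2x2 block; integrated
        densities 40/600 then 160/600 give TI(t1) = 4 exactly."""
        marker = np.zeros((8, 8))
        marker[2:4, 2:4] = 100.0
        cargo0 = np.full((8, 8), 10.0)
        cargo1 = np.full((8, 8), 10.0)
        cargo1[2:4, 2:4] = 40.0
        cargo = ImageStack(np.stack([cargo0, cargo1])[:, None], timepoints_min=(0, 30))
        marker_stack = ImageStack(
            np.stack([marker, marker])[:, None], timepoints_min=(0, 30)
        )
        roi = CellROI(1, np.ones((8, 8), bool))
        traj = transport.compute_transport_index(
            cargo, marker_stack, roi, background_radius_px=4, erosions=0
        )
        assert traj.raw_ratio[0] == pytest.approx(40 / 600)
        assert traj.raw_ratio[1] == pytest.approx(160 / 600)
        assert traj.ti[1] == pytest.approx(4.0)

    def test_matches_closed_form_noise_free(self, transport_series):
        stack, truth, roi, kinetics = transport_series
        cargo, marker = split_channels(stack)
        traj = transport.compute_transport_index(
            cargo, marker, roi, background_radius_px=25
        )
        pred = simulate.transport_index_closed_form(
            np.array(kinetics.golgi_fraction), kinetics.golgi_fraction[0]
        )
        assert np.abs(traj.ti - pred).max() / pred.max() <= 0.02
        assert np.all(np.abs(traj.ti - pred) <= 0.02 * pred)

    def test_normalization_contract(self, transport_series):
        stack, truth, roi, _ = transport_series
        cargo, marker = split_channels(stack)
        traj = transport.compute_transport_index(cargo, marker, roi, background_radius_px=25)
        assert traj.ti[0] == 1.0

    def test_scale_invariance_of_cargo_channel(self, transport_series):
        stack, truth, roi, _ = transport_series
        cargo, marker = split_channels(stack)
        scaled = ImageStack(
            cargo.data * 3.7, timepoints_min=cargo.timepoints_min
        )
        a = transport.compute_transport_index(cargo, marker, roi, background_radius_px=25)
        b = transport.compute_transport_index(scaled, marker, roi, background_radius_px=25)
        assert np.allclose(a.ti, b.ti, rtol=1e-9)

    def test_ti_monotone_in_planted_fraction(self):
        """On noise-free series, the measured TI at a timepoint strictly
        increases with the planted Golgi fraction."""
        tis = []
        for f_end in (0.1, 0.3, 0.6):
            scene = simulate.SceneParams(seed=5)
            kin = simulate.TransportKinetics(
                golgi_fraction=(0.05, 0.06, 0.07, 0.08, f_end)
            )
            stack, truth = simulate.generate_transport_series(scene, kin)
            roi = CellROI(1, truth.cell_masks_true == 1, "ground_truth")
            cargo, marker = split_channels(stack)
            traj = transport.compute_transport_index(cargo, marker, roi, background_radius_px=25)
            tis.append(traj.ti[-1])
        assert tis[0] < tis[1] < tis[2]

    def test_timepoint_mismatch_rejected(self, transport_series):
        stack, truth, roi, _ = transport_series
        cargo, marker = split_channels(stack)
        bad_marker = ImageStack(
            marker.data, timepoints_min=(0, 1, 2, 3, 4)
        )
        with pytest.raises(InputError):
            transport.compute_transport_index(cargo, bad_marker, roi, background_radius_px=25)


def _traj(ti_values, timepoints=(0.0, 3.0, 7.0, 15.0, 30.0), cargo_type="soluble"):
    ti = np.asarray(ti_values, dtype=float)
    return transport.TITrajectory(
        cell_label=1,
        timepoints_min=tuple(timepoints),
        raw_ratio=ti * 0.1,
        ti=ti,
        cargo_type=cargo_type,
    )


class TestClassification:
    @pytest.mark.parametrize(
        "ti30, expected",
        [
            (12.0, "very_high"),
            (1.0, "none"),
            (5.0, "high"),  # boundary goes to the higher class
            (10.0, "very_high"),
            (2.0, "moderate"),
            (1.99, "none"),
        ],
    )
    def test_soluble_thresholds(self, ti30, expected):
        traj = _traj((1, 1.5, 2, min(ti30, 3), ti30) if ti30 >= 3 else (1, 1, 1, 1, ti30))
        assert transport.classify_transport(traj).label == expected

    @pytest.mark.parametrize(
        "ti15, expected",
        [(8.0, "high"), (12.0, "very_high"), (4.0, "moderate"), (3.0, "none")],
    )
    def test_transmembrane_uses_15min_and_own_thresholds(self, ti15, expected):
        traj = _traj((1, 2, 3, ti15, ti15), cargo_type="transmembrane")
        assert transport.classify_transport(traj).label == expected

    def test_missing_decision_timepoint_rejected(self):
        traj = _traj((1, 2, 3), timepoints=(0.0, 3.0, 7.0))
        with pytest.raises(InputError):
            transport.classify_transport(traj)


class TestPopulationSummary:
    def test_single_cell_sem_zero(self):
        tc, freq = transport.summarize_population([_traj((1, 2, 3, 4, 12))])
        assert (tc["sem_ti"] == 0).all()
        assert (tc["n_cells"] == 1).all()

    def test_two_cell_class_frequencies(self):
        trajs = [_traj((1, 2, 3, 5, 12)), _traj((1, 1.5, 2, 2.5, 3))]
        tc, freq = transport.summarize_population(trajs)
        freq = freq.set_index("transport_class")
        assert freq.loc["very_high", "percent"] == 50.0
        assert freq.loc["moderate", "percent"] == 50.0
        assert freq["count"].sum() == 2

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            transport.summarize_population([])

    def test_planted_cohort_frequency_recovery(self):
        """A 40-cell cohort planted with 40% very-high kinetics recovers
        that frequency within binomial sampling error (exactly, since the
        classifier is deterministic on noise-free trajectories)."""
        rng = np.random.default_rng(0)
        trajs = []
        for i in range(40):
            cls = "very_high" if i < 16 else "moderate"
            kin = simulate.kinetics_preset(cls, "soluble")
            pred = simulate.transport_index_closed_form(
                np.array(kin.golgi_fraction), kin.golgi_fraction[0]
            )
            pred = pred * (1 + rng.normal(0, 0.02, pred.size))
            pred[0] = 1.0
            trajs.append(_traj(np.clip(pred, 1e-6, None)))
        _, freq = transport.summarize_population(trajs)
        vh = freq.set_index("transport_class").loc["very_high", "percent"]
        assert abs(vh - 40.0) <= 10.0

    def test_chi_square_comparison_runs(self):
        trajs_a = [_traj((1, 2, 3, 5, 12))] * 10 + [_traj((1, 1, 1, 1, 1))] * 10
        trajs_b = [_traj((1, 2, 3, 5, 12))] * 18 + [_traj((1, 1, 1, 1, 1))] * 2
        _, fa = transport.summarize_population(trajs_a)
        _, fb = transport.summarize_population(trajs_b)
        res = transport.compare_class_frequencies(fa, fb)
        assert 0 <= res["p_value"] <= 1
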