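"""Directional heatmap, coherence, correlation matrix and pair table."""
import numpy as np
import pandas as pd
import pytest

from dyadsync.composites import (DEFAULT_DIRECTION_MAP, VALENCE, AROUSAL,
                                 build_heatmap, combined_pair_table,
                                 correlation_matrix, epoch_deltas,
                                 middle_epochs)
from dyadsync.session import ValidationError


def _me(values, metric="HR", subject="H1", subsession="INT1"):
    return pd.DataFrame({
        "subsession": subsession,
        "epoch": np.arange(len(values)),
        "subject": subject,
        "placement": "chest",
        "metric": metric,
        "value": values,
    })


class TestEpochDeltas:
    def test_signs(self):
        d = epoch_deltas(_me([3.0, 5.0, 4.0]))
        assert list(d["delta"]) == [1.0, -1.0]
        assert not d["tie"].any()

    def test_tie_renders_decrease_but_flagged(self):
        d = epoch_deltas(_me([2.0, 2.0]))
        assert list(d["delta"]) == [-1.0]
        assert d["tie"].all()

    def test_first_epoch_has_no_delta(self):
        d = epoch_deltas(_me([1.0, 2.0, 3.0]))
        assert set(d["epoch"]) == {1, 2}

    def test_missing_propagates(self):
        d = epoch_deltas(_me([1.0, np.nan, 3.0]))
        assert len(d) == 0  # no adjacent finite pair


class TestBuildHeatmap:
    def _deltas(self):
        me = pd.concat([
            _me([10.0, 12, 11, 13] + [10.0] * 14, "HR", "H1"),
            _me([50.0, 52, 51, 49] + [50.0] * 14, "SDNN", "H1"),
            _me([95.0, 96, 94, 97] + [95.0] * 14, "HR", "C1"),
        ], ignore_index=True)
        return epoch_deltas(me)

    def test_orientation_composition(self):
        hm = build_heatmap(self._deltas(), range(18), "INT1",
                           species_of={"H1": "human", "C1": "canine"})
        # an SDNN increase is a positive valence cell; HR increase -> arousal up
        sdnn_row = hm.frame.xs((VALENCE, "human"), level=("dimension",
                                                          "species"))
        hr_row = hm.frame.xs((AROUSAL, "human"), level=("dimension",
                                                        "species"))
        assert sdnn_row.iloc[0][1] == 1.0 and sdnn_row.iloc[0][3] == -1.0
        assert hr_row.iloc[0][1] == 1.0 and hr_row.iloc[0][2] == -1.0

    def test_orientation_flip_is_involution(self):
        dmap = dict(DEFAULT_DIRECTION_MAP)
        flipped = dict(dmap)
        flipped["SDNN"] = (VALENCE, "inverse")
        hm = build_heatmap(self._deltas(), range(18), "INT1", dmap,
                           species_of={"H1": "human", "C1": "canine"})
        hm2 = build_heatmap(self._deltas(), range(18), "INT1", flipped,
                            species_of={"H1": "human", "C1": "canine"})
        for key in hm.frame.index:
            a = hm.frame.loc[key]
            b = hm2.frame.loc[key]
            if key[3] == "SDNN":
                assert np.allclose(a.to_numpy(float), -b.to_numpy(float),
                                   equal_nan=True)
            else:
                assert np.allclose(a.to_numpy(float), b.to_numpy(float),
                                   equal_nan=True)

    def test_rows_ordered_valence_then_arousal_human_first(self):
        hm = build_heatmap(self._deltas(), range(18), "INT1",
                           species_of={"H1": "human", "C1": "canine"})
        dims = list(hm.frame.index.get_level_values("dimension"))
        assert dims == sorted(dims, key=lambda d: 0 if d == VALENCE else 1)
        arousal_species = [sp for (d, sp, _, _) in hm.frame.index
                           if d == AROUSAL]
        assert arousal_species == ["human", "canine"]

    def test_unmapped_metric_rejected(self):
        me = _me([1.0, 2.0], metric="SDNN_RMSSD")
        with pytest.raises(ValidationError, match="direction mapping"):
            build_heatmap(epoch_deltas(me), range(18), "INT1")

    def test_cell_count_invariant(self):
        hm = build_heatmap(self._deltas(), range(18), "INT1",
                           species_of={"H1": "human", "C1": "canine"})
        defined = np.isfinite(hm.frame.to_numpy(float)).sum()
        assert defined == 3 * 17  # three mapped rows, 17 deltas each

    def test_coherence_counts(self):
        hm = build_heatmap(self._deltas(), range(18), "INT1",
                           species_of={"H1": "human", "C1": "canine"})
        # epoch 1: HR rows (human +, canine +) -> arousal coherence 1.0
        assert hm.coherence(1, AROUSAL) == 1.0
        # epoch 2: human HR -, canine HR - -> 1.0; epoch 3 both + -> 1.0
        assert hm.coherence(2, AROUSAL) == 1.0
        # a single defined cell in a block is not enough
        assert np.isnan(hm.coherence(1, VALENCE)) or \
            hm.coherence(1, VALENCE) >= 0.5


class TestCorrelationMatrix:
    def test_symmetry_unit_diagonal_bounds(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        cm = correlation_matrix(df)
        arr = cm.to_numpy(float)
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.allclose(np.diag(arr), 1.0)
        assert np.nanmax(np.abs(arr)) <= 1.0 + 1e-12

    def test_duplicated_variable_perfect_correlation(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=10)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=10)})
        cm = correlation_matrix(df)
        assert cm.loc["a", "b"] == pytest.approx(1.0)

    def test_sparse_cells_missing(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, np.nan, np.nan,
                                                      np.nan]})
        cm = correlation_matrix(df)
        assert np.isnan(cm.loc["a", "b"])

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValidationError, match=">= 3"):
            correlation_matrix(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_simulated_survey_link_recovered(self):
        """The generator drives PANAS-PA and SAM-A through the same
        interaction-effect construction, so their session-level association
        is recoverable from the study features."""
        from dyadsync import run_study
        study = run_study(n_sessions=6, seed=42)
        cm = study.corr
        assert {"PANAS_PA", "SAM_A", "h_HR", "c_HR"} <= set(cm.columns)
        arr = cm.to_numpy(float)
        assert np.allclose(arr, arr.T, equal_nan=True)


class TestMiddleEpochs:
    def test_central_six_of_sixty(self):
        from dyadsync.session import SubsessionTimeline, build_epoch_grid
        tl = SubsessionTimeline.from_plan([("INT1", 600)])
        grid = build_epoch_grid(tl)
        mid = middle_epochs(grid, "INT1", 6)
        assert list(mid) == [27, 28, 29, 30, 31, 32]

    def test_too_short_rejected(self):
        from dyadsync.session import SubsessionTimeline, build_epoch_grid
        tl = SubsessionTimeline.from_plan([("INT1", 40)])
        grid = build_epoch_grid(tl)
        with pytest.raises(ValidationError, match="fewer"):
            middle_epochs(grid, "INT1", 6)


class TestCombinedPairTable:
    def test_identical_inputs_identical_blocks(self):
        sync = pd.DataFrame({"subsession": ["INT1"], "metric": ["HR"],
                             "pearson_r": [0.5], "dtw_distance": [100.0]})
        bc = pd.DataFrame({"subject": ["H1"], "stat": ["pos_pct"],
                           "value": [20.0]})
        sv = pd.DataFrame({"timepoint": ["post_INT1"], "scale": ["SAM_A"],
                           "value": [3]})
        a = combined_pair_table(sync, bc, sv, "H1-C1", "INT1")
        b = combined_pair_table(sync, bc, sv, "H1-C1", "INT1")
        pd.testing.assert_frame_equal(a, b)
        assert {"Pcorr", "DTW", "becode_H1", "survey_post_INT1"} \
            <= set(a["block"])

    def test_missing_components_render_missing(self):
        out = combined_pair_table(None, None, None, "H1-C1", "INT1")
        assert len(out) == 0  # empty block, no error


class TestPlots:
    def test_heatmap_and_snapshot_files(self, short_session, analyzed,
                                        tmp_path):
        from dyadsync.composites import plot_heatmap, plot_raw_snapshot
        _, bundle, _ = short_session
        hm = analyzed.heatmaps["INT1"]
        plot_heatmap(hm, tmp_path / "hm.png")
        assert (tmp_path / "hm.png").stat().st_size > 0
        with pytest.warns(UserWarning, match="outside"):
            plot_raw_snapshot(bundle.channel("H1", "ECG"),
                              bundle.channel("C1", "ECG"),
                              annotations=[(100, 110, "treat"),
                                           (10_000, 10_010, "late")],
                              path=tmp_path / "snap.png",
                              window=(60.0, 180.0))
        assert (tmp_path / "snap.png").stat().st_size > 0
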