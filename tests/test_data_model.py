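"""Session/record/master structure, annotation arithmetic and serialization."""

import numpy as np
import pytest
import scipy.io

from mepkit.data_model import (DataFormatError, RecordFile, ResultsBundle,
                               SessionData, SessionResult, ValidationError,
                               annotate_session, build_master, build_record,
                               export_results, load_master, load_record,
                               load_results, load_session, remove_trials,
                               reorder_by_intensity, save_record,
                               save_session, save_master)


def _session(n_sweeps=60, n_samples=100, n_channels=1, annotate=True,
             n_int=6, rng=None):
    rng = rng or np.random.default_rng(1)
    data = SessionData(rng.normal(size=(n_samples, n_channels, n_sweeps)))
    if annotate:
        trials = np.full(n_int, n_sweeps // n_int)
        data = annotate_session(data, np.arange(1, n_int + 1, dtype=float),
                                trials, 5000.0)
    return data


class TestLoadSession:
    def test_mat_identity_layout(self, tmp_path):
        arr = np.random.default_rng(0).normal(size=(1000, 1, 60))
        scipy.io.savemat(tmp_path / "s.mat", {"sweeps": arr})
        sess = load_session(tmp_path / "s.mat")
        assert sess.sweeps.shape == (1000, 1, 60)
        assert sess.n_sweeps == 60 and sess.n_channels == 1

    @pytest.mark.parametrize("layout,shape", [
        (("sweeps", "samples"), (5, 9)),
        (("samples", "sweeps"), (9, 5)),
        (("sweeps", "channels", "samples"), (5, 2, 9)),
        (("channels", "samples", "sweeps"), (2, 9, 5)),
    ])
    def test_layout_transposition_preserves_elements(self, tmp_path, layout,
                                                     shape):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=shape)
        scipy.io.savemat(tmp_path / "s.mat", {"x": arr})
        sess = load_session(tmp_path / "s.mat", dataset_key="x",
                            layout=layout)
        assert sess.sweeps.shape == (9, 2 if len(shape) == 3 else 1, 5)
        # element-wise lookup oracle against the stored array
        for t, c, k in [(0, 0, 0), (3, 0, 2), (8, 0, 4)]:
            idx = tuple({"samples": t, "channels": c, "sweeps": k}[a]
                        for a in layout)
            assert sess.sweeps[t, c, k] == arr[idx]

    def test_unreadable_container(self, tmp_path):
        p = tmp_path / "notes.txt"
        p.write_text("this is not a session container")
        with pytest.raises(DataFormatError):
            load_session(p)

    def test_missing_file_and_bad_ndim(self, tmp_path):
        with pytest.raises(DataFormatError):
            load_session(tmp_path / "absent.mat")
        scipy.io.savemat(tmp_path / "bad.mat",
                         {"x": np.zeros((2, 2, 2, 2))})
        with pytest.raises(DataFormatError):
            load_session(tmp_path / "bad.mat", dataset_key="x")

    def test_hdf5_roundtrip_bit_identical(self, tmp_path):
        sess = _session()
        save_session(sess, tmp_path / "s.h5")
        back = load_session(tmp_path / "s.h5")
        assert np.array_equal(back.sweeps, sess.sweeps)
        assert np.array_equal(back.stim_intensities, sess.stim_intensities)
        assert np.array_equal(back.trials_per_stim, sess.trials_per_stim)
        assert back.sampling_rate_hz == sess.sampling_rate_hz


class TestAnnotate:
    def test_six_by_ten_is_sixty(self):
        sess = _session(60, annotate=False)
        out = annotate_session(sess, np.arange(1.0, 7.0), np.full(6, 10),
                               5000.0)
        assert out.n_sweeps == 60
        assert int(out.trials_per_stim.sum()) == 60

    def test_mismatch_rejected(self):
        sess = _session(60, annotate=False)
        with pytest.raises(ValidationError, match="mismatch"):
            annotate_session(sess, np.arange(1.0, 7.0),
                             np.array([10, 10, 10, 10, 10, 5]), 5000.0)

    def test_ragged_offsets(self):
        sess = _session(20, annotate=False)
        out = annotate_session(sess, [1.0, 2.0, 3.0], [5, 5, 10], 5000.0)
        # hand-enumerated flat indices per intensity block
        assert [out.sweep_index(0, 0), out.sweep_index(1, 0),
                out.sweep_index(2, 0)] == [0, 5, 10]
        assert out.sweep_index(2, 9) == 19

    def test_non_ascending_rejected(self):
        sess = _session(20, annotate=False)
        with pytest.raises(ValidationError, match="ascending"):
            annotate_session(sess, [2.0, 1.0], [10, 10], 5000.0)

    @pytest.mark.parametrize("fs,trials", [(0.0, [10, 10]), (-1.0, [10, 10]),
                                           (5000.0, [20, 0])])
    def test_bad_rate_or_trials(self, fs, trials):
        sess = _session(20, annotate=False)
        with pytest.raises(ValidationError):
            annotate_session(sess, [1.0, 2.0], trials, fs)


class TestReorder:
    def test_stable_sort_example(self):
        sess = _session(4, annotate=False)
        out = reorder_by_intensity(sess, [2.0, 1.0, 1.0, 2.0])
        # stable order: sweeps 1,2 (label 1) then 0,3 (label 2)
        for new, old in enumerate([1, 2, 0, 3]):
            assert np.array_equal(out.sweeps[:, :, new],
                                  sess.sweeps[:, :, old])
        assert np.array_equal(out.stim_intensities, [1.0, 2.0])
        assert np.array_equal(out.trials_per_stim, [2, 2])

    def test_idempotent(self):
        sess = _session(6, annotate=False)
        labels = [3.0, 1.0, 2.0, 1.0, 3.0, 2.0]
        once = reorder_by_intensity(sess, labels)
        sorted_labels = sorted(labels)
        twice = reorder_by_intensity(once, sorted_labels)
        assert np.array_equal(once.sweeps, twice.sweeps)

    def test_label_count_mismatch(self):
        sess = _session(2, annotate=False)
        with pytest.raises(ValidationError):
            reorder_by_intensity(sess, [1.0])


class TestRemoveTrials:
    def test_fig8_layout_recount(self):
        sess = _session(45, n_int=9)
        out = remove_trials(sess, [(2, 1)])
        assert out.n_sweeps == 44
        assert out.trials_per_stim[2] == 4
        assert np.array_equal(np.delete(sess.sweeps, 11, axis=2), out.sweeps)

    def test_empty_flag_list_identity(self):
        sess = _session(45, n_int=9)
        assert remove_trials(sess, []) is sess

    def test_cannot_empty_an_intensity(self):
        sess = _session(45, n_int=9)
        flags = [(0, j) for j in range(5)]
        with pytest.raises(ValidationError, match="left empty"):
            remove_trials(sess, flags)

    def test_count_decreases_by_flag_count(self):
        sess = _session(45, n_int=9)
        flags = [(0, 0), (3, 2), (8, 4)]
        out = remove_trials(sess, flags)
        assert out.n_sweeps == sess.n_sweeps - len(flags)
        assert int(out.trials_per_stim.sum()) == out.n_sweeps


class TestRecordMaster:
    def _sessions(self, n):
        return [(k, f"s{k}.h5", "baseline" if k == 0 else f"c{k}")
                for k in range(n)]

    def test_baseline_is_first(self):
        rec = build_record("rat1", self._sessions(3))
        assert rec.baseline_index == 0
        assert rec.sessions[0][2] == "baseline"

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            RecordFile("rat1", [(0, "a.h5", "x"), (0, "b.h5", "y")])

    def test_master_rejects_unequal_session_counts(self):
        r1 = build_record("rat1", self._sessions(4))
        r2 = build_record("rat2", self._sessions(3))
        with pytest.raises(ValidationError, match="same number"):
            build_master([r1, r2])

    def test_master_4x4(self):
        records = [build_record(f"rat{i}", self._sessions(4))
                   for i in range(4)]
        m = build_master(records)
        assert len(m.records) == 4
        assert len(m.condition_labels) == 4

    def test_manifest_roundtrip(self, tmp_path):
        rec = build_record("rat1", self._sessions(2))
        save_record(rec, tmp_path / "rec.json")
        back = load_record(tmp_path / "rec.json")
        assert back.subject_id == "rat1"
        assert [s[2] for s in back.sessions] == ["baseline", "c1"]
        save_master(build_master([rec]), tmp_path / "master.json",
                    ["rec.json"])
        m = load_master(tmp_path / "master.json")
        assert len(m.records) == 1


class TestExportResults:
    def _bundle(self):
        rng = np.random.default_rng(7)
        per_trial = [rng.normal(size=5) for _ in range(6)]
        return ResultsBundle(sessions=[SessionResult(
            session_id=1, start_ms=8.0, stop_ms=22.0, channel_index=0,
            filtered=False, sampling_rate_hz=5000.0,
            stim_intensities=np.arange(1.0, 7.0),
            trials_per_stim=np.full(6, 5),
            epochs=rng.normal(size=(70, 30)), metric_name="rms",
            per_trial=per_trial,
            per_intensity_mean=np.array([v.mean() for v in per_trial]),
            fit_params={"P": 0.1, "M": 2.0, "L": 0.0, "K": 3.0, "Q": 1.0},
            fit_error=0.02, tolerance_used=0.1, r_squared=0.99,
            saturated=True, iterations=3,
            rec_curve_x=np.linspace(1, 6, 50),
            rec_curve_y=np.linspace(0.1, 2.0, 50))])

    def test_hdf5_roundtrip_identity(self, tmp_path):
        bundle = self._bundle()
        export_results(bundle, tmp_path / "res.h5", "hdf5")
        back = load_results(tmp_path / "res.h5")
        s0, s1 = bundle.sessions[0], back.sessions[0]
        for name in ("stim_intensities", "trials_per_stim", "epochs",
                     "per_intensity_mean", "rec_curve_x", "rec_curve_y"):
            assert np.array_equal(getattr(s0, name), getattr(s1, name))
        for a, b in zip(s0.per_trial, s1.per_trial):
            assert np.array_equal(a, b)
        assert s1.fit_params == s0.fit_params

    def test_csv_export_layout(self, tmp_path):
        bundle = self._bundle()
        files = export_results(bundle, tmp_path / "out", "csv")
        means = (tmp_path / "out" / "per_intensity_mean.csv").read_text()
        assert len(means.strip().splitlines()) == 1 + 6  # header + 6 rows
        import json
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["sessions"][0]["metric"] == "rms"
        assert manifest["sessions"][0]["tolerance"] == 0.1
        assert any(p.endswith("manifest.json") for p in files)

    def test_partial_bundle_refused(self, tmp_path):
        bundle = self._bundle()
        bundle.sessions[0].per_intensity_mean = np.empty(0)
        with pytest.raises(ValidationError):
            export_results(bundle, tmp_path / "res.h5", "hdf5")
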