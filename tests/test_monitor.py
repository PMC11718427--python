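"""Monitoring models: campaign alignment, golden-batch control charts and
excursion detection, batch-wise unfolding and whole-batch classification."""

import numpy as np
import pytest

from cmpmonitor import FluxMatrix, align_campaign, classify_batch, monitor_batch
from cmpmonitor import monitor as mon
from cmpmonitor.monitor import (
    bem_from_dict, bem_to_dict, blm_from_dict, blm_to_dict, classify_flux_matrix,
    separation_statistic, train_bem, train_blm, train_blm_from_campaign,
    unfold_batchwise,
)


def stub_matrix(batch_id, times, values=None, n_cols=3):
    times = np.asarray(times, dtype=float)
    if values is None:
        rng = np.random.default_rng(abs(hash(batch_id)) % 2**31)
        values = rng.normal(size=(times.size, n_cols))
    return FluxMatrix(batch_id=batch_id, times=times,
                      columns=[f"r{i}" for i in range(n_cols - 1)] + ["total_ATP"],
                      values=np.asarray(values, dtype=float))


class TestAlignment:
    def test_identical_daily_batches_keep_all_anchors(self):
        times = np.arange(0.0, 241.0, 24.0)
        aligned = align_campaign([stub_matrix("a", times), stub_matrix("b", times)])
        assert aligned.common_times.size == 11
        np.testing.assert_array_equal(aligned.common_times, times)

    def test_shorter_batch_truncates_the_grid(self):
        long = stub_matrix("a", np.arange(0.0, 241.0, 24.0))
        short = stub_matrix("b", np.arange(0.0, 217.0, 24.0))
        aligned = align_campaign([long, short])
        assert aligned.common_times[-1] == 216.0

    def test_jittered_times_match_within_window(self):
        rng = np.random.default_rng(0)
        base = np.arange(0.0, 241.0, 24.0)
        jittered = stub_matrix("a", base + rng.uniform(-1, 1, base.size))
        clean = stub_matrix("b", base)
        aligned = align_campaign([jittered, clean])
        assert aligned.common_times.size == base.size

    def test_post_feed_samples_lose_the_tie(self):
        times = np.sort(np.append(np.arange(0.0, 241.0, 24.0), [72.1, 144.1]))
        m = stub_matrix("a", times)
        aligned = align_campaign([m])
        assert aligned.common_times.size == 11
        # the matched row at 72 h is the pre-feed row, not the 72.1 one
        i72 = list(times).index(72.0)
        np.testing.assert_array_equal(
            aligned.values[0, list(aligned.common_times).index(72.0)], m.values[i72])

    def test_empty_intersection_rejected(self):
        a = stub_matrix("a", [0.0, 24.0])
        b = stub_matrix("b", [120.0, 144.0])
        with pytest.raises(ValueError, match="intersection"):
            align_campaign([a, b])

    def test_max_time_truncation(self):
        m = stub_matrix("a", np.arange(0.0, 241.0, 24.0))
        aligned = align_campaign([m], max_time_h=216.0)
        assert aligned.common_times[-1] == 216.0


class TestUnfolding:
    def test_shape_and_column_order(self):
        times = np.arange(0.0, 9 * 24.0, 24.0)
        mats = [stub_matrix(f"b{i}", times) for i in range(12)]
        aligned = align_campaign(mats)
        rows = unfold_batchwise(aligned)
        assert rows.shape == (12, 9 * 3)
        # time-major: the first n_cols entries are the first time's variables
        np.testing.assert_array_equal(rows[0, :3], aligned.values[0, 0])
        ids = mon.batchwise_column_ids(aligned)
        assert ids[0] == "t0h:r0" and ids[3] == "t24h:r0"

    def test_identical_batches_identical_rows(self):
        times = np.arange(0.0, 120.0, 24.0)
        m = stub_matrix("a", times)
        twin = stub_matrix("b", times, values=m.values)
        rows = unfold_batchwise(align_campaign([m, twin]))
        np.testing.assert_array_equal(rows[0], rows[1])

    def test_batch_permutation_permutes_rows_only(self):
        times = np.arange(0.0, 120.0, 24.0)
        mats = [stub_matrix(f"b{i}", times) for i in range(4)]
        r1 = unfold_batchwise(align_campaign(mats))
        r2 = unfold_batchwise(align_campaign(mats[::-1]))
        np.testing.assert_array_equal(r1, r2[::-1])


@pytest.fixture(scope="module")
def trained_bem(training_campaign):
    normals = training_campaign.by_condition("normal")[:6]
    aligned = align_campaign([training_campaign.matrices[i] for i in normals])
    return train_bem(aligned, n_components=3)


class TestBem:

    def test_chart_count_matches_components(self, training_campaign):
        normals = training_campaign.by_condition("normal")[:2]
        aligned = align_campaign([training_campaign.matrices[i] for i in normals])
        bem = train_bem(aligned, n_components=1)
        assert len(bem.charts) == 1
        assert bem.monitored_components == [1]

    def test_two_identical_batches_flagged_degenerate(self):
        times = np.arange(0.0, 120.0, 24.0)
        m = stub_matrix("a", times)
        twin = stub_matrix("b", times, values=m.values)
        with pytest.warns(UserWarning, match="degenerate"):
            train_bem(align_campaign([m, twin]), n_components=1)

    def test_single_batch_rejected(self):
        m = stub_matrix("a", np.arange(0.0, 120.0, 24.0))
        with pytest.raises(ValueError, match="2 training batches"):
            train_bem(align_campaign([m]), 1)

    def test_training_batches_stay_inside_their_own_limits(self, trained_bem,
                                                           training_campaign):
        """A training batch can deviate at most (n-1)/sqrt(n) ~ 2.04 SD from
        the 6-batch mean, so it can never breach the ±3 SD chart."""
        normals = training_campaign.by_condition("normal")[:6]
        for i in normals:
            report = monitor_batch(trained_bem, training_campaign.matrices[i])
            assert report.in_control.all()
            assert report.first_excursion_time is None

    def test_heldout_normals_covered_at_three_sigma(self, trained_bem, training_campaign):
        held = training_campaign.by_condition("normal")[6:]
        in_pts = tot = 0
        for i in held:
            report = monitor_batch(trained_bem, training_campaign.matrices[i])
            in_pts += report.in_control.sum()
            tot += report.in_control.size
        assert in_pts / tot >= 0.90

    def test_shifted_batches_detected_after_the_shift(self, trained_bem, training_campaign):
        shifted = training_campaign.by_condition("shifted")
        for i in shifted:
            rec = training_campaign.records[i]
            report = monitor_batch(trained_bem, training_campaign.matrices[i], sustained_k=3)
            assert report.first_excursion_time is not None
            assert report.first_excursion_time >= rec.shift_time
            assert report.first_excursion_time <= rec.shift_time + 48.0

    def test_monitoring_does_not_mutate_the_model(self, trained_bem, training_campaign):
        chart_mean = trained_bem.charts[0].mean.copy()
        m = training_campaign.matrices[training_campaign.by_condition("shifted")[0]]
        r1 = monitor_batch(trained_bem, m)
        r2 = monitor_batch(trained_bem, m)
        np.testing.assert_array_equal(trained_bem.charts[0].mean, chart_mean)
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_column_mismatch_reported(self, trained_bem):
        alien = stub_matrix("x", np.arange(0.0, 241.0, 24.0), n_cols=4)
        with pytest.raises(ValueError, match="mismatch"):
            monitor_batch(trained_bem, alien)

    def test_report_frame_layout(self, trained_bem, training_campaign):
        m = training_campaign.matrices[0]
        frame = monitor_batch(trained_bem, m).to_frame(trained_bem)
        assert list(frame.columns) == ["batch_id", "time_h", "component",
                                       "score", "lower", "upper", "in_control"]
        assert (frame["lower"] <= frame["upper"]).all()


@pytest.fixture(scope="module")
def trained_blm(training_campaign):
    idx = (training_campaign.by_condition("normal")[:6]
           + training_campaign.by_condition("shifted")[:6])
    aligned = align_campaign([training_campaign.matrices[i] for i in idx])
    labels = [training_campaign.records[i].condition for i in idx]
    return train_blm_from_campaign(aligned, labels, n_components=2), idx, aligned


class TestBlm:

    def test_training_classification_is_perfect(self, trained_blm, training_campaign):
        blm, idx, aligned = trained_blm
        rows = unfold_batchwise(aligned)
        for row, i in zip(rows, idx):
            label, _ = classify_batch(blm, row)
            assert label == training_campaign.records[i].condition

    def test_threshold_sits_between_class_means(self, trained_blm):
        blm, _, _ = trained_blm
        T = blm.latent.scores_train[:, blm.discriminating_component - 1]
        m_n, m_s = T[:6].mean(), T[6:].mean()
        assert min(m_n, m_s) < blm.threshold < max(m_n, m_s)

    def test_class_score_distributions_do_not_overlap(self, trained_blm):
        blm, _, _ = trained_blm
        T = blm.latent.scores_train[:, blm.discriminating_component - 1]
        normal, shifted = T[:6], T[6:]
        if normal.mean() > shifted.mean():
            assert normal.min() > shifted.max()
        else:
            assert normal.max() < shifted.min()

    def test_shuffled_labels_separate_worse(self, trained_blm):
        """Permutation sanity check: the labeled separation exceeds the
        separation of randomly relabeled data."""
        blm, idx, aligned = trained_blm
        rows = unfold_batchwise(aligned)
        labels = ["normal"] * 6 + ["shifted"] * 6
        observed = separation_statistic(rows, labels, 2)
        rng = np.random.default_rng(0)
        beaten = 0
        for _ in range(100):
            perm = rng.permutation(12)
            shuffled = [labels[i] for i in perm]
            if separation_statistic(rows, shuffled, 2) >= observed:
                beaten += 1
        assert beaten == 0

    def test_tie_classified_as_shifted(self, trained_blm):
        blm, _, aligned = trained_blm
        # build a row that projects exactly onto the threshold
        direction = np.zeros(blm.latent.n_components)
        direction[blm.discriminating_component - 1] = blm.threshold
        scaler = blm.latent.scaler
        base = scaler.means.copy()
        row = np.zeros(scaler.n_columns)
        row[scaler.retained] = base + (blm.latent.loadings @ direction) * scaler.sds
        label, score = classify_batch(blm, row)
        assert score == pytest.approx(blm.threshold, abs=1e-8)
        assert label == "shifted"

    def test_duplicated_batches_with_flipped_labels_rejected(self):
        times = np.arange(0.0, 120.0, 24.0)
        mats = [stub_matrix(f"b{i}", times) for i in range(2)]
        twins = [stub_matrix(f"c{i}", times, values=m.values) for i, m in enumerate(mats)]
        aligned = align_campaign(mats + twins)
        rows = unfold_batchwise(aligned)
        with pytest.raises(ValueError, match="coincide|zero-width"):
            train_blm(rows, ["normal", "normal", "shifted", "shifted"], 2)

    def test_single_class_rejected(self):
        rows = np.random.default_rng(0).normal(size=(4, 6))
        with pytest.raises(ValueError, match="labels"):
            train_blm(rows, ["normal"] * 4, 2)

    def test_classify_flux_matrix_aligns_on_the_stored_grid(self, trained_blm,
                                                            training_campaign):
        blm, idx, _ = trained_blm
        held = [i for i in training_campaign.by_condition("shifted") if i not in idx]
        m = training_campaign.matrices[held[0]]
        label, _ = classify_flux_matrix(blm, m)
        assert label == "shifted"

    def test_serialization_round_trips(self, trained_blm, training_campaign):
        blm, idx, aligned = trained_blm
        back = blm_from_dict(blm_to_dict(blm))
        row = unfold_batchwise(aligned)[0]
        assert classify_batch(back, row) == classify_batch(blm, row)

        normals = training_campaign.by_condition("normal")[:6]
        bem = train_bem(align_campaign([training_campaign.matrices[i] for i in normals]), 2)
        bem_back = bem_from_dict(bem_to_dict(bem))
        m = training_campaign.matrices[normals[0]]
        np.testing.assert_allclose(monitor_batch(bem_back, m).scores,
                                   monitor_batch(bem, m).scores, atol=1e-12)
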