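import numpy as np
import pandas as pd
import pytest

from vocalnet import (
    SimulationConfig,
    estimate_transition_matrix,
    make_classifier_corpus,
    render_session,
    simulate_caller_stream,
    simulate_session,
    simulate_spaced_stream,
)


class TestCallerStream:
    def test_same_seed_identical_tables(self):
        cfg = SimulationConfig(seed=10, duration_s=120.0)
        t1, _ = simulate_caller_stream(cfg)
        t2, _ = simulate_caller_stream(cfg)
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_degenerate_self_transition_matrix(self):
        P = np.eye(4)
        cfg = SimulationConfig(seed=3, duration_s=200.0, transition_matrix=P)
        table, _ = simulate_caller_stream(cfg)
        assert table.df["bird_id"].nunique() == 1

    def test_uniform_matrix_recovered_from_long_stream(self):
        cfg = SimulationConfig(seed=4, duration_s=10_000.0, call_rate_hz=0.25)
        table, truth = simulate_caller_stream(cfg)
        assert len(table) >= 9000
        m = estimate_transition_matrix(table.df["bird_id"].tolist(), cfg.bird_ids)
        assert np.abs(m.probs - 0.25).max() < 0.02

    def test_invalid_transition_matrix_rejected(self):
        cfg = SimulationConfig(seed=1, transition_matrix=np.full((4, 4), 0.3))
        with pytest.raises(ValueError, match="row-stochastic"):
            simulate_caller_stream(cfg)

    def test_events_fit_in_duration(self):
        cfg = SimulationConfig(seed=6, duration_s=30.0, call_rate_hz=1.0)
        table, _ = simulate_caller_stream(cfg)
        assert (table.df["end_s"] <= 30.0).all()

    def test_spaced_stream_nonoverlap_guarantee(self):
        cfg = SimulationConfig(seed=9)
        table, _ = simulate_spaced_stream(cfg, 50, gap_s=0.5)
        df = table.df
        assert (df["start_s"].values[1:] >= df["end_s"].values[:-1]).all()

    def test_spaced_stream_overlap_pairs_are_diagonal(self):
        cfg = SimulationConfig(seed=9)
        table, _ = simulate_spaced_stream(cfg, 100, overlap_fraction=0.2)
        df = table.df
        overlapping = []
        for i in range(len(df) - 1):
            if df["end_s"].iloc[i] > df["start_s"].iloc[i + 1]:
                overlapping.append((df["bird_id"].iloc[i], df["bird_id"].iloc[i + 1]))
        assert len(overlapping) == 10
        assert all({a, b} in ({"bird1", "bird3"}, {"bird2", "bird4"}) for a, b in overlapping)


class TestRenderSession:
    def test_emitter_channel_loudest_and_earliest(self, quiet_config):
        table, _ = simulate_spaced_stream(quiet_config, 1)
        session, _ = render_session(table, quiet_config)
        bird = table.df["bird_id"].iloc[0]
        peaks = {b: float(np.abs(session.channel(b)).max()) for b in session.layout.bird_ids}
        assert max(peaks, key=peaks.get) == bird
        onsets = {b: int(np.flatnonzero(np.abs(session.channel(b)) > 1e-6)[0])
                  for b in session.layout.bird_ids}
        assert min(onsets, key=onsets.get) == bird

    def test_cross_channel_delay_matches_geometry(self, quiet_config, layout):
        table, _ = simulate_spaced_stream(quiet_config, 1)
        session, _ = render_session(table, quiet_config)
        bird = table.df["bird_id"].iloc[0]
        diagonal = {"bird1": "bird3", "bird2": "bird4", "bird3": "bird1", "bird4": "bird2"}[bird]
        sr = session.sample_rate
        onset_own = np.flatnonzero(np.abs(session.channel(bird)) > 1e-6)[0]
        onset_diag = np.flatnonzero(np.abs(session.channel(diagonal)) > 1e-6)[0]
        expected = (layout.distance_m(bird, diagonal) - layout.distance_m(bird, bird)) / 343.0
        assert (onset_diag - onset_own) / sr == pytest.approx(expected, abs=1.5 / sr)

    def test_attenuation_follows_inverse_distance(self, quiet_config, layout):
        table, _ = simulate_spaced_stream(quiet_config, 1)
        session, _ = render_session(table, quiet_config)
        bird = table.df["bird_id"].iloc[0]
        diagonal = {"bird1": "bird3", "bird2": "bird4", "bird3": "bird1", "bird4": "bird2"}[bird]
        ratio = np.abs(session.channel(bird)).max() / np.abs(session.channel(diagonal)).max()
        expected = layout.distance_m(bird, diagonal) / layout.distance_m(bird, bird)
        assert ratio == pytest.approx(expected, rel=0.05)

    def test_zero_events_gives_noise_only(self):
        from vocalnet import EventTable

        cfg = SimulationConfig(seed=2, duration_s=5.0, click_rate_hz=0.0)
        session, _ = render_session(EventTable.empty(), cfg, duration_s=5.0)
        x = session.channel("bird1")
        assert np.abs(x).max() < 6 * cfg.noise_level  # Gaussian tail only
        assert np.abs(x).max() > 0

    def test_render_deterministic(self, quiet_config):
        s1, _ = simulate_session(quiet_config)
        s2, _ = simulate_session(quiet_config)
        np.testing.assert_array_equal(s1.channel("bird2"), s2.channel("bird2"))


class TestClassifierCorpus:
    def test_balanced_counts(self):
        corpus = make_classifier_corpus(20, SimulationConfig(seed=30))
        assert len(corpus) == 40
        assert corpus.labels.count("vocalization") == 20

    def test_same_seed_byte_identical(self):
        c1 = make_classifier_corpus(15, SimulationConfig(seed=31))
        c2 = make_classifier_corpus(15, SimulationConfig(seed=31))
        for a, b in zip(c1.clips, c2.clips):
            np.testing.assert_array_equal(a, b)

    def test_calls_have_higher_inband_energy_fraction(self):
        # band-energy oracle via direct rFFT over each whole clip
        corpus = make_classifier_corpus(40, SimulationConfig(seed=32))

        def inband_fraction(clip):
            spec = np.abs(np.fft.rfft(clip)) ** 2
            freqs = np.fft.rfftfreq(len(clip), 1 / corpus.sample_rate)
            band = (freqs >= 500) & (freqs <= 6000)
            return spec[band].sum() / spec.sum()

        fractions = {"vocalization": [], "non-vocalization": []}
        for clip, label in zip(corpus.clips, corpus.labels):
            fractions[label].append(inband_fraction(clip))
        assert np.mean(fractions["vocalization"]) > np.mean(fractions["non-vocalization"])

    def test_too_few_clips_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            make_classifier_corpus(5, SimulationConfig(seed=33))

    def test_corpus_save_manifest(self, tmp_path):
        corpus = make_classifier_corpus(10, SimulationConfig(seed=34))
        manifest = corpus.save(tmp_path / "corpus")
        df = pd.read_csv(manifest)
        assert len(df) == 20
        assert (tmp_path / "corpus" / df["clip_path"].iloc[0]).exists()


class TestFullPipelineStatisticalRecovery:
    def test_networks_from_recovered_table_match_truth_networks(self):
        """cc and max-transition edges from detect->attribute output stay
        within 0.05 of the same edges computed from the true event table."""
        from vocalnet import (
            attribute_session,
            build_cc_network,
            caller_sequence,
            detect_session,
            max_transition_edges,
        )

        config = SimulationConfig(seed=60, click_rate_hz=0.0)
        table, truth = simulate_spaced_stream(config, 120, gap_s=1.0, overlap_fraction=0.1)
        session, _ = render_session(table, config)
        recovered = attribute_session(detect_session(session), session.layout)
        dur = session.duration_s

        cc_true = build_cc_network(truth.table, config.bird_ids, dur)
        cc_rec = build_cc_network(recovered, config.bird_ids, dur)
        for dyad, w in cc_true.weights.items():
            assert abs(w - cc_rec.weights[dyad]) <= 0.05, dyad

        mt_true = max_transition_edges(
            estimate_transition_matrix(caller_sequence(truth.table), config.bird_ids))
        mt_rec = max_transition_edges(
            estimate_transition_matrix(caller_sequence(recovered), config.bird_ids))
        for dyad, w in mt_true.weights.items():
            assert abs(w - mt_rec.weights[dyad]) <= 0.05, dyad
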