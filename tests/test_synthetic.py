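"""Generator behaviour: trace shapes, seeded determinism, sampling laws."""

import numpy as np
import pytest
from scipy import stats

from clonefate import synthetic as syn
from clonefate.classify import compute_response_threshold
from clonefate.transitions import gate_events


def make_params(**over):
    base = dict(fate="DP", onset_time_G=20.0, onset_time_R=40.0,
                amplitude_G=150.0, amplitude_R=150.0, baseline=100.0,
                rise_width=0.5, division_times=(), noise_sd=0.0, seed=1)
    base.update(over)
    return syn.CloneParams(**base)


class TestCloneTrace:
    def test_zero_amplitude_noise_free_trace_is_flat_baseline(self):
        spec = syn.th17_spec()
        params = make_params(fate="DN", amplitude_G=0.0, amplitude_R=0.0)
        trace = syn.simulate_clone_trace(params, spec)
        assert np.all(trace.total_G == 100.0)
        assert np.all(trace.total_R == 100.0)

    def test_sigmoid_midpoint_sits_at_onset_time(self):
        spec = syn.th17_spec()
        params = make_params(fate="SPR", amplitude_R=0.0, onset_time_G=20.0,
                             rise_width=0.05)
        trace = syn.simulate_clone_trace(params, spec)
        half = 100.0 + 150.0 / 2
        # t = 20 is on the frame grid: the sigmoid is exactly at half-rise
        i20 = np.flatnonzero(trace.times == 20.0)[0]
        assert trace.total_G[i20] == pytest.approx(half)
        crossing = trace.times[np.flatnonzero(trace.total_G > half)[0]]
        assert 19.5 <= crossing <= 20.5

    def test_same_seed_gives_bitwise_identical_traces_and_pixels(self):
        spec = syn.th17_spec()
        params = make_params(noise_sd=25.0, division_times=(38.0, 50.0))
        t1 = syn.simulate_clone_trace(params, spec)
        t2 = syn.simulate_clone_trace(params, spec)
        assert np.array_equal(t1.total_G, t2.total_G)
        assert np.array_equal(t1.total_R, t2.total_R)
        f1 = syn.simulate_well_pixels(params, spec)
        f2 = syn.simulate_well_pixels(params, spec)
        assert all(np.array_equal(a.G, b.G) and np.array_equal(a.R, b.R)
                   for a, b in zip(f1, f2))

    def test_partial_pixel_render_matches_full_render(self):
        spec = syn.th17_spec()
        params = make_params(noise_sd=10.0, division_times=(38.0,))
        full = syn.simulate_well_pixels(params, spec)
        last = syn.simulate_well_pixels(params, spec,
                                        frame_indices=range(100, 105))
        for sub, ref in zip(last, full[100:]):
            assert np.array_equal(sub.G, ref.G)

    def test_non_positive_rise_width_rejected(self):
        with pytest.raises(ValueError, match="rise_width"):
            make_params(rise_width=0.0)

    def test_trace_length_is_duration_over_interval_plus_one(self):
        spec = syn.th17_spec()
        trace = syn.simulate_clone_trace(make_params(), spec)
        assert len(trace.times) == 105
        assert trace.times[-1] == 52.0

    def test_total_fluorescence_continuous_at_division_times(self):
        # daughters split the parent's signal: no jump at division, and a
        # step-doubling model would jump by ~amplitude/2 here
        spec = syn.th17_spec()
        params = make_params(fate="SPR", amplitude_R=0.0, onset_time_G=20.0,
                             division_times=(30.0, 42.0))
        trace = syn.simulate_clone_trace(params, spec)
        jumps = np.abs(np.diff(trace.total_G))
        assert jumps.max() < 40.0
        # by the second division the signal has doubled relative to the first
        g = trace.total_G - 100.0
        i30 = np.flatnonzero(trace.times == 30.0)[0]
        i42 = np.flatnonzero(trace.times == 42.0)[0]
        assert g[i42] == pytest.approx(2 * g[i30], rel=1e-6)


class TestPopulation:
    def test_forced_fate_fraction_one(self):
        spec = syn.th17_spec(n_clones=50, fate_fractions={"SPR": 1.0})
        records = syn.simulate_population(spec, seed=3)
        assert all(r.params.fate == "SPR" for r in records)

    def test_fate_fractions_recovered_within_3_binomial_sd(self):
        spec = syn.th17_spec(n_clones=1000)
        records = syn.simulate_population(spec, seed=4)
        frac = np.mean([r.params.fate == "SPR" for r in records])
        sd = np.sqrt(0.57 * 0.43 / 1000)
        assert abs(frac - 0.57) < 3 * sd

    def test_onset_sampling_law_of_large_numbers(self):
        # n = 2000 sample mean/sd within 3 standard errors of the
        # configured RORγt onset distribution
        spec = syn.th17_spec(n_clones=2000, fate_fractions={"SPR": 1.0})
        records = syn.simulate_population(spec, seed=1234)
        onsets = np.array([r.params.onset_time_G for r in records])
        mean, sd = spec.onset_G_dist
        se_mean = sd / np.sqrt(len(onsets))
        assert abs(onsets.mean() - mean) < 3 * se_mean
        se_sd = sd / np.sqrt(2 * (len(onsets) - 1))
        assert abs(onsets.std(ddof=1) - sd) < 3 * se_sd
        # sampling is confined to the observation window
        assert onsets.min() >= 0 and onsets.max() <= spec.duration

    def test_division_times_follow_condition_distribution(self):
        spec = syn.treg_spec(n_clones=1500)
        records = syn.simulate_population(spec, seed=5)
        first = np.array([min(r.params.division_times) for r in records
                          if r.params.division_times])
        assert abs(first.mean() - 36.0) < 3 * 6.0 / np.sqrt(len(first))

    def test_invalid_fate_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            syn.th17_spec(fate_fractions={"SPR": 0.5})


class TestFlowEvents:
    def test_zero_transition_probability_gates_to_origin(self):
        events = syn.simulate_flow_events(
            2000, origin_fractions={"SPR": 0.5, "DP": 0.5}, seed=6)
        naive = syn.simulate_flow_events(
            300, origin_fractions={"DN": 1.0}, dye_labeling=False, seed=7)
        thr = compute_response_threshold(naive["G_intensity"],
                                         naive["R_intensity"], k=3.0)
        gates = gate_events(events, thr)
        assert (gates.to_numpy() == events["origin"].to_numpy()).mean() > 0.995

    def test_transition_probability_recovered_binomially(self):
        p = 0.217
        events = syn.simulate_flow_events(
            10_000, transition_probs={("SPR", "DP"): p}, seed=8)
        naive = syn.simulate_flow_events(
            300, origin_fractions={"DN": 1.0}, dye_labeling=False, seed=9)
        thr = compute_response_threshold(naive["G_intensity"],
                                         naive["R_intensity"], k=3.0)
        gates = gate_events(events, thr)
        dyed = events["dye_positive"]
        freq = (gates[dyed] == "DP").mean()
        assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / dyed.sum())

    def test_dye_labeling_off_drops_origin_columns(self):
        events = syn.simulate_flow_events(100, dye_labeling=False, seed=10)
        assert "origin" not in events.columns
        assert "dye_positive" not in events.columns

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            syn.simulate_flow_events(10, transition_probs={("SPR", "DP"): 1.5})


class TestExpressionTable:
    def test_all_spr_like_places_dp_at_spr_mean(self):
        table, truth = syn.simulate_expression_table(
            n_genes=100, frac_spr_like=1.0, frac_intermediate=0.0,
            frac_distinct=0.0, n_de=40, rep_sd=0.0, seed=11)
        de = truth[truth.is_de]
        assert np.allclose(de["mean_DP"], de["mean_SPR"])

    def test_zero_effect_size_yields_no_de_genes(self):
        from clonefate.similarity import differential_genes
        table, _ = syn.simulate_expression_table(
            n_genes=300, effect_size=0.0, n_de=100, seed=12)
        de = differential_genes(table)
        assert de["de_any"].sum() <= 3    # chance-level at p < 0.05

    def test_noise_free_round_trip_recovers_assigned_classes(self):
        from clonefate.similarity import bin_similarity, similarity_table
        table, truth = syn.simulate_expression_table(
            n_genes=400, n_de=200, rep_sd=0.0, seed=13)
        st = similarity_table(table).loc[truth.gene_id]
        de = truth.is_de.to_numpy()
        expected = truth.loc[de].apply(
            lambda row: {"SPR-like": "SPR-like", "SPF-like": "SPF-like",
                         "intermediate": "intermediate"}.get(
                row.true_class,
                "distinct-high" if row.true_similarity > 0 else "distinct-low"),
            axis=1)
        got = st["bin"].to_numpy()[de]
        assert (got == expected.to_numpy()).all()

    def test_n_reps_validation(self):
        with pytest.raises(ValueError, match="n_reps"):
            syn.simulate_expression_table(n_genes=10, n_reps=1)
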