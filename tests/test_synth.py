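import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meanet import (
    FiringParams,
    GrowthSchedule,
    LatentNetwork,
    MixtureSpec,
    StimProtocol,
    default_manifest,
    generate_latent_trajectory,
    generate_study,
    generate_z_mixture,
    simulate_spontaneous,
    simulate_stimulation_session,
)
from meanet.data import PLATING_TABLE
from meanet.synth import batch_adjusted_schedule, session_seed


class TestLatentTrajectory:
    def test_zero_growth_gives_zero_edges(self, emap):
        sched = dataclasses.replace(GrowthSchedule(), plateau_density=0.0)
        traj = generate_latent_trajectory(emap, sched, seed=0)
        assert all(net.n_edges == 0 for net in traj)

    def test_deterministic_given_seed(self, emap):
        a = generate_latent_trajectory(emap, GrowthSchedule(), seed=42)
        b = generate_latent_trajectory(emap, GrowthSchedule(), seed=42)
        for na, nb in zip(a, b):
            pd.testing.assert_frame_equal(na.edges, nb.edges)

    def test_edge_count_grows_between_early_and_late_days(self, emap):
        e3, e30 = [], []
        for seed in range(20):
            traj = generate_latent_trajectory(emap, GrowthSchedule(), seed=seed)
            e3.append(traj[2].n_edges)
            e30.append(traj[29].n_edges)
        assert np.mean(e3) < np.mean(e30)

    def test_core_edge_count_non_decreasing(self, emap):
        sched = GrowthSchedule()
        traj = generate_latent_trajectory(emap, sched, seed=3)
        targets = [sched.target_edge_count(d, 59) for d in range(1, 41)]
        counts = [net.n_edges for net in traj]
        assert counts == targets  # expressed count follows the monotone schedule
        assert all(t2 >= t1 for t1, t2 in zip(targets, targets[1:]))

    def test_mean_edge_length_rises_through_growth(self, emap):
        lengths = np.zeros(40)
        for seed in range(15):
            traj = generate_latent_trajectory(emap, GrowthSchedule(), seed=seed)
            lengths += [net.mean_edge_length() if net.n_edges else 0.0 for net in traj]
        lengths /= 15
        assert lengths[7] < lengths[16]  # mid-growth shorter than plateau onset

    def test_schedule_exceeding_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            GrowthSchedule(quiescent_days=20, growth_days=25, n_days=40)

    def test_no_self_edges_and_weights_in_unit_interval(self, emap):
        traj = generate_latent_trajectory(emap, GrowthSchedule(), seed=5)
        edges = traj[-1].edges
        assert (edges["src"] != edges["dst"]).all()
        assert edges["weight"].between(0, 1).all()


class TestSpontaneous:
    def test_zero_rates_give_empty_session(self, emap):
        params = FiringParams(baseline_hz=0.0, burst_rate_hz=0.0)
        out = simulate_spontaneous(emap, 1, params, 10.0, seed=0)
        assert len(out.spikes) == 0

    def test_poisson_total_count(self, emap):
        # 1 Hz x 100 s x 59 electrodes: mean 5900, sd sqrt(5900)
        params = FiringParams(baseline_hz=1.0, burst_rate_hz=0.0)
        out = simulate_spontaneous(emap, 1, params, 100.0, seed=1)
        assert abs(len(out.spikes) - 5900) < 3 * np.sqrt(5900)

    def test_deterministic_given_seed(self, emap):
        params = FiringParams()
        a = simulate_spontaneous(emap, 1, params, 30.0, seed=9)
        b = simulate_spontaneous(emap, 1, params, 30.0, seed=9)
        pd.testing.assert_frame_equal(a.spikes, b.spikes)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            FiringParams(baseline_hz=-1.0)
        with pytest.raises(ValueError):
            simulate_spontaneous(None, 1, FiringParams(), duration_s=0.0, seed=0)


def _single_edge_network(emap, schedule, src="12", dst="45", weight=1.0):
    d = emap.distance_matrix()
    i, j = emap.index_of(src), emap.index_of(dst)
    edges = pd.DataFrame(
        [{"src": src, "dst": dst, "weight": weight, "latency_class": "direct",
          "length_um": d[i, j]}]
    )
    return LatentNetwork(day=10, electrode_ids=emap.analysis_ids, edges=edges, schedule=schedule)


class TestStimulation:
    def test_pulse_table_has_59x50_pulses(self, emap):
        sched = GrowthSchedule()
        net = LatentNetwork(day=1, electrode_ids=emap.analysis_ids,
                            edges=pd.DataFrame(columns=["src", "dst", "weight", "latency_class", "length_um"]),
                            schedule=sched)
        out = simulate_stimulation_session(emap, net, background=None, seed=0)
        assert len(out.pulses) == 59 * 50
        assert set(out.pulses["trial_index"]) == set(range(50))

    def test_empty_network_zero_background_gives_zero_spikes(self, emap):
        sched = GrowthSchedule()
        net = LatentNetwork(day=1, electrode_ids=emap.analysis_ids,
                            edges=pd.DataFrame(columns=["src", "dst", "weight", "latency_class", "length_um"]),
                            schedule=sched)
        out = simulate_stimulation_session(emap, net, background=None, seed=0)
        assert len(out.spikes) == 0

    def test_deterministic_unit_edge_fixed_latency(self, emap):
        sched = dataclasses.replace(GrowthSchedule(), direct_band_ms=(10.0, 10.0))
        net = _single_edge_network(emap, sched)
        out = simulate_stimulation_session(emap, net, background=None, seed=0)
        assert len(out.spikes) == 50
        assert (out.spikes["electrode_id"] == "45").all()
        pulse_times = out.pulses.loc[out.pulses["stim_electrode_id"] == "12", "pulse_time_s"]
        np.testing.assert_allclose(
            np.sort(out.spikes["time_s"].to_numpy()), np.sort(pulse_times.to_numpy()) + 0.010
        )

    def test_evoked_spikes_never_precede_their_pulse(self, emap):
        traj = generate_latent_trajectory(emap, GrowthSchedule(), seed=2)
        net = traj[25]
        out = simulate_stimulation_session(emap, net, background=None, seed=7)
        max_latency = max(net.schedule.barrage_band_ms) / 1000.0
        srcs_into = net.edges.groupby("dst")["src"].apply(set)
        pulses_by_src = {
            s: g["pulse_time_s"].to_numpy() for s, g in out.pulses.groupby("stim_electrode_id")
        }
        for _, spike in out.spikes.iterrows():
            candidates = np.concatenate(
                [pulses_by_src[s] for s in srcs_into.get(spike["electrode_id"], set())]
            )
            lags = spike["time_s"] - candidates
            lags = lags[lags > 0]
            # the causing pulse strictly precedes the spike within the band
            assert len(lags) and lags.min() <= max_latency + 1e-9

    def test_mismatched_network_rejected(self, emap):
        sched = GrowthSchedule()
        net = LatentNetwork(day=1, electrode_ids=["x", "y"],
                            edges=pd.DataFrame(columns=["src", "dst", "weight", "latency_class", "length_um"]),
                            schedule=sched)
        with pytest.raises(ValueError, match="match"):
            simulate_stimulation_session(emap, net, seed=0)

    def test_latency_class_fractions_recovered(self, emap):
        sched = GrowthSchedule()
        traj = generate_latent_trajectory(emap, sched, seed=8)
        edges = traj[-1].edges
        frac = edges["latency_class"].value_counts(normalize=True)
        for cls, expected in zip(("direct", "early", "barrage"), sched.latency_fractions):
            assert abs(frac.get(cls, 0.0) - expected) < 0.12


class TestStudy:
    def test_one_culture_two_days_writes_four_session_files(self, tmp_path):
        manifest = default_manifest()
        manifest.cultures = manifest.cultures.iloc[:1].copy()
        manifest.cultures.at[0, "days"] = [3, 10]
        index = generate_study(manifest, GrowthSchedule(), seed=0, out_dir=tmp_path,
                               spontaneous_duration_s=10.0)
        assert len(index) == 2
        session_files = [p for p in tmp_path.iterdir() if "spikes" in p.name]
        assert len(session_files) == 4  # 2 days x (stim + spont)
        assert all((tmp_path / f).exists() for f in index["truth_edges"])

    def test_plating_metadata_matches_volume_times_density(self):
        meta = default_manifest().plating_metadata()
        for _, row in meta.iterrows():
            t = PLATING_TABLE[row["density_class"]]
            assert row["nominal_plated_cells"] == t["plating_volume_ul"] * t["suspension_density_cells_per_ul"]

    def test_same_batch_cultures_more_similar_than_cross_batch(self):
        manifest = default_manifest()
        sched = GrowthSchedule()
        within, across = [], []
        for seed in range(50):
            scheds = [batch_adjusted_schedule(sched, manifest, ci, seed) for ci in range(6)]
            e30 = [s.target_edge_count(30, 59) for s in scheds]
            within.append(abs(e30[0] - e30[1]))   # cultures 0,1: batch1
            across.append(abs(e30[0] - e30[3]))   # cultures 0,3: batch1 vs batch2
        assert np.mean(within) < np.mean(across)

    def test_session_seed_scheme_is_stable(self):
        assert session_seed(7, 0, 3, "stimulation") == session_seed(7, 0, 3, "stimulation")
        assert session_seed(7, 0, 3, "stimulation") != session_seed(7, 0, 3, "spontaneous")
        assert session_seed(7, 0, 3, "stimulation") < 2**31


class TestZMixture:
    def test_epsilon_zero_all_null(self):
        rm, truth = generate_z_mixture(MixtureSpec(epsilon=0.0, seed=1))
        assert not truth.any()

    def test_epsilon_one_point_mass(self):
        spec = MixtureSpec(epsilon=1.0, f1_sampler=lambda rng, k: np.full(k, 5.0), seed=1)
        rm, truth = generate_z_mixture(spec)
        assert truth.all()
        np.testing.assert_array_equal(rm.z, np.full((59, 59), 5.0))

    def test_non_null_count_binomial(self):
        # 3481 entries, eps 0.05: mean 174.05, sd sqrt(3481*.05*.95)=12.86
        counts = [generate_z_mixture(MixtureSpec(seed=s))[1].sum() for s in range(100)]
        assert abs(np.mean(counts) - 174.05) < 3 * 12.86 / np.sqrt(100)

    def test_null_entries_match_gaussian(self):
        rm, truth = generate_z_mixture(MixtureSpec(epsilon=0.05, sigma=1.0, dims=(100, 100), seed=12))
        nulls = rm.z[~truth]
        assert stats.kstest(nulls, "norm").pvalue > 0.01

    def test_deterministic_given_seed(self):
        a, ta = generate_z_mixture(MixtureSpec(seed=5))
        b, tb = generate_z_mixture(MixtureSpec(seed=5))
        np.testing.assert_array_equal(a.z, b.z)
        np.testing.assert_array_equal(ta, tb)
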