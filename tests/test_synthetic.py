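"""Generator tests: atlas construction, signal model, cohorts, fixtures."""

import json

import numpy as np
import pytest

import ednet
from ednet.synthetic import (CORTICAL_NETWORKS, SUBCORTICAL_STRUCTURES,
                             SubjectRecipe, default_recipe, make_atlas,
                             make_ground_truth, simulate_subject)


class TestAtlas:
    def test_minimal_covering_has_one_bilateral_pair_per_network(self):
        atlas = make_atlas(34, 7, seed=1)
        counts = atlas.table["network_label"].value_counts()
        assert all(counts[n] == 2 for n in CORTICAL_NETWORKS)
        assert all(counts[s] == 1 for s in SUBCORTICAL_STRUCTURES)
        assert atlas.n_parcels == 41

    def test_deterministic_for_fixed_seed(self):
        a = make_atlas(100, 8, seed=1)
        b = make_atlas(100, 8, seed=1)
        assert a.table.equals(b.table)

    def test_too_few_cortical_parcels_names_uncovered_network(self):
        with pytest.raises(ValueError, match="LIM_B"):
            make_atlas(33, 7)
        with pytest.raises(ValueError, match="BF"):
            make_atlas(34, 6)

    def test_limbic_flag_marks_exactly_lim_parcels(self):
        atlas = make_atlas(51, 7)
        lim = np.isin(atlas.network_labels, ("LIM_A", "LIM_B"))
        assert np.array_equal(lim, atlas.is_limbic)

    def test_parcel_ids_contiguous(self):
        atlas = make_atlas(40, 10)
        assert np.array_equal(atlas.parcel_ids, np.arange(1, 51))


class TestRecipe:
    def test_nonincreasing_tes_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SubjectRecipe(seed=0, tes=(30.0, 13.7, 47.0))

    def test_negative_t2star_rejected(self):
        with pytest.raises(ValueError, match="T2"):
            SubjectRecipe(seed=0, t2star_map=np.array([30.0, -5.0]))

    def test_dropout_maps_sit_below_nondropout_median(self):
        atlas = make_atlas(34, 7)
        recipe = default_recipe(atlas, seed=3)
        drop = atlas.is_ventral_dropout
        assert np.all(recipe.t2star_map[drop] < np.median(recipe.t2star_map[~drop]))
        assert np.all(recipe.s0_map[drop] < np.median(recipe.s0_map[~drop]))


@pytest.fixture(scope="module")
def clean_run():
    atlas = make_atlas(34, 7)
    truth = make_ground_truth(atlas, "merged", seed=5)
    recipe = default_recipe(atlas, seed=5, noise_sd=0.0, pct_artifact=0.0,
                            n_timepoints=500)
    return atlas, truth, simulate_subject(atlas, truth, recipe)


class TestSignalModel:

    def test_bold_percent_amplitude_increases_with_te(self, clean_run):
        atlas, truth, run = clean_run
        gt = run.ground_truth
        z = gt.z_bold[:, 0]
        amps = []
        for e in range(run.n_echoes):
            pct = run.data[e] / run.data[e].mean(axis=1, keepdims=True) - 1
            beta = pct @ z / np.sum(z ** 2)
            amps.append(np.abs(beta).sum())
        assert amps[0] < amps[1] < amps[2]
        # ΔR2*-like: amplitude proportional to TE
        ratio = np.array(amps) / amps[1]
        assert np.allclose(ratio, run.tes / run.tes[1], rtol=0.02)

    def test_artifact_percent_amplitude_flat_across_te(self):
        atlas = make_atlas(34, 7)
        truth = make_ground_truth(atlas, "merged", seed=5)
        recipe = default_recipe(atlas, seed=5, noise_sd=0.0, pct_bold=0.0,
                                n_timepoints=400)
        run = simulate_subject(atlas, truth, recipe)
        z = run.ground_truth.z_artifact[:, 0]
        amps = []
        for e in range(run.n_echoes):
            pct = run.data[e] / run.data[e].mean(axis=1, keepdims=True) - 1
            beta = pct @ z / np.sum(z ** 2)
            amps.append(np.abs(beta).sum())
        assert np.allclose(amps, amps[1], rtol=1e-6)

    def test_merged_limbic_series_tracks_assigned_dn_latent(self, clean_run):
        atlas, truth, run = clean_run
        fit = ednet.fit_decay(run)
        combined = ednet.optimal_combine(run, fit)
        gt = run.ground_truth
        names = truth.latent_names
        for pid, cluster in truth.planted_lim_clusters.items():
            latent = ("DN_A", "DN_B", "DN_C")[cluster - 1]
            z = gt.z_bold[:, names.index(latent)]
            r = np.corrcoef(combined[pid - 1], z)[0, 1]
            assert r > 0.9

    def test_bit_identical_for_same_recipe(self):
        atlas = make_atlas(34, 7)
        truth = make_ground_truth(atlas, "merged", seed=2)
        recipe = default_recipe(atlas, seed=9, n_timepoints=50)
        a = simulate_subject(atlas, truth, recipe)
        b = simulate_subject(atlas, truth, recipe)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.motion, b.motion)

    def test_no_spikes_keeps_fd_below_threshold(self):
        atlas = make_atlas(34, 7)
        truth = make_ground_truth(atlas, "merged", seed=2)
        run = simulate_subject(atlas, truth,
                               default_recipe(atlas, seed=4, motion_spike_rate=0.0))
        assert ednet.framewise_displacement(run.motion).max() < 0.5

    def test_spikes_raise_fd_above_threshold(self):
        atlas = make_atlas(34, 7)
        truth = make_ground_truth(atlas, "merged", seed=2)
        run = simulate_subject(
            atlas, truth,
            default_recipe(atlas, seed=4, forced_spike_frames=(60, 120)))
        fd = ednet.framewise_displacement(run.motion)
        assert fd[59] > 0.5 or fd[60] > 0.5

    def test_dropout_parcels_have_lower_single_echo_tsnr_at_longest_te(self):
        atlas = make_atlas(34, 7)
        truth = make_ground_truth(atlas, "merged", seed=6)
        run = simulate_subject(atlas, truth, default_recipe(atlas, seed=6))
        tsnr = ednet.compute_tsnr(run.data[-1]).tsnr
        drop = atlas.is_ventral_dropout
        assert tsnr[drop].mean() < tsnr[~drop].mean()


class TestCohort:
    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError, match="2"):
            ednet.simulate_cohort(1, "merged", 0)

    def test_cohort_deterministic(self):
        a = ednet.simulate_cohort(3, "merged", 7, p_cortical=34,
                                  p_subcortical=7, n_timepoints=60)
        b = ednet.simulate_cohort(3, "merged", 7, p_cortical=34,
                                  p_subcortical=7, n_timepoints=60)
        for ra, rb in zip(a.runs, b.runs):
            assert np.array_equal(ra.data, rb.data)
        assert np.array_equal(a.truth.planted_partition, b.truth.planted_partition)

    def test_scenario_switch_controls_limbic_loadings(self):
        merged = ednet.simulate_cohort(2, "merged", 3, p_cortical=34,
                                       p_subcortical=7, n_timepoints=40)
        distinct = ednet.simulate_cohort(2, "distinct", 3, p_cortical=34,
                                         p_subcortical=7, n_timepoints=40)
        names_m = merged.truth.latent_names
        lim_rows = merged.atlas.is_limbic
        dn_cols = [names_m.index(n) for n in ("DN_A", "DN_B", "DN_C")]
        assert np.all(
            np.abs(merged.truth.latent_loadings[lim_rows][:, dn_cols]).sum(axis=1) > 0)
        names_d = distinct.truth.latent_names
        assert "LIM" in names_d
        dn_cols_d = [names_d.index(n) for n in ("DN_A", "DN_B", "DN_C")]
        assert np.all(
            distinct.truth.latent_loadings[lim_rows][:, dn_cols_d] == 0)
        assert np.all(
            distinct.truth.latent_loadings[lim_rows, names_d.index("LIM")] != 0)

    def test_few_components_violation_needs_enough_latents(self):
        with pytest.raises(ValueError, match="BOLD latents"):
            ednet.simulate_cohort(3, "merged", 0, qc_violations={1: {"few_components"}})


@pytest.fixture(scope="module")
def tiny_cohort():
    return ednet.simulate_cohort(2, "merged", 5, p_cortical=34,
                                 p_subcortical=7, n_timepoints=30)


class TestFixtureIO:

    def test_manifest_counts_files(self, tiny_cohort, tmp_path):
        manifest = ednet.write_fixture(tiny_cohort, str(tmp_path / "fx"))
        names = list(manifest["files"])
        assert sum(n.startswith("sub-") and "echo" in n for n in names) == 6
        assert sum(n.endswith("motion.tsv") for n in names) == 2
        assert "atlas.tsv" in names and "truth.json" in names

    def test_round_trip_within_float_tolerance(self, tiny_cohort, tmp_path):
        d = str(tmp_path / "fx2")
        ednet.write_fixture(tiny_cohort, d)
        back = ednet.read_fixture(d)
        for ra, rb in zip(tiny_cohort.runs, back.runs):
            np.testing.assert_allclose(ra.data, rb.data, rtol=1e-9)
            np.testing.assert_allclose(ra.motion, rb.motion, rtol=1e-9)
        assert back.atlas.table["network_label"].equals(
            tiny_cohort.atlas.table["network_label"])
        assert back.truth.scenario == tiny_cohort.truth.scenario

    def test_nifti_mode_round_trips_through_voxels(self, tiny_cohort, tmp_path):
        d = str(tmp_path / "fxn")
        ednet.write_fixture(tiny_cohort, d, mode="nifti")
        back = ednet.read_fixture(d)
        np.testing.assert_allclose(back.runs[0].data, tiny_cohort.runs[0].data,
                                   rtol=1e-5)

    def test_identical_fixtures_for_fixed_master_seed(self, tiny_cohort, tmp_path):
        m1 = ednet.write_fixture(tiny_cohort, str(tmp_path / "a"))
        cohort2 = ednet.simulate_cohort(2, "merged", 5, p_cortical=34,
                                        p_subcortical=7, n_timepoints=30)
        m2 = ednet.write_fixture(cohort2, str(tmp_path / "b"))
        assert m1["files"] == m2["files"]  # sha256 equality = byte-identical

    def test_unwritable_target_raises_and_leaves_no_manifest(self, tiny_cohort,
                                                             tmp_path):
        blocker = tmp_path / "not-a-dir"
        blocker.write_text("occupied")
        with pytest.raises(OSError):
            ednet.write_fixture(tiny_cohort, str(blocker))
        assert not (tmp_path / "not-a-dir" / "manifest.json").exists()

    def test_truth_json_is_valid(self, tiny_cohort, tmp_path):
        d = tmp_path / "fx3"
        ednet.write_fixture(tiny_cohort, str(d))
        doc = json.loads((d / "truth.json").read_text())
        assert set(doc["bold_component_ids"]).isdisjoint(doc["artifact_component_ids"])
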