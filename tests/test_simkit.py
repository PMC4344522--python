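"""Generator behavior: closed-form agreement, determinism, planted truth."""

import numpy as np
import pytest

from chromodyn import frap, simkit
from chromodyn.simkit import (
    AcquisitionParams,
    CohortSpec,
    ExpressionSimSpec,
    KineticParams,
    NucleusImageSpec,
    ProteinSimSpec,
    Region,
    simulate_expression,
    simulate_frap_traces,
    simulate_genotype_cohort,
    simulate_nucleus_pair,
    simulate_protein,
)


class TestFrapTraces:
    def test_default_frame_counts(self):
        trace = simulate_frap_traces(KineticParams(), AcquisitionParams(), seed=0)[0]
        assert trace.n_prebleach == 10
        assert trace.n_postbleach == 180

    def test_noise_free_curve_matches_closed_form_everywhere(self):
        kin = KineticParams(tau_half=5.0, immobile_fraction=0.2,
                            bleach_depth=0.4, acq_bleach_rate=0.001, noise_sd=0.0)
        trace = simulate_frap_traces(kin, seed=0)[0]
        curve = frap.normalize_trace(trace)
        np.testing.assert_allclose(curve.values, simkit.recovery_curve(curve.times, kin),
                                   atol=1e-12)
        np.testing.assert_allclose(curve.prebleach_values, 1.0, atol=1e-12)

    def test_fully_immobile_pool_gives_flat_post_bleach_curve(self):
        kin = KineticParams(immobile_fraction=1.0, bleach_depth=0.35, noise_sd=0.0)
        curve = frap.normalize_trace(simulate_frap_traces(kin, seed=0)[0])
        np.testing.assert_allclose(curve.values, 0.35, atol=1e-12)

    def test_tau_estimate_matches_generating_rate_without_noise(self):
        kin = KineticParams(tau_half=9.0, immobile_fraction=0.1, noise_sd=0.0)
        curve = frap.normalize_trace(simulate_frap_traces(kin, seed=0)[0])
        summary = frap.fit_recovery(frap.aggregate_curves([curve]))
        assert summary.tau_half == pytest.approx(9.0, abs=1.0)  # one frame interval

    def test_seed_determinism_byte_identical(self):
        kin = KineticParams(noise_sd=0.05)
        a = simulate_frap_traces(kin, n_nuclei=3, seed=42)
        b = simulate_frap_traces(kin, n_nuclei=3, seed=42)
        for ta, tb in zip(a, b):
            assert ta.roi_mean.tobytes() == tb.roi_mean.tobytes()
            assert ta.nucleus_mean.tobytes() == tb.nucleus_mean.tobytes()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(tau_half=0.0)
        with pytest.raises(ValueError):
            KineticParams(bleach_depth=1.0)
        with pytest.raises(ValueError):
            AcquisitionParams(n_prebleach=4)


class TestFrapMovie:
    def test_zero_drift_registration_recovers_zero_shifts(self):
        movie = simkit.simulate_frap_movie(
            KineticParams(noise_sd=0.01),
            AcquisitionParams(n_prebleach=5, n_postbleach=15),
            drift_per_frame=(0.0, 0.0), seed=1, nucleus_radius=20,
        )
        _, shifts = frap.register_stack(movie["stack"])
        assert np.all(shifts == 0)

    def test_integer_drift_recovered_exactly(self):
        kin = KineticParams(noise_sd=0.0)
        acq = AcquisitionParams(n_prebleach=5, n_postbleach=4)
        movie = simkit.simulate_frap_movie(
            kin, acq, drift_per_frame=(1.0, -1.0), seed=1, nucleus_radius=16)
        still = simkit.simulate_frap_movie(
            kin, acq, drift_per_frame=(0.0, 0.0), seed=1, nucleus_radius=16)
        registered, shifts = frap.register_stack(movie["stack"])
        np.testing.assert_allclose(shifts, -movie["shifts"])
        # registration must restore every drifted frame to the still movie
        np.testing.assert_allclose(registered, still["stack"])

    def test_subpixel_drift_recovered_within_quarter_pixel(self):
        movie = simkit.simulate_frap_movie(
            KineticParams(noise_sd=0.0),
            AcquisitionParams(n_prebleach=5, n_postbleach=10),
            drift_per_frame=(0.5, 0.0), seed=1, nucleus_radius=20,
        )
        _, shifts = frap.register_stack(movie["stack"])
        assert np.abs(shifts - (-movie["shifts"])).max() <= 0.25

    def test_trace_from_movie_matches_trace_generator_model(self):
        kin = KineticParams(noise_sd=0.01)
        movie = simkit.simulate_frap_movie(
            kin, AcquisitionParams(n_prebleach=5, n_postbleach=30),
            drift_per_frame=(0.0, 0.0), seed=3, nucleus_radius=20,
        )
        trace = frap.extract_trace(
            movie["stack"], movie["roi_mask"], movie["nucleus_mask"],
            movie["params"]["bleach_frame_index"],
        )
        curve = frap.normalize_trace(trace)
        expected = simkit.recovery_curve(curve.times, kin)
        assert np.abs(curve.values - expected).max() < 5 * kin.noise_sd

    def test_excessive_drift_rejected(self):
        with pytest.raises(ValueError, match="outside the frame"):
            simkit.simulate_frap_movie(
                KineticParams(), AcquisitionParams(n_prebleach=5, n_postbleach=40),
                drift_per_frame=(2.0, -2.0), seed=0,
            )


class TestNucleusPair:
    def test_zero_foci_give_empty_segmentation(self):
        from chromodyn.localization import segment_foci

        sim = simulate_nucleus_pair(NucleusImageSpec(n_foci=0, noise_sd=0.0), seed=0)
        labels, centers = segment_foci(sim["dna"], sim["nucleus_mask"])
        assert labels.max() == 0 and centers == []

    def test_planted_focus_centers_are_ground_truth(self):
        sim = simulate_nucleus_pair(NucleusImageSpec(n_foci=3, noise_sd=0.0), seed=5)
        assert len(sim["focus_centers"]) == 3
        for cy, cx in sim["focus_centers"]:
            assert sim["focus_labels"][int(round(cy)), int(round(cx))] > 0

    def test_protein_channel_enrichment_in_expectation(self):
        spec = NucleusImageSpec(enrichment=2.5, noise_sd=0.0)
        sim = simulate_nucleus_pair(spec, seed=2)
        foci = sim["focus_labels"] > 0
        nucleoplasm = sim["nucleus_mask"] & ~foci
        ratio = sim["protein"][foci].mean() / sim["protein"][nucleoplasm].mean()
        assert ratio == pytest.approx(2.5)

    def test_oversized_focus_rejected(self):
        with pytest.raises(ValueError):
            NucleusImageSpec(focus_radius=50, nucleus_radius=48)


class TestGenotypeCohort:
    def test_mendelian_null_counts_within_three_binomial_sd(self):
        n = 100_000
        gc, _ = simulate_genotype_cohort(CohortSpec(n_total_pups=n), seed=0)
        for obs, p in zip(gc.observed, (0.25, 0.5, 0.25)):
            sd = np.sqrt(n * p * (1 - p))
            assert abs(obs - n * p) < 3 * sd

    def test_survival_thinning_mean_matches_expectation(self):
        # a quarter of 784 pups at 39% survival -> about 76 survivors
        counts = [
            simulate_genotype_cohort(
                CohortSpec(n_total_pups=784, survival_by_genotype=(1, 1, 0.39)),
                seed=s,
            )[0].observed[2]
            for s in range(200)
        ]
        assert np.mean(counts) == pytest.approx(784 * 0.25 * 0.39, rel=0.05)

    def test_sex_split_and_determinism(self):
        spec = CohortSpec(n_total_pups=130, sex_ratio_ko=0.4)
        gc1, extra1 = simulate_genotype_cohort(spec, seed=7)
        gc2, extra2 = simulate_genotype_cohort(spec, seed=7)
        assert gc1.observed == gc2.observed and extra1 == extra2
        assert extra1["ko_males"] + extra1["ko_females"] == gc1.observed[2]


class TestExpressionSim:
    def test_global_null_yields_no_discoveries(self):
        from chromodyn.expression import de_pipeline

        spec = ExpressionSimSpec(n_genes=3000, n_up=0, n_down=0)
        matrix, _ = simulate_expression(spec, seed=1)
        result = de_pipeline(matrix, ["a"] * 3 + ["b"] * 3, min_fold=1.4, max_q=0.1)
        assert result["n_up"] + result["n_down"] <= 3

    def test_truth_table_matches_planted_design(self):
        spec = ExpressionSimSpec(n_genes=500, n_up=20, n_down=7)
        matrix, truth = simulate_expression(spec, seed=3)
        assert (truth["direction"] == "up").sum() == 20
        assert (truth["direction"] == "down").sum() == 7
        assert matrix.shape == (500, 6)
        assert truth.loc[truth["direction"] == "down", "true_fold"].max() <= -spec.fold_range[0]

    def test_overplanted_design_rejected(self):
        with pytest.raises(ValueError):
            ExpressionSimSpec(n_genes=10, n_up=8, n_down=8)


class TestProteinSim:
    def test_default_protein_is_553_residues_with_planted_motif(self):
        seq, regions = simulate_protein(ProteinSimSpec(), seed=0)
        assert len(seq) == 553
        assert seq[254:259] == "PQVKL"
        assert [r[0] for r in regions] == ["NTD", "GD1", "GD2", "GD3", "DE", "CTD"]

    def test_composition_targets_honored_within_five_points(self):
        from chromodyn.seqfeat import composition_profile

        seq, regions = simulate_protein(ProteinSimSpec(motif_position=None), seed=1)
        ctd = [c for c in composition_profile(seq, regions) if c.name == "CTD"][0]
        assert 35.0 <= ctd.pct_basic <= 45.0
        de = [c for c in composition_profile(seq, regions) if c.name == "DE"][0]
        assert de.pct_acidic == 100.0

    def test_no_motif_and_v_free_composition_yields_no_hits(self):
        from chromodyn.seqfeat import scan_pxvxl

        layout = (Region("X", 200, {"A": 0.5, "K": 0.3, "E": 0.2}),)
        seq, _ = simulate_protein(
            ProteinSimSpec(region_layout=layout, motif_position=None), seed=2,
        )
        assert scan_pxvxl(seq) == []

    def test_motif_outside_any_region_rejected(self):
        layout = (Region("X", 10), Region("Y", 10))
        with pytest.raises(ValueError, match="region boundaries"):
            ProteinSimSpec(region_layout=layout, motif_position=8)
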