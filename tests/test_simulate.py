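"""Simulator tests: determinism, planted-intensity fidelity, class invariants,
marker-correlation calibration and cohort structure."""

import numpy as np
import pandas as pd
import pytest

from cytoctc.simulate import (
    CHANNELS,
    CohortParams,
    ImageParams,
    PlacementError,
    draw_marker_expression,
    generate_cohort,
    generate_cytospin,
    normal_scale_rho,
)


def small_params(**kw):
    base = dict(shape=(400, 400), n_leukocytes=5, n_classical=2)
    base.update(kw)
    return ImageParams(**base)


class TestCytospin:
    def test_zero_cells_gives_background_only(self):
        gt = generate_cytospin(
            ImageParams(shape=(200, 200), n_leukocytes=0, n_classical=0), seed=0
        )
        assert gt.cells == []
        assert gt.truth_labels.max() == 0
        # background + Gaussian noise only
        assert abs(gt.image.mean() - gt.background_level) < 0.1

    def test_requested_counts_and_gate_separation(self):
        gt = generate_cytospin(small_params(n_leukocytes=10, n_classical=2), seed=1)
        assert len(gt.cells) == 12
        tumor_like = [
            s
            for s in gt.cells
            if s.channel_means["AF488_tumor"] >= 21
            and s.channel_means["AF647_CD45"] <= 10
        ]
        assert len(tumor_like) == 2

    def test_seeded_determinism_bit_identical(self):
        a = generate_cytospin(small_params(), seed=11)
        b = generate_cytospin(small_params(), seed=11)
        assert np.array_equal(a.image, b.image)
        assert a.to_frame().equals(b.to_frame())

    def test_different_seeds_differ(self):
        a = generate_cytospin(small_params(), seed=1)
        b = generate_cytospin(small_params(), seed=2)
        assert not np.array_equal(a.image, b.image)

    def test_intensity_fidelity_on_planted_masks(self, slide):
        """Planted-mask mean grey values sit within the sampling noise of the
        planted means (3 sd of the mean for ~99% of cell/channel pairs)."""
        devs = []
        for i, spec in enumerate(slide.cells):
            rows, cols = slide.cell_mask(i)
            for c, ch in enumerate(CHANNELS):
                if ch == "DAPI":
                    sel = slide.nucleus_labels == i + 1
                    vals = slide.image[c][sel]
                else:
                    vals = slide.image[c, rows, cols]
                sigma_mean = slide.noise_sd / np.sqrt(vals.size)
                devs.append(abs(float(vals.mean()) - spec.channel_means[ch]) / sigma_mean)
        devs = np.asarray(devs)
        assert (devs <= 3.0).mean() >= 0.99
        assert devs.max() <= 5.0

    def test_all_ground_truth_cells_satisfy_class_invariants(self, slide):
        for spec in slide.cells:
            spec.validate()  # raises on any violation
        labels = {s.class_label for s in slide.cells}
        assert labels == {
            "leukocyte",
            "classical_ctc",
            "large_cell",
            "multinucleated_cell",
            "cluster_member",
        }
        for s in slide.cells:
            assert (s.cluster_id is not None) == (s.class_label == "cluster_member")

    def test_cluster_members_touch(self, slide):
        """Masks of members of one cluster are 8-connected to each other."""
        by_cluster = {}
        for i, s in enumerate(slide.cells):
            if s.cluster_id is not None:
                by_cluster.setdefault(s.cluster_id, []).append(i)
        assert by_cluster
        for members in by_cluster.values():
            sel = np.isin(slide.truth_labels, [i + 1 for i in members])
            from scipy import ndimage as ndi

            n_comp = ndi.label(sel, structure=np.ones((3, 3)))[0].max()
            assert n_comp == 1

    def test_infeasible_density_raises(self):
        with pytest.raises(PlacementError):
            generate_cytospin(
                ImageParams(shape=(120, 120), n_leukocytes=200, n_classical=0), seed=0
            )

    def test_oversized_cell_raises(self):
        params = ImageParams(shape=(60, 60), n_leukocytes=0, n_classical=0, n_large=1)
        with pytest.raises(PlacementError):
            generate_cytospin(params, seed=0)


class TestMarkerCorrelation:
    def test_independent_markers_near_zero(self):
        p = CohortParams.for_entity("breast", cd74_cd44_rho=0.0)
        df = draw_marker_expression(p, 500, np.random.default_rng(0))
        r = np.corrcoef(df["mean_CD74"], df["mean_CD44"])[0, 1]
        assert abs(r) < 0.1

    def test_breast_default_rho_high(self):
        p = CohortParams.for_entity("breast")
        df = draw_marker_expression(p, 40, np.random.default_rng(1))
        r = np.corrcoef(df["mean_CD74"], df["mean_CD44"])[0, 1]
        assert 0.90 <= r <= 1.0

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.97])
    def test_calibration_mean_r_within_005(self, rho):
        """Over 100 replicate 40-cell cohorts the mean sample Pearson r tracks
        the configured observed-scale correlation to within 0.05."""
        p = CohortParams.for_entity("breast", cd74_cd44_rho=rho)
        rs = [
            np.corrcoef(*draw_marker_expression(p, 40, np.random.default_rng(500 + s)).T.values)[0, 1]
            for s in range(100)
        ]
        assert abs(float(np.mean(rs)) - rho) <= 0.05

    def test_unattainable_rho_raises(self):
        with pytest.raises(ValueError):
            normal_scale_rho(-0.999, 2.0, 2.0)

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            CohortParams.for_entity("breast", cd74_cd44_rho=1.2).validate()


class TestCohort:
    def test_deterministic_under_seed(self):
        pa, ca = generate_cohort(CohortParams.for_entity("breast", seed=7))
        pb, cb = generate_cohort(CohortParams.for_entity("breast", seed=7))
        assert pa.equals(pb) and ca.equals(cb)

    def test_positive_patients_reproducible_binomial_draw(self):
        p = CohortParams.for_entity("breast", ctc_prevalence=0.5, seed=3)
        n_pos = int(generate_cohort(p)[0]["ctc_positive_ge1"].sum())
        assert n_pos == int(generate_cohort(p)[0]["ctc_positive_ge1"].sum())
        assert 0 <= n_pos <= 14

    def test_counts_zero_truncated_and_flags_consistent(self):
        patients, cells = generate_cohort(CohortParams.for_entity("nsclc", seed=5))
        pos = patients[patients["ctc_positive_ge1"]]
        assert (pos["ctc_count"] >= 1).all()
        assert ((patients["ctc_count"] >= 1) == patients["ctc_positive_ge1"]).all()
        assert ((patients["ctc_count"] >= 2) == patients["ctc_positive_ge2"]).all()
        # morphotype counts partition the CTC count
        total = (
            patients["n_classical"]
            + patients["n_large"]
            + patients["n_multinucleated"]
            + patients["n_cluster_members"]
        )
        assert (total == patients["ctc_count"]).all()
        # one marker row per counted CTC
        assert len(cells) == int(patients["ctc_count"].sum())

    def test_no_large_only_patients(self):
        for seed in range(10):
            patients, _ = generate_cohort(CohortParams.for_entity("breast", seed=seed))
            pos = patients[patients["ctc_count"] > 0]
            assert (pos["n_classical"] >= 1).all()

    def test_survival_times_positive_and_status_consistent(self):
        patients, _ = generate_cohort(CohortParams.for_entity("melanoma", seed=2))
        assert (patients["survival_months"] > 0).all()
        assert (
            patients["vital_status"].eq("dead") == patients["event"].astype(bool)
        ).all()

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            CohortParams.for_entity("breast", nb_mean=-1.0).validate()
        with pytest.raises(ValueError):
            CohortParams.for_entity("martian")
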