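"""Phantom generator: atlas geometry, ageing trends, disease offsets, I/O."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import stats

import mechage as mg
from mechage.phantom import default_region_spec
from mechage.types import SUBCORTICAL_REGIONS


class TestAtlas:
    def test_region_size_ordering(self, default_atlas):
        """Cerebellum-analogue largest, accumbens-analogue smallest."""
        cfg, atlas = default_atlas
        counts = {name: atlas.voxel_count(atlas.label_of(name))
                  for name in SUBCORTICAL_REGIONS}
        assert counts["cerebellum"] > counts["thalamus"] > counts["accumbens"]
        assert min(counts.values()) == counts["accumbens"]
        assert max(counts.values()) == counts["cerebellum"]

    def test_deterministic(self):
        cfg = mg.PhantomConfig()
        a = mg.generate_atlas(cfg)
        b = mg.generate_atlas(cfg)
        assert np.array_equal(a.labels, b.labels)

    def test_overlapping_regions_rejected(self):
        spec = default_region_spec()
        spec[1] = dataclasses.replace(spec[1], centre=spec[0].centre)
        cfg = mg.PhantomConfig(region_spec=spec)
        with pytest.raises(ValueError, match="overlapping regions"):
            mg.generate_atlas(cfg)

    def test_wm_gm_cover_rest_of_head(self, default_atlas):
        cfg, atlas = default_atlas
        assert atlas.voxel_count(atlas.label_of("white_matter")) > 0
        assert atlas.voxel_count(atlas.label_of("grey_matter")) > 0


class TestCohortGeneration:
    def test_zero_noise_slope_is_exact(self):
        """Two noiseless subjects at age_ref and age_ref+1: the whole-brain
        mean stiffness ratio equals 1 + slope/100 exactly."""
        cfg = mg.PhantomConfig(grid_shape=(16, 16, 16), n_subjects=2,
                               noise_sd_frac=0.0, subject_offset_sd_frac=0.0,
                               seed=0)
        atlas = mg.generate_atlas(cfg)
        # pin the reference age and generate one subject at age_ref and one
        # at age_ref + 1
        ref = cfg.age_ref
        c0 = dataclasses.replace(cfg, age_range=(ref, ref), n_subjects=1,
                                 age_ref_years=ref)
        c1 = dataclasses.replace(cfg, age_range=(ref + 1, ref + 1),
                                 n_subjects=1, age_ref_years=ref)
        v0, _ = mg.generate_cohort(c0, "HC", atlas)
        v1, _ = mg.generate_cohort(c1, "HC", atlas)
        m0 = v0[0].channels[0].values[v0[0].brain_mask].mean()
        m1 = v1[0].channels[0].values[v1[0].brain_mask].mean()
        assert m1 / m0 == pytest.approx(1 + cfg.stiffness_slope_pct / 100,
                                        abs=1e-12)

    def test_age_stiffness_correlation_strongly_negative(self):
        cfg = mg.PhantomConfig(grid_shape=(16, 16, 16), n_subjects=300, seed=0)
        vols, recs = mg.generate_cohort(cfg, "HC")
        ages = np.array([r.age for r in recs])
        means = np.array([v.channels[0].values[v.brain_mask].mean()
                          for v in vols])
        assert np.corrcoef(means, ages)[0, 1] < -0.5

    @pytest.mark.parametrize("channel,attr,sign", [
        (0, "stiffness_slope_pct", -1), (1, "damping_slope_pct", +1)])
    def test_trend_recovery_within_tolerance(self, channel, attr, sign):
        """A robust fit of whole-brain means vs age recovers the configured
        %/yr slope within 0.05 percentage points (n=300)."""
        cfg = mg.PhantomConfig(n_subjects=300, seed=0)
        vols, recs = mg.generate_cohort(cfg, "HC")
        ages = np.array([r.age for r in recs])
        means = np.array([v.channels[channel].values[v.brain_mask].mean()
                          for v in vols])
        res = stats.theilslopes(means, ages, method="joint")
        mid = res.intercept + res.slope * cfg.age_ref
        pct = 100 * res.slope / mid
        assert np.sign(pct) == sign
        assert pct == pytest.approx(getattr(cfg, attr), abs=0.05)

    def test_disease_offset_shifts_listed_region_only(self):
        """Noiseless AD phantom: the thalamus-analogue equals the HC value at
        age + 30; other regions match HC exactly."""
        cfg = mg.PhantomConfig(grid_shape=(16, 16, 16), n_subjects=1,
                               noise_sd_frac=0.0, subject_offset_sd_frac=0.0,
                               age_range=(50.0, 50.0), age_ref_years=50.0,
                               seed=0,
                               disease_spec={"AD": [("thalamus", 30.0)]})
        atlas = mg.generate_atlas(cfg)
        ad_vols, _ = mg.generate_cohort(cfg, "AD", atlas)
        hc_vols, _ = mg.generate_cohort(cfg, "HC", atlas)
        older = dataclasses.replace(cfg, age_range=(80.0, 80.0))
        hc80, _ = mg.generate_cohort(older, "HC", atlas)
        thal = atlas.region_mask(atlas.label_of("thalamus"))
        other = atlas.region_mask(atlas.label_of("caudate"))
        assert ad_vols[0].channels[0].values[thal].mean() == pytest.approx(
            hc80[0].channels[0].values[thal].mean(), abs=1e-12)
        assert np.allclose(ad_vols[0].channels[0].values[other],
                           hc_vols[0].channels[0].values[other])

    def test_nonlisted_regions_distributed_as_hc(self):
        """With noise on, regions without a disease offset keep the HC
        distribution (two-sample test, n=100 per group)."""
        cfg = mg.PhantomConfig(grid_shape=(16, 16, 16), n_subjects=100, seed=5,
                               age_range=(50.0, 50.0))
        atlas = mg.generate_atlas(cfg)
        hc, _ = mg.generate_cohort(cfg, "HC", atlas)
        ad, _ = mg.generate_cohort(cfg, "AD", atlas)
        caud = atlas.region_mask(atlas.label_of("caudate"))
        a = np.array([v.channels[0].values[caud].mean() for v in hc])
        b = np.array([v.channels[0].values[caud].mean() for v in ad])
        assert stats.mannwhitneyu(a, b).pvalue > 0.01

    def test_seed_determinism(self):
        cfg = mg.PhantomConfig(grid_shape=(8, 8, 8), n_subjects=3, seed=9)
        v1, r1 = mg.generate_cohort(cfg, "HC")
        v2, r2 = mg.generate_cohort(cfg, "HC")
        assert all(np.array_equal(a.channels[0].values, b.channels[0].values)
                   for a, b in zip(v1, v2))
        assert [r.age for r in r1] == [r.age for r in r2]

    def test_n_subjects_guard(self):
        with pytest.raises(ValueError, match="n_subjects"):
            mg.generate_cohort(mg.PhantomConfig(n_subjects=0), "HC")


class TestPhantomIO:
    def test_write_load_round_trip(self, tmp_path):
        cfg = mg.PhantomConfig(grid_shape=(8, 8, 8), n_subjects=5, seed=1)
        atlas = mg.generate_atlas(cfg)
        vols, recs = mg.generate_cohort(cfg, "HC", atlas)
        manifest = mg.write_phantom_dataset(vols, recs, atlas, tmp_path / "d")
        files = list((tmp_path / "d").glob("HC*_*.nii.gz"))
        # 2 channels + 2 mask sidecars per subject
        assert len(files) == 5 * 4
        back = mg.load_manifest(manifest)
        assert [r.subject_id for r in back] == [r.subject_id for r in recs]
        assert [r.age for r in back] == pytest.approx([r.age for r in recs])
        loaded = mg.load_subject_volumes(back[:1])
        assert np.allclose(loaded[0].channels[0].values.astype(np.float32),
                           vols[0].channels[0].values.astype(np.float32))

    def test_manifest_byte_identical_across_runs(self, tmp_path):
        cfg = mg.PhantomConfig(grid_shape=(8, 8, 8), n_subjects=3, seed=2)
        atlas = mg.generate_atlas(cfg)
        vols, recs = mg.generate_cohort(cfg, "HC", atlas)
        p1 = mg.write_phantom_dataset(vols, recs, atlas, tmp_path / "a")
        vols2, recs2 = mg.generate_cohort(cfg, "HC", atlas)
        p2 = mg.write_phantom_dataset(vols2, recs2, atlas, tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()
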