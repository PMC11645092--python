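"""Synthetic corpus generation: determinism, planted effect, bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from gazeattr.synth import (
    SocialRegion,
    SyntheticSpec,
    build_dataset,
    category_allocation,
    generate_scanpath,
    generate_stimulus,
    write_corpus,
)


class TestStimuli:
    def test_same_seed_and_index_give_identical_pixels(self):
        spec = SyntheticSpec(seed=5)
        a, ra = generate_stimulus(spec, 3)
        b, rb = generate_stimulus(spec, 3)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert (ra is None) == (rb is None)

    def test_landscapes_have_no_social_region(self):
        spec = SyntheticSpec(seed=1)
        cats = category_allocation(spec)
        idx = cats.index("landscapes")
        stim, region = generate_stimulus(spec, idx)
        assert stim.category == "landscapes" and region is None

    def test_people_images_have_social_region(self):
        spec = SyntheticSpec(seed=1)
        idx = category_allocation(spec).index("people")
        stim, region = generate_stimulus(spec, idx)
        assert region is not None
        h, w = spec.image_size
        assert 0 <= region.cx < w and 0 <= region.cy < h

    def test_category_counts_match_mix_exactly(self):
        """Fixed apportionment: counts are within (trivially, at) the
        multinomial 99% bounds for a balanced mix over 30 images."""
        spec = SyntheticSpec(n_images=30, seed=2)
        cats = category_allocation(spec)
        counts = {c: cats.count(c) for c in set(cats)}
        assert sum(counts.values()) == 30
        lo, hi = stats.binom.ppf([0.005, 0.995], 30, 1 / 3)
        for c in ("people", "objects", "landscapes"):
            assert lo <= counts[c] <= hi


class TestScanpaths:
    def _setup(self, **kw):
        spec = SyntheticSpec(seed=3, **kw)
        idx = category_allocation(spec).index("people")
        stim, region = generate_stimulus(spec, idx)
        return spec, stim, region

    def test_fixation_count_in_configured_range(self):
        spec, stim, region = self._setup()
        for p in range(20):
            sp = generate_scanpath(spec, stim, region, "TD", p, np.random.default_rng(p))
            assert spec.fixations_min <= len(sp) <= spec.fixations_max

    @pytest.mark.parametrize("p_td, p_asd, expect_all_in", [(1.0, 0.999, True), (0.001, 0.0005, False)])
    def test_extreme_social_probabilities(self, p_td, p_asd, expect_all_in):
        spec, stim, region = self._setup(p_social_td=p_td, p_social_asd=p_asd)
        rng = np.random.default_rng(9)
        hits = []
        for p in range(30):
            sp = generate_scanpath(spec, stim, region, "TD", p, rng)
            hits.extend(region.contains(f.x, f.y) for f in sp.fixations)
        if expect_all_in:
            assert np.mean(hits) > 0.99
        else:
            assert sum(hits) / len(hits) < 0.01

    def test_in_region_fraction_within_binomial_ci(self):
        """1000 TD scanpaths at p=0.7: in-region rate inside the 99% CI."""
        spec, stim, region = self._setup()
        rng = np.random.default_rng(10)
        inside = total = 0
        for p in range(1000):
            sp = generate_scanpath(spec, stim, region, "TD", p, rng)
            # 0.1-px coordinate rounding can move an exact boundary point
            pad = SocialRegion(region.cx, region.cy, region.radius + 0.1)
            inside += sum(pad.contains(f.x, f.y) for f in sp.fixations)
            total += len(sp)
        lo, hi = stats.binom.ppf([0.005, 0.995], total, spec.p_social_td) / total
        assert lo <= inside / total <= hi

    def test_durations_positive_and_lognormal_scale(self):
        spec, stim, region = self._setup()
        rng = np.random.default_rng(11)
        durs = []
        for p in range(100):
            sp = generate_scanpath(spec, stim, region, "ASD", p, rng)
            durs.extend(f.duration for f in sp.fixations)
        durs = np.array(durs)
        assert (durs > 0).all()
        assert 150 < np.median(durs) < 400  # median of lognormal(log 250, 0.5)


class TestBuildDataset:
    def test_record_count_is_full_cross(self):
        spec = SyntheticSpec(n_images=10, n_participants_per_group=5, seed=4)
        records, truth = build_dataset(spec)
        assert len(records) == 100
        assert truth["flipped_sample_ids"] == []

    def test_label_noise_flips_exact_count_reproducibly(self):
        spec = SyntheticSpec(n_images=10, n_participants_per_group=10, label_noise_rate=0.1, seed=6)
        r1, t1 = build_dataset(spec)
        r2, t2 = build_dataset(spec)
        assert len(t1["flipped_sample_ids"]) == 20
        assert t1["flipped_sample_ids"] == t2["flipped_sample_ids"]
        flipped = set(t1["flipped_sample_ids"])
        for rec in r1:
            expected = t1["true_labels"][rec.sample_id]
            if rec.sample_id in flipped:
                expected = 1 - expected
            assert rec.label == expected

    def test_full_reproducibility_of_dataset(self):
        spec = SyntheticSpec(n_images=4, n_participants_per_group=2, seed=8)
        r1, _ = build_dataset(spec)
        r2, _ = build_dataset(spec)
        assert [r.sample_id for r in r1] == [r.sample_id for r in r2]
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.image.pixels, b.image.pixels)
            np.testing.assert_array_equal(a.fixation_map, b.fixation_map)
            assert a.scanpath.fixations == b.scanpath.fixations
            assert a.label == b.label

    def test_corpus_on_disk_is_loadable_and_complete(self, tmp_path):
        spec = SyntheticSpec(n_images=3, n_participants_per_group=2, seed=9)
        manifest = write_corpus(spec, tmp_path)
        assert manifest.exists()
        assert len(list((tmp_path / "stimuli").glob("*.png"))) == 3
        assert len(list((tmp_path / "scanpaths").glob("*.txt"))) == 6
        from gazeattr.io import load_dataset

        records, reports = load_dataset(manifest)
        assert len(records) == 12
        assert all(rep.n_scanpaths == 2 for rep in reports)

    def test_planted_separability_by_region_fraction(self):
        """The in-social-region fixation fraction separates groups well above
        chance on people images at default parameters."""
        spec = SyntheticSpec(seed=12)
        records, truth = build_dataset(spec)
        regions = truth["social_regions"]
        correct = total = 0
        for rec in records:
            reg = regions.get(rec.image_id)
            if reg is None:
                continue
            xy = rec.scanpath.xy()
            frac = float(
                np.mean((xy[:, 0] - reg["cx"]) ** 2 + (xy[:, 1] - reg["cy"]) ** 2 <= (reg["radius"] + 1) ** 2)
            )
            pred = 0 if frac >= 0.5 else 1  # TD fixates the region more
            correct += pred == rec.label
            total += 1
        assert total > 0 and correct / total >= 0.7

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(p_social_td=0.3, p_social_asd=0.7)
        with pytest.raises(ValueError):
            SyntheticSpec(fixations_min=1)
        with pytest.raises(ValueError):
            SyntheticSpec(category_mix={"people": 0.5, "objects": 0.2, "landscapes": 0.2})
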