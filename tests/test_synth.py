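import numpy as np
import pytest

from deepamend import (
    SyntheticCommunitySpec,
    ValidationError,
    bray_curtis,
    contaminant_filter,
    generate_control_samples,
    generate_otu_table,
    to_relative_abundance,
)
from deepamend.synth import BLOOM_OTUS, METHANOGEN_OTU, load_succession_fixture


class TestSpecValidation:
    def test_effect_otu_indices_must_exist(self):
        with pytest.raises(ValidationError, match="outside"):
            SyntheticCommunitySpec(
                n_otus=5,
                substrate_bins=("background",),
                substrate_effect={7: ("background", 2.0)},
            )

    def test_library_range_ordering(self):
        with pytest.raises(ValidationError):
            SyntheticCommunitySpec(library_size_range=(100, 50))

    def test_dominance_bounds(self):
        with pytest.raises(ValidationError):
            SyntheticCommunitySpec(dominance=1.5)

    def test_dominant_otu_reaches_declared_share(self):
        spec = SyntheticCommunitySpec(dominance=0.3)
        assert spec.base_composition()[0] >= 0.3


class TestGenerateOtuTable:
    def test_seeded_determinism(self):
        spec = SyntheticCommunitySpec(seed=42)
        t1, m1 = generate_otu_table(spec)
        t2, m2 = generate_otu_table(spec)
        assert t1 == t2 and m1 == m2

    def test_counts_sum_to_drawn_library_sizes(self):
        spec = SyntheticCommunitySpec(seed=3)
        t, _ = generate_otu_table(spec)
        lo, hi = spec.library_size_range
        totals = t.counts.sum(axis=1)
        assert ((totals >= lo) & (totals <= hi)).all()

    def test_dominant_otu_mean_share_matches_spec(self):
        # Monte-Carlo against the generative mean: 200 samples, dominance 0.5
        spec = SyntheticCommunitySpec(
            n_samples_per_group=200,
            substrate_bins=("background",),
            incubations=(1,),
            dominance=0.5,
            seed=11,
        )
        t, _ = generate_otu_table(spec)
        rel = to_relative_abundance(t)
        assert abs(rel.values.iloc[:, 0].mean() - 0.5) < 0.05

    def test_mean_composition_converges_to_dirichlet_mean(self):
        # 500 replicates, all OTUs within 3 standard errors of the target mean
        spec = SyntheticCommunitySpec(
            n_otus=20,
            n_samples_per_group=500,
            substrate_bins=("background",),
            incubations=(1,),
            seed=5,
        )
        t, _ = generate_otu_table(spec)
        rel = to_relative_abundance(t).values.to_numpy()
        target = spec.base_composition()
        se = rel.std(axis=0, ddof=1) / np.sqrt(rel.shape[0])
        assert (np.abs(rel.mean(axis=0) - target) <= 3 * se + 1e-12).all()

    def test_substrate_effect_shifts_mean(self):
        spec = SyntheticCommunitySpec(
            n_samples_per_group=100,
            substrate_bins=("background", "carbonate"),
            incubations=(1,),
            substrate_effect={1: ("carbonate", 10.0)},
            seed=9,
        )
        t, meta = generate_otu_table(spec)
        rel = to_relative_abundance(t).values
        bins = np.array([m.substrate_bin for m in meta])
        boosted = rel.iloc[:, 1].to_numpy()
        base = spec.base_composition()
        expected = base.copy()
        expected[1] *= 10.0
        expected /= expected.sum()
        assert boosted[bins == "background"].mean() == pytest.approx(base[1], abs=0.02)
        assert boosted[bins == "carbonate"].mean() == pytest.approx(expected[1], abs=0.02)


class TestControls:
    def test_planted_contaminants_exceed_cutoff_in_every_control(self):
        spec = SyntheticCommunitySpec(contaminant_otus=(3, 7), seed=2)
        controls = generate_control_samples(spec, 4)
        rel = controls.counts.div(controls.counts.sum(axis=1), axis=0)
        assert (rel.iloc[:, [3, 7]] >= 5e-4).all().all()
        assert (controls.counts.sum(axis=1) == spec.control_depth).all()

    def test_empty_contaminants_give_clean_controls(self):
        spec = SyntheticCommunitySpec(contaminant_otus=(), seed=2)
        table, _ = generate_otu_table(spec)
        controls = generate_control_samples(spec, 2)
        _, removed = contaminant_filter(table, controls)
        assert removed == []

    def test_n_controls_validated(self):
        with pytest.raises(ValidationError):
            generate_control_samples(SyntheticCommunitySpec(), 0)

    def test_contaminant_filter_recovers_exactly_planted_otus(self):
        spec = SyntheticCommunitySpec(n_otus=50, contaminant_otus=(4, 21), seed=8)
        table, _ = generate_otu_table(spec)
        _, removed = contaminant_filter(table, generate_control_samples(spec, 3))
        assert sorted(removed) == sorted(
            [spec.otu_ids()[4], spec.otu_ids()[21]]
        )


class TestSuccessionFixture:
    def test_packaged_fixture_matches_regeneration(self, succession):
        table, meta = load_succession_fixture()
        assert table == succession[0]
        assert meta == succession[1]

    def test_bloom_otus_peak_in_incubation_3(self, succession):
        table, meta = succession
        rel = to_relative_abundance(table).values.to_numpy()
        incs = np.array([m.incubation for m in meta])
        for o in BLOOM_OTUS:
            by_inc = {i: rel[incs == i, o].mean() for i in range(1, 6)}
            assert by_inc[3] == max(by_inc.values())

    def test_methanogen_peaks_in_incubation_4(self, succession):
        table, meta = succession
        rel = to_relative_abundance(table).values.to_numpy()
        incs = np.array([m.incubation for m in meta])
        by_inc = {i: rel[incs == i, METHANOGEN_OTU].mean() for i in range(1, 6)}
        assert by_inc[4] == max(by_inc.values())

    def test_community_recovers_by_incubation_5(self, succession):
        table, meta = succession
        rel = to_relative_abundance(table).values.to_numpy()
        incs = np.array([m.incubation for m in meta])
        mean = {i: rel[incs == i].mean(axis=0) for i in (1, 3, 5)}
        assert bray_curtis(mean[5], mean[1]) < bray_curtis(mean[3], mean[1])
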