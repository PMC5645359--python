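"""Properties of the synthetic-cohort generators: reproducibility, null
calibration, effect injection, and the constructed tissue structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sticomics import (
    CohortConfig,
    MirnaConfig,
    NormalPoolConfig,
    ScnaConfig,
    generate_copy_number,
    generate_mirna_counts,
    generate_normal_pools,
    generate_tumor_expression,
    generate_tumors_from_tissue,
)
from sticomics.de import GroupComparison
from sticomics.preprocess import log_normalize, size_factors, ward_cluster
from sticomics.simulate import TISSUES, segments_from_calls


class TestTumorCohort:
    def test_seeded_reproducibility(self):
        cfg = CohortConfig(n_genes=500, n_stic=8, n_nostic=8, seed=3)
        a = generate_tumor_expression(cfg)
        b = generate_tumor_expression(cfg)
        assert a.matrix.values.equals(b.matrix.values)
        assert a.de_genes == b.de_genes
        assert (a.subtypes == b.subtypes).all()

    def test_counts_are_nonnegative_integers(self, small_cohort):
        vals = small_cohort.matrix.to_numpy()
        assert np.all(vals >= 0)
        assert np.allclose(vals, np.round(vals))

    def test_group_sizes_and_subtype_support(self, small_cohort):
        groups = small_cohort.groups
        assert (groups == "STIC").sum() == 20
        assert (groups == "NOSTIC").sum() == 20
        assert set(small_cohort.subtypes) <= {"S1", "S2", "S3", "S4"}

    def test_rejects_too_many_de_genes(self):
        with pytest.raises(ValueError):
            generate_tumor_expression(CohortConfig(n_genes=500, n_de_genes=501)).matrix

    def test_effect_injection_matches_nominal_shift(self):
        """Mean log2 group difference at DE genes ~ de_effect_sd * bio_sd
        (within 10% over seeds)."""
        effect, bio = 1.0, 1.0
        diffs = []
        for seed in range(20):
            cfg = CohortConfig(
                n_genes=1000,
                n_stic=25,
                n_nostic=25,
                n_de_genes=50,
                de_effect_sd=effect,
                bio_sd=bio,
                seed=seed,
            )
            c = generate_tumor_expression(cfg)
            logn = log_normalize(c.matrix, size_factors(c.matrix))
            stic = (c.groups == "STIC").to_numpy()
            sub = logn.values.loc[c.de_genes].to_numpy()
            diffs.append((sub[:, stic].mean() - sub[:, ~stic].mean()))
        assert np.mean(diffs) == pytest.approx(effect * bio, rel=0.10)

    def test_null_p_values_uniform(self):
        """Under the global null pooled raw p-values pass a KS test at alpha 0.01."""
        ps = []
        for seed in (101, 102):
            c = generate_tumor_expression(
                CohortConfig(n_genes=4000, n_stic=30, n_nostic=30, seed=seed)
            )
            logn = log_normalize(c.matrix, size_factors(c.matrix))
            ps.append(GroupComparison(logn).fit().table["p"].to_numpy())
        stat, p = sps.kstest(np.concatenate(ps), "uniform")
        assert p > 0.01, (stat, p)


class TestNormalPools:
    def test_mesothelial_tissues_most_correlated(self, small_normals_log, small_normals):
        lab = small_normals.tissues
        prof = {
            t: small_normals_log.values.loc[:, (lab == t).to_numpy()].mean(axis=1)
            for t in TISSUES
        }
        c = {
            pair: np.corrcoef(prof[pair[0]], prof[pair[1]])[0, 1]
            for pair in (("OSE", "PER"), ("OSE", "FT"), ("PER", "FT"))
        }
        assert c[("OSE", "PER")] > c[("OSE", "FT")]
        assert c[("OSE", "PER")] > c[("PER", "FT")]

    def test_ward_joins_ose_and_per_before_ft(self, small_normals_log, small_normals):
        labels = ward_cluster(small_normals_log, "euclidean").cut(2)
        lab = small_normals.tissues
        ft_clusters = set(labels[(lab == "FT").to_numpy()])
        meso_clusters = set(labels[(lab != "FT").to_numpy()])
        assert len(ft_clusters) == 1 and len(meso_clusters) == 1
        assert ft_clusters != meso_clusters

    def test_marker_sets_disjoint(self, small_normals):
        m = small_normals.marker_genes
        assert not (set(m["FT"]) & set(m["OSE"]))
        assert not (set(m["FT"]) & set(m["PER"]))
        assert not (set(m["OSE"]) & set(m["PER"]))

    def test_null_construction_is_exchangeable(self):
        """With no marker shifts, no shared mesothelial component and no
        contamination, one-vs-rest DE counts stay near the false-positive
        level."""
        from sticomics.origin import count_tissue_de

        cfg = NormalPoolConfig(
            n_genes=2000,
            n_ft_markers=400,
            n_ov_markers=60,
            n_per_markers=60,
            marker_shift_sd=0.0,
            mesothelial_corr=0.0,
            cross_contamination=0.0,
            seed=5,
        )
        normals = generate_normal_pools(cfg)
        nlog = log_normalize(normals.matrix, size_factors(normals.matrix))
        counts = count_tissue_de(nlog, alpha=0.05)
        assert counts.max() <= 5  # BH keeps null discoveries near zero

    def test_replication_required(self):
        with pytest.raises(ValueError, match="pools"):
            generate_normal_pools(NormalPoolConfig(n_pools_per_tissue=1))

    def test_seeded_reproducibility(self):
        cfg = NormalPoolConfig(n_genes=300, n_ft_markers=60, n_ov_markers=10, n_per_markers=10, seed=9)
        assert generate_normal_pools(cfg).matrix.values.equals(
            generate_normal_pools(cfg).matrix.values
        )


class TestTumorsFromTissue:
    @pytest.fixture()
    def prototypes(self, rng):
        genes = [f"g{i}" for i in range(300)]
        return pd.DataFrame(
            rng.normal(6, 1.5, size=(300, 3)), index=genes, columns=list(TISSUES)
        )

    def test_zero_noise_reproduces_prototype(self, prototypes):
        t = generate_tumors_from_tissue(prototypes, {"FT": 1.0}, n_tumors=3, noise_sd=0.0)
        for s in t.samples:
            assert t.values[s].to_numpy() == pytest.approx(prototypes["FT"].to_numpy())

    def test_origin_annotation_matches_mix(self, prototypes):
        t = generate_tumors_from_tissue(
            prototypes, {"FT": 0.5, "OSE": 0.5}, n_tumors=200, noise_sd=0.1, seed=4
        )
        frac_ft = (t.annotation("origin") == "FT").mean()
        assert 0.38 < frac_ft < 0.62
        assert set(t.annotation("origin")) <= {"FT", "OSE"}

    def test_ov_alias_accepted(self, prototypes):
        t = generate_tumors_from_tissue(prototypes, {"FT": 0.0, "OV": 1.0}, n_tumors=2)
        assert set(t.annotation("origin")) == {"OSE"}

    def test_invalid_inputs(self, prototypes):
        with pytest.raises(ValueError):
            generate_tumors_from_tissue(prototypes, {"FT": 0.7}, n_tumors=2)
        with pytest.raises(ValueError):
            generate_tumors_from_tissue(prototypes, {"FT": 1.0}, noise_sd=-1)


class TestMirna:
    def test_low_abundance_dominates(self):
        cfg = MirnaConfig(seed=2)
        sim = generate_mirna_counts(cfg)
        means = sim.matrix.values.mean(axis=1)
        assert (means < cfg.low_abundance_threshold).mean() >= 0.80

    def test_de_mirnas_in_low_tail(self):
        cfg = MirnaConfig(seed=2)
        sim = generate_mirna_counts(cfg)
        assert len(sim.de_genes) == cfg.n_de

    def test_seeded_reproducibility(self):
        cfg = MirnaConfig(n_mirnas=100, n_stic=6, n_nostic=6, seed=8)
        assert generate_mirna_counts(cfg).matrix.values.equals(
            generate_mirna_counts(cfg).matrix.values
        )


class TestCopyNumber:
    def test_zero_baseline_all_zero(self):
        sim = generate_copy_number(ScnaConfig(n_regions=10, baseline_alteration_freq=0.0))
        assert (sim.calls.calls.to_numpy() == 0).all()

    def test_baseline_one_always_altered(self):
        sim = generate_copy_number(
            ScnaConfig(n_regions=4, baseline_alteration_freq=1.0, seed=3)
        )
        assert (np.abs(sim.calls.calls.to_numpy()) == 2).all()

    def test_frequency_matches_baseline(self):
        sim = generate_copy_number(
            ScnaConfig(n_regions=50, n_stic=100, n_nostic=100, baseline_alteration_freq=0.3, seed=1)
        )
        freq = (np.abs(sim.calls.calls.to_numpy()) == 2).mean()
        assert freq == pytest.approx(0.3, abs=0.02)

    def test_group_delta_bounds_checked(self):
        with pytest.raises(ValueError):
            generate_copy_number(ScnaConfig(baseline_alteration_freq=0.9, group_delta=0.2))

    def test_segments_round_trip_to_calls(self):
        from sticomics.scna import call_regions

        sim = generate_copy_number(
            ScnaConfig(n_regions=8, n_stic=5, n_nostic=5, baseline_alteration_freq=0.4, seed=6)
        )
        segs = segments_from_calls(sim.calls)
        back = call_regions(segs, sim.calls.regions)
        assert back.calls.to_numpy() == pytest.approx(sim.calls.calls.to_numpy())
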