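import dataclasses

import numpy as np
import pandas as pd
import pytest

from enterochron.io import CountTable
from enterochron.simulate import (
    CohortConfig,
    AMR_PANEL,
    NO_GROWTH,
    generate_design,
    generate_bacterial_counts,
    generate_fungal_counts,
    generate_amr_observations,
    generate_qpcr_observations,
    simulate_cohort,
)
from enterochron.amr import standardize_gene_copies
from enterochron.metrics import alpha_diversity


def test_default_design_matches_study_layout():
    design = generate_design(CohortConfig(seed=0))
    assert len(design) == 162
    assert sum(r.microbiome_subset for r in design) == 72
    assert len({r.age_weeks for r in design}) == 9
    # microbiome subset balanced across cohorts at every age
    df = pd.DataFrame([dataclasses.asdict(r) for r in design])
    per_age = df[df.microbiome_subset].groupby(["age_weeks", "cohort"]).size()
    assert (per_age == 4).all()


def test_single_pig_single_age_design():
    cfg = CohortConfig(
        n_pigs=1, cohort_sizes=(1, 0), age_grid=(3,), microbiome_subset_size=1,
        trajectory_map={3: 0}, alpha_growth={3: 1.0},
        library_size_model={3: (4.0, 0.1)}, n_reverting_pigs=0,
    )
    assert len(generate_design(cfg)) == 1


def test_subset_larger_than_cohort_errors():
    with pytest.raises(ValueError):
        CohortConfig(microbiome_subset_size=25)


def test_generators_are_deterministic_given_seed():
    a = simulate_cohort(CohortConfig(seed=5))
    b = simulate_cohort(CohortConfig(seed=5))
    np.testing.assert_array_equal(a.bacterial_counts.counts, b.bacterial_counts.counts)
    np.testing.assert_array_equal(a.fungal_counts.counts, b.fungal_counts.counts)
    pd.testing.assert_frame_equal(a.amr, b.amr)
    pd.testing.assert_frame_equal(a.qpcr, b.qpcr)
    assert a.truth.sample_component == b.truth.sample_component
    c = simulate_cohort(CohortConfig(seed=6))
    assert (a.bacterial_counts.counts != c.bacterial_counts.counts).any()


def test_zero_variance_library_fixes_row_sums():
    cfg = CohortConfig(
        seed=1,
        library_size_model={a: (4.0, 0.0) for a in (3, 6, 10, 12, 22, 32, 49, 50, 53)},
    )
    design = generate_design(cfg)
    counts, _ = generate_bacterial_counts(design, cfg)
    assert (counts.counts.sum(axis=1) == 10000).all()


def test_counts_nonnegative_and_truth_covers_subset(default_cohort):
    _, design, counts, truth = default_cohort
    assert (counts.counts >= 0).all()
    subset_ids = {r.sample_id for r in design if r.microbiome_subset}
    assert set(truth.sample_component) == subset_ids
    assert len(truth.reverting_pigs) == 2


def test_shannon_rises_from_week3_to_week32(default_cohort):
    _, design, counts, _ = default_cohort
    alpha = alpha_diversity(counts)
    ages = {r.sample_id: r.age_weeks for r in design}
    alpha["age"] = alpha["sample_id"].map(ages)
    means = alpha.groupby("age")["shannon"].mean()
    assert means[3.0] < means[32.0]


def test_raw_read_counts_written_back(default_cohort):
    _, design, counts, _ = default_cohort
    sums = dict(zip(counts.sample_ids, counts.counts.sum(axis=1)))
    for rec in design:
        if rec.microbiome_subset:
            assert rec.raw_read_count == sums[rec.sample_id]


class TestFungal:
    def test_taxon_count_and_phyla(self):
        cfg = CohortConfig(seed=2)
        design = generate_design(cfg)
        fungal = generate_fungal_counts(design, cfg)
        assert fungal.n_taxa == 291
        asco = [t for t in fungal.taxon_ids if not t.startswith("Basidiomycota")]
        ra = fungal.relative_abundance()
        assert ra[asco].sum(axis=1).mean() > 0.5  # dominant phylum

    def test_concentration_limit_approaches_profile(self):
        cfg = CohortConfig(seed=3, fungal_concentration=5e5)
        design = generate_design(cfg)
        fungal = generate_fungal_counts(design, cfg)
        ra = fungal.relative_abundance().to_numpy()
        # growing-stage samples share one profile; their spread collapses
        spread = ra.std(axis=0).max()
        assert spread < 0.02

    def test_candida_bloom_at_parturition(self):
        from enterochron.simulate import CANDIDA_LIKE

        cfg = CohortConfig(seed=4)
        design = generate_design(cfg)
        fungal = generate_fungal_counts(design, cfg)
        ra = fungal.relative_abundance()
        ages = {r.sample_id: r.age_weeks for r in design}
        candida = ra[list(CANDIDA_LIKE)].sum(axis=1)
        by_age = candida.groupby(candida.index.map(ages)).mean()
        assert by_age[50.0] > by_age[22.0]


class TestAmr:
    def test_row_count_arithmetic(self, default_cohort):
        cfg, design, _, _ = default_cohort
        amr, _ = generate_amr_observations(design, cfg)
        expected = 162 * sum(len(panel) for panel in AMR_PANEL.values())
        assert len(amr) == expected

    def test_no_growth_combinations_are_blank(self, default_cohort):
        cfg, design, _, _ = default_cohort
        amr, _ = generate_amr_observations(design, cfg)
        for bact, dclass in NO_GROWTH:
            sub = amr[(amr.bacterium == bact) & (amr.drug_class == dclass)]
            assert len(sub) > 0 and sub.log10_cfu_per_g.isna().all()

    def test_noiseless_limit_reproduces_curves(self):
        cfg = CohortConfig(seed=1, ar1_phi=0.0, noise_sd=0.0)
        design = generate_design(cfg)
        amr, truth = generate_amr_observations(design, cfg)
        sub = amr[(amr.bacterium == "coliform") & (amr.drug_class == "tetracyclines")]
        ages = {r.sample_id: int(r.age_weeks) for r in design}
        curve = truth.amr_true_curves[("coliform", "tetracyclines")]
        for _, row in sub.iterrows():
            assert row.log10_cfu_per_g == pytest.approx(curve[ages[row.sample_id]])

    def test_ar1_correlation_matches_phi(self):
        # Monte-Carlo oracle: regress consecutive same-pig residuals on the
        # continuous-time decay and recover phi
        cfg = CohortConfig(seed=9, noise_sd=0.7)
        design = generate_design(cfg)
        amr, truth = generate_amr_observations(design, cfg)
        ages = {r.sample_id: r.age_weeks for r in design}
        sub = amr[(amr.bacterium == "coliform") & (amr.drug == "tetracycline")].copy()
        sub["age"] = sub.sample_id.map(ages)
        sub["pig"] = sub.sample_id.str.split("_").str[0]
        curve = truth.amr_true_curves[("coliform", "tetracyclines")]
        sub["resid"] = sub.log10_cfu_per_g - sub.age.map(lambda a: curve[int(a)])
        num = den = 0.0
        for _, grp in sub.groupby("pig"):
            grp = grp.sort_values("age")
            e = grp.resid.to_numpy()
            dt = np.diff(grp.age.to_numpy())
            # only short gaps carry signal about per-week decay
            short = dt <= 3
            rho = cfg.ar1_phi**dt[short]
            num += np.sum(rho * e[:-1][short] * e[1:][short])
            den += np.sum(rho**2 * e[:-1][short] ** 2)
        # implied scaling of the decay: ~1 when phi is right
        assert num / den == pytest.approx(1.0, abs=0.35)


class TestQpcr:
    def test_noiseless_week3_baselines(self):
        cfg = CohortConfig(seed=1, qpcr_pig_sd=0.0, qpcr_noise_sd=0.0)
        design = generate_design(cfg)
        qpcr = generate_qpcr_observations(design, cfg)
        w3 = qpcr[qpcr.sample_id.str.endswith("_w03")]
        teta = np.log10(w3[w3.gene == "tetA"].copies_per_g)
        bla = np.log10(w3[w3.gene == "blaCTXM"].copies_per_g)
        assert np.allclose(teta, 7.10)
        assert np.allclose(bla, 5.35)

    def test_standardized_identity(self):
        cfg = CohortConfig(seed=2, qpcr_pig_sd=0.0, qpcr_noise_sd=0.0)
        design = generate_design(cfg)
        qpcr = generate_qpcr_observations(design, cfg)
        std = standardize_gene_copies(qpcr)
        wide = qpcr.pivot(index="sample_id", columns="gene", values="copies_per_g")
        for _, row in std.iterrows():
            expected = np.log10(wide.loc[row.sample_id, row.gene]) - np.log10(
                wide.loc[row.sample_id, "16S"]
            )
            assert row.log10_standardized == pytest.approx(expected)
        # week-3 standardized tetA opens at -3.6 by construction
        w3 = std[(std.gene == "tetA") & std.sample_id.str.endswith("_w03")]
        assert np.allclose(w3.log10_standardized, -3.6)
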