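"""mSNP scanning, probe exclusion, specificity, attribution, clone counts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methpop.msnp import (
    MsnpCatalog,
    _ScanContext,
    attribute_population_difference,
    estimate_msnp_fdr,
    flag_probe_overlaps,
    scan_local_associations,
    summarize_clone_counts,
)
from methpop.msnp import test_population_specificity as population_specificity
from methpop.types import (
    BetaMatrix,
    GenotypeMatrix,
    ProbeManifest,
    ValidationError,
    VariantCatalog,
)


# ---------------------------------------------------------------- probe flags
def _manifest_one_probe(start=100, end=149):
    return ProbeManifest(
        pd.DataFrame(
            {
                "chrom": ["chr1"],
                "probe_start": [start],
                "probe_end": [end],
                "cpg_pos": [start],
                "gene": ["G"],
            },
            index=pd.Index(["cg0"], name="cpg_id"),
        )
    )


@pytest.mark.parametrize(
    "pos,expected",
    [(100, True), (149, True), (150, False), (99, False), (125, True)],
)
def test_probe_overlap_boundaries_inclusive(pos, expected):
    variants = VariantCatalog(
        pd.DataFrame({"chrom": ["chr1"], "pos": [pos], "population": ["popA"]})
    )
    flagged = flag_probe_overlaps(_manifest_one_probe(), variants, "popA")
    assert (("cg0" in flagged) is expected)


def test_probe_overlap_is_population_specific():
    variants = VariantCatalog(
        pd.DataFrame({"chrom": ["chr1"], "pos": [120], "population": ["popB"]})
    )
    assert flag_probe_overlaps(_manifest_one_probe(), variants, "popA") == set()


def test_flagged_set_matches_truth(small_cohort):
    ds, _ = small_cohort
    truth = set(ds.truth["artifact"])
    for pop in ("popA", "popB"):
        assert flag_probe_overlaps(ds.manifest, ds.variants, pop) == truth


# -------------------------------------------------------------------- scanning
def test_affine_dosage_relationship_is_perfect_hit(small_cohort):
    ds, _ = small_cohort
    cpg = ds.beta.site_ids[0]
    chrom = ds.beta.positions.loc[cpg, "chrom"]
    cpos = ds.beta.positions.loc[cpg, "pos"]
    near = ds.genotypes.positions[
        (ds.genotypes.positions["chrom"] == chrom)
        & ((ds.genotypes.positions["pos"] - cpos).abs() <= 100_000)
    ].index
    snp = near[0]
    vals = ds.beta.values.copy()
    vals.loc[cpg] = 0.2 + 0.1 * ds.genotypes.dosages.loc[snp].astype(float)
    beta = BetaMatrix(vals, ds.beta.positions)
    cat = scan_local_associations(beta, ds.genotypes, ds.pedigree, "popA")
    assert cat.table.loc[cpg, "abs_r"] == pytest.approx(1.0)
    assert bool(cat.table.loc[cpg, "is_hit"])


def test_low_mac_snp_excluded_from_testing(small_cohort):
    """A perfectly correlated SNP with only 4 minor alleles is never tested."""
    ds, _ = small_cohort
    cpg = ds.beta.site_ids[0]
    chrom = ds.beta.positions.loc[cpg, "chrom"]
    cpos = int(ds.beta.positions.loc[cpg, "pos"])
    samples = list(ds.genotypes.sample_ids)
    rare = pd.Series(0.0, index=samples)
    rare.iloc[[0, 3, 6, 9]] = 1.0  # MAC 4 overall, fewer within a population
    dosages = pd.concat(
        [ds.genotypes.dosages, rare.to_frame("snp_rare").T]
    )
    positions = pd.concat(
        [
            ds.genotypes.positions,
            pd.DataFrame({"chrom": [chrom], "pos": [cpos + 500]}, index=["snp_rare"]),
        ]
    )
    geno = GenotypeMatrix(dosages, positions)
    vals = ds.beta.values.copy()
    vals.loc[cpg] = np.clip(0.1 + 0.5 * rare.to_numpy(), 0, 1)
    beta = BetaMatrix(vals, ds.beta.positions)
    cat = scan_local_associations(beta, geno, ds.pedigree, "popA", mac_min=5)
    assert cat.table.loc[cpg, "snp_id"] != "snp_rare"


def test_association_invariant_to_dosage_recoding(small_cohort):
    ds, _ = small_cohort
    flipped = GenotypeMatrix(2.0 - ds.genotypes.dosages, ds.genotypes.positions)
    a = scan_local_associations(ds.beta, ds.genotypes, ds.pedigree, "popA")
    b = scan_local_associations(ds.beta, flipped, ds.pedigree, "popA")
    assert np.allclose(a.table["abs_r"].to_numpy(float),
                       b.table["abs_r"].to_numpy(float), equal_nan=True)


def test_scan_independent_of_snp_input_order(small_cohort):
    ds, _ = small_cohort
    order = np.random.default_rng(3).permutation(len(ds.genotypes.snp_ids))
    shuffled = GenotypeMatrix(
        ds.genotypes.dosages.iloc[order], ds.genotypes.positions.iloc[order]
    )
    a = scan_local_associations(ds.beta, ds.genotypes, ds.pedigree, "popA")
    b = scan_local_associations(ds.beta, shuffled, ds.pedigree, "popA")
    pd.testing.assert_frame_equal(a.table, b.table)


def test_exclusion_only_removes_hits(small_cohort):
    ds, _ = small_cohort
    excl = flag_probe_overlaps(ds.manifest, ds.variants, "popA")
    with_excl = scan_local_associations(
        ds.beta, ds.genotypes, ds.pedigree, "popA", excluded_probes=excl
    )
    without = scan_local_associations(ds.beta, ds.genotypes, ds.pedigree, "popA")
    assert set(with_excl.table.index) == set(without.table.index) - excl
    assert len(with_excl.hits) <= len(without.hits)
    assert not excl & set(with_excl.table.index)


def test_planted_msnps_recovered(small_cohort):
    ds, _ = small_cohort
    excl = flag_probe_overlaps(ds.manifest, ds.variants, "popA")
    cat = scan_local_associations(
        ds.beta, ds.genotypes, ds.pedigree, "popA", excluded_probes=excl
    )
    hits = 0
    active = {c: r for c, r in ds.truth["msnp"].items() if r["effect_popA"] != 0}
    for cpg, rec in active.items():
        if cat.table.loc[cpg, "snp_id"] == rec["snp_id"]:
            hits += 1
    assert hits >= 0.8 * len(active)  # small cohort, generous bound


def test_artifact_probes_yield_excess_hits_when_not_excluded(small_cohort):
    """Mirrors the elevated mSNP frequency at variant-overlapping probes."""
    ds, _ = small_cohort
    cat = scan_local_associations(ds.beta, ds.genotypes, ds.pedigree, "popA")
    flagged = list(ds.truth["artifact"])
    clean = [
        c
        for c in cat.table.index
        if c not in set(flagged) and c not in ds.truth["msnp"]
    ]
    r_flagged = cat.table.loc[flagged, "abs_r"].astype(float).mean()
    r_clean = cat.table.loc[clean, "abs_r"].astype(float).mean()
    assert r_flagged > r_clean * 1.5


def test_null_max_r_matches_bruteforce_oracle(null_cohort):
    """The vectorized rescan equals direct corrcoef computation for
    arbitrary profile-to-genotype pairings on a small instance."""
    ds, _ = null_cohort
    samples = ds.pedigree.samples_in("popA")
    ctx = _ScanContext(ds.beta, ds.genotypes, samples, 100_000, 5, set())
    rng = np.random.default_rng(0)
    for _ in range(5):
        perm = rng.permutation(len(samples))
        permuted = ctx.beta_vals[:, perm]
        fast = ctx.max_abs_r(permuted)
        for k in (0, 7, 33):
            entry = ctx.candidates[k]
            if entry["snp_rows"].size == 0:
                assert np.isnan(fast[k])
                continue
            dos = ds.genotypes.dosages[samples].to_numpy(float)[entry["snp_rows"]]
            y = permuted[entry["row"]]
            brute = max(abs(np.corrcoef(y, d)[0, 1]) for d in dos)
            assert fast[k] == pytest.approx(brute, abs=1e-12)


# ------------------------------------------------------------------------- FDR
def test_msnp_fdr_null_and_consistency(null_cohort):
    ds, _ = null_cohort
    cat = scan_local_associations(
        ds.beta, ds.genotypes, ds.pedigree, "popA", r_min=0.3
    )
    fdr = estimate_msnp_fdr(
        cat, ds.beta, ds.genotypes, ds.pedigree, R=40, seed=1
    )
    assert 0.4 < fdr["all"]["fdr"] < 2.0  # null data: observed ~ null hits
    # a single randomization is consistent with the R=40 estimate
    fdr1 = estimate_msnp_fdr(cat, ds.beta, ds.genotypes, ds.pedigree, R=1, seed=2)
    assert fdr1["all"]["observed_hits"] == fdr["all"]["observed_hits"]
    spread = 4 * np.std(
        [fdr1["all"]["mean_null_hits"], fdr["all"]["mean_null_hits"]]
    ) + 4 * np.sqrt(max(fdr["all"]["mean_null_hits"], 1.0))
    assert abs(fdr1["all"]["mean_null_hits"] - fdr["all"]["mean_null_hits"]) <= spread


def test_msnp_fdr_zero_hits_sentinel(null_cohort):
    ds, _ = null_cohort
    cat = scan_local_associations(
        ds.beta, ds.genotypes, ds.pedigree, "popA", r_min=0.999
    )
    fdr = estimate_msnp_fdr(cat, ds.beta, ds.genotypes, ds.pedigree, R=3, seed=0)
    assert fdr["all"]["observed_hits"] == 0 and np.isnan(fdr["all"]["fdr"])


# ----------------------------------------------------------------- specificity
def _catalog_from(rows, population, n_samples=90):
    table = pd.DataFrame(rows).set_index("cpg_id")
    return MsnpCatalog(
        population=population,
        table=table,
        n_samples=n_samples,
        r_min=0.6,
        window_bp=100_000,
        mac_min=5,
    )


def test_specificity_closed_form():
    a = _catalog_from(
        [{"cpg_id": "cg1", "snp_id": "s1", "abs_r": 0.9, "is_hit": True}], "popA"
    )
    b = _catalog_from(
        [{"cpg_id": "cg1", "snp_id": "s2", "abs_r": 0.0, "is_hit": False}], "popB"
    )
    res = population_specificity(a, b)
    z_expected = np.arctanh(0.9) / np.sqrt(2 / 87)
    assert res.loc["cg1", "z"] == pytest.approx(z_expected, rel=1e-6)
    assert res.loc["cg1", "z"] == pytest.approx(9.71, abs=0.02)
    assert res.loc["cg1", "p_value"] < 0.005 and bool(res.loc["cg1", "specific"])


def test_specificity_equal_correlations_p_one():
    a = _catalog_from(
        [{"cpg_id": "cg1", "snp_id": "s1", "abs_r": 0.7, "is_hit": True}], "popA"
    )
    b = _catalog_from(
        [{"cpg_id": "cg1", "snp_id": "s1", "abs_r": 0.7, "is_hit": True}], "popB"
    )
    res = population_specificity(a, b)
    assert res.loc["cg1", "p_value"] == pytest.approx(1.0)
    assert not bool(res.loc["cg1", "specific"])


def test_specificity_clamps_perfect_correlation():
    a = _catalog_from(
        [{"cpg_id": "cg1", "snp_id": "s1", "abs_r": 1.0, "is_hit": True}], "popA"
    )
    b = _catalog_from(
        [{"cpg_id": "cg1", "snp_id": "s1", "abs_r": 0.5, "is_hit": False}], "popB"
    )
    res = population_specificity(a, b)
    assert np.isfinite(res.loc["cg1", "z"])


# ----------------------------------------------------------------- attribution
def test_attribution_genotype_driven_site(small_cohort):
    """Beta built purely from a dosage with divergent allele frequencies:
    the SNP, not population, is the stronger predictor."""
    ds, _ = small_cohort
    rec = next(iter(ds.truth["msnp"].values()))
    cpg = next(iter(ds.truth["msnp"]))
    snp = rec["snp_id"]
    vals = ds.beta.values.copy()
    rng = np.random.default_rng(1)
    d = ds.genotypes.dosages.loc[snp].astype(float)
    vals.loc[cpg] = np.clip(0.2 + 0.2 * d + rng.normal(0, 0.02, len(d)), 0, 1)
    beta = BetaMatrix(vals, ds.beta.positions)
    res = attribute_population_difference(
        beta, ds.genotypes, ds.pedigree, [cpg], mac_min=1
    )
    assert res.loc[cpg, "classification"] == "snp_stronger"


def test_attribution_pure_population_offset(small_cohort):
    ds, _ = small_cohort
    cpg = ds.beta.site_ids[5]
    vals = ds.beta.values.copy()
    rng = np.random.default_rng(2)
    popb = set(ds.pedigree.samples_in("popB"))
    offset = np.array([0.3 if s in popb else 0.0 for s in vals.columns])
    vals.loc[cpg] = np.clip(0.3 + offset + rng.normal(0, 0.02, len(offset)), 0, 1)
    beta = BetaMatrix(vals, ds.beta.positions)
    res = attribute_population_difference(
        beta, ds.genotypes, ds.pedigree, [cpg], mac_min=1
    )
    assert res.loc[cpg, "classification"] == "population_stronger"


def test_attribution_no_shared_snp_flagged(small_cohort):
    ds, _ = small_cohort
    cpg = ds.beta.site_ids[10]
    res = attribute_population_difference(
        ds.beta, ds.genotypes, ds.pedigree, [cpg], window_bp=1
    )
    assert res.loc[cpg, "no_shared_snp"]
    assert res.loc[cpg, "classification"] == "population_stronger"


def test_attribution_t_stats_match_statsmodels(small_cohort):
    import statsmodels.api as sm

    ds, _ = small_cohort
    cpg = next(iter(ds.truth["msnp"]))
    res = attribute_population_difference(ds.beta, ds.genotypes, ds.pedigree, [cpg])
    snp = res.loc[cpg, "snp_id"]
    pops = ds.pedigree.populations
    pop_of = ds.pedigree.population_of()
    samples = [s for s in ds.beta.sample_ids if s in pop_of.index]
    y = ds.beta.values.loc[cpg, samples].to_numpy(float)
    d = ds.genotypes.dosages.loc[snp, samples].to_numpy(float)
    ind = (pop_of.reindex(samples) == pops[1]).to_numpy(float)
    X = sm.add_constant(np.column_stack([d - d.mean(), ind]))
    fit = sm.OLS(y, X).fit()
    assert res.loc[cpg, "t_snp"] == pytest.approx(abs(fit.tvalues[1]), rel=1e-8)
    assert res.loc[cpg, "t_population"] == pytest.approx(abs(fit.tvalues[2]), rel=1e-8)


# ---------------------------------------------------------------- clone counts
def test_clone_counts_worked_example():
    counts = pd.DataFrame(
        {
            "genotype": ["CC", "CC", "CT", "TT", "CT", "CC"],
            "methylated": [2, 1, 3, 8, 2, 1],
            "total": [10, 9, 10, 10, 8, 8],
        }
    )
    res = summarize_clone_counts(counts)
    assert res.loc["CC", "pct_methylated"] == 14.8  # 4/27 pooled
    assert res.loc["CT", "pct_methylated"] == 27.8  # 5/18 pooled
    assert res.loc["TT", "pct_methylated"] == 80.0  # 8/10
    assert res["monotonic"].all()
    assert list(res.index) == ["CC", "CT", "TT"]  # ordered by dosage


def test_clone_counts_errors():
    with pytest.raises(ValidationError):
        summarize_clone_counts(
            pd.DataFrame({"genotype": ["CC"], "methylated": [1], "total": [0]})
        )
    with pytest.raises(ValidationError):
        summarize_clone_counts(
            pd.DataFrame({"genotype": ["CCC"], "methylated": [1], "total": [2]})
        )
    with pytest.raises(ValidationError):
        summarize_clone_counts(
            pd.DataFrame({"genotype": ["CC"], "methylated": [3], "total": [2]})
        )
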