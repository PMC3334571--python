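"""Local mSNP (cis-mQTL) mapping and population-specificity analysis.

An mSNP is a SNP whose genotype dosage correlates with methylation at a
nearby CpG site. Mapping is per population: for each CpG, every SNP on
the same chromosome within ``window_bp`` (default 100 kb) and with at
least ``mac_min`` minor alleles among that population's samples is
tested by Pearson correlation of dosage against beta, and the SNP with
the largest |r| is recorded (the sign is discarded because 0/1/2 allele
coding is arbitrary). Hits are best SNPs with |r| above ``r_min``.

Probes whose genomic interval overlaps a known variant in the scanned
population are excluded beforehand: a variant under the probe can
disrupt hybridization in carriers and fabricate a genotype-methylation
correlation. The exclusion applies only to mSNP scanning - heritability
and population-difference analyses keep these sites.

FDR comes from randomization (methylation profiles re-paired with
genotypes, whole trios moving as units under the trio scheme), with a
high-confidence tier restricted to CpGs whose methylation is heritable
(h2 above a cutoff). Between-population comparison of association
strength uses Fisher's r-to-z; attribution of a population difference to
genotype versus population uses a joint linear model of beta on the best
shared local SNP's dosage and a population indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    BetaMatrix,
    GenotypeMatrix,
    ProbeManifest,
    TrioPedigree,
    ValidationError,
    VariantCatalog,
)

logger = logging.getLogger(__name__)

__all__ = [
    "flag_probe_overlaps",
    "MsnpCatalog",
    "scan_local_associations",
    "estimate_msnp_fdr",
    "test_population_specificity",
    "attribute_population_difference",
    "summarize_clone_counts",
]

WINDOW_BP = 100_000
MAC_MIN = 5
R_MIN = 0.6
H2_CUT = 0.2
SPECIFICITY_P = 0.005


def flag_probe_overlaps(
    manifest: ProbeManifest, variants: VariantCatalog, population: str
) -> set[str]:
    """CpG ids whose probe interval contains a catalog variant of ``population``.

    Intervals are 1-based inclusive on both ends: a variant at
    ``probe_start`` or ``probe_end`` overlaps; one at ``probe_end + 1``
    does not.
    """
    var = variants.for_population(population)
    flagged: set[str] = set()
    probes = manifest.probes
    for chrom, sub in var.groupby("chrom"):
        pr = probes[probes["chrom"] == chrom]
        if pr.empty:
            continue
        pos = sub["pos"].to_numpy()
        start = pr["probe_start"].to_numpy()[:, None]
        end = pr["probe_end"].to_numpy()[:, None]
        hit = ((pos[None, :] >= start) & (pos[None, :] <= end)).any(axis=1)
        flagged.update(pr.index[hit])
    return flagged


class _ScanContext:
    """Per-population candidate sets and centered dosages for fast rescans.

    Built once per scan; a label-preserving methylation permutation only
    changes the beta vector, so each rescan is a single matrix-vector
    correlation per CpG.
    """

    def __init__(
        self,
        beta: BetaMatrix,
        genotypes: GenotypeMatrix,
        samples: list[str],
        window_bp: int,
        mac_min: int,
        excluded_probes: set[str],
    ):
        if beta.positions is None:
            raise ValidationError("beta matrix has no coordinates; cannot scan")
        self.samples = samples
        self.beta_vals = beta.values[samples].to_numpy(float)
        self.site_ids = beta.site_ids
        site_pos = beta.positions.loc[self.site_ids]
        dos = genotypes.dosages[samples].to_numpy(float)
        if np.isnan(dos).any():
            # mean-impute rare missing calls; dosage correlation is robust
            # to this and it keeps the scan fully vectorized
            row_mean = np.nanmean(dos, axis=1)
            idx = np.where(np.isnan(dos))
            dos[idx] = row_mean[idx[0]]
        n2 = 2 * len(samples)
        alt = dos.sum(axis=1)
        self.mac = np.minimum(alt, n2 - alt)

        snp_pos = genotypes.positions
        self.snp_ids = genotypes.snp_ids.to_numpy()
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in pd.unique(snp_pos["chrom"]):
            m = (snp_pos["chrom"] == chrom).to_numpy()
            order = np.argsort(snp_pos["pos"].to_numpy()[m], kind="mergesort")
            by_chrom[chrom] = (
                np.flatnonzero(m)[order],
                snp_pos["pos"].to_numpy()[m][order],
            )

        dc = dos - dos.mean(axis=1, keepdims=True)
        dnorm = np.sqrt((dc**2).sum(axis=1))

        self.scanned: list[str] = []  # CpGs actually scanned (not excluded)
        self.candidates: list[dict] = []
        usable = self.mac >= mac_min
        for i, cpg in enumerate(self.site_ids):
            if cpg in excluded_probes:
                continue
            chrom = site_pos["chrom"].iloc[i]
            cpos = int(site_pos["pos"].iloc[i])
            entry = {"row": i, "cpg_id": cpg, "chrom": chrom, "cpg_pos": cpos}
            if chrom in by_chrom:
                idx_sorted, pos_sorted = by_chrom[chrom]
                lo = np.searchsorted(pos_sorted, cpos - window_bp, side="left")
                hi = np.searchsorted(pos_sorted, cpos + window_bp, side="right")
                cand = idx_sorted[lo:hi]
                cand = cand[usable[cand] & (dnorm[cand] > 0)]
            else:
                cand = np.empty(0, dtype=int)
            entry["snp_rows"] = cand
            entry["dc"] = dc[cand]
            entry["dnorm"] = dnorm[cand]
            entry["dist"] = np.abs(
                snp_pos["pos"].to_numpy()[cand] - cpos
            ).astype(int)
            self.scanned.append(cpg)
            self.candidates.append(entry)

    def abs_r(self, entry: dict, y: np.ndarray) -> np.ndarray:
        yc = y - y.mean()
        ynorm = np.sqrt((yc**2).sum())
        if ynorm == 0 or entry["snp_rows"].size == 0:
            return np.full(entry["snp_rows"].size, np.nan)
        return np.abs(entry["dc"] @ yc) / (entry["dnorm"] * ynorm)

    def max_abs_r(self, beta_vals: np.ndarray) -> np.ndarray:
        """Best |r| per scanned CpG for a (possibly permuted) beta matrix."""
        out = np.full(len(self.candidates), np.nan)
        for k, entry in enumerate(self.candidates):
            r = self.abs_r(entry, beta_vals[entry["row"]])
            if r.size and not np.all(np.isnan(r)):
                out[k] = np.nanmax(r)
        return out


@dataclass
class MsnpCatalog:
    """Best local SNP per CpG in one population, with hit calls."""

    population: str
    table: pd.DataFrame  # index cpg_id; snp_id, abs_r, r2, mac, distance, is_hit
    n_samples: int
    r_min: float
    window_bp: int
    mac_min: int
    excluded_probes: set[str] = field(default_factory=set)
    fdr: float | None = None

    @property
    def hits(self) -> pd.DataFrame:
        return self.table[self.table["is_hit"] == True]  # noqa: E712 - None-safe


def scan_local_associations(
    beta: BetaMatrix,
    genotypes: GenotypeMatrix,
    pedigree: TrioPedigree,
    population: str,
    window_bp: int = WINDOW_BP,
    mac_min: int = MAC_MIN,
    r_min: float = R_MIN,
    excluded_probes: set[str] | None = None,
) -> MsnpCatalog:
    """Map the strongest local SNP association for every non-excluded CpG.

    Ties on |r| break toward the smaller CpG-SNP distance, then the
    lexicographically smaller SNP id, so output is independent of SNP
    input order. CpGs with no testable SNP in the window are reported
    with a missing best SNP.
    """
    samples = pedigree.samples_in(population)
    if len(samples) < 3:
        raise ValidationError(f"population {population!r} has fewer than 3 samples")
    excluded = set(excluded_probes or ())
    ctx = _ScanContext(beta, genotypes, samples, window_bp, mac_min, excluded)

    rows = []
    for entry in ctx.candidates:
        y = ctx.beta_vals[entry["row"]]
        ok = ~np.isnan(y)
        if ok.sum() < 3:
            r = np.full(entry["snp_rows"].size, np.nan)
        elif ok.all():
            r = ctx.abs_r(entry, y)
        else:  # pairwise-complete fallback for sites with missing beta
            r = np.array(
                [
                    _abs_corr(y[ok], d[ok])
                    for d in entry["dc"]
                ]
            )
        base = {
            "cpg_id": entry["cpg_id"],
            "chrom": entry["chrom"],
            "cpg_pos": entry["cpg_pos"],
        }
        valid = ~np.isnan(r)
        if not valid.any():
            rows.append(
                base
                | {
                    "snp_id": None,
                    "snp_pos": np.nan,
                    "abs_r": np.nan,
                    "r2": np.nan,
                    "mac": np.nan,
                    "distance": np.nan,
                    "is_hit": None,
                }
            )
            continue
        cand = entry["snp_rows"][valid]
        rv = r[valid]
        dist = entry["dist"][valid]
        ids = ctx.snp_ids[cand]
        best = np.lexsort((ids, dist, -rv))[0]
        rows.append(
            base
            | {
                "snp_id": ids[best],
                "snp_pos": int(genotypes.positions.loc[ids[best], "pos"]),
                "abs_r": float(rv[best]),
                "r2": float(rv[best] ** 2),
                "mac": int(ctx.mac[cand[best]]),
                "distance": int(dist[best]),
                "is_hit": bool(rv[best] > r_min),
            }
        )
    table = pd.DataFrame(rows).set_index("cpg_id")
    return MsnpCatalog(
        population=population,
        table=table,
        n_samples=len(samples),
        r_min=r_min,
        window_bp=window_bp,
        mac_min=mac_min,
        excluded_probes=excluded,
    )


def _abs_corr(y: np.ndarray, d: np.ndarray) -> float:
    if np.std(y) == 0 or np.std(d) == 0:
        return np.nan
    return float(abs(np.corrcoef(y, d)[0, 1]))


def _permuted_beta(
    rng: np.random.Generator,
    beta_vals: np.ndarray,
    samples: list[str],
    pedigree: TrioPedigree,
    population: str,
    scheme: str,
) -> np.ndarray:
    """Re-pair methylation profiles with genotypes within the population."""
    n = len(samples)
    if scheme == "individual":
        return beta_vals[:, rng.permutation(n)]
    if scheme == "trio":
        n_trio = n // 3
        perm = rng.permutation(n_trio)
        cols = np.concatenate([np.arange(3 * t, 3 * t + 3) for t in perm])
        return beta_vals[:, cols]
    raise ValidationError(f"unknown permutation scheme {scheme!r}")


def estimate_msnp_fdr(
    catalog: MsnpCatalog,
    beta: BetaMatrix,
    genotypes: GenotypeMatrix,
    pedigree: TrioPedigree,
    R: int = 1000,
    scheme: str = "trio",
    seed: int = 0,
    h2_estimates: pd.DataFrame | None = None,
    h2_cut: float = H2_CUT,
) -> dict:
    """Randomization FDR for an mSNP catalog, with a heritable-only tier.

    Each randomization re-pairs methylation profiles with genotypes
    (whole trios move together under the trio scheme), rescans for the
    best local |r| per CpG and counts how many exceed the hit threshold.
    FDR = mean null hit count / observed hit count. When per-site h2
    estimates are supplied, the same computation restricted to CpGs with
    h2 > ``h2_cut`` yields the high-confidence tier's FDR.
    """
    if R < 1:
        raise ValidationError("R must be >= 1")
    samples = pedigree.samples_in(catalog.population)
    ctx = _ScanContext(
        beta,
        genotypes,
        samples,
        catalog.window_bp,
        catalog.mac_min,
        catalog.excluded_probes,
    )
    scanned = pd.Index(ctx.scanned)
    obs_r = catalog.table.loc[scanned, "abs_r"].to_numpy(float)
    tiers: dict[str, np.ndarray] = {"all": np.ones(len(scanned), bool)}
    if h2_estimates is not None:
        h2 = h2_estimates["h2"].reindex(scanned).to_numpy(float)
        tiers["heritable"] = h2 > h2_cut

    observed = {
        t: int((obs_r[m] > catalog.r_min).sum()) for t, m in tiers.items()
    }
    rng = np.random.default_rng(seed)
    null_counts = {t: [] for t in tiers}
    for _ in range(R):
        perm_beta = _permuted_beta(
            rng, ctx.beta_vals, samples, pedigree, catalog.population, scheme
        )
        max_r = ctx.max_abs_r(perm_beta)
        for t, m in tiers.items():
            null_counts[t].append(int((max_r[m] > catalog.r_min).sum()))
    out: dict = {"r": R, "scheme": scheme, "population": catalog.population}
    for t in tiers:
        mean_null = float(np.mean(null_counts[t]))
        if observed[t] == 0:
            logger.warning("tier %r has no observed hits; FDR undefined", t)
            fdr = float("nan")
        else:
            fdr = mean_null / observed[t]
        out[t] = {
            "observed_hits": observed[t],
            "mean_null_hits": mean_null,
            "fdr": fdr,
        }
    return out


def test_population_specificity(
    catalog_a: MsnpCatalog,
    catalog_b: MsnpCatalog,
    p_threshold: float = SPECIFICITY_P,
) -> pd.DataFrame:
    """Compare each hit CpG's best association strength between populations.

    For every CpG that is a hit in either catalog, the best local |r| in
    each population (possibly with different SNPs) is compared by
    Fisher's r-to-z: z = (atanh r_A - atanh r_B) / sqrt(1/(n_A-3) +
    1/(n_B-3)), two-sided. Because both correlations enter as absolute
    values, the difference can only be underestimated. CpGs excluded or
    unscanned in one population get a missing comparison.
    """
    hit_cpgs = catalog_a.hits.index.union(catalog_b.hits.index)
    rows = []
    se = np.sqrt(1.0 / (catalog_a.n_samples - 3) + 1.0 / (catalog_b.n_samples - 3))
    for cpg in hit_cpgs:
        ra = catalog_a.table["abs_r"].get(cpg, np.nan)
        rb = catalog_b.table["abs_r"].get(cpg, np.nan)
        if np.isnan(ra) or np.isnan(rb):
            rows.append(
                {
                    "cpg_id": cpg,
                    "r_a": ra,
                    "r_b": rb,
                    "z": np.nan,
                    "p_value": np.nan,
                    "specific": None,
                }
            )
            continue
        clamp = 1.0 - 1e-12
        if ra >= 1.0 or rb >= 1.0:
            logger.warning("|r| = 1 at %s; clamping for r-to-z", cpg)
        z = (np.arctanh(min(ra, clamp)) - np.arctanh(min(rb, clamp))) / se
        p = float(min(2.0 * stats.norm.sf(abs(z)), 1.0))
        rows.append(
            {
                "cpg_id": cpg,
                "r_a": float(ra),
                "r_b": float(rb),
                "z": float(z),
                "p_value": p,
                "specific": p < p_threshold,
            }
        )
    return pd.DataFrame(
        rows, columns=["cpg_id", "r_a", "r_b", "z", "p_value", "specific"]
    ).set_index("cpg_id")


def attribute_population_difference(
    beta: BetaMatrix,
    genotypes: GenotypeMatrix,
    pedigree: TrioPedigree,
    diff_sites: list[str],
    window_bp: int = WINDOW_BP,
    mac_min: int = MAC_MIN,
) -> pd.DataFrame:
    """Is a site's population difference better explained by a local SNP?

    For each site that differs between populations, the local SNP most
    correlated with methylation across ALL samples pooled is entered
    into a joint linear model ``beta ~ dosage + population`` (population
    coded 0/1), and the site is classified ``snp_stronger`` when the
    dosage coefficient's |t| exceeds the population coefficient's. Only
    SNPs polymorphic (MAC >= ``mac_min``) in both populations are used;
    a site with no shared SNP in its window defaults to
    ``population_stronger`` and is flagged.
    """
    pops = pedigree.populations
    if len(pops) != 2:
        raise ValidationError(f"expected two populations, got {pops}")
    pop_of = pedigree.population_of()
    samples = [s for s in beta.sample_ids if s in pop_of.index]
    pop_ind = (pop_of.reindex(samples) == pops[1]).to_numpy(float)

    # shared SNPs: adequately polymorphic in each population separately
    keep = np.ones(len(genotypes.snp_ids), bool)
    for pop in pops:
        ps = pedigree.samples_in(pop)
        d = genotypes.dosages[ps].to_numpy(float)
        alt = np.nansum(d, axis=1)
        mac = np.minimum(alt, 2 * len(ps) - alt)
        keep &= mac >= mac_min
    shared = GenotypeMatrix(
        genotypes.dosages.loc[keep], genotypes.positions.loc[keep]
    )

    sub_beta = BetaMatrix(beta.values.loc[diff_sites, samples], beta.positions)
    ctx = _ScanContext(sub_beta, shared, samples, window_bp, mac_min, set())

    rows = []
    for entry in ctx.candidates:
        y = ctx.beta_vals[entry["row"]]
        cpg = entry["cpg_id"]
        if entry["snp_rows"].size == 0:
            rows.append(
                {
                    "cpg_id": cpg,
                    "snp_id": None,
                    "t_snp": np.nan,
                    "t_population": np.nan,
                    "classification": "population_stronger",
                    "no_shared_snp": True,
                }
            )
            continue
        r = ctx.abs_r(entry, y)
        best = np.lexsort((ctx.snp_ids[entry["snp_rows"]], entry["dist"], -r))[0]
        d = entry["dc"][best] + 0.0  # centered dosage; centering is harmless in OLS
        X = np.column_stack([np.ones_like(y), d, pop_ind])
        coef, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        n, k = X.shape
        resid = y - X @ coef
        s2 = float(resid @ resid) / max(n - k, 1)
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 1e-300))
        t = coef / se
        t_snp, t_pop = abs(float(t[1])), abs(float(t[2]))
        rows.append(
            {
                "cpg_id": cpg,
                "snp_id": ctx.snp_ids[entry["snp_rows"]][best],
                "t_snp": t_snp,
                "t_population": t_pop,
                "classification": "snp_stronger"
                if t_snp > t_pop
                else "population_stronger",
                "no_shared_snp": False,
            }
        )
    return pd.DataFrame(rows).set_index("cpg_id")


def summarize_clone_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Pool bisulfite-sequencing clone counts by genotype.

    ``counts`` has one row per individual with columns ``genotype``
    (two-letter label, e.g. CC/CT/TT), ``methylated`` and ``total``
    clone counts. Clones are pooled across individuals per genotype and
    the methylated percentage reported to one decimal, with genotypes
    ordered by copies of the allele that appears in the heterozygote
    last; a ``monotonic`` flag records whether percentages are ordered
    with dosage.
    """
    for col in ("genotype", "methylated", "total"):
        if col not in counts.columns:
            raise ValidationError(f"clone counts missing column {col!r}")
    if (counts["total"] <= 0).any():
        raise ValidationError("clone totals must be positive")
    if (counts["methylated"] > counts["total"]).any():
        raise ValidationError("methylated clone count exceeds total")
    bad = counts["genotype"].astype(str).str.len() != 2
    if bad.any():
        raise ValidationError(
            f"unknown genotype label(s): {counts['genotype'][bad].unique().tolist()}"
        )
    pooled = counts.groupby("genotype")[["methylated", "total"]].sum()
    alleles = sorted({a for g in pooled.index for a in g})
    if len(alleles) > 2:
        raise ValidationError(f"more than two alleles in genotypes: {alleles}")
    ref = alleles[0]
    dosage = pooled.index.map(lambda g: sum(a != ref for a in g))
    pooled = pooled.assign(dosage=dosage).sort_values("dosage")
    pct = 100.0 * pooled["methylated"] / pooled["total"]
    pooled["pct_methylated"] = pct.round(1)
    seq = pooled["pct_methylated"].to_numpy()
    mono = bool(np.all(np.diff(seq) >= 0) or np.all(np.diff(seq) <= 0))
    pooled["monotonic"] = mono
    return pooled
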