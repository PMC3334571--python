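"""Synthetic two-population trio cohorts with planted epigenetic effects.

The generator emulates the design of a population methylation study:
two populations of family trios (father/mother/child), bead-array beta
values at CpG sites near gene promoters, and dense local SNP genotypes.
Effects are planted on a latent logit ("liability") scale and mapped
through the inverse logit so beta stays in [0, 1] without truncation:

    latent = baseline + population shift + mSNP effect x dosage
             + polygenic value + probe-artifact distortion + noise
    beta   = expit(latent)

Planted effect classes (disjoint site sets, recorded in a truth table):

* population shift  - a latent offset calibrated by root finding so the
  realized mean beta difference between populations matches the
  requested magnitude to within 5e-3;
* heritable sites   - an additive polygenic value; the child's value is
  the midparent average plus segregation noise with half the additive
  variance, giving narrow-sense heritability h2 and the classical
  midparent-offspring correlation h2/sqrt(2);
* cis-mSNP sites    - an additive effect of a nearby SNP's dosage whose
  size is calibrated per population to a target |Pearson r|; a fraction
  of planted mSNPs act in exactly one population while the SNP remains
  polymorphic in both (the gene x gene / gene x environment signature);
* probe artifacts   - probes overlapping a genetic variant, where the
  variant's dosage distorts the readout and induces a spurious
  genotype-methylation association.

Allele frequencies diverge between populations under a Balding-Nichols
model: per-population frequencies are Beta-distributed around an
ancestral frequency with drift parameter Fst. Parents are drawn in
Hardy-Weinberg proportions; children receive one allele from each
parent by Mendelian transmission.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .types import (
    BetaMatrix,
    Dataset,
    GenotypeMatrix,
    IntensityTable,
    ProbeManifest,
    TrioPedigree,
    ValidationError,
    VariantCatalog,
)

__all__ = ["SimConfig", "simulate_cohort", "simulate_raw_intensities", "make_external_catalog"]

POP_A = "popA"
POP_B = "popB"

_SITES_PER_CHROM = 100
_SITE_SPACING = 1_000_000  # bp between CpGs; keeps 100 kb windows disjoint
_FIRST_SITE_POS = 500_000
_PROBE_LEN = 50  # probe interval covers [cpg_pos, cpg_pos + 49]
_WINDOW = 100_000


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the real study's conditions at desk scale: 30 trios
    per population (90 samples each), an Fst of 0.15 between a European-
    and an African-ancestry population, planted mean-methylation shifts
    of 0.1 beta, cis-mSNPs targeting |r| = 0.8 (variance explained 64%,
    the middle of the reported 36-92% range), and ~10% of probes
    overlapping a catalog variant.
    """

    n_trios_per_pop: int = 30
    n_sites: int = 2000
    n_snps: int = 6000  # decoy/background SNPs, beyond planted and artifact SNPs
    fst: float = 0.15
    frac_pop_shift_sites: float = 0.20
    shift_magnitude: float = 0.10
    frac_heritable_sites: float = 0.05
    h2_planted: float = 0.5
    n_msnp_sites: int = 20
    frac_pop_specific_msnps: float = 0.8
    msnp_r: float = 0.8  # target |Pearson r| of planted dosage-beta associations
    frac_probe_overlap: float = 0.10
    artifact_effect: float = 1.0  # latent distortion per copy of the overlapping variant
    noise_sd: float = 0.35
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_pop_shift_sites": self.frac_pop_shift_sites,
            "frac_heritable_sites": self.frac_heritable_sites,
            "frac_pop_specific_msnps": self.frac_pop_specific_msnps,
            "frac_probe_overlap": self.frac_probe_overlap,
            "missing_rate": self.missing_rate,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.h2_planted < 1.0:
            raise ValidationError(f"h2_planted must be in [0,1), got {self.h2_planted}")
        if not 0.0 < self.fst < 1.0:
            raise ValidationError(f"fst must be in (0,1), got {self.fst}")
        if not 0.0 <= self.msnp_r < 1.0:
            raise ValidationError(f"msnp_r must be in [0,1), got {self.msnp_r}")
        if self.n_msnp_sites > self.n_sites:
            raise ValidationError("n_msnp_sites exceeds n_sites")
        n_plant = (
            self._n_shift + self._n_herit + self.n_msnp_sites + self._n_flag
        )
        if n_plant > self.n_sites:
            raise ValidationError(
                f"planted site classes ({n_plant}) exceed n_sites ({self.n_sites})"
            )
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")

    @property
    def _n_shift(self) -> int:
        return round(self.frac_pop_shift_sites * self.n_sites)

    @property
    def _n_herit(self) -> int:
        return round(self.frac_heritable_sites * self.n_sites)

    @property
    def _n_flag(self) -> int:
        return round(self.frac_probe_overlap * self.n_sites)


def _rng(seed: int, component: int) -> np.random.Generator:
    # Named substreams: the genotype stream is independent of the
    # methylation streams, so changing n_sites never perturbs genotypes.
    return np.random.default_rng(np.random.SeedSequence((int(seed), component)))


_STREAM_GENO = 0
_STREAM_LAYOUT = 1
_STREAM_METH = 2
_STREAM_POLY = 3
_STREAM_INTENS = 4
_STREAM_MISS = 5


def _site_coords(n_sites: int) -> pd.DataFrame:
    idx = np.arange(n_sites)
    chrom = [f"chr{i // _SITES_PER_CHROM + 1}" for i in idx]
    pos = _FIRST_SITE_POS + (idx % _SITES_PER_CHROM) * _SITE_SPACING
    ids = [f"cg{i:06d}" for i in idx]
    return pd.DataFrame({"chrom": chrom, "pos": pos}, index=pd.Index(ids, name="cpg_id"))


def _balding_nichols(rng, p0: np.ndarray, fst: float, size) -> np.ndarray:
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    return np.clip(rng.beta(a, b, size=size), 0.01, 0.99)


def _mendelian_children(rng, father: np.ndarray, mother: np.ndarray) -> np.ndarray:
    # one allele from each parent; heterozygous parents transmit fairly
    return rng.binomial(1, father / 2.0) + rng.binomial(1, mother / 2.0)


def simulate_cohort(config: SimConfig) -> Dataset:
    """Generate a complete trio cohort with a truth table of planted effects."""
    cfg = config
    n_trio = cfg.n_trios_per_pop
    sites = _site_coords(cfg.n_sites)
    site_ids = sites.index

    # ------------------------------------------------------------------ layout
    lay = _rng(cfg.seed, _STREAM_LAYOUT)
    perm = lay.permutation(cfg.n_sites)
    shift_idx = perm[: cfg._n_shift]
    herit_idx = perm[cfg._n_shift : cfg._n_shift + cfg._n_herit]
    k = cfg._n_shift + cfg._n_herit
    msnp_idx = perm[k : k + cfg.n_msnp_sites]
    k += cfg.n_msnp_sites
    flag_idx = perm[k : k + cfg._n_flag]

    # baselines: planted sites at intermediate methylation (where array beta
    # responds near-linearly to the liability, as variably methylated promoter
    # sites do in practice); null sites bimodal like real promoter methylomes
    baseline = np.empty(cfg.n_sites)
    planted = np.concatenate([shift_idx, herit_idx, msnp_idx])
    is_planted = np.zeros(cfg.n_sites, bool)
    is_planted[planted] = True
    baseline[is_planted] = lay.uniform(-0.5, 0.5, size=is_planted.sum())
    n_null = (~is_planted).sum()
    pole = lay.random(n_null) < 0.7
    mid = lay.uniform(-1.5, 1.5, size=n_null)
    ext = lay.choice([-1.0, 1.0], size=n_null) * lay.uniform(1.5, 3.5, size=n_null)
    baseline[~is_planted] = np.where(pole, ext, mid)

    # ------------------------------------------------------------ SNP placement
    site_chrom = sites["chrom"].to_numpy()
    site_pos = sites["pos"].to_numpy()

    snp_site = []  # target site index per SNP
    snp_off = []  # offset from the site's CpG
    snp_kind = []  # decoy | planted | artifact
    # decoys: cycle over sites, 75% inside the 100 kb window, 25% just outside
    for j in range(cfg.n_snps):
        s = j % cfg.n_sites
        if lay.random() < 0.75:
            off = int(lay.integers(-_WINDOW, _WINDOW + 1))
            while -10 <= off <= _PROBE_LEN + 10:  # keep decoys off the probe
                off = int(lay.integers(-_WINDOW, _WINDOW + 1))
        else:
            off = int(lay.integers(_WINDOW + 1, 4 * _WINDOW)) * int(lay.choice([-1, 1]))
        snp_site.append(s)
        snp_off.append(off)
        snp_kind.append("decoy")
    planted_snp_of_site: dict[int, int] = {}
    for s in msnp_idx:
        off = int(lay.integers(-_WINDOW, _WINDOW + 1))
        while -10 <= off <= _PROBE_LEN + 10:
            off = int(lay.integers(-_WINDOW, _WINDOW + 1))
        planted_snp_of_site[int(s)] = len(snp_site)
        snp_site.append(int(s))
        snp_off.append(off)
        snp_kind.append("planted")
    artifact_snp_of_site: dict[int, int] = {}
    for s in flag_idx:
        artifact_snp_of_site[int(s)] = len(snp_site)
        snp_site.append(int(s))
        snp_off.append(5)  # inside the probe interval
        snp_kind.append("artifact")

    snp_site = np.asarray(snp_site, dtype=int)
    snp_off = np.asarray(snp_off, dtype=int)
    n_snps_total = len(snp_site)
    snp_ids = pd.Index([f"snp{j:06d}" for j in range(n_snps_total)], name="snp_id")
    snp_pos = pd.DataFrame(
        {
            "chrom": site_chrom[snp_site],
            "pos": np.maximum(site_pos[snp_site] + snp_off, 1),
        },
        index=snp_ids,
    )

    # ------------------------------------------------------------- genotypes
    gen = _rng(cfg.seed, _STREAM_GENO)
    kind = np.asarray(snp_kind)
    p0 = gen.uniform(0.05, 0.95, size=n_snps_total)
    p0[kind == "planted"] = gen.uniform(0.3, 0.7, size=(kind == "planted").sum())
    freq = {
        POP_A: _balding_nichols(gen, p0, cfg.fst, n_snps_total),
        POP_B: _balding_nichols(gen, p0, cfg.fst, n_snps_total),
    }
    # planted mSNPs stay common in both populations so the variant is
    # polymorphic everywhere even when its effect is population-specific;
    # artifact variants stay common enough to be observed (hence flagged)
    # in every population
    for pop in (POP_A, POP_B):
        freq[pop][kind == "planted"] = np.clip(freq[pop][kind == "planted"], 0.2, 0.8)
        freq[pop][kind == "artifact"] = np.clip(freq[pop][kind == "artifact"], 0.1, 0.9)

    sample_ids: list[str] = []
    pop_of_sample: list[str] = []
    trio_rows = []
    dosage_cols = {}
    for pop in (POP_A, POP_B):
        p = freq[pop]
        fathers = gen.binomial(2, p[:, None], size=(n_snps_total, n_trio))
        mothers = gen.binomial(2, p[:, None], size=(n_snps_total, n_trio))
        children = _mendelian_children(gen, fathers, mothers)
        for t in range(n_trio):
            fid, mid_, cid = (f"{pop}_t{t:03d}_{r}" for r in ("f", "m", "c"))
            trio_rows.append(
                {"father": fid, "mother": mid_, "child": cid, "population": pop}
            )
            dosage_cols[fid] = fathers[:, t]
            dosage_cols[mid_] = mothers[:, t]
            dosage_cols[cid] = children[:, t]
            sample_ids.extend([fid, mid_, cid])
            pop_of_sample.extend([pop] * 3)

    dosages = pd.DataFrame(dosage_cols, index=snp_ids)[sample_ids]
    pedigree = TrioPedigree(pd.DataFrame(trio_rows))
    pop_arr = np.asarray(pop_of_sample)
    in_a = pop_arr == POP_A
    in_b = pop_arr == POP_B
    dos = dosages.to_numpy(float)

    # ----------------------------------------------------------- methylation
    met = _rng(cfg.seed, _STREAM_METH)
    pol = _rng(cfg.seed, _STREAM_POLY)
    n_samples = len(sample_ids)
    latent = np.tile(baseline[:, None], (1, n_samples))

    # polygenic values at heritable sites
    truth_h2 = np.zeros(cfg.n_sites)
    if len(herit_idx) and cfg.h2_planted > 0:
        sg = cfg.noise_sd * np.sqrt(cfg.h2_planted / (1 - cfg.h2_planted))
        g = np.zeros((len(herit_idx), n_samples))
        # column order is father, mother, child per trio
        for t0 in range(0, n_samples, 3):
            gf = pol.normal(0, sg, size=len(herit_idx))
            gm = pol.normal(0, sg, size=len(herit_idx))
            gc = 0.5 * (gf + gm) + pol.normal(0, sg / np.sqrt(2), size=len(herit_idx))
            g[:, t0], g[:, t0 + 1], g[:, t0 + 2] = gf, gm, gc
        latent[herit_idx] += g
        truth_h2[herit_idx] = cfg.h2_planted

    # planted cis-mSNP effects, calibrated per population to the target |r|
    msnp_truth: dict[str, dict] = {}
    ratio = (
        np.sqrt(cfg.msnp_r**2 / (1 - cfg.msnp_r**2)) * cfg.noise_sd
        if cfg.msnp_r > 0
        else 0.0
    )
    for s in msnp_idx:
        j = planted_snp_of_site[int(s)]
        d = dos[j]
        specific = met.random() < cfg.frac_pop_specific_msnps
        silent_pop = met.choice([POP_A, POP_B]) if specific else None
        eff = {}
        for pop, mask in ((POP_A, in_a), (POP_B, in_b)):
            sd_d = d[mask].std()
            a = 0.0 if (pop == silent_pop or sd_d == 0) else ratio / sd_d
            eff[pop] = a
            latent[s, mask] += a * d[mask]
        msnp_truth[site_ids[s]] = {
            "snp_id": snp_ids[j],
            "effect_popA": float(eff[POP_A]),
            "effect_popB": float(eff[POP_B]),
            "target_r": float(cfg.msnp_r),
        }

    # probe-artifact distortion: the overlapping variant's dosage perturbs
    # the readout in every carrier regardless of population
    artifact_truth: dict[str, dict] = {}
    for s in flag_idx:
        j = artifact_snp_of_site[int(s)]
        latent[s] += cfg.artifact_effect * (dos[j] - dos[j].mean())
        artifact_truth[site_ids[s]] = {"snp_id": snp_ids[j]}

    latent += met.normal(0, cfg.noise_sd, size=latent.shape)

    # population mean shifts, calibrated on the realized latent values
    shift_truth: dict[str, dict] = {}
    for s in shift_idx:
        sign = -1.0 if met.random() < 0.5 else 1.0
        target = sign * cfg.shift_magnitude
        la, lb = latent[s, in_a], latent[s, in_b]
        base_gap = expit(lb).mean() - expit(la).mean()

        def gap(delta: float) -> float:
            return expit(lb + delta).mean() - expit(la).mean() - target

        delta = brentq(gap, -30.0, 30.0, xtol=1e-10)
        latent[s, in_b] += delta
        shift_truth[site_ids[s]] = {
            "magnitude": float(target),
            "latent_offset": float(delta),
            "baseline_gap": float(base_gap),
        }

    beta = expit(latent)
    if cfg.missing_rate > 0:
        mis = _rng(cfg.seed, _STREAM_MISS)
        beta[mis.random(beta.shape) < cfg.missing_rate] = np.nan

    beta_df = pd.DataFrame(beta, index=site_ids, columns=sample_ids)

    # ------------------------------------------------------ manifest & catalog
    manifest = ProbeManifest(
        pd.DataFrame(
            {
                "chrom": sites["chrom"],
                "probe_start": sites["pos"],
                "probe_end": sites["pos"] + _PROBE_LEN - 1,
                "cpg_pos": sites["pos"],
                "gene": [f"GENE{i // 2:05d}" for i in range(cfg.n_sites)],
            },
            index=site_ids,
        )
    )

    # presence-based variant catalog: a variant is listed for a population
    # when its minor allele is actually observed in that population's samples
    var_rows = []
    for s in flag_idx:
        j = artifact_snp_of_site[int(s)]
        for pop, mask in ((POP_A, in_a), (POP_B, in_b)):
            d = dos[j, mask]
            if 0 < d.sum() < 2 * mask.sum():
                var_rows.append(
                    {
                        "chrom": snp_pos["chrom"].iloc[j],
                        "pos": int(snp_pos["pos"].iloc[j]),
                        "population": pop,
                    }
                )
    variants = VariantCatalog(
        pd.DataFrame(var_rows, columns=["chrom", "pos", "population"])
    )

    truth = {
        "config": asdict(cfg),
        "populations": [POP_A, POP_B],
        "pop_shift": shift_truth,
        "heritable": {site_ids[s]: float(cfg.h2_planted) for s in herit_idx},
        "msnp": msnp_truth,
        "artifact": artifact_truth,
    }

    return Dataset(
        beta=BetaMatrix(beta_df, sites),
        genotypes=GenotypeMatrix(dosages, snp_pos),
        pedigree=pedigree,
        manifest=manifest,
        variants=variants,
        truth=truth,
    )


def simulate_raw_intensities(
    dataset: Dataset,
    config: SimConfig,
    scale: float = 2000.0,
    background_range: tuple[float, float] = (50.0, 300.0),
) -> IntensityTable:
    """Invert the beta calculation into two-channel raw intensities.

    Emits methylated/unmethylated intensities ``M = beta * scale + b`` and
    ``U = (1 - beta) * scale + b`` with a per-sample, per-channel additive
    background ``b`` that is also reported by the negative-control probes,
    so the normalization pipeline's background subtraction is exercised and
    the recovered beta matches the input. Channels alternate green/red by
    site, as a two-dye array delivers them.
    """
    rng = _rng(config.seed, _STREAM_INTENS)
    beta = dataset.beta.values
    sites = beta.index
    samples = beta.columns
    channels = np.where(np.arange(len(sites)) % 2 == 0, "green", "red")

    bg = {
        (s, ch): float(rng.uniform(*background_range))
        for s in samples
        for ch in ("green", "red")
    }
    rows = []
    arr = beta.to_numpy(float)
    for i, site in enumerate(sites):
        ch = channels[i]
        for j, samp in enumerate(samples):
            b = bg[(samp, ch)]
            v = arr[i, j]
            if np.isnan(v):
                m, u = b, b  # signal absent -> beta undefined after subtraction
            else:
                m, u = v * scale + b, (1 - v) * scale + b
            rows.append((site, samp, m, u, ch, int(rng.integers(8, 20)),
                         float(rng.uniform(0, 0.01))))
    data = pd.DataFrame(
        rows, columns=["site", "sample", "M", "U", "channel", "n_beads", "detection_p"]
    )
    controls = pd.DataFrame(
        [(s, ch, bg[(s, ch)]) for s in samples for ch in ("green", "red")],
        columns=["sample", "channel", "neg_mean"],
    )
    return IntensityTable(data, controls)


def make_external_catalog(
    dataset: Dataset,
    share_frac: float,
    seed: int,
    background_frac: float = 0.012,
) -> set[str]:
    """Emulate an external-tissue mSNP catalog for overlap testing.

    Includes each planted population-A mSNP target CpG independently with
    probability ``share_frac``, plus a random ``background_frac`` of the
    remaining CpG universe.
    """
    if not 0.0 <= share_frac <= 1.0:
        raise ValidationError(f"share_frac must be in [0,1], got {share_frac}")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 99)))
    truth = dataset.truth or {}
    targets = [
        cpg for cpg, rec in truth.get("msnp", {}).items() if rec["effect_popA"] != 0.0
    ]
    catalog = {c for c in targets if rng.random() < share_frac}
    rest = [c for c in dataset.beta.site_ids if c not in set(targets)]
    catalog |= {c for c in rest if rng.random() < background_frac}
    return catalog
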