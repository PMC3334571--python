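"""Readers and writers for the pipeline's plain-text file formats.

A dataset bundle is a directory of TSVs plus a PED pedigree:

* ``beta.tsv``      - CpG x sample beta matrix; first column ``cpg_id``;
  missing beta encoded as an empty field.
* ``genotypes.tsv`` - SNP x sample dosage matrix with ``snp_id``, ``chrom``,
  ``pos`` columns first; missing dosage encoded as ``.``.
* ``pedigree.ped``  - 6-column PED (FID IID father mother sex phenotype);
  the population label is the FID prefix before ``:``.
* ``manifest.tsv``  - probe intervals, declared 1-based inclusive in the
  header comment (not half-open BED).
* ``variants.tsv``  - known variant positions per population.
* ``truth.json``    - optional planted-effect record for simulated data.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

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

logger = logging.getLogger(__name__)

__all__ = [
    "write_bundle",
    "read_dataset",
    "write_results",
    "read_intensities",
    "write_intensities",
    "write_vcf",
    "read_vcf",
]

_MANIFEST_HEADER = (
    "# probe manifest; all coordinates 1-based, intervals inclusive on both ends\n"
)


def write_bundle(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write the full dataset bundle; returns the path of each file."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    beta = dataset.beta.values.copy()
    beta.index.name = "cpg_id"
    paths["beta"] = out / "beta.tsv"
    beta.to_csv(paths["beta"], sep="\t", na_rep="")

    geno = dataset.genotypes.positions.join(dataset.genotypes.dosages)
    geno.index.name = "snp_id"
    paths["genotypes"] = out / "genotypes.tsv"
    geno.to_csv(paths["genotypes"], sep="\t", na_rep=".")

    paths["pedigree"] = out / "pedigree.ped"
    with open(paths["pedigree"], "w") as fh:
        for k, row in dataset.pedigree.trios.reset_index(drop=True).iterrows():
            fid = f"{row['population']}:trio{k:03d}"
            fh.write(f"{fid}\t{row['father']}\t0\t0\t1\t0\n")
            fh.write(f"{fid}\t{row['mother']}\t0\t0\t2\t0\n")
            sex = 1 + k % 2
            fh.write(f"{fid}\t{row['child']}\t{row['father']}\t{row['mother']}\t{sex}\t0\n")

    man = dataset.manifest.probes.reset_index()
    man = man[["chrom", "probe_start", "probe_end", "cpg_id", "cpg_pos", "gene"]]
    paths["manifest"] = out / "manifest.tsv"
    with open(paths["manifest"], "w") as fh:
        fh.write(_MANIFEST_HEADER)
        man.to_csv(fh, sep="\t", index=False)

    paths["variants"] = out / "variants.tsv"
    dataset.variants.variants.to_csv(paths["variants"], sep="\t", index=False)

    if dataset.truth is not None:
        paths["truth"] = out / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(dataset.truth, fh, indent=1, sort_keys=True)
    return paths


def _read_pedigree(path: Path) -> TrioPedigree:
    ped = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    rows = []
    for _, row in ped.iterrows():
        if row["father"] != "0" and row["mother"] != "0":
            rows.append(
                {
                    "father": row["father"],
                    "mother": row["mother"],
                    "child": row["iid"],
                    "population": row["fid"].split(":")[0],
                }
            )
    if not rows:
        raise ValidationError(f"no complete trios found in {path}")
    return TrioPedigree(pd.DataFrame(rows))


def read_dataset(
    directory: str | Path,
    *,
    drop_sex_chromosomes: bool = True,
) -> Dataset:
    """Load and validate a dataset bundle written by :func:`write_bundle`.

    Sample ordering is canonicalized to the beta matrix's column order;
    chrX/chrY sites are dropped (with a logged count) unless disabled.
    """
    d = Path(directory)
    beta_df = pd.read_csv(d / "beta.tsv", sep="\t", index_col="cpg_id")
    man = pd.read_csv(d / "manifest.tsv", sep="\t", comment="#").set_index("cpg_id")
    manifest = ProbeManifest(man[["chrom", "probe_start", "probe_end", "cpg_pos", "gene"]])

    positions = man.rename(columns={"cpg_pos": "pos"})[["chrom", "pos"]]
    missing_pos = beta_df.index.difference(positions.index)
    if len(missing_pos):
        raise ValidationError(
            f"beta sites missing from manifest: {missing_pos[:5].tolist()}"
        )
    beta = BetaMatrix(beta_df, positions.loc[beta_df.index])
    if drop_sex_chromosomes:
        before = len(beta.site_ids)
        beta = beta.autosomal()
        dropped = before - len(beta.site_ids)
        if dropped:
            logger.info("excluded %d sex-chromosome sites", dropped)
        manifest = ProbeManifest(manifest.probes.loc[beta.site_ids])

    geno = pd.read_csv(d / "genotypes.tsv", sep="\t", index_col="snp_id", na_values=".")
    positions_g = geno[["chrom", "pos"]]
    dosages = geno.drop(columns=["chrom", "pos"])
    # canonical sample order comes from the beta matrix
    missing_samples = [s for s in beta.sample_ids if s not in dosages.columns]
    if missing_samples:
        raise ValidationError(f"samples absent from genotypes: {missing_samples[:5]}")
    genotypes = GenotypeMatrix(dosages[list(beta.sample_ids)], positions_g)

    pedigree = _read_pedigree(d / "pedigree.ped")
    variants = VariantCatalog(pd.read_csv(d / "variants.tsv", sep="\t"))

    truth = None
    if (d / "truth.json").exists():
        with open(d / "truth.json") as fh:
            truth = json.load(fh)

    return Dataset(
        beta=beta,
        genotypes=genotypes,
        pedigree=pedigree,
        manifest=manifest,
        variants=variants,
        truth=truth,
    )


_SORT_PREFERENCE = ("chrom", "pos", "cpg_pos", "cpg_id", "snp_id", "population")


def write_results(results: pd.DataFrame, path: str | Path) -> Path:
    """Write a stage-output table with deterministic row and column order.

    Rows are sorted by whichever of (chrom, pos, cpg_id, snp_id, ...) are
    present, so rereading a file always yields the same table regardless
    of upstream iteration order.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = results.copy()
    keys = [c for c in _SORT_PREFERENCE if c in df.columns]
    if keys:
        df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def write_intensities(table: IntensityTable, path: str | Path) -> Path:
    path = Path(path)
    table.data.to_csv(path, sep="\t", index=False)
    table.controls.to_csv(path.with_suffix(".controls.tsv"), sep="\t", index=False)
    return path


def read_intensities(path: str | Path) -> IntensityTable:
    path = Path(path)
    data = pd.read_csv(path, sep="\t")
    controls = pd.read_csv(path.with_suffix(".controls.tsv"), sep="\t")
    return IntensityTable(data, controls)


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    """Write dosages as a minimal unphased diploid VCF (alt-allele dosage)."""
    path = Path(path)
    samples = list(genotypes.sample_ids)
    order = genotypes.positions.sort_values(["chrom", "pos"], kind="mergesort").index
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(genotypes.positions["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for snp in order:
            chrom = genotypes.positions.loc[snp, "chrom"]
            pos = genotypes.positions.loc[snp, "pos"]
            calls = [
                _GT_CODE.get(float(v), "./.") if not pd.isna(v) else "./."
                for v in genotypes.dosages.loc[snp, samples]
            ]
            fh.write(f"{chrom}\t{pos}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t")
            fh.write("\t".join(calls) + "\n")
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Ingest a diploid VCF, mapping GT to alt-allele dosage {0,1,2}."""
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        gt = var.gt_types.astype(float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dos)
    dosages = pd.DataFrame(rows, index=pd.Index(ids, name="snp_id"), columns=samples)
    positions = pd.DataFrame({"chrom": chroms, "pos": poss}, index=dosages.index)
    return GenotypeMatrix(dosages, positions)
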