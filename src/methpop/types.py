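"""Core in-memory containers for the methylation population pipeline.

All genomic coordinates are 1-based and intervals are inclusive on both
ends, matching the convention of array manifests and the published
per-site tables this pipeline emulates. Methylation is carried as
``beta`` fractions in [0, 1]: the share of methylated signal at a CpG
site, ``M / (M + U)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "BetaMatrix",
    "GenotypeMatrix",
    "TrioPedigree",
    "ProbeManifest",
    "VariantCatalog",
    "IntensityTable",
    "Dataset",
]


class ValidationError(ValueError):
    """Raised when an input file or container violates its invariants."""


def _check_unique(ids: Sequence, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dup}")


@dataclass
class BetaMatrix:
    """CpG sites x samples matrix of methylation fractions.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by CpG site id, columns by sample id; entries are
        beta fractions in [0, 1] or NaN for missing.
    positions : pandas.DataFrame or None
        Indexed by site id with columns ``chrom`` (str) and ``pos``
        (1-based int). Every site in ``values`` must appear here. May be
        None for a matrix that has not been mapped to coordinates yet
        (e.g. fresh off normalization).
    """

    values: pd.DataFrame
    positions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "CpG site id")
        _check_unique(self.values.columns, "sample id")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0,1] at site {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {arr[i, j]}"
            )
        if self.positions is not None:
            missing = self.values.index.difference(self.positions.index)
            if len(missing):
                raise ValidationError(
                    f"sites without coordinates: {missing[:5].tolist()}"
                )

    @property
    def site_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def autosomal(self) -> "BetaMatrix":
        """Drop chrX/chrY sites (case-insensitive; accepts 'X'/'chrX')."""
        if self.positions is None:
            raise ValidationError("cannot filter sex chromosomes without coordinates")
        chrom = self.positions.loc[self.site_ids, "chrom"].astype(str).str.lower()
        keep = ~chrom.str.removeprefix("chr").isin(["x", "y"])
        kept = self.site_ids[keep.to_numpy()]
        return BetaMatrix(self.values.loc[kept], self.positions.loc[kept])


@dataclass
class GenotypeMatrix:
    """SNPs x samples minor-allele dosage matrix.

    Dosages are coded 0/1/2 (coding per SNP is arbitrary but consistent);
    NaN marks a missing call.
    """

    dosages: pd.DataFrame
    positions: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.dosages.index, "SNP id")
        arr = self.dosages.to_numpy(dtype=float)
        bad = ~(np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0)))
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage not in {{0,1,2,missing}} at SNP {self.dosages.index[i]!r}, "
                f"sample {self.dosages.columns[j]!r}: {arr[i, j]}"
            )

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns


@dataclass
class TrioPedigree:
    """Father/mother/child triples with a population label per trio."""

    trios: pd.DataFrame  # columns: father, mother, child, population

    REQUIRED = ("father", "mother", "child", "population")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.trios.columns]
        if missing:
            raise ValidationError(f"pedigree missing columns: {missing}")
        members = pd.concat(
            [self.trios[c] for c in ("father", "mother", "child")]
        )
        _check_unique(members, "pedigree sample (sample in two trios?)")

    @property
    def populations(self) -> list[str]:
        return sorted(self.trios["population"].unique())

    def trios_in(self, population: str) -> pd.DataFrame:
        return self.trios[self.trios["population"] == population]

    def samples_in(self, population: str) -> list[str]:
        sub = self.trios_in(population)
        out: list[str] = []
        for _, row in sub.iterrows():
            out.extend([row["father"], row["mother"], row["child"]])
        return out

    @property
    def all_samples(self) -> list[str]:
        out: list[str] = []
        for _, row in self.trios.iterrows():
            out.extend([row["father"], row["mother"], row["child"]])
        return out

    def population_of(self) -> pd.Series:
        """Sample id -> population label."""
        rec = {}
        for _, row in self.trios.iterrows():
            for role in ("father", "mother", "child"):
                rec[row[role]] = row["population"]
        return pd.Series(rec, name="population")


@dataclass
class ProbeManifest:
    """Array probe intervals and CpG coordinates (1-based inclusive)."""

    probes: pd.DataFrame  # index cpg_id; chrom, probe_start, probe_end, cpg_pos, gene

    def __post_init__(self) -> None:
        _check_unique(self.probes.index, "manifest cpg_id")
        bad = self.probes["probe_start"] > self.probes["probe_end"]
        if bad.any():
            raise ValidationError(
                f"probe interval reversed for {self.probes.index[bad][:5].tolist()}"
            )


@dataclass
class VariantCatalog:
    """Known variant positions per population (e.g. a sequencing catalog)."""

    variants: pd.DataFrame  # columns: chrom, pos, population

    def __post_init__(self) -> None:
        if (self.variants["pos"] <= 0).any():
            raise ValidationError("variant catalog contains non-positive position")

    def for_population(self, population: str) -> pd.DataFrame:
        return self.variants[self.variants["population"] == population]


@dataclass
class IntensityTable:
    """Raw two-channel array intensities before normalization.

    ``data`` is long-form with one row per (site, sample): methylated
    intensity ``M``, unmethylated intensity ``U``, dye ``channel``
    ('green'/'red'), ``n_beads`` and ``detection_p``. ``controls`` holds
    the per-sample, per-channel mean negative-control intensity used for
    background subtraction.
    """

    data: pd.DataFrame  # site, sample, M, U, channel, n_beads, detection_p
    controls: pd.DataFrame  # sample, channel, neg_mean

    def __post_init__(self) -> None:
        for col in ("M", "U"):
            if not np.isfinite(self.data[col].to_numpy(dtype=float)).all():
                raise ValidationError(f"non-finite {col} intensity")
        dp = self.data["detection_p"].to_numpy(dtype=float)
        if ((dp < 0) | (dp > 1)).any():
            raise ValidationError("detection_p outside [0,1]")
        if (self.data["n_beads"].to_numpy() < 0).any():
            raise ValidationError("negative n_beads")


@dataclass
class Dataset:
    """A validated bundle of every input the pipeline consumes."""

    beta: BetaMatrix
    genotypes: GenotypeMatrix
    pedigree: TrioPedigree
    manifest: ProbeManifest
    variants: VariantCatalog
    truth: dict | None = None

    def __post_init__(self) -> None:
        samples = set(self.beta.sample_ids)
        for s in self.pedigree.all_samples:
            if s not in samples:
                raise ValidationError(f"pedigree sample {s!r} absent from beta matrix")
            if s not in set(self.genotypes.sample_ids):
                raise ValidationError(
                    f"pedigree sample {s!r} absent from genotype matrix"
                )
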