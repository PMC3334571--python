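"""Trio-based narrow-sense heritability of methylation.

Per site and population, h2 is estimated as the Pearson correlation
between the midparent beta (the two parents' average) and the child's
beta across family trios. Estimates may be negative at finite sample
size. Under the standard additive model with unrelated mates the
midparent variance is half the offspring variance, so the expected
correlation is h2/sqrt(2) while the regression slope is h2; this
estimator reports the correlation as defined.

The aggregate number of heritable sites is estimated against a
randomized null: children are shuffled among families within the
population (parents stay together), the per-site h2 distribution is
recomputed, and the count is the positive-side excess of the real h2
histogram over the null histogram, clipped at zero per bin and averaged
over randomizations. The procedure counts heritable sites without
identifying which sites they are, so no per-site FDR is attached.

Variant-overlapping probes are deliberately NOT excluded here (nor from
the population-difference stage): probe artifacts fabricate genotype
associations, not parent-offspring resemblance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import BetaMatrix, TrioPedigree, ValidationError

__all__ = ["estimate_h2", "HeritableCount", "estimate_heritable_count"]

MIN_TRIOS = 3


def _row_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally shaped matrices."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return r


def _trio_matrices(
    beta: BetaMatrix, pedigree: TrioPedigree, population: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    trios = pedigree.trios_in(population)
    if len(trios) < MIN_TRIOS:
        raise ValidationError(
            f"need at least {MIN_TRIOS} trios in {population!r}, got {len(trios)}"
        )
    vals = beta.values
    F = vals[trios["father"].tolist()].to_numpy(float)
    M = vals[trios["mother"].tolist()].to_numpy(float)
    C = vals[trios["child"].tolist()].to_numpy(float)
    return F, M, C


def _h2_from_matrices(F: np.ndarray, M: np.ndarray, C: np.ndarray) -> np.ndarray:
    mid = 0.5 * (F + M)
    complete = ~(np.isnan(mid) | np.isnan(C))
    all_complete = complete.all(axis=1)
    h2 = np.full(F.shape[0], np.nan)
    if all_complete.any():
        h2[all_complete] = _row_pearson(mid[all_complete], C[all_complete])
    for i in np.flatnonzero(~all_complete):
        ok = complete[i]
        if ok.sum() < MIN_TRIOS:
            continue
        h2[i] = _row_pearson(mid[i, ok][None, :], C[i, ok][None, :])[0]
    return h2


def estimate_h2(
    beta: BetaMatrix, pedigree: TrioPedigree, population: str
) -> pd.DataFrame:
    """Per-site midparent-offspring correlation in one population.

    Trios with a missing value at a site are dropped for that site; a
    site with fewer than three complete trios, or zero variance in the
    midparent or child vector, gets a missing estimate.
    """
    F, M, C = _trio_matrices(beta, pedigree, population)
    h2 = _h2_from_matrices(F, M, C)
    n_trios = (~(np.isnan(0.5 * (F + M)) | np.isnan(C))).sum(axis=1)
    return pd.DataFrame(
        {
            "cpg_id": beta.site_ids,
            "population": population,
            "h2": h2,
            "n_trios": n_trios,
        }
    ).set_index("cpg_id")


@dataclass
class HeritableCount:
    """Aggregate count of heritable sites from the histogram-excess method."""

    population: str
    bin_edges: np.ndarray
    real_hist: np.ndarray
    null_hists: np.ndarray = field(repr=False)  # R x n_bins
    count_estimate: float = 0.0
    r: int = 0


def estimate_heritable_count(
    estimates: pd.DataFrame,
    beta: BetaMatrix,
    pedigree: TrioPedigree,
    R: int = 1000,
    bin_width: float = 0.05,
    seed: int = 0,
) -> HeritableCount:
    """Estimate how many sites carry heritable methylation in a population.

    For each of ``R`` randomizations, children are permuted among the
    population's trios and per-site h2 recomputed; the count for that
    randomization sums, over histogram bins on the positive side, the
    excess of real over null bin counts (clipped at zero). The estimate
    is the mean count across randomizations.
    """
    if R < 1:
        raise ValidationError("R must be >= 1")
    pops = estimates["population"].unique()
    if len(pops) != 1:
        raise ValidationError("estimates must come from a single population")
    population = pops[0]
    F, M, C = _trio_matrices(beta, pedigree, population)
    n_trios = C.shape[1]
    if n_trios < 2:
        raise ValidationError("need at least two trios to permute children")

    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    real = estimates["h2"].to_numpy(float)
    real_hist, _ = np.histogram(real[~np.isnan(real)], bins=edges)
    positive = edges[:-1] >= 0.0

    rng = np.random.default_rng(seed)
    null_hists = np.zeros((R, len(edges) - 1), dtype=int)
    counts = np.zeros(R)
    for k in range(R):
        perm = rng.permutation(n_trios)
        h2_null = _h2_from_matrices(F, M, C[:, perm])
        null_hists[k], _ = np.histogram(h2_null[~np.isnan(h2_null)], bins=edges)
        excess = np.clip(real_hist - null_hists[k], 0, None)
        counts[k] = excess[positive].sum()
    return HeritableCount(
        population=population,
        bin_edges=edges,
        real_hist=real_hist,
        null_hists=null_hists,
        count_estimate=float(counts.mean()),
        r=R,
    )
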