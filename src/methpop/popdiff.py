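"""Between-population methylation differences and randomization FDR.

Each CpG site is tested with a two-sided Wilcoxon rank-sum (Mann-Whitney)
test comparing all samples of one population against the other. Exact
enumeration is used when both groups have at most ``EXACT_MAX_N`` samples
and the data are tie-free; otherwise the normal approximation with tie
and continuity correction applies (at 90 vs 90 samples the approximation
is the only practical choice).

False discovery rates are estimated by randomization: population labels
are reassigned, the per-site statistic is recomputed, and the FDR is the
mean number of null sites passing the threshold divided by the observed
number. Labels can be permuted over individual samples or over whole
trios ("trio-aware"), keeping each family's three correlated profiles
together so the null respects the cohort's relatedness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import BetaMatrix, TrioPedigree, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EXACT_MAX_N",
    "RanksumEngine",
    "wilcoxon_rank_sum",
    "test_population_differences",
    "PermutationFdr",
    "permutation_fdr",
]

EXACT_MAX_N = 10


def _tie_term(data: np.ndarray) -> np.ndarray:
    """Sum of t^3 - t over tie groups, per row."""
    nrow, N = data.shape
    srt = np.sort(data, axis=1)
    boundary = np.ones_like(srt, dtype=bool)
    boundary[:, 1:] = srt[:, 1:] != srt[:, :-1]
    gid = np.cumsum(boundary, axis=1) - 1
    flat = (gid + np.arange(nrow)[:, None] * N).ravel()
    counts = np.bincount(flat, minlength=nrow * N).reshape(nrow, N)
    return (counts.astype(float) ** 3 - counts).sum(axis=1)


class RanksumEngine:
    """Vectorized tie- and continuity-corrected rank-sum tests per site.

    Ranks depend only on the data, not on the group labels, so they are
    computed once; each call with a new label mask costs a single masked
    rank sum. This is what makes thousand-fold label randomization cheap.
    """

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=float)
        if np.isnan(self.values).any():
            raise ValidationError("RanksumEngine requires complete data")
        self.ranks = stats.rankdata(self.values, axis=1)
        self.tie = _tie_term(self.values)
        self.N = self.values.shape[1]

    def pvalues(self, mask_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Two-sided P-values and U statistics for group A = ``mask_a``."""
        na = int(mask_a.sum())
        nb = self.N - na
        if na < 2 or nb < 2:
            raise ValidationError("need at least two samples per population")
        r_a = self.ranks[:, mask_a].sum(axis=1)
        u = r_a - na * (na + 1) / 2.0
        mu = na * nb / 2.0
        var = (
            na * nb / 12.0
            * ((self.N + 1) - self.tie / (self.N * (self.N - 1.0)))
        )
        sd = np.sqrt(var)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (np.abs(u - mu) - 0.5) / sd
        z = np.where(var > 0, np.maximum(z, 0.0), 0.0)
        p = np.minimum(2.0 * stats.norm.sf(z), 1.0)
        return p, u


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test for one site; exact for small tie-free groups."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 1 or y.size < 1:
        return np.nan, np.nan
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == pooled.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and tie_free:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    eng = RanksumEngine(pooled[None, :])
    mask = np.zeros(pooled.size, bool)
    mask[: x.size] = True
    p, u = eng.pvalues(mask)
    return float(u[0]), float(p[0])


def _population_masks(
    beta: BetaMatrix, pedigree: TrioPedigree
) -> tuple[str, str, np.ndarray]:
    pops = pedigree.populations
    if len(pops) != 2:
        raise ValidationError(f"expected exactly two populations, got {pops}")
    pop_of = pedigree.population_of()
    labels = pop_of.reindex(beta.sample_ids)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()][:5])
        raise ValidationError(f"samples without population label: {missing}")
    return pops[0], pops[1], (labels == pops[0]).to_numpy()


def test_population_differences(
    beta: BetaMatrix, pedigree: TrioPedigree
) -> pd.DataFrame:
    """Per-site two-population Wilcoxon tests with magnitude bins.

    Returns one row per CpG: U statistic and two-sided P, per-population
    mean beta, the mean difference (first population minus second), and
    significance / magnitude flags at the conventional thresholds
    (P < 0.01, P < 0.001; |mean difference| > 0.05 and > 0.10).
    """
    pop_a, pop_b, mask_a = _population_masks(beta, pedigree)
    vals = beta.values.to_numpy(float)
    n_sites = vals.shape[0]
    has_nan = np.isnan(vals).any(axis=1)

    pvals = np.full(n_sites, np.nan)
    ustat = np.full(n_sites, np.nan)
    if (~has_nan).any():
        eng = RanksumEngine(vals[~has_nan])
        p, u = eng.pvalues(mask_a)
        pvals[~has_nan] = p
        ustat[~has_nan] = u
    for i in np.flatnonzero(has_nan):
        x = vals[i, mask_a]
        y = vals[i, ~mask_a]
        if np.all(np.isnan(x)) or np.all(np.isnan(y)):
            continue  # flagged missing: one population entirely absent
        ustat[i], pvals[i] = wilcoxon_rank_sum(x, y)

    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        mean_a = np.nanmean(vals[:, mask_a], axis=1)
        mean_b = np.nanmean(vals[:, ~mask_a], axis=1)
    diff = mean_a - mean_b
    return pd.DataFrame(
        {
            "cpg_id": beta.site_ids,
            "statistic": ustat,
            "p_value": pvals,
            f"mean_{pop_a}": mean_a,
            f"mean_{pop_b}": mean_b,
            "mean_diff": diff,
            "sig_p01": pvals < 0.01,
            "sig_p001": pvals < 0.001,
            "absdiff_gt_05": np.abs(diff) > 0.05,
            "absdiff_gt_10": np.abs(diff) > 0.10,
        }
    ).set_index("cpg_id")


@dataclass
class PermutationFdr:
    """Randomization FDR at a P-value threshold."""

    threshold: float
    observed_count: int
    mean_null_count: float
    fdr: float  # NaN sentinel when observed_count == 0
    r: int
    scheme: str
    null_counts: list[int] = field(repr=False, default_factory=list)


def _permuted_mask(
    rng: np.random.Generator,
    scheme: str,
    beta: BetaMatrix,
    pedigree: TrioPedigree,
    pop_a: str,
) -> np.ndarray:
    sample_index = pd.Index(beta.sample_ids)
    if scheme == "individual":
        n_a = (pedigree.population_of().reindex(sample_index) == pop_a).sum()
        mask = np.zeros(len(sample_index), bool)
        mask[rng.choice(len(sample_index), size=n_a, replace=False)] = True
        return mask
    if scheme == "trio":
        trios = pedigree.trios.reset_index(drop=True)
        n_a = int((trios["population"] == pop_a).sum())
        chosen = rng.choice(len(trios), size=n_a, replace=False)
        mask = np.zeros(len(sample_index), bool)
        for t in chosen:
            for role in ("father", "mother", "child"):
                mask[sample_index.get_loc(trios.loc[t, role])] = True
        return mask
    raise ValidationError(f"unknown permutation scheme {scheme!r}")


def permutation_fdr(
    beta: BetaMatrix,
    pedigree: TrioPedigree,
    threshold: float = 0.01,
    R: int = 1000,
    scheme: str = "trio",
    seed: int = 0,
    statistic_fn=None,
) -> PermutationFdr:
    """Estimate the FDR of the population-difference test by label shuffling.

    ``statistic_fn(values, mask_a) -> p-values`` defaults to the rank-sum
    engine; ``scheme`` chooses whether labels are permuted over samples
    ("individual") or over whole trios ("trio"), each time preserving the
    number of samples (or trios) per population.
    """
    if R < 1:
        raise ValidationError("R must be >= 1")
    pop_a, _, mask_obs = _population_masks(beta, pedigree)
    vals = beta.values.to_numpy(float)
    complete = ~np.isnan(vals).any(axis=1)
    vals = vals[complete]
    if statistic_fn is None:
        eng = RanksumEngine(vals)

        def statistic_fn(values, mask_a):  # noqa: F811 - default engine
            p, _ = eng.pvalues(mask_a)
            return p

    observed = int((statistic_fn(vals, mask_obs) < threshold).sum())
    rng = np.random.default_rng(seed)
    null_counts = []
    for _ in range(R):
        mask = _permuted_mask(rng, scheme, beta, pedigree, pop_a)
        null_counts.append(int((statistic_fn(vals, mask) < threshold).sum()))
    mean_null = float(np.mean(null_counts))
    if observed == 0:
        logger.warning("no observed sites pass threshold %g; FDR undefined", threshold)
        fdr = float("nan")
    else:
        fdr = mean_null / observed
    return PermutationFdr(
        threshold=threshold,
        observed_count=observed,
        mean_null_count=mean_null,
        fdr=fdr,
        r=R,
        scheme=scheme,
        null_counts=null_counts,
    )
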