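"""Array normalization and quality control for two-channel methylation data.

The normalization mirrors the GenomeStudio-style workflow for single-type
bead arrays: per-sample background subtraction using negative-control
probes (done separately for the green and red dye channels), clamping of
negative intensities to zero, quantile normalization of the
background-adjusted intensities across samples within each channel, and
recomputation of beta as M / (M + U) from the normalized intensities.
No denominator offset is added and no between-channel (dye-bias or probe
type) correction is applied; the 27K-style design is single-type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import BetaMatrix, IntensityTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "QcReport",
    "quantile_normalize",
    "normalize_intensities",
    "sample_qc",
    "batch_effect_check",
    "replicate_concordance",
]


def quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of ``X`` to a common distribution.

    The reference distribution is the mean across columns of the sorted
    values. Ties within a column receive the mean of the reference order
    statistics spanning their ranks, which makes the result deterministic
    and independent of input order.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        sorter = np.argsort(col, kind="mergesort")
        sorted_col = col[sorter]
        # collapse tie spans onto the mean reference value for the span
        _, starts, counts = np.unique(sorted_col, return_index=True, return_counts=True)
        span_means = np.add.reduceat(ref, starts) / counts
        mapped = np.repeat(span_means, counts)
        out[sorter, j] = mapped
    return out


def _pivot(table: IntensityTable, col: str) -> pd.DataFrame:
    return table.data.pivot(index="site", columns="sample", values=col)


def normalize_intensities(raw: IntensityTable) -> BetaMatrix:
    """Background-subtract, quantile-normalize per channel, recompute beta.

    Sites whose normalized M + U intensity is zero for a sample get a
    missing beta (logged); everything else lands in [0, 1] by
    construction since normalized intensities are non-negative.
    """
    M = _pivot(raw, "M")
    U = _pivot(raw, "U").loc[M.index, M.columns]
    chan = raw.data.drop_duplicates("site").set_index("site")["channel"].loc[M.index]
    per_site_channels = raw.data.groupby("site")["channel"].nunique()
    if (per_site_channels > 1).any():
        raise ValidationError("a site reports intensities on more than one channel")

    ctrl = raw.controls.set_index(["sample", "channel"])["neg_mean"]
    M_adj = M.copy().astype(float)
    U_adj = U.copy().astype(float)
    for ch in chan.unique():
        sites = chan.index[chan == ch]
        bg = np.array([ctrl.get((s, ch), 0.0) for s in M.columns])
        M_adj.loc[sites] = M.loc[sites].to_numpy(float) - bg
        U_adj.loc[sites] = U.loc[sites].to_numpy(float) - bg
    M_adj = M_adj.clip(lower=0.0)
    U_adj = U_adj.clip(lower=0.0)

    # quantile-normalize the pooled per-sample intensity vector (M stacked
    # on U) within each channel, as the array delivers them
    for ch in chan.unique():
        sites = chan.index[chan == ch]
        stacked = np.vstack([M_adj.loc[sites].to_numpy(), U_adj.loc[sites].to_numpy()])
        normed = quantile_normalize(stacked)
        k = len(sites)
        M_adj.loc[sites] = normed[:k]
        U_adj.loc[sites] = normed[k:]

    denom = M_adj.to_numpy() + U_adj.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, M_adj.to_numpy() / denom, np.nan)
    n_missing = int(np.isnan(beta).sum())
    if n_missing:
        logger.warning("%d site/sample betas undefined (zero total intensity)", n_missing)
    return BetaMatrix(pd.DataFrame(beta, index=M.index, columns=M.columns))


@dataclass
class QcReport:
    """Per-sample QC outcome: failing-site fraction and pass flag."""

    samples: pd.DataFrame  # index sample; columns fail_frac, passed
    detection_threshold: float
    min_beads: int
    max_fail_frac: float


def sample_qc(
    raw: IntensityTable,
    detection_threshold: float = 0.05,
    min_beads: int = 5,
    max_fail_frac: float = 0.05,
) -> QcReport:
    """Flag samples with too many unreliable sites.

    A site fails for a sample when its detection p-value exceeds the
    threshold (i.e. the signal is not distinguishable from background)
    or it is measured by fewer than ``min_beads`` beads; a sample passes
    when its failing fraction is strictly below ``max_fail_frac``.
    Missing detection or bead fields count as failures.
    """
    df = raw.data
    dp = df["detection_p"].to_numpy(float)
    nb = df["n_beads"].to_numpy(float)
    fail = (dp > detection_threshold) | (nb < min_beads) | np.isnan(dp) | np.isnan(nb)
    frac = pd.Series(fail, index=df["sample"].to_numpy()).groupby(level=0).mean()
    report = pd.DataFrame({"fail_frac": frac, "passed": frac < max_fail_frac})
    report.index.name = "sample"
    return QcReport(report, detection_threshold, min_beads, max_fail_frac)


def batch_effect_check(beta: BetaMatrix, batch_labels: pd.Series) -> dict:
    """Test whether samples from the same batch have more similar profiles.

    Computes all pairwise Pearson correlations between sample beta
    profiles and compares the within-batch pair correlations against all
    pair correlations with a two-sided Wilcoxon rank-sum test; a small P
    indicates a batch effect.
    """
    labels = batch_labels.reindex(beta.sample_ids)
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 2).all():
        raise ValidationError("need at least two batches with two or more samples")
    vals = beta.values.to_numpy(float)
    corr = np.corrcoef(vals.T)
    n = corr.shape[0]
    iu = np.triu_indices(n, k=1)
    all_pairs = corr[iu]
    same = (labels.to_numpy()[iu[0]] == labels.to_numpy()[iu[1]])
    within = all_pairs[same]
    if within.size == 0:
        raise ValidationError("no within-batch sample pairs")
    stat, p = stats.mannwhitneyu(within, all_pairs, alternative="two-sided")
    return {
        "p_value": float(p),
        "statistic": float(stat),
        "median_within": float(np.median(within)),
        "median_all": float(np.median(all_pairs)),
        "n_within_pairs": int(within.size),
        "n_pairs": int(all_pairs.size),
    }


def replicate_concordance(
    beta: BetaMatrix, replicate_pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson r and r^2 per technical replicate pair across all sites."""
    rows = []
    for a, b in replicate_pairs:
        for s in (a, b):
            if s not in beta.sample_ids:
                raise ValidationError(f"replicate sample {s!r} not in beta matrix")
        x = beta.values[a].to_numpy(float)
        y = beta.values[b].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"sample_a": a, "sample_b": b, "r": r, "r2": r * r})
    return pd.DataFrame(rows)
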