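"""Overlap statistics between mSNP catalogs.

Catalogs are compared as sets of CpG sites (the unit the analyses share:
"sites associated with an mSNP"), against a declared universe of tested
sites. The chance baseline follows random-set logic: a random catalog of
|A| sites drawn from the universe is expected to contain a fraction
|B|/|universe| of the other catalog, and the tail probability of the
observed intersection is hypergeometric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

from scipy import stats

from .types import ValidationError

__all__ = ["OverlapResult", "compare_catalogs"]


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_intersection: int
    n_universe: int
    observed_fraction: float  # of A found in B
    expected_fraction: float  # |B| / universe
    fold_enrichment: float
    p_value: float  # hypergeometric tail P(X >= observed)
    shared_fraction_union: float  # intersection / union before exclusions
    shared_fraction_union_post_exclusion: float
    n_excluded_a: int = 0
    n_excluded_b: int = 0


def compare_catalogs(
    catalog_a: Collection[str],
    catalog_b: Collection[str],
    universe: Collection[str],
    exclusions: Collection[str] = (),
) -> OverlapResult:
    """Overlap of two CpG-site catalogs with a random-draw baseline.

    ``exclusions`` (e.g. sites whose probe overlaps a variant in the
    other population) are removed from both catalogs before counting,
    but the union-based shared fraction is reported both ways since
    published overlap figures differ in which denominator they use.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    a0 = set(catalog_a) & uni
    b0 = set(catalog_b) & uni
    excl = set(exclusions)
    a = a0 - excl
    b = b0 - excl
    inter = a & b
    union0 = a0 | b0
    union = a | b

    expected = len(b) / len(uni)
    observed = len(inter) / len(a) if a else 0.0
    fold = observed / expected if expected > 0 else float("nan")
    # P(X >= |inter|) drawing |A| sites from a universe containing |B| marked
    p = float(stats.hypergeom.sf(len(inter) - 1, len(uni), len(b), len(a)))
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_intersection=len(inter),
        n_universe=len(uni),
        observed_fraction=observed,
        expected_fraction=expected,
        fold_enrichment=fold,
        p_value=p,
        shared_fraction_union=len(inter) / len(union0) if union0 else 0.0,
        shared_fraction_union_post_exclusion=(
            len(inter) / len(union) if union else 0.0
        ),
        n_excluded_a=len(a0 & excl),
        n_excluded_b=len(b0 & excl),
    )
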