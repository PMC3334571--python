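"""End-to-end orchestration: simulate/load -> test -> map -> summarize.

Every stage is a pure function of (inputs, config, seed); the pipeline
wires them together, writes per-stage TSVs and a JSON summary, and logs
enough (seed, config hash, version) to reproduce a run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .heritability import estimate_h2, estimate_heritable_count
from .io_core import read_dataset, write_bundle, write_results
from .msnp import (
    attribute_population_difference,
    estimate_msnp_fdr,
    flag_probe_overlaps,
    scan_local_associations,
    test_population_specificity,
)
from .overlap import compare_catalogs
from .popdiff import permutation_fdr, test_population_differences
from .simdata import SimConfig, simulate_cohort
from .types import Dataset, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and knobs for a full pipeline run.

    Defaults mirror the analysis conventions this pipeline implements:
    hit threshold |r| > 0.6 within 100 kb at MAC >= 5, heritable tier at
    h2 > 0.2, specificity at P < 0.005, population differences at
    P < 0.01 and P < 0.001, and at least 1,000 randomizations for FDRs.
    """

    data_dir: str | None = None
    out_dir: str = "results"
    simulate: bool = False
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    p_thresholds: tuple[float, ...] = (0.01, 0.001)
    attribution_p: float = 0.001
    r_min: float = 0.6
    window_bp: int = 100_000
    mac_min: int = 5
    h2_cut: float = 0.2
    specificity_p: float = 0.005
    fdr_reps: int = 1000
    scheme: str = "trio"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.r_min <= 1.0:
            raise ValidationError(f"r_min must be in (0,1], got {self.r_min}")
        for p in (*self.p_thresholds, self.attribution_p, self.specificity_p):
            if not 0.0 < p < 1.0:
                raise ValidationError(f"P threshold must be in (0,1), got {p}")
        if self.window_bp <= 0:
            raise ValidationError("window_bp must be positive")
        if self.mac_min < 0:
            raise ValidationError("mac_min must be non-negative")
        if self.fdr_reps < 1:
            raise ValidationError("fdr_reps must be >= 1")
        if self.scheme not in ("trio", "individual"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        if not -1.0 <= self.h2_cut <= 1.0:
            raise ValidationError("h2_cut must be in [-1,1]")
        if self.data_dir is None and not self.simulate:
            raise ValidationError("either data_dir or simulate is required")

    def config_hash(self) -> str:
        # hash only the scientific parameters, not filesystem locations
        d = dataclasses.asdict(self)
        d.pop("data_dir", None)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_pipeline(config: PipelineConfig, dataset: Dataset | None = None) -> dict:
    """Run every stage and write per-stage tables plus a JSON summary.

    Returns the summary dictionary. A pre-loaded ``dataset`` skips I/O
    (useful for tests); otherwise data are simulated or read from
    ``config.data_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if dataset is None:
            if config.simulate:
                sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
                dataset = simulate_cohort(sim_cfg)
                write_bundle(dataset, out / "simulated_data")
            else:
                dataset = read_dataset(config.data_dir)
        pops = dataset.pedigree.populations

        stage = "popdiff"
        diff = test_population_differences(dataset.beta, dataset.pedigree)
        write_results(diff.reset_index(), out / "population_differences.tsv")
        popdiff_summary = {
            "n_sites": int(len(diff)),
            "counts": {
                str(p): int((diff["p_value"] < p).sum()) for p in config.p_thresholds
            },
            "n_absdiff_gt_05": int(diff["absdiff_gt_05"].sum()),
            "n_absdiff_gt_10": int(diff["absdiff_gt_10"].sum()),
            "fdr": {},
        }
        for p in config.p_thresholds:
            f = permutation_fdr(
                dataset.beta,
                dataset.pedigree,
                threshold=p,
                R=config.fdr_reps,
                scheme=config.scheme,
                seed=config.seed,
            )
            popdiff_summary["fdr"][str(p)] = {
                "observed": f.observed_count,
                "mean_null": f.mean_null_count,
                "fdr": f.fdr,
            }

        stage = "heritability"
        h2_by_pop = {}
        herit_summary = {}
        for pop in pops:
            est = estimate_h2(dataset.beta, dataset.pedigree, pop)
            h2_by_pop[pop] = est
            write_results(est.reset_index(), out / f"heritability_{pop}.tsv")
            count = estimate_heritable_count(
                est,
                dataset.beta,
                dataset.pedigree,
                R=config.fdr_reps,
                seed=config.seed,
            )
            herit_summary[pop] = {
                "heritable_count": count.count_estimate,
                "r": count.r,
            }

        stage = "msnp"
        catalogs = {}
        msnp_summary = {}
        for pop in pops:
            excluded = flag_probe_overlaps(dataset.manifest, dataset.variants, pop)
            cat = scan_local_associations(
                dataset.beta,
                dataset.genotypes,
                dataset.pedigree,
                pop,
                window_bp=config.window_bp,
                mac_min=config.mac_min,
                r_min=config.r_min,
                excluded_probes=excluded,
            )
            catalogs[pop] = cat
            write_results(cat.table.reset_index(), out / f"msnp_catalog_{pop}.tsv")
            fdr = estimate_msnp_fdr(
                cat,
                dataset.beta,
                dataset.genotypes,
                dataset.pedigree,
                R=config.fdr_reps,
                scheme=config.scheme,
                seed=config.seed,
                h2_estimates=h2_by_pop[pop],
                h2_cut=config.h2_cut,
            )
            msnp_summary[pop] = {
                "n_excluded_probes": len(excluded),
                "n_hits": int(len(cat.hits)),
                "fdr": {t: fdr[t] for t in ("all", "heritable") if t in fdr},
            }

        stage = "specificity"
        spec = test_population_specificity(
            catalogs[pops[0]], catalogs[pops[1]], p_threshold=config.specificity_p
        )
        write_results(spec.reset_index(), out / "specificity.tsv")
        tested = spec["specific"].notna()
        spec_summary = {
            "n_compared": int(tested.sum()),
            "n_specific": int(spec.loc[tested, "specific"].sum()),
        }

        stage = "attribution"
        diff_sites = diff.index[diff["p_value"] < config.attribution_p].tolist()
        attr_summary = {"n_diff_sites": len(diff_sites)}
        if diff_sites:
            attr = attribute_population_difference(
                dataset.beta,
                dataset.genotypes,
                dataset.pedigree,
                diff_sites,
                window_bp=config.window_bp,
                mac_min=config.mac_min,
            )
            write_results(attr.reset_index(), out / "attribution.tsv")
            n_snp = int((attr["classification"] == "snp_stronger").sum())
            attr_summary |= {
                "n_snp_stronger": n_snp,
                "frac_snp_stronger": n_snp / len(attr),
            }

        stage = "overlap"
        universe = set(dataset.beta.site_ids)
        excl = (
            (set(catalogs[pops[0]].hits.index) & catalogs[pops[1]].excluded_probes)
            | (set(catalogs[pops[1]].hits.index) & catalogs[pops[0]].excluded_probes)
        )
        ov = compare_catalogs(
            set(catalogs[pops[0]].hits.index),
            set(catalogs[pops[1]].hits.index),
            universe,
            exclusions=excl,
        )
        overlap_summary = dataclasses.asdict(ov)

    except ValidationError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = _jsonable(
        {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "populations": pops,
            "popdiff": popdiff_summary,
            "heritability": herit_summary,
            "msnp": msnp_summary,
            "specificity": spec_summary,
            "attribution": attr_summary,
            "overlap": overlap_summary,
        }
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: seed=%d hash=%s", config.seed, config.config_hash())
    return summary
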