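"""Overlap of mSNP catalogs: between populations and with an external tissue.

Counts shared mSNP-target CpGs between the two populations' catalogs
(excluding sites whose probe overlaps a variant in the other population)
and against a simulated external-tissue catalog that shares 40% of one
population's targets, with random-draw baselines and hypergeometric
tail probabilities.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from methpop.io_core import read_dataset
from methpop.msnp import flag_probe_overlaps, scan_local_associations
from methpop.overlap import compare_catalogs
from methpop.simdata import make_external_catalog


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    ds = read_dataset(args.out / "cohort")
    pops = ds.pedigree.populations
    catalogs, excluded = {}, {}
    for pop in pops:
        excluded[pop] = flag_probe_overlaps(ds.manifest, ds.variants, pop)
        catalogs[pop] = scan_local_associations(
            ds.beta, ds.genotypes, ds.pedigree, pop, excluded_probes=excluded[pop]
        )
    universe = set(ds.beta.site_ids)
    hits_a = set(catalogs[pops[0]].hits.index)
    hits_b = set(catalogs[pops[1]].hits.index)
    cross_excl = (hits_a & excluded[pops[1]]) | (hits_b & excluded[pops[0]])
    between = compare_catalogs(hits_a, hits_b, universe, exclusions=cross_excl)

    external = make_external_catalog(ds, share_frac=0.4, seed=args.seed)
    vs_external = compare_catalogs(hits_a, external, universe)

    report = {
        "between_populations": dataclasses.asdict(between),
        "vs_external_catalog": dataclasses.asdict(vs_external),
    }
    (args.out / "07_catalog_overlap.json").write_text(json.dumps(report, indent=1))
    print(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
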