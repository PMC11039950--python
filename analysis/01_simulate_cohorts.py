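"""Generate the synthetic study inputs: ten taxon GWAS and one aneurysm GWAS.

Emulates the two-sample design: taxon-abundance summary statistics for ten
taxa (one truly protective, OR 0.62 per SD; nine null) and a single binary
aneurysm GWAS panel holding the outcome effects for every instrument.  Writes
plain TSVs that the rest of the analysis scripts (and the CLI) consume.
"""

import dataclasses
import pathlib
import sys

import numpy as np

from gutmr import (
    SummaryStatistics,
    SyntheticConfig,
    simulate_pair,
    write_manifest,
    write_summary_stats,
)

SEED = 20240410
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence([SEED, 0]).generate_state(10) % (2 ** 31)
    merged = {}
    taxa = []
    for i in range(10):
        beta0 = float(np.log(0.62)) if i == 0 else 0.0
        name = "phylum_protective" if i == 0 else f"taxon_null{i:02d}"
        exposure, outcome, truth = simulate_pair(
            SyntheticConfig(J=14, beta0=beta0, seed=int(seeds[i]))
        )
        exposure.trait_id = name
        for k in range(len(exposure.records)):
            new_id = f"rs{1000 * (i + 1) + k}"
            exposure.records[k] = dataclasses.replace(exposure.records[k], snp_id=new_id)
            merged[new_id] = dataclasses.replace(outcome.records[k], snp_id=new_id)
        write_summary_stats(exposure, OUT / f"exposure_{name}.tsv")
        taxa.append((name, beta0, len(exposure)))
    outcome_all = SummaryStatistics(
        trait_id="synthetic_aaa", trait_type="binary", records=list(merged.values())
    )
    write_summary_stats(outcome_all, OUT / "outcome_synthetic_aaa.tsv")
    write_manifest(OUT / "manifest.json", seed=SEED,
                   taxa=[{"trait": t, "beta0": b, "n_snp": n} for t, b, n in taxa],
                   outcome_variants=len(outcome_all))
    print(f"wrote {len(taxa)} taxon GWAS and 1 outcome panel "
          f"({len(outcome_all)} variants) under {OUT}")
    print("true effects: phylum_protective beta0 = ln(0.62) = -0.478; all others 0")


if __name__ == "__main__":
    sys.exit(main())
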