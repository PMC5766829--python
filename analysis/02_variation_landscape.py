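#!/usr/bin/env python
"""Per-receptor variation landscape and the trio-based de novo missense rate.

Summarizes the missense table into the per-receptor landscape (counts,
density, rare/common split at MAF 1e-3, per-category z-scores) and reports
the de novo rate implied by published trio counts: 1,762 control trios with
6 offspring carrying a new missense variant in a drug-target receptor.
"""

from pathlib import Path

import pandas as pd

from gpcrvar.population import TrioSummary, de_novo_rate
from gpcrvar.variants import build_receptor_landscape, read_missense_tsv

FIXTURE = Path("results/fixture")
OUT = Path("results")


def main() -> None:
    receptors = pd.read_csv(FIXTURE / "receptors.tsv", sep="\t")
    lengths = dict(zip(receptors["receptor"], receptors["length"]))
    variants = read_missense_tsv(FIXTURE / "missense_variants.tsv")
    genotypes = pd.read_csv(FIXTURE / "genotypes.tsv", sep="\t", index_col=0)

    landscape = build_receptor_landscape(
        variants, [], [], lengths, cohort_size=len(genotypes)
    )
    out = OUT / "landscape.tsv"
    landscape.to_csv(out, sep="\t", index=False)
    print(f"landscape for {len(landscape)} receptors -> {out}")
    print(f"  mean MVs/receptor: {landscape['n_mv'].mean():.1f} "
          f"(rare {landscape['n_rare'].mean():.1f}, common {landscape['n_common'].mean():.2f})")
    print(f"  mean MV density: {landscape['mv_density'].mean():.3f} per residue")

    rate, label = de_novo_rate(
        TrioSummary(n_trios=1762, n_offspring_with_denovo_mv_in_target=6)
    )
    print(f"de novo missense rate in drug targets: {rate:.5f} per newborn ({label})")


if __name__ == "__main__":
    main()
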