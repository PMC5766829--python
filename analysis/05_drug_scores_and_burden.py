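#!/usr/bin/env python
"""Drug prioritization scores and the prescription-cost burden estimate.

S_polymorphic sums, over a drug's targets, the fraction of known functional
sites carrying a missense variant; the burden multiplies each drug's average
yearly prescription cost (window 2013-2016, partial boundary years excluded)
by the fraction of individuals affected under each criterion.
"""

from pathlib import Path

import pandas as pd

from gpcrvar.drugs import (
    burden_table,
    rank_drugs_by_polymorphic_score,
    read_drug_target_tsv,
    read_prescriptions_csv,
)
from gpcrvar.numbering import read_segment_maps
from gpcrvar.population import CRITERIA, GenotypeMatrix, fraction_sites_polymorphic
from gpcrvar.sites import read_annotations_tsv
from gpcrvar.variants import read_missense_tsv

FIXTURE = Path("results/fixture")
OUT = Path("results")


def main() -> None:
    receptors = pd.read_csv(FIXTURE / "receptors.tsv", sep="\t")
    classes = dict(zip(receptors["receptor"], receptors["receptor_class"]))
    maps = read_segment_maps(FIXTURE / "segment_maps.tsv", receptor_classes=classes)
    variants = read_missense_tsv(FIXTURE / "missense_variants.tsv")
    annotations = read_annotations_tsv(FIXTURE / "functional_sites.tsv", receptor_classes=classes)
    target_map = read_drug_target_tsv(FIXTURE / "drug_targets.tsv")
    ledger = read_prescriptions_csv(FIXTURE / "prescriptions.csv")
    genotypes = GenotypeMatrix.read_tsv(FIXTURE / "genotypes.tsv")
    genotypes.site_receptors = {s: s.split(":", 1)[0] for s in genotypes.sites}
    flags_df = pd.read_csv(OUT / "variant_sites.tsv", sep="\t")
    site_flags = {
        r.site_id: (bool(r.known_functional), bool(r.putative_functional))
        for r in flags_df.itertuples(index=False)
    }

    by_rec: dict[str, list] = {}
    for v in variants:
        by_rec.setdefault(v.receptor, []).append(v)
    ann_by_rec: dict[str, list] = {}
    for a in annotations:
        ann_by_rec.setdefault(a.receptor, []).append(a)
    poly = {
        rec: fraction_sites_polymorphic(by_rec.get(rec, []), ann_by_rec.get(rec, []), sm)
        for rec, sm in maps.items()
    }

    scores = rank_drugs_by_polymorphic_score(target_map, poly)
    out = OUT / "drug_scores.tsv"
    scores.to_csv(out, sep="\t", index=False)
    top = scores.iloc[0]
    print(f"drug scores for {len(scores)} drugs -> {out}")
    print(f"  most variable: {top['drug']} (S_polymorphic = {top['s_polymorphic']:.2f}, "
          f"{int(top['n_targets'])} targets)")

    burden = burden_table(target_map, ledger, genotypes, site_flags, criteria=list(CRITERIA))
    out = OUT / "burden.tsv"
    burden.to_csv(out, sep="\t", index=False)
    lo = burden["burden_hom_known"].sum() / 1e6
    hi = burden["burden_any_known_or_putative"].sum() / 1e6
    print(f"burden table -> {out}")
    print(f"  panel burden range: {lo:.1f}M (criterion i) to {hi:.1f}M GBP/yr (criterion iv)")


if __name__ == "__main__":
    main()
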