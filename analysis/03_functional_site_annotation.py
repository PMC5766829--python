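#!/usr/bin/env python
"""Classify every missense variant against the functional-site annotation.

Each variant receives the set of known-site categories containing its
position (ligand binding, effector interfaces, micro-switches, sodium
pocket, PTM) and a putative-impact flag from the SIFT <= 0.05 / PolyPhen >
0.1 rule.  Also prints the sizes of the built-in class A registries.
"""

from pathlib import Path

import pandas as pd

from gpcrvar.numbering import read_segment_maps
from gpcrvar.sites import annotate_variant_sites, builtin_class_a_registries, read_annotations_tsv
from gpcrvar.variants import read_missense_tsv

FIXTURE = Path("results/fixture")
OUT = Path("results")


def main() -> None:
    receptors = pd.read_csv(FIXTURE / "receptors.tsv", sep="\t")
    classes = dict(zip(receptors["receptor"], receptors["receptor_class"]))
    maps = read_segment_maps(FIXTURE / "segment_maps.tsv", receptor_classes=classes)
    variants = read_missense_tsv(FIXTURE / "missense_variants.tsv")
    annotations = read_annotations_tsv(FIXTURE / "functional_sites.tsv", receptor_classes=classes)

    micro, sodium = builtin_class_a_registries("A")
    print(f"class A registries: {len(micro)} micro-switches, {len(sodium)} sodium-pocket positions")

    classified = annotate_variant_sites(variants, annotations, maps)
    out = OUT / "variant_sites.tsv"
    classified.sort_values(["receptor", "residue_index", "site_id"]).to_csv(
        out, sep="\t", index=False
    )
    n_known = int(classified["known_functional"].sum())
    n_put = int(classified["putative_functional"].sum())
    print(f"{len(classified)} variants classified -> {out}")
    print(f"  {n_known} ({100 * n_known / len(classified):.1f}%) in known functional sites")
    print(f"  {n_put} ({100 * n_put / len(classified):.1f}%) with putative impact (SIFT/PolyPhen)")


if __name__ == "__main__":
    main()
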