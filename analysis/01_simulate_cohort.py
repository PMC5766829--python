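#!/usr/bin/env python
"""Generate the synthetic study: receptor panel, variants, cohort, drugs, ledger.

Emits a complete fixture directory under results/fixture/ in the same table
dialects the ingest modules read.  All later analysis steps start from these
files.  The defaults are the study conditions: 30 receptors, a 2,504-
individual cohort, exome-scale allele numbers, and a rare-dominated
allele-frequency spectrum.
"""

from pathlib import Path

from gpcrvar.simulate import SimulationConfig, simulate_study, write_fixture_dir

OUT = Path("results/fixture")


def main() -> None:
    config = SimulationConfig(seed=0)
    study = simulate_study(config)
    paths = write_fixture_dir(study, OUT)
    print(f"receptor panel: {config.n_receptors} receptors, "
          f"{len(study.variants)} missense variants, "
          f"{study.genotypes.n_individuals} genotyped individuals")
    print(f"drug map: {len(study.target_map.drugs)} drugs, "
          f"{len(study.prescriptions)} monthly ledger rows")
    for name, p in sorted(paths.items()):
        print(f"  wrote {name}: {p}")


if __name__ == "__main__":
    main()
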