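import numpy as np
import pytest

from gpcrvar.numbering import GenericPosition, SegmentMap
from gpcrvar.simulate import SimulationConfig, simulate_study


def make_toy_segment_map(receptor: str = "R1", receptor_class: str = "A") -> SegmentMap:
    """Small hand-built receptor: 10-residue N-term, 7 x 5-residue TMs with
    x48..x52 generic numbers, 3-residue loops, 4-residue H8 (8x49..), 10-residue
    C-term; total length 67."""
    pieces = [
        ("N-term", 10),
        ("TM1", 5), ("ICL1", 3), ("TM2", 5), ("ECL1", 3), ("TM3", 5),
        ("ICL2", 3), ("TM4", 5), ("ECL2", 3), ("TM5", 5), ("ICL3", 3),
        ("TM6", 5), ("ECL3", 3), ("TM7", 5), ("H8", 4), ("C-term", 10),
    ]
    ranges, pos = {}, 0
    for seg, n in pieces:
        ranges[seg] = (pos + 1, pos + n)
        pos += n
    generic = {}
    for tm in range(1, 8):
        start, _ = ranges[f"TM{tm}"]
        for k in range(5):
            generic[start + k] = GenericPosition(str(tm), 48 + k, receptor_class=receptor_class)
    h8_start, _ = ranges["H8"]
    for k in range(4):
        generic[h8_start + k] = GenericPosition("8", 49 + k, receptor_class=receptor_class)
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=pos))
    return SegmentMap(
        receptor=receptor, length=pos, ranges=ranges,
        generic_positions=generic, sequence=seq, receptor_class=receptor_class,
    )


@pytest.fixture(scope="session")
def toy_segment_map() -> SegmentMap:
    return make_toy_segment_map()


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    cfg = SimulationConfig(
        seed=11, n_receptors=8, n_individuals=120, n_drugs=10,
        functional_site_fraction=0.2,
    )
    return simulate_study(cfg)
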