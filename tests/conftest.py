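import numpy as np
import pytest

from lethalmap.io_formats import (
    MarkerMap,
    Pedigree,
    PedigreeRecord,
    PhasedGenotypes,
)


def make_marker_map(n=6, chrom="8", spacing=1_000_000, alleles=("A", "B")):
    return MarkerMap(
        marker_ids=[f"M{j}" for j in range(n)],
        chroms=[chrom] * n,
        positions=np.arange(1, n + 1) * spacing,
        alleles=[alleles] * n,
    )


def make_population(hap_by_animal, parents=None, live=None):
    """Build (phased, pedigree) from {animal: (strand0, strand1)} allele
    strings; ``parents`` maps animal -> (sire, dam)."""
    parents = parents or {}
    live = live or {}
    animal_ids = list(hap_by_animal)
    n_markers = len(next(iter(hap_by_animal.values()))[0])
    haps = np.zeros((len(animal_ids), n_markers, 2), dtype=np.int8)
    for i, aid in enumerate(animal_ids):
        s0, s1 = hap_by_animal[aid]
        haps[i, :, 0] = [int(c) if c != "." else -1 for c in s0]
        haps[i, :, 1] = [int(c) if c != "." else -1 for c in s1]
    records = {}
    for aid in animal_ids:
        sire, dam = parents.get(aid, (None, None))
        records[aid] = PedigreeRecord(
            sire_id=sire, dam_id=dam, sex="U", is_live=live.get(aid, True)
        )
    return PhasedGenotypes(animal_ids, haps), Pedigree(records)


@pytest.fixture(scope="session")
def sim_population():
    """One simulated population shared by read-only tests."""
    from lethalmap.simulate import SimulationConfig, simulate_population

    return simulate_population(SimulationConfig(seed=1))
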