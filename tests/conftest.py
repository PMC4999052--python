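import numpy as np
import pytest

import radosage as rd
from radosage.types import GenotypeMatrix


def genotype_cohort(sim: rd.CohortSim, ploidy_map=None, **call_kwargs) -> GenotypeMatrix:
    """Run the dosage genotyper over a simulated cohort into a GenotypeMatrix."""
    if ploidy_map is None:
        ploidy_map = sim.truth.ploidy
    loci = [ld.locus_id for ld in sim.truth.locus_defs]
    gm = GenotypeMatrix(list(sim.counts), loci, ploidy_map)
    for s, recs in sim.counts.items():
        for call in rd.genotype_sample(recs, ploidy_map[s], **call_kwargs):
            if call.is_called:
                gm.set_call(s, call.locus_id, call.allele_dosages)
    return gm


@pytest.fixture(scope="session")
def small_cohort() -> rd.CohortSim:
    """3 samples x 40 loci, all ploidies, used by io and filter tests."""
    cfg = rd.SimConfig(n_samples={2: 1, 3: 1, 4: 1}, n_loci=40, seed=2024)
    return rd.simulate_cohort(cfg)


@pytest.fixture()
def toy_matrix() -> GenotypeMatrix:
    gm = GenotypeMatrix(
        ["d1", "d2", "t1"],
        ["ctg1:100", "ctg1:200", "ctg1:300"],
        {"d1": 2, "d2": 2, "t1": 4},
    )
    gm.set_call("d1", "ctg1:100", {"A": 1, "T": 1})
    gm.set_call("d2", "ctg1:100", {"A": 2})
    gm.set_call("t1", "ctg1:100", {"A": 3, "T": 1})
    gm.set_call("d1", "ctg1:200", {"C": 2})
    gm.set_call("t1", "ctg1:200", {"C": 4})
    gm.set_call("d2", "ctg1:300", {"G": 1, "-": 1})
    return gm
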