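import numpy as np
import pytest

import metaboqtl as mq


@pytest.fixture(scope="session")
def default_panel():
    """Small structured panel with planted QTLs shared by several tests."""
    cfg = mq.SimulationConfig(
        n_strains=100,
        n_snps=600,
        planted_qtls=[(0, 100, 0.3), (1, 300, 0.5), (2, 500, 0.7)],
        replicate_strains=[(0, 5), (1, 2), (2, 2)],
        seed=7,
    )
    G = mq.simulate_genotypes(cfg)
    met, truth = mq.simulate_metabolome(G, cfg)
    z = mq.preprocess_pipeline(met)
    K = mq.compute_ibs_kinship(G)
    return {"config": cfg, "G": G, "met": met, "truth": truth, "z": z, "K": K}


def aligned_phenotype(z, G, variable):
    """Phenotype column of the standardized table, ordered by G.strains."""
    idx = {s: i for i, s in enumerate(z.strain_ids)}
    j = z.variables.index(variable)
    return np.array([z.zvalues[idx[s], j] for s in G.strains])
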