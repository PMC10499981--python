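import numpy as np
import pandas as pd
import pytest

from ucbranch import quant, synthetic


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic cohort shared across tests."""
    cfg = synthetic.CohortConfig(
        seed=7, n_per_class=6, n_proteins=120, n_phospho=60, n_ddr_markers=10
    )
    return synthetic.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_protein_matrix(small_bundle):
    """Filtered, imputed log2 protein matrix from the small bundle."""
    n_obs = {
        p: quant.count_observable_peptides(s) for p, s in small_bundle.sequences.items()
    }
    ibaq, _ = quant.ibaq_matrix(small_bundle.peptides, n_obs)
    mat = quant.filter_and_impute(quant.fot_matrix(ibaq))
    values = mat.values.reindex(small_bundle.cohort.index).fillna(np.log2(quant.FOT_FLOOR))
    mask = mat.mask.reindex(small_bundle.cohort.index).fillna(True)
    return quant.AbundanceMatrix(values=values, scale="log2FOT", mask=mask)


def truth_fot_matrix(bundle):
    """FOT-scale matrix built directly from true log2 abundances (no dropout)."""
    linear = np.power(2.0, bundle.protein_truth.to_numpy())
    fot = linear / linear.sum(axis=1, keepdims=True) * quant.FOT_SCALE
    values = pd.DataFrame(
        np.maximum(fot, quant.FOT_FLOOR),
        index=bundle.protein_truth.index,
        columns=bundle.protein_truth.columns,
    )
    return quant.AbundanceMatrix(values=values, scale="FOT")
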