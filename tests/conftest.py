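import pytest

from pancsel import (
    LibraryDesign,
    SelectionSimParams,
    default_ground_truth,
    default_input_abundance,
)
from pancsel.sim_selection import run_selection


@pytest.fixture(scope="session")
def design():
    return LibraryDesign()


@pytest.fixture(scope="session")
def small_design():
    """One mutagenized codon: 21 protein variants, fast to enumerate."""
    return LibraryDesign(
        n_positions=1,
        position_labels=(331,),
        wildtype_protein="D",
    )


@pytest.fixture(scope="session")
def small_library_sim(design):
    """A 500-variant simulated arm with known ground truth (shared, read-only)."""
    import numpy as np

    truth = default_ground_truth(design, seed=11)
    space = sorted(truth.rho_map(1.0))
    rng = np.random.default_rng(14)
    variants = sorted(rng.choice(space, 500, replace=False))
    if design.wildtype_protein not in variants:
        variants[0] = design.wildtype_protein
    abundance = default_input_abundance(design, seed=12, variants=variants)
    params = SelectionSimParams(
        design=design,
        propagation_factor={v: truth.rho(v) for v in variants},
        input_abundance=abundance,
        read_depth=1_000_000,
        seed=13,
    )
    pools, table, emission = run_selection(params)
    return {
        "truth": truth,
        "params": params,
        "pools": pools,
        "table": table,
        "emission": emission,
    }
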