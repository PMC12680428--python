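import numpy as np
import pandas as pd
import pytest

from landgea.genotypes import apply_qc_filters, impute_within_population
from landgea.simulate import LandscapePanelSpec, simulate_landscape_panel


@pytest.fixture(scope="session")
def default_panel():
    """Default clinal panel: 39 pops, 2000 neutral + 20 adaptive loci."""
    return simulate_landscape_panel(LandscapePanelSpec(seed=0))


@pytest.fixture(scope="session")
def qc_default(default_panel):
    """QC'd genotypes with imputed dosages and population frequencies."""
    G, report = apply_qc_filters(default_panel.genotypes)
    X = impute_within_population(G)
    pops = np.asarray(G.population_labels)
    freq = pd.DataFrame(
        [X[pops == p].mean(axis=0) / 2.0 for p in G.populations],
        index=G.populations,
        columns=G.locus_ids,
    )
    return G, X, freq


@pytest.fixture(scope="session")
def neutral_panel():
    """Panel with no adaptive loci (pure Balding-Nichols background)."""
    return simulate_landscape_panel(LandscapePanelSpec(seed=11, n_adaptive=0))
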