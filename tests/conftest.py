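import numpy as np
import pytest

import nanocascade as nc
from nanocascade.enzymes import EnzymeDef, MMParams


@pytest.fixture(scope="session")
def enzyme_table():
    return nc.default_enzyme_table()


@pytest.fixture(scope="session")
def spec_7e(enzyme_table):
    return nc.build_cascade("7E", enzyme_table)


@pytest.fixture(scope="session")
def cond_7e():
    return nc.assay_conditions("7E")


@pytest.fixture(scope="session")
def fig_concs():
    """Enzyme concentrations (uM) of the fixed-enzyme 7E assay."""
    return dict(nc.FIG_RATIO_CONCS_7E)


@pytest.fixture(scope="session")
def sim_7e(spec_7e, cond_7e, fig_concs):
    """The reference free-enzyme 7E simulation, shared across tests."""
    return nc.simulate(spec_7e, cond_7e, fig_concs)


def toy_enzyme(abbrev: str, kcat: float, km: float, subunits: int = 1) -> EnzymeDef:
    """Minimal single-step enzyme for constructed cascades."""
    return EnzymeDef(
        name=abbrev, abbreviation=abbrev, subunits=subunits, monomer_mw=50.0,
        params_free=MMParams(kcat=kcat, km=km),
        params_bound=MMParams(kcat=kcat, km=km),
    )


def chain_spec(enzymes, species=None, name="toy") -> nc.CascadeSpec:
    """Linear cascade S0 -E1-> S1 -E2-> ... -> Sn monitoring the end product."""
    n = len(enzymes)
    if species is None:
        species = [f"S{i}" for i in range(n + 1)]
    steps = [
        nc.ReactionStep(
            enzyme=e,
            substrate_stoich={species[i]: 1},
            product_stoich={species[i + 1]: 1},
            limiting_species=species[i],
        )
        for i, e in enumerate(enzymes)
    ]
    registry = {s: "intermediate" for s in species}
    registry[species[0]] = "substrate"
    registry[species[-1]] = "product"
    return nc.CascadeSpec(
        name=name, steps=steps, species_registry=registry,
        input_substrate=species[0], monitored_species=species[-1],
        monitored_sign=+1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
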