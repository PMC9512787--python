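import numpy as np
import pytest

from augmintools.structio import AtomRecord, Selection, Structure
from augmintools.synthetic import BundleSpec, default_chain_map, make_bundle

SMALL_BUNDLE = BundleSpec(n_chains=4, residues_per_chain=60)


@pytest.fixture(scope="session")
def small_bundle():
    """A 4-chain, 60-residue Cα helix bundle (deterministic)."""
    return make_bundle(SMALL_BUNDLE)


@pytest.fixture(scope="session")
def small_chain_map():
    return default_chain_map(SMALL_BUNDLE.n_chains)


@pytest.fixture
def full_selection():
    """All residues of the small bundle, Cα only."""
    return Selection(
        tuple(
            (f"S{i + 1}", 1, SMALL_BUNDLE.residues_per_chain)
            for i in range(SMALL_BUNDLE.n_chains)
        )
    )


def line_structure(n_res=5, chain="A", start=1, spacing=3.8, res_name="ALA"):
    """Cα trace along x with a given residue numbering."""
    atoms = [
        AtomRecord(chain, start + i, "", res_name, "CA", "C", (i * spacing, 0.0, 0.0))
        for i in range(n_res)
    ]
    return Structure([atoms])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
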