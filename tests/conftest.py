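import pytest

import cbmscreen as cs


@pytest.fixture(scope="session")
def screen_dataset():
    """Synthetic 200-protein screen input with planted MMH/REF motifs."""
    return cs.gen_domain_dataset(n_proteins=200, mmh_fraction=0.25,
                                 ref_fraction=0.5,
                                 geometry_violator_fraction=0.2,
                                 seed=cs.DEFAULT_SEED)


@pytest.fixture(scope="session")
def screen_models(screen_dataset):
    """Cα-only PDB models consistent with the dataset's truth ledger."""
    return cs.gen_structures(screen_dataset, seed=cs.DEFAULT_SEED)


def make_domain(residues, protein_id="p", family="CBM2", start=1):
    return cs.DomainSequence(protein_id=protein_id, family=family,
                             start=start, end=start + len(residues) - 1,
                             residues=residues)
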