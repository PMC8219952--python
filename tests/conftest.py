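import numpy as np
import pytest

from tcrdockeval import make_reference, make_unbound
from tcrdockeval.correspondence import identity_correspondence
from tcrdockeval.synthetic import ToyCaseParams


@pytest.fixture(scope="session")
def ref_case():
    """One bound synthetic docking case shared across read-only tests."""
    return make_reference(ToyCaseParams(seed=0))


@pytest.fixture(scope="session")
def reference(ref_case):
    return ref_case.reference


@pytest.fixture(scope="session")
def ref_corr(reference):
    return identity_correspondence(reference)


@pytest.fixture(scope="session")
def full_case(ref_case):
    """The same case with noise-free unbound components attached."""
    case = ref_case
    if case.tcr_unbound is None:
        case.tcr_unbound, case.pmhc_unbound = make_unbound(case, 0.0, seed=11)
    return case


def brute_force_contacts(cx, group_a, group_b, cutoff):
    """O(n^2) all-pairs reference for residue contacts (heavy atoms, strict <)."""
    from tcrdockeval.correspondence import key_of

    res_by_key = {key_of(r): r for r in cx.residues()}
    pairs = set()
    for ka in group_a:
        for kb in group_b:
            ra, rb = res_by_key[ka], res_by_key[kb]
            for atom_a in ra.atoms:
                if atom_a.element in ("H", "D"):
                    continue
                for atom_b in rb.atoms:
                    if atom_b.element in ("H", "D"):
                        continue
                    if np.linalg.norm(atom_a.position - atom_b.position) < cutoff:
                        pairs.add((ka, kb))
    return pairs
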