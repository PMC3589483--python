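import numpy as np
import pytest

from oxohb.fragments import AtomRecord, Fragment, build_fragment


@pytest.fixture(scope="session")
def fragments():
    """All nine packaged fragments, built once."""
    kinds = ["glu", "pser2", "pser1", "ptyr2", "ptyr1", "styr",
             "arg", "lys", "amide"]
    return {k: build_fragment(k) for k in kinds}


def make_fragment(atom_specs, kind="TEST", net_charge=0, resname="UNK",
                  anchors=None):
    """Ad-hoc fragment for closed-form energy tests.

    atom_specs: iterable of (name, element, xyz, charge, sigma, epsilon).
    """
    atoms = [AtomRecord(n, e, np.asarray(p, float), q, s, eps)
             for (n, e, p, q, s, eps) in atom_specs]
    return Fragment(kind, atoms, net_charge, resname, anchors or {})
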