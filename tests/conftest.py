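import numpy as np
import pytest

from misfoldscan import synthgen
from misfoldscan.struct_io import CAStructure, build_native_contacts


@pytest.fixture(scope="session")
def helix_system():
    """30-residue ideal helix with its geometric contact map."""
    spec = synthgen.SyntheticSpec(recipe="helix", n_residues=30, seed=11)
    native, contacts = synthgen.make_structure(spec)
    return spec, native, contacts


@pytest.fixture(scope="session")
def loop_thread_system():
    """Loop-plus-thread chain: unentangled native, threaded (g=+1) variant."""
    spec = synthgen.SyntheticSpec(recipe="loop_thread", planted_g=1,
                                  n_residues=60, seed=3)
    native, contacts = synthgen.make_structure(spec)
    entangled = synthgen.make_entangled_structure(spec)
    return spec, native, contacts, entangled


@pytest.fixture()
def extended_chain():
    """Fully extended chain at 3.8 Å spacing (no geometric contacts)."""
    n = 25
    coords = np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)])
    return CAStructure(coords)


@pytest.fixture()
def two_strands():
    """Two antiparallel strands 5 Å apart, flagged synthetic (bond at turn)."""
    n = 8
    s1 = np.column_stack([np.zeros(n), 3.8 * np.arange(n), np.zeros(n)])
    s2 = np.column_stack([np.full(n, 5.0), 3.8 * np.arange(n)[::-1],
                          np.zeros(n)])
    return CAStructure(np.vstack([s1, s2]), synthetic_stretched=True)
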