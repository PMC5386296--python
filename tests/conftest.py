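from __future__ import annotations

import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


@pytest.fixture()
def toy_structure(tmp_path):
    """Factory: write toy-complex PDB text and parse it back."""
    from phosphoswitch import simulate, structures

    def build(filename="toy.pdb", **kwargs):
        path = tmp_path / filename
        path.write_text(simulate.make_toy_complex(**kwargs))
        return structures.read_structure(path)

    return build


@pytest.fixture()
def delta_matrix():
    """Full-alphabet matrix with hand-set phosphorylation deltas:
    Delta(S->pS | K) = +1.2 and Delta(S->pS | E) = -2.0."""
    import numpy as np

    from phosphoswitch.potentials import PairPotentialMatrix
    from phosphoswitch.residues import ALPHABET

    n = len(ALPHABET)
    scores = np.zeros((n, n))
    m = PairPotentialMatrix(ALPHABET, scores)

    def put(a, b, v):
        i, j = m.index(a), m.index(b)
        scores[i, j] = scores[j, i] = v

    put("S", "K", -0.2)
    put("pS", "K", 1.0)
    put("S", "E", -0.2)
    put("pS", "E", -2.2)
    return PairPotentialMatrix(ALPHABET, scores)
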