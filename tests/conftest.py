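import numpy as np
import pytest

import bindkin as bk
from bindkin.potentials import PotentialSpec


@pytest.fixture(scope="session")
def two_state_net():
    """Q = [[-1, 1], [2, -2]] 1/ns: pi = (2/3, 1/3), MFPT(0->1) = 1 ns."""
    return bk.KineticNetwork([[-1.0, 1.0], [2.0, -2.0]])


@pytest.fixture(scope="session")
def benchmark_net():
    return bk.benchmark_network()


@pytest.fixture(scope="session")
def double_well():
    """8 kT barrier at kT = 0.6 kcal/mol."""
    return PotentialSpec("double_well", {"barrier": 4.8, "half_width": 1.0})


@pytest.fixture(scope="session")
def random_reversible_model():
    """A 6-state reversible transition model from symmetric random counts."""
    rng = np.random.default_rng(42)
    C = rng.integers(1, 80, size=(6, 6)).astype(float)
    C = C + C.T
    return bk.estimate_reversible(C, lag_time=1.0)


TOY_PDB = """\
REMARK synthetic three-residue toy structure with a benzene-like ligand
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  H   ALA A   1       2.000   2.000   1.000  1.00  0.00           H
ATOM      5  CA  VAL A   2       4.000   0.000   0.000  1.00  0.00           C
ATOM      6  O   VAL A   2       4.500   1.200   0.500  1.00  0.00           O
HETATM    7  C1  BNZ A  90      10.000  10.000  10.000  1.00  0.00           C
HETATM    8  C2  BNZ A  90      11.400  10.000  10.000  1.00  0.00           C
HETATM    9  C3  BNZ A  90      12.100  11.210  10.000  1.00  0.00           C
HETATM   10  C4  BNZ A  90      11.400  12.420  10.000  1.00  0.00           C
HETATM   11  C5  BNZ A  90      10.000  12.420  10.000  1.00  0.00           C
HETATM   12  C6  BNZ A  90       9.300  11.210  10.000  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def toy_pdb_text():
    return TOY_PDB


@pytest.fixture(scope="session")
def small_pipeline_models():
    """A modest benchmark run shared by invariant-style tests:
    5 trajectories x 8000 frames, 30 clusters."""
    from bindkin.coarse import HiddenMarkovMSM
    from bindkin.markov import MaximumLikelihoodMSM, cluster_kmeans
    from bindkin.tica import TICA

    frame = 0.1
    dtrajs, ftrajs, network = bk.benchmark_ensemble(
        5, 8000, frame, master_seed=11, time_scale=300.0
    )
    tica = TICA(lag_time=0.5).fit(ftrajs, frame_interval=frame)
    proj = tica.transform(ftrajs)
    dts, centers = cluster_kmeans(proj, k=30, seed=3, frame_interval=frame, max_iter=50)
    msm = MaximumLikelihoodMSM(lag_time=0.2).fit(dts)
    hmm = HiddenMarkovMSM(n_macrostates=4, lag_time=0.2, max_iter=20).fit(dts, msm=msm)
    return {
        "network": network,
        "true_dtrajs": dtrajs,
        "ftrajs": ftrajs,
        "tica": tica,
        "dtrajs": dts,
        "msm": msm,
        "hmm": hmm,
    }
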