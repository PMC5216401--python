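import numpy as np
import pandas as pd
import pytest

from docksel.svr import tiny_grid
from docksel.synth import SyntheticConfig, generate_benchmark


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic ensemble bundle (3 structures,
    18 ligands, 4 conformers x 3 poses)."""
    cfg = SyntheticConfig(n_structures=3, n_ligands=18,
                          conformers_per_ligand=4, seed=11)
    return generate_benchmark(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The full default benchmark bundle (7 x 40 x 10 x 3), seed 1."""
    return generate_benchmark(SyntheticConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def grid12():
    return tiny_grid()


def random_pose_table(rng, n_ligands=3, n_structures=2, n_conf=2, n_poses=2,
                      n_terms=3, with_rmsd=True):
    rows = []
    for li in range(n_ligands):
        for si in range(n_structures):
            for c in range(1, n_conf + 1):
                for p in range(1, n_poses + 1):
                    rows.append((f"L{li}", f"S{si}", c, 1, p))
    df = pd.DataFrame(rows, columns=[
        "ligand_id", "structure_id", "conformer_id", "run_id", "pose_id"])
    for t in range(n_terms):
        df[f"term_{t}"] = rng.normal(size=len(df))
    if with_rmsd:
        df["observed_rmsd"] = rng.uniform(0, 8, len(df))
    return df
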