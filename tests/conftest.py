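import numpy as np
import pytest
from hypothesis import settings

import immunemap as im

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def make_matrix(values, genes=None, cells=None, centered=False) -> im.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or tuple(f"g{i + 1}" for i in range(values.shape[0]))
    cells = cells or tuple(f"c{j + 1}" for j in range(values.shape[1]))
    return im.ExpressionMatrix(values, tuple(genes), tuple(cells), centered=centered)


def random_hierarchy(rng: np.random.Generator) -> im.MapHierarchy:
    """A random but valid hierarchy with occasional shared genes across pathways."""
    n_zones = int(rng.integers(1, 4))
    zones, metas, modules, pathways = {}, {}, {}, {}
    pool = [f"G{i:03d}" for i in range(60)]
    mm = mo = pw = 0
    for z in range(n_zones):
        zone = f"Z{z + 1}"
        zones[zone] = []
        for _ in range(int(rng.integers(1, 4))):
            mm += 1
            meta = f"MM{mm}"
            zones[zone].append(meta)
            metas[meta] = []
            for _ in range(int(rng.integers(1, 4))):
                mo += 1
                mod = f"M{mo}"
                metas[meta].append(mod)
                modules[mod] = []
                for _ in range(int(rng.integers(1, 4))):
                    pw += 1
                    path = f"P{pw}"
                    modules[mod].append(path)
                    k = int(rng.integers(1, 6))
                    pathways[path] = list(rng.choice(pool, size=k, replace=False))
    return im.build_hierarchy(zones, metas, modules, pathways)


@pytest.fixture(scope="session")
def default_spec() -> im.SimulationSpec:
    return im.SimulationSpec()


@pytest.fixture(scope="session")
def default_map(default_spec):
    return im.generate_map(default_spec)


@pytest.fixture(scope="session")
def default_dataset(default_map):
    """Hierarchy, entities, centred matrix and ground truth at seed 0."""
    hierarchy, entities = default_map
    matrix, truth = im.generate_cells(hierarchy, im.SimulationSpec(seed=0))
    return hierarchy, entities, im.preprocess(matrix.to_frame()), truth


@pytest.fixture(scope="session")
def ranked_dataset(default_dataset):
    """Oriented ICA result and sign-split groups for the seed-0 dataset."""
    hierarchy, _, matrix, truth = default_dataset
    result = im.orient_component(im.run_ica(matrix, seed=0), hierarchy)
    groups = im.split_by_sign(result)
    return hierarchy, matrix, truth, result, groups


@pytest.fixture()
def chain_hierarchy() -> im.MapHierarchy:
    """Minimal single-chain hierarchy with an anti-tumor zone."""
    return im.build_hierarchy(
        {"Anti-tumor": ["M1"]},
        {"M1": ["mod1"]},
        {"mod1": ["p1"]},
        {"p1": ["g1", "g2"]},
    )


def truth_groups(matrix: im.ExpressionMatrix, truth: im.GroundTruth) -> im.CellGroups:
    labels = np.where(truth.groups == 1, "group1", "group2").astype(object)
    return im.CellGroups(matrix.cells, labels)
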