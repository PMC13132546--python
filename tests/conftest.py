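import numpy as np
import pytest

from depscreen.io_formats import EffectMatrix, GeneId, SeedList
from depscreen.synthetic_data import ModuleSpec, simulate_effect_matrix


@pytest.fixture
def small_matrix() -> EffectMatrix:
    """5 genes x 8 lines with two perfectly related columns.

    B duplicates A, C is A negated; D and E are independent noise.
    """
    rng = np.random.default_rng(7)
    a = rng.standard_normal(8)
    values = np.column_stack([
        a, a.copy(), -a, rng.standard_normal(8), rng.standard_normal(8)])
    genes = [GeneId("A", 1), GeneId("B", 2), GeneId("C", 3),
             GeneId("D", 4), GeneId("E", 5)]
    return EffectMatrix([f"L{i}" for i in range(8)], genes, values)


@pytest.fixture
def module_matrix():
    """40-gene matrix with one planted 6-gene module (fixed seed)."""
    members = tuple(f"G{i + 1:04d}" for i in range(6))
    matrix, truth = simulate_effect_matrix(
        40, 100, [ModuleSpec(members, loading=1.0)],
        noise_sd=0.5, rng_seed=11)
    return matrix, members


@pytest.fixture
def module_seeds(module_matrix) -> SeedList:
    _, members = module_matrix
    return SeedList([GeneId(s) for s in members[:4]], label="module-seeds")
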