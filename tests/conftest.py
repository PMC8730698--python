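import numpy as np
import pytest

from comprof import ComplexomeMatrix, SampleDesign


@pytest.fixture
def design_2x2() -> SampleDesign:
    return SampleDesign.from_groups({"WT": 2, "lpa2": 2}, sep="_")


@pytest.fixture
def design_3x3() -> SampleDesign:
    return SampleDesign.from_groups({"WT": 3, "lpa2": 3}, sep="_")


@pytest.fixture
def small_matrix(design_2x2) -> ComplexomeMatrix:
    """2 proteins x 3 slices x 4 samples with hand-set values."""
    values = np.zeros((2, 3, 4))
    # P1: WT replicates [1,2,3] and [3,4,5]; lpa2 replicates [2,2,2], [0,0,0]
    values[0, :, 0] = [1, 2, 3]
    values[0, :, 1] = [3, 4, 5]
    values[0, :, 2] = [2, 2, 2]
    values[0, :, 3] = [0, 0, 0]
    # P2: constant 1 everywhere
    values[1] = 1.0
    return ComplexomeMatrix(["P1", "P2"], 3, design_2x2, values)


def random_matrix(rng: np.random.Generator, n_proteins=5, n_slices=4,
                  design: SampleDesign | None = None) -> ComplexomeMatrix:
    if design is None:
        design = SampleDesign.from_groups({"A": 2, "B": 1}, sep="_")
    values = rng.uniform(0, 10, size=(n_proteins, n_slices, len(design.samples)))
    values[rng.random(values.shape) < 0.2] = 0.0
    return ComplexomeMatrix([f"P{i}" for i in range(n_proteins)], n_slices,
                            design, values)
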