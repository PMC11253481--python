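import numpy as np
import pytest

from haploquant.catalog import VariantMatrix, VariantRecord


@pytest.fixture
def three_hap_matrix() -> VariantMatrix:
    """3 haplotypes over 2 SNVs: variant sets {v1}, {v1, v2}, {v2}."""
    v1 = VariantRecord("ref", 10, "A", "G")
    v2 = VariantRecord("ref", 25, "C", "T")
    V = np.array([[1, 0], [1, 1], [0, 1]], dtype=np.int8)
    Cov = np.ones_like(V)
    return VariantMatrix(["h1", "h2", "h3"], [v1, v2], V, Cov, {"ref": 50})


@pytest.fixture
def carrier_pair_matrix() -> VariantMatrix:
    """h1 carries the single variant, h2 spans it without carrying it."""
    v1 = VariantRecord("ref", 5, "A", "T")
    return VariantMatrix(
        ["h1", "h2"],
        [v1],
        np.array([[1], [0]], dtype=np.int8),
        np.array([[1], [1]], dtype=np.int8),
        {"ref": 20},
    )


def random_matrix(rng: np.random.Generator, n: int, k: int) -> VariantMatrix:
    """Random V/Cov pair honouring the V-implies-Cov invariant."""
    while True:
        V = rng.integers(0, 2, size=(n, k)).astype(np.int8)
        if k == 0 or np.all(V.sum(axis=0) >= 1):
            break
    extra = rng.integers(0, 2, size=(n, k)).astype(np.int8)
    Cov = np.maximum(V, extra)
    variants = [
        VariantRecord("ref", 10 * (j + 1), "A", "CGT"[j % 3]) for j in range(k)
    ]
    names = [f"h{i + 1}" for i in range(n)]
    return VariantMatrix(names, variants, V, Cov, {"ref": 10 * (k + 2)})
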