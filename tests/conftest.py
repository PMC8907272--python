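import numpy as np
import pytest

from assemblage_dnci import IncidenceMatrix, LevelMetadata


def make_metadata(level_ids, stages=None, regions=None, oxygen=None):
    stages = stages or ["S1"] * len(level_ids)
    regions = regions or ["R1"] * len(level_ids)
    oxygen = oxygen or [False] * len(level_ids)
    return {
        lv: LevelMetadata(
            level_id=lv,
            region=r,
            stage=s,
            site=f"site-{lv}",
            depositional_setting="offshore",
            oxygen_stress=o,
        )
        for lv, s, r, o in zip(level_ids, stages, regions, oxygen)
    }


@pytest.fixture
def toy_matrix():
    """4 levels x 3 taxa with complete metadata; L1/L2 vs L3/L4 blocks."""
    values = np.array(
        [
            [1, 1, 0],
            [1, 0, 0],
            [0, 1, 1],
            [0, 0, 1],
        ],
        dtype=np.int8,
    )
    levels = ["L1", "L2", "L3", "L4"]
    taxa = ["A", "B", "C"]
    return IncidenceMatrix(values, levels, taxa, make_metadata(levels))


@pytest.fixture
def block_matrix():
    """Two tight 4-level blocks with disjoint taxa plus shared noise taxon."""
    rng = np.random.default_rng(0)
    n = 8
    X = np.zeros((n, 9), dtype=np.int8)
    X[:4, :4] = 1
    X[4:, 4:8] = 1
    X[:, 8] = rng.integers(0, 2, n)
    X[0, 0] = 0  # a little within-block variation
    X[5, 4] = 0
    levels = [f"L{i}" for i in range(n)]
    taxa = [f"t{j}" for j in range(9)]
    return IncidenceMatrix(X, levels, taxa, make_metadata(levels))


def bruteforce_simper(X, n1):
    """Independent pairwise SIMPER decomposition (double loop)."""
    A, B = X[:n1], X[n1:]
    T = X.shape[1]
    contribs = np.zeros(T)
    ds = []
    n_pairs = 0
    for j in range(A.shape[0]):
        for k in range(B.shape[0]):
            denom = (A[j] + B[k]).sum()
            if denom == 0:
                continue
            n_pairs += 1
            diff = np.abs(A[j] - B[k])
            ds.append(diff.sum() / denom)
            contribs += diff / denom
    contribs /= n_pairs
    return float(np.mean(ds)), contribs
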