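import numpy as np
import pandas as pd
import pytest

from clonotrace import simulate as sim
from clonotrace import genotyping as gt


@pytest.fixture(scope="session")
def two_clone_hierarchy():
    return [
        sim.SimClone("A", None, {"EIF6_m1": "het"}, 0.15),
        sim.SimClone("B", None, {"TP53_m1": "het"}, 0.05),
    ]


@pytest.fixture(scope="session")
def two_clone_cells(two_clone_hierarchy):
    cfg = sim.SimConfig(n_cells=10000, ado_rate=0.05, doublet_rate=0.02, seed=11)
    return sim.simulate_cells(two_clone_hierarchy, cfg)


@pytest.fixture(scope="session")
def two_clone_genotypes(two_clone_cells):
    return gt.genotype_matrix(two_clone_cells.depth, two_clone_cells.alt)


def expected_ado_ratio(
    d: float,
    depth_mean: float = 80.0,
    depth_disp: float = 10.0,
    e: float = 1e-3,
    max_depth: int = 600,
) -> float:
    """Exact expected hom/het appearance ratio at a germline het SNP.

    Independent oracle for the ADO estimator: integrates the genotyping
    thresholds (DP >= 10, alt >= 3, fraction >= 0.30, hom >= 0.90) over
    the negative-binomial depth distribution and the three surviving-
    allele states (both kept, alt only, ref only).  The leading-order
    value is 2d/(1-d); threshold miscalls at finite depth add a small
    positive correction because fluctuation-driven wt calls at a het SNP
    count as homozygous reference.
    """
    from scipy import stats as sps

    r = depth_disp
    p = r / (r + depth_mean)
    n = np.arange(10, max_depth)
    w = sps.nbinom.pmf(n, r, p)

    def probs(f):
        kp = np.maximum(3, np.ceil(0.3 * n - 1e-9)).astype(int)
        kh = np.maximum(kp, np.ceil(0.9 * n - 1e-9)).astype(int)
        sf_p = sps.binom.sf(kp - 1, n, f)
        sf_h = sps.binom.sf(kh - 1, n, f)
        return (w * (1 - sf_p)).sum(), (w * (sf_p - sf_h)).sum(), (w * sf_h).sum()

    states = [((1 - d) ** 2, 0.5), (d * (1 - d), 1 - e), (d * (1 - d), e)]
    wt = het = hom = 0.0
    for wgt, f in states:
        a, b, c = probs(f)
        wt += wgt * a
        het += wgt * b
        hom += wgt * c
    return (wt + hom) / het


def make_genotype_frame(counts: dict[tuple[int, ...], int], loci: list[str]) -> pd.DataFrame:
    """Build a genotype matrix from {genotype vector: n_cells} directly."""
    rows = []
    for vec, n in counts.items():
        rows.extend([list(vec)] * n)
    idx = [f"c{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx, columns=loci)
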