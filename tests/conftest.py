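import numpy as np
import pytest

from gcmtblup.pedigree import Pedigree
from gcmtblup.simulate import table1_fixture


@pytest.fixture
def table1():
    return table1_fixture()


def random_pedigree(rng, n_founders=20, n_generations=3, per_generation=40,
                    with_sex=False):
    """Random-mating multi-generation pedigree for oracle tests."""
    ids = list(range(1, n_founders + 1))
    sires = [0] * n_founders
    dams = [0] * n_founders
    sex = ["M" if i % 2 == 0 else "F" for i in range(n_founders)]
    cur = list(range(n_founders))
    nid = n_founders
    for _ in range(n_generations):
        males = [i for i in cur if sex[i] == "M"]
        females = [i for i in cur if sex[i] == "F"]
        new = []
        for _k in range(per_generation):
            nid += 1
            ids.append(nid)
            sires.append(int(rng.choice(males)) + 1)
            dams.append(int(rng.choice(females)) + 1)
            sex.append("M" if rng.random() < 0.5 else "F")
            new.append(nid - 1)
        cur = new
    return Pedigree.from_parents(ids, sires, dams, sex=sex if with_sex else None)


def gene_drop(ped, p, rng, with_polygenic=None):
    """Drop a biallelic autosomal gene through a pedigree."""
    n = ped.n
    alleles = np.zeros((n, 2), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for k, par in enumerate((s, d)):
            if par < 0:
                alleles[i, k] = rng.random() < p
            else:
                alleles[i, k] = alleles[par, rng.integers(2)]
    return alleles.sum(axis=1).astype(float)


@pytest.fixture
def rng():
    return np.random.default_rng(20150917)
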