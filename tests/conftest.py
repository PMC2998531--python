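import numpy as np
import pytest

import corescan as cs

#: Deterministic homolog chain: A ~ B (shared 9-mer), B ~ C (shared 9-mer),
#: A !~ C (max 5 aligned matches).  A < B < C lexicographically.
CHAIN_A = "AAAAAAAAAAAAAAA"
CHAIN_B = "AAAAAAAAAAKKKKK"
CHAIN_C = "KKKKKAAAAAKKKKK"
LONER_D = "WYWYWYWYWYWYWYW"


@pytest.fixture(scope="session")
def bench_world():
    """The fixed synthetic benchmark world (defaults, master seed 42)."""
    return cs.SyntheticWorld(seed=42)


@pytest.fixture(scope="session")
def bench_dataset(bench_world):
    """The n=1000 benchmark dataset with the default homolog mix."""
    return cs.simulate_dataset(bench_world, 1000)


@pytest.fixture(scope="session")
def bench_folds(bench_dataset):
    return cs.make_folds(bench_dataset, k=5, seed=42)


@pytest.fixture()
def toy_dataset():
    """Six fully dissimilar peptides, three binders and three non-binders."""
    seqs_ic50 = [
        ("ACDEFGHIKLMNPQR", 50.0),
        ("WYWYWYWYWYWYWYW", 200.0),
        ("KLKLKLKLKLKLKLK", 800.0),
        ("TVTVTVTVTVTVTVT", 1500.0),
        ("MNMNMNMNMNMNMNM", 5000.0),
        ("GHGHGHGHGHGHGHG", 20000.0),
    ]
    records = [cs.AffinityRecord("HLA-TEST*0101", s, x) for s, x in seqs_ic50]
    return cs.AffinityDataset("HLA-TEST*0101", records)


def random_peptides(rng: np.random.Generator, n: int, length=15):
    """Distinct random peptides (length may be an int or (lo, hi) range)."""
    out = []
    seen = set()
    while len(out) < n:
        ln = length if isinstance(length, int) else int(rng.integers(length[0], length[1] + 1))
        pep = "".join(cs.ALPHABET[i] for i in rng.integers(0, 20, ln))
        if pep not in seen:
            seen.add(pep)
            out.append(pep)
    return out
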