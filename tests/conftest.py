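import numpy as np
import pandas as pd
import pytest

from selfmeth.core_io import MISSING, BandMatrix, GenotypeMatrix, PipelineConfig
from selfmeth.synthetic_data import default_study_config, simulate


@pytest.fixture(scope="session")
def study_dataset():
    """One full simulated study dataset shared across tests (fixed seed)."""
    return simulate(default_study_config(rng_seed=11))


@pytest.fixture
def tiny_genotypes():
    """Three individuals, two loci; individual C missing at locus 2."""
    calls = np.array(
        [
            [[101, 101], [1, 2]],
            [[101, 103], [1, 1]],
            [[103, 103], [MISSING, MISSING]],
        ]
    )
    return GenotypeMatrix(["A", "B", "C"], ["s1", "s1", "s2"], ["L1", "L2"], calls)


@pytest.fixture
def config():
    return PipelineConfig()


# ---------------------------------------------------------------------------
# Independent oracles (loop-based, written from the definitions; these stay
# deliberately naive and separate from the package implementations)
# ---------------------------------------------------------------------------


def amova_oracle(d: np.ndarray, groups) -> float:
    """Brute-force Phi_ST from squared distances, plain loops."""
    groups = list(groups)
    n = len(groups)
    labels = list(dict.fromkeys(groups))
    k = len(labels)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    sizes = []
    for lab in labels:
        members = [i for i in range(n) if groups[i] == lab]
        sizes.append(len(members))
        acc = 0.0
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                acc += d[members[a], members[b]] ** 2
        ss_within += acc / len(members)
    ss_among = ss_total - ss_within
    sigma_b = ss_within / (n - k)
    n_bar = (n - sum(s**2 for s in sizes) / n) / (k - 1)
    sigma_a = (ss_among / (k - 1) - sigma_b) / n_bar
    return sigma_a / (sigma_a + sigma_b)


def mw_u_oracle(x, y) -> float:
    """U of the first sample by direct pair counting (ties count half)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def kw_h_oracle(values, groups) -> float:
    """Kruskal-Wallis H with tie correction, computed from scratch."""
    values = list(values)
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    labels = list(dict.fromkeys(groups))
    h = 0.0
    for lab in labels:
        idx = [i for i in range(n) if groups[i] == lab]
        rsum = sum(ranks[i] for i in idx)
        h += rsum**2 / len(idx)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    correction = 1 - sum(c**3 - c for c in counts.values()) / (n**3 - n)
    return h / correction if correction > 0 else 0.0
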