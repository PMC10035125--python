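"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use plain-Python sliding-window counting and direct
formula transcription so they share no code with the package's vectorized
encoders.
"""
from __future__ import annotations

from collections import Counter
from itertools import product

import numpy as np
import pytest

import subloc as sl

ACGT = set("ACGT")
EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}


def words(k: int) -> list[str]:
    return ["".join(p) for p in product("ACGT", repeat=k)]


def valid_window_counts(seq: str, k: int) -> tuple[Counter, int]:
    c = Counter()
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if set(w) <= ACGT:
            c[w] += 1
    return c, sum(c.values())


def naive_kmer_vector(seq: str, ks=(2, 3, 4, 5)) -> list[float]:
    out = []
    for k in ks:
        c, _ = valid_window_counts(seq, k)
        out.extend(c[w] / len(seq) for w in words(k))
    return out


def naive_freqs(seq: str, k: int) -> dict[str, float]:
    c, n = valid_window_counts(seq, k)
    return {w: c[w] / n for w in words(k)}


def naive_pseeiip(seq: str) -> list[float]:
    f = naive_freqs(seq, 3)
    return [(EIIP[w[0]] + EIIP[w[1]] + EIIP[w[2]]) * f[w] for w in words(3)]


def naive_property_weighted(seq: str, table, k: int) -> list[float]:
    f = naive_freqs(seq, k)
    out = []
    for prop in table.index:
        for w in words(k):
            out.append(table.loc[prop, w] * f[w])
    return out


def naive_zcurve_triplets(f: dict[str, float]) -> list[float]:
    out = []
    for xy in words(2):
        p = {n: f.get(xy + n, 0.0) for n in "ACGT"}
        out.append((p["A"] + p["G"]) - (p["C"] + p["T"]))
        out.append((p["A"] + p["C"]) - (p["G"] + p["T"]))
        out.append((p["A"] + p["T"]) - (p["C"] + p["G"]))
    return out


def naive_zc48(seq: str) -> list[float]:
    return naive_zcurve_triplets(naive_freqs(seq, 3))


def naive_zc144(seq: str) -> list[float]:
    out = []
    for phase in range(3):
        c = Counter()
        for i in range(phase, len(seq) - 2, 3):
            w = seq[i:i + 3]
            if set(w) <= ACGT:
                c[w] += 1
        n = sum(c.values())
        out.extend(naive_zcurve_triplets({w: c[w] / n for w in c}))
    return out


def naive_pseknc(seq: str, std_table, ks=(2, 3, 4, 5), lam=10, weight=0.1,
                 prop_names=("Twist", "Tilt", "Roll", "Shift", "Slide",
                             "Rise")) -> list[float]:
    props = [std_table.loc[p] for p in prop_names]

    def theta_pair(a: str, b: str) -> float:
        return sum((p[a] - p[b]) ** 2 for p in props) / len(props)

    dis = [seq[i:i + 2] for i in range(len(seq) - 1)]
    thetas = []
    for j in range(1, lam + 1):
        pairs = [(dis[i], dis[i + j]) for i in range(len(dis) - j)
                 if set(dis[i]) <= ACGT and set(dis[i + j]) <= ACGT]
        thetas.append(sum(theta_pair(a, b) for a, b in pairs) / len(pairs))
    denom = 1.0 + weight * sum(thetas)
    out = []
    for k in ks:
        f = naive_freqs(seq, k)
        out.extend(f[w] / denom for w in words(k))
    out.extend(weight * t / denom for t in thetas)
    return out


def random_dna(rng: np.random.Generator, length: int,
               alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture(scope="session")
def tables() -> sl.EncoderTables:
    return sl.default_tables()


@pytest.fixture(scope="session")
def cfg() -> sl.PseKNCConfig:
    return sl.PseKNCConfig()


@pytest.fixture(scope="session")
def small_corpus() -> sl.LabeledCorpus:
    """Three-location corpus, 24 sequences each, strong composition bias."""
    config = sl.SyntheticCorpusConfig(
        locations=("cytoplasm", "nucleus", "ER"),
        n_per_location=24,
        composition={"cytoplasm": (0.55, 0.15, 0.15, 0.15),
                     "nucleus": (0.15, 0.55, 0.15, 0.15),
                     "ER": (0.15, 0.15, 0.55, 0.15)},
        length_range=(60, 150),
        seed=7)
    return sl.generate_synthetic_corpus(config)
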