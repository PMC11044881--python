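"""Shared fixtures and independent brute-force oracles.

The oracle helpers here deliberately re-derive everything by plain
enumeration over all 4^l sequences (or by explicit Markov-chain matrix
powering), sharing no code path with the package, so they can certify the
compressed distance-space implementation.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from allelekde import Alignment, tally_alleles

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = "ACGT"
INF = float("inf")


# ---------------------------------------------------------------- fixtures
@pytest.fixture
def aa_at_alignment() -> Alignment:
    """The worked sample: three AA and three AT sequences."""
    seqs = ("AA", "AA", "AA", "AT", "AT", "AT")
    return Alignment(ids=tuple(str(i + 1) for i in range(6)), sequences=seqs)


@pytest.fixture
def aa_at_table(aa_at_alignment):
    return tally_alleles(aa_at_alignment)


# ----------------------------------------------------------------- oracles
def oracle_hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def all_sequences(l: int) -> list[str]:
    return ["".join(t) for t in product(BASES, repeat=l)]


def oracle_transition_probability(g: int, mu: float) -> float:
    """One-base substitution probability by explicit 4-state matrix powering."""
    M = np.full((4, 4), mu / 3.0)
    np.fill_diagonal(M, 1.0 - mu)
    return float(np.linalg.matrix_power(M, g)[0, 1])


def oracle_kernel_mass(P: float, l: int, m: int, x: int, renormalize: bool) -> float:
    """Per-sequence kernel mass by direct evaluation + explicit normalization."""
    if x > m:
        return 0.0
    raw = (1.0 - 3.0 * P) ** (l - x) * P**x
    if not renormalize or m == l:
        return raw
    total = sum(
        math.comb(l, y) * 3**y * (1.0 - 3.0 * P) ** (l - y) * P**y
        for y in range(m + 1)
    )
    return raw / total


def oracle_distance_space(detected: tuple[str, ...], m: int):
    """Censored coordinates and multiplicities by scanning all 4^l sequences.

    Returns (coords dict: full-tuple -> multiplicity, members dict).
    Detected alleles keep uncensored vectors; undetected coordinates censor
    entries above m to INF.
    """
    l = len(detected[0])
    coords: dict[tuple, int] = {}
    members: dict[tuple, list[str]] = {}
    for seq in all_sequences(l):
        vec = [oracle_hamming(seq, d) for d in detected]
        if min(vec) > m:
            continue
        if 0 in vec:
            key = tuple(vec)
        else:
            key = tuple(d if d <= m else INF for d in vec)
        coords[key] = coords.get(key, 0) + 1
        members.setdefault(key, []).append(seq)
    return coords, members


def oracle_sequence_space_estimate(
    sample: list[str], P: float, m: int, renormalize: bool
) -> dict[str, float]:
    """Full sequence-space KDE by direct summation over every sequence."""
    l = len(sample[0])
    n = len(sample)
    return {
        seq: sum(
            oracle_kernel_mass(P, l, m, oracle_hamming(seq, a), renormalize)
            for a in sample
        )
        / n
        for seq in all_sequences(l)
    }


def oracle_loo(sample: list[str], P: float, m: int, renormalize: bool, i: int) -> float:
    """Leave-one-out density at sample i over the remaining n-1 sequences."""
    l = len(sample[0])
    rest = sample[:i] + sample[i + 1 :]
    return sum(
        oracle_kernel_mass(P, l, m, oracle_hamming(sample[i], a), renormalize)
        for a in rest
    ) / len(rest)


def oracle_lscv(sample: list[str], P: float, m: int, renormalize: bool) -> float:
    est = oracle_sequence_space_estimate(sample, P, m, renormalize)
    n = len(sample)
    ise = sum(v * v for v in est.values())
    loo = sum(oracle_loo(sample, P, m, renormalize, i) for i in range(n))
    return ise - 2.0 / n * loo


def oracle_lcv(sample: list[str], P: float, m: int, renormalize: bool) -> float:
    n = len(sample)
    total = 0.0
    for i in range(n):
        v = oracle_loo(sample, P, m, renormalize, i)
        if v <= 0.0:
            return -math.inf
        total += math.log(v)
    return total


def oracle_pi(freqs: dict[str, float], l: int) -> float:
    """Nucleotide diversity by the explicit double sum over allele pairs."""
    alleles = list(freqs)
    return sum(
        freqs[a] * freqs[b] * oracle_hamming(a, b) / l
        for a in alleles
        for b in alleles
    )


def oracle_joint_distance_counts(A: str, B: str, x: int) -> dict[int, int]:
    """Distance-to-B histogram of the full x-shell around A, by enumeration."""
    counts: dict[int, int] = {}
    for seq in all_sequences(len(A)):
        if oracle_hamming(seq, A) == x:
            y = oracle_hamming(seq, B)
            counts[y] = counts.get(y, 0) + 1
    return counts


def random_detected(rng: np.random.Generator, l: int, k: int) -> tuple[str, ...]:
    """k distinct random alleles of length l."""
    out: set[str] = set()
    while len(out) < k:
        out.add("".join(rng.choice(list(BASES), size=l)))
    return tuple(sorted(out))
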