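"""Nucleotide diversity, concordance rate and replicate evaluation statistics.

Nucleotide diversity pi is the expected proportion of differing sites
between two alleles drawn from the frequency distribution:

    pi = sum_i sum_j p_i p_j d_ij / l,

with d_ij the Hamming distance and l the sequence length (so the i = j
terms vanish and 0 <= pi <= 3/4, the Jukes-Cantor saturation ceiling).

On the compressed distance space the pairwise distances between undetected
alleles are unknown, so the *approximate* diversity keeps the
detected-detected terms, recovers the detected-undetected terms (including
censored INF entries, via the joint-distance combinatorics), and drops the
undetected-undetected terms; since every dropped term is non-negative the
approximation never exceeds the full-space value on the same estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigurationError
from .estimator import FrequencyEstimate
from .io import encode_sequences
from .spaces import DistanceSpace, SequenceSpace, expected_distance_beyond


@dataclass(frozen=True)
class DiversityResult:
    """Nucleotide diversity value with the terms it includes."""

    pi: float
    terms: str  # "all" or "detected_pairs_plus_detected_undetected"
    l: int

    def __float__(self) -> float:
        return self.pi


@dataclass(frozen=True)
class EvaluationStats:
    """Relative bias / accuracy of replicate estimates against a known truth."""

    relative_bias: float
    accuracy: float
    squared_accuracy: float
    sd_relative_bias: float
    sd_accuracy: float
    sd_squared_accuracy: float
    n_replicates: int


def nucleotide_diversity_exact(
    freqs: Mapping[str, float], l: int | None = None, *, tol: float = 1e-6
) -> DiversityResult:
    """Exact pi from a full allele -> frequency map (all pairs included)."""
    alleles = list(freqs)
    p = np.array([freqs[a] for a in alleles], dtype=float)
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    if l is None:
        l = len(alleles[0])
    if any(len(a) != l for a in alleles):
        raise ValueError("alleles must share one length")
    codes = encode_sequences(alleles)
    D = (codes[:, None, :] != codes[None, :, :]).sum(axis=2)
    pi = float(p @ (D / l) @ p)
    return DiversityResult(pi=pi, terms="all", l=l)


def counting_diversity(table) -> DiversityResult:
    """Plug-in pi from observed allele counts (the no-KDE baseline)."""
    return nucleotide_diversity_exact(table.frequencies, table.length)


def _dbar_table(D_row: np.ndarray, x: int, l: int, m: int, cache: dict) -> np.ndarray:
    """Expected censored distance for each detected allele given anchor distance x."""
    out = np.empty(len(D_row))
    for i, dd in enumerate(D_row):
        key = (int(dd), x)
        if key not in cache:
            cache[key] = expected_distance_beyond(int(dd), l, x, m)
        out[i] = cache[key]
    return out


def nucleotide_diversity_approx(
    est: FrequencyEstimate, *, include_undetected_pairs: bool = False
) -> DiversityResult:
    """Approximate pi from a KDE estimate on a distance space.

    Detected-detected terms use the exact inter-allele distances. Each
    undetected coordinate contributes its detected-undetected terms: finite
    distance entries are used directly; for entries censored to INF the
    coordinate's sequences are known to sit at an exact distance x from
    their nearest finite "anchor" allele and farther than m from the
    censored one, so the term uses the mean of that conditional distance
    distribution (ties between equally near anchors break toward the
    lexicographically smallest allele). Undetected-undetected terms are
    omitted unless ``include_undetected_pairs``, which requires the space to
    have been built with ``keep_members=True`` and then reproduces the
    full-space computation exactly.
    """
    space = est.space
    if not isinstance(space, DistanceSpace):
        raise ConfigurationError("approximate diversity requires a distance space")
    if include_undetected_pairs:
        if space.members is None:
            raise ConfigurationError(
                "include_undetected_pairs requires keep_members=True on the space"
            )
        freqs: dict[str, float] = {}
        for i, members in enumerate(space.members):
            for seq in members:
                freqs[seq] = float(est.per_sequence_mass[i])
        total = sum(freqs.values())
        if total <= 0:
            return DiversityResult(0.0, "all", space.l)
        freqs = {s: f / total for s, f in freqs.items()}
        res = nucleotide_diversity_exact(freqs, space.l)
        return DiversityResult(res.pi, "all", space.l)

    k, l, m = space.k, space.l, space.m
    p_det = est.mass[:k]
    D = space.distance_matrix
    pi = float(p_det @ (D / l) @ p_det)

    cache: dict = {}
    for idx in range(k, len(space)):
        p_c = float(est.mass[idx])
        if p_c == 0.0:
            continue
        entries = space.finite_entries(idx)
        anchor, x = min(entries, key=lambda e: (e[1], space.detected[e[0]]))
        eff = _dbar_table(D[anchor], x, l, m, cache)
        finite_idx = [j for j, _ in entries]
        eff[finite_idx] = [d for _, d in entries]
        pi += 2.0 * p_c * float(p_det @ eff) / l
    return DiversityResult(pi, "detected_pairs_plus_detected_undetected", l)


def concordance_rate(true_freqs: Mapping[str, float], est: FrequencyEstimate) -> float:
    """1 minus the total absolute frequency discrepancy, on the estimate's space.

    Population alleles are mapped onto the estimate's coordinates (several
    may share one coordinate; their true frequencies then add). Alleles
    outside a truncated distance space contribute their whole frequency as
    discrepancy. Equals 1 iff the distributions are identical; can be as
    low as -1 for disjoint supports.
    """
    space = est.space
    if isinstance(space, SequenceSpace):
        true_on_space = np.zeros(len(est.mass))
        for seq, f in true_freqs.items():
            true_on_space[space.index_of(seq)] += f
        return float(1.0 - np.abs(true_on_space - est.mass).sum())

    true_on_space = np.zeros(len(est.mass))
    outside = 0.0
    for seq, f in true_freqs.items():
        idx = space.locate_sequence(seq)
        if idx is None:
            outside += f
        else:
            true_on_space[idx] += f
    return float(1.0 - np.abs(true_on_space - est.mass).sum() - outside)


def evaluation_stats(estimates, truth) -> EvaluationStats:
    """Relative bias, accuracy and squared accuracy of replicate estimates.

    ``truth`` may be a scalar or a per-replicate array (each replicate
    compared with its own known population value); the bare per-replicate
    sums are divided by the replicate count so the statistics are
    comparable across designs.
    """
    x = np.asarray(estimates, dtype=float)
    X = np.asarray(truth, dtype=float)
    if x.size < 1:
        raise ValueError("at least one replicate is required")
    if np.any(X == 0.0):
        raise ValueError("truth must be nonzero")
    r = (x - X) / X
    sd = lambda v: float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
    return EvaluationStats(
        relative_bias=float(r.mean()),
        accuracy=float(np.abs(r).mean()),
        squared_accuracy=float((r**2).mean()),
        sd_relative_bias=sd(r),
        sd_accuracy=sd(np.abs(r)),
        sd_squared_accuracy=sd(r**2),
        n_replicates=int(x.size),
    )
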