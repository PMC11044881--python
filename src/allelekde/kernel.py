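"""The Jukes-Cantor-derived kernel on nucleotide sequence space.

The kernel is parameterized by a single scalar bandwidth P, the probability
that one specific base has become one specific other base. Under the
Jukes-Cantor substitution model this probability after g generations at
per-base mutation rate mu is

    P(g, mu) = 1/4 + (mu/3 - 1/4) (1 - 4 mu / 3)^(g-1)
             = (1 - (1 - 4 mu / 3)^g) / 4,

which rises from 0 to the saturation value 1/4. Neither g nor mu is needed
to run the density estimate: P is selected directly (by cross-validation),
so the bandwidth lives in [0, 1/4). The per-sequence kernel mass at Hamming
distance x from the center, for sequences of length l, is

    Q_P(x) = (1 - 3P)^(l-x) * P^x,

i.e. the probability of one *specific* sequence at distance x. Summed over
the C(l, x) 3^x sequences in each distance shell this is a binomial
distribution and totals 1. Truncating the kernel at a maximum distance m
(the "mutation number") zeroes the mass beyond m; the truncated kernel can
optionally be renormalized so each sample still contributes total mass 1.

All kernel masses are computed in log space and exponentiated once at the
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

MAX_BANDWIDTH = 0.25  # exclusive; at P = 1/4 the kernel is uniform


def validate_bandwidth(P: float) -> float:
    P = float(P)
    if not 0.0 <= P < MAX_BANDWIDTH:
        raise ValueError(f"bandwidth P must lie in [0, 1/4), got {P}")
    return P


def total_change_probability(t: float, mu: float) -> float:
    """Probability a site differs from its ancestor after t generations.

    Continuous-in-t form of the Jukes-Cantor chain, 3 * P(t, mu); valid for
    any real t >= 0 (branch lengths from the coalescent are not integers).
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    if not 0.0 <= mu <= 0.75:
        raise ValueError(f"mu must lie in [0, 3/4], got {mu}")
    return 0.75 * (1.0 - (1.0 - 4.0 * mu / 3.0) ** t)


def substitution_probability(g: float, mu: float) -> float:
    """P(g, mu): probability one specific base becomes one specific other.

    Parameters
    ----------
    g : number of generations, >= 1.
    mu : per-generation per-base mutation rate in [0, 3/4].
    """
    if g < 1:
        raise ValueError(f"g must be >= 1, got {g}")
    return total_change_probability(g, mu) / 3.0


def jc_transition_matrix(t: float, mu: float) -> np.ndarray:
    """4x4 Jukes-Cantor transition matrix after t generations."""
    p = total_change_probability(t, mu) / 3.0
    M = np.full((4, 4), p)
    np.fill_diagonal(M, 1.0 - 3.0 * p)
    return M


@dataclass(frozen=True)
class KernelSpec:
    """Kernel configuration: bandwidth P, length l, mutation number m.

    ``m`` truncates the kernel: sequences farther than m substitutions from
    the center receive zero mass (m = l means no truncation; m = 0 makes the
    kernel a point mass, i.e. plain counting). With ``renormalize`` the
    truncated masses are rescaled to total 1 over the within-m shells.
    """

    P: float
    l: int
    m: int | None = None
    renormalize: bool = True

    def __post_init__(self) -> None:
        validate_bandwidth(self.P)
        if self.l < 1:
            raise ValueError(f"sequence length l must be >= 1, got {self.l}")
        if self.m is None:
            object.__setattr__(self, "m", self.l)
        if not 0 <= self.m <= self.l:
            raise ValueError(f"mutation number m={self.m} must lie in [0, l={self.l}]")


def log_shell_sizes(l: int, m: int) -> np.ndarray:
    """log(C(l, x) * 3^x) for x = 0..m: the number of sequences per shell."""
    x = np.arange(m + 1)
    return gammaln(l + 1) - gammaln(x + 1) - gammaln(l - x + 1) + x * math.log(3.0)


def log_kernel_masses(spec: KernelSpec) -> np.ndarray:
    """Log per-sequence kernel mass at distances x = 0..m.

    Point-mass limits (P = 0 or m = 0) are handled exactly.
    """
    m = spec.m
    if spec.P == 0.0:
        out = np.full(m + 1, -np.inf)
        out[0] = 0.0
        return out
    x = np.arange(m + 1)
    out = (spec.l - x) * math.log1p(-3.0 * spec.P) + x * math.log(spec.P)
    if spec.renormalize and m < spec.l:
        out -= logsumexp(out + log_shell_sizes(spec.l, m))
    return out


def kernel_mass_per_sequence(spec: KernelSpec, x: int) -> float:
    """Mass assigned to ONE specific sequence at Hamming distance x.

    Zero beyond the mutation number; raises for x outside [0, l].
    """
    if not 0 <= x <= spec.l:
        raise ValueError(f"distance x={x} out of range [0, {spec.l}]")
    if x > spec.m:
        return 0.0
    return float(np.exp(log_kernel_masses(spec)[x]))


def kernel_mass_by_distance(spec: KernelSpec) -> np.ndarray:
    """Total kernel mass per distance shell x = 0..m.

    Sums to 1 when m = l or when renormalized; to < 1 when truncated
    without renormalization.
    """
    return np.exp(log_kernel_masses(spec) + log_shell_sizes(spec.l, spec.m))
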