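"""KDE of allele frequency and cross-validated bandwidth selection.

Each of the n sampled sequences spreads its 1/n share of frequency over the
space through the truncated Jukes-Cantor kernel:

    f_hat(a) = (1/n) * sum_i Q_P(d(a, a_i)),

where d(a, a_i) is the Hamming distance from coordinate a to sample
sequence a_i and Q_P is the per-sequence kernel mass (zero beyond the
mutation number m). On the distance space, every sequence sharing a
coordinate receives the same per-sequence mass, so the coordinate's total
mass is that value times its multiplicity.

The bandwidth P is selected on a deterministic grid over [0, 1/4) by
least-squares cross-validation (LSCV; minimize the discrete
integrated-squared-error criterion) or likelihood cross-validation (LCV;
maximize the summed log leave-one-out density), with optional
golden-section refinement around the grid optimum. Derivative-based
selectors (plug-in rules) have no analogue here: the sequence space admits
no useful differential structure.

The module also carries the user-facing model objects:
:class:`AlleleFrequencyKDE` (built from an alignment, an allele table or a
FASTA file) and :class:`KDEResults` (estimates, diversity, concordance,
summary table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ConfigurationError
from .io import Alignment, AlleleTable, hamming_matrix, read_alignment, tally_alleles
from .kernel import MAX_BANDWIDTH, KernelSpec, log_kernel_masses
from .spaces import (
    DEFAULT_GUARD,
    DistanceSpace,
    SequenceSpace,
    build_distance_space,
)

DEFAULT_GRID_MAX = 0.2499


def default_bandwidth_grid(num: int = 64) -> np.ndarray:
    """0 plus `num` log-spaced candidates from 1e-8 to just below 1/4."""
    return np.concatenate([[0.0], np.geomspace(1e-8, DEFAULT_GRID_MAX, num)])


@dataclass(frozen=True)
class CVResult:
    """Outcome of grid cross-validation for the bandwidth P."""

    method: str
    grid: np.ndarray
    scores: np.ndarray
    selected_P: float
    selected_score: float
    fallback: bool = False  # all LCV candidates were -inf; P = 0 by convention
    refined: bool = False


@dataclass
class FrequencyEstimate:
    """A normalized frequency mass function over a sequence or distance space.

    ``mass`` is the total mass per coordinate; ``per_sequence_mass`` divides
    it by the coordinate's multiplicity (the estimated frequency of any one
    specific allele at that coordinate).
    """

    space: DistanceSpace | SequenceSpace
    mass: np.ndarray
    per_sequence_mass: np.ndarray
    spec: KernelSpec
    table: AlleleTable

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    def sequence_mass(self, seq: str) -> float:
        """Estimated frequency of one specific sequence (0 outside the space)."""
        if isinstance(self.space, SequenceSpace):
            return float(self.per_sequence_mass[self.space.index_of(seq)])
        idx = self.space.locate_sequence(seq)
        return 0.0 if idx is None else float(self.per_sequence_mass[idx])

    def to_frame(self):
        """Coordinates with multiplicities and estimated frequencies."""
        import pandas as pd

        if isinstance(self.space, SequenceSpace):
            return pd.DataFrame(
                {
                    "sequence": list(self.space.sequences()),
                    "multiplicity": 1,
                    "frequency": self.mass,
                }
            )
        df = self.space.to_frame()
        df["frequency"] = self.mass
        df["per_sequence_frequency"] = self.per_sequence_mass
        return df


def _check_compat(table: AlleleTable, spec: KernelSpec, space) -> None:
    if spec.l != table.length:
        raise ConfigurationError(
            f"kernel length l={spec.l} does not match allele length {table.length}"
        )
    if isinstance(space, DistanceSpace):
        if space.detected != table.alleles:
            raise ConfigurationError(
                "distance space was not built from this table's alleles"
            )
        if space.m != spec.m:
            raise ConfigurationError(
                f"space truncation m={space.m} != kernel mutation number {spec.m}"
            )
    elif isinstance(space, SequenceSpace):
        if space.l != table.length:
            raise ConfigurationError(
                f"sequence space length {space.l} != allele length {table.length}"
            )
    else:
        raise ConfigurationError(f"unsupported space type {type(space).__name__}")


def _entry_count_matrix(space: DistanceSpace, counts) -> np.ndarray:
    """S[c, x] = summed sample counts of alleles at distance x (<= m) from coord c."""
    S = np.zeros((len(space), space.m + 1))
    counts = np.asarray(counts, dtype=float)
    for i in range(len(space)):
        for j, d in space.finite_entries(i):
            S[i, d] += counts[j]
    return S


def _sequence_space_distance_matrix(space: SequenceSpace, table: AlleleTable) -> np.ndarray:
    return hamming_matrix(list(space.sequences()), table.alleles)


def estimate_frequencies(
    table: AlleleTable, spec: KernelSpec, space: DistanceSpace | SequenceSpace
) -> FrequencyEstimate:
    """Kernel density estimate of the allele frequency mass function."""
    _check_compat(table, spec, space)
    q = np.exp(log_kernel_masses(spec))
    n = table.n
    if isinstance(space, DistanceSpace):
        S = _entry_count_matrix(space, table.counts)
        per_seq = S @ q / n
        mass = per_seq * space.multiplicity
    else:
        dists = _sequence_space_distance_matrix(space, table)
        qx = np.zeros(spec.l + 1)
        qx[: spec.m + 1] = q
        per_seq = qx[dists] @ np.asarray(table.counts, dtype=float) / n
        mass = per_seq
    return FrequencyEstimate(space, mass, per_seq, spec, table)


def _loo_allele_masses(table: AlleleTable, spec: KernelSpec, D: np.ndarray | None = None):
    """Leave-one-out per-sequence mass at each distinct allele, vector of length k."""
    if table.n < 2:
        raise ValueError("cross-validation requires n >= 2")
    if D is None:
        D = hamming_matrix(table.alleles)
    q = np.exp(log_kernel_masses(spec))
    counts = np.asarray(table.counts, dtype=float)
    T = np.zeros((table.k, spec.m + 1))
    for x in range(spec.m + 1):
        T[:, x] = ((D == x) * counts[None, :]).sum(axis=1)
    return (T @ q - q[0]) / (table.n - 1)


def loo_density(table: AlleleTable, spec: KernelSpec, i: int) -> float:
    """f_hat_{-i}(a_i): held-out per-sequence mass at individual i's allele.

    Leave-one-out removes one individual (one sequence record), not one
    allele type; the denominator is n - 1.
    """
    k = table.allele_index_of_individual(i)
    return float(_loo_allele_masses(table, spec)[k])


def lscv_score(
    table: AlleleTable, spec: KernelSpec, space: DistanceSpace | SequenceSpace
) -> float:
    """Discrete integrated-squared-error criterion; lower is better.

    sum_c multiplicity(c) * f_hat(c)^2  -  (2/n) * sum_i f_hat_{-i}(a_i),
    with f_hat the per-sequence mass. Weighting the squared mass by the
    multiplicity makes the distance-space criterion equal the sequence-space
    one.
    """
    est = estimate_frequencies(table, spec, space)
    mult = (
        space.multiplicity if isinstance(space, DistanceSpace) else np.ones(len(est.mass))
    )
    loo = _loo_allele_masses(table, spec)
    counts = np.asarray(table.counts, dtype=float)
    return float((mult * est.per_sequence_mass**2).sum() - 2.0 / table.n * (counts @ loo))


def lcv_score(table: AlleleTable, spec: KernelSpec) -> float:
    """Summed log leave-one-out density; higher is better; -inf on any zero."""
    loo = _loo_allele_masses(table, spec)
    if np.any(loo <= 0.0):
        return -math.inf
    counts = np.asarray(table.counts, dtype=float)
    return float(counts @ np.log(loo))


def _grid_scores(table, m, method, grid, renormalize, space):
    """Vectorized criterion over all bandwidth candidates at once."""
    l = table.length
    counts = np.asarray(table.counts, dtype=float)
    n = table.n
    D = hamming_matrix(table.alleles)
    Q = np.empty((m + 1, len(grid)))
    for g, P in enumerate(grid):
        Q[:, g] = np.exp(
            log_kernel_masses(KernelSpec(P=P, l=l, m=m, renormalize=renormalize))
        )
    T = np.zeros((table.k, m + 1))
    for x in range(m + 1):
        T[:, x] = ((D == x) * counts[None, :]).sum(axis=1)
    LOO = (T @ Q - Q[0, :][None, :]) / (n - 1)  # (k, G)
    if method == "lcv":
        with np.errstate(divide="ignore"):
            logs = np.where(LOO > 0.0, np.log(np.maximum(LOO, 1e-300)), -np.inf)
        scores = counts @ logs
        scores[np.any(LOO <= 0.0, axis=0)] = -np.inf
        return scores
    S = _entry_count_matrix(space, counts)
    PS = S @ Q / n  # (ncoords, G)
    ise = space.multiplicity @ PS**2
    return ise - 2.0 / n * (counts @ LOO)


def select_bandwidth(
    table: AlleleTable,
    m: int,
    method: str = "lscv",
    *,
    grid: np.ndarray | None = None,
    renormalize: bool = True,
    space: DistanceSpace | None = None,
    refine: bool = True,
    guard: int = DEFAULT_GUARD,
) -> CVResult:
    """Select the kernel bandwidth P by cross-validation on a fixed grid.

    Ties are broken toward smaller P (less smoothing). If every LCV
    candidate scores -inf (some held-out allele always has zero
    leave-one-out mass) the selection falls back to P = 0 with
    ``fallback=True``, which reduces the estimate to plain counting.
    """
    method = method.lower()
    if method not in ("lscv", "lcv"):
        raise ValueError(f"unknown CV method {method!r}")
    if table.n < 2:
        raise ValueError("cross-validation requires n >= 2")
    if grid is None:
        grid = default_bandwidth_grid()
    grid = np.asarray(grid, dtype=float)
    if space is None:
        space = build_distance_space(table.alleles, m, guard=guard)
    scores = _grid_scores(table, m, method, grid, renormalize, space)

    sign = 1.0 if method == "lscv" else -1.0  # minimize sign * criterion
    objective = sign * scores
    if not np.isfinite(objective).any():
        zero = int(np.flatnonzero(grid == 0.0)[0]) if (grid == 0.0).any() else 0
        return CVResult(method, grid, scores, float(grid[zero]), float(scores[zero]),
                        fallback=True)
    best = int(np.nanargmin(np.where(np.isfinite(objective), objective, np.inf)))
    best_P, best_score = float(grid[best]), float(scores[best])

    refined = False
    if refine and len(grid) > 2:
        lo = float(grid[max(best - 1, 0)])
        hi = float(grid[min(best + 1, len(grid) - 1)])
        if hi > lo:
            l_, mm, rn = table.length, m, renormalize

            def f(P: float) -> float:
                P = min(max(P, 0.0), MAX_BANDWIDTH - 1e-12)
                spec = KernelSpec(P=P, l=l_, m=mm, renormalize=rn)
                val = (
                    lscv_score(table, spec, space)
                    if method == "lscv"
                    else lcv_score(table, spec)
                )
                return sign * val if math.isfinite(val) else math.inf

            res = minimize_scalar(
                f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-7}
            )
            if math.isfinite(res.fun) and res.fun < sign * best_score:
                best_P, best_score = float(res.x), float(sign * res.fun)
                refined = True
    return CVResult(method, grid, scores, best_P, best_score, refined=refined)


class AlleleFrequencyKDE:
    """Kernel density model of allele frequency over sequence space.

    Parameters
    ----------
    data : Alignment, AlleleTable, or iterable of equal-length sequences.
    mutation_number : truncation radius m of the kernel; 0 reduces the
        model to plain counting.
    renormalize : rescale the truncated kernel so each sample contributes
        total mass exactly 1/n (keeps the estimate a proper mass function).
    space : a pre-built DistanceSpace or SequenceSpace to estimate on; by
        default the distance space of the observed alleles is built lazily.

    Examples
    --------
    >>> model = AlleleFrequencyKDE(["AA", "AA", "AA", "AT", "AT", "AT"],
    ...                            mutation_number=2)
    >>> res = model.fit(method="lscv")
    >>> round(res.estimate.total_mass, 12)
    1.0
    """

    def __init__(
        self,
        data,
        mutation_number: int = 1,
        *,
        renormalize: bool = True,
        space=None,
        guard: int = DEFAULT_GUARD,
    ) -> None:
        if isinstance(data, AlleleTable):
            self.table = data
        elif isinstance(data, Alignment):
            self.table = tally_alleles(data)
        else:
            seqs = tuple(data)
            aln = Alignment(ids=tuple(str(i) for i in range(len(seqs))), sequences=seqs)
            self.table = tally_alleles(aln)
        self.mutation_number = int(mutation_number)
        if not 0 <= self.mutation_number <= self.table.length:
            raise ValueError(
                f"mutation number {mutation_number} out of range "
                f"[0, {self.table.length}]"
            )
        self.renormalize = renormalize
        self.guard = guard
        self._space = space
        if space is not None:
            spec = KernelSpec(
                P=0.0, l=self.table.length, m=self.mutation_number,
                renormalize=renormalize,
            )
            _check_compat(self.table, spec, space)

    @classmethod
    def from_fasta(cls, path, mutation_number: int = 1, **kwargs) -> "AlleleFrequencyKDE":
        return cls(read_alignment(path), mutation_number=mutation_number, **kwargs)

    @cached_property
    def space(self):
        if self._space is None:
            self._space = build_distance_space(
                self.table.alleles, self.mutation_number, guard=self.guard
            )
        return self._space

    def fit(
        self,
        method: str = "lscv",
        *,
        bandwidth: float | None = None,
        grid: np.ndarray | None = None,
        refine: bool = True,
    ) -> "KDEResults":
        """Select the bandwidth (unless given) and estimate frequencies.

        ``method`` is "lscv", "lcv" or "none" (the latter requires an
        explicit ``bandwidth``). With mutation number 0 the kernel is a
        point mass and no selection is performed.
        """
        cv = None
        if self.mutation_number == 0:
            bandwidth = 0.0
        elif bandwidth is None:
            if method.lower() == "none":
                raise ValueError("method='none' requires an explicit bandwidth")
            cv = select_bandwidth(
                self.table,
                self.mutation_number,
                method,
                grid=grid,
                renormalize=self.renormalize,
                space=self.space if isinstance(self.space, DistanceSpace) else None,
                refine=refine,
            )
            bandwidth = cv.selected_P
        spec = KernelSpec(
            P=float(bandwidth),
            l=self.table.length,
            m=self.mutation_number,
            renormalize=self.renormalize,
        )
        est = estimate_frequencies(self.table, spec, self.space)
        return KDEResults(model=self, spec=spec, cv=cv, estimate=est)


@dataclass
class KDEResults:
    """Fitted allele-frequency estimate with its bandwidth and diagnostics."""

    model: AlleleFrequencyKDE
    spec: KernelSpec
    cv: CVResult | None
    estimate: FrequencyEstimate

    @property
    def bandwidth(self) -> float:
        return self.spec.P

    def nucleotide_diversity(self):
        """Approximate nucleotide diversity of the fitted estimate."""
        from .diversity import nucleotide_diversity_approx

        return nucleotide_diversity_approx(self.estimate)

    def concordance(self, population) -> float:
        """Concordance rate against a known population (Alignment or freq map)."""
        from .diversity import concordance_rate

        if isinstance(population, Alignment):
            population = tally_alleles(population).frequencies
        elif isinstance(population, AlleleTable):
            population = population.frequencies
        return concordance_rate(population, self.estimate)

    def to_frame(self):
        return self.estimate.to_frame()

    def summary(self) -> str:
        table = self.model.table
        space = self.estimate.space
        ncoord = len(space) if isinstance(space, DistanceSpace) else 4**space.l
        kind = "distance" if isinstance(space, DistanceSpace) else "sequence"
        lines = [
            "        Allele-frequency KDE results",
            "=" * 46,
            f"{'Sample size (n)':<28}{table.n:>18}",
            f"{'Distinct alleles (k)':<28}{table.k:>18}",
            f"{'Sequence length (l)':<28}{table.length:>18}",
            f"{'Mutation number (m)':<28}{self.spec.m:>18}",
            f"{'Space':<28}{f'{kind} ({ncoord})':>18}",
            f"{'Renormalized kernel':<28}{str(self.spec.renormalize):>18}",
            f"{'Bandwidth P':<28}{self.bandwidth:>18.8g}",
        ]
        if self.cv is not None:
            lines += [
                f"{'Selection method':<28}{self.cv.method.upper():>18}",
                f"{'Criterion value':<28}{self.cv.selected_score:>18.8g}",
                f"{'LCV fallback to P=0':<28}{str(self.cv.fallback):>18}",
            ]
        else:
            lines.append(f"{'Selection method':<28}{'fixed':>18}")
        lines += [
            f"{'Total estimated mass':<28}{self.estimate.total_mass:>18.12f}",
            "-" * 46,
            "Detected-allele frequencies:",
        ]
        for j, (allele, count) in enumerate(zip(table.alleles, table.counts)):
            shown = allele if len(allele) <= 18 else allele[:15] + "..."
            freq = (
                self.estimate.mass[j]
                if isinstance(space, DistanceSpace)
                else self.estimate.sequence_mass(allele)
            )
            lines.append(f"  {shown:<20}{count:>6}  {freq:>14.8f}")
        lines.append("=" * 46)
        return "\n".join(lines)
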