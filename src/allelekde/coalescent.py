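"""Single-deme coalescent simulator with finite-sites Jukes-Cantor mutation.

Generates a synthetic population of equal-length sequences: a standard
n-coalescent genealogy (exponential waiting times with rate C(k, 2) while k
lineages remain, in coalescent units of 2N generations), then mutations
dropped on each branch with the same Jukes-Cantor engine that defines the
KDE kernel — for a branch of b generations each site independently ends in
one specific other base with probability P(b, mu), applied in a single
draw per branch (the multi-hit chain collapsed exactly, no per-generation
looping). No recombination, demography, migration or selection.

All randomness flows from one seed: callers pass either a seed or a numpy
Generator; composite drivers split seeds with numpy SeedSequence spawning.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .io import Alignment, decode_sequence
from .kernel import total_change_probability


def as_rng(rng=None, seed=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


@dataclass
class Genealogy:
    """Binary coalescent tree: nodes 0..2n-2, leaves 0..n-1, root last.

    ``time`` holds node ages in generations (0 for leaves); ``parent`` is -1
    at the root; ``children`` records each internal node's merge pair in the
    order drawn.
    """

    n_leaves: int
    parent: np.ndarray
    time: np.ndarray
    children: dict[int, tuple[int, int]]

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def branch_length(self, node: int) -> float:
        """Length of the branch above `node`, in generations."""
        p = self.parent[node]
        if p < 0:
            return 0.0
        return float(self.time[p] - self.time[node])

    def tmrca(self, i: int, j: int) -> float:
        """Age of the most recent common ancestor of leaves i and j."""
        anc = set()
        node = i
        while node >= 0:
            anc.add(node)
            node = int(self.parent[node])
        node = j
        while node not in anc:
            node = int(self.parent[node])
        return float(self.time[node])

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if node < self.n_leaves:
                label = f"seq_{node + 1}"
            else:
                a, b = self.children[node]
                label = f"({render(a)},{render(b)})"
            return f"{label}:{self.branch_length(node):.6f}"

        a, b = self.children[self.root]
        return f"({render(a)},{render(b)});"


@dataclass
class SimPopulation:
    """A simulated population: sequences, their genealogy, mutations per branch."""

    alignment: Alignment
    genealogy: Genealogy
    mutations: np.ndarray  # observed site changes on the branch above each node


def simulate_genealogy(
    n_leaves: int, *, population_size: int | None = None, rng=None, seed=None
) -> Genealogy:
    """Random n-coalescent genealogy with branch lengths in generations.

    The continuous coalescent is scaled by 2N generations per coalescent
    time unit, so a pair of lineages finds its common ancestor after 2N
    generations in expectation. By default the population *is* the sampled
    lineages (N = n_leaves); pass ``population_size`` to decouple the
    timescale from the number of sequences.
    """
    if n_leaves < 2:
        raise ValueError("a genealogy needs at least 2 leaves")
    N = population_size if population_size is not None else n_leaves
    rng = as_rng(rng, seed)
    n_nodes = 2 * n_leaves - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    children: dict[int, tuple[int, int]] = {}
    active = list(range(n_leaves))
    t = 0.0
    nxt = n_leaves
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / comb(k, 2)) * 2.0 * N
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        children[nxt] = (a, b)
        # replace the first merged lineage, drop the second
        active[i] = nxt
        active.pop(j)
        nxt += 1
    return Genealogy(n_leaves=n_leaves, parent=parent, time=time, children=children)


def mutate_sequences(
    genealogy: Genealogy, l: int, mu: float, *, rng=None, seed=None
) -> SimPopulation:
    """Drop Jukes-Cantor mutations on a genealogy and emit leaf sequences.

    The root sequence is uniform over {A, C, G, T}^l; on a branch of b
    generations each site changes with total probability 3 P(b, mu), the
    new base uniform over the three alternatives.
    """
    if l < 1:
        raise ValueError("sequence length must be >= 1")
    rng = as_rng(rng, seed)
    n = genealogy.n_leaves
    seqs: dict[int, np.ndarray] = {}
    mutations = np.zeros(2 * n - 1, dtype=np.int64)
    root = genealogy.root
    seqs[root] = rng.integers(0, 4, size=l, dtype=np.uint8)
    stack = [root]
    while stack:
        node = stack.pop()
        if node < n:
            continue
        for child in genealogy.children[node]:
            b = genealogy.branch_length(child)
            p_change = total_change_probability(b, mu)
            seq = seqs[node].copy()
            mask = rng.random(l) < p_change
            n_mut = int(mask.sum())
            if n_mut:
                seq[mask] = (seq[mask] + rng.integers(1, 4, size=n_mut, dtype=np.uint8)) % 4
            seqs[child] = seq
            mutations[child] = n_mut
            stack.append(child)
    ids = tuple(f"seq_{i + 1}" for i in range(n))
    sequences = tuple(decode_sequence(seqs[i]) for i in range(n))
    return SimPopulation(
        alignment=Alignment(ids=ids, sequences=sequences),
        genealogy=genealogy,
        mutations=mutations,
    )


def simulate_population(
    n: int, l: int, mu: float, *, population_size: int | None = None, rng=None, seed=None
) -> SimPopulation:
    """Convenience: genealogy + mutations from one random stream."""
    rng = as_rng(rng, seed)
    gen = simulate_genealogy(n, population_size=population_size, rng=rng)
    return mutate_sequences(gen, l, mu, rng=rng)


def resample(population: Alignment, k: int, *, rng=None, seed=None) -> Alignment:
    """Draw k records uniformly without replacement (seeded)."""
    n = len(population)
    if not 1 <= k <= n:
        raise ValueError(f"sample size {k} out of range [1, {n}]")
    rng = as_rng(rng, seed)
    idx = rng.choice(n, size=k, replace=False)
    return Alignment(
        ids=tuple(population.ids[i] for i in idx),
        sequences=tuple(population.sequences[i] for i in idx),
    )
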