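"""Nucleotide sequence space and its distance-space compression.

The full sequence space of length-l sequences has 4^l coordinates and can
only be materialized for tiny l (a configurable guard refuses anything
larger). The *distance space* compresses it: each detected allele gets its
own coordinate, and every other sequence is recorded only by its vector of
Hamming distances to the detected alleles. Truncating the kernel at
mutation number m means sequences farther than m from every detected allele
carry no mass and are dropped entirely, and distance entries of undetected
coordinates that exceed m are censored to infinity. Several sequences can
share one coordinate; that count is the coordinate's *multiplicity*.

Detected alleles keep their full, uncensored distance vectors (these
distances are known exactly from the data); censoring applies to undetected
coordinates only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb, inf

import numpy as np

from .errors import CapacityError
from .io import BASES, decode_sequence, encode_sequences, hamming_matrix

INF = inf  # distance entry censored to "farther than the mutation number"

DEFAULT_GUARD = 4**10  # largest sequence space that may be materialized
DEFAULT_WORK_GUARD = 20_000_000  # neighborhood-enumeration work ceiling


@dataclass(frozen=True)
class SequenceSpace:
    """The set of all 4^l sequences of length l, in lexicographic order."""

    l: int
    guard: int = DEFAULT_GUARD

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError(f"sequence length must be >= 1, got {self.l}")
        if 4**self.l > self.guard:
            raise CapacityError(
                f"sequence space 4^{self.l} exceeds the materialization guard "
                f"of {self.guard} coordinates"
            )

    def __len__(self) -> int:
        return 4**self.l

    def __iter__(self):
        return self.sequences()

    def sequences(self):
        """Yield all sequences in lexicographic order (A < C < G < T)."""
        for tup in product(BASES, repeat=self.l):
            yield "".join(tup)

    def index_of(self, seq: str) -> int:
        """Rank of `seq` in the lexicographic enumeration."""
        idx = 0
        for c in seq:
            idx = idx * 4 + BASES.index(c)
        return idx


def build_sequence_space(l: int, guard: int = DEFAULT_GUARD) -> SequenceSpace:
    return SequenceSpace(l=l, guard=guard)


# A distance-space coordinate is stored sparsely as a sorted tuple of
# (detected-allele index, distance) pairs covering its finite entries <= m;
# all omitted entries are censored (INF).
SparseKey = tuple[tuple[int, int], ...]


class DistanceSpace:
    """Compressed coordinate system over the detected alleles.

    Attributes
    ----------
    detected : tuple of the k distinct detected alleles (input order).
    distance_matrix : (k, k) Hamming distances between detected alleles.
    m : the mutation number (truncation radius).
    l : sequence length.
    multiplicity : number of distinct sequences realizing each coordinate.
    members : per-coordinate lists of member sequences, when retained.

    Coordinates are canonically ordered: detected alleles first (input
    order), then undetected coordinates lexicographically with INF last.
    """

    def __init__(
        self,
        detected: tuple[str, ...],
        distance_matrix: np.ndarray,
        m: int,
        undetected_keys: list[SparseKey],
        undetected_mult: list[int],
        members: list[list[str]] | None = None,
    ) -> None:
        self.detected = detected
        self.distance_matrix = distance_matrix
        self.m = int(m)
        self.l = len(detected[0])
        self.k = len(detected)
        self._undetected_keys = undetected_keys
        self.multiplicity = np.concatenate(
            [np.ones(self.k, dtype=np.int64), np.asarray(undetected_mult, dtype=np.int64)]
        )
        self.members = members
        self._coords: list[tuple] | None = None
        self._index: dict[tuple, int] | None = None

    def __len__(self) -> int:
        return self.k + len(self._undetected_keys)

    @property
    def n_undetected(self) -> int:
        return len(self._undetected_keys)

    def finite_entries(self, i: int) -> SparseKey:
        """Mass-bearing entries (allele index, distance <= m) of coordinate i."""
        if i < self.k:
            row = self.distance_matrix[i]
            return tuple((j, int(row[j])) for j in range(self.k) if row[j] <= self.m)
        return self._undetected_keys[i - self.k]

    def expand(self, i: int) -> tuple:
        """Coordinate i as a full k-tuple (ints; INF for censored entries)."""
        if i < self.k:
            return tuple(int(d) for d in self.distance_matrix[i])
        vec = [INF] * self.k
        for j, d in self._undetected_keys[i - self.k]:
            vec[j] = d
        return tuple(vec)

    def coordinates(self) -> list[tuple]:
        """All coordinates as full k-tuples, in canonical order."""
        if self._coords is None:
            self._coords = [self.expand(i) for i in range(len(self))]
        return self._coords

    def index_of(self, coord: tuple) -> int:
        """Index of a coordinate given as a full k-tuple; LookupError if absent."""
        if self._index is None:
            self._index = {c: i for i, c in enumerate(self.coordinates())}
        key = tuple(int(d) if d != INF else INF for d in coord)
        try:
            return self._index[key]
        except KeyError:
            raise LookupError(f"coordinate {coord} is not in the distance space")

    def locate_sequence(self, seq: str) -> int | None:
        """Index of the coordinate holding `seq`, or None if outside the space."""
        dists = hamming_matrix([seq], self.detected)[0]
        dmin = int(dists.min())
        if dmin > self.m:
            return None
        hit = np.flatnonzero(dists == 0)
        if hit.size:
            return int(hit[0])
        key = tuple((int(j), int(dists[j])) for j in np.flatnonzero(dists <= self.m))
        return self.index_of_key(key)

    def index_of_key(self, key: SparseKey) -> int:
        if not hasattr(self, "_key_index"):
            self._key_index = {k: self.k + i for i, k in enumerate(self._undetected_keys)}
        try:
            return self._key_index[key]
        except KeyError:
            raise LookupError(f"coordinate key {key} is not in the distance space")

    def to_frame(self):
        """Distance-space dump: one row per coordinate, d_1..d_k + multiplicity."""
        import pandas as pd

        rows = []
        for i in range(len(self)):
            vec = self.expand(i)
            row = {f"d_{j + 1}": ("Inf" if d == INF else int(d)) for j, d in enumerate(vec)}
            row["multiplicity"] = int(self.multiplicity[i])
            rows.append(row)
        return pd.DataFrame(rows)


def _neighborhood_work(l: int, m: int, k: int) -> int:
    return k * sum(comb(l, r) * 3**r for r in range(1, m + 1))


def build_distance_space(
    detected,
    m: int,
    *,
    strategy: str = "auto",
    guard: int = DEFAULT_GUARD,
    work_guard: int = DEFAULT_WORK_GUARD,
    keep_members: bool = False,
) -> DistanceSpace:
    """Construct the distance space of the detected alleles at mutation number m.

    The realizable coordinates are found constructively: either by brute
    enumeration of the full 4^l sequence space (small l only, guarded) or by
    enumeration of all mutated-position patterns within distance m around
    each detected allele (polynomial in l for small m). Both routes yield
    identical coordinates and multiplicities.

    Parameters
    ----------
    detected : distinct, equal-length alleles (order is preserved).
    m : mutation number (0 gives exactly the detected alleles).
    strategy : "auto" (cost-based), "enumerate" (4^l), or "neighborhood".
    keep_members : retain per-coordinate member sequences (needed for
        exact all-terms diversity; memory grows with the space).
    """
    detected = tuple(detected)
    if len(set(detected)) != len(detected):
        raise ValueError("detected alleles must be pairwise distinct")
    l = len(detected[0])
    if any(len(a) != l for a in detected):
        raise ValueError("detected alleles must share one length")
    if not 0 <= m <= l:
        raise ValueError(f"mutation number m={m} must lie in [0, l={l}]")
    k = len(detected)
    D = hamming_matrix(detected)

    if m == 0:
        members = [[a] for a in detected] if keep_members else None
        return DistanceSpace(detected, D, m, [], [], members)

    enum_cost = 4**l
    neigh_cost = _neighborhood_work(l, m, k)
    if strategy == "auto":
        if enum_cost <= min(guard, neigh_cost):
            strategy = "enumerate"
        elif neigh_cost <= work_guard:
            strategy = "neighborhood"
        else:
            raise CapacityError(
                f"distance space too large: enumeration needs {enum_cost} > guard "
                f"{guard} and neighborhood search needs {neigh_cost} > {work_guard}"
            )
    if strategy == "enumerate" and enum_cost > guard:
        raise CapacityError(
            f"sequence space 4^{l} exceeds the materialization guard of {guard}"
        )
    if strategy == "neighborhood" and neigh_cost > work_guard:
        raise CapacityError(
            f"neighborhood enumeration needs {neigh_cost} work units > {work_guard}"
        )

    if strategy == "enumerate":
        found = _coords_by_enumeration(detected, D, m, keep_members)
    elif strategy == "neighborhood":
        found = _coords_by_neighborhood(detected, D, m, keep_members)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    keys = sorted(found, key=lambda key: _sort_vec(key, k))
    mult = [found[key][0] for key in keys]
    members = None
    if keep_members:
        members = [[a] for a in detected] + [found[key][1] for key in keys]
    return DistanceSpace(detected, D, m, keys, mult, members)


def _sort_vec(key: SparseKey, k: int) -> tuple:
    vec = [INF] * k
    for j, d in key:
        vec[j] = d
    return tuple(vec)


def _coords_by_enumeration(detected, D, m, keep_members):
    """Reference route: scan all 4^l sequences (l small, pre-guarded)."""
    l = len(detected[0])
    M = encode_sequences(detected)
    all_codes = np.array(list(product(range(4), repeat=l)), dtype=np.uint8)
    dists = (all_codes[:, None, :] != M[None, :, :]).sum(axis=2)
    found: dict[SparseKey, list] = {}
    for row, codes in zip(dists, all_codes):
        dmin = row.min()
        if dmin > m or dmin == 0:
            continue  # outside the space, or a detected allele
        key = tuple((int(j), int(row[j])) for j in np.flatnonzero(row <= m))
        slot = found.setdefault(key, [0, []])
        slot[0] += 1
        if keep_members:
            slot[1].append(decode_sequence(codes))
    return found


def _coords_by_neighborhood(detected, D, m, keep_members):
    """Enumerate mutated-position patterns within distance m of each allele.

    A sequence at distance r <= m from anchor allele i is the anchor with r
    positions changed to specific other bases. Changing position p of the
    anchor to base b shifts its distance to detected allele j by +1 if
    allele j agreed with the anchor at p, by -1 if b is exactly allele j's
    base there, and by 0 otherwise; distances to all detected alleles are
    therefore updated incrementally, never recomputed from scratch.
    Sequences are deduplicated across anchors by their exact identity.
    """
    l = len(detected[0])
    k = len(detected)
    M = encode_sequences(detected)
    found: dict[SparseKey, list] = {}
    seen: set[bytes] = set()
    for a in detected:
        seen.add(a.encode("ascii"))

    for i in range(k):
        anchor = M[i]
        base_row = D[i].astype(np.int64)
        # delta[p, c, j]: distance shift to allele j when position p of the
        # anchor is changed to its c-th alternative base
        alts = np.empty((l, 3), dtype=np.uint8)
        for p in range(l):
            alts[p] = [b for b in range(4) if b != anchor[p]]
        agree = M == anchor[None, :]  # (k, l)
        delta = np.empty((l, 3, k), dtype=np.int8)
        for c in range(3):
            hit = M.T == alts[:, c][:, None]  # (l, k): allele j's base == alt
            delta[:, c, :] = np.where(agree.T, 1, np.where(hit, -1, 0))

        anchor_bytes = bytearray(decode_sequence(anchor).encode("ascii"))
        base_letters = [BASES[b].encode("ascii")[0] for b in range(4)]

        for r in range(1, m + 1):
            for positions in combinations(range(l), r):
                for choices in product(range(3), repeat=r):
                    buf = bytearray(anchor_bytes)
                    for p, c in zip(positions, choices):
                        buf[p] = base_letters[alts[p, c]]
                    key_bytes = bytes(buf)
                    if key_bytes in seen:
                        continue
                    seen.add(key_bytes)
                    row = base_row.copy()
                    for p, c in zip(positions, choices):
                        row += delta[p, c]
                    if row.min() == 0:  # pragma: no cover - detected are pre-seen
                        continue
                    key = tuple(
                        (int(j), int(row[j])) for j in np.flatnonzero(row <= m)
                    )
                    slot = found.setdefault(key, [0, []])
                    slot[0] += 1
                    if keep_members:
                        slot[1].append(key_bytes.decode("ascii"))
    return found


def coordinate_multiplicity(space: DistanceSpace, coord: tuple) -> int:
    """Exact number of distinct sequences realizing `coord` (full k-tuple)."""
    return int(space.multiplicity[space.index_of(coord)])


def joint_distance_counts(d: int, l: int, x: int) -> dict[int, int]:
    """Counts of sequences at distance x from allele A by their distance to B.

    A and B are two alleles at Hamming distance d. Every sequence at
    distance exactly x from A arises by changing x positions of A: a change
    at one of the l-d positions where A and B agree shifts the distance to B
    by +1 (3 base choices); a change at one of the d differing positions
    shifts it by -1 if the new base is B's base (1 choice) or by 0 otherwise
    (2 choices). Convolving these cases gives, for each possible distance y
    to B, the exact number of such sequences; the counts total C(l, x) 3^x.
    """
    if not 0 <= d <= l:
        raise ValueError(f"d={d} out of range [0, {l}]")
    if not 0 <= x <= l:
        raise ValueError(f"x={x} out of range [0, {l}]")
    counts: dict[int, int] = {}
    for i in range(max(0, x - d), min(l - d, x) + 1):  # changed agreeing positions
        rem = x - i  # changed differing positions
        if rem > d:
            continue
        for j1 in range(rem + 1):  # of those, changed exactly to B's base
            j2 = rem - j1
            y = d - j1 + i
            cnt = comb(l - d, i) * 3**i * comb(d, rem) * comb(rem, j1) * 2**j2
            counts[y] = counts.get(y, 0) + cnt
    return counts


def expected_distance_beyond(d: int, l: int, x: int, m: int) -> float:
    """Mean distance to B over sequences at distance x from A with distance-to-B > m.

    Used to recover the distance term of coordinates whose entry for an
    allele was censored to INF: the sequences behind such a coordinate sit
    at a known distance x from a finite "anchor" allele A and farther than m
    from B, so their distances to B are distributed per
    :func:`joint_distance_counts` restricted to y > m. Returns NaN when no
    sequence at distance x from A can be farther than m from B (a censored
    entry can then never occur).
    """
    counts = joint_distance_counts(d, l, x)
    num = sum(y * c for y, c in counts.items() if y > m)
    den = sum(c for y, c in counts.items() if y > m)
    if den == 0:
        return float("nan")
    return num / den
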