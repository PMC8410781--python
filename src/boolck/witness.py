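"""Minimal witness sets, the distinguishing-node variant, teaching dimension.

A witness set for a member of a family of distinct binary n-tuples is a set
of coordinates that distinguishes it from every other member.  Finding a
minimal one is a minimum hitting-set problem over the per-pair difference
sets, which is NP-hard, so the exact solver enumerates candidate subsets by
increasing size under a budget and falls back to a greedy upper bound.

Attractors of Boolean networks enter through two cycle rules:

* distinguishing a target from a *cycle*: any coordinate at which the cycle
  is non-constant always distinguishes (the cycle visits the opposite value);
* a *cyclic target* may only use its own constant coordinates, since
  distinguishing nodes must be pinned to static values.  A witness may then
  fail to exist.

When both members are cycles sharing constant coordinates the two rules are
applied simultaneously (their conjunction); see docs/methods.md.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd

from .attractors import Attractor

__all__ = [
    "FamilyMember",
    "VectorFamily",
    "WitnessResult",
    "difference_coordinates",
    "minimal_witness",
    "mean_min_witness",
    "teaching_dimension",
    "read_vector_family_csv",
]

DEFAULT_BUDGET = 10_000_000


@dataclass(frozen=True)
class FamilyMember:
    """One tuple (or attractor) of a vector family.

    ``values`` holds the value at each coordinate where ``constant`` is True;
    entries at non-constant coordinates are ignored.  Plain vectors are
    constant everywhere.
    """

    values: tuple[int, ...]
    constant: tuple[bool, ...]

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def is_cyclic(self) -> bool:
        return not all(self.constant)

    def key(self):
        return tuple(v if c else None for v, c in zip(self.values, self.constant))

    @classmethod
    def from_vector(cls, bits) -> "FamilyMember":
        bits = tuple(int(b) for b in bits)
        if any(b not in (0, 1) for b in bits):
            raise ValueError("vector entries must be 0/1")
        return cls(bits, (True,) * len(bits))

    @classmethod
    def from_attractor(cls, attractor: Attractor, n: int) -> "FamilyMember":
        mask, values = attractor.constant_profile(n)
        return cls(tuple((values >> i) & 1 for i in range(n)),
                   tuple(bool((mask >> i) & 1) for i in range(n)))


class VectorFamily:
    """A family of r distinct binary n-tuples (or attractor profiles).

    Plain vector families must be pairwise distinct.  Families built from
    attractors may contain *cycles with identical constant profiles*: such
    pairs cannot be separated by any static pinning, so their witnesses are
    reported nonexistent rather than rejected up front.
    """

    def __init__(self, members: list[FamilyMember], n: int | None = None,
                 _check_distinct: bool = True):
        if not members:
            raise ValueError("family must contain at least one member")
        self.members = list(members)
        self.n = n if n is not None else members[0].n
        if any(m.n != self.n for m in self.members):
            raise ValueError("all members must have the same length")
        if _check_distinct:
            keys = [m.key() for m in self.members]
            if len(set(keys)) != len(keys):
                raise ValueError("family members must be pairwise distinct")

    @property
    def r(self) -> int:
        return len(self.members)

    @classmethod
    def from_vectors(cls, vectors) -> "VectorFamily":
        return cls([FamilyMember.from_vector(v) for v in vectors])

    @classmethod
    def from_attractors(cls, attractors: list[Attractor], n: int) -> "VectorFamily":
        if len({a.states for a in attractors}) != len(attractors):
            raise ValueError("attractors must be pairwise distinct")
        return cls([FamilyMember.from_attractor(a, n) for a in attractors],
                   n=n, _check_distinct=False)


@dataclass(frozen=True)
class WitnessResult:
    """Outcome of a minimal-witness search for one family member."""

    index: int
    witness: tuple[int, ...] | None
    size: int | None
    status: str  # exact | upper_bound | nonexistent

    @property
    def exists(self) -> bool:
        return self.status != "nonexistent"


def difference_coordinates(target: FamilyMember, other: FamilyMember) -> frozenset[int]:
    """Coordinates at which pinning the target's value excludes ``other``.

    Restricted to the target's constant coordinates.  A coordinate qualifies
    if ``other`` is non-constant there, or constant with the opposite value.
    """
    out = []
    for j in range(target.n):
        if not target.constant[j]:
            continue
        if not other.constant[j] or other.values[j] != target.values[j]:
            out.append(j)
    return frozenset(out)


def _difference_masks(fam: VectorFamily, i: int) -> list[int] | None:
    target = fam.members[i]
    masks = []
    for j, other in enumerate(fam.members):
        if j == i:
            continue
        diff = difference_coordinates(target, other)
        if not diff:
            return None
        m = 0
        for c in diff:
            m |= 1 << c
        masks.append(m)
    return masks


def _greedy_hitting_set(masks: list[int], n: int) -> tuple[int, ...]:
    remaining = list(masks)
    chosen = []
    while remaining:
        best, best_cover = None, -1
        for c in range(n):
            bit = 1 << c
            cover = sum(1 for m in remaining if m & bit)
            if cover > best_cover:
                best, best_cover = c, cover
        chosen.append(best)
        bit = 1 << best
        remaining = [m for m in remaining if not m & bit]
    return tuple(sorted(chosen))


def minimal_witness(fam: VectorFamily, i: int,
                    budget: int = DEFAULT_BUDGET) -> WitnessResult:
    """Exact minimal witness for member ``i`` by hitting-set enumeration.

    Candidate subsets are drawn from the union of the difference sets only
    (coordinates outside it can never help) and enumerated by increasing
    size, ties broken lexicographically on the sorted coordinate tuple, so
    the reported witness is deterministic.  ``budget`` caps the number of
    subset tests; exceeding it returns a greedy upper bound flagged
    ``upper_bound``.
    """
    if not 0 <= i < fam.r:
        raise IndexError("member index out of range")
    if fam.r == 1:
        return WitnessResult(i, (), 0, "exact")
    masks = _difference_masks(fam, i)
    if masks is None:
        return WitnessResult(i, None, None, "nonexistent")
    universe = 0
    for m in masks:
        universe |= m
    coords = [c for c in range(fam.n) if (universe >> c) & 1]
    if fam.n <= 62:
        hit = _search_vectorized(masks, coords, budget)
    else:
        hit = _search_scalar(masks, coords, budget)
    if hit is None:
        w = _greedy_hitting_set(masks, fam.n)
        return WitnessResult(i, w, len(w), "upper_bound")
    return WitnessResult(i, hit, len(hit), "exact")


def _search_scalar(masks, coords, budget):
    """Reference subset enumeration (arbitrary width coordinates)."""
    tests = 0
    for k in range(1, len(coords) + 1):
        for combo in itertools.combinations(coords, k):
            tests += 1
            if tests > budget:
                return None
            sub = 0
            for c in combo:
                sub |= 1 << c
            if all(m & sub for m in masks):
                return combo
    raise AssertionError("unreachable: full coordinate set always hits")


def _search_vectorized(masks, coords, budget, chunk=4096):
    """Same enumeration order as `_search_scalar`, evaluated in numpy
    batches (int64 bitmasks); the first hit in order is returned, so
    results and tie-breaking are identical."""
    marr = np.asarray(masks, dtype=np.int64)
    tests = 0
    for k in range(1, len(coords) + 1):
        gen = itertools.combinations(coords, k)
        while True:
            batch = list(itertools.islice(gen, chunk))
            if not batch:
                break
            if tests >= budget:
                return None
            if tests + len(batch) > budget:
                batch = batch[: budget - tests]
            tests += len(batch)
            subs = np.array([_mask_of(c) for c in batch], dtype=np.int64)
            ok = np.ones(len(batch), dtype=bool)
            for m in marr:
                ok &= (subs & m) != 0
                if not ok.any():
                    break
            if ok.any():
                return batch[int(np.argmax(ok))]
    raise AssertionError("unreachable: full coordinate set always hits")


def _mask_of(combo) -> int:
    sub = 0
    for c in combo:
        sub |= 1 << c
    return sub


def all_minimal_witnesses(fam: VectorFamily, i: int,
                          budget: int = DEFAULT_BUDGET) -> list[WitnessResult]:
    """Every minimal-size witness for member ``i``, in lexicographic order."""
    first = minimal_witness(fam, i, budget=budget)
    if first.status != "exact" or first.size == 0:
        return [first]
    masks = _difference_masks(fam, i)
    universe = 0
    for m in masks:
        universe |= m
    coords = [c for c in range(fam.n) if (universe >> c) & 1]
    out = []
    for combo in itertools.combinations(coords, first.size):
        sub = 0
        for c in combo:
            sub |= 1 << c
        if all(m & sub for m in masks):
            out.append(WitnessResult(i, combo, first.size, "exact"))
    return out


def minimal_witnesses(fam: VectorFamily,
                      budget: int = DEFAULT_BUDGET) -> list[WitnessResult]:
    """Minimal witness for every member of the family."""
    return [minimal_witness(fam, i, budget=budget) for i in range(fam.r)]


def mean_min_witness(fam: VectorFamily, budget: int = DEFAULT_BUDGET,
                     allow_bounds: bool = False,
                     results: list[WitnessResult] | None = None) -> float:
    """Average minimal witness size over members whose witness exists.

    Raises if any member's search hit the budget, unless ``allow_bounds``
    accepts the greedy sizes (the mean is then itself an upper bound).
    """
    if results is None:
        results = minimal_witnesses(fam, budget=budget)
    if not allow_bounds and any(r.status == "upper_bound" for r in results):
        raise RuntimeError(
            "budget exhausted for some members; pass allow_bounds=True to "
            "accept an upper-bound mean")
    sizes = [r.size for r in results if r.exists]
    if not sizes:
        raise ValueError("no member has an existing witness")
    return sum(sizes) / len(sizes)


def teaching_dimension(fam: VectorFamily, budget: int = DEFAULT_BUDGET) -> int:
    """Largest exact minimal witness size over the family."""
    results = minimal_witnesses(fam, budget=budget)
    if any(r.status == "upper_bound" for r in results):
        raise RuntimeError("budget exhausted; teaching dimension undetermined")
    sizes = [r.size for r in results if r.exists]
    if not sizes:
        raise ValueError("no member has an existing witness")
    return max(sizes)


def read_vector_family_csv(text_or_path) -> VectorFamily:
    """Read a vector family from CSV: one row per tuple, 0/1 cells, optional
    leading id column (any non-binary first column is treated as ids)."""
    if isinstance(text_or_path, str) and "\n" in text_or_path:
        df = pd.read_csv(StringIO(text_or_path), header=None)
    else:
        df = pd.read_csv(text_or_path, header=None)
    first = df.iloc[:, 0]
    if not set(pd.unique(first)).issubset({0, 1, "0", "1"}):
        df = df.iloc[:, 1:]
    vectors = df.astype(int).to_numpy().tolist()
    return VectorFamily.from_vectors(vectors)
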