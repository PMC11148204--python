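"""Modularizations and their equality index sets.

A functional module is a set of observable components that interact
with the rest of the network only through one (possibly latent) binary
interface variable. A modularization is a family of such modules that
is flat (pairwise disjoint) or nested (pairwise disjoint-or-contained).
Each module forces groups of moment ratios to share a common value;
combining the groups of all modules by transitive merging yields a
partition of the ratio indices whose constrained sets define the null
hypothesis tested downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .estimators import ratio_count, vec_index

__all__ = [
    "FunctionalModule",
    "Modularization",
    "IndexSetFamily",
    "classify",
    "index_sets",
    "degrees_of_freedom",
    "enumerate_candidates",
    "linear_membership_family",
]


@dataclass(frozen=True)
class FunctionalModule:
    """Indices (1-based) of the observable components inside one module."""

    members: frozenset[int]
    linear: bool = False

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> tuple[int, ...]:
        return tuple(sorted(self.members))


@dataclass(frozen=True)
class Modularization:
    """A family of functional modules with a fixed reference component.

    ``kind`` distinguishes ordinary flat/nested families from the fully
    linear model, in which all non-reference components sum linearly
    into the reference and every above-diagonal moment ratio shares one
    value.
    """

    modules: frozenset[FunctionalModule]
    ref: int
    kind: str = "nested"  # flat | nested | linear_full
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "modules", frozenset(self.modules))

    @staticmethod
    def from_sets(sets, ref: int, kind: str = "nested", label: str = "") -> "Modularization":
        mods = frozenset(FunctionalModule(frozenset(s)) for s in sets)
        return Modularization(modules=mods, ref=ref, kind=kind, label=label)

    def sorted_modules(self) -> list[tuple[int, ...]]:
        return sorted((m.sorted_members() for m in self.modules), key=lambda t: (len(t), t))


@dataclass
class IndexSetFamily:
    """Partition of the ratio indices 1..d_x0 into equality sets.

    Sets of size >= 2 are equality constraints; singletons are
    unconstrained ratios kept so the family always covers every index.
    """

    sets: list[frozenset[int]]
    d_x0: int

    def __post_init__(self):
        covered: set[int] = set()
        for s in self.sets:
            if covered & s:
                raise ValueError("index sets must be disjoint")
            covered |= s
        if covered != set(range(1, self.d_x0 + 1)):
            raise ValueError("index sets must partition 1..d_x0")

    @property
    def d_x(self) -> int:
        return len(self.sets)

    def constrained_sets(self) -> list[frozenset[int]]:
        return [s for s in self.sets if len(s) > 1]


def _valid_module(members: frozenset[int], d: int) -> str | None:
    """Reason a module is invalid for ``d`` components, or None."""
    non_ref = set(range(1, d))
    if len(members) < 2:
        return "module smaller than 2 components"
    if d in members or not members <= non_ref:
        return "module contains the reference or an out-of-range component"
    if members == non_ref:
        return "module equals the full set of non-reference components"
    return None


def classify(m: Modularization, d: int) -> str:
    """Classify a modularization as ``flat``, ``nested`` or ``invalid``."""
    if m.kind == "linear_full":
        return "flat" if not m.modules else "invalid"
    for mod in m.modules:
        if _valid_module(mod.members, d) is not None:
            return "invalid"
    flat = True
    for a, b in itertools.combinations(m.modules, 2):
        sa, sb = a.members, b.members
        if sa & sb:
            flat = False
            if not (sa <= sb or sb <= sa):
                return "invalid"
    return "flat" if flat else "nested"


def index_sets(m: Modularization, d: int) -> IndexSetFamily:
    """Equality index sets of a modularization over the ratio indices.

    Each module S forces, for every non-reference component l outside S,
    the ratios {v(k, l) : k in S} to one common value. Constraints from
    different modules sharing an index are merged transitively
    (union-find); ratios under no constraint remain singletons. A linear
    module additionally ties together all above-diagonal ratios of its
    own submatrix; the fully linear model ties all ratio indices.
    """
    d_x0 = ratio_count(d)
    parent = list(range(d_x0 + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    def tie(indices: list[int]) -> None:
        for v in indices[1:]:
            union(indices[0], v)

    non_ref = range(1, d)
    groups: list[list[int]] = []
    for mod in m.modules:
        reason = _valid_module(mod.members, d)
        if reason is not None:
            raise ValueError(f"invalid module {sorted(mod.members)}: {reason}")
        for l in non_ref:
            if l in mod.members:
                continue
            groups.append(
                [vec_index(min(k, l), max(k, l), d) for k in sorted(mod.members)]
            )
        if mod.linear:
            groups.append(
                [
                    vec_index(k, l, d)
                    for k, l in itertools.combinations(sorted(mod.members), 2)
                ]
            )
    if m.kind == "linear_full":
        groups.append(list(range(1, d_x0 + 1)))
    for g in groups:
        tie(g)

    buckets: dict[int, set[int]] = {}
    for v in range(1, d_x0 + 1):
        buckets.setdefault(find(v), set()).add(v)
    sets = sorted((frozenset(s) for s in buckets.values()), key=lambda s: min(s))
    return IndexSetFamily(sets=sets, d_x0=d_x0)


def degrees_of_freedom(f: IndexSetFamily) -> float:
    """Shape parameter of the null gamma distribution: (d_x0 - d_x) / 2."""
    return 0.5 * (f.d_x0 - f.d_x)


def enumerate_candidates(
    d: int, include_linear: bool = False, max_d: int = 24
) -> list[Modularization]:
    """All flat/nested modularizations of ``d`` components with reference d.

    Modules have at least 2 members, never include the reference, never
    equal the full non-reference set, and are pairwise disjoint or
    nested. Candidates are returned in a fixed canonical order (by
    number of modules, then lexicographically by sorted member tuples)
    so labels are reproducible. For d = 5 there are exactly 25
    candidates, 26 with the fully linear model appended.
    """
    if d < 3:
        raise ValueError("need at least 3 components")
    if d > max_d:
        raise ValueError(f"enumeration capped at {max_d} components")
    non_ref = list(range(1, d))
    subsets = [
        frozenset(c)
        for size in range(2, d - 1)
        for c in itertools.combinations(non_ref, size)
    ]

    def compatible(a: frozenset, b: frozenset) -> bool:
        return not (a & b) or a <= b or b <= a

    families: list[tuple[frozenset, ...]] = []

    def grow(start: int, chosen: list[frozenset]) -> None:
        for i in range(start, len(subsets)):
            cand = subsets[i]
            if all(compatible(cand, c) for c in chosen):
                chosen.append(cand)
                families.append(tuple(chosen))
                grow(i + 1, chosen)
                chosen.pop()

    grow(0, [])
    mods = [Modularization.from_sets(f, ref=d) for f in families]
    mods.sort(key=lambda m: (len(m.modules), m.sorted_modules()))
    for i, m in enumerate(mods, start=1):
        object.__setattr__(m, "label", f"M{i}")
    if include_linear:
        lin = Modularization(frozenset(), ref=d, kind="linear_full", label="ML")
        mods.append(lin)
    return mods


def linear_membership_family(
    unit: frozenset[int] | int,
    groups: list[frozenset[int]],
    size: int,
    d: int,
) -> list[IndexSetFamily]:
    """Families testing whether ``unit`` joins a linear module of fixed size.

    ``groups`` partition the candidate components into modules/branches.
    One family is produced per combination of groups that contains
    ``unit`` and totals exactly ``size`` observable components; each
    family carries the linear-module constraint (all above-diagonal
    ratios of the combination's submatrix equal). Testing at a fixed
    size keeps the degrees of freedom identical across units; an empty
    list means the unit is not testable at this size.
    """
    if isinstance(unit, int):
        unit = frozenset({unit})
    else:
        unit = frozenset(unit)
    if unit not in [frozenset(g) for g in groups]:
        groups = [unit] + [frozenset(g) for g in groups if frozenset(g) != unit]
    else:
        groups = [frozenset(g) for g in groups]
    others = [g for g in groups if g != unit]
    families: list[IndexSetFamily] = []
    need = size - len(unit)
    if need < 0:
        return []
    for r in range(len(others) + 1):
        for combo in itertools.combinations(others, r):
            if sum(len(g) for g in combo) != need:
                continue
            members = frozenset().union(unit, *combo)
            mod = FunctionalModule(members, linear=True)
            m = Modularization(frozenset({mod}), ref=d, kind="nested")
            families.append(index_sets(m, d))
    return families
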