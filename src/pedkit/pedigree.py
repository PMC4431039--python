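"""Core pedigree data structures.

An ascending genealogy is a directed acyclic graph over individuals where
edges run from children to parents.  Individuals are identified by positive
integers; a parent id of 0 means "unknown".  Sex is coded 1 (male) /
2 (female).  Probands (the present-day sampled individuals the genealogy was
reconstructed from) sit at generation 0 and generations count back in time,
so a proband's parents are at generation 1, grandparents at generation 2,
and so on.  Because relatives marry, a single ancestor may occupy several
generation indices at once (pedigree collapse).
"""

from __future__ import annotations

import heapq
from collections import Counter, deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PedigreeRecord",
    "Genealogy",
    "PedigreeError",
    "CycleError",
    "build_genealogy",
]

UNKNOWN = 0

MALE = 1
FEMALE = 2


class PedigreeError(ValueError):
    """Structural problem in a pedigree table."""


class CycleError(PedigreeError):
    """The parent relation contains a cycle; carries one offending cycle."""

    def __init__(self, cycle: Sequence[int]):
        self.cycle = list(cycle)
        super().__init__(
            "pedigree contains a cycle: " + " -> ".join(map(str, self.cycle))
        )


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: id, father id, mother id (0 = unknown) and sex (1/2)."""

    id: int
    father_id: int
    mother_id: int
    sex: int

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise PedigreeError(f"individual id must be positive, got {self.id}")
        if self.father_id < 0 or self.mother_id < 0:
            raise PedigreeError(f"parent ids must be >= 0 for individual {self.id}")
        if self.sex not in (MALE, FEMALE):
            raise PedigreeError(
                f"sex must be 1 (male) or 2 (female) for individual {self.id}, got {self.sex}"
            )


class Genealogy:
    """A validated ascending genealogy.

    Parameters
    ----------
    records
        Pedigree records, one per individual.  Ids must be unique, sexes
        consistent with parental roles, and the parent relation acyclic.
    auto_complete
        When True (default), a parent id that is referenced but has no row of
        its own is synthesized as a founder of the appropriate sex.  When
        False such dangling references raise :class:`PedigreeError`.
    probands
        Optional explicit proband set.  Defaults to every individual with no
        children in the table.

    Attributes
    ----------
    probands : frozenset[int]
        Generation-0 individuals.
    founders : frozenset[int]
        Individuals with both parents unknown.
    half_founders : frozenset[int]
        Individuals with exactly one known parent.
    """

    def __init__(
        self,
        records: Iterable[PedigreeRecord],
        *,
        auto_complete: bool = True,
        probands: Iterable[int] | None = None,
    ):
        recs: dict[int, PedigreeRecord] = {}
        for r in records:
            if r.id in recs:
                raise PedigreeError(f"duplicate individual id {r.id}")
            recs[r.id] = r

        if not recs:
            raise PedigreeError("pedigree table is empty")

        # Parental roles: an id used as a father must be male, as a mother female.
        fathers = {r.father_id for r in recs.values()} - {UNKNOWN}
        mothers = {r.mother_id for r in recs.values()} - {UNKNOWN}
        both = fathers & mothers
        if both:
            raise PedigreeError(
                f"id(s) used both as father and as mother: {sorted(both)}"
            )
        for pid in fathers:
            if pid in recs and recs[pid].sex != MALE:
                raise PedigreeError(
                    f"individual {pid} is used as a father but has sex {recs[pid].sex}"
                )
        for pid in mothers:
            if pid in recs and recs[pid].sex != FEMALE:
                raise PedigreeError(
                    f"individual {pid} is used as a mother but has sex {recs[pid].sex}"
                )

        dangling = (fathers | mothers) - recs.keys()
        if dangling:
            if not auto_complete:
                raise PedigreeError(
                    "parent id(s) referenced but absent from the table "
                    f"(auto_complete is off): {sorted(dangling)}"
                )
            for pid in sorted(dangling):
                sex = MALE if pid in fathers else FEMALE
                recs[pid] = PedigreeRecord(pid, UNKNOWN, UNKNOWN, sex)

        self._records = recs

        children: dict[int, set[int]] = {i: set() for i in recs}
        for r in recs.values():
            if r.father_id != UNKNOWN:
                children[r.father_id].add(r.id)
            if r.mother_id != UNKNOWN:
                children[r.mother_id].add(r.id)
        # Sorted tuples for full determinism regardless of input row order.
        self._children: dict[int, tuple[int, ...]] = {
            i: tuple(sorted(c)) for i, c in children.items()
        }

        self._topo_order = self._toposort()
        self._topo_index = {i: k for k, i in enumerate(self._topo_order)}

        self.founders = frozenset(
            i for i, r in recs.items()
            if r.father_id == UNKNOWN and r.mother_id == UNKNOWN
        )
        self.half_founders = frozenset(
            i for i, r in recs.items()
            if (r.father_id == UNKNOWN) != (r.mother_id == UNKNOWN)
        )
        if probands is None:
            self.probands = frozenset(i for i in recs if not self._children[i])
        else:
            probands = frozenset(probands)
            missing = probands - recs.keys()
            if missing:
                raise PedigreeError(f"unknown proband id(s): {sorted(missing)}")
            self.probands = probands

        self._gen_occ_cache: dict[frozenset[int], dict[int, Counter]] = {}

    # ------------------------------------------------------------------ basics

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, ind: int) -> bool:
        return ind in self._records

    def __iter__(self):
        return iter(self._topo_order)

    @property
    def individuals(self) -> tuple[int, ...]:
        """All ids in topological order (founders first, ties by ascending id)."""
        return tuple(self._topo_order)

    def record(self, ind: int) -> PedigreeRecord:
        self._check(ind)
        return self._records[ind]

    def sex(self, ind: int) -> int:
        return self.record(ind).sex

    def parents(self, ind: int) -> tuple[int, int]:
        """(father_id, mother_id), 0 for unknown."""
        r = self.record(ind)
        return r.father_id, r.mother_id

    def known_parents(self, ind: int) -> tuple[int, ...]:
        return tuple(p for p in self.parents(ind) if p != UNKNOWN)

    def children_of(self, ind: int) -> tuple[int, ...]:
        self._check(ind)
        return self._children[ind]

    def topo_index(self, ind: int) -> int:
        return self._topo_index[ind]

    def _check(self, ind: int) -> None:
        if ind not in self._records:
            raise PedigreeError(f"unknown individual id {ind}")

    def _toposort(self) -> list[int]:
        """Founders-first topological order, ties broken by ascending id."""
        indeg = {
            i: len(self.known_parents_raw(r)) for i, r in self._records.items()
        }
        heap = [i for i, d in indeg.items() if d == 0]
        heapq.heapify(heap)
        order: list[int] = []
        children: dict[int, list[int]] = {i: [] for i in self._records}
        for i, r in self._records.items():
            for p in self.known_parents_raw(r):
                children[p].append(i)
        while heap:
            i = heapq.heappop(heap)
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(heap, c)
        if len(order) < len(self._records):
            raise CycleError(self._find_cycle())
        return order

    @staticmethod
    def known_parents_raw(r: PedigreeRecord) -> tuple[int, ...]:
        return tuple(p for p in (r.father_id, r.mother_id) if p != UNKNOWN)

    def _find_cycle(self) -> list[int]:
        """Locate one offending cycle in the child->parent relation (DFS)."""
        WHITE, GREY, BLACK = 0, 1, 2
        color = dict.fromkeys(self._records, WHITE)
        for start in self._records:
            if color[start] != WHITE:
                continue
            stack = [(start, iter(self.known_parents_raw(self._records[start])))]
            color[start] = GREY
            path = [start]
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if color[p] == GREY:
                        return path[path.index(p):] + [p]
                    if color[p] == WHITE:
                        color[p] = GREY
                        path.append(p)
                        stack.append(
                            (p, iter(self.known_parents_raw(self._records[p])))
                        )
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    path.pop()
                    stack.pop()
        raise AssertionError("cycle reported but none found")  # pragma: no cover

    # -------------------------------------------------------------- closures

    def ancestors(self, ind: int, include_self: bool = False) -> frozenset[int]:
        """Strict ancestors of ``ind`` (or ancestor-or-self set)."""
        self._check(ind)
        seen: set[int] = set()
        stack = list(self.known_parents(ind))
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            stack.extend(self.known_parents(x))
        if include_self:
            seen.add(ind)
        return frozenset(seen)

    def descendants(self, ind: int, include_self: bool = False) -> frozenset[int]:
        self._check(ind)
        seen: set[int] = set()
        stack = list(self._children[ind])
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            stack.extend(self._children[x])
        if include_self:
            seen.add(ind)
        return frozenset(seen)

    def min_distance(self, descendant: int, ancestor: int) -> int | None:
        """Minimal number of meioses from ``descendant`` up to ``ancestor``.

        Returns None when ``ancestor`` is not an ancestor-or-self of
        ``descendant``; 0 when they are the same individual.
        """
        self._check(descendant)
        self._check(ancestor)
        if descendant == ancestor:
            return 0
        dist = {descendant: 0}
        q = deque([descendant])
        while q:
            x = q.popleft()
            for p in self.known_parents(x):
                if p not in dist:
                    dist[p] = dist[x] + 1
                    if p == ancestor:
                        return dist[p]
                    q.append(p)
        return None

    # ---------------------------------------------------- generation layering

    def generation_occurrences(
        self, probands: Iterable[int] | None = None
    ) -> dict[int, Counter]:
        """Per individual, multiset of generation indices over all ascending
        paths from the given probands (default: the genealogy's probands).

        ``result[i][g]`` is the number of (proband, path) placements of
        individual ``i`` at generation ``g``.  Computed by dynamic programming
        on the child -> parent relation, so pedigree collapse is handled
        without path enumeration.
        """
        pro = self.probands if probands is None else frozenset(probands)
        missing = pro - self._records.keys()
        if missing:
            raise PedigreeError(f"unknown proband id(s): {sorted(missing)}")
        key = frozenset(pro)
        cached = self._gen_occ_cache.get(key)
        if cached is not None:
            return cached
        occ: dict[int, Counter] = {}
        # Descendants before ancestors: reverse topological order.
        for ind in reversed(self._topo_order):
            c = Counter()
            if ind in pro:
                c[0] += 1
            for child in self._children[ind]:
                child_occ = occ.get(child)
                if child_occ:
                    for g, n in child_occ.items():
                        c[g + 1] += n
            if c:
                occ[ind] = c
        self._gen_occ_cache[key] = occ
        return occ

    # ------------------------------------------------------------ extraction

    def branch(
        self,
        probands: Iterable[int],
        ancestors: Iterable[int] | None = None,
    ) -> "Genealogy":
        """Extract the sub-genealogy from the requested probands up to (and
        through) the requested ancestors.

        With ``ancestors`` empty/None the full ascending closure of the
        requested probands is kept.  Otherwise an individual is kept when it
        lies above a requested proband AND is on a path to a requested
        ancestor or above one.  The requested probands become the proband set
        of the result.
        """
        pro = frozenset(probands)
        for i in pro:
            self._check(i)
        keep: set[int] = set()
        for p in pro:
            keep |= self.ancestors(p, include_self=True)
        if ancestors is not None:
            anc = frozenset(ancestors)
            if anc:
                for a in anc:
                    self._check(a)
                allowed: set[int] = set()
                for a in anc:
                    allowed |= self.descendants(a, include_self=True)
                    allowed |= self.ancestors(a, include_self=True)
                keep &= allowed
                keep |= pro
        new_records = [self._restricted_record(i, keep) for i in sorted(keep)]
        return Genealogy(new_records, auto_complete=False, probands=pro)

    def _restricted_record(self, ind: int, keep: set[int]) -> PedigreeRecord:
        r = self._records[ind]
        f = r.father_id if r.father_id in keep else UNKNOWN
        m = r.mother_id if r.mother_id in keep else UNKNOWN
        return PedigreeRecord(ind, f, m, r.sex)

    def extract_lineage(
        self, probands: Iterable[int], side: str
    ) -> "Genealogy":
        """Uniparental chains: ``side='paternal'`` keeps father-of-father-of-…,
        ``side='maternal'`` the mother line, for each requested proband."""
        if side not in ("maternal", "paternal"):
            raise ValueError("side must be 'maternal' or 'paternal'")
        idx = 0 if side == "paternal" else 1
        pro = frozenset(probands)
        keep: set[int] = set()
        links: dict[int, int] = {}  # child -> retained parent
        for p in pro:
            self._check(p)
            x = p
            keep.add(x)
            while True:
                nxt = self.parents(x)[idx]
                if nxt == UNKNOWN:
                    break
                links[x] = nxt
                keep.add(nxt)
                x = nxt
        new_records = []
        for i in sorted(keep):
            r = self._records[i]
            parent = links.get(i, UNKNOWN)
            f = parent if idx == 0 else UNKNOWN
            m = parent if idx == 1 else UNKNOWN
            new_records.append(PedigreeRecord(i, f, m, r.sex))
        return Genealogy(new_records, auto_complete=False, probands=pro)

    # ---------------------------------------------------------- id classes

    def sibship(self, ind: int, include_half: bool = False) -> frozenset[int]:
        """Full sibs of ``ind`` (same two known parents), excluding ``ind``.

        With ``include_half`` individuals sharing exactly one known parent
        are added."""
        f, m = self.parents(ind)
        full: set[int] = set()
        half: set[int] = set()
        candidates: set[int] = set()
        if f != UNKNOWN:
            candidates |= set(self._children[f])
        if m != UNKNOWN:
            candidates |= set(self._children[m])
        for c in candidates:
            if c == ind:
                continue
            cf, cm = self.parents(c)
            shared = (f != UNKNOWN and cf == f) + (m != UNKNOWN and cm == m)
            if shared == 2:
                full.add(c)
            elif shared == 1:
                half.add(c)
        return frozenset(full | half) if include_half else frozenset(full)

    def identify(self, what: str, ind: int | None = None, **kw) -> frozenset[int]:
        """Structurally defined individual classes by name.

        ``what`` is one of founders, half_founders, probands, children_of,
        sibship, parents; the latter three require ``ind``.
        """
        if what == "founders":
            return self.founders
        if what == "half_founders":
            return self.half_founders
        if what == "probands":
            return self.probands
        if ind is None:
            raise ValueError(f"class {what!r} requires an individual id")
        if what == "children_of":
            return frozenset(self.children_of(ind))
        if what == "sibship":
            return self.sibship(ind, include_half=kw.get("include_half", False))
        if what == "parents":
            return frozenset(self.known_parents(ind))
        raise ValueError(f"unknown individual class {what!r}")

    # ------------------------------------------------------ common ancestry

    def common_ancestors(
        self, subjects: Iterable[int], founders_only: bool = False
    ) -> frozenset[int]:
        """Individuals that are ancestors of every subject.

        A subject counts as its own ancestor only if it is in ``subjects``
        itself (so a parent is a common ancestor of {parent, child}).
        """
        subs = sorted(set(subjects))
        if len(subs) < 2:
            raise PedigreeError("need at least 2 subjects for common ancestors")
        common: frozenset[int] | None = None
        for s in subs:
            anc = self.ancestors(s, include_self=True)
            common = anc if common is None else common & anc
        assert common is not None
        # A subject survives the intersection only when it is an ancestor of
        # every other subject, which is exactly the self-as-ancestor rule.
        if founders_only:
            common &= self.founders
        return common

    def find_mrca(
        self, subjects: Iterable[int]
    ) -> dict[int, dict[int, int]]:
        """Most recent common ancestors of ``subjects``.

        Returns ``{mrca_id: {subject: minimal meiotic distance}}``.  An MRCA
        is a common ancestor none of whose own descendants is also a common
        ancestor of the subjects.  Empty dict when there is no common
        ancestor.
        """
        subs = sorted(set(subjects))
        ca = self.common_ancestors(subs)
        out: dict[int, dict[int, int]] = {}
        for a in sorted(ca):
            if self.descendants(a) & ca:
                continue
            dists = {s: self.min_distance(s, a) for s in subs}
            assert all(d is not None for d in dists.values())
            out[a] = {s: int(d) for s, d in dists.items()}  # type: ignore[arg-type]
        return out

    # -------------------------------------------------------------- tabular

    def to_table(self) -> pd.DataFrame:
        """Pedigree rows (ind, father, mother, sex) sorted by id.

        Round-trips: rebuilding from this table reproduces the genealogy,
        including any founder rows synthesized by auto-completion.
        """
        rows = sorted(self._records.values(), key=lambda r: r.id)
        return pd.DataFrame(
            {
                "ind": [r.id for r in rows],
                "father": [r.father_id for r in rows],
                "mother": [r.mother_id for r in rows],
                "sex": [r.sex for r in rows],
            }
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Genealogy: {len(self)} individuals, {len(self.probands)} probands, "
            f"{len(self.founders)} founders, {len(self.half_founders)} half-founders>"
        )


def build_genealogy(
    table: pd.DataFrame | Iterable[Mapping[str, int] | Sequence[int]],
    *,
    auto_complete: bool = True,
    probands: Iterable[int] | None = None,
) -> Genealogy:
    """Build a validated :class:`Genealogy` from a pedigree table.

    ``table`` may be a DataFrame with columns ind/father/mother/sex (id/fid/mid
    aliases accepted) or any iterable of 4-sequences or mappings.  The result
    is deterministic for identical input regardless of row order.
    """
    records: list[PedigreeRecord] = []
    if isinstance(table, pd.DataFrame):
        cols = _resolve_columns(table)
        for row in table[list(cols)].itertuples(index=False):
            records.append(
                PedigreeRecord(int(row[0]), int(row[1]), int(row[2]), int(row[3]))
            )
    else:
        for item in table:
            if isinstance(item, Mapping):
                records.append(
                    PedigreeRecord(
                        int(item["ind"]), int(item["father"]),
                        int(item["mother"]), int(item["sex"]),
                    )
                )
            else:
                i, f, m, s = item
                records.append(PedigreeRecord(int(i), int(f), int(m), int(s)))
    return Genealogy(records, auto_complete=auto_complete, probands=probands)


_COLUMN_ALIASES = {
    "ind": ("ind", "id", "iid"),
    "father": ("father", "fid", "father_id", "pere"),
    "mother": ("mother", "mid", "mother_id", "mere"),
    "sex": ("sex", "sexe"),
}


def _resolve_columns(df: pd.DataFrame) -> tuple[str, str, str, str]:
    lower = {c.lower(): c for c in df.columns}
    out = []
    for canonical, aliases in _COLUMN_ALIASES.items():
        for a in aliases:
            if a in lower:
                out.append(lower[a])
                break
        else:
            raise PedigreeError(
                f"missing required pedigree column {canonical!r} "
                f"(have: {list(df.columns)})"
            )
    return tuple(out)  # type: ignore[return-value]
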