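"""Kinship, inbreeding and genetic contribution on collapsed genealogies.

The kinship coefficient phi(i, j) is the probability that one allele drawn
at random from i and one from j are identical by descent.  It is computed by
the standard recursion (founders pairwise unrelated and non-inbred):

    phi(i, i) = (1 + f_i) / 2          with f_i = phi(father_i, mother_i)
    phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2
                where i is not an ancestor of j (unknown parents give 0)

which is equivalent to the path-counting form
phi_ij = sum over common ancestors a of (1 + f_a) (1/2)^{g_ai + g_aj + 1}
with the sum running over pairs of non-overlapping ascending paths; the
recursion avoids enumerating paths, which is exponential on collapsed
genealogies.

The genetic contribution GC(s, a) is the expected fraction of s's genome
contributed by ancestor a: GC(s, a) = sum over ascending paths p of
(1/2)^{len(p)}, computed by a linear-time downward sweep.  Transmission
weights may be customised per parent sex.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .pedigree import Genealogy, PedigreeError, PedigreeRecord, UNKNOWN

__all__ = [
    "KinshipMatrix",
    "ContributionMatrix",
    "kinship",
    "kinship_pair",
    "inbreeding",
    "genetic_contribution",
    "cumulative_contribution",
]


@dataclass
class KinshipMatrix:
    """Symmetric kinship matrix over an ordered subject list.

    Diagonal entries are phi(i, i) = (1 + f_i) / 2 >= 1/2.  ``depth_used`` is
    the generation cap applied (None = unlimited).
    """

    subjects: tuple[int, ...]
    phi: np.ndarray
    depth_used: int | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.subjects, name="id")
        return pd.DataFrame(self.phi, index=idx, columns=idx)

    def __getitem__(self, pair: tuple[int, int]) -> float:
        i, j = pair
        return float(
            self.phi[self.subjects.index(i), self.subjects.index(j)]
        )


@dataclass
class ContributionMatrix:
    """Genetic contributions GC(s, a) for probands (rows) x ancestors (cols)."""

    probands: tuple[int, ...]
    ancestors: tuple[int, ...]
    gc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.gc,
            index=pd.Index(self.probands, name="proband"),
            columns=pd.Index(self.ancestors, name="ancestor"),
        )

    def __getitem__(self, pair: tuple[int, int]) -> float:
        s, a = pair
        return float(
            self.gc[self.probands.index(s), self.ancestors.index(a)]
        )


# -------------------------------------------------------------- truncation


def _truncate(gen: Genealogy, subjects: Iterable[int], depth: int) -> Genealogy:
    """Cut parent links of every individual whose minimal generation relative
    to ``subjects`` is >= depth, so ancestors beyond ``depth`` generations are
    treated as unreachable and generation-``depth`` individuals become
    founders."""
    if depth <= 0:
        raise PedigreeError(f"depth must be positive, got {depth}")
    occ = gen.generation_occurrences(subjects)
    min_gen = {i: min(c) for i, c in occ.items()}
    records = []
    for i in gen:
        r = gen.record(i)
        g = min_gen.get(i)
        if g is not None and g >= depth:
            records.append(PedigreeRecord(i, UNKNOWN, UNKNOWN, r.sex))
        else:
            records.append(r)
    return Genealogy(records, auto_complete=True, probands=gen.probands)


# ----------------------------------------------------------------- kinship


class _KinshipEngine:
    """Memoized kinship recursion over a founders-first topological order.

    The memo is a plain dict shared across worker threads: the recursion is a
    pure function of the pedigree, so a racy duplicate evaluation writes the
    same value and results are bit-identical for any thread count.
    """

    def __init__(self, gen: Genealogy):
        self.gen = gen
        self.memo: dict[tuple[int, int], float] = {}

    def phi(self, i: int, j: int) -> float:
        if i == UNKNOWN or j == UNKNOWN:
            return 0.0
        key = (i, j) if i <= j else (j, i)
        hit = self.memo.get(key)
        if hit is not None:
            return hit
        # Iterative evaluation to survive deep pedigrees (recursion depth
        # grows with genealogy depth x collapse).
        self._evaluate(key)
        return self.memo[key]

    def _value(self, i: int, j: int) -> float | tuple:
        """Either the final value or the list of dependency keys."""
        gen = self.gen
        if i == j:
            f, m = gen.parents(i)
            if f == UNKNOWN or m == UNKNOWN:
                return 0.5
            dep = (f, m) if f <= m else (m, f)
            return ("self", dep)
        # Recurse on the individual later in topological order: it cannot be
        # an ancestor of the other.
        a, b = (i, j) if gen.topo_index(i) > gen.topo_index(j) else (j, i)
        f, m = gen.parents(a)
        deps = []
        for p in (f, m):
            if p != UNKNOWN:
                deps.append((p, b) if p <= b else (b, p))
        return ("pair", tuple(deps))

    def _evaluate(self, key: tuple[int, int]) -> None:
        stack = [key]
        while stack:
            k = stack[-1]
            if k in self.memo:
                stack.pop()
                continue
            v = self._value(*k)
            if v == 0.5:
                self.memo[k] = 0.5
                stack.pop()
                continue
            kind, deps = v
            if kind == "self":
                dep = deps
                if dep in self.memo:
                    self.memo[k] = 0.5 * (1.0 + self.memo[dep])
                    stack.pop()
                else:
                    stack.append(dep)
            else:
                missing = [d for d in deps if d not in self.memo]
                if missing:
                    stack.extend(missing)
                else:
                    self.memo[k] = 0.5 * sum(self.memo[d] for d in deps)
                    stack.pop()


def kinship_pair(gen: Genealogy, i: int, j: int) -> float:
    """Kinship coefficient of a single pair."""
    gen._check(i)
    gen._check(j)
    return _KinshipEngine(gen).phi(i, j)


def kinship(
    gen: Genealogy,
    subjects: Iterable[int] | None = None,
    depth: int | None = None,
    threads: int = 1,
) -> KinshipMatrix:
    """Kinship matrix over ``subjects`` (default: the probands).

    ``depth`` caps the ancestral generations considered: individuals beyond
    ``depth`` generations above the subjects are treated as unrelated
    founders.  ``threads`` partitions the pairwise matrix into row blocks
    computed from a shared memo; the result is identical for any thread
    count.
    """
    subs = tuple(sorted(gen.probands if subjects is None else set(subjects)))
    for s in subs:
        gen._check(s)
    work = gen if depth is None else _truncate(gen, subs, depth)
    eng = _KinshipEngine(work)
    n = len(subs)
    phi = np.zeros((n, n))

    def fill_rows(rows: range) -> None:
        for a in rows:
            for b in range(a, n):
                phi[a, b] = eng.phi(subs[a], subs[b])

    if threads <= 1 or n < 2:
        fill_rows(range(n))
    else:
        blocks = [range(k, n, threads) for k in range(threads)]
        with ThreadPoolExecutor(max_workers=threads) as ex:
            list(ex.map(fill_rows, blocks))
    phi = np.triu(phi) + np.triu(phi, 1).T
    return KinshipMatrix(subs, phi, depth_used=depth)


def inbreeding(
    gen: Genealogy,
    subjects: Iterable[int] | None = None,
    depth: int | None = None,
) -> pd.Series:
    """Inbreeding coefficient f_i = kinship of i's parents (0 when a parent
    is unknown).  ``depth`` truncates ancestries as in :func:`kinship`."""
    subs = tuple(sorted(gen.probands if subjects is None else set(subjects)))
    for s in subs:
        gen._check(s)
    work = gen if depth is None else _truncate(gen, subs, depth)
    eng = _KinshipEngine(work)
    out = []
    for s in subs:
        f, m = work.parents(s)
        out.append(0.0 if (f == UNKNOWN or m == UNKNOWN) else eng.phi(f, m))
    return pd.Series(out, index=pd.Index(subs, name="id"), name="inbreeding")


# ----------------------------------------------------- genetic contribution


def genetic_contribution(
    gen: Genealogy,
    probands: Iterable[int] | None = None,
    ancestors: Iterable[int] | None = None,
    weights: tuple[float, float] = (0.5, 0.5),
) -> ContributionMatrix:
    """Expected genomic contribution GC(s, a) of each ancestor to each proband.

    GC(s, a) = [s = a] + w_pat * GC(father(s), a) + w_mat * GC(mother(s), a),
    evaluated by one downward sweep in topological order per ancestor.
    ``weights`` are the (paternal, maternal) per-meiosis transmission weights;
    the default (1/2, 1/2) is the autosomal inheritance pattern.
    """
    pro = tuple(sorted(gen.probands if probands is None else set(probands)))
    anc = tuple(sorted(gen.founders if ancestors is None else set(ancestors)))
    if not pro or not anc:
        raise PedigreeError("proband and ancestor sets must be nonempty")
    for x in pro + anc:
        gen._check(x)
    w_pat, w_mat = weights
    order = gen.individuals
    gc = np.zeros((len(pro), len(anc)))
    pro_pos = {p: k for k, p in enumerate(pro)}
    for col, a in enumerate(anc):
        val: dict[int, float] = {a: 1.0}
        start = gen.topo_index(a)
        for ind in order[start + 1:]:
            f, m = gen.parents(ind)
            v = 0.0
            if f != UNKNOWN:
                v += w_pat * val.get(f, 0.0)
            if m != UNKNOWN:
                v += w_mat * val.get(m, 0.0)
            if v:
                val[ind] = v
        for p, row in pro_pos.items():
            gc[row, col] = val.get(p, 0.0)
    return ContributionMatrix(pro, anc, gc)


def cumulative_contribution(
    cm: ContributionMatrix,
    group: Iterable[int] | None = None,
    fraction: float = 0.5,
) -> tuple[pd.DataFrame, int]:
    """Cumulative founder-contribution curve for a proband group.

    Ancestors are sorted by decreasing total contribution to the group (ties
    by ascending id).  Returns the curve (per ancestor: contribution,
    cumulative share of the total) and the minimal number of ancestors whose
    cumulative share reaches ``fraction``.  When every lineage terminates at
    the supplied ancestors, equal contributions put the curve on the
    diagonal.
    """
    rows = (
        tuple(range(len(cm.probands)))
        if group is None
        else tuple(cm.probands.index(p) for p in group)
    )
    if not rows:
        raise PedigreeError("proband group is empty")
    totals = cm.gc[list(rows), :].sum(axis=0)
    if totals.sum() <= 0:
        raise PedigreeError("all contributions are zero for this group")
    order = sorted(range(len(cm.ancestors)), key=lambda k: (-totals[k], cm.ancestors[k]))
    sorted_tot = totals[order]
    cum = np.cumsum(sorted_tot) / totals.sum()
    curve = pd.DataFrame(
        {
            "ancestor": [cm.ancestors[k] for k in order],
            "contribution": sorted_tot,
            "cumulative_share": cum,
        }
    )
    n_for_fraction = int(np.searchsorted(cum, fraction - 1e-12) + 1)
    return curve, n_for_fraction
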