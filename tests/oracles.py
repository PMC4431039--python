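"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — explicit path enumeration and exact
rational arithmetic — and shares no code with the production algorithms it
checks (which use dynamic programming / memoized recursion in floats).
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product

from pedkit.pedigree import Genealogy, UNKNOWN


def ascending_paths(gen: Genealogy, subject: int, ancestor: int) -> list[tuple[int, ...]]:
    """All distinct ascending paths subject -> ... -> ancestor (DFS)."""
    out: list[tuple[int, ...]] = []

    def walk(x: int, path: tuple[int, ...]) -> None:
        path = path + (x,)
        if x == ancestor:
            out.append(path)
            return
        for p in gen.known_parents(x):
            walk(p, path)

    walk(subject, ())
    return out


def occurrences_oracle(gen: Genealogy, ancestor: int, subject: int) -> int:
    return len(ascending_paths(gen, subject, ancestor))


def gc_oracle(gen: Genealogy, subject: int, ancestor: int) -> Fraction:
    """Genetic contribution as an explicit path sum of (1/2)^path_length."""
    return sum(
        (Fraction(1, 2) ** (len(p) - 1) for p in ascending_paths(gen, subject, ancestor)),
        Fraction(0),
    )


def all_root_paths(gen: Genealogy, proband: int) -> list[tuple[int, ...]]:
    """Every maximal ascending path from the proband (each ends where a
    parent is unknown)."""
    out: list[tuple[int, ...]] = []

    def walk(x: int, path: tuple[int, ...]) -> None:
        path = path + (x,)
        parents = gen.known_parents(x)
        if not parents:
            out.append(path)
            return
        for p in parents:
            walk(p, path)
        # A half-founder continues on the known side only; the missing side
        # simply contributes no further slots (no extra maximal path).

    walk(proband, ())
    return out


def generation_placements_oracle(gen: Genealogy, proband: int) -> dict[int, dict[int, int]]:
    """{individual: {generation: number of ascending paths of that length}}
    by explicit enumeration of all ascending walks from the proband."""
    counts: dict[int, dict[int, int]] = {}

    def walk(x: int, g: int) -> None:
        counts.setdefault(x, {})
        counts[x][g] = counts[x].get(g, 0) + 1
        for p in gen.known_parents(x):
            walk(p, g + 1)

    walk(proband, 0)
    return counts


def mean_depth_oracle(gen: Genealogy, proband: int) -> tuple[Fraction, Fraction]:
    """(D, variance) from the founder-occurrence closed form evaluated over
    explicitly enumerated maximal paths: D = sum over founder-terminated
    paths of N (1/2)^N."""
    d = Fraction(0)
    m2 = Fraction(0)
    for path in all_root_paths(gen, proband):
        terminus = path[-1]
        if terminus in gen.founders:
            n = len(path) - 1
            w = Fraction(1, 2) ** n
            d += n * w
            m2 += n * n * w
    return d, m2 - d * d


# ------------------------------------------------------------------ kinship


def inbreeding_oracle(gen: Genealogy, ind: int) -> Fraction:
    f, m = gen.parents(ind)
    if f == UNKNOWN or m == UNKNOWN:
        return Fraction(0)
    return kinship_oracle(gen, f, m)


def kinship_oracle(gen: Genealogy, i: int, j: int) -> Fraction:
    """Wright's path-counting kinship: sum over common ancestors a and over
    pairs of ascending paths (i -> a, j -> a) sharing no individual except a
    of (1 + f_a) (1/2)^{g_ai + g_aj + 1}, with f_a itself evaluated by this
    oracle.  Exact rational arithmetic."""
    if i == j:
        return Fraction(1, 2) * (1 + inbreeding_oracle(gen, i))
    total = Fraction(0)
    common = gen.ancestors(i, include_self=True) & gen.ancestors(j, include_self=True)
    for a in sorted(common):
        fa = inbreeding_oracle(gen, a)
        paths_i = ascending_paths(gen, i, a)
        paths_j = ascending_paths(gen, j, a)
        for pi, pj in product(paths_i, paths_j):
            if set(pi) & set(pj) != {a}:
                continue
            g_sum = (len(pi) - 1) + (len(pj) - 1)
            total += (1 + fa) * Fraction(1, 2) ** (g_sum + 1)
    return total


# ---------------------------------------------------------------- gene-drop


def genedrop_exact(
    gen: Genealogy,
    ancestor_states: dict[int, int],
    subjects: tuple[int, ...],
    transmit=None,
    survival: float = 1.0,
    breakage: dict[int, float] | None = None,
) -> dict[tuple[int, ...], Fraction]:
    """Exact copy-count distribution over the subjects by exhaustive
    enumeration of every gamete outcome, individual by individual in
    topological order.

    ``transmit[(parent_sex, child_sex)]`` is the per-copy carry probability
    (default 1/2); ``breakage[parent_sex]`` multiplies the per-meiosis
    transmission by (1 - r).  Homozygote deaths are conditioned on survival
    at the individual level (resample-until-survive semantics).  Returns
    {subject copy vector: exact probability} — only valid on tiny pedigrees.
    """
    transmit = transmit or {}
    breakage = breakage or {}
    sv = Fraction(survival).limit_denominator(10**9)

    def t(psex: int, csex: int) -> Fraction:
        base = Fraction(transmit.get((psex, csex), Fraction(1, 2))).limit_denominator(10**9)
        r = Fraction(breakage.get(psex, 0)).limit_denominator(10**9)
        return base * (1 - r)

    order = [
        x for x in gen.individuals
        if x not in ancestor_states
    ]
    dist: dict[tuple[tuple[int, int], ...], Fraction] = {
        tuple(sorted(ancestor_states.items())): Fraction(1)
    }
    for ind in order:
        f, m = gen.parents(ind)
        csex = gen.sex(ind)
        new: dict[tuple[tuple[int, int], ...], Fraction] = {}
        for state, prob in dist.items():
            sd = dict(state)
            pf = min(t(1, csex) * sd.get(f, 0), Fraction(1)) if f != UNKNOWN else Fraction(0)
            pm = min(t(2, csex) * sd.get(m, 0), Fraction(1)) if m != UNKNOWN else Fraction(0)
            outcomes = {}
            for gf, gm in product((0, 1), repeat=2):
                p = (pf if gf else 1 - pf) * (pm if gm else 1 - pm)
                if p == 0:
                    continue
                c = gf + gm
                if c == 2:
                    p *= sv
                outcomes[c] = outcomes.get(c, Fraction(0)) + p
            norm = sum(outcomes.values())
            if norm == 0:
                continue  # no surviving genotype possible in this branch
            for c, p in outcomes.items():
                if c:
                    key = tuple(sorted((*state, (ind, c))))
                else:
                    key = state
                new[key] = new.get(key, Fraction(0)) + prob * p / norm
        dist = new
    result: dict[tuple[int, ...], Fraction] = {}
    for state, prob in dist.items():
        sd = dict(state)
        vec = tuple(sd.get(s, 0) for s in subjects)
        result[vec] = result.get(vec, Fraction(0)) + prob
    return result


def ibd_sharing_exact(
    gen: Genealogy, pair: tuple[int, int], ancestor: int,
    breakage: dict[int, float] | None = None,
) -> Fraction:
    dist = genedrop_exact(gen, {ancestor: 1}, pair, breakage=breakage)
    return sum(
        (p for vec, p in dist.items() if vec[0] >= 1 and vec[1] >= 1),
        Fraction(0),
    )
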