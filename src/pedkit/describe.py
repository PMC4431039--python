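"""Descriptive statistics of genealogical information content.

Quantifies how much of an ascending genealogy is actually known and how
collapsed it is:

* completeness  C_g = A_g / 2^g — fraction of the 2^g theoretical ancestor
  slots at generation g filled by known ancestors (with multiplicity);
* implex        I_g = distinct A_g / 2^g — same but each distinct ancestor
  counted once; I_g <= C_g, and the gap measures pedigree collapse;
* mean genealogical depth D = sum_g g * F_g / T_g = sum_f N_f (1/2)^{N_f} —
  the expected generation at which a random ascending lineage terminates at
  a founder (F_g counts founder *occurrences* at generation g, T_g = 2^g).

All per-generation quantities are computed by dynamic programming on the
child -> parent relation (see Genealogy.generation_occurrences), never by
path enumeration, so heavily collapsed genealogies stay tractable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .pedigree import Genealogy, PedigreeError, MALE, FEMALE

__all__ = [
    "GenerationProfile",
    "counts",
    "generation_span",
    "depth",
    "completeness",
    "implex",
    "mean_depth",
    "coverage",
    "occurrences",
    "path_distance",
    "min_mrca_distance",
    "describe_report",
    "UNRELATED",
]

UNRELATED = -1  # marker in distance matrices for pairs with no common ancestor


@dataclass
class GenerationProfile:
    """Per-generation ancestor bookkeeping for one proband.

    ``known[g]`` (A_g) counts ancestor occurrences at generation g with
    multiplicity, ``distinct[g]`` counts each distinct ancestor once, and
    ``founder_occ[g]`` (F_g) counts founder occurrences terminating a lineage
    at g.  Expected slots are T_g = 2^g.
    """

    proband: int
    known: dict[int, int] = field(default_factory=dict)
    distinct: dict[int, int] = field(default_factory=dict)
    founder_occ: dict[int, int] = field(default_factory=dict)

    @property
    def max_generation(self) -> int:
        return max(self.known) if self.known else 0

    def expected(self, g: int) -> int:
        return 2 ** g


def _profile(gen: Genealogy, proband: int) -> GenerationProfile:
    occ = gen.generation_occurrences([proband])
    prof = GenerationProfile(proband)
    for ind, gens in occ.items():
        is_founder = ind in gen.founders
        for g, n in gens.items():
            prof.known[g] = prof.known.get(g, 0) + n
            prof.distinct[g] = prof.distinct.get(g, 0) + 1
            if is_founder:
                prof.founder_occ[g] = prof.founder_occ.get(g, 0) + n
    return prof


def generation_profiles(
    gen: Genealogy, probands: Iterable[int] | None = None
) -> list[GenerationProfile]:
    """One :class:`GenerationProfile` per proband."""
    pro = sorted(gen.probands if probands is None else set(probands))
    if not pro:
        raise PedigreeError("proband set is empty")
    return [_profile(gen, p) for p in pro]


# ------------------------------------------------------------------- counts


def counts(gen: Genealogy) -> dict[str, int]:
    """Exact counts of individuals, men and women."""
    men = sum(1 for i in gen if gen.sex(i) == MALE)
    women = sum(1 for i in gen if gen.sex(i) == FEMALE)
    return {"individuals": len(gen), "men": men, "women": women}


def generation_span(
    gen: Genealogy, ind: int, probands: Iterable[int] | None = None
) -> dict[str, float]:
    """Min / mean / max generation index of ``ind`` over all ascending paths
    from the probands.  The mean is weighted by the number of (proband, path)
    placements."""
    occ = gen.generation_occurrences(probands)
    gens = occ.get(ind)
    if not gens:
        raise PedigreeError(
            f"individual {ind} is not a proband nor an ancestor of one"
        )
    total = sum(gens.values())
    return {
        "min": min(gens),
        "mean": sum(g * n for g, n in gens.items()) / total,
        "max": max(gens),
    }


def depth(gen: Genealogy, probands: Iterable[int] | None = None) -> int:
    """Number of generation levels, generation 0 included (max index + 1)."""
    occ = gen.generation_occurrences(probands)
    return 1 + max(max(c) for c in occ.values())


# ------------------------------------------------- completeness and implex


def _per_generation_table(
    values: list[dict[int, float]], max_g: int
) -> np.ndarray:
    arr = np.zeros((len(values), max_g + 1))
    for k, v in enumerate(values):
        for g, x in v.items():
            arr[k, g] = x
    return arr


def completeness(
    gen: Genealogy,
    probands: Iterable[int] | None = None,
    mode: str = "mean",
) -> pd.Series | pd.DataFrame:
    """Completeness profile C_g = A_g / 2^g.

    ``mode='mean'`` (default) averages the per-proband profiles, matching a
    corpus-level summary; ``mode='per_proband'`` returns one column per
    proband.  C_0 = 1 and C is non-increasing in g.
    """
    profs = generation_profiles(gen, probands)
    max_g = max(p.max_generation for p in profs)
    vals = [
        {g: n / 2 ** g for g, n in p.known.items()} for p in profs
    ]
    arr = _per_generation_table(vals, max_g)
    idx = pd.RangeIndex(max_g + 1, name="generation")
    if mode == "per_proband":
        return pd.DataFrame(arr.T, index=idx, columns=[p.proband for p in profs])
    if mode == "mean":
        return pd.Series(arr.mean(axis=0), index=idx, name="completeness")
    raise ValueError(f"unknown mode {mode!r}")


def implex(
    gen: Genealogy,
    probands: Iterable[int] | None = None,
    mode: str = "mean",
) -> pd.Series | pd.DataFrame:
    """Implex profile I_g = distinct A_g / 2^g (pedigree-collapse index).

    Bounded above by the completeness.  ``mode`` is 'mean' (average of
    per-proband profiles, default), 'per_proband', or 'pooled' (ancestors
    distinct across the whole proband set: sum of per-generation distinct
    counts over the union of trees divided by n_probands * 2^g).
    """
    pro = sorted(gen.probands if probands is None else set(probands))
    if mode == "pooled":
        occ = gen.generation_occurrences(pro)
        distinct: Counter = Counter()
        for gens in occ.values():
            for g in gens:
                distinct[g] += 1
        max_g = max(distinct)
        vals = pd.Series(
            [distinct.get(g, 0) / (len(pro) * 2 ** g) for g in range(max_g + 1)],
            index=pd.RangeIndex(max_g + 1, name="generation"),
            name="implex",
        )
        return vals
    profs = generation_profiles(gen, pro)
    max_g = max(p.max_generation for p in profs)
    vals = [{g: n / 2 ** g for g, n in p.distinct.items()} for p in profs]
    arr = _per_generation_table(vals, max_g)
    idx = pd.RangeIndex(max_g + 1, name="generation")
    if mode == "per_proband":
        return pd.DataFrame(arr.T, index=idx, columns=[p.proband for p in profs])
    if mode == "mean":
        return pd.Series(arr.mean(axis=0), index=idx, name="implex")
    raise ValueError(f"unknown mode {mode!r}")


# ------------------------------------------------------------------- depth D


def mean_depth(
    gen: Genealogy,
    probands: Iterable[int] | None = None,
    per_proband: bool = False,
) -> dict[str, float] | pd.DataFrame:
    """Mean genealogical depth D and its variance.

    D = sum_g g * F_g / T_g, equivalently sum over founder occurrences f of
    N_f (1/2)^{N_f}; the variance is sum_g g^2 F_g / T_g - D^2.  For a
    proband whose every lineage terminates at a founder the founder weights
    (1/2)^{N_f} sum to one and D is the expectation of the termination
    generation.  Averaged over probands unless ``per_proband``.
    """
    profs = generation_profiles(gen, probands)
    rows = []
    for p in profs:
        d = sum(g * n / 2 ** g for g, n in p.founder_occ.items())
        m2 = sum(g * g * n / 2 ** g for g, n in p.founder_occ.items())
        rows.append((p.proband, d, m2 - d * d))
    df = pd.DataFrame(rows, columns=["proband", "depth", "variance"])
    if per_proband:
        return df.set_index("proband")
    return {
        "depth": float(df["depth"].mean()),
        "variance": float(df["variance"].mean()),
    }


def founder_weight_sum(gen: Genealogy, proband: int) -> float:
    """sum over founder occurrences of (1/2)^generation; equals 1 when every
    lineage of the proband terminates at a founder (no half-founders above)."""
    p = _profile(gen, proband)
    return float(sum(n / 2 ** g for g, n in p.founder_occ.items()))


# ------------------------------------------------------- paths and coverage


def occurrences(gen: Genealogy, ancestor: int, subject: int) -> int:
    """Number of distinct ascending paths linking ``subject`` to ``ancestor``.

    occ(s, a) = [s = a] + occ(father(s), a) + occ(mother(s), a), with
    occ(unknown, .) = 0; paths are not mutually exclusive.  0 when unrelated.
    """
    gen._check(ancestor)
    gen._check(subject)
    memo: dict[int, int] = {}

    def occ(s: int) -> int:
        if s == 0:
            return 0
        if s == ancestor:
            return 1
        hit = memo.get(s)
        if hit is not None:
            return hit
        f, m = gen.parents(s)
        v = occ(f) + occ(m)
        memo[s] = v
        return v

    return occ(subject)


def coverage(
    gen: Genealogy,
    probands: Iterable[int] | None = None,
    ancestors: Iterable[int] | None = None,
) -> pd.Series:
    """For each ancestor, the number of probands that descend from it
    (ancestor-or-self, so occ >= 1)."""
    pro = sorted(gen.probands if probands is None else set(probands))
    anc = sorted(gen.founders if ancestors is None else set(ancestors))
    if not pro or not anc:
        raise PedigreeError("proband and ancestor sets must be nonempty")
    desc_sets = {}
    for a in anc:
        gen._check(a)
        desc_sets[a] = gen.descendants(a, include_self=True)
    vals = [sum(1 for p in pro if p in desc_sets[a]) for a in anc]
    return pd.Series(vals, index=pd.Index(anc, name="ancestor"), name="coverage")


def path_distance(gen: Genealogy, i: int, j: int, ancestor: int) -> int:
    """Minimal total meiotic distance g_ai + g_aj linking ``i`` and ``j``
    through ``ancestor``.  The two ascending paths need not be disjoint."""
    di = gen.min_distance(i, ancestor)
    dj = gen.min_distance(j, ancestor)
    if di is None or dj is None:
        raise PedigreeError(
            f"{ancestor} is not a common ancestor of {i} and {j}"
        )
    return di + dj


def min_mrca_distance(
    gen: Genealogy, subjects: Iterable[int]
) -> pd.DataFrame:
    """Pairwise minimal meiotic distances through MRCAs.

    Entry (i, j) is min over MRCAs a of the pair of path_distance(i, j, a);
    ``UNRELATED`` (-1) marks pairs without a common ancestor; the diagonal
    is 0.
    """
    subs = sorted(set(subjects))
    if len(subs) < 2:
        raise PedigreeError("need at least 2 subjects")
    n = len(subs)
    mat = np.zeros((n, n), dtype=int)
    for a in range(n):
        for b in range(a + 1, n):
            mrcas = gen.find_mrca([subs[a], subs[b]])
            if not mrcas:
                d = UNRELATED
            else:
                d = min(sum(dd.values()) for dd in mrcas.values())
            mat[a, b] = mat[b, a] = d
    idx = pd.Index(subs, name="id")
    return pd.DataFrame(mat, index=idx, columns=idx)


# -------------------------------------------------------------------- report


def describe_report(gen: Genealogy) -> pd.DataFrame:
    """Corpus-level per-generation table (C_g, I_g, founder occurrences)
    plus scalars, as used by the ``describe`` CLI subcommand."""
    c = completeness(gen)
    i = implex(gen)
    profs = generation_profiles(gen)
    fo: Counter = Counter()
    for p in profs:
        fo.update(p.founder_occ)
    table = pd.DataFrame({"completeness": c, "implex": i})
    table["founder_occurrences"] = [fo.get(g, 0) for g in table.index]
    table.attrs.update(counts(gen))
    table.attrs["depth"] = depth(gen)
    table.attrs.update(
        {f"mean_{k}": v for k, v in mean_depth(gen).items()}
    )
    table.attrs["n_founders"] = len(gen.founders)
    table.attrs["n_half_founders"] = len(gen.half_founders)
    table.attrs["n_probands"] = len(gen.probands)
    return table
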