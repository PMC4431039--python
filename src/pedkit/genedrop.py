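"""Monte-Carlo gene-dropping and segment-dropping simulation.

Alleles (or chromosomal segments) are assigned to chosen ancestors and
segregated down the genealogy: in topological order every individual draws
one gamete per parent, and a gamete carries the tracked allele with
probability min(t * c, 1) where c is the parent's copy number and t the
per-copy transmission probability for that (parent sex, child sex) pair —
t = 1/2 everywhere reproduces Mendelian segregation (a heterozygous parent
transmits with probability 1/2, a homozygous parent with certainty).

Segment dropping multiplies the per-meiosis transmission probability by
(1 - r_sex), the chance the segment survives recombination on the parent's
sex-specific genetic map; a segment that fails to transmit intact is lost to
that line.  Homozygote carriers may be subject to viability selection with
survival probability s: a non-surviving individual's gamete pair is redrawn
until a surviving genotype results (or, optionally, the whole replicate is
rejected).

Replicates are simulated in fixed-size chunks, each driven by its own
counter-based Philox stream keyed on (seed, chunk index), so results are
bit-identical regardless of how chunks are scheduled across workers.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .pedigree import Genealogy, PedigreeError, UNKNOWN, MALE, FEMALE

__all__ = [
    "TransmissionModel",
    "SegmentModel",
    "SimulationResult",
    "drop_alleles",
    "genotype_probs",
    "allele_frequencies",
    "ibd_sharing_prob",
    "drop_segment",
    "classify_ancestor",
]

CHUNK = 65_536  # replicates per RNG substream; fixed so worker count is moot


def _check_prob(p: float, what: str) -> float:
    if not (0.0 <= p <= 1.0):
        raise PedigreeError(f"{what} must be in [0, 1], got {p}")
    return float(p)


@dataclass
class TransmissionModel:
    """Sex-stratified transmission and homozygote-viability parameters.

    ``transmit[(parent_sex, child_sex)]`` is the per-copy probability that a
    gamete carries the tracked allele; default 1/2 everywhere (Mendelian).
    ``homozygote_survival`` is the probability a two-copy carrier survives;
    with ``reject_replicates`` a death discards the whole replicate instead
    of redrawing the individual's gametes.
    """

    transmit: Mapping[tuple[int, int], float] = field(default_factory=dict)
    homozygote_survival: float = 1.0
    reject_replicates: bool = False

    def __post_init__(self) -> None:
        full = {(p, c): 0.5 for p in (MALE, FEMALE) for c in (MALE, FEMALE)}
        for k, v in dict(self.transmit).items():
            if k not in full:
                raise PedigreeError(f"invalid (parent_sex, child_sex) key {k}")
            full[k] = _check_prob(v, f"transmit{k}")
        object.__setattr__(self, "transmit", full)
        _check_prob(self.homozygote_survival, "homozygote_survival")

    def t(self, parent_sex: int, child_sex: int) -> float:
        return self.transmit[(parent_sex, child_sex)]


@dataclass
class SegmentModel:
    """A chromosomal segment with sex-specific genetic lengths.

    Per meiosis the segment is transmitted intact with probability
    t * (1 - r_sex) where r_sex is the breakage probability on the
    transmitting parent's map.  When not given explicitly, r is derived from
    the map length L (cM) by Haldane's map function r = 1 - exp(-L/100)
    (Poisson crossover model); r = 0 for L = 0 and r is non-decreasing in L.
    """

    length_male_cm: float = 0.0
    length_female_cm: float = 0.0
    breakage_male: float | None = None
    breakage_female: float | None = None

    def __post_init__(self) -> None:
        if self.length_male_cm < 0 or self.length_female_cm < 0:
            raise PedigreeError("segment lengths must be non-negative")
        for r in (self.breakage_male, self.breakage_female):
            if r is not None:
                _check_prob(r, "breakage")

    def r(self, parent_sex: int) -> float:
        if parent_sex == MALE:
            if self.breakage_male is not None:
                return self.breakage_male
            return 1.0 - float(np.exp(-self.length_male_cm / 100.0))
        if self.breakage_female is not None:
            return self.breakage_female
        return 1.0 - float(np.exp(-self.length_female_cm / 100.0))


@dataclass
class SimulationResult:
    """Per-replicate copy counts for the requested subjects.

    ``counts[r, k]`` is the number of tracked copies (0/1/2) carried by
    subject ``subjects[k]`` in replicate r.
    """

    subjects: tuple[int, ...]
    counts: np.ndarray
    n_replicates: int
    seed: int

    def column(self, subject: int) -> np.ndarray:
        return self.counts[:, self.subjects.index(subject)]


# ------------------------------------------------------------------- engine


def _simulation_plan(
    gen: Genealogy,
    ancestor_states: Mapping[int, int],
    segment: SegmentModel | None,
    model: TransmissionModel,
) -> list[tuple[int, int, float, int, float]]:
    """Flatten the genealogy into per-individual transmission instructions.

    Only individuals descending from a seeded ancestor can carry the allele;
    everyone else stays at 0 copies and is skipped.  Returns tuples
    (ind, father, p_father_per_copy, mother, p_mother_per_copy).
    """
    for a, c in ancestor_states.items():
        gen._check(a)
        if c not in (1, 2):
            raise PedigreeError(
                f"seeded copies must be 1 or 2, got {c} for ancestor {a}"
            )
    relevant: set[int] = set()
    for a in ancestor_states:
        relevant |= gen.descendants(a, include_self=True)
    plan = []
    for ind in gen.individuals:
        if ind in ancestor_states or ind not in relevant:
            continue
        f, m = gen.parents(ind)
        csex = gen.sex(ind)
        pf = pm = 0.0
        if f != UNKNOWN and f in relevant:
            pf = model.t(MALE, csex)
            if segment is not None:
                pf *= 1.0 - segment.r(MALE)
        else:
            f = UNKNOWN
        if m != UNKNOWN and m in relevant:
            pm = model.t(FEMALE, csex)
            if segment is not None:
                pm *= 1.0 - segment.r(FEMALE)
        else:
            m = UNKNOWN
        plan.append((ind, f, pf, m, pm))
    return plan


def _run_chunk(
    plan: list[tuple[int, int, float, int, float]],
    ancestor_states: Mapping[int, int],
    subjects: tuple[int, ...],
    m: int,
    model: TransmissionModel,
    seed: int,
    chunk_idx: int,
) -> np.ndarray:
    rng = np.random.Generator(
        np.random.Philox(key=(np.uint64(seed) << np.uint64(20)) + np.uint64(chunk_idx))
    )
    copies: dict[int, np.ndarray] = {
        a: np.full(m, c, dtype=np.int8) for a, c in ancestor_states.items()
    }
    s = model.homozygote_survival
    alive = np.ones(m, dtype=bool) if model.reject_replicates else None
    zeros = np.zeros(m, dtype=np.int8)
    for ind, f, pf, mo, pm in plan:
        gf = _gamete(rng, copies.get(f, zeros), pf, m)
        gm = _gamete(rng, copies.get(mo, zeros), pm, m)
        c = gf + gm
        if s < 1.0:
            dead = (c == 2) & (rng.random(m) >= s)
            if model.reject_replicates:
                alive &= ~dead
            else:
                tries = 0
                while dead.any():
                    tries += 1
                    if tries > 10_000:
                        raise PedigreeError(
                            "cannot realise a surviving genotype for "
                            f"individual {ind}; survival too low"
                        )
                    idx = np.nonzero(dead)[0]
                    gf[idx] = _gamete(rng, copies.get(f, zeros)[idx], pf, len(idx))
                    gm[idx] = _gamete(rng, copies.get(mo, zeros)[idx], pm, len(idx))
                    c[idx] = gf[idx] + gm[idx]
                    dead[idx] = (c[idx] == 2) & (rng.random(len(idx)) >= s)
        copies[ind] = c
    out = np.zeros((m, len(subjects)), dtype=np.int8)
    for k, subj in enumerate(subjects):
        col = copies.get(subj)
        if col is None:
            col = zeros
        out[:, k] = col
    if alive is not None:
        out = out[alive]
    return out


def _gamete(
    rng: np.random.Generator, parent_copies: np.ndarray, p: float, m: int
) -> np.ndarray:
    """Bernoulli gamete: carries the allele with prob min(p * copies, 1)."""
    if p == 0.0:
        return np.zeros(m, dtype=np.int8)
    prob = np.minimum(p * parent_copies, 1.0)
    return (rng.random(m) < prob).astype(np.int8)


def drop_alleles(
    gen: Genealogy,
    ancestor_states: Mapping[int, int],
    subjects: Iterable[int],
    n: int,
    model: TransmissionModel | None = None,
    seed: int = 0,
    segment: SegmentModel | None = None,
    threads: int = 1,
) -> SimulationResult:
    """Segregate seeded alleles down the genealogy for ``n`` replicates.

    ``ancestor_states`` maps ancestor id -> seeded copy number (1 or 2);
    founders not seeded carry 0 copies.  Reproducible given ``seed``; the
    replicate stream is chunked so ``threads`` never changes the result.
    """
    if n < 1:
        raise PedigreeError("need at least one replicate")
    model = model or TransmissionModel()
    subs = tuple(sorted(set(subjects)))
    for x in subs:
        gen._check(x)
    plan = _simulation_plan(gen, ancestor_states, segment, model)
    chunks = [(k, min(CHUNK, n - k * CHUNK)) for k in range((n + CHUNK - 1) // CHUNK)]

    def job(arg: tuple[int, int]) -> np.ndarray:
        k, m = arg
        return _run_chunk(plan, ancestor_states, subs, m, model, seed, k)

    if threads <= 1 or len(chunks) == 1:
        parts = [job(c) for c in chunks]
    else:
        with ThreadPoolExecutor(max_workers=threads) as ex:
            parts = list(ex.map(job, chunks))
    counts = np.vstack(parts)
    return SimulationResult(subs, counts, counts.shape[0], seed)


# ---------------------------------------------------------------- summaries


def genotype_probs(result: SimulationResult) -> pd.DataFrame:
    """Per-subject probabilities of carrying 0/1/2 copies, with Monte-Carlo
    standard errors sqrt(p(1-p)/n).  Rows sum to one."""
    n = result.n_replicates
    rows = []
    for k, s in enumerate(result.subjects):
        col = result.counts[:, k]
        for copies in (0, 1, 2):
            p = float(np.mean(col == copies))
            rows.append((s, copies, p, float(np.sqrt(p * (1 - p) / n))))
    return pd.DataFrame(rows, columns=["id", "copies", "prob", "se"])


def allele_frequencies(result: SimulationResult) -> pd.Series:
    """Mean copy count per subject.  Under default transmission this equals
    GC(subject, ancestor) x seeded copies in expectation."""
    means = result.counts.mean(axis=0)
    return pd.Series(
        means, index=pd.Index(result.subjects, name="id"), name="mean_copies"
    )


# --------------------------------------------------------------- IBD sharing


def _require_common(gen: Genealogy, pair: tuple[int, int], ancestor: int) -> None:
    i, j = pair
    if ancestor not in gen.common_ancestors([i, j]):
        raise PedigreeError(
            f"{ancestor} is not a common ancestor of {i} and {j}"
        )


def ibd_sharing_prob(
    gen: Genealogy,
    pair: tuple[int, int],
    ancestor: int,
    n: int,
    seed: int = 0,
    model: TransmissionModel | None = None,
    segment: SegmentModel | None = None,
    threads: int = 1,
) -> dict[str, float]:
    """Probability the pair shares >= 1 allele IBD inherited from ``ancestor``.

    One copy of a distinct tracked allele is seeded in the ancestor per
    replicate; the estimate is the fraction of replicates in which both
    subjects carry a descendant copy.  For an MRCA of the pair this equals
    the product of the ancestor's genetic contributions to the two subjects;
    for more remote common ancestors it exceeds the product.  Returns
    ``{"prob": .., "se": .., "n": ..}``.
    """
    _require_common(gen, pair, ancestor)
    res = drop_alleles(
        gen, {ancestor: 1}, pair, n, model=model, seed=seed,
        segment=segment, threads=threads,
    )
    i, j = pair
    both = (res.column(i) >= 1) & (res.column(j) >= 1)
    p = float(np.mean(both))
    return {
        "prob": p,
        "se": float(np.sqrt(p * (1 - p) / res.n_replicates)),
        "n": res.n_replicates,
    }


def drop_segment(
    gen: Genealogy,
    pair: tuple[int, int],
    ancestor: int,
    segment: SegmentModel,
    n: int,
    seed: int = 0,
    model: TransmissionModel | None = None,
    threads: int = 1,
) -> dict[str, float]:
    """Probability both pair members carry the ancestor's segment intact.

    Per meiosis the segment is transmitted whole with probability
    t * (1 - r_sex); a broken segment is lost for all further transmission.
    With r = 0 on both maps this reduces to :func:`ibd_sharing_prob`.
    """
    return ibd_sharing_prob(
        gen, pair, ancestor, n, seed=seed, model=model,
        segment=segment, threads=threads,
    )


def classify_ancestor(gen: Genealogy, pair: tuple[int, int], ancestor: int) -> str:
    """Ancestor class for a pair: 'MRCA-Founder', 'MRCA', 'Founder' or
    'In between' (a common ancestor that is neither a founder nor most
    recent)."""
    _require_common(gen, pair, ancestor)
    is_mrca = ancestor in gen.find_mrca(list(pair))
    is_founder = ancestor in gen.founders
    if is_mrca and is_founder:
        return "MRCA-Founder"
    if is_mrca:
        return "MRCA"
    if is_founder:
        return "Founder"
    return "In between"
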