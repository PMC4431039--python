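"""Worked pedigrees and a synthetic-genealogy generator.

The worked pedigrees encode the classic relationship configurations with
analytically known kinship/inbreeding/contribution values (full sibs,
first/second/double-first cousins, a child of full sibs, ...).  The generator
produces layered founder-population genealogies: discrete non-overlapping
generations, random mating within a generation, Poisson offspring counts, and
optional erasure of parental links to emulate incomplete records.  Extracting
the ascending tree of sampled probands from such a population mimics the
shape of genealogies reconstructed from vital-record databases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Genealogy, build_genealogy, MALE, FEMALE

__all__ = ["FixtureSpec", "worked_pedigree", "generate", "WORKED_NAMES"]


def _table(rows: list[tuple[int, int, int, int]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["ind", "father", "mother", "sex"])


def _worked_tables() -> dict[str, pd.DataFrame]:
    t: dict[str, pd.DataFrame] = {}

    # Child (3) with both parents known: phi(parent, child) = 1/4.
    t["trio"] = _table([(1, 0, 0, 1), (2, 0, 0, 2), (3, 1, 2, 1)])

    # Two full sibs (3, 4): phi = 1/4.
    t["full_sibs"] = _table(
        [(1, 0, 0, 1), (2, 0, 0, 2), (3, 1, 2, 1), (4, 1, 2, 2)]
    )

    # First cousins 7 and 8 (phi = 1/16); their child 9 has f = 1/16.
    t["first_cousins"] = _table(
        [
            (1, 0, 0, 1), (2, 0, 0, 2),          # shared grandparents
            (3, 1, 2, 1), (4, 1, 2, 2),          # sibs
            (5, 0, 0, 2), (6, 0, 0, 1),          # their spouses
            (7, 3, 5, 1), (8, 6, 4, 2),          # the cousins
            (9, 7, 8, 1),                        # child: f = 1/16
        ]
    )

    # Second cousins 11 and 12 (phi = 1/64); their child 13 has f = 1/64.
    t["second_cousins"] = _table(
        [
            (1, 0, 0, 1), (2, 0, 0, 2),
            (3, 1, 2, 1), (4, 1, 2, 2),
            (5, 0, 0, 2), (6, 0, 0, 1),
            (7, 3, 5, 1), (8, 6, 4, 2),          # first cousins
            (9, 0, 0, 2), (10, 0, 0, 1),
            (11, 7, 9, 1), (12, 10, 8, 2),       # second cousins
            (13, 11, 12, 1),                     # child: f = 1/64
        ]
    )

    # Double first cousins 9 and 10 (phi = 1/8); their child 11 has f = 1/8.
    t["double_first_cousins"] = _table(
        [
            (1, 0, 0, 1), (2, 0, 0, 2),          # couple A
            (5, 0, 0, 1), (6, 0, 0, 2),          # couple B
            (3, 1, 2, 1), (4, 1, 2, 2),          # A's children
            (7, 5, 6, 1), (8, 5, 6, 2),          # B's children
            (9, 3, 8, 1),                        # A-son x B-daughter
            (10, 7, 4, 2),                       # B-son x A-daughter
            (11, 9, 10, 1),                      # child: f = 1/8
        ]
    )

    # Child (5) of full sibs: I_2 = 0.5 while C_2 = 1; occ(5 -> 1) = 2;
    # f_5 = 1/4.
    t["incest_loop"] = _table(
        [(1, 0, 0, 1), (2, 0, 0, 2), (3, 1, 2, 1), (4, 1, 2, 2), (5, 3, 4, 1)]
    )

    # Proband (6) whose parents are paternal half sibs: GC(6, 1) = 1/2 via
    # two grandparental paths even though 1 fills only half the slots.
    t["collapsed_gc"] = _table(
        [
            (1, 0, 0, 1), (2, 0, 0, 2), (3, 0, 0, 2),
            (4, 1, 2, 1), (5, 1, 3, 2),
            (6, 4, 5, 1),
        ]
    )
    return t


WORKED_NAMES = tuple(sorted(_worked_tables().keys()))


def worked_pedigree(name: str) -> pd.DataFrame:
    """A named worked pedigree table with analytically known measures."""
    tables = _worked_tables()
    if name not in tables:
        raise KeyError(
            f"unknown worked pedigree {name!r}; choose from {WORKED_NAMES}"
        )
    return tables[name]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic layered-population generator.

    ``n_founders`` individuals form the top generation; each of
    ``n_generations - 1`` subsequent generations is produced by pairing the
    previous generation's males and females and drawing per-couple offspring
    counts from a Poisson(``mean_offspring``) truncated at ``max_offspring``.
    ``missing_parent_prob`` independently erases each parental link after
    construction (emulating incomplete records; never creates cycles).  The
    output carries a ``generation`` annotation column (0 = founding layer),
    so the final layer can be used as the sampled proband set.
    ``mating`` is 'random' (uniform pairing, remating allowed across couples),
    'sib-avoiding' (pairs sharing a parent are rejected) or
    'allow-inbreeding' (alias of random; with a small founder pool inbred
    descendants arise quickly).
    """

    n_founders: int = 20
    n_generations: int = 5
    mean_offspring: float = 2.2
    missing_parent_prob: float = 0.0
    mating: str = "random"
    seed: int = 0
    max_offspring: int = 8


def generate(spec: FixtureSpec) -> pd.DataFrame:
    """Generate a reproducible synthetic pedigree table per ``spec``.

    The returned table always passes validation; the last non-empty
    generation's individuals are the childless probands.
    """
    if spec.n_founders < 2:
        raise ValueError("need at least 2 founders")
    if spec.mating not in ("random", "sib-avoiding", "allow-inbreeding"):
        raise ValueError(f"unknown mating scheme {spec.mating!r}")
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple[int, int, int, int, int]] = []
    next_id = 1
    layer = 0

    def new_ind(father: int, mother: int) -> tuple[int, int]:
        nonlocal next_id
        sex = MALE if rng.random() < 0.5 else FEMALE
        rows.append((next_id, father, mother, sex, layer))
        next_id += 1
        return rows[-1][0], sex

    current: list[tuple[int, int]] = [new_ind(0, 0) for _ in range(spec.n_founders)]
    parents_of: dict[int, tuple[int, int]] = {i: (0, 0) for i, _ in current}

    for layer in range(1, spec.n_generations):
        males = [i for i, s in current if s == MALE]
        females = [i for i, s in current if s == FEMALE]
        if not males or not females:
            break
        n_couples = min(len(males), len(females))
        males = list(rng.permutation(males))
        females = list(rng.permutation(females))
        nxt: list[tuple[int, int]] = []
        for k in range(n_couples):
            f, m = int(males[k]), int(females[k])
            if spec.mating == "sib-avoiding":
                pf, pm = parents_of[f], parents_of[m]
                shares = any(
                    p != 0 and p in pm for p in pf
                )
                if shares:
                    continue
            n_kids = min(int(rng.poisson(spec.mean_offspring)), spec.max_offspring)
            for _ in range(n_kids):
                cid, csex = new_ind(f, m)
                parents_of[cid] = (f, m)
                nxt.append((cid, csex))
        if not nxt:
            break
        current = nxt

    df = pd.DataFrame(
        rows, columns=["ind", "father", "mother", "sex", "generation"]
    )
    if spec.missing_parent_prob > 0:
        erase_f = rng.random(len(df)) < spec.missing_parent_prob
        erase_m = rng.random(len(df)) < spec.missing_parent_prob
        df.loc[erase_f, "father"] = 0
        df.loc[erase_m, "mother"] = 0
    return df


def generate_genealogy(spec: FixtureSpec) -> Genealogy:
    """Convenience: generate and build in one step (auto-completion on, so
    erased links never leave dangling references — erasure only removes
    links, it cannot create any)."""
    return build_genealogy(generate(spec))
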