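from __future__ import annotations

import pytest

from pedkit import build_genealogy, worked_pedigree
from pedkit.fixtures import FixtureSpec, generate, WORKED_NAMES


@pytest.fixture(params=WORKED_NAMES)
def worked(request):
    """Every named worked pedigree, built."""
    return build_genealogy(worked_pedigree(request.param))


@pytest.fixture
def trio():
    return build_genealogy(worked_pedigree("trio"))


@pytest.fixture
def full_sibs():
    return build_genealogy(worked_pedigree("full_sibs"))


@pytest.fixture
def first_cousins():
    return build_genealogy(worked_pedigree("first_cousins"))


@pytest.fixture
def incest_loop():
    return build_genealogy(worked_pedigree("incest_loop"))


@pytest.fixture
def collapsed_gc():
    return build_genealogy(worked_pedigree("collapsed_gc"))


def random_genealogies(n, *, start_seed=0, max_individuals=None, **kw):
    """Deterministic stream of small synthetic genealogies for oracle tests."""
    defaults = dict(n_founders=6, n_generations=4, mean_offspring=2.0,
                    mating="allow-inbreeding")
    defaults.update(kw)
    out = []
    seed = start_seed
    while len(out) < n:
        g = build_genealogy(generate(FixtureSpec(seed=seed, **defaults)))
        seed += 1
        if max_individuals is not None and len(g) > max_individuals:
            continue
        out.append(g)
    return out
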