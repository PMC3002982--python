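"""Shared fixtures: small CRM models, trees and simulated datasets."""

import numpy as np
import pytest

from crmalign.birth_death import BirthDeathParams
from crmalign.model import CRMModelSpec, IndelParams, assemble_crm_template
from crmalign.phylo import parse_newick
from crmalign.profiles import BindingProfile
from crmalign.substitution import build_gtr


def informative_profile(name, length, seed, concentration=0.1):
    """A peaked binding profile with the information content typical of
    curated PWMs (~1.3-1.8 bits per column)."""
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(4, concentration), size=length)
    cols = np.clip(cols, 5e-3, None)
    cols /= cols.sum(axis=1, keepdims=True)
    return BindingProfile(name, cols)


@pytest.fixture(scope="session")
def background_gtr():
    return build_gtr([0.9, 2.2, 0.7, 1.0, 2.5, 1.0], [0.3, 0.2, 0.2, 0.3])


@pytest.fixture(scope="session")
def six_taxon_tree():
    return parse_newick(
        "(((a:0.04,b:0.05):0.03,(c:0.06,d:0.04):0.02):0.03,"
        "(e:0.07,f:0.06):0.04);"
    )


def make_spec(n_factors=2, length=8, delta=0.15, mu=0.08, alpha=0.02,
              beta=0.55, seed=0):
    from crmalign.birth_death import derive_lambda

    profiles = [
        informative_profile(f"tf{i}", length, seed + 17 * i)
        for i in range(n_factors)
    ]
    lam = derive_lambda(delta, mu)
    return CRMModelSpec(
        profiles=profiles,
        bd_params=BirthDeathParams(lam, mu),
        indel_params=IndelParams(alpha, beta),
    )


def turnover_free_spec(n_factors=3, length=12, delta=0.1):
    """Study conditions for coordinate-exact round-trip checks: no indels,
    vanishing turnover, and high-information motifs (~18-20 bits, the sharp
    end of curated PWMs) so that site identity is unambiguous and exact
    recovery probes the machinery rather than detection power."""
    from crmalign.birth_death import derive_lambda

    profiles = [
        informative_profile(f"tf{i}", length, 100 + i, concentration=0.03)
        for i in range(n_factors)
    ]
    lam = derive_lambda(delta, 1e-9)
    return CRMModelSpec(
        profiles=profiles,
        bd_params=BirthDeathParams(lam, 1e-9),
        indel_params=IndelParams(1e-9, 0.5),
    )


@pytest.fixture(scope="session")
def small_spec():
    return make_spec(n_factors=2, length=6)


@pytest.fixture(scope="session")
def small_template(small_spec, background_gtr):
    return assemble_crm_template(small_spec, background_gtr)
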