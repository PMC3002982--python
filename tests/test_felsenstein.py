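"""Clade emission likelihoods vs. brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from crmalign.birth_death import BirthDeathParams, turnover_probabilities
from crmalign.felsenstein import clade_vectors, emission_likelihood
from crmalign.model import BG, CRMModelSpec, IndelParams, assemble_crm_template
from crmalign.phylo import parse_newick
from crmalign.profiles import BindingProfile
from crmalign.substitution import (
    ALPHABET,
    NUC_INDEX,
    build_gtr,
    cross_functional_matrix,
    substitution_probabilities,
)

BD = BirthDeathParams(0.02, 0.08)


def make_template(seed=0, length=1):
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(4, 0.8), size=length)
    cols = np.clip(cols, 1e-3, None)
    cols /= cols.sum(axis=1, keepdims=True)
    bg = build_gtr(rng.uniform(0.3, 2.0, 6), rng.dirichlet(np.full(4, 6.0)))
    spec = CRMModelSpec(
        profiles=[BindingProfile("tf", cols)],
        bd_params=BD,
        indel_params=IndelParams(0.02, 0.6),
    )
    return assemble_crm_template(spec, bg)


def branch_matrices(template, cls_id, t):
    """(P_same, P_to_bg, p_col, q_col) for one branch via the public API.

    Per-column turnover weights are the whole-site retention/loss
    probabilities raised to 1/L (L = profile length): a class history that
    keeps or drops an entire site across a branch is charged the site-level
    p(t) or q(t) exactly once.
    """
    cls = template.class_registry[cls_id]
    bg = template.class_registry[BG]
    p_same = substitution_probabilities(cls.rate_matrix, t).probs
    p_mix = (
        p_same if cls_id == BG else cross_functional_matrix(cls, bg, t).probs
    )
    if cls_id == BG:
        return p_same, p_mix, 1.0, 0.0
    tp = turnover_probabilities(BD, t)
    L = template.site_length(cls_id)
    return p_same, p_mix, tp.retention ** (1.0 / L), tp.loss ** (1.0 / L)


def enumerate_standard(template, tree, seqs, cls_id, pi):
    """Sum over all internal-node nucleotide assignments, single class."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    mats = {
        n.name: branch_matrices(template, cls_id, n.length)[0]
        for n in tree.postorder()
        if n.parent is not None
    }
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internals)):
        x = {n.name: a for n, a in zip(internals, assign)}
        for leaf in tree.leaves:
            x[leaf.name] = NUC_INDEX[seqs[leaf.name]]
        lik = pi[x[tree.root.name]]
        for n in tree.postorder():
            if n.parent is not None:
                lik *= mats[n.name][x[n.parent.name], x[n.name]]
        total += lik
    return math.log(total)


def enumerate_lossy(template, tree, seqs, cls_id, pi):
    """Sum over all monotone loss labelings x internal nucleotides.

    A labeling assigns the site class or bg to every node below the root
    (root keeps ``cls_id``); once a lineage drops to bg it stays bg.  Each
    branch contributes the retention weight p (class kept) or loss weight q
    (class dropped, substitution via the change-time mixture matrix).
    """
    nodes = [n for n in tree.postorder() if n.parent is not None]
    internals = [n for n in tree.postorder() if not n.is_leaf]
    total = 0.0
    for labels in itertools.product([cls_id, BG], repeat=len(nodes)):
        lab = {n.name: l for n, l in zip(nodes, labels)}
        lab[tree.root.name] = cls_id
        ok = all(
            not (lab[n.parent.name] == BG and lab[n.name] != BG) for n in nodes
        )
        if not ok:
            continue
        weight = 1.0
        for n in nodes:
            pc, cc = lab[n.parent.name], lab[n.name]
            _, _, p, q = branch_matrices(template, cls_id, n.length)
            if pc != BG:
                weight *= p if cc != BG else q
        for assign in itertools.product(range(4), repeat=len(internals)):
            x = {n.name: a for n, a in zip(internals, assign)}
            for leaf in tree.leaves:
                x[leaf.name] = NUC_INDEX[seqs[leaf.name]]
            lik = pi[x[tree.root.name]]
            for n in nodes:
                pc, cc = lab[n.parent.name], lab[n.name]
                p_same, p_mix, _, _ = branch_matrices(
                    template, cls_id if pc != BG else BG, n.length
                )
                mat = p_same if pc == cc else p_mix
                lik *= mat[x[n.parent.name], x[n.name]]
            total += weight * lik
    return math.log(total)


def recurse_gainloss(template, node, seqs, x, cls_id):
    """Plain-Python recursion choosing, per branch and parent nucleotide, the
    higher-probability class history (retention vs. loss to background)."""
    if node.is_leaf:
        return 1.0 if NUC_INDEX[seqs[node.name]] == x else 0.0
    prod = 1.0
    for child in node.children:
        p_same, p_mix, p, q = branch_matrices(template, cls_id, child.length)
        stay = sum(
            p_same[x, y] * recurse_gainloss(template, child, seqs, y, cls_id)
            for y in range(4)
        )
        if cls_id == BG:
            prod *= stay
        else:
            lose = sum(
                p_mix[x, y] * recurse_gainloss(template, child, seqs, y, BG)
                for y in range(4)
            )
            prod *= max(p * stay, q * lose)
    return prod


@pytest.fixture(scope="module")
def template():
    return make_template(seed=5)


def random_clade(template, newick, seed):
    tree = parse_newick(newick)
    rng = np.random.default_rng(seed)
    seqs = {name: ALPHABET[rng.integers(4)] for name in tree.leaf_names}
    return tree, seqs


class TestEmissionOracles:
    def test_single_leaf_base_case(self, template):
        tree = parse_newick("(a:0.1,b:0.1);")
        leaf = tree.nodes["a"]
        pi = template.class_registry[BG].rate_matrix.equilibrium
        got = emission_likelihood(template, leaf, {"a": "C"}, BG)
        assert got == pytest.approx(math.log(pi[1]), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_standard_matches_enumeration(self, template, seed):
        tree, seqs = random_clade(
            template, "((a:0.21,b:0.34):0.18,c:0.42);", seed
        )
        for cls_id in [BG, "tf|+|0", "tf|-|0"]:
            pi = template.class_registry[cls_id].rate_matrix.equilibrium
            want = enumerate_standard(template, tree, seqs, cls_id, pi)
            got = emission_likelihood(template, tree.root, seqs, cls_id,
                                      "standard")
            assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_lossy_matches_labeling_enumeration(self, template, seed):
        tree, seqs = random_clade(
            template, "((a:0.3,b:0.25):0.2,(c:0.4,d:0.15):0.1);", seed
        )
        cls_id = "tf|+|0"
        pi = template.class_registry[cls_id].rate_matrix.equilibrium
        want = enumerate_lossy(template, tree, seqs, cls_id, pi)
        got = emission_likelihood(template, tree.root, seqs, cls_id, "lossy")
        assert got == pytest.approx(want, abs=1e-10)

    def test_lossy_for_background_equals_standard(self, template):
        tree, seqs = random_clade(template, "((a:0.3,b:0.2):0.1,c:0.5);", 3)
        got_l = emission_likelihood(template, tree.root, seqs, BG, "lossy")
        got_s = emission_likelihood(template, tree.root, seqs, BG, "standard")
        assert got_l == pytest.approx(got_s, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_gainloss_matches_recursion_oracle(self, template, seed):
        tree, seqs = random_clade(
            template, "((a:0.3,b:0.25):0.2,(c:0.4,d:0.15):0.1);", seed
        )
        cls_id = "tf|+|0"
        cls = template.class_registry[cls_id]
        pi = cls.rate_matrix.equilibrium
        want = math.log(
            sum(
                pi[x] * recurse_gainloss(template, tree.root, seqs, x, cls_id)
                for x in range(4)
            )
        )
        got = emission_likelihood(template, tree.root, seqs, cls_id, "gainloss")
        assert got == pytest.approx(want, abs=1e-10)

    def test_gainloss_upper_bounded_by_lossy(self, template):
        # max over histories <= sum over histories, pointwise
        for seed in range(5):
            tree, seqs = random_clade(
                template, "((a:0.3,b:0.25):0.2,c:0.6);", seed
            )
            gl = emission_likelihood(template, tree.root, seqs, "tf|+|0",
                                     "gainloss")
            lo = emission_likelihood(template, tree.root, seqs, "tf|+|0",
                                     "lossy")
            assert gl <= lo + 1e-12

    @pytest.mark.parametrize("seed", range(4))
    def test_multi_column_site_classes_match_oracle(self, seed):
        # a column from the middle of an L = 3 profile behaves identically
        # to the single-column oracle under its own class
        template = make_template(seed=11, length=3)
        tree, seqs = random_clade(
            template, "((a:0.3,b:0.25):0.2,c:0.45);", seed
        )
        cls_id = "tf|+|1"
        pi = template.class_registry[cls_id].rate_matrix.equilibrium

        want = enumerate_lossy(template, tree, seqs, cls_id, pi)
        got = emission_likelihood(template, tree.root, seqs, cls_id, "lossy")
        assert got == pytest.approx(want, abs=1e-10)

    def test_vectors_scale_consistency(self, template):
        # normalisation bookkeeping: scaled vectors reproduce plain products
        tree, seqs = random_clade(template, "((a:0.3,b:0.2):0.1,c:0.5);", 9)
        vec = clade_vectors(template, tree.root, seqs, "standard")
        assert np.all(vec.values <= 1.0 + 1e-12)
        assert np.all(np.isfinite(vec.log_scale[0]))
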