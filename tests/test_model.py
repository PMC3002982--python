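"""Structural and normalisation tests for PPHMM template assembly."""

import numpy as np
import pytest

from crmalign.birth_death import BirthDeathParams
from crmalign.model import (
    BG,
    CRMModelSpec,
    IndelParams,
    ModelConstructionError,
    PPHMMTemplate,
    StateKind,
    assemble_crm_template,
    build_background_template,
    build_gain_submodel,
    build_loss_submodel,
    build_retention_submodel,
    crm_state_count,
    submodel_states,
)
from crmalign.profiles import BindingProfile
from crmalign.substitution import build_gtr, jukes_cantor, substitution_probabilities

BD = BirthDeathParams(0.02, 0.08)
INDEL = IndelParams(0.03, 0.6)


def make_profile(name="tf1", length=6, seed=0):
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(4, 0.8), size=length)
    cols = np.clip(cols, 1e-3, None)
    cols /= cols.sum(axis=1, keepdims=True)
    return BindingProfile(name, cols)


def background():
    return build_gtr([0.8, 2.0, 0.9, 1.1, 2.2, 1.0], [0.3, 0.2, 0.2, 0.3])


@pytest.fixture(scope="module")
def crm_template():
    spec = CRMModelSpec(profiles=[make_profile()], bd_params=BD, indel_params=INDEL)
    return assemble_crm_template(spec, background())


class TestBackgroundTemplate:
    def test_rows_normalise(self):
        tpl = build_background_template(INDEL, BD)
        for t in (0.1, 0.2, 1.0):
            T = tpl.transition_matrix(t)
            sums = T.sum(axis=1)
            sums[tpl._ix["stop"]] = 1.0
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_tiny_alpha_suppresses_gap_open(self):
        tpl = build_background_template(IndelParams(1e-9, 0.6), BD)
        T = tpl.transition_matrix(0.1)
        ix = tpl._ix
        assert T[ix["M"], ix["I"]] < 1e-8
        assert T[ix["M"], ix["D"]] < 1e-8

    def test_insert_delete_symmetry(self):
        tpl = build_background_template(INDEL, BD)
        T = tpl.transition_matrix(0.3)
        ix = tpl._ix
        assert T[ix["M"], ix["I"]] == pytest.approx(T[ix["M"], ix["D"]], abs=1e-15)
        assert T[ix["I"], ix["I"]] == pytest.approx(T[ix["D"], ix["D"]], abs=1e-15)
        assert T[ix["I"], ix["M"]] == pytest.approx(T[ix["D"], ix["M"]], abs=1e-15)
        assert T[ix["I"], ix["D"]] == 0.0 and T[ix["D"], ix["I"]] == 0.0


class TestSiteSubmodels:
    def test_retention_chain_structure(self):
        prof = make_profile(length=8)
        _, chain = build_retention_submodel(prof, "+", background())
        assert len(chain) == 8
        assert all(s.kind == StateKind.MATCH for s in chain)
        assert [s.site.position for s in chain] == list(range(8))
        assert all(s.anc_class == s.desc_class for s in chain)

    def test_retention_identity_profile_matches_background_emission(self):
        bg = background()
        prof = BindingProfile("flat", np.tile(bg.equilibrium, (1, 1)))
        tpl, chain = build_retention_submodel(prof, "+", bg)
        model = tpl.instantiate(0.4)
        want = substitution_probabilities(bg, 0.4).probs
        assert np.allclose(model.match_probs[chain[0].id], want, atol=1e-9)

    def test_minus_strand_involution(self):
        prof = make_profile(length=5, seed=3)
        bg = background()
        tpl_plus, _ = build_retention_submodel(prof, "+", bg)
        tpl_rc, _ = build_retention_submodel(
            prof.reverse_complement(), "-", bg
        )
        # minus strand of the reverse complement == plus strand of the original
        for i in range(5):
            a = tpl_plus.class_registry[f"{prof.factor_name}|+|{i}"]
            b = tpl_rc.class_registry[f"{prof.factor_name}|-|{i}"]
            assert np.allclose(a.rate_matrix.rates, b.rate_matrix.rates, atol=1e-12)

    def test_gain_submodel_has_no_same_class_site_states(self):
        prof = make_profile(length=6)
        _, chain = build_gain_submodel(prof, "+", background())
        for st in chain:
            assert not (st.anc_class == st.desc_class and st.anc_class != BG)
        matches = [s for s in chain if s.kind == StateKind.MATCH]
        assert all(s.anc_class == BG and s.desc_class != BG for s in matches)

    def test_loss_mirrors_gain(self):
        prof = make_profile(length=6)
        _, gain = build_gain_submodel(prof, "+", background())
        _, loss = build_loss_submodel(prof, "+", background())
        gk = sorted((s.kind for s in gain))
        # mirror: inserts <-> deletes
        mirrored = sorted(
            {StateKind.INSERT: StateKind.DELETE,
             StateKind.DELETE: StateKind.INSERT,
             StateKind.MATCH: StateKind.MATCH}[s.kind]
            for s in loss
        )
        assert gk == mirrored

    def test_indels_only_on_nonfunctional_lineage(self, crm_template):
        for st in crm_template.states:
            if st.site is None:
                continue
            if st.site.event == "retention":
                assert st.kind == StateKind.MATCH
            elif st.site.event == "gain":
                # ancestor is the non-functional side: gaps appear there
                if st.kind == StateKind.INSERT:
                    assert st.anc_class is None and st.desc_class != BG
                if st.kind == StateKind.DELETE:
                    assert st.anc_class == BG
            elif st.site.event == "loss":
                if st.kind == StateKind.INSERT:
                    assert st.desc_class == BG
                if st.kind == StateKind.DELETE:
                    assert st.anc_class != BG


class TestAssembly:
    def test_state_count_formula(self, crm_template):
        assert len(crm_template.states) == crm_state_count([6])

    def test_all_rows_normalise_across_t_grid(self, crm_template):
        for t in (0.01, 0.1, 0.5, 1.0, 2.0):
            T = crm_template.transition_matrix(t)
            sums = T.sum(axis=1)
            sums[crm_template._ix["stop"]] = 1.0
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_no_gain_entry_when_lambda_zero(self):
        spec = CRMModelSpec(
            profiles=[make_profile()],
            bd_params=BirthDeathParams(0.0, 0.08),
            indel_params=INDEL,
        )
        tpl = assemble_crm_template(spec, background())
        T = tpl.transition_matrix(0.5)
        outside = [
            s.id for s in tpl.states
            if s.site is None or s.site.event != "gain"
        ]
        for st in tpl.states:
            if st.site is not None and st.site.event == "gain":
                assert T[np.ix_(outside, [st.id])].sum() == 0.0

    def test_seven_factor_model_instantiates(self):
        profiles = [make_profile(f"f{i}", length=5, seed=i) for i in range(7)]
        spec = CRMModelSpec(profiles=profiles, bd_params=BD, indel_params=INDEL)
        tpl = assemble_crm_template(spec, background())
        assert len(tpl.states) == crm_state_count([5] * 7)
        for t in (0.01, 0.5, 2.0):
            model = tpl.instantiate(t)
            sums = model.transition_probs.sum(axis=1)
            sums[tpl._ix["stop"]] = 1.0
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_bad_factor_frequencies_rejected(self):
        with pytest.raises(ModelConstructionError):
            CRMModelSpec(
                profiles=[make_profile()],
                bd_params=BD,
                factor_frequencies={"tf1": 0.5},
            )

    def test_assembly_deterministic(self):
        spec = CRMModelSpec(profiles=[make_profile()], bd_params=BD,
                            indel_params=INDEL)
        a = assemble_crm_template(spec, background())
        b = assemble_crm_template(spec, background())
        assert [s.name for s in a.states] == [s.name for s in b.states]
        assert np.array_equal(a.transition_matrix(0.3), b.transition_matrix(0.3))


class TestInstantiate:
    def test_identity_coefficients(self, crm_template):
        direct = crm_template.transition_matrix(0.37)
        model = crm_template.instantiate(0.37, c_branch=1.0, c_indel=1.0)
        assert np.array_equal(model.transition_probs, direct)

    def test_c_branch_rescales(self, crm_template):
        a = crm_template.instantiate(0.2, c_branch=2.0)
        b = crm_template.instantiate(0.4)
        assert np.allclose(a.transition_probs, b.transition_probs, atol=1e-12)
        assert np.allclose(a.match_probs, b.match_probs, atol=1e-12)

    def test_match_emissions_chapman_kolmogorov(self):
        # JC background: retention emission at 2t equals (P(t))^2
        spec = CRMModelSpec(profiles=[], bd_params=BD, indel_params=INDEL)
        tpl = assemble_crm_template(spec, jukes_cantor())
        m1 = tpl.instantiate(0.3)
        m2 = tpl.instantiate(0.6)
        mid = tpl._ix["M"]
        assert np.allclose(
            m1.match_probs[mid] @ m1.match_probs[mid],
            m2.match_probs[mid],
            atol=1e-8,
        )

    def test_invalid_branch(self, crm_template):
        from crmalign.substitution import InvalidBranchError

        with pytest.raises(InvalidBranchError):
            crm_template.instantiate(0.0)
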