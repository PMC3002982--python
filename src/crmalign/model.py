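"""PPHMM templates for CRM evolution and their instantiation at a branch.

A *template* is a state graph whose transition probabilities are closures of
the branch length ``t``; instantiating it at a concrete ``t`` yields a
*phylogenetic pair HMM* (PPHMM) with numeric transition and emission
matrices.  The CRM template wires together:

* a reversible affine **background** indel model (match / insert / delete)
  whose gap-open probability scales as ``1 - e^{-alpha t}`` and whose total
  probability of leaving the background is the birth-death quantity
  ``s(t) = 1 - (1 - b_inf)(1 - b(t))``;

* per factor and strand, three **site submodels**: a gapless *retention*
  chain (ancestral and descendant class both ``W_i``), a *gain* chain
  (ancestor background, descendant functional) and its mirror *loss* chain.
  Within gain/loss submodels indels are permitted only on the non-functional
  lineage; the functional copy of the site is always gapless.

Entry masses from the background into the (factor, strand, event) submodels
are ``freq_f * 0.5 * w_event`` with ``w_gain = (1 - b_inf) b(t)``,
``w_loss = b_inf q(t)`` and ``w_retention = b_inf p(t)``; the three weights
sum to ``s(t)`` and the gain/loss pair balances exactly
(``(1-b_inf) b = b_inf q``), which keeps the overall model reversible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .birth_death import BirthDeathParams, turnover_probabilities
from .profiles import BindingProfile
from .substitution import (
    FunctionalClass,
    InvalidBranchError,
    RateMatrix,
    cross_functional_matrix,
    halpern_bruno,
    substitution_probabilities,
)

__all__ = [
    "StateKind",
    "PPHMMState",
    "PPHMMTemplate",
    "PPHMM",
    "IndelParams",
    "CRMModelSpec",
    "SiteRole",
    "ModelConstructionError",
    "build_background_template",
    "build_retention_submodel",
    "build_gain_submodel",
    "build_loss_submodel",
    "submodel_states",
    "assemble_crm_template",
    "crm_state_count",
    "site_class_id",
]

BG = "bg"


class ModelConstructionError(ValueError):
    pass


class StateKind(IntEnum):
    MATCH = 0
    INSERT = 1
    DELETE = 2
    START = 3
    STOP = 4


@dataclass(frozen=True)
class SiteRole:
    """Where a state sits inside a site submodel (for parse bookkeeping)."""

    factor: str
    strand: str      # '+' or '-'
    event: str       # 'retention' | 'gain' | 'loss'
    position: int    # 0-based profile column, -1 for junction indel states
    length: int


@dataclass(frozen=True)
class PPHMMState:
    id: int
    name: str
    kind: StateKind
    anc_class: str | None   # None = gap on the ancestral side
    desc_class: str | None  # None = gap on the descendant side
    site: SiteRole | None = None

    @property
    def is_emitting(self) -> bool:
        return self.kind in (StateKind.MATCH, StateKind.INSERT, StateKind.DELETE)

    @property
    def cross_functional(self) -> bool:
        return (
            self.anc_class is not None
            and self.desc_class is not None
            and self.anc_class != self.desc_class
        )


@dataclass(frozen=True)
class IndelParams:
    """Gap-open rate ``alpha`` (per unit branch length) and extension
    probability ``beta``."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")


@dataclass
class CRMModelSpec:
    """Everything needed to assemble the CRM evolution model."""

    profiles: list[BindingProfile]
    bd_params: BirthDeathParams
    factor_frequencies: dict[str, float] | None = None
    strand_factor: float = 0.5
    epsilon: float = 0.00001
    indel_params: IndelParams = field(default_factory=lambda: IndelParams(0.02, 0.6))
    # complete-orthology variant: sites are modeled but never gain or lose
    # function (no cross-functional states); site entry mass is the
    # stationary density b_inf
    complete_orthology: bool = False

    def __post_init__(self):
        names = [p.factor_name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ModelConstructionError("duplicate factor names")
        if self.factor_frequencies is None:
            if names:
                self.factor_frequencies = {n: 1.0 / len(names) for n in names}
            else:
                self.factor_frequencies = {}
        if names:
            total = sum(self.factor_frequencies.get(n, 0.0) for n in names)
            if abs(total - 1.0) > 1e-8:
                raise ModelConstructionError(
                    f"factor frequencies must sum to 1, got {total}"
                )
        if self.epsilon <= 0:
            raise ModelConstructionError("epsilon must be positive")


def site_class_id(factor: str, strand: str, position: int) -> str:
    return f"{factor}|{strand}|{position}"


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------

class PPHMMTemplate:
    """State graph + branch-length closures for transition probabilities."""

    def __init__(
        self,
        spec: CRMModelSpec,
        background: RateMatrix,
        states: list[PPHMMState],
        class_registry: dict[str, FunctionalClass],
        index: dict[str, int],
    ):
        self.spec = spec
        self.background = background
        self.states = states
        self.class_registry = class_registry
        self._ix = index  # state name -> id
        self.n_states = len(states)
        self.class_ids = [BG] + [c for c in class_registry if c != BG]
        self.class_index = {c: i for i, c in enumerate(self.class_ids)}
        self._lengths = {p.factor_name: p.length for p in spec.profiles}

    def site_length(self, class_id: str) -> int | None:
        """Profile length of a site class (None for background)."""
        if class_id == BG:
            return None
        return self._lengths[class_id.split("|")[0]]

    # -- closures -----------------------------------------------------------

    def _branch_quantities(self, t: float, c_indel: float):
        alpha = self.spec.indel_params.alpha * c_indel
        beta = min(self.spec.indel_params.beta * c_indel, 0.999)
        g = min(1.0 - math.exp(-alpha * t), 0.49)
        # The birth-death densities are per candidate *interval* (one per
        # site length); transition closures are per *column*.  The factor
        # kappa/b_inf converts between the two so that the stationary
        # fraction of residues inside sites equals delta = b_inf exactly.
        if self.spec.profiles:
            b_inf = self.spec.bd_params.asymptotic_gain
            mean_len = sum(
                self.spec.factor_frequencies[p.factor_name] * p.length
                for p in self.spec.profiles
            )
            col_scale = 1.0 / (mean_len * (1.0 - b_inf) + b_inf)
        if self.spec.profiles and self.spec.complete_orthology:
            w = {"gain": 0.0, "loss": 0.0,
                 "retention": b_inf * col_scale}
            s = b_inf * col_scale
        elif self.spec.profiles:
            tp = turnover_probabilities(self.spec.bd_params, t)
            w = {
                "gain": (1.0 - b_inf) * tp.gain * col_scale,
                "loss": b_inf * tp.loss * col_scale,
                "retention": b_inf * tp.retention * col_scale,
            }
            s = tp.background_exit * col_scale
        else:
            w = {"gain": 0.0, "loss": 0.0, "retention": 0.0}
            s = 0.0
        return g, beta, s, w

    def transition_matrix(self, t: float, c_indel: float = 1.0) -> np.ndarray:
        """Evaluate all transition closures at branch length ``t``."""
        if t <= 0:
            raise InvalidBranchError(f"branch length must be positive, got {t}")
        g, e, s, w = self._branch_quantities(t, c_indel)
        tau = self.spec.epsilon
        ix = self._ix
        T = np.zeros((self.n_states, self.n_states))

        def exit_row(row: np.ndarray, scale: float = 1.0, self_extend: float = 0.0):
            """Distribution over what follows a completed main-chain column."""
            if self_extend:
                scale = scale * (1.0 - self_extend)
            row[ix["stop"]] += scale * tau
            for p in self.spec.profiles:
                freq = self.spec.factor_frequencies[p.factor_name]
                for strand in "+-":
                    mass = scale * (1.0 - tau) * freq * self.spec.strand_factor
                    row[ix[f"R|{p.factor_name}|{strand}|0"]] += mass * w["retention"]
                    if self.spec.complete_orthology:
                        continue
                    row[ix[f"G|{p.factor_name}|{strand}|0"]] += (
                        mass * w["gain"] * (1.0 - g)
                    )
                    row[ix[f"GI|{p.factor_name}|{strand}|0"]] += mass * w["gain"] * g
                    row[ix[f"L|{p.factor_name}|{strand}|0"]] += (
                        mass * w["loss"] * (1.0 - g)
                    )
                    row[ix[f"LD|{p.factor_name}|{strand}|0"]] += mass * w["loss"] * g
            bg_mass = scale * (1.0 - tau) * (1.0 - s)
            if self_extend:
                # indel states re-open no second gap: all remaining mass to M
                row[ix["M"]] += bg_mass
            else:
                row[ix["I"]] += bg_mass * g
                row[ix["D"]] += bg_mass * g
                row[ix["M"]] += bg_mass * (1.0 - 2.0 * g)

        exit_row(T[ix["start"]])
        exit_row(T[ix["M"]])
        T[ix["I"], ix["I"]] = e
        exit_row(T[ix["I"]], self_extend=e)
        T[ix["D"], ix["D"]] = e
        exit_row(T[ix["D"]], self_extend=e)

        for p in self.spec.profiles:
            f = p.factor_name
            L = p.length
            for strand in "+-":
                def k(tag, i):
                    return ix[f"{tag}|{f}|{strand}|{i}"]

                # retention: gapless chain
                for i in range(L - 1):
                    T[k("R", i), k("R", i + 1)] = 1.0
                exit_row(T[k("R", L - 1)])

                if self.spec.complete_orthology:
                    continue

                # gain: descendant carries the site; ancestor is background
                for i in range(L - 1):
                    for src in (k("G", i), k("GI", i)):
                        T[src, k("GD", i)] = g
                        T[src, k("GI", i + 1)] = (1.0 - g) * g
                        T[src, k("G", i + 1)] = (1.0 - g) ** 2
                    T[k("GD", i), k("GD", i)] = e
                    T[k("GD", i), k("GI", i + 1)] = (1.0 - e) * g
                    T[k("GD", i), k("G", i + 1)] = (1.0 - e) * (1.0 - g)
                exit_row(T[k("G", L - 1)])
                exit_row(T[k("GI", L - 1)])

                # loss: ancestor carries the site; descendant is background
                for i in range(L - 1):
                    for src in (k("L", i), k("LD", i)):
                        T[src, k("LI", i)] = g
                        T[src, k("LD", i + 1)] = (1.0 - g) * g
                        T[src, k("L", i + 1)] = (1.0 - g) ** 2
                    T[k("LI", i), k("LI", i)] = e
                    T[k("LI", i), k("LD", i + 1)] = (1.0 - e) * g
                    T[k("LI", i), k("L", i + 1)] = (1.0 - e) * (1.0 - g)
                exit_row(T[k("L", L - 1)])
                exit_row(T[k("LD", L - 1)])

        sums = T.sum(axis=1)
        sums[ix["stop"]] = 1.0  # stop is absorbing; no outgoing mass
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = np.argmax(np.abs(sums - 1.0))
            raise ModelConstructionError(
                f"transition closure row {self.states[bad].name!r} sums to "
                f"{sums[bad]} at t={t}"
            )
        return T

    # -- instantiation ------------------------------------------------------

    def instantiate(self, t: float, c_branch: float = 1.0,
                    c_indel: float = 1.0) -> "PPHMM":
        """Concrete PPHMM for a branch of length ``t``.

        ``c_branch`` rescales the branch before closure/emission evaluation;
        ``c_indel`` rescales the indel parameters.  Both default to identity.
        """
        if t <= 0:
            raise InvalidBranchError(f"branch length must be positive, got {t}")
        t_eff = t * c_branch
        T = self.transition_matrix(t_eff, c_indel)
        n = self.n_states
        match_p = np.tile(np.eye(4), (n, 1, 1))
        anc_pi = np.full((n, 4), 0.25)
        ins_pi = np.full((n, 4), 0.25)
        pair_cache: dict[tuple[str, str], np.ndarray] = {}
        for st in self.states:
            if st.kind == StateKind.MATCH:
                key = (st.anc_class, st.desc_class)
                if key not in pair_cache:
                    ca = self.class_registry[st.anc_class]
                    cb = self.class_registry[st.desc_class]
                    if ca == cb:
                        pair_cache[key] = substitution_probabilities(
                            ca.rate_matrix, t_eff
                        ).probs
                    else:
                        pair_cache[key] = cross_functional_matrix(
                            ca, cb, t_eff
                        ).probs
                match_p[st.id] = pair_cache[key]
                anc_pi[st.id] = self.class_registry[st.anc_class].rate_matrix.equilibrium
            elif st.kind == StateKind.DELETE:
                anc_pi[st.id] = self.class_registry[st.anc_class].rate_matrix.equilibrium
            elif st.kind == StateKind.INSERT:
                ins_pi[st.id] = self.class_registry[st.desc_class].rate_matrix.equilibrium
        return PPHMM(
            template=self,
            t=t,
            t_eff=t_eff,
            transition_probs=T,
            match_probs=match_p,
            anc_equilibrium=anc_pi,
            ins_equilibrium=ins_pi,
        )


@dataclass
class PPHMM:
    """A PPHMM instantiated at a concrete branch length."""

    template: PPHMMTemplate
    t: float
    t_eff: float
    transition_probs: np.ndarray   # (S, S)
    match_probs: np.ndarray        # (S, 4, 4); identity for non-match states
    anc_equilibrium: np.ndarray    # (S, 4)
    ins_equilibrium: np.ndarray    # (S, 4)

    @property
    def states(self) -> list[PPHMMState]:
        return self.template.states

    @property
    def log_transition(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.transition_probs)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _build_states_and_registry(spec: CRMModelSpec, background: RateMatrix):
    registry: dict[str, FunctionalClass] = {
        BG: FunctionalClass(BG, background)
    }
    states: list[PPHMMState] = []
    index: dict[str, int] = {}

    def add(name, kind, anc, desc, site=None):
        st = PPHMMState(len(states), name, kind, anc, desc, site)
        states.append(st)
        index[name] = st.id
        return st

    add("start", StateKind.START, None, None)
    add("stop", StateKind.STOP, None, None)
    add("M", StateKind.MATCH, BG, BG)
    add("I", StateKind.INSERT, None, BG)
    add("D", StateKind.DELETE, BG, None)

    for p in spec.profiles:
        f = p.factor_name
        for strand in "+-":
            oriented = p if strand == "+" else p.reverse_complement()
            L = oriented.length
            cls_ids = []
            for i in range(L):
                cid = site_class_id(f, strand, i)
                registry[cid] = FunctionalClass(
                    cid, halpern_bruno(background, oriented.columns[i])
                )
                cls_ids.append(cid)
            for i in range(L):
                role = lambda ev, pos=i: SiteRole(f, strand, ev, pos, L)
                add(f"R|{f}|{strand}|{i}", StateKind.MATCH,
                    cls_ids[i], cls_ids[i], role("retention"))
            if spec.complete_orthology:
                continue
            for i in range(L):
                add(f"G|{f}|{strand}|{i}", StateKind.MATCH,
                    BG, cls_ids[i], SiteRole(f, strand, "gain", i, L))
                add(f"GI|{f}|{strand}|{i}", StateKind.INSERT,
                    None, cls_ids[i], SiteRole(f, strand, "gain", i, L))
            for i in range(L - 1):
                add(f"GD|{f}|{strand}|{i}", StateKind.DELETE,
                    BG, None, SiteRole(f, strand, "gain", -1, L))
            for i in range(L):
                add(f"L|{f}|{strand}|{i}", StateKind.MATCH,
                    cls_ids[i], BG, SiteRole(f, strand, "loss", i, L))
                add(f"LD|{f}|{strand}|{i}", StateKind.DELETE,
                    cls_ids[i], None, SiteRole(f, strand, "loss", i, L))
            for i in range(L - 1):
                add(f"LI|{f}|{strand}|{i}", StateKind.INSERT,
                    None, BG, SiteRole(f, strand, "loss", -1, L))
    return states, registry, index


def crm_state_count(profile_lengths) -> int:
    """Documented state-count formula: 5 fixed states (start, stop, M, I, D)
    plus, per factor and strand, ``7L - 2`` submodel states
    (L retention + (3L - 1) gain + (3L - 1) loss)."""
    return 5 + sum(2 * (7 * L - 2) for L in profile_lengths)


def assemble_crm_template(spec: CRMModelSpec, background: RateMatrix) -> PPHMMTemplate:
    """Assemble the full CRM evolution template (background + all site
    submodels for every factor and strand)."""
    states, registry, index = _build_states_and_registry(spec, background)
    template = PPHMMTemplate(spec, background, states, registry, index)
    for t_probe in (0.05, 0.5, 2.0):
        template.transition_matrix(t_probe)  # raises on malformed closures
    return template


def submodel_states(template: PPHMMTemplate, factor: str, strand: str,
                    event: str) -> list[PPHMMState]:
    """All states of one (factor, strand, event) submodel, in chain order."""
    return [
        st for st in template.states
        if st.site is not None
        and st.site.factor == factor
        and st.site.strand == strand
        and st.site.event == event
    ]


def _single_factor_template(profile: BindingProfile, background: RateMatrix,
                            indel: IndelParams | None,
                            bd: BirthDeathParams | None) -> PPHMMTemplate:
    spec = CRMModelSpec(
        profiles=[profile],
        bd_params=bd if bd is not None else BirthDeathParams(0.02, 0.08),
        indel_params=indel if indel is not None else IndelParams(0.02, 0.6),
    )
    return assemble_crm_template(spec, background)


def build_retention_submodel(profile: BindingProfile, strand: str,
                             background: RateMatrix,
                             indel: IndelParams | None = None,
                             bd: BirthDeathParams | None = None):
    """Single-factor template plus the gapless retention chain for ``strand``."""
    template = _single_factor_template(profile, background, indel, bd)
    return template, submodel_states(template, profile.factor_name, strand,
                                     "retention")


def build_gain_submodel(profile: BindingProfile, strand: str,
                        background: RateMatrix,
                        indel: IndelParams | None = None,
                        bd: BirthDeathParams | None = None):
    """Single-factor template plus the gain chain (ancestor bg, descendant
    functional; indels only on the ancestral, non-functional lineage)."""
    template = _single_factor_template(profile, background, indel, bd)
    return template, submodel_states(template, profile.factor_name, strand, "gain")


def build_loss_submodel(profile: BindingProfile, strand: str,
                        background: RateMatrix,
                        indel: IndelParams | None = None,
                        bd: BirthDeathParams | None = None):
    """Mirror of the gain submodel: ancestor functional, descendant bg."""
    template = _single_factor_template(profile, background, indel, bd)
    return template, submodel_states(template, profile.factor_name, strand, "loss")


def build_background_template(
    indel: IndelParams,
    bd: BirthDeathParams | None = None,
    background: RateMatrix | None = None,
    epsilon: float = 0.00001,
) -> PPHMMTemplate:
    """Background-only template: match/insert/delete plus start/stop.

    With no site submodels attached the background-exit mass ``s(t)`` has no
    destination, so transitions renormalise with ``s = 0``; the indel
    structure (``alpha``, ``beta``, affine extension, insert/delete symmetry)
    is identical to the background portion of the full CRM template.
    """
    from .substitution import jukes_cantor

    bg = background if background is not None else jukes_cantor()
    spec = CRMModelSpec(
        profiles=[],
        bd_params=bd if bd is not None else BirthDeathParams(0.0, 0.08),
        indel_params=indel,
        epsilon=epsilon,
    )
    return assemble_crm_template(spec, bg)
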