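"""Forward simulation of CRM evolution along a phylogeny.

The simulator and the aligner share one evolutionary model: residues evolve
under their functional class's substitution process (background GTR or the
per-column Halpern-Bruno regime of a binding profile), whole sites turn over
via the birth-death process (retention ``p(t)``, loss ``q(t)``, gain
``b(t)``), residues crossing a change of function substitute under the
uniform change-time mixture, and background residues acquire affine
insertions/deletions governed by ``alpha`` and ``beta``.  Indels are never
placed inside currently functional sites.

Each residue carries a persistent identity through replication, which gives
the exact molecular-homology relation: the true multiple alignment over all
nodes (ancestors included), true site annotations per node, and a per-branch
event log.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .alignment import MultipleAlignment, SitePrediction
from .birth_death import turnover_probabilities
from .model import BG, CRMModelSpec, site_class_id
from .phylo import Phylogeny
from .substitution import (
    ALPHABET,
    FunctionalClass,
    RateMatrix,
    cross_functional_matrix,
    halpern_bruno,
    substitution_probabilities,
)

__all__ = ["SimulatedDataset", "Simulator", "simulate"]

logger = logging.getLogger(__name__)


def _draw(cum: np.ndarray, u: float) -> int:
    """Inverse-CDF draw from a cumulative distribution, guarded at 1.0."""
    return min(int(np.searchsorted(cum, u, side="right")), len(cum) - 1)


@dataclass
class _Residue:
    uid: int
    base: int
    site_id: int | None = None
    site_pos: int = -1


@dataclass
class _Site:
    sid: int
    factor: str
    strand: str
    event: str  # 'ancestral' | 'gained' | 'retained'


@dataclass
class _TaxonState:
    residues: list
    sites: dict  # sid -> _Site


@dataclass
class SimulatedDataset:
    """Leaf sequences plus complete ground truth."""

    leaf_sequences: dict
    alignment: MultipleAlignment          # all nodes, ancestors included
    sites: list                           # SitePrediction per node
    events: list                          # per-branch event dicts
    seed: int

    def sites_for(self, taxa) -> list:
        taxa = set(taxa)
        return [s for s in self.sites if s.taxon in taxa]


class Simulator:
    def __init__(self, spec: CRMModelSpec, background: RateMatrix,
                 c_branch: float = 1.0):
        self.spec = spec
        self.background = background
        self.c_branch = c_branch
        self.bg_class = FunctionalClass(BG, background)
        self.site_classes = {}
        self.oriented = {}
        for p in spec.profiles:
            for strand in "+-":
                prof = p if strand == "+" else p.reverse_complement()
                self.oriented[(p.factor_name, strand)] = prof
                for i in range(prof.length):
                    cid = site_class_id(p.factor_name, strand, i)
                    self.site_classes[cid] = FunctionalClass(
                        cid, halpern_bruno(background, prof.columns[i])
                    )
        freqs = spec.factor_frequencies
        self.factors = [p.factor_name for p in spec.profiles]
        self.factor_probs = np.array([freqs[f] for f in self.factors]) if (
            self.factors
        ) else np.zeros(0)
        if self.factors:
            self.mean_len = float(
                sum(freqs[p.factor_name] * p.length for p in spec.profiles)
            )
        else:
            self.mean_len = 1.0
        self._matrix_cache: dict = {}

    # -- substitution machinery ---------------------------------------------

    def _matrix(self, anc_cls: str, desc_cls: str, t: float) -> np.ndarray:
        key = (anc_cls, desc_cls, t)
        if key not in self._matrix_cache:
            ca = self.bg_class if anc_cls == BG else self.site_classes[anc_cls]
            cb = self.bg_class if desc_cls == BG else self.site_classes[desc_cls]
            if ca.id == cb.id:
                m = substitution_probabilities(ca.rate_matrix, t).probs
            else:
                m = cross_functional_matrix(ca, cb, t).probs
            self._matrix_cache[key] = np.cumsum(m, axis=1)
        return self._matrix_cache[key]

    def _substitute(self, base: int, anc_cls: str, desc_cls: str, t: float,
                    rng) -> int:
        cum = self._matrix(anc_cls, desc_cls, t)
        return _draw(cum[base], rng.random())

    def _residue_class(self, res: _Residue, sites: dict) -> str:
        if res.site_id is None:
            return BG
        site = sites[res.site_id]
        return site_class_id(site.factor, site.strand, res.site_pos)

    # -- root ---------------------------------------------------------------

    def sample_root(self, length: int, rng) -> _TaxonState:
        """Stationary root: background equilibrium residues with sites seeded
        at the stationary density ``b_inf`` implied by the birth-death
        parameters."""
        if length < 1:
            raise ValueError("root length must be >= 1")
        uid = itertools.count()
        residues: list = []
        sites: dict = {}
        sid_counter = itertools.count()
        eq_cum = np.cumsum(self.background.equilibrium)
        if self.factors:
            delta = self.spec.bd_params.asymptotic_gain
            kappa = delta / (self.mean_len * (1.0 - delta) + delta)
        else:
            kappa = 0.0
        max_len = max((p.length for p in self.spec.profiles), default=0)
        if 0 < length < max_len and kappa > 0:
            logger.warning(
                "root shorter than the longest profile; no sites seeded"
            )
        while len(residues) < length:
            room = length - len(residues)
            if kappa > 0 and rng.random() < kappa:
                f = self.factors[
                    _draw(np.cumsum(self.factor_probs), rng.random())
                ]
                strand = "+" if rng.random() < 0.5 else "-"
                prof = self.oriented[(f, strand)]
                if prof.length <= room:
                    sid = next(sid_counter)
                    sites[sid] = _Site(sid, f, strand, "ancestral")
                    for i in range(prof.length):
                        base = _draw(np.cumsum(prof.columns[i]),
                                     rng.random())
                        residues.append(_Residue(next(uid), base, sid, i))
                    continue
            base = _draw(eq_cum, rng.random())
            residues.append(_Residue(next(uid), base))
        self._uid = uid
        self._sid = sid_counter
        return _TaxonState(residues, sites)

    # -- branch evolution ---------------------------------------------------

    def evolve_branch(self, parent: _TaxonState, t: float, rng):
        """One branch: site turnover, substitutions, background indels."""
        t = t * self.c_branch
        spec = self.spec
        events = []
        if self.factors:
            tp = turnover_probabilities(spec.bd_params, t)
        alpha = spec.indel_params.alpha
        beta = spec.indel_params.beta
        d_open = (1.0 - math.exp(-alpha * t)) / 2.0

        # 1. site survival decisions
        lost = set()
        child_sites: dict = {}
        for sid, site in parent.sites.items():
            if rng.random() < tp.loss:
                lost.add(sid)
                events.append({"type": "site_loss", "factor": site.factor,
                               "strand": site.strand, "sid": sid})
            else:
                child_sites[sid] = _Site(sid, site.factor, site.strand,
                                         "retained")

        # 2. gains on vacant (background) windows of the parent
        gained: dict = {}  # parent index -> (_Site, oriented profile)
        if self.factors:
            bg_positions = [
                k for k, r in enumerate(parent.residues) if r.site_id is None
            ]
            n_cand = int(len(bg_positions) // self.mean_len)
            n_gain = rng.binomial(n_cand, tp.gain) if n_cand > 0 else 0
            occupied = set()
            for _ in range(n_gain):
                f = self.factors[
                    _draw(np.cumsum(self.factor_probs), rng.random())
                ]
                strand = "+" if rng.random() < 0.5 else "-"
                prof = self.oriented[(f, strand)]
                starts = [
                    k for k in bg_positions
                    if k + prof.length <= len(parent.residues)
                    and all(
                        parent.residues[k + d].site_id is None
                        and (k + d) not in occupied
                        for d in range(prof.length)
                    )
                ]
                if not starts:
                    continue
                start = starts[int(rng.integers(len(starts)))]
                sid = next(self._sid)
                site = _Site(sid, f, strand, "gained")
                child_sites[sid] = site
                gained[start] = (site, prof)
                occupied.update(range(start, start + prof.length))
                events.append({"type": "site_gain", "factor": f,
                               "strand": strand, "sid": sid,
                               "parent_start": start})

        # 3. substitutions according to (parent class -> child class)
        child_residues = []
        k = 0
        n = len(parent.residues)
        while k < n:
            res = parent.residues[k]
            if k in gained:
                site, prof = gained[k]
                for i in range(prof.length):
                    src = parent.residues[k + i]
                    cid = site_class_id(site.factor, site.strand, i)
                    base = self._substitute(src.base, BG, cid, t, rng)
                    child_residues.append(_Residue(src.uid, base, site.sid, i))
                k += prof.length
                continue
            anc_cls = self._residue_class(res, parent.sites)
            if res.site_id is not None and res.site_id in lost:
                desc_cls = BG
                new = _Residue(res.uid,
                               self._substitute(res.base, anc_cls, BG, t, rng))
            elif res.site_id is not None:
                new = _Residue(
                    res.uid,
                    self._substitute(res.base, anc_cls, anc_cls, t, rng),
                    res.site_id, res.site_pos,
                )
            else:
                new = _Residue(res.uid,
                               self._substitute(res.base, BG, BG, t, rng))
            child_residues.append(new)
            k += 1

        # 4. deletions on child-background residues
        surviving = []
        k = 0
        eq_cum = np.cumsum(self.background.equilibrium)
        while k < len(child_residues):
            res = child_residues[k]
            if res.site_id is None and rng.random() < d_open:
                run = int(rng.geometric(1.0 - beta))
                dropped = 0
                while (
                    dropped < run
                    and k < len(child_residues)
                    and child_residues[k].site_id is None
                ):
                    events.append({"type": "deletion",
                                   "uid": child_residues[k].uid})
                    k += 1
                    dropped += 1
                continue
            surviving.append(res)
            k += 1
        child_residues = surviving

        # 5. insertions at junctions outside functional sites
        out = []
        n = len(child_residues)
        for k in range(n + 1):
            left = child_residues[k - 1] if k > 0 else None
            right = child_residues[k] if k < n else None
            inside_site = (
                left is not None
                and right is not None
                and left.site_id is not None
                and left.site_id == right.site_id
            )
            if not inside_site and rng.random() < d_open:
                m = int(rng.geometric(1.0 - beta))
                anchor_uid = left.uid if left is not None else None
                before_uid = right.uid if right is not None else None
                new_uids = []
                for _ in range(m):
                    base = _draw(eq_cum, rng.random())
                    r = _Residue(next(self._uid), base)
                    out.append(r)
                    new_uids.append(r.uid)
                events.append({"type": "insertion", "after_uid": anchor_uid,
                               "before_uid": before_uid, "uids": new_uids})
            if right is not None:
                out.append(right)
        return _TaxonState(out, child_sites), events


def simulate(spec: CRMModelSpec, background: RateMatrix, tree: Phylogeny,
             root_length: int, seed: int,
             c_branch: float = 1.0) -> SimulatedDataset:
    """Simulate one CRM along ``tree`` and assemble full ground truth."""
    rng = np.random.default_rng(seed)
    sim = Simulator(spec, background, c_branch)
    states = {tree.root.name: sim.sample_root(root_length, rng)}
    master = [r.uid for r in states[tree.root.name].residues]
    event_log = []

    for node in tree.preorder():
        if node.parent is None:
            continue
        child_state, events = sim.evolve_branch(
            states[node.parent.name], node.length, rng
        )
        states[node.name] = child_state
        for ev in events:
            ev["branch"] = f"{node.parent.name}->{node.name}"
            event_log.append(ev)
            if ev["type"] == "insertion":
                if ev["after_uid"] is not None:
                    pos = master.index(ev["after_uid"]) + 1
                elif ev["before_uid"] is not None:
                    pos = master.index(ev["before_uid"])
                else:
                    pos = len(master)
                master[pos:pos] = ev["uids"]

    rows = {}
    col_of = {u: i for i, u in enumerate(master)}
    for node in tree.preorder():
        row = ["-"] * len(master)
        for r in states[node.name].residues:
            row[col_of[r.uid]] = ALPHABET[r.base]
        rows[node.name] = "".join(row)
    alignment = MultipleAlignment(rows)

    sites = []
    for node in tree.preorder():
        st = states[node.name]
        pos = 0
        k = 0
        while k < len(st.residues):
            res = st.residues[k]
            if res.site_id is None:
                k += 1
                pos += 1
                continue
            site = st.sites[res.site_id]
            L = 1
            while (
                k + L < len(st.residues)
                and st.residues[k + L].site_id == res.site_id
            ):
                L += 1
            sites.append(SitePrediction(node.name, site.factor, site.strand,
                                        pos, pos + L, site.event))
            k += L
            pos += L

    leaf_sequences = {
        name: alignment.ungapped(name) for name in tree.leaf_names
    }
    return SimulatedDataset(leaf_sequences, alignment, sites, event_log, seed)
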