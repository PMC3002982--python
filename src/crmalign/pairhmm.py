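"""Pairwise Viterbi decoding of PPHMMs over clade profiles.

The decoder aligns an *ancestral-side* profile (rows) to a *descendant-side*
profile (columns) under an instantiated PPHMM.  Dynamic programming runs in
log space with a dense state set; the inner relaxation is a numba kernel
whose arrays are laid out state-last so that all states of one DP cell share
cache lines.  Two strategies are provided:

* full-matrix Viterbi with traceback (quadratic memory), and
* Hirschberg divide-and-conquer decoding whose memory is proportional to
  ``n_states * shorter dimension`` per level, engaged automatically when the
  DP volume exceeds a configurable state-cell budget.

Decoding can be *constrained* to state paths whose ancestral-side functional
class sequence equals a fixed functional parse of the ancestor (the
down-pass re-alignment step); the constraint enters as a per-(row, state)
feasibility mask.

Tie-breaking is deterministic: match is preferred over delete over insert,
then the lowest state id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .felsenstein import ColumnVectors
from .model import PPHMM, StateKind

__all__ = ["PairDecoder", "DecodeResult", "AlignedPair"]

NEG = -1.0e300

_KIND_PRIORITY = {
    StateKind.MATCH: 0,
    StateKind.DELETE: 1,
    StateKind.INSERT: 2,
    StateKind.START: 3,
    StateKind.STOP: 3,
}


@njit(cache=True)
def _combine_split(F, R, logT):
    """Best (score, j, s1, s2) of F[j, s1] + logT[s1, s2] + R[nB - j, s2]."""
    nB1, S = F.shape
    best = NEG
    bj = bs1 = bs2 = -1
    for j in range(nB1):
        for s1 in range(S):
            f = F[j, s1]
            if f <= NEG / 2:
                continue
            for s2 in range(S):
                r = R[nB1 - 1 - j, s2]
                if r <= NEG / 2:
                    continue
                val = f + logT[s1, s2] + r
                if val > best:
                    best = val
                    bj, bs1, bs2 = j, s1, s2
    return best, bj, bs1, bs2


@njit(cache=True)
def _dp_full(kinds, prio, pred_ptr, pred_idx, pred_logp, first_logp,
             wm, sam, vb, sbm, dmat, imat, allowed,
             entry_w, jsrc, jbase, nA, nB):
    S = kinds.shape[0]
    V = np.full((nA + 1, nB + 1, S), NEG)
    BP = np.full((nA + 1, nB + 1, S), np.int16(-1))
    J = np.full((nA + 1, nB + 1), NEG)
    JA = np.full((nA + 1, nB + 1), np.int16(-1))
    JP = np.full((nA + 1, nB + 1), np.int64(1 << 30))
    for i in range(nA + 1):
        for j in range(nB + 1):
            for s in range(S):
                k = kinds[s]
                if k == 0:
                    if i == 0 or j == 0 or not allowed[i, s]:
                        continue
                    pi_, pj = i - 1, j - 1
                elif k == 2:
                    if i == 0 or not allowed[i, s]:
                        continue
                    pi_, pj = i - 1, j
                elif k == 1:
                    if j == 0:
                        continue
                    pi_, pj = i, j - 1
                else:
                    continue
                best = NEG
                arg = -1
                bestpr = 1 << 30
                if pi_ == 0 and pj == 0 and first_logp[s] > NEG / 2:
                    best = first_logp[s]
                    arg = -2
                    bestpr = -1
                if entry_w[s] > NEG / 2 and J[pi_, pj] > NEG / 2:
                    val = J[pi_, pj] + entry_w[s]
                    if val > best or (val == best and JP[pi_, pj] < bestpr):
                        best = val
                        arg = JA[pi_, pj]
                        bestpr = JP[pi_, pj]
                row = V[pi_, pj]
                for q in range(pred_ptr[s], pred_ptr[s + 1]):
                    p = pred_idx[q]
                    val = row[p] + pred_logp[q]
                    if val > best or (val == best and prio[p] < bestpr):
                        best = val
                        arg = p
                        bestpr = prio[p]
                if arg == -1 or best <= NEG / 2:
                    continue
                if k == 0:
                    dot = (wm[i, s, 0] * vb[j, s, 0] + wm[i, s, 1] * vb[j, s, 1]
                           + wm[i, s, 2] * vb[j, s, 2] + wm[i, s, 3] * vb[j, s, 3])
                    if dot <= 0.0:
                        continue
                    e = np.log(dot) + sam[i, s] + sbm[j, s]
                elif k == 2:
                    e = dmat[i, s]
                else:
                    e = imat[j, s]
                if e <= NEG / 2:
                    continue
                V[i, j, s] = best + e
                BP[i, j, s] = arg
            # junction over exit-row sources, reused by all entry states
            jb = NEG
            ja = -1
            jp = 1 << 30
            for q in range(jbase.shape[0]):
                s = jsrc[q]
                v = V[i, j, s]
                if v > NEG / 2:
                    val = v + jbase[q]
                    if val > jb or (val == jb and prio[s] < jp):
                        jb = val
                        ja = s
                        jp = prio[s]
            J[i, j] = jb
            JA[i, j] = np.int16(ja)
            JP[i, j] = jp
    return V, BP


@njit(cache=True)
def _dp_scores(kinds, prio, pred_ptr, pred_idx, pred_logp, first_logp,
               wm, sam, vb, sbm, dmat, imat, allowed,
               entry_w, jsrc, jbase, nA, nB):
    """Rolling-row forward scores; returns V after consuming all nA rows."""
    S = kinds.shape[0]
    V = np.full((2, nB + 1, S), NEG)
    J = np.full((2, nB + 1), NEG)
    JP = np.full((2, nB + 1), np.int64(1 << 30))
    for i in range(nA + 1):
        cur = i % 2
        prev = 1 - cur
        V[cur, :, :] = NEG
        J[cur, :] = NEG
        for j in range(nB + 1):
            for s in range(S):
                k = kinds[s]
                if k == 0:
                    if i == 0 or j == 0 or not allowed[i, s]:
                        continue
                    row = V[prev, j - 1]
                    jrow, jprio = J[prev, j - 1], JP[prev, j - 1]
                    si, sj = i - 1, j - 1
                elif k == 2:
                    if i == 0 or not allowed[i, s]:
                        continue
                    row = V[prev, j]
                    jrow, jprio = J[prev, j], JP[prev, j]
                    si, sj = i - 1, j
                elif k == 1:
                    if j == 0:
                        continue
                    row = V[cur, j - 1]
                    jrow, jprio = J[cur, j - 1], JP[cur, j - 1]
                    si, sj = i, j - 1
                else:
                    continue
                best = NEG
                arg = -1
                bestpr = 1 << 30
                if si == 0 and sj == 0 and first_logp[s] > NEG / 2:
                    best = first_logp[s]
                    arg = -2
                    bestpr = -1
                if entry_w[s] > NEG / 2 and jrow > NEG / 2:
                    val = jrow + entry_w[s]
                    if val > best or (val == best and jprio < bestpr):
                        best = val
                        arg = -3
                        bestpr = jprio
                for q in range(pred_ptr[s], pred_ptr[s + 1]):
                    p = pred_idx[q]
                    val = row[p] + pred_logp[q]
                    if val > best or (val == best and prio[p] < bestpr):
                        best = val
                        arg = p
                        bestpr = prio[p]
                if arg == -1 or best <= NEG / 2:
                    continue
                if k == 0:
                    dot = (wm[i, s, 0] * vb[j, s, 0] + wm[i, s, 1] * vb[j, s, 1]
                           + wm[i, s, 2] * vb[j, s, 2] + wm[i, s, 3] * vb[j, s, 3])
                    if dot <= 0.0:
                        continue
                    e = np.log(dot) + sam[i, s] + sbm[j, s]
                elif k == 2:
                    e = dmat[i, s]
                else:
                    e = imat[j, s]
                if e <= NEG / 2:
                    continue
                V[cur, j, s] = best + e
            jb = NEG
            jp = 1 << 30
            for q in range(jbase.shape[0]):
                s = jsrc[q]
                v = V[cur, j, s]
                if v > NEG / 2:
                    val = v + jbase[q]
                    if val > jb or (val == jb and prio[s] < jp):
                        jb = val
                        jp = prio[s]
            J[cur, j] = jb
            JP[cur, j] = jp
    return V[nA % 2].copy()


@dataclass
class AlignedPair:
    """Monotone alignment between ancestor columns and descendant columns.

    ``steps`` is a list of ``(state_id, anc_index, desc_index)`` with 0-based
    indices and ``None`` on the gapped side.
    """

    steps: list

    def mirrored(self, kind_swap) -> "AlignedPair":
        return AlignedPair(
            [(kind_swap.get(s, s), j, i) for (s, i, j) in self.steps]
        )


@dataclass
class DecodeResult:
    score: float
    path: AlignedPair
    used_hirschberg: bool


class PairDecoder:
    """Viterbi decoding of one (ancestor profile, descendant profile) pair."""

    def __init__(
        self,
        model: PPHMM,
        anc: ColumnVectors,
        desc: ColumnVectors,
        anc_parse: list | None = None,
        cell_budget: float = 5e7,
        hirschberg_base_rows: int = 32,
        hirschberg_base_cells: float = 20_000_000,
    ):
        self.h_base_rows = hirschberg_base_rows
        self.h_base_cells = hirschberg_base_cells
        self.model = model
        tpl = model.template
        self.nA = anc.n_cols
        self.nB = desc.n_cols
        S = tpl.n_states
        self.S = S
        kinds = np.empty(S, dtype=np.int8)
        prio = np.empty(S, dtype=np.int64)
        for st in tpl.states:
            kinds[st.id] = int(st.kind)
            prio[st.id] = _KIND_PRIORITY[st.kind] * S + st.id
        self.kinds = kinds
        self.prio = prio

        with np.errstate(divide="ignore"):
            self.logT = np.log(model.transition_probs)
        self.start_id = tpl._ix["start"]
        self.stop_id = tpl._ix["stop"]
        self._pred = self._factorize(self.logT, self._build_adjacency(self.logT))
        self._succ = self._factorize(self.logT.T,
                                     self._build_adjacency(self.logT.T))

        self._build_emissions(anc, desc)
        self._build_allowed(anc_parse)
        self.cell_budget = cell_budget

    # -- precomputation -----------------------------------------------------

    @staticmethod
    def _build_adjacency(logT):
        S = logT.shape[0]
        ptr = np.zeros(S + 1, dtype=np.int64)
        idx_list, logp_list = [], []
        for s in range(S):
            preds = np.where(np.isfinite(logT[:, s]))[0]
            ptr[s + 1] = ptr[s] + len(preds)
            idx_list.append(preds)
            logp_list.append(logT[preds, s])
        idx = (np.concatenate(idx_list) if idx_list else np.zeros(0)).astype(
            np.int64
        )
        logp = np.concatenate(logp_list) if logp_list else np.zeros(0)
        return ptr, idx, logp

    def _factorize(self, logT, adjacency):
        """Detect the separable 'exit row -> entry states' structure.

        Many states share one outgoing distribution up to a per-source scale
        (``logT[u, e] = base[u] + w[e]``); replacing those edges with a
        per-cell junction maximum cuts the DP edge count several-fold.  The
        factorisation is verified numerically and states that do not fit
        keep their explicit predecessor lists.
        """
        ptr, idx, logp = adjacency
        S = logT.shape[0]
        no_fact = (
            (ptr, idx, logp),
            np.full(S, NEG),
            np.zeros(0, dtype=np.int64),
            np.zeros(0),
        )
        from collections import Counter

        emitting = {
            st.id for st in self.model.template.states if st.is_emitting
        }
        cands = [s for s in range(S) if ptr[s + 1] - ptr[s] >= 12]
        if len(cands) < 6:
            return no_fact
        keys = Counter(
            tuple(idx[ptr[s]:ptr[s + 1]]) for s in cands
        )
        key, count = keys.most_common(1)[0]
        if count < 6:
            return no_fact
        E = [s for s in cands if tuple(idx[ptr[s]:ptr[s + 1]]) == key]
        U = [int(u) for u in key if u in emitting]
        if len(U) < 4:
            return no_fact
        e0, u0 = E[0], U[0]
        w = {e: logT[u0, e] for e in E}
        base = {u: logT[u, e0] - w[e0] for u in U}

        def fits(e):
            return all(
                abs(logT[u, e] - base[u] - w[e])
                <= 1e-10 * max(1.0, abs(logT[u, e]))
                for u in U
            )

        E = [e for e in E if np.isfinite(w[e]) and fits(e)]
        if len(E) < 6:
            return no_fact
        ekeep = set(E)
        ukeep = set(U)
        entry_w = np.full(S, NEG)
        for e in E:
            entry_w[e] = w[e]
        new_idx, new_logp = [], []
        new_ptr = np.zeros(S + 1, dtype=np.int64)
        for s in range(S):
            lo, hi = ptr[s], ptr[s + 1]
            if s in ekeep:
                keep = [q for q in range(lo, hi) if idx[q] not in ukeep]
            else:
                keep = list(range(lo, hi))
            new_ptr[s + 1] = new_ptr[s] + len(keep)
            new_idx.extend(int(idx[q]) for q in keep)
            new_logp.extend(float(logp[q]) for q in keep)
        jsrc = np.array(U, dtype=np.int64)
        jbase = np.array([base[u] for u in U])
        return (
            (new_ptr, np.array(new_idx, dtype=np.int64), np.array(new_logp)),
            entry_w, jsrc, jbase,
        )

    def _build_emissions(self, anc: ColumnVectors, desc: ColumnVectors):
        tpl = self.model.template
        S, nA, nB = self.S, self.nA, self.nB
        cidx = tpl.class_index
        wm = np.zeros((S, nA + 1, 4))
        sam = np.zeros((S, nA + 1))
        vb = np.zeros((S, nB + 1, 4))
        sbm = np.zeros((S, nB + 1))
        dmat = np.full((S, nA + 1), NEG)
        imat = np.full((S, nB + 1), NEG)
        for st in tpl.states:
            s = st.id
            if st.kind == StateKind.MATCH:
                ai, di = cidx[st.anc_class], cidx[st.desc_class]
                joint = (
                    self.model.anc_equilibrium[s][:, None]
                    * self.model.match_probs[s]
                )
                if st.anc_class == st.desc_class and np.allclose(
                    joint, joint.T, atol=1e-12
                ):
                    # reversible same-class state: symmetrising the joint
                    # makes decoding bitwise symmetric under input exchange
                    joint = (joint + joint.T) / 2.0
                wm[s, 1:] = anc.values[:, ai, :] @ joint
                sam[s, 1:] = anc.log_scale[:, ai]
                vb[s, 1:] = desc.values[:, di, :]
                sbm[s, 1:] = desc.log_scale[:, di]
            elif st.kind == StateKind.DELETE:
                ai = cidx[st.anc_class]
                dot = anc.values[:, ai, :] @ self.model.anc_equilibrium[s]
                with np.errstate(divide="ignore"):
                    dmat[s, 1:] = np.where(
                        dot > 0, np.log(np.clip(dot, 1e-320, None)), NEG
                    ) + anc.log_scale[:, ai]
            elif st.kind == StateKind.INSERT:
                di = cidx[st.desc_class]
                dot = desc.values[:, di, :] @ self.model.ins_equilibrium[s]
                with np.errstate(divide="ignore"):
                    imat[s, 1:] = np.where(
                        dot > 0, np.log(np.clip(dot, 1e-320, None)), NEG
                    ) + desc.log_scale[:, di]
        # state-last layout for cache-friendly kernels
        self.wm = np.ascontiguousarray(wm.transpose(1, 0, 2))
        self.sam = np.ascontiguousarray(sam.T)
        self.vb = np.ascontiguousarray(vb.transpose(1, 0, 2))
        self.sbm = np.ascontiguousarray(sbm.T)
        self.dmat = np.ascontiguousarray(dmat.T)
        self.imat = np.ascontiguousarray(imat.T)

    def _build_allowed(self, anc_parse):
        self.allowed = np.ones((self.nA + 1, self.S), dtype=np.bool_)
        if anc_parse is None:
            return
        if len(anc_parse) != self.nA:
            raise ValueError("ancestral parse length must match profile length")
        for st in self.model.template.states:
            if st.kind in (StateKind.MATCH, StateKind.DELETE):
                for i, cls in enumerate(anc_parse, start=1):
                    self.allowed[i, st.id] = st.anc_class == cls

    # -- decoding -----------------------------------------------------------

    def decode(self, force: str | None = None) -> DecodeResult:
        if self.nA == 0 and self.nB == 0:
            return DecodeResult(
                float(self.logT[self.start_id, self.stop_id]),
                AlignedPair([]), False,
            )
        volume = self.S * max(self.nA, 1) * max(self.nB, 1)
        use_h = force == "hirschberg" or (
            force is None and volume > self.cell_budget
        )
        first = self.logT[self.start_id].copy()
        end = self.logT[:, self.stop_id].copy()
        if use_h:
            score, steps = self._hirschberg(
                0, self.nA, 0, self.nB, first, end
            )
        else:
            score, steps = self._full(0, self.nA, 0, self.nB, first, end)
        return DecodeResult(score, AlignedPair(steps), use_h)

    # coordinates below: [a0, a1) x [b0, b1) ranges of 0-based profile columns

    def _slices(self, a0, a1, b0, b1, rev=False):
        wm = self.wm[a0:a1 + 1]
        sam = self.sam[a0:a1 + 1]
        dmat = self.dmat[a0:a1 + 1]
        allowed = self.allowed[a0:a1 + 1]
        vb = self.vb[b0:b1 + 1]
        sbm = self.sbm[b0:b1 + 1]
        imat = self.imat[b0:b1 + 1]
        if rev:
            def flip(arr):
                out = arr.copy()
                out[1:] = arr[1:][::-1]
                return np.ascontiguousarray(out)

            wm, sam, dmat, allowed = map(flip, (wm, sam, dmat, allowed))
            vb, sbm, imat = map(flip, (vb, sbm, imat))
        else:
            wm, sam, dmat, allowed, vb, sbm, imat = map(
                np.ascontiguousarray, (wm, sam, dmat, allowed, vb, sbm, imat)
            )
        return wm, sam, vb, sbm, dmat, imat, allowed

    def _full(self, a0, a1, b0, b1, first_logp, end_logp):
        nA, nB = a1 - a0, b1 - b0
        wm, sam, vb, sbm, dmat, imat, allowed = self._slices(a0, a1, b0, b1)
        (ptr, idx, logp), entry_w, jsrc, jbase = self._pred
        V, BP = _dp_full(
            self.kinds, self.prio, ptr, idx, logp, first_logp,
            wm, sam, vb, sbm, dmat, imat, allowed,
            entry_w, jsrc, jbase, nA, nB,
        )
        finals = V[nA, nB, :] + end_logp
        order = np.lexsort((self.prio, -finals))
        s = int(order[0])
        score = float(finals[s])
        if score <= NEG / 2:
            return score, []
        steps = []
        i, j = nA, nB
        while True:
            steps.append((s, a0 + i - 1 if self.kinds[s] != 1 else None,
                          b0 + j - 1 if self.kinds[s] != 2 else None))
            p = int(BP[i, j, s])
            k = self.kinds[s]
            if k == 0:
                i, j = i - 1, j - 1
            elif k == 2:
                i -= 1
            else:
                j -= 1
            if p == -2:
                break
            s = p
        steps.reverse()
        return score, steps

    def _scores(self, a0, a1, b0, b1, first_logp, rev):
        nA, nB = a1 - a0, b1 - b0
        wm, sam, vb, sbm, dmat, imat, allowed = self._slices(
            a0, a1, b0, b1, rev=rev
        )
        (ptr, idx, logp), entry_w, jsrc, jbase = (
            self._succ if rev else self._pred
        )
        return _dp_scores(
            self.kinds, self.prio, ptr, idx, logp, first_logp,
            wm, sam, vb, sbm, dmat, imat, allowed,
            entry_w, jsrc, jbase, nA, nB,
        )

    def _hirschberg(self, a0, a1, b0, b1, first_logp, end_logp):
        nA, nB = a1 - a0, b1 - b0
        if nA <= self.h_base_rows or self.S * nA * nB <= self.h_base_cells:
            return self._full(a0, a1, b0, b1, first_logp, end_logp)
        h = nA // 2
        F = self._scores(a0, a0 + h, b0, b1, first_logp, rev=False)
        R = self._scores(a0 + h, a1, b0, b1, end_logp, rev=True)
        best, best_j, best_s1, best_s2 = _combine_split(F, R, self.logT)
        if best <= NEG / 2:
            # infeasible split (should not happen for feasible problems)
            return self._full(a0, a1, b0, b1, first_logp, end_logp)
        jm = b0 + best_j
        pin_end = np.full(self.S, NEG)
        pin_end[best_s1] = 0.0
        left_score, left = self._hirschberg(
            a0, a0 + h, b0, jm, first_logp, pin_end
        )
        cont_first = self.logT[best_s1].copy()
        right_score, right = self._hirschberg(
            a0 + h, a1, jm, b1, cont_first, end_logp
        )
        return best, left + right

    # -- utilities ----------------------------------------------------------

    def score_path(self, steps) -> float:
        """Score an explicit state path (for cross-checking)."""
        total = 0.0
        prev = None
        for (s, i, j) in steps:
            if prev is None:
                total += self.logT[self.start_id, s]
            else:
                total += self.logT[prev, s]
            k = self.kinds[s]
            ii = 0 if i is None else i + 1
            jj = 0 if j is None else j + 1
            if k == 0:
                dot = float(self.wm[ii, s] @ self.vb[jj, s])
                total += np.log(dot) + self.sam[ii, s] + self.sbm[jj, s]
            elif k == 2:
                total += self.dmat[ii, s]
            else:
                total += self.imat[jj, s]
            prev = s
        total += self.logT[prev, self.stop_id]
        return float(total)
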