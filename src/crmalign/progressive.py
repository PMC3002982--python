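"""Two-pass progressive alignment and annotation.

The aligner proceeds in three stages over a rooted binary phylogeny:

1. **Liberal up-pass.**  Sibling clades are aligned post-order with a PPHMM
   instantiated on the combined branch ``t1 + t2``; emissions marginalise
   each clade with the *Lossy Felsenstein* recursion (retention and loss
   allowed below, gains not).  The parent profile is the union of the
   sibling columns — only matches and deletions-from-parent are expressible
   on the way up, which deliberately over-populates ancestors.

2. **Dollo parsimony filter.**  Every column's origin is the MRCA of the
   leaves carrying it; the column is removed from all ancestors above the
   origin, trimming the residues the up-pass propagated too far.

3. **Conservative down-pass.**  The root profile is decoded with a
   single-sequence phylo-HMM to fix the root functional parse; each branch
   is then re-decoded with Viterbi *constrained* to state paths whose
   ancestral-side class sequence equals the parent's parse, with
   *Gain-Loss Felsenstein* emissions on the descendant side.  This yields a
   consistent multiple alignment over all taxa (ancestors included) plus a
   functional parse per taxon, from which binding-site predictions are
   extracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP, FunctionalParse, MultipleAlignment, SitePrediction
from .felsenstein import BranchOperator, ColumnVectors, combine, leaf_vectors
from .model import BG, PPHMMTemplate, StateKind
from .pairhmm import PairDecoder
from .phylo import Phylogeny
from .substitution import ALPHABET

logger = logging.getLogger(__name__)

__all__ = [
    "CladeProfile",
    "AnnotationResult",
    "progressive_up_pass",
    "dollo_filter",
    "down_pass",
    "extract_site_predictions",
    "align_and_annotate",
]


@dataclass
class CladeProfile:
    """Working profile of a clade during progressive alignment."""

    node: str
    members: list                      # per column: {leaf_name: residue_idx}
    lossy: ColumnVectors
    gainloss: ColumnVectors
    child_brackets: dict = field(default_factory=dict)  # child -> lossy brackets
    kept: list | None = None           # post-Dollo column indices

    @property
    def n_cols(self) -> int:
        return len(self.members)

    @property
    def kept_cols(self) -> list:
        return self.kept if self.kept is not None else list(range(self.n_cols))


@dataclass
class AnnotationResult:
    alignment: MultipleAlignment
    parses: dict
    predictions: list
    leaf_alignment: MultipleAlignment = None
    up_scores: dict = field(default_factory=dict)
    down_scores: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# up-pass
# ---------------------------------------------------------------------------

def _leaf_profile(name: str, seq: str, n_classes: int) -> CladeProfile:
    vec = leaf_vectors(seq, n_classes)
    members = [{name: i} for i in range(len(seq))]
    return CladeProfile(name, members, vec, vec)


def progressive_up_pass(
    template: PPHMMTemplate,
    tree: Phylogeny,
    leaves: dict,
    c_branch: float = 1.0,
    c_indel: float = 1.0,
    cell_budget: float = 5e7,
):
    """Post-order sibling alignment; returns per-node CladeProfiles."""
    missing = set(tree.leaf_names) - set(leaves)
    extra = set(leaves) - set(tree.leaf_names)
    if missing or extra:
        raise ValueError(
            f"leaf/sequence mismatch: missing={sorted(missing)}, "
            f"unmatched={sorted(extra)}"
        )
    n_classes = len(template.class_ids)
    profiles: dict[str, CladeProfile] = {}
    scores: dict[str, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            profiles[node.name] = _leaf_profile(
                node.name, leaves[node.name], n_classes
            )
            continue
        left, right = node.children
        pl, pr = profiles[left.name], profiles[right.name]
        t_pair = (left.length + right.length) * c_branch
        model = template.instantiate(t_pair, 1.0, c_indel)
        dec = PairDecoder(model, pl.lossy, pr.lossy, cell_budget=cell_budget)
        res = dec.decode()
        scores[node.name] = res.score

        br = {}
        for child, prof in ((left, pl), (right, pr)):
            op = BranchOperator(template, child.length * c_branch)
            br[child.name] = {
                "lossy": op.propagate(prof.lossy, "lossy"),
                "gainloss": op.propagate(prof.gainloss, "gainloss"),
            }

        members = []
        l_idx, r_idx = [], []
        for (s, i, j) in res.path.steps:
            st = template.states[s]
            if st.kind == StateKind.MATCH:
                members.append({**pl.members[i], **pr.members[j]})
                l_idx.append(i)
                r_idx.append(j)
            elif st.kind == StateKind.DELETE:
                members.append(dict(pl.members[i]))
                l_idx.append(i)
                r_idx.append(None)
            else:
                members.append(dict(pr.members[j]))
                l_idx.append(None)
                r_idx.append(j)

        parent = {}
        for mode in ("lossy", "gainloss"):
            n_cols = len(members)
            vals = np.ones((n_cols, n_classes, 4))
            scale = np.zeros((n_cols, n_classes))
            parts = {left.name: l_idx, right.name: r_idx}
            child_cols = {}
            for cname, idxs in parts.items():
                cv = br[cname][mode]
                cvals = np.ones((n_cols, n_classes, 4))
                cscale = np.zeros((n_cols, n_classes))
                sel = [k for k, ii in enumerate(idxs) if ii is not None]
                src = [idxs[k] for k in sel]
                cvals[sel] = cv.values[src]
                cscale[sel] = cv.log_scale[src]
                vals = vals * cvals
                scale = scale + cscale
                child_cols[cname] = ColumnVectors(cvals, cscale)
            parent[mode] = ColumnVectors(vals, scale).normalised()
            if mode == "lossy":
                brackets = child_cols
        prof = CladeProfile(
            node.name, members, parent["lossy"], parent["gainloss"],
            child_brackets=brackets,
        )
        profiles[node.name] = prof
    return profiles, scores


# ---------------------------------------------------------------------------
# Dollo parsimony filter
# ---------------------------------------------------------------------------

def dollo_filter(profiles: dict, tree: Phylogeny) -> dict:
    """Assign each column its Dollo origin (the MRCA of the member leaves)
    and drop the column from every node above the origin.  Profiles are
    annotated in place with their kept column indices and also returned."""
    ancestors: dict[str, set] = {}
    for node in tree.preorder():
        if node.parent is None:
            ancestors[node.name] = set()
        else:
            ancestors[node.name] = ancestors[node.parent.name] | {
                node.parent.name
            }
    for node in tree.postorder():
        prof = profiles[node.name]
        if node.is_leaf:
            prof.kept = list(range(prof.n_cols))
            continue
        kept = []
        for k, mem in enumerate(prof.members):
            origin = tree.mrca(mem.keys()).name
            # keep the column unless this node sits strictly above the origin
            if origin == node.name or origin in ancestors[node.name]:
                kept.append(k)
        prof.kept = kept
    return profiles


# ---------------------------------------------------------------------------
# root decoding (single-sequence phylo-HMM)
# ---------------------------------------------------------------------------

def _root_decode(template: PPHMMTemplate, prof: CladeProfile):
    """Viterbi parse of the root profile under a stationary site-density HMM."""
    spec = template.spec
    cols = prof.kept_cols
    n = len(cols)
    if not spec.profiles or n == 0:
        return [BG] * n, [None] * n

    # chain construction: state 0 = bg, then per (factor, strand) a run of
    # profile-column states; entry mass b_inf * freq * strand_factor
    class_seq = [BG]
    chain_meta = [None]
    entry = {0: 0.0}
    starts = []
    b_inf = spec.bd_params.asymptotic_gain
    tau = spec.epsilon
    mean_len = sum(
        spec.factor_frequencies[p.factor_name] * p.length
        for p in spec.profiles
    )
    # per-column site-entry probability at the stationary density b_inf
    kappa = b_inf / (mean_len * (1.0 - b_inf) + b_inf)
    for p in spec.profiles:
        for strand in "+-":
            starts.append(len(class_seq))
            L = p.length
            for i in range(L):
                class_seq.append(f"{p.factor_name}|{strand}|{i}")
                chain_meta.append((p.factor_name, strand, i, L))
            entry[starts[-1]] = (
                kappa
                * spec.factor_frequencies[p.factor_name]
                * spec.strand_factor
            )
    S = len(class_seq)
    entry[0] = 1.0 - kappa

    # emissions: log sum_x pi_c(x) V[col, c, x]
    cls_idx = [template.class_index[c] for c in class_seq]
    pis = np.stack(
        [template.class_registry[c].rate_matrix.equilibrium for c in class_seq]
    )
    vals = prof.gainloss.values[cols][:, cls_idx, :]      # (n, S, 4)
    scales = prof.gainloss.log_scale[cols][:, cls_idx]    # (n, S)
    with np.errstate(divide="ignore"):
        emis = np.log(np.einsum("nsx,sx->ns", vals, pis)) + scales

    NEG = -1.0e300
    V = np.full((n, S), NEG)
    BP = np.full((n, S), -1, dtype=np.int64)
    entry_ids = np.array(sorted(entry), dtype=np.int64)
    log_entry = np.array([
        np.log((1.0 - tau) * entry[s]) if entry[s] > 0 else NEG
        for s in entry_ids
    ])
    interior = np.array(
        [s for s in range(S)
         if chain_meta[s] is not None and chain_meta[s][2] > 0],
        dtype=np.int64,
    )
    exits = np.array([0] + [s + chain_meta[s][3] - 1 for s in starts],
                     dtype=np.int64)

    V[0, entry_ids] = log_entry + emis[0, entry_ids]
    BP[0, entry_ids] = -2
    for c in range(1, n):
        ev = V[c - 1, exits]
        m = int(np.argmax(ev))
        if ev[m] > NEG / 2:
            V[c, entry_ids] = ev[m] + log_entry + emis[c, entry_ids]
            BP[c, entry_ids] = exits[m]
        if interior.size:
            prev = V[c - 1, interior - 1]
            ok = prev > NEG / 2
            V[c, interior[ok]] = prev[ok] + emis[c, interior[ok]]
            BP[c, interior[ok]] = interior[ok] - 1
    ends = [(V[n - 1, e], e) for e in exits if V[n - 1, e] > NEG / 2]
    if not ends:
        return [BG] * n, [None] * n
    s = max(ends)[1]
    labels = [None] * n
    events = [None] * n
    c = n - 1
    while c >= 0:
        labels[c] = class_seq[s]
        events[c] = "ancestral" if class_seq[s] != BG else None
        s_prev = BP[c, s]
        if s_prev == -2:
            break
        s = s_prev
        c -= 1
    return labels, events


# ---------------------------------------------------------------------------
# down-pass
# ---------------------------------------------------------------------------

class _GlobalColumn:
    """A column of the final alignment, ordered via before/after chains."""

    __slots__ = ("before", "after", "entries")

    def __init__(self):
        self.before = []   # columns emitted immediately before this one
        self.after = []    # columns emitted immediately after this one
        self.entries = {}  # node name -> local kept-column position


def down_pass(
    template: PPHMMTemplate,
    tree: Phylogeny,
    profiles: dict,
    c_branch: float = 1.0,
    c_indel: float = 1.0,
    cell_budget: float = 5e7,
):
    """Pre-order constrained re-alignment; returns (alignment, parses, scores)."""
    parses: dict[str, tuple] = {}
    scores: dict[str, float] = {}
    root = tree.root
    root_prof = profiles[root.name]
    labels, events = _root_decode(template, root_prof)
    parses[root.name] = (labels, events)

    head = _GlobalColumn()
    colmap: dict[str, list] = {}
    root_cols = []
    for pos, _ in enumerate(root_prof.kept_cols):
        gc = _GlobalColumn()
        gc.entries[root.name] = pos
        root_cols.append(gc)
    colmap[root.name] = root_cols

    for node in tree.preorder():
        if node.is_leaf:
            continue
        for child in node.children:
            _decode_branch(
                template, node, child, profiles, parses, scores, colmap,
                head, c_branch, c_indel, cell_budget,
            )

    # final column order: the root chain is the top-level spine; inserted
    # columns hang off their anchors via before/after trees
    order = []

    def emit(gc):
        for prv in gc.before:
            emit(prv)
        if gc is not head:
            order.append(gc)
        for nxt in gc.after:
            emit(nxt)

    emit(head)
    for gc in root_cols:
        emit(gc)

    alignment = _render_alignment(template, tree, profiles, parses, order)
    return alignment, {
        name: FunctionalParse(name, labs, evs)
        for name, (labs, evs) in parses.items()
    }, scores


def _decode_branch(template, parent, child, profiles, parses, scores, colmap,
                   head, c_branch, c_indel, cell_budget):
    pprof = profiles[parent.name]
    cprof = profiles[child.name]
    plabels, _ = parses[parent.name]
    sibling = next(c for c in parent.children if c is not child)

    anc_cols = pprof.kept_cols
    sib_br = pprof.child_brackets[sibling.name]
    anc_vec = sib_br.subset(anc_cols)
    desc_vec = cprof.gainloss.subset(cprof.kept_cols)

    model = template.instantiate(child.length, c_branch, c_indel)
    dec = PairDecoder(
        model, anc_vec, desc_vec, anc_parse=list(plabels),
        cell_budget=cell_budget,
    )
    res = dec.decode()
    if not np.isfinite(res.score):
        logger.warning(
            "constrained decode infeasible on branch %s->%s; falling back to "
            "unconstrained decoding", parent.name, child.name,
        )
        dec = PairDecoder(model, anc_vec, desc_vec, cell_budget=cell_budget)
        res = dec.decode()
    scores[child.name] = res.score

    n_child = len(cprof.kept_cols)
    labels = [BG] * n_child
    events = [None] * n_child
    child_cols = [None] * n_child
    pcols = colmap[parent.name]
    steps = res.path.steps

    # an inserted child column must sit strictly between the previous and the
    # next *consumed parent column* in the global order; anchoring it before
    # the next parent column (or after the last one at the path tail)
    # guarantees this regardless of what other branches hung off the anchors
    next_anchor = [None] * len(steps)
    upcoming = None
    for k in range(len(steps) - 1, -1, -1):
        next_anchor[k] = upcoming
        s, i, j = steps[k]
        if template.states[s].kind != StateKind.INSERT:
            upcoming = pcols[i]

    last_anchor = None
    run_prev = None
    for k, (s, i, j) in enumerate(steps):
        st = template.states[s]
        if st.kind == StateKind.MATCH:
            gc = pcols[i]
            child_cols[j] = gc
            last_anchor = gc
            run_prev = None
        elif st.kind == StateKind.DELETE:
            last_anchor = pcols[i]
            run_prev = None
        else:  # insert
            gc = _GlobalColumn()
            if run_prev is not None:
                run_prev.after.append(gc)
            elif next_anchor[k] is not None:
                next_anchor[k].before.append(gc)
            elif last_anchor is not None:
                last_anchor.after.append(gc)
            else:
                head.after.append(gc)
            run_prev = gc
            child_cols[j] = gc
        if st.kind in (StateKind.MATCH, StateKind.INSERT):
            labels[j] = st.desc_class
            if st.site is not None:
                if st.site.event == "gain":
                    events[j] = "gained"
                elif st.site.event == "retention":
                    events[j] = "retained"

    for j, gc in enumerate(child_cols):
        if gc is None:
            raise AssertionError("descendant column left unaligned")
        gc.entries[child.name] = j
    colmap[child.name] = child_cols
    parses[child.name] = (labels, events)


def _render_alignment(template, tree, profiles, parses, order):
    rows = {}
    for node in tree.preorder():
        prof = profiles[node.name]
        labels, _ = parses[node.name]
        if node.is_leaf:
            seq = _leaf_residues(prof)
        else:
            seq = _ancestor_residues(template, prof, labels)
        row = []
        for gc in order:
            if node.name in gc.entries:
                row.append(seq[gc.entries[node.name]])
            else:
                row.append(GAP)
        rows[node.name] = "".join(row)
    return MultipleAlignment(rows)


def _leaf_residues(prof: CladeProfile):
    # leaf columns are one-hot over the residue at that position
    out = []
    for k in prof.kept_cols:
        x = int(np.argmax(prof.lossy.values[k, 0]))
        out.append(ALPHABET[x])
    return out


def _ancestor_residues(template, prof: CladeProfile, labels):
    out = []
    for pos, k in enumerate(prof.kept_cols):
        cls = labels[pos] if pos < len(labels) else BG
        ci = template.class_index[cls]
        pi = template.class_registry[cls].rate_matrix.equilibrium
        x = int(np.argmax(prof.gainloss.values[k, ci] * pi))
        out.append(ALPHABET[x])
    return out


# ---------------------------------------------------------------------------
# site extraction and the top-level pipeline
# ---------------------------------------------------------------------------

def extract_site_predictions(parses: dict,
                             profile_lengths: dict | None = None) -> list:
    """Complete profile runs in each taxon's parse, as site predictions.

    Partial runs (which the state machine should never produce) are dropped
    with a warning when ``profile_lengths`` is provided.
    """
    predictions = []
    for name, parse in parses.items():
        labels, events = parse.labels, parse.events
        i = 0
        n = len(labels)
        while i < n:
            lab = labels[i]
            if lab == BG:
                i += 1
                continue
            factor, strand, pos = lab.split("|")
            if int(pos) != 0:
                logger.warning(
                    "dropping partial site run at %s residue %d (%s)",
                    name, i, lab,
                )
                i += 1
                continue
            L = 1
            while i + L < n and labels[i + L] == f"{factor}|{strand}|{L}":
                L += 1
            if (
                profile_lengths is not None
                and profile_lengths.get(factor) not in (None, L)
            ):
                logger.warning(
                    "dropping incomplete site run (%s, %d/%s columns) at %s",
                    factor, L, profile_lengths.get(factor), name,
                )
                i += L
                continue
            run_events = {events[k] for k in range(i, i + L) if events[k]}
            event = run_events.pop() if len(run_events) == 1 else (
                "gained" if "gained" in run_events else None
            )
            predictions.append(
                SitePrediction(name, factor, strand, i, i + L, event)
            )
            i += L
    return predictions


def align_and_annotate(
    template: PPHMMTemplate,
    tree: Phylogeny,
    leaves: dict,
    c_branch: float = 1.0,
    c_indel: float = 1.0,
    cell_budget: float = 5e7,
) -> AnnotationResult:
    """Full pipeline: up-pass, Dollo filter, down-pass, site extraction."""
    if len(tree.leaf_names) == 1:
        return _single_taxon(template, tree, leaves)
    profiles, up_scores = progressive_up_pass(
        template, tree, leaves, c_branch, c_indel, cell_budget
    )
    dollo_filter(profiles, tree)
    alignment, parses, down_scores = down_pass(
        template, tree, profiles, c_branch, c_indel, cell_budget
    )
    lengths = {p.factor_name: p.length for p in template.spec.profiles}
    predictions = extract_site_predictions(parses, lengths)
    result = AnnotationResult(
        alignment=alignment,
        parses=parses,
        predictions=predictions,
        leaf_alignment=alignment.restricted(tree.leaf_names),
        up_scores=up_scores,
        down_scores=down_scores,
    )
    _check_alignment_validity(result.alignment, tree, leaves)
    return result


def _single_taxon(template, tree, leaves):
    name = tree.leaf_names[0]
    prof = _leaf_profile(name, leaves[name], len(template.class_ids))
    labels, events = _root_decode(template, prof)
    parses = {name: FunctionalParse(name, labels, events)}
    alignment = MultipleAlignment({name: leaves[name]})
    return AnnotationResult(
        alignment=alignment,
        parses=parses,
        predictions=extract_site_predictions(parses),
        leaf_alignment=alignment,
    )


def _check_alignment_validity(alignment: MultipleAlignment, tree, leaves):
    for name, seq in leaves.items():
        got = alignment.ungapped(name)
        if got != seq:
            raise AssertionError(
                f"alignment row for {name!r} does not reproduce its input "
                "sequence"
            )
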