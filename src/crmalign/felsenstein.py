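"""Class-conditional likelihood recursions over clades.

Each alignment column of a clade profile carries, for every functional class
``c`` in the model, a conditional likelihood vector

    L_X^c(x) = P(leaf residues below X | residue x of class c at X)

computed bottom-up (Felsenstein pruning).  Three variants differ in how the
functional class may change along branches inside the clade:

``standard``
    no class change: plain pruning under a single class;
``lossy``
    used during the liberal up-pass: a site class may be *lost* to
    background along any branch (weight ``q(t)``; retention weight
    ``p(t)``) but never gained, and the two options are *summed*;
``gainloss``
    used during the conservative down-pass: along every branch the class
    history with maximum probability is chosen (retention ``p(t)`` vs. loss
    ``q(t)`` into background), i.e. the sum is replaced by a per-branch,
    per-nucleotide maximisation.  Gains inside the clade are handled by the
    explicit gain states of the branch decoding step rather than inside this
    recursion.

Vectors are stored linearly with a per-(column, class) log scale factor to
avoid underflow on deep clades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .birth_death import turnover_probabilities
from .model import BG, PPHMMTemplate
from .substitution import NUC_INDEX, cross_functional_matrix, substitution_probabilities

__all__ = ["BranchOperator", "ColumnVectors", "leaf_vectors", "emission_likelihood"]

MODES = ("standard", "lossy", "gainloss")


@dataclass
class ColumnVectors:
    """Scaled likelihood vectors for a run of columns.

    ``values`` has shape (n_cols, n_classes, 4); ``log_scale`` has shape
    (n_cols, n_classes); the true likelihood is
    ``values * exp(log_scale)[..., None]``.
    """

    values: np.ndarray
    log_scale: np.ndarray

    @property
    def n_cols(self) -> int:
        return self.values.shape[0]

    def normalised(self) -> "ColumnVectors":
        m = self.values.max(axis=2)
        safe = np.where(m > 0, m, 1.0)
        vals = self.values / safe[..., None]
        with np.errstate(divide="ignore"):
            scale = self.log_scale + np.where(m > 0, np.log(safe), -np.inf)
        return ColumnVectors(vals, scale)

    def subset(self, cols) -> "ColumnVectors":
        return ColumnVectors(self.values[cols], self.log_scale[cols])


def leaf_vectors(sequence: str, n_classes: int) -> ColumnVectors:
    """Indicator vectors for an observed sequence; ``N`` marginalises."""
    n = len(sequence)
    values = np.zeros((n, n_classes, 4))
    for i, ch in enumerate(sequence):
        if ch == "N":
            values[i, :, :] = 1.0
        else:
            values[i, :, NUC_INDEX[ch]] = 1.0
    return ColumnVectors(values, np.zeros((n, n_classes)))


class BranchOperator:
    """Per-branch transfer of likelihood vectors from a child to its parent.

    Precomputes, for every functional class, the within-class substitution
    matrix ``P_c(t)`` and the class-to-background mixture ``P_{c->bg}(t)``
    at the (already ``c_branch``-scaled) branch length ``t``, along with the
    retention/loss weights ``p(t)``, ``q(t)``.
    """

    def __init__(self, template: PPHMMTemplate, t: float):
        self.template = template
        self.t = t
        ids = template.class_ids
        n = len(ids)
        self.p_same = np.empty((n, 4, 4))
        self.p_to_bg = np.empty((n, 4, 4))
        bg_class = template.class_registry[BG]
        for k, cid in enumerate(ids):
            cls = template.class_registry[cid]
            self.p_same[k] = substitution_probabilities(cls.rate_matrix, t).probs
            if cid == BG:
                self.p_to_bg[k] = self.p_same[k]
            else:
                self.p_to_bg[k] = cross_functional_matrix(cls, bg_class, t).probs
        # Turnover is a whole-site event but the recursion runs per column:
        # each column of an L-column site class carries the L-th root of the
        # site-level retention/loss probability, so a class history that
        # keeps (or drops) the entire site across a branch is charged
        # exactly p(t) (or q(t)) once per branch.
        self.retention = np.ones(n)
        self.loss = np.zeros(n)
        if template.spec.profiles and not template.spec.complete_orthology:
            tp = turnover_probabilities(template.spec.bd_params, t)
            for k, cid in enumerate(ids):
                if cid == BG:
                    continue
                L = template.site_length(cid)
                self.retention[k] = tp.retention ** (1.0 / L)
                self.loss[k] = tp.loss ** (1.0 / L)

    def propagate(self, child: ColumnVectors, mode: str) -> ColumnVectors:
        """Bracket term BR(x) for the parent, given the child's vectors."""
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        vals, scale = child.values, child.log_scale
        # same-class transfer: out[n, k, x] = sum_y P_k[x, y] vals[n, k, y]
        same = np.einsum("kxy,nky->nkx", self.p_same, vals, optimize=True)
        if mode == "standard":
            return ColumnVectors(same, scale.copy()).normalised()

        # class-to-background option, weighted by the per-column loss weight
        cross = np.einsum("kxy,ny->nkx", self.p_to_bg, vals[:, 0, :], optimize=True)
        stay_scale = scale.copy()
        lose_scale = np.broadcast_to(scale[:, [0]], scale.shape).copy()
        stay = self.retention[None, :, None] * same
        lose = self.loss[None, :, None] * cross

        m = np.maximum(stay_scale, lose_scale)
        a = stay * np.exp(np.clip(stay_scale - m, -745, 0))[..., None]
        b = lose * np.exp(np.clip(lose_scale - m, -745, 0))[..., None]
        out = a + b if mode == "lossy" else np.maximum(a, b)
        return ColumnVectors(out, m).normalised()


def combine(parent_parts: list[ColumnVectors]) -> ColumnVectors:
    """Pointwise product of bracket terms from several children."""
    vals = parent_parts[0].values.copy()
    scale = parent_parts[0].log_scale.copy()
    for part in parent_parts[1:]:
        vals = vals * part.values
        scale = scale + part.log_scale
    return ColumnVectors(vals, scale).normalised()


def clade_vectors(template: PPHMMTemplate, node, sequences: dict[str, str],
                  mode: str, c_branch: float = 1.0) -> ColumnVectors:
    """Likelihood vectors at ``node`` for aligned (equal-length) sequences.

    Utility for single-column / gapless clades (testing and the emission
    contract): every leaf sequence must have the same length, and column ``i``
    of the result describes column ``i`` of that implicit gapless alignment.
    """
    n_classes = len(template.class_ids)
    if node.is_leaf:
        return leaf_vectors(sequences[node.name], n_classes)
    parts = []
    for child in node.children:
        below = clade_vectors(template, child, sequences, mode, c_branch)
        op = BranchOperator(template, child.length * c_branch)
        parts.append(op.propagate(below, mode))
    return combine(parts)


def emission_likelihood(template: PPHMMTemplate, node, sequences: dict[str, str],
                        class_id: str, mode: str = "standard",
                        column: int = 0, c_branch: float = 1.0) -> float:
    """Log marginal emission likelihood of one clade column under a class.

    Computes ``log sum_x P_eq(x | class) L_root(x, class)`` with the chosen
    recursion mode; for a single-leaf clade this reduces to the log of the
    equilibrium-weighted indicator of the observed base.
    """
    vec = clade_vectors(template, node, sequences, mode, c_branch)
    pi = template.class_registry[class_id].rate_matrix.equilibrium
    k = template.class_index[class_id]
    val = float(np.dot(pi, vec.values[column, k]))
    if val <= 0:
        return -math.inf
    return math.log(val) + float(vec.log_scale[column, k])
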