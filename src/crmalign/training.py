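"""Parameter estimation.

Covers the estimators the aligner needs before it can run on new data:

* indel parameters ``alpha`` (gap-open rate per unit branch length) and
  ``beta`` (gap extension) from counts on training alignments;
* the birth rate via the density constraint ``lambda = delta mu / (1 -
  delta)``, so the stationary site density equals the observed fraction
  ``delta`` of residues inside sites (``mu`` defaults to 0.08);
* a GTR background substitution matrix and branch lengths, jointly, by
  maximum likelihood on background alignment columns (rates and times are
  confounded, so only their product is identified — the rate matrix is kept
  normalised and the scale lives in the branch lengths);
* per-factor relative site frequencies with add-one smoothing;
* discriminative coordinate-wise hill-climbing of ``c_indel`` and
  ``c_branch`` (optionally the turnover rate) against site-level F on
  annotated training regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import GAP
from .birth_death import BirthDeathParams, derive_lambda
from .evaluation import site_accuracy
from .model import CRMModelSpec, IndelParams, assemble_crm_template
from .phylo import Phylogeny
from .progressive import align_and_annotate
from .substitution import NUC_INDEX, RateMatrix, build_gtr

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "estimate_indel_params",
    "derive_lambda",
    "fit_background_model",
    "estimate_factor_frequencies",
    "fit_discriminative_coeffs",
]


@dataclass
class TrainingConfig:
    delta: float = 0.1            # estimated binding-site density
    mu: float = 0.08              # site death rate
    c_indel: float = 1.0
    c_branch: float = 1.0
    coarse_step: float = 1.5      # multiplicative hill-climb steps
    fine_step: float = 1.1
    max_rounds: int = 20
    optimize: tuple = ("c_indel", "c_branch")

    def __post_init__(self):
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        if self.c_indel <= 0 or self.c_branch <= 0:
            raise ValueError("coefficients must be positive")


# ---------------------------------------------------------------------------
# indel parameters
# ---------------------------------------------------------------------------

def _pair_transitions(row_a: str, row_b: str):
    """(opens, match_steps, extends, closes) for one aligned row pair."""
    opens = match = extends = closes = 0
    state = "M"
    for ca, cb in zip(row_a, row_b):
        if ca == GAP and cb == GAP:
            continue
        here = "M" if (ca != GAP and cb != GAP) else "G"
        if state == "M" and here == "G":
            opens += 1
        elif state == "M" and here == "M":
            match += 1
        elif state == "G" and here == "G":
            extends += 1
        else:
            closes += 1
        state = here
    return opens, match, extends, closes


def estimate_indel_params(alignments, tree: Phylogeny | None = None,
                          default_divergence: float = 1.0) -> IndelParams:
    """Count-based estimation of (alpha, beta) from training alignments.

    When a tree is given and the alignments carry rows for internal nodes,
    counting runs over parent/child row pairs at their branch lengths; the
    gap-open rate is then the pooled maximum-likelihood ``alpha`` under
    ``P(open at distance t) = 1 - e^{-alpha t}``.  Without a tree, adjacent
    row pairs at ``default_divergence`` are used.  Counts carry add-one
    smoothing.
    """
    if not alignments:
        raise ValueError("need at least one training alignment")
    counts = []  # (opens, match, extends, closes, t)
    for aln in alignments:
        if aln.n_cols == 0:
            raise ValueError("alignment has no columns")
        pairs = []
        if tree is not None:
            for node in tree.postorder():
                if node.parent is None:
                    continue
                if node.name in aln.rows and node.parent.name in aln.rows:
                    pairs.append((node.parent.name, node.name, node.length))
        if not pairs:
            names = list(aln.rows)
            if len(names) < 2:
                raise ValueError("alignment needs at least two rows")
            pairs = [
                (names[k], names[k + 1], default_divergence)
                for k in range(len(names) - 1)
            ]
        for a, b, t in pairs:
            counts.append((*_pair_transitions(aln.rows[a], aln.rows[b]), t))

    opens = sum(c[0] for c in counts) + 1
    match = sum(c[1] for c in counts) + 1
    extends = sum(c[2] for c in counts) + 1
    closes = sum(c[3] for c in counts) + 1

    def neg_loglik(log_alpha):
        alpha = math.exp(log_alpha)
        ll = 0.0
        for o, m, _, _, t in counts:
            p_open = -math.expm1(-alpha * t)
            p_open = min(max(p_open, 1e-12), 1 - 1e-12)
            ll += o * math.log(p_open) + m * math.log1p(-p_open)
        return -ll

    res = minimize_scalar(neg_loglik, bounds=(math.log(1e-8), math.log(5.0)),
                          method="bounded")
    alpha = float(np.clip(math.exp(res.x), 1e-8, 0.999))
    beta = float(np.clip(extends / (extends + closes), 1e-6, 1 - 1e-6))
    # smoothing floor when no gaps were seen at all
    if opens == 1 and extends == 1:
        alpha = 1e-6
    return IndelParams(alpha, beta)


# ---------------------------------------------------------------------------
# background model + branch lengths
# ---------------------------------------------------------------------------

def _column_patterns(alignments, leaf_names):
    patterns: dict[tuple, int] = {}
    for aln in alignments:
        rows = [aln.rows[n] for n in leaf_names]
        for c in range(aln.n_cols):
            col = tuple(row[c] for row in rows)
            if any(ch == GAP or ch == "N" for ch in col):
                continue
            key = tuple(NUC_INDEX[ch] for ch in col)
            patterns[key] = patterns.get(key, 0) + 1
    return patterns


def _felsenstein_loglik(q: RateMatrix, tree: Phylogeny, lengths: dict,
                        patterns: dict, leaf_names):
    from scipy.linalg import expm

    mats = {
        node.name: expm(lengths[node.name] * q.rates)
        for node in tree.postorder()
        if node.parent is not None
    }
    keys = np.array(list(patterns.keys()))       # (P, n_leaves)
    weights = np.array(list(patterns.values()))
    leaf_pos = {n: i for i, n in enumerate(leaf_names)}
    P = keys.shape[0]
    partial: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            arr = np.zeros((P, 4))
            arr[np.arange(P), keys[:, leaf_pos[node.name]]] = 1.0
            partial[node.name] = arr
        else:
            arr = np.ones((P, 4))
            for child in node.children:
                arr = arr * (partial[child.name] @ mats[child.name].T)
            partial[node.name] = arr
    root = partial[tree.root.name] @ q.equilibrium
    return float(np.dot(weights, np.log(np.clip(root, 1e-300, None))))


def fit_background_model(alignments, tree: Phylogeny, tol: float = 1e-6,
                         max_iter: int = 500):
    """Joint ML fit of GTR exchangeabilities, equilibrium and branch lengths.

    Returns ``(rate_matrix, branch_lengths, history)`` where history is the
    per-iteration log-likelihood trace (non-decreasing).
    """
    leaf_names = tree.leaf_names
    patterns = _column_patterns(alignments, leaf_names)
    if not patterns:
        raise ValueError("no gap-free columns available for training")
    if len(patterns) == 1:
        logger.warning(
            "single-column training input; estimates will be prior-dominated"
        )
    branch_nodes = [n.name for n in tree.postorder() if n.parent is not None]
    counts = np.zeros(4)
    for key, w in patterns.items():
        for k in key:
            counts[k] += w
    eq0 = (counts + 1) / (counts.sum() + 4)

    def unpack(x):
        ex = np.concatenate([np.exp(x[:5]), [1.0]])
        eq_logits = np.concatenate([x[5:8], [0.0]])
        eq = np.exp(eq_logits - eq_logits.max())
        eq = eq / eq.sum()
        lengths = dict(zip(branch_nodes, np.exp(x[8:])))
        return build_gtr(ex, eq), lengths

    x0 = np.concatenate([
        np.zeros(5),
        np.log(eq0[:3] / eq0[3]),
        np.log([max(n.length, 1e-3) for n in tree.postorder()
                if n.parent is not None]),
    ])

    history = []

    def objective(x):
        try:
            q, lengths = unpack(x)
        except Exception:
            return 1e12
        return -_felsenstein_loglik(q, tree, lengths, patterns, leaf_names)

    def callback(x):
        history.append(-objective(x))

    res = minimize(
        objective, x0, method="L-BFGS-B", callback=callback,
        options={"maxiter": max_iter, "ftol": tol * 1e-3},
    )
    q, lengths = unpack(res.x)
    if not history:
        history = [-objective(res.x)]
    return q, lengths, history


# ---------------------------------------------------------------------------
# factor frequencies
# ---------------------------------------------------------------------------

def estimate_factor_frequencies(sites, factor_names) -> dict:
    """Smoothed relative site frequencies per factor (add-one)."""
    counts = {f: 1.0 for f in factor_names}
    for s in sites:
        if s.factor in counts:
            counts[s.factor] += 1.0
    total = sum(counts.values())
    return {f: c / total for f, c in counts.items()}


# ---------------------------------------------------------------------------
# discriminative hill-climbing
# ---------------------------------------------------------------------------

def fit_discriminative_coeffs(instances, spec: CRMModelSpec,
                              background: RateMatrix,
                              config: TrainingConfig | None = None):
    """Coordinate-wise multiplicative hill-climb on site-level F.

    ``instances`` is a list of ``(leaves, tree, truth_sites)`` training
    regions.  Coordinates are taken from ``config.optimize`` (subset of
    ``c_indel``, ``c_branch``, ``lambda``); the step schedule is coarse
    (x1.5) then fine (x1.1), stopping when no single-coordinate move
    improves the objective.  Ties keep the current value.

    Returns ``(values, best_objective, trace)``.
    """
    if not instances:
        raise ValueError("need at least one training instance")
    config = config or TrainingConfig()
    values = {
        "c_indel": config.c_indel,
        "c_branch": config.c_branch,
        "lambda": spec.bd_params.birth_rate,
    }

    def objective(vals):
        bd = BirthDeathParams(vals["lambda"], spec.bd_params.death_rate)
        current = replace(spec, bd_params=bd, profiles=spec.profiles)
        template = assemble_crm_template(current, background)
        fs = []
        for leaves, tree, truth in instances:
            result = align_and_annotate(
                template, tree, leaves,
                c_branch=vals["c_branch"], c_indel=vals["c_indel"],
            )
            preds = [p for p in result.predictions
                     if p.taxon in tree.leaf_names]
            truth_leaf = [s for s in truth if s.taxon in tree.leaf_names]
            fs.append(site_accuracy(preds, truth_leaf).f_score)
        return float(np.mean(fs))

    best = objective(values)
    trace = [best]
    if best == 0.0:
        probe_zero = True
    for step in (config.coarse_step, config.fine_step):
        for _ in range(config.max_rounds):
            improved = False
            for coord in config.optimize:
                for factor in (step, 1.0 / step):
                    cand = dict(values)
                    cand[coord] = values[coord] * factor
                    score = objective(cand)
                    if score > best:
                        best = score
                        values = cand
                        trace.append(best)
                        improved = True
            if not improved:
                break
    if best == 0.0:
        logger.warning(
            "objective identically zero on the probed grid; returning "
            "default coefficients"
        )
    return values, best, trace
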