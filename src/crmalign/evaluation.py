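"""Accuracy metrics for alignments and binding-site predictions.

Three scores, each reported as sensitivity (Sn), specificity (Sp — used in
the positive-predictive-value sense) and their harmonic mean
``F = 2 Sn Sp / (Sn + Sp)``:

* **alignment F** — an alignment is read as an undirected homology graph
  over (taxon, residue) nodes, one edge per aligned residue pair; predicted
  and true edge sets are compared;
* **nucleotide-level accuracy** — residues classified foreground (inside
  any site) vs. background, factor identity ignored;
* **site-level accuracy** — a true site counts as found when at least half
  of its residues (``ceil(L/2)``) overlap a predicted site of the same
  factor (and, by default, strand); matching is greedy one-to-one so a
  prediction validates at most one true site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alignment import MultipleAlignment, SitePrediction

__all__ = [
    "EvaluationScores",
    "alignment_fscore",
    "nucleotide_accuracy",
    "site_accuracy",
]


@dataclass(frozen=True)
class EvaluationScores:
    sensitivity: float
    specificity: float

    @property
    def f_score(self) -> float:
        sn, sp = self.sensitivity, self.specificity
        if sn + sp == 0:
            return 0.0
        return 2.0 * sn * sp / (sn + sp)

    def __iter__(self):
        yield from (self.sensitivity, self.specificity, self.f_score)


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def alignment_fscore(predicted: MultipleAlignment,
                     truth: MultipleAlignment,
                     taxa=None) -> EvaluationScores:
    """Homology-graph comparison of two alignments over the same sequences."""
    use = set(taxa) if taxa is not None else set(truth.rows)
    for t in use:
        if predicted.ungapped(t) != truth.ungapped(t):
            raise ValueError(
                f"alignments disagree on the ungapped sequence of {t!r}"
            )
    pred_edges = predicted.homology_edges(use)
    true_edges = truth.homology_edges(use)
    shared = len(pred_edges & true_edges)
    return EvaluationScores(
        _ratio(shared, len(true_edges)), _ratio(shared, len(pred_edges))
    )


def nucleotide_accuracy(predicted, truth, sequence_lengths: dict,
                        taxa=None) -> EvaluationScores:
    """Foreground/background residue classification, factor ignored."""
    use = set(taxa) if taxa is not None else set(sequence_lengths)
    pred_fg = set()
    true_fg = set()
    for sites, store in ((predicted, pred_fg), (truth, true_fg)):
        for s in sites:
            if s.taxon not in use:
                continue
            n = sequence_lengths[s.taxon]
            if s.start < 0 or s.end > n:
                raise ValueError(
                    f"site {s} out of bounds for {s.taxon} (length {n})"
                )
            store.update((s.taxon, k) for k in range(s.start, s.end))
    tp = len(pred_fg & true_fg)
    return EvaluationScores(_ratio(tp, len(true_fg)), _ratio(tp, len(pred_fg)))


def site_accuracy(predicted, truth, taxa=None,
                  match_strand: bool = True) -> EvaluationScores:
    """Whole-site scoring under the half-overlap same-factor rule."""
    use = set(taxa) if taxa is not None else None

    def keep(sites):
        return [s for s in sites if use is None or s.taxon in use]

    preds = keep(predicted)
    truths = keep(truth)

    def compatible(p: SitePrediction, t: SitePrediction) -> bool:
        if p.taxon != t.taxon or p.factor != t.factor:
            return False
        if match_strand and p.strand != t.strand:
            return False
        need = math.ceil((t.end - t.start) / 2)
        return p.overlap(t) >= need

    # greedy one-to-one: order candidate pairs by overlap, ties leftmost
    pairs = sorted(
        (
            (-p.overlap(t), t.start, p.start, ti, pi)
            for ti, t in enumerate(truths)
            for pi, p in enumerate(preds)
            if compatible(p, t)
        ),
    )
    matched_t: set = set()
    matched_p: set = set()
    for _, _, _, ti, pi in pairs:
        if ti in matched_t or pi in matched_p:
            continue
        matched_t.add(ti)
        matched_p.add(pi)
    return EvaluationScores(
        _ratio(len(matched_t), len(truths)), _ratio(len(matched_p), len(preds))
    )
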