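"""Multiple alignments, functional parses and site predictions."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MultipleAlignment", "SitePrediction", "FunctionalParse", "GAP"]

GAP = "-"


@dataclass(frozen=True)
class SitePrediction:
    """One predicted (or true) binding site in one taxon.

    Coordinates are 0-based, half-open, in the taxon's ungapped sequence.
    ``event`` describes the branch above the taxon: ``gained``, ``retained``,
    or ``ancestral`` for sites already present at the root.
    """

    taxon: str
    factor: str
    strand: str
    start: int
    end: int
    event: str | None = None

    def overlap(self, other: "SitePrediction") -> int:
        if self.taxon != other.taxon:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class FunctionalParse:
    """Per-residue functional-class labels for one taxon.

    ``labels[i]`` is the class id (``bg`` or ``factor|strand|pos``) of
    residue ``i``; ``events[i]`` carries the turnover event of the state
    that emitted the residue, where applicable.
    """

    taxon: str
    labels: list
    events: list

    def __len__(self):
        return len(self.labels)


class MultipleAlignment:
    """Aligned rows over a shared column set; may include ancestral taxa."""

    def __init__(self, rows: dict[str, str]):
        lengths = {len(v) for v in rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        self.rows = dict(rows)
        self.n_cols = lengths.pop() if lengths else 0

    @property
    def taxa(self):
        return list(self.rows)

    def ungapped(self, taxon: str) -> str:
        return self.rows[taxon].replace(GAP, "")

    def column_residues(self):
        """Per column, the mapping taxon -> ungapped residue index."""
        counters = {t: 0 for t in self.rows}
        out = []
        for c in range(self.n_cols):
            col = {}
            for t, row in self.rows.items():
                if row[c] != GAP:
                    col[t] = counters[t]
                    counters[t] += 1
            out.append(col)
        return out

    def homology_edges(self, taxa=None) -> set:
        """The alignment as an undirected graph over (taxon, residue) nodes:
        one edge for every aligned residue pair in a column."""
        taxa = set(taxa) if taxa is not None else set(self.rows)
        edges = set()
        for col in self.column_residues():
            present = sorted((t, i) for t, i in col.items() if t in taxa)
            for a in range(len(present)):
                for b in range(a + 1, len(present)):
                    edges.add((present[a], present[b]))
        return edges

    def restricted(self, taxa) -> "MultipleAlignment":
        sub = {t: self.rows[t] for t in taxa}
        keep = [
            c for c in range(self.n_cols)
            if any(row[c] != GAP for row in sub.values())
        ]
        return MultipleAlignment(
            {t: "".join(row[c] for c in keep) for t, row in sub.items()}
        )

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{row}\n" for t, row in self.rows.items())

    def __repr__(self):
        return f"MultipleAlignment({len(self.rows)} taxa x {self.n_cols} cols)"
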