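"""Binding-site profiles (PWMs) and the JASPAR PFM reader."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .substitution import ALPHABET

__all__ = ["BindingProfile", "read_jaspar_pfm", "ProfileFormatError"]

_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G index map


class ProfileFormatError(ValueError):
    """Malformed PFM input."""


@dataclass(frozen=True)
class BindingProfile:
    """A transcription factor binding profile as per-position base probabilities.

    ``columns`` is an (L, 4) array of strictly positive probabilities (each
    row sums to 1) over A, C, G, T, obtained from integer counts with a
    pseudocount added to every cell before normalisation.
    """

    factor_name: str
    columns: np.ndarray

    def __post_init__(self):
        cols = np.asarray(self.columns, dtype=float)
        if cols.ndim != 2 or cols.shape[1] != 4 or cols.shape[0] < 1:
            raise ProfileFormatError("profile must be an (L, 4) matrix with L >= 1")
        if np.any(cols <= 0):
            raise ProfileFormatError(
                f"profile {self.factor_name!r} has a non-positive probability; "
                "apply a pseudocount before normalisation"
            )
        if not np.allclose(cols.sum(axis=1), 1.0, atol=1e-9):
            raise ProfileFormatError("each profile column must sum to 1")
        object.__setattr__(self, "columns", cols)

    @property
    def length(self) -> int:
        return self.columns.shape[0]

    def reverse_complement(self) -> "BindingProfile":
        """The minus-strand profile: reversed column order, complemented bases."""
        return BindingProfile(self.factor_name, self.columns[::-1, _COMPLEMENT])

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.columns.argmax(axis=1))


def read_jaspar_pfm(path, pseudocount: float = 0.1,
                    factor_name: str | None = None) -> BindingProfile:
    """Read a JASPAR-style PFM: 4 count rows for A, C, G, T.

    Accepts both the raw 4-row format and the bracketed JASPAR format
    (``A [ 1 2 3 ]``), with an optional ``>ID name`` header line.  The
    pseudocount (default 0.1) is added to every count before column
    normalisation.
    """
    path = Path(path)
    name = factor_name or path.stem
    rows: list[list[float]] = []
    order = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            parts = line[1:].split()
            if factor_name is None and parts:
                name = parts[-1]
            continue
        base = None
        if line[0].upper() in "ACGT" and (len(line) == 1 or not line[1].isdigit()):
            base = line[0].upper()
            line = line[1:].strip()
        line = line.replace("[", " ").replace("]", " ")
        try:
            values = [float(tok) for tok in line.split()]
        except ValueError as exc:
            raise ProfileFormatError(f"{path}:{lineno}: non-numeric count: {exc}")
        if not values:
            continue
        if any(v < 0 for v in values):
            raise ProfileFormatError(f"{path}:{lineno}: negative count")
        rows.append(values)
        order.append(base)
    if len(rows) != 4:
        raise ProfileFormatError(f"{path}: expected 4 count rows, found {len(rows)}")
    if len({len(r) for r in rows}) != 1:
        raise ProfileFormatError(f"{path}: ragged count rows")
    if all(b is not None for b in order) and order != list("ACGT"):
        idx = [order.index(b) for b in "ACGT"]
        rows = [rows[i] for i in idx]
    counts = np.asarray(rows, dtype=float).T  # (L, 4)
    probs = counts + pseudocount
    total = probs.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ProfileFormatError(f"{path}: zero column with zero pseudocount")
    return BindingProfile(name, probs / total)
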