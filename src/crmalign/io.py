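"""Readers and writers: FASTA, GFF3, BED6, TSV.

Readers validate and reject malformed input (with file/line context) rather
than silently coercing; writers are byte-deterministic given identical
inputs.  Coordinates are 0-based half-open internally and 1-based closed in
GFF3.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .alignment import MultipleAlignment, SitePrediction

__all__ = [
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "read_alignment_fasta",
    "write_gff3",
    "read_gff3",
    "write_bed6",
    "predictions_to_frame",
    "write_outputs",
]

VALID = set("ACGTN")


class FastaFormatError(ValueError):
    pass


def read_fasta(path) -> dict:
    """Named nucleotide sequences, uppercased; ``N`` allowed (treated as
    missing data downstream); anything else rejected with coordinates."""
    path = Path(path)
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in out:
            raise FastaFormatError(f"{path}: duplicate record name {name!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path}: empty record {name!r}")
        for pos, ch in enumerate(seq):
            if ch not in VALID:
                raise FastaFormatError(
                    f"{path}: record {name!r} position {pos + 1}: "
                    f"invalid symbol {ch!r}"
                )
        out[name] = seq
    if not out:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: dict, path, width: int = 70):
    lines = []
    for name, seq in sequences.items():
        lines.append(f">{name}")
        for k in range(0, len(seq), width):
            lines.append(seq[k:k + width])
    Path(path).write_text("\n".join(lines) + "\n")


def read_alignment_fasta(path) -> MultipleAlignment:
    """Aligned multi-FASTA (gap symbol ``-``)."""
    path = Path(path)
    rows = {}
    for record in SeqIO.parse(str(path), "fasta"):
        rows[record.id] = str(record.seq).upper()
    if not rows:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return MultipleAlignment(rows)


def write_alignment_fasta(alignment: MultipleAlignment, path, width: int = 70):
    write_fasta(alignment.rows, path, width)


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

def write_gff3(predictions, path, source: str = "crmalign"):
    lines = ["##gff-version 3"]
    for p in sorted(predictions, key=lambda s: (s.taxon, s.start, s.factor)):
        attrs = f"Factor={p.factor}"
        if p.event:
            attrs += f";Event={p.event}"
        lines.append(
            "\t".join([
                p.taxon, source, "TF_binding_site",
                str(p.start + 1), str(p.end), ".", p.strand, ".", attrs,
            ])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list:
    preds = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
        taxon, _, _, start, end, _, strand, _, attrs = fields
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        preds.append(SitePrediction(
            taxon=taxon,
            factor=attr_map.get("Factor", "unknown"),
            strand=strand,
            start=int(start) - 1,
            end=int(end),
            event=attr_map.get("Event"),
        ))
    return preds


def write_bed6(predictions, path):
    lines = []
    for p in sorted(predictions, key=lambda s: (s.taxon, s.start, s.factor)):
        lines.append("\t".join([
            p.taxon, str(p.start), str(p.end), p.factor, "0", p.strand,
        ]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def predictions_to_frame(predictions) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": p.taxon, "factor": p.factor, "strand": p.strand,
                "start": p.start, "end": p.end, "event": p.event or "",
            }
            for p in sorted(predictions,
                            key=lambda s: (s.taxon, s.start, s.factor))
        ],
        columns=["taxon", "factor", "strand", "start", "end", "event"],
    )


def write_outputs(alignment: MultipleAlignment, predictions, prefix):
    """Aligned multi-FASTA + GFF3 + TSV under a shared path prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_alignment_fasta(alignment, f"{prefix}.aln.fasta")
    write_gff3(predictions, f"{prefix}.sites.gff3")
    predictions_to_frame(predictions).to_csv(
        f"{prefix}.sites.tsv", sep="\t", index=False
    )
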