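"""Multiple sequence alignment handling and Ballesteros–Weinstein labelling.

Alignment columns are addressed by Ballesteros–Weinstein (BW) labels:
``h.xx`` with helix h ∈ 1..8 and xx the offset around the most conserved
position x.50, extended with ``Lp2.xx`` for the second extracellular loop
(ECL2), where Lp2.50 is the conserved cysteine disulfide-bonded to 3.25.
The mapping from 0-based alignment columns to labels is an input artifact
(a two-column TSV), not derived from conservation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from .errors import AlignmentFormatError, PositionMapError, ValidationError

GAP = "-"

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

_VALID_SYMBOLS = frozenset(AMINO_ACIDS) | {GAP}

_HELIX_LABEL = re.compile(r"^[1-8]\.\d{2}$")
_LOOP_LABEL = re.compile(r"^Lp2\.\d{2}$")


def read_alignment(file, format: str | None = None) -> dict:
    """Read a FASTA or Stockholm alignment into ``{id: sequence}``.

    Sequences are upper-cased and ``.`` gaps normalized to ``-``. Raises
    :class:`AlignmentFormatError` on ragged or empty input and
    :class:`ValidationError` on symbols outside the 20 amino acids + gap.
    """
    path = Path(file)
    if format is None:
        format = "stockholm" if path.suffix.lower() in {".sto", ".stk"} else "fasta"
    if format not in {"fasta", "stockholm"}:
        raise AlignmentFormatError(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot read alignment {path}: {exc}") from exc
    records = {}
    width = aln.get_alignment_length()
    for rec in aln:
        seq = str(rec.seq).upper().replace(".", GAP)
        if len(seq) != width:
            raise AlignmentFormatError(
                f"record {rec.id!r}: length {len(seq)} != alignment width {width}"
            )
        bad = set(seq) - _VALID_SYMBOLS
        if bad:
            raise ValidationError(
                f"record {rec.id!r}: illegal symbols {sorted(bad)} "
                "(expected the 20 amino acids or a gap)"
            )
        if rec.id in records:
            raise ValidationError(f"duplicate sequence identifier {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise AlignmentFormatError(f"alignment {path} contains no sequences")
    return records


@dataclass
class PositionMap:
    """0-based alignment column index → BW label."""

    entries: dict

    def __post_init__(self):
        labels = list(self.entries.values())
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise PositionMapError(f"duplicate BW label(s) {dupes}")
        for col, label in self.entries.items():
            if not isinstance(col, (int, np.integer)) or col < 0:
                raise PositionMapError(f"column index {col!r} is not a non-negative integer")
            if not (_HELIX_LABEL.match(label) or _LOOP_LABEL.match(label)):
                raise PositionMapError(
                    f"label {label!r} matches neither h.xx (h in 1..8) nor Lp2.xx"
                )


def read_position_map(file) -> PositionMap:
    """Read a position-map TSV with columns ``column_index`` and ``bw_label``."""
    df = pd.read_csv(file, sep="\t", dtype=str)
    for col in ("column_index", "bw_label"):
        if col not in df.columns:
            raise PositionMapError(f"position map missing column {col!r}")
    entries = {int(r.column_index): str(r.bw_label) for r in df.itertuples()}
    if len(entries) != len(df):
        raise PositionMapError("duplicate column_index in position map")
    return PositionMap(entries)


@dataclass
class AlignmentPositionTable:
    """Residue symbols for each (receptor, BW-labelled position).

    ``matrix[i, j]`` is the residue of ``receptor_ids[i]`` at ``labels[j]``.
    """

    receptor_ids: list
    labels: list
    matrix: np.ndarray  # dtype '<U1', shape (n_receptors, n_labels)

    def __post_init__(self):
        self._row = {r: i for i, r in enumerate(self.receptor_ids)}
        self._col = {l: j for j, l in enumerate(self.labels)}

    def column(self, label: str) -> np.ndarray:
        """Residue vector (one symbol per receptor) at a BW position."""
        if label not in self._col:
            raise KeyError(f"unknown BW position {label!r}")
        return self.matrix[:, self._col[label]]

    def receptor_rows(self, receptor_ids) -> np.ndarray:
        """Row indices for a sequence of receptor IDs (validates presence)."""
        try:
            return np.array([self._row[r] for r in receptor_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"receptor {exc.args[0]!r} absent from alignment") from exc


def label_positions(alignment: dict, position_map: PositionMap) -> AlignmentPositionTable:
    """Retain exactly the mapped columns of an alignment, keyed by BW label."""
    ids = list(alignment)
    width = len(next(iter(alignment.values())))
    cols = sorted(position_map.entries)
    for c in cols:
        if c >= width:
            raise PositionMapError(f"column index {c} out of range for width-{width} alignment")
    labels = [position_map.entries[c] for c in cols]
    seq_matrix = np.array([list(alignment[i]) for i in ids], dtype="<U1")
    return AlignmentPositionTable(ids, labels, seq_matrix[:, cols])


def residue_observations(
    table: AlignmentPositionTable,
    position: str,
    subset,
    gap_policy: str = "drop",
):
    """Per-pair residue symbols at a position for an analysis subset.

    A receptor's residue repeats once per ligand it contributes to the
    subset, so the vector is one observation per receptor–ligand pair.
    Under ``gap_policy='drop'`` pairs whose receptor is gapped at the
    position are removed; ``'keep'`` retains the gap as a 21st symbol.

    Returns ``(symbols, n_dropped)``.
    """
    if gap_policy not in {"drop", "keep"}:
        raise ValidationError(f"unknown gap policy {gap_policy!r}")
    col = table.column(position)
    rows = table.receptor_rows([p.receptor_id for p in subset.pairs])
    symbols = col[rows]
    if gap_policy == "drop":
        kept = symbols[symbols != GAP]
        return kept, len(symbols) - len(kept)
    return symbols, 0
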