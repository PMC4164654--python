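"""Lysine-centered peptide windows.

Proteins carrying experimentally annotated modified lysines (sumoylation or
acetylation) are loaded from a FASTA file plus a site table, and a 21-residue
window is cut around every annotated lysine: 10 residues upstream, the lysine
itself at slot 11, and 10 residues downstream.  Positions that fall outside
the protein are BLANK slots; downstream encoders map BLANK to all-zero
features.  Windows centered on a sumoylated lysine are the positive class,
acetylated lysines the negative class.

Because acetylation sites vastly outnumber sumoylation sites, the negative
windows can be split into equally sized, non-overlapping random parts, each of
which is paired with the full positive set to form a balanced-enough dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

#: Distinguished slot state for positions outside the protein (not a residue).
BLANK = "-"

WINDOW_SIZE = 21
#: 1-based slot number of the central lysine.
CENTER_SLOT = 11
FLANK = 10

SUMOYLATION = "sumoylation"
ACETYLATION = "acetylation"
MOD_TYPES = (SUMOYLATION, ACETYLATION)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class ProteinRecord:
    """A protein sequence with its annotated modified-lysine sites.

    ``sites`` holds ``(position, mod_type)`` pairs with 1-based positions;
    every annotated position must carry a lysine.
    """

    id: str
    sequence: str
    sites: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideWindow:
    """A 21-slot window centered on a modified lysine.

    Slot ``i`` (1-based, 1..21) maps to sequence position
    ``center_pos + (i - 11)``; out-of-range slots hold :data:`BLANK`.
    """

    protein_id: str
    center_pos: int
    slots: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        if len(self.slots) != WINDOW_SIZE:
            raise ValueError(f"expected {WINDOW_SIZE} slots, got {len(self.slots)}")
        if self.slots[CENTER_SLOT - 1] != "K":
            raise ValueError("center slot must hold a lysine")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown label {self.label!r}")

    def slot_position(self, slot: int) -> int:
        """Sequence position (1-based) mapped to 1-based ``slot``."""
        return self.center_pos + (slot - CENTER_SLOT)

    def is_blank(self, slot: int) -> bool:
        return self.slots[slot - 1] == BLANK


@dataclass
class DatasetPartition:
    """All positive windows bundled with one part of the negatives."""

    name: str
    positives: list[PeptideWindow]
    negatives: list[PeptideWindow]

    @property
    def windows(self) -> list[PeptideWindow]:
        return list(self.positives) + list(self.negatives)


def load_annotations(
    fasta_source: Union[str, Path],
    site_table_source: Union[str, Path],
) -> list[ProteinRecord]:
    """Load proteins and their modification-site annotations.

    ``site_table_source`` is a TSV with header columns ``protein_id``,
    ``position`` (1-based) and ``mod_type`` (``sumoylation`` or
    ``acetylation``).  Proteins whose sequence contains letters outside the
    20 standard amino acids are dropped with a warning (their annotations are
    discarded with them).  Annotations referencing an unknown protein, an
    out-of-range position, or a non-lysine residue raise ``ValueError``.
    Proteins without annotations are retained; they simply yield no windows.
    """
    sequences: dict[str, str] = {}
    dropped: set[str] = set()
    for rec in SeqIO.parse(str(fasta_source), "fasta"):
        seq = str(rec.seq).upper()
        if not set(seq) <= _STANDARD_SET:
            bad = sorted(set(seq) - _STANDARD_SET)
            logger.warning(
                "dropping protein %s: non-standard residues %s", rec.id, "".join(bad)
            )
            dropped.add(rec.id)
            continue
        sequences[rec.id] = seq

    table = pd.read_csv(site_table_source, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "mod_type"}
    if not required <= set(table.columns):
        raise ValueError(f"site table must have columns {sorted(required)}")

    sites: dict[str, list[tuple[int, str]]] = {pid: [] for pid in sequences}
    for row in table.itertuples(index=False):
        pid = str(row.protein_id)
        if pid in dropped:
            logger.warning("ignoring site on dropped protein %s", pid)
            continue
        if pid not in sequences:
            raise ValueError(f"site annotation references unknown protein id {pid!r}")
        pos = int(row.position)
        mod = str(row.mod_type)
        if mod not in MOD_TYPES:
            raise ValueError(f"unknown modification type {mod!r} on protein {pid}")
        seq = sequences[pid]
        if not 1 <= pos <= len(seq):
            raise ValueError(
                f"site position {pos} out of range for protein {pid} (length {len(seq)})"
            )
        if seq[pos - 1] != "K":
            raise ValueError(
                f"annotated position {pos} of protein {pid} holds "
                f"{seq[pos - 1]!r}, expected 'K'"
            )
        sites[pid].append((pos, mod))

    return [ProteinRecord(pid, seq, sites[pid]) for pid, seq in sequences.items()]


def extract_windows(record: ProteinRecord) -> list[PeptideWindow]:
    """Cut one 21-residue window per annotated site of ``record``.

    Windows that extend past either terminus are padded with BLANK slots.
    """
    seq = record.sequence
    n = len(seq)
    windows = []
    for pos, mod in record.sites:
        slots = tuple(
            seq[p - 1] if 1 <= p <= n else BLANK
            for p in range(pos - FLANK, pos + FLANK + 1)
        )
        label = POSITIVE if mod == SUMOYLATION else NEGATIVE
        windows.append(PeptideWindow(record.id, pos, slots, label))
    return windows


def extract_all_windows(records: Iterable[ProteinRecord]) -> list[PeptideWindow]:
    out: list[PeptideWindow] = []
    for rec in records:
        out.extend(extract_windows(rec))
    return out


def split_negatives(
    windows: Sequence[PeptideWindow],
    n_parts: int = 3,
    seed: int = 0,
) -> list[DatasetPartition]:
    """Randomly split the negative windows into ``n_parts`` disjoint parts.

    Each partition bundles ALL positive windows with one part of the
    negatives.  Part sizes differ by at most one; when the negatives do not
    divide evenly, the later parts receive the extra windows (2780 negatives
    in 3 parts gives 926/927/927).  The assignment is a seeded uniform random
    permutation, so the same seed reproduces the same split.
    """
    if n_parts < 2:
        raise ValueError("n_parts must be at least 2")
    positives = [w for w in windows if w.label == POSITIVE]
    negatives = [w for w in windows if w.label == NEGATIVE]
    if len(negatives) < n_parts:
        raise ValueError(
            f"cannot split {len(negatives)} negatives into {n_parts} parts"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(negatives))
    base, rem = divmod(len(negatives), n_parts)
    sizes = [base + (1 if i >= n_parts - rem else 0) for i in range(n_parts)]
    parts: list[DatasetPartition] = []
    start = 0
    for i, size in enumerate(sizes):
        idx = order[start : start + size]
        parts.append(
            DatasetPartition(
                name=f"dataset{i + 1}",
                positives=list(positives),
                negatives=[negatives[j] for j in idx],
            )
        )
        start += size
    return parts


# ---------------------------------------------------------------------------
# TSV round-trip for windows

_SLOT_COLS = [f"slot{i}" for i in range(1, WINDOW_SIZE + 1)]


def windows_to_frame(windows: Sequence[PeptideWindow]) -> pd.DataFrame:
    rows = [
        {"protein_id": w.protein_id, "center_pos": w.center_pos, "label": w.label}
        | dict(zip(_SLOT_COLS, w.slots))
        for w in windows
    ]
    return pd.DataFrame(rows, columns=["protein_id", "center_pos", "label"] + _SLOT_COLS)


def write_windows_tsv(windows: Sequence[PeptideWindow], path: Union[str, Path]) -> None:
    windows_to_frame(windows).to_csv(path, sep="\t", index=False)


def read_windows_tsv(path: Union[str, Path]) -> list[PeptideWindow]:
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return [
        PeptideWindow(
            protein_id=str(row.protein_id),
            center_pos=int(row.center_pos),
            slots=tuple(getattr(row, c) for c in _SLOT_COLS),
            label=str(row.label),
        )
        for row in frame.itertuples(index=False)
    ]
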