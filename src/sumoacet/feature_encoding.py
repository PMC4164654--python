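"""646-dimensional encoding of 21-residue peptide windows.

Five feature blocks are concatenated per window:

=====================  =====  ==================================================
block                  size   per-slot content
=====================  =====  ==================================================
PSSM                   420    20 profile conservation scores per slot (21 x 20)
AAFactor               100    5 Atchley factors per flanking slot (20 x 5; the
                              central lysine is skipped — it is always K)
SecondaryStructure      63    one-hot (helix, strand, other) per slot
SolventAccessibility    42    one-hot (buried, exposed) per slot
Disorder                21    one disorder score per slot
=====================  =====  ==================================================

BLANK slots (window positions outside the protein) contribute zeros in every
block.  Per-residue provider tables — a PSI-BLAST-style PSSM, 3-state
secondary-structure strings, 2-state solvent-accessibility strings and
per-residue disorder scores — are consumed as given, with no rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .peptide_windows import (
    BLANK,
    CENTER_SLOT,
    NEGATIVE,
    POSITIVE,
    STANDARD_AA,
    WINDOW_SIZE,
    PeptideWindow,
)

# Block names
PSSM = "PSSM"
AA_FACTOR = "AAFactor"
SECONDARY_STRUCTURE = "SecondaryStructure"
SOLVENT_ACCESSIBILITY = "SolventAccessibility"
DISORDER = "Disorder"

BLOCKS = (PSSM, AA_FACTOR, SECONDARY_STRUCTURE, SOLVENT_ACCESSIBILITY, DISORDER)
BLOCK_SIZES = {PSSM: 420, AA_FACTOR: 100, SECONDARY_STRUCTURE: 63,
               SOLVENT_ACCESSIBILITY: 42, DISORDER: 21}
TOTAL_FEATURES = 646

FACTOR_NAMES = (
    "polarity",
    "secondary_structure",
    "molecular_volume",
    "codon_diversity",
    "electrostatic_charge",
)

SS_STATES = "HEO"  # helix, strand, other
SS_SUBTYPES = ("helix", "strand", "other")
SA_STATES = "BX"  # buried, exposed
SA_SUBTYPES = ("buried", "exposed")

# Atchley's five-factor solution for the 20 amino acids (multivariate summary
# of the AAindex property database).  Column order follows FACTOR_NAMES:
# factor I  — polarity / hydrophobicity
# factor II — secondary-structure propensity
# factor III — molecular volume / size
# factor IV — codon diversity / composition
# factor V  — electrostatic charge
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one feature column: block, window slot, and subtype.

    ``subtype`` is an amino-acid letter for PSSM columns, a factor name for
    AAFactor, a structural state for SecondaryStructure /
    SolventAccessibility, and ``"score"`` for Disorder.  ``index`` is the
    column's position in the assembled 646-vector.
    """

    block: str
    site: int
    subtype: str
    index: int

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity used to compare descriptors across datasets."""
        return (self.block, self.site, self.subtype)

    @property
    def name(self) -> str:
        return f"{self.block}.s{self.site:02d}.{self.subtype}"


@lru_cache(maxsize=1)
def descriptor_table() -> tuple[FeatureDescriptor, ...]:
    """The canonical, fixed ordering of all 646 feature columns.

    Blocks appear in the order PSSM, AAFactor, SecondaryStructure,
    SolventAccessibility, Disorder; within a block slots run 1..21 (AAFactor
    skips slot 11) and within a slot the subtypes follow the documented fixed
    order (alphabetical one-letter amino acids for PSSM).
    """
    descs: list[FeatureDescriptor] = []
    idx = 0
    for site in range(1, WINDOW_SIZE + 1):
        for aa in STANDARD_AA:
            descs.append(FeatureDescriptor(PSSM, site, aa, idx))
            idx += 1
    for site in range(1, WINDOW_SIZE + 1):
        if site == CENTER_SLOT:
            continue
        for factor in FACTOR_NAMES:
            descs.append(FeatureDescriptor(AA_FACTOR, site, factor, idx))
            idx += 1
    for site in range(1, WINDOW_SIZE + 1):
        for sub in SS_SUBTYPES:
            descs.append(FeatureDescriptor(SECONDARY_STRUCTURE, site, sub, idx))
            idx += 1
    for site in range(1, WINDOW_SIZE + 1):
        for sub in SA_SUBTYPES:
            descs.append(FeatureDescriptor(SOLVENT_ACCESSIBILITY, site, sub, idx))
            idx += 1
    for site in range(1, WINDOW_SIZE + 1):
        descs.append(FeatureDescriptor(DISORDER, site, "score", idx))
        idx += 1
    assert idx == TOTAL_FEATURES
    return tuple(descs)


def descriptor_frame() -> pd.DataFrame:
    """Descriptor table as a DataFrame (index, block, site, subtype)."""
    return pd.DataFrame(
        [
            {"index": d.index, "block": d.block, "site": d.site, "subtype": d.subtype}
            for d in descriptor_table()
        ]
    )


@dataclass
class ProviderBundle:
    """Per-residue provider outputs for one protein.

    ``pssm`` has one row per residue and 20 columns in alphabetical
    amino-acid order; ``ss`` is a string over {H, E, O}; ``sa`` a string over
    {B, X}; ``disorder`` one score in [0, 1] per residue.
    """

    pssm: np.ndarray
    ss: str
    sa: str
    disorder: np.ndarray

    def validate(self, protein_id: str, length: int) -> None:
        if self.pssm.shape != (length, 20):
            raise ValueError(
                f"PSSM for {protein_id} has shape {self.pssm.shape}, "
                f"expected ({length}, 20)"
            )
        for name, n in (("ss", len(self.ss)), ("sa", len(self.sa)),
                        ("disorder", len(self.disorder))):
            if n != length:
                raise ValueError(
                    f"{name} provider for {protein_id} has length {n}, "
                    f"expected {length}"
                )


def _slot_positions(window: PeptideWindow):
    """Yield (0-based slot, 1-based sequence position, is_blank)."""
    for i in range(WINDOW_SIZE):
        pos = window.center_pos + (i + 1 - CENTER_SLOT)
        yield i, pos, window.slots[i] == BLANK


def _check_provider_cover(window: PeptideWindow, length: int, kind: str) -> None:
    for _, pos, blank in _slot_positions(window):
        if not blank and not 1 <= pos <= length:
            raise ValueError(
                f"{kind} provider for {window.protein_id} has {length} rows "
                f"but window at {window.center_pos} needs position {pos}"
            )


def encode_pssm(window: PeptideWindow, providers: ProviderBundle) -> np.ndarray:
    """420 conservation scores: slot-major, 20 alphabetical columns per slot."""
    _check_provider_cover(window, providers.pssm.shape[0], "PSSM")
    out = np.zeros((WINDOW_SIZE, 20))
    for i, pos, blank in _slot_positions(window):
        if not blank:
            out[i] = providers.pssm[pos - 1]
    return out.ravel()


def encode_aafactors(
    window: PeptideWindow,
    factor_table: Mapping[str, Sequence[float]] = ATCHLEY_FACTORS,
) -> np.ndarray:
    """100 Atchley-factor values for the 20 flanking slots.

    The central slot is skipped (always lysine, so it carries no
    information); each remaining slot contributes its residue's five factor
    values in the order of :data:`FACTOR_NAMES`.  BLANK slots give zeros.
    """
    out = np.zeros((WINDOW_SIZE - 1, 5))
    j = 0
    for i in range(WINDOW_SIZE):
        if i + 1 == CENTER_SLOT:
            continue
        aa = window.slots[i]
        if aa != BLANK:
            if aa not in factor_table:
                raise ValueError(f"no factor values for residue {aa!r}")
            out[j] = factor_table[aa]
        j += 1
    return out.ravel()


def encode_secondary_structure(
    window: PeptideWindow, providers: ProviderBundle
) -> np.ndarray:
    """63 one-hot values: (helix, strand, other) per slot; BLANK -> zeros."""
    _check_provider_cover(window, len(providers.ss), "secondary-structure")
    out = np.zeros((WINDOW_SIZE, 3))
    for i, pos, blank in _slot_positions(window):
        if blank:
            continue
        state = providers.ss[pos - 1]
        try:
            out[i, SS_STATES.index(state)] = 1.0
        except ValueError:
            raise ValueError(
                f"unknown secondary-structure state {state!r} at position "
                f"{pos} of {window.protein_id} (expected one of H/E/O)"
            ) from None
    return out.ravel()


def encode_solvent_accessibility(
    window: PeptideWindow, providers: ProviderBundle
) -> np.ndarray:
    """42 one-hot values: (buried, exposed) per slot; BLANK -> zeros."""
    _check_provider_cover(window, len(providers.sa), "solvent-accessibility")
    out = np.zeros((WINDOW_SIZE, 2))
    for i, pos, blank in _slot_positions(window):
        if blank:
            continue
        state = providers.sa[pos - 1]
        try:
            out[i, SA_STATES.index(state)] = 1.0
        except ValueError:
            raise ValueError(
                f"unknown solvent-accessibility state {state!r} at position "
                f"{pos} of {window.protein_id} (expected B or X)"
            ) from None
    return out.ravel()


def encode_disorder(window: PeptideWindow, providers: ProviderBundle) -> np.ndarray:
    """21 per-residue disorder scores; BLANK -> 0."""
    _check_provider_cover(window, len(providers.disorder), "disorder")
    out = np.zeros(WINDOW_SIZE)
    for i, pos, blank in _slot_positions(window):
        if not blank:
            out[i] = providers.disorder[pos - 1]
    return out


def assemble_features(
    window: PeptideWindow,
    providers: ProviderBundle,
    factor_table: Mapping[str, Sequence[float]] = ATCHLEY_FACTORS,
) -> np.ndarray:
    """Concatenate the five blocks into the 646-vector of the canonical order."""
    return np.concatenate(
        [
            encode_pssm(window, providers),
            encode_aafactors(window, factor_table),
            encode_secondary_structure(window, providers),
            encode_solvent_accessibility(window, providers),
            encode_disorder(window, providers),
        ]
    )


def encode_windows(
    windows: Sequence[PeptideWindow],
    providers: Mapping[str, ProviderBundle],
    factor_table: Mapping[str, Sequence[float]] = ATCHLEY_FACTORS,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode windows into an (n, 646) matrix and a 0/1 label vector.

    Labels are 1 for positive (sumoylation) and 0 for negative (acetylation).
    """
    X = np.empty((len(windows), TOTAL_FEATURES))
    y = np.empty(len(windows), dtype=int)
    for i, w in enumerate(windows):
        if w.protein_id not in providers:
            raise KeyError(f"no provider bundle for protein {w.protein_id}")
        X[i] = assemble_features(w, providers[w.protein_id], factor_table)
        y[i] = 1 if w.label == POSITIVE else 0
    return X, y


# ---------------------------------------------------------------------------
# Provider-table readers

_PSSM_AA_COLS = list(STANDARD_AA)


def read_pssm_tsv(path: Union[str, Path]) -> dict[str, np.ndarray]:
    """Read the plain PSSM dialect: protein_id, position, 20 alphabetical columns."""
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out: dict[str, np.ndarray] = {}
    for pid, grp in frame.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        if not np.array_equal(positions, np.arange(1, len(grp) + 1)):
            raise ValueError(f"PSSM rows for {pid} are not contiguous from 1")
        out[str(pid)] = grp[_PSSM_AA_COLS].to_numpy(dtype=float)
    return out


def read_pssm_psiblast(path: Union[str, Path]) -> np.ndarray:
    """Parse one PSI-BLAST ASCII matrix dump into an (L, 20) array.

    Only the first 20 numeric columns (the log-odds block) are used; columns
    are reordered from the file's header order (classically
    A R N D C Q E G H I L K M F P S T W Y V) into alphabetical order.
    """
    header_order: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            if header_order is None and all(t in _STANDARD_SET_LIST for t in tokens):
                if len(tokens) >= 20:
                    header_order = tokens[:20]
                continue
            if tokens[0].lstrip("-").isdigit() and len(tokens) >= 22:
                rows.append([float(v) for v in tokens[2:22]])
    if header_order is None or not rows:
        raise ValueError(f"{path} does not look like a PSI-BLAST matrix dump")
    mat = np.asarray(rows, dtype=float)
    order = [header_order.index(aa) for aa in STANDARD_AA]
    return mat[:, order]


_STANDARD_SET_LIST = set(STANDARD_AA)


def read_state_strings_tsv(path: Union[str, Path], column: str) -> dict[str, str]:
    """Read per-protein state strings (TSV: protein_id, <column>)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return {str(r.protein_id): str(getattr(r, column)) for r in frame.itertuples(index=False)}


def read_disorder_tsv(path: Union[str, Path]) -> dict[str, np.ndarray]:
    """Read per-residue disorder scores (TSV: protein_id, position, score)."""
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out: dict[str, np.ndarray] = {}
    for pid, grp in frame.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        out[str(pid)] = grp["score"].to_numpy(dtype=float)
    return out


def load_providers(
    pssm_path: Union[str, Path],
    ss_path: Union[str, Path],
    sa_path: Union[str, Path],
    disorder_path: Union[str, Path],
) -> dict[str, ProviderBundle]:
    """Assemble ProviderBundles from the four provider TSV files."""
    pssm = read_pssm_tsv(pssm_path)
    ss = read_state_strings_tsv(ss_path, "ss")
    sa = read_state_strings_tsv(sa_path, "sa")
    disorder = read_disorder_tsv(disorder_path)
    bundles: dict[str, ProviderBundle] = {}
    for pid in pssm:
        if pid not in ss or pid not in sa or pid not in disorder:
            raise ValueError(f"protein {pid} missing from one of the provider tables")
        bundles[pid] = ProviderBundle(pssm[pid], ss[pid], sa[pid], disorder[pid])
    return bundles


def write_providers(
    providers: Mapping[str, ProviderBundle],
    pssm_path: Union[str, Path],
    ss_path: Union[str, Path],
    sa_path: Union[str, Path],
    disorder_path: Union[str, Path],
) -> None:
    """Write provider bundles in the TSV dialects read by :func:`load_providers`."""
    pssm_rows = []
    dis_rows = []
    ss_rows = []
    sa_rows = []
    for pid, b in providers.items():
        for i in range(b.pssm.shape[0]):
            pssm_rows.append([pid, i + 1, *b.pssm[i]])
            dis_rows.append([pid, i + 1, b.disorder[i]])
        ss_rows.append([pid, b.ss])
        sa_rows.append([pid, b.sa])
    pd.DataFrame(pssm_rows, columns=["protein_id", "position"] + _PSSM_AA_COLS).to_csv(
        pssm_path, sep="\t", index=False, float_format="%.4f"
    )
    pd.DataFrame(ss_rows, columns=["protein_id", "ss"]).to_csv(ss_path, sep="\t", index=False)
    pd.DataFrame(sa_rows, columns=["protein_id", "sa"]).to_csv(sa_path, sep="\t", index=False)
    pd.DataFrame(dis_rows, columns=["protein_id", "position", "score"]).to_csv(
        disorder_path, sep="\t", index=False, float_format="%.4f"
    )


def features_to_frame(
    windows: Sequence[PeptideWindow], X: np.ndarray
) -> pd.DataFrame:
    """Feature matrix as a DataFrame keyed by window identity, for TSV export."""
    cols = [d.name for d in descriptor_table()]
    frame = pd.DataFrame(X, columns=cols)
    frame.insert(0, "protein_id", [w.protein_id for w in windows])
    frame.insert(1, "center_pos", [w.center_pos for w in windows])
    frame.insert(2, "label", [w.label for w in windows])
    return frame


def read_features_tsv(path: Union[str, Path]) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Read a features TSV back into (metadata frame, X, y)."""
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    cols = [d.name for d in descriptor_table()]
    X = frame[cols].to_numpy(dtype=float)
    y = (frame["label"] == POSITIVE).to_numpy(dtype=int)
    return frame[["protein_id", "center_pos", "label"]], X, y
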