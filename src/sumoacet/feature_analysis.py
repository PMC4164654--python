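"""Analysis of optimal feature sets and positional residue frequencies.

The per-dataset optimal feature sets are merged (duplicates removed, with
per-dataset provenance kept), then summarized three ways: counts per feature
block, counts per window site cross-tabulated by block, and counts per
subtype within a block.  Separately, per-class 21 x 20 positional
amino-acid frequency matrices are computed from the raw windows — the matrix
behind a sequence logo.  BLANK slots are excluded from both numerator and
denominator, so each row is the residue distribution among windows that
actually cover that site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import pandas as pd

from .feature_encoding import (
    BLOCK_SIZES,
    BLOCKS,
    FACTOR_NAMES,
    SA_SUBTYPES,
    SS_SUBTYPES,
    AA_FACTOR,
    DISORDER,
    PSSM,
    SECONDARY_STRUCTURE,
    SOLVENT_ACCESSIBILITY,
)
from .peptide_windows import (
    BLANK,
    STANDARD_AA,
    WINDOW_SIZE,
    PeptideWindow,
)

_KEY_COLS = ["block", "site", "subtype"]

_BLOCK_SUBTYPES = {
    PSSM: tuple(STANDARD_AA),
    AA_FACTOR: FACTOR_NAMES,
    SECONDARY_STRUCTURE: SS_SUBTYPES,
    SOLVENT_ACCESSIBILITY: SA_SUBTYPES,
    DISORDER: ("score",),
}


@dataclass
class CombinedOptimalSet:
    """Deduplicated union of optimal feature sets with provenance.

    ``frame`` has one row per distinct (block, site, subtype) triple and a
    ``provenance`` column listing the dataset names that selected it
    (comma-joined, in input order).
    """

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)


def _as_key_frame(feature_set) -> pd.DataFrame:
    """Accept a DataFrame with block/site/subtype columns or a descriptor list."""
    if isinstance(feature_set, pd.DataFrame):
        return feature_set[_KEY_COLS].copy()
    rows = []
    for d in feature_set:
        if isinstance(d, tuple):
            rows.append(dict(zip(_KEY_COLS, d)))
        else:
            rows.append({"block": d.block, "site": d.site, "subtype": d.subtype})
    return pd.DataFrame(rows, columns=_KEY_COLS)


def combine_optimal_sets(
    sets: Sequence,
    names: Sequence[str] | None = None,
) -> CombinedOptimalSet:
    """Union the per-dataset optimal sets, excluding duplicate features.

    Features are identified by (block, site, subtype), not by their rank or
    column index, so sets derived from different datasets' mRMR tables merge
    correctly.  First-seen order is preserved.
    """
    if names is None:
        names = [f"dataset{i + 1}" for i in range(len(sets))]
    seen: dict[tuple, list[str]] = {}
    order: list[tuple] = []
    for name, fs in zip(names, sets):
        frame = _as_key_frame(fs)
        for row in frame.itertuples(index=False):
            key = (str(row.block), int(row.site), str(row.subtype))
            if key not in seen:
                seen[key] = []
                order.append(key)
            if name not in seen[key]:
                seen[key].append(name)
    out = pd.DataFrame(order, columns=_KEY_COLS)
    out["provenance"] = [",".join(seen[k]) for k in order]
    return CombinedOptimalSet(frame=out)


def block_distribution(combined: CombinedOptimalSet) -> pd.DataFrame:
    """Selected-feature counts per block, with each block's total and fraction."""
    counts = combined.frame["block"].value_counts()
    rows = []
    for block in BLOCKS:
        n = int(counts.get(block, 0))
        rows.append(
            {
                "block": block,
                "selected": n,
                "block_total": BLOCK_SIZES[block],
                "fraction_of_block": n / BLOCK_SIZES[block],
            }
        )
    return pd.DataFrame(rows)


def site_distribution(combined: CombinedOptimalSet) -> pd.DataFrame:
    """Selected-feature counts per window site (rows 1..21) by block (columns)."""
    table = pd.DataFrame(0, index=range(1, WINDOW_SIZE + 1), columns=list(BLOCKS))
    for row in combined.frame.itertuples(index=False):
        table.loc[int(row.site), str(row.block)] += 1
    table.index.name = "site"
    return table


def subtype_distribution(combined: CombinedOptimalSet, block: str) -> pd.DataFrame:
    """Selected-feature counts per subtype of one block (zeros included)."""
    if block not in BLOCKS:
        raise ValueError(f"unknown block {block!r}")
    sub = combined.frame[combined.frame["block"] == block]
    counts = sub["subtype"].value_counts()
    return pd.DataFrame(
        {
            "subtype": list(_BLOCK_SUBTYPES[block]),
            "selected": [int(counts.get(s, 0)) for s in _BLOCK_SUBTYPES[block]],
        }
    )


def position_frequency_matrix(
    windows: Sequence[PeptideWindow], label: str
) -> pd.DataFrame:
    """Per-site residue frequencies over all windows of one class.

    Rows are window sites 1..21, columns the 20 amino acids (alphabetical).
    BLANK slots are excluded from the counts, so every row with at least one
    covering window sums to 1; site 11 is 1.0 at K by construction.
    """
    selected = [w for w in windows if w.label == label]
    if not selected:
        raise ValueError(f"no windows with label {label!r}")
    counts = pd.DataFrame(
        0.0, index=range(1, WINDOW_SIZE + 1), columns=list(STANDARD_AA)
    )
    for w in selected:
        for i, aa in enumerate(w.slots):
            if aa != BLANK:
                counts.loc[i + 1, aa] += 1
    totals = counts.sum(axis=1)
    freq = counts.div(totals.where(totals > 0, 1.0), axis=0)
    freq.index.name = "site"
    return freq


def write_analysis(
    combined: CombinedOptimalSet,
    outdir: Union[str, "Path"],
    windows: Sequence[PeptideWindow] | None = None,
) -> None:
    """Write the combined set and all summary tables as TSVs under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    combined.frame.to_csv(outdir / "combined_optimal_features.tsv", sep="\t", index=False)
    block_distribution(combined).to_csv(outdir / "block_distribution.tsv", sep="\t", index=False)
    site_distribution(combined).to_csv(outdir / "site_distribution.tsv", sep="\t")
    for block in BLOCKS:
        subtype_distribution(combined, block).to_csv(
            outdir / f"subtype_distribution_{block}.tsv", sep="\t", index=False
        )
    if windows is not None:
        from .peptide_windows import NEGATIVE, POSITIVE

        for label in (POSITIVE, NEGATIVE):
            if any(w.label == label for w in windows):
                position_frequency_matrix(windows, label).to_csv(
                    outdir / f"position_frequencies_{label}.tsv", sep="\t",
                    float_format="%.5f",
                )
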