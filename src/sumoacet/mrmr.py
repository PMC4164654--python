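"""Maximum-Relevance Minimum-Redundancy (mRMR) feature ranking.

The difference (MID) form is used: each candidate feature f is scored by

    score(f) = I(f; class) - mean over already-selected s of I(f; s)

where I is plug-in mutual information in bits on discretized values.  Greedy
forward selection orders ALL features: the first ranked feature maximizes
relevance alone, and each later rank maximizes relevance minus mean
redundancy against the features ranked before it.  Ties go to the smaller
column index.

Continuous features are discretized into three states at mean +/- one
standard deviation; binary (e.g. one-hot) columns keep their two native
states.  The ranking is computed once on the full dataset by default, which
mirrors the classical mRMR+IFS workflow of building one ranked table per
dataset before cross-validation; callers that want leakage-free estimates can
re-rank inside each training fold (see :func:`sumoacet.ifs.ifs_curve`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .feature_encoding import FeatureDescriptor, descriptor_table


@dataclass
class DiscretizedMatrix:
    """Categorical codes per feature column plus class labels.

    ``codes`` is (n_samples, n_features) of small integer codes; ``labels``
    the class codes; ``edges`` records the (low, high) thresholds used for
    each continuous column (``None`` for columns kept in their native
    states).
    """

    codes: np.ndarray
    labels: np.ndarray
    edges: list[Optional[tuple[float, float]]] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.codes.shape[1]


def discretize(values: np.ndarray) -> np.ndarray:
    """Discretize one feature column into categorical codes.

    Columns with at most two distinct values (binary / one-hot / constant)
    keep their native states; other columns are cut into three states at
    mean +/- one standard deviation, coded -1 / 0 / +1.
    """
    values = np.asarray(values)
    uniq = np.unique(values)
    if uniq.size <= 2:
        return np.searchsorted(uniq, values).astype(np.int8)
    mu = values.mean()
    sd = values.std()
    return np.where(values < mu - sd, -1, np.where(values > mu + sd, 1, 0)).astype(np.int8)


def discretize_edges(values: np.ndarray) -> Optional[tuple[float, float]]:
    values = np.asarray(values)
    if np.unique(values).size <= 2:
        return None
    mu, sd = values.mean(), values.std()
    return (float(mu - sd), float(mu + sd))


def discretize_matrix(X: np.ndarray, labels: np.ndarray) -> DiscretizedMatrix:
    """Discretize every feature column of ``X`` (thresholds per column)."""
    X = np.asarray(X)
    codes = np.empty(X.shape, dtype=np.int8)
    edges: list[Optional[tuple[float, float]]] = []
    for j in range(X.shape[1]):
        codes[:, j] = discretize(X[:, j])
        edges.append(discretize_edges(X[:, j]))
    return DiscretizedMatrix(codes=codes, labels=np.asarray(labels), edges=edges)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information, in bits, between two categorical vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("mutual information of empty input is undefined")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    return _mi_from_codes(xi, xi.max() + 1, yi, yi.max() + 1)


def _mi_from_codes(xi: np.ndarray, nx: int, yi: np.ndarray, ny: int) -> float:
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    joint = joint / joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def mrmr_rank(
    matrix: DiscretizedMatrix,
    descriptors: Optional[Sequence[FeatureDescriptor]] = None,
) -> pd.DataFrame:
    """Order all features by greedy mRMR (difference form).

    Returns the mRMR table: one row per feature with columns ``rank``
    (1-based), ``index`` (column position in the input matrix), the
    descriptor identity (``block``, ``site``, ``subtype``) when descriptors
    are supplied, and the per-step ``relevance``, ``redundancy`` and
    ``score = relevance - redundancy``.
    """
    codes = matrix.codes
    y = matrix.labels
    n, p = codes.shape
    if p < 2:
        raise ValueError("mRMR ranking needs at least 2 features")
    if descriptors is not None and len(descriptors) != p:
        raise ValueError("descriptor list does not match feature count")

    # Pre-factorize every column once; MI then reduces to a joint bincount.
    col_codes = np.empty_like(codes, dtype=np.int64)
    arity = np.empty(p, dtype=np.int64)
    for j in range(p):
        u, inv = np.unique(codes[:, j], return_inverse=True)
        col_codes[:, j] = inv
        arity[j] = u.size
    _, yi = np.unique(y, return_inverse=True)
    ny = int(yi.max()) + 1

    relevance = np.array(
        [_mi_from_codes(col_codes[:, j], arity[j], yi, ny) for j in range(p)]
    )

    red_sum = np.zeros(p)
    unselected = np.ones(p, dtype=bool)
    rows = []
    for step in range(p):
        redundancy = red_sum / step if step else np.zeros(p)
        score = relevance - redundancy
        score[~unselected] = -np.inf
        j = int(np.argmax(score))  # argmax takes the first max: smallest index
        rows.append(
            {
                "rank": step + 1,
                "index": j,
                "relevance": relevance[j],
                "redundancy": float(redundancy[j]),
                "score": float(score[j]),
            }
        )
        unselected[j] = False
        if step < p - 1:
            xj, nj = col_codes[:, j], int(arity[j])
            for k in np.nonzero(unselected)[0]:
                red_sum[k] += _mi_from_codes(col_codes[:, k], int(arity[k]), xj, nj)

    table = pd.DataFrame(rows)
    if descriptors is not None:
        table["block"] = [descriptors[j].block for j in table["index"]]
        table["site"] = [descriptors[j].site for j in table["index"]]
        table["subtype"] = [descriptors[j].subtype for j in table["index"]]
        table = table[
            ["rank", "index", "block", "site", "subtype", "relevance", "redundancy", "score"]
        ]
    return table


def rank_features(
    X: np.ndarray,
    y: np.ndarray,
    descriptors: Optional[Sequence[FeatureDescriptor]] = None,
) -> pd.DataFrame:
    """Convenience wrapper: discretize then rank.

    When ``X`` has exactly 646 columns and no descriptors are given, the
    canonical descriptor table is attached.
    """
    if descriptors is None and X.shape[1] == len(descriptor_table()):
        descriptors = descriptor_table()
    return mrmr_rank(discretize_matrix(X, y), descriptors)


def write_mrmr_tsv(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_mrmr_tsv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
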