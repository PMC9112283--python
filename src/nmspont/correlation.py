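"""Correlation structure of spontaneous activity.

All correlations are full-recording sample Pearson coefficients of
ΔF/F0 traces at native sampling (no detrending, no lag search).  Four
views of the population structure are provided: per-pair values with a
pairing class, neighbor-averaged per-cell values (a cell against its 3-4
nearest neighbors), all-pairs synchrony within a class (the efferent
terminal measure), and within-cell apex-base compartment coupling.
"""
from __future__ import annotations

import logging
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "pearson_full",
    "neighbor_mean_r",
    "allpairs_r",
    "paired_compartment_r",
    "correlation_heatmap",
    "pairwise_table",
]

PAIRING_CLASSES = (
    "SC_SC_neighbor",
    "HC_HC_neighbor",
    "HC_SC",
    "HC_efferent",
    "bundle_presynapse",
    "terminal_pair",
)


def pearson_full(dff_a: np.ndarray, dff_b: np.ndarray) -> float:
    """Sample Pearson correlation over all frames of the recording."""
    a = np.asarray(dff_a, dtype=float)
    b = np.asarray(dff_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be 1-D and of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 frames")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a zero-variance trace")
    return float(np.corrcoef(a, b)[0, 1])


def _nearest_neighbors(
    center: np.ndarray,
    candidates: np.ndarray,
    k: int,
    rtol: float = 1e-9,
) -> np.ndarray:
    """Indices of the k nearest candidates; k+1 on a tie at the k-th rank."""
    d = np.linalg.norm(candidates - center, axis=1)
    order = np.argsort(d, kind="stable")
    kk = min(k, len(order))
    if len(order) > kk and math.isclose(
        d[order[kk]], d[order[kk - 1]], rel_tol=rtol, abs_tol=1e-12
    ):
        kk += 1
    return order[:kk]


def neighbor_mean_r(
    dffs: Mapping[str, np.ndarray],
    positions: Mapping[str, Sequence[float]],
    k: int = 3,
    candidate_dffs: Optional[Mapping[str, np.ndarray]] = None,
    candidate_positions: Optional[Mapping[str, Sequence[float]]] = None,
) -> tuple[dict[str, float], float]:
    """Neighbor-averaged Pearson R per cell, and the neuromast mean.

    For every target cell the k nearest candidate cells (Euclidean
    ROI-center distance; k+1 on a distance tie at rank k) are taken and
    the per-cell value is the mean R against them.  By default candidates
    are the other cells of ``dffs`` (same-class pairing, e.g. SC-SC);
    passing a separate candidate set gives cross-class pairings such as a
    hair cell against its surrounding supporting cells.  Cells with
    undefined correlations (zero variance) are excluded and logged.
    """
    same_class = candidate_dffs is None
    if same_class:
        candidate_dffs = dffs
        candidate_positions = positions
    if candidate_positions is None:
        raise ValueError("candidate_positions required with candidate_dffs")
    cand_ids = list(candidate_dffs)
    cand_pos = np.asarray([candidate_positions[c] for c in cand_ids], float)
    per_cell: dict[str, float] = {}
    for cid, dff in dffs.items():
        ids = cand_ids
        pos = cand_pos
        if same_class:
            keep = [i for i, c in enumerate(ids) if c != cid]
            if not keep:
                continue
            ids = [ids[i] for i in keep]
            pos = cand_pos[keep]
        if len(ids) < k:
            log.warning(
                "cell %s has only %d neighbor candidates (k=%d); using all",
                cid, len(ids), k,
            )
        center = np.asarray(positions[cid], dtype=float)
        rs = []
        for idx in _nearest_neighbors(center, pos, k):
            try:
                rs.append(pearson_full(dff, candidate_dffs[ids[idx]]))
            except ValueError:
                log.info("skipping undefined correlation %s-%s", cid, ids[idx])
        if rs:
            per_cell[cid] = float(np.mean(rs))
        else:
            log.info("cell %s has no defined neighbor correlations", cid)
    mean = float(np.mean(list(per_cell.values()))) if per_cell else float("nan")
    return per_cell, mean


def allpairs_r(
    dffs: Mapping[str, np.ndarray]
) -> tuple[float, pd.DataFrame]:
    """Mean R over all unordered pairs of one class, plus the full matrix.

    Used for efferent-terminal synchrony: every terminal against every
    other terminal in the neuromast.  The symmetric matrix (unit
    diagonal) is returned for heat-map rendering.
    """
    ids = list(dffs)
    if len(ids) < 2:
        raise ValueError("need at least 2 traces for all-pairs correlation")
    n = len(ids)
    mat = np.eye(n)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            r = pearson_full(dffs[ids[i]], dffs[ids[j]])
            mat[i, j] = mat[j, i] = r
            vals.append(r)
    return float(np.mean(vals)), pd.DataFrame(mat, index=ids, columns=ids)


def paired_compartment_r(
    bundle_dffs: Mapping[str, np.ndarray],
    presynapse_dffs: Mapping[str, np.ndarray],
) -> tuple[dict[str, float], float, float]:
    """Within-cell apex-base coupling: bundle vs presynapse R per cell.

    Returns (per-cell R, population mean, SEM).  Cells missing a
    compartment or with an undefined correlation (e.g. a silent
    presynapse) are skipped with a log entry.
    """
    per_cell: dict[str, float] = {}
    for cid, bdff in bundle_dffs.items():
        if cid not in presynapse_dffs:
            log.info("cell %s lacks a presynapse trace; skipped", cid)
            continue
        try:
            per_cell[cid] = pearson_full(bdff, presynapse_dffs[cid])
        except ValueError as e:
            log.info("cell %s skipped: %s", cid, e)
    vals = np.array(list(per_cell.values()))
    if len(vals) == 0:
        return per_cell, float("nan"), float("nan")
    sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return per_cell, float(vals.mean()), sem


def pairwise_table(
    dffs: Mapping[str, np.ndarray], pairing_class: str
) -> pd.DataFrame:
    """Tidy (roi_a, roi_b, class, R) rows over all unordered pairs."""
    ids = list(dffs)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            try:
                r = pearson_full(dffs[ids[i]], dffs[ids[j]])
            except ValueError:
                continue
            rows.append((ids[i], ids[j], pairing_class, r))
    return pd.DataFrame(rows, columns=["roi_a", "roi_b", "pairing_class", "R"])


def correlation_heatmap(matrix: pd.DataFrame, out_path) -> None:
    """Render a correlation matrix as a heat map on the fixed [-1, 1] scale."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"correlation matrix must be square, got {mat.shape}")
    labels = list(matrix.index) if isinstance(matrix, pd.DataFrame) else None
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(mat, vmin=-1.0, vmax=1.0, cmap="RdBu_r")
    if labels:
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
        ax.set_yticks(range(len(labels)), labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson R")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
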