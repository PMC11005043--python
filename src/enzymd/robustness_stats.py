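"""Trajectory-robustness protocol: chunking, chunk-vs-first ANOVA,
Hausdorff path-similarity analysis with Ward clustering, the 20-fold
shuffle retention test, and the minimum-informative-length decision rule.

These statistics ask two questions of a set of replicate trajectories:
does extending the simulation change the sampled RMSD distribution
(chunk ANOVA / path similarity), and does averaging biodescriptors over a
trajectory erase the real variability between replicates (retention test)?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .io_formats import TrajectoryData
from .trajectory_features import superpose_frames

__all__ = [
    "PathDistance",
    "chunk_trajectory",
    "anova_oneway",
    "chunk_anova_matrix",
    "hausdorff_distance",
    "psa_matrix",
    "classify_similarity",
    "retention_shuffle_test",
    "choose_min_length",
]


@dataclass(frozen=True)
class PathDistance:
    """Symmetric Hausdorff distance between two conformational paths."""

    delta_h: float
    directed_pq: float
    directed_qp: float

    def __post_init__(self) -> None:
        if self.delta_h < 0:
            raise ValueError("delta_h must be non-negative")
        assert abs(self.delta_h - max(self.directed_pq, self.directed_qp)) < 1e-9


def chunk_trajectory(
    traj: TrajectoryData, chunk_ns: float, dt_ps: float | None = None
) -> list[TrajectoryData]:
    """Split into contiguous, non-overlapping chunks of ``chunk_ns``
    nanoseconds (trailing partial chunk dropped)."""
    dt = traj.dt_ps if dt_ps is None else dt_ps
    frames_per_chunk = int(round(chunk_ns * 1000.0 / dt))
    if frames_per_chunk < 1:
        raise ValueError("chunk shorter than one frame interval")
    if frames_per_chunk > traj.n_frames:
        raise ValueError(
            f"chunk of {frames_per_chunk} frames longer than trajectory "
            f"({traj.n_frames} frames)"
        )
    n_chunks = traj.n_frames // frames_per_chunk
    return [
        TrajectoryData(
            traj.frames[c * frames_per_chunk : (c + 1) * frames_per_chunk],
            dt, traj.structure,
        )
        for c in range(n_chunks)
    ]


def anova_oneway(groups: list[np.ndarray]) -> dict[str, float]:
    """Classical one-way ANOVA; degenerate all-equal input returns
    F = 0, p = 1."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs at least two values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return {"F": 0.0, "p": 1.0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):  # zero within-group variance
        f, p = np.inf, 0.0
    return {"F": float(f), "p": float(p)}


def chunk_anova_matrix(
    series_by_variant: dict[str, list[np.ndarray]],
    frames_per_chunk: int,
    alpha: float = 0.05,
    mode: str = "pooled",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """For every variant, one-way ANOVA of each chunk's RMSD values against
    the first chunk's.

    ``mode='pooled'`` pools frames across replicates within a chunk
    (default); ``mode='replicate_means'`` compares per-replicate chunk
    means.  Returns the p-value matrix (rows: chunk 2..K) and the boolean
    significance mask at ``alpha``.
    """
    if mode not in ("pooled", "replicate_means"):
        raise ValueError(f"unknown mode {mode!r}")
    pvals: dict[str, list[float]] = {}
    n_chunks_global = None
    for variant, series_list in series_by_variant.items():
        if len(series_list) < 2:
            raise ValueError(f"variant {variant}: need >= 2 replicates")
        n_chunks = min(len(s) // frames_per_chunk for s in series_list)
        if n_chunks < 2:
            raise ValueError("need at least two full chunks")
        n_chunks_global = n_chunks if n_chunks_global is None else min(
            n_chunks_global, n_chunks)
        chunks = []
        for c in range(n_chunks):
            sl = slice(c * frames_per_chunk, (c + 1) * frames_per_chunk)
            if mode == "pooled":
                chunks.append(np.concatenate([s[sl] for s in series_list]))
            else:
                chunks.append(np.array([s[sl].mean() for s in series_list]))
        pvals[variant] = [
            anova_oneway([chunks[0], chunks[c]])["p"] for c in range(1, n_chunks)
        ]
    rows = [f"chunk{c + 2}" for c in range(n_chunks_global - 1)]
    p_df = pd.DataFrame(
        {v: p[: n_chunks_global - 1] for v, p in pvals.items()}, index=rows
    )
    return p_df, p_df < alpha


# ---------------------------------------------------------------------------
# Path similarity analysis
# ---------------------------------------------------------------------------

def _pairwise_frame_rmsd(path_p: np.ndarray, path_q: np.ndarray) -> np.ndarray:
    """(F_p, F_q) matrix of pairwise superposed RMSDs between frames."""
    if path_p.shape[1:] != path_q.shape[1:]:
        raise ValueError("paths have mismatched atom counts")
    out = np.empty((path_p.shape[0], path_q.shape[0]))
    for i in range(path_p.shape[0]):
        _, rmsd = superpose_frames(path_q, path_p[i])
        out[i] = rmsd
    return out


def hausdorff_distance(
    path_p: np.ndarray | TrajectoryData, path_q: np.ndarray | TrajectoryData
) -> PathDistance:
    """Symmetric Hausdorff distance between two paths under the
    pairwise-superposed-RMSD frame metric."""
    p = path_p.frames if isinstance(path_p, TrajectoryData) else np.asarray(path_p)
    q = path_q.frames if isinstance(path_q, TrajectoryData) else np.asarray(path_q)
    if p.shape[0] == 0 or q.shape[0] == 0:
        raise ValueError("paths must be non-empty")
    d = _pairwise_frame_rmsd(p, q)
    directed_pq = float(d.min(axis=1).max())
    directed_qp = float(d.min(axis=0).max())
    return PathDistance(max(directed_pq, directed_qp), directed_pq, directed_qp)


def psa_matrix(
    chunks: list[np.ndarray | TrajectoryData],
) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise Hausdorff distances plus the Ward-linkage leaf order."""
    k = len(chunks)
    if k < 2:
        raise ValueError("need at least two paths")
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dist[i, j] = dist[j, i] = hausdorff_distance(chunks[i], chunks[j]).delta_h
    order = leaves_list(linkage(squareform(dist, checks=False), method="ward"))
    return dist, order


def classify_similarity(delta_h: float) -> str:
    """Similarity band for a Hausdorff distance: < 0.5 A identical,
    > 3.0 A highly different, intermediate otherwise."""
    if delta_h < 0:
        raise ValueError("delta_h must be non-negative")
    if delta_h < 0.5:
        return "identical"
    if delta_h > 3.0:
        return "highly_different"
    return "intermediate"


# ---------------------------------------------------------------------------
# Retention-under-averaging shuffle test
# ---------------------------------------------------------------------------

def retention_shuffle_test(
    rmsd_series: list[np.ndarray],
    n_folds: int = 20,
    keep_frac: float = 0.8,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Does replicate-to-replicate RMSD variability survive averaging?

    Each fold draws a random ``keep_frac`` subsample of frames per replicate
    and records the subsample mean; a one-way ANOVA across replicates on the
    fold means decides retention (p < alpha).
    """
    if len(rmsd_series) < 2:
        raise ValueError("need at least two replicates")
    for s in rmsd_series:
        if len(s) < 10:
            raise ValueError("each replicate needs at least 10 frames")
    rng = np.random.default_rng(seed)
    lengths = {len(s) for s in rmsd_series}
    if len(lengths) != 1:
        raise ValueError("replicate series must have equal length")
    n_frames = lengths.pop()
    means = np.zeros((n_folds, len(rmsd_series)))
    for fold in range(n_folds):
        # one subsample per fold, shared across replicates (paired design:
        # identical replicates then give identical fold means)
        keep = rng.choice(n_frames, size=int(round(keep_frac * n_frames)),
                          replace=False)
        for r, s in enumerate(rmsd_series):
            means[fold, r] = np.asarray(s)[keep].mean()
    res = anova_oneway([means[:, r] for r in range(len(rmsd_series))])
    return {
        "fold_means": pd.DataFrame(
            means, columns=[f"rep{r + 1}" for r in range(len(rmsd_series))]
        ),
        "anova_p": res["p"],
        "retained": res["p"] < alpha,
    }


def choose_min_length(
    p_matrix: pd.DataFrame,
    chunk_ns: float = 10.0,
    agreement_frac: float = 0.8,
    alpha: float = 0.05,
) -> dict:
    """Minimum informative simulation length from the chunk-ANOVA p-matrix.

    A variant "agrees" through chunk c when none of chunks 2..c differ
    significantly from chunk 1.  If >= ``agreement_frac`` of variants agree
    through the whole horizon, the first chunk length is informative; if
    agreement never reaches the threshold the longest length is returned
    with a warning; otherwise the longest agreeing prefix length is chosen.
    """
    if p_matrix.empty:
        raise ValueError("empty p-value matrix")
    nonsig = (p_matrix >= alpha).to_numpy()
    n_rows = nonsig.shape[0]
    agree_through = np.cumprod(nonsig, axis=0)  # variant agrees at all rows <= r
    frac = agree_through.mean(axis=1)
    if frac[-1] >= agreement_frac:
        return {"chunk_index": 1, "length_ns": chunk_ns, "warning": False}
    prefix = 0
    for r in range(n_rows):
        if frac[r] >= agreement_frac:
            prefix = r + 1
        else:
            break
    if prefix == 0:
        warnings.warn("no simulation length satisfies the agreement criterion; "
                      "returning the longest")
        return {"chunk_index": n_rows + 1, "length_ns": (n_rows + 1) * chunk_ns,
                "warning": True}
    return {"chunk_index": prefix + 1, "length_ns": (prefix + 1) * chunk_ns,
            "warning": False}
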