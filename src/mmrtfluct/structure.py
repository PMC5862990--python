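"""Coordinate-based analyses: superposition, clustering, RMSF, state tests.

These support the fluctuation pipeline: conformational substates are defined
by clustering Cα-RMSD features (K-means for a known small cluster count,
hierarchical agglomerative with a distance cutoff otherwise), and per-residue
flexibility is quantified as RMSF about a running-average reference so that
slow conformational drift does not masquerade as fast fluctuation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation
from scipy.stats import ttest_ind
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoordinateTrajectory",
    "RegionDefinition",
    "RMSFProfile",
    "kabsch_superpose",
    "pairwise_rmsd",
    "kmeans_cluster",
    "hierarchical_cluster",
    "running_average_rmsf",
    "rmsf_state_test",
]


@dataclass
class CoordinateTrajectory:
    """Frames of atomic coordinates (Å) with per-atom annotation."""

    frames: np.ndarray           # (F, N, 3)
    atom_names: np.ndarray       # (N,) e.g. "CA"
    residue_ids: np.ndarray      # (N,) 1-based integers from input
    chain_ids: np.ndarray        # (N,)
    time_step_ps: float = 10.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("coordinates must be finite")
        n = self.frames.shape[1]
        self.atom_names = np.asarray(self.atom_names)
        self.residue_ids = np.asarray(self.residue_ids)
        self.chain_ids = np.asarray(self.chain_ids)
        for arr, name in (
            (self.atom_names, "atom_names"),
            (self.residue_ids, "residue_ids"),
            (self.chain_ids, "chain_ids"),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per atom")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def ca_selection(self, exclude_residues: Sequence[int] = ()) -> np.ndarray:
        """Indices of Cα atoms, optionally excluding residue ids."""
        sel = self.atom_names == "CA"
        if len(exclude_residues):
            sel &= ~np.isin(self.residue_ids, np.asarray(exclude_residues))
        idx = np.nonzero(sel)[0]
        if idx.size == 0:
            raise ValueError("empty Cα selection")
        return idx


@dataclass(frozen=True)
class RegionDefinition:
    """A named structural region as inclusive residue-id ranges per chain."""

    name: str
    ranges: tuple[tuple[str, int, int], ...]  # (chain, first_res, last_res)

    def mask(self, traj: CoordinateTrajectory) -> np.ndarray:
        if not self.ranges:
            raise ValueError(f"region {self.name!r} has no ranges")
        m = np.zeros(traj.n_atoms, dtype=bool)
        for chain, lo, hi in self.ranges:
            m |= (
                (traj.chain_ids == chain)
                & (traj.residue_ids >= lo)
                & (traj.residue_ids <= hi)
            )
        if not m.any():
            raise ValueError(f"region {self.name!r} selects no atoms")
        return m


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Å) for one replicate of one state."""

    residue_ids: np.ndarray
    rmsf: np.ndarray
    replicate_id: str = "r0"
    state: str = "reactant"

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF must be non-negative")


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD to the reference
    over the selected atoms. The rotation is proper (det = +1), obtained via
    the quaternion/SVD solution behind
    :meth:`scipy.spatial.transform.Rotation.align_vectors`.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    sel = np.arange(mob.shape[0]) if selection is None else np.asarray(selection)
    if sel.size < 3:
        raise ValueError("need at least 3 selected atoms")
    m, r = mob[sel], ref[sel]
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    m0, r0 = m - mc, r - rc
    if np.linalg.matrix_rank(m0, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) geometry")
    rot, rssd = Rotation.align_vectors(r0, m0)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    rmsd = rssd / np.sqrt(sel.size)
    return R, t, float(rmsd)


def pairwise_rmsd(
    traj: CoordinateTrajectory,
    selection: Optional[np.ndarray] = None,
    exclude_residues: Sequence[int] = (),
) -> np.ndarray:
    """Symmetric F×F matrix of post-superposition RMSDs over a selection.

    Default selection is all Cα atoms; ``exclude_residues`` drops flexible
    termini from the fit (their motion would otherwise dominate the metric).
    """
    if selection is None:
        selection = traj.ca_selection(exclude_residues)
    else:
        selection = np.asarray(selection)
        if len(exclude_residues):
            keep = ~np.isin(traj.residue_ids[selection], np.asarray(exclude_residues))
            selection = selection[keep]
    if selection.size == 0:
        raise ValueError("empty selection after exclusions")
    F = traj.n_frames
    coords = traj.frames[:, selection, :]
    # pre-centre every frame once
    centred = coords - coords.mean(axis=1, keepdims=True)
    D = np.zeros((F, F))
    for i in range(F):
        for j in range(i + 1, F):
            _, rssd = Rotation.align_vectors(centred[i], centred[j])
            D[i, j] = D[j, i] = rssd / np.sqrt(selection.size)
    return D


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def kmeans_cluster(
    features: np.ndarray, k: int, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """K-means conformational clustering (k-means++, 10 restarts, seeded).

    ``features`` is any (F, d) frame-feature array — typically rows of the
    pairwise RMSD matrix. Returns frame labels and an occupancy table (%).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > X.shape[0]:
        raise ValueError(f"k ({k}) exceeds the number of frames ({X.shape[0]})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return labels, _occupancy_table(labels)


def hierarchical_cluster(
    rmsd_matrix: np.ndarray,
    epsilon: float,
    method: str = "average",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Agglomerative clustering of a distance matrix with a merge cutoff.

    Merging proceeds (default average linkage; ``single``/``complete``
    configurable) until the smallest inter-cluster linkage distance exceeds
    ``epsilon``. ``epsilon = 0`` leaves every frame in its own cluster; an
    epsilon above the matrix maximum yields one cluster.
    """
    D = np.asarray(rmsd_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("rmsd_matrix must be square")
    if D.shape[0] == 1:
        labels = np.zeros(1, dtype=int)
        return labels, _occupancy_table(labels)
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=epsilon, criterion="distance") - 1
    return labels, _occupancy_table(labels)


def _occupancy_table(labels: np.ndarray) -> pd.DataFrame:
    vals, counts = np.unique(labels, return_counts=True)
    return pd.DataFrame(
        {
            "cluster": vals,
            "n_frames": counts,
            "occupancy_pct": 100.0 * counts / labels.size,
        }
    )


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def running_average_rmsf(
    traj: CoordinateTrajectory,
    window_ps: float = 10000.0,
    replicate_id: str = "r0",
    state: str = "reactant",
) -> RMSFProfile:
    """Per-residue Cα RMSF about a running-average reference structure.

    Frames are first aligned (Cα Kabsch fit) to the initial frame to remove
    global rigid motion, a running-average structure is computed over a
    centred window (truncated at the ends), each frame is re-fit to its own
    running average, and the RMSF of each Cα about its windowed mean position
    is reported. Referencing a running average keeps slow inter-substate
    drift out of the fluctuation measure.
    """
    ca = traj.ca_selection()
    w_frames = max(int(round(window_ps / traj.time_step_ps)), 1)
    if w_frames < 2:
        raise ValueError("window must span at least 2 frames")
    if w_frames > traj.n_frames:
        raise ValueError(
            f"window ({w_frames} frames) exceeds trajectory ({traj.n_frames})"
        )
    F = traj.n_frames
    # pass 1: remove global rigid motion
    aligned = np.empty((F, ca.size, 3))
    ref0 = traj.frames[0, ca, :]
    for i in range(F):
        R, t, _ = kabsch_superpose(traj.frames[i, ca, :], ref0)
        aligned[i] = traj.frames[i, ca, :] @ R.T + t
    # pass 2: centred running average via cumulative sums; a window covering
    # the full trajectory degenerates to the global mean for every frame
    if w_frames >= F:
        run_avg = np.broadcast_to(aligned.mean(axis=0), (F, ca.size, 3))
    else:
        half = w_frames // 2
        csum = np.concatenate(
            [np.zeros((1, ca.size, 3)), np.cumsum(aligned, axis=0)]
        )
        lo = np.maximum(np.arange(F) - half, 0)
        hi = np.minimum(np.arange(F) + (w_frames - half), F)
        run_avg = (csum[hi] - csum[lo]) / (hi - lo)[:, None, None]
    # pass 3: fit each frame to its running average and accumulate deviations
    sq = np.zeros(ca.size)
    for i in range(F):
        R, t, _ = kabsch_superpose(aligned[i], run_avg[i])
        dev = aligned[i] @ R.T + t - run_avg[i]
        sq += np.sum(dev * dev, axis=1)
    rmsf = np.sqrt(sq / F)
    return RMSFProfile(
        residue_ids=traj.residue_ids[ca],
        rmsf=rmsf,
        replicate_id=replicate_id,
        state=state,
    )


def rmsf_state_test(
    profiles_a: Sequence[RMSFProfile],
    profiles_b: Sequence[RMSFProfile],
    alpha: float = 0.01,
    correction: Optional[str] = None,
) -> pd.DataFrame:
    """Per-residue Welch two-sample t-test between two states' RMSF replicates.

    Flags residues with p below ``alpha`` (default 0.01, per-residue, no
    multiple-testing correction; ``correction='fdr_bh'`` enables
    Benjamini–Hochberg). Residues where both samples are constant and equal
    get p = 1 and no flag.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("need at least 2 replicates per state")
    A = np.stack([p.rmsf for p in profiles_a])
    B = np.stack([p.rmsf for p in profiles_b])
    if A.shape[1] != B.shape[1]:
        raise ValueError("states have different residue counts")
    residue_ids = profiles_a[0].residue_ids
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = ttest_ind(A, B, axis=0, equal_var=False)
    degenerate = (np.ptp(A, axis=0) == 0) & (np.ptp(B, axis=0) == 0) & (
        A[0] == B[0]
    )
    pvals = np.where(degenerate, 1.0, pvals)
    pvals = np.nan_to_num(pvals, nan=1.0)
    if correction == "fdr_bh":
        flags, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        p_report = p_adj
    elif correction is None:
        flags = pvals < alpha
        p_report = pvals
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return pd.DataFrame(
        {
            "residue_id": residue_ids,
            "mean_a": A.mean(axis=0),
            "mean_b": B.mean(axis=0),
            "p_value": p_report,
            "significant": flags,
        }
    )
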