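"""Attention modulation index (AMI), cluster permutation tests and ROIs.

AMI = (attend left - attend right) / (attend left + attend right), computed
on condition-mean power. Positive values over the left hemisphere and
negative over the right indicate the expected ipsilateral enhancement /
contralateral suppression of beta power.

The cluster-based permutation test controls for multiple comparisons across
channels (or channel x bin elements): paired t statistics are thresholded
(two-sided, alpha = 0.05) into sign-consistent neighbour-connected clusters,
the null distribution of the maximum absolute cluster mass is built by
randomly flipping each subject's condition labels, and Monte-Carlo p-values
use the (b + 1)/(n + 1) correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components

from .layout import ChannelLayout

DEFAULT_N_PERMUTATIONS = 10_000
DEFAULT_CLUSTER_ALPHA = 0.05
DEFAULT_ROI_SIZE = 10


def compute_ami(power_attend_left, power_attend_right) -> np.ndarray:
    """Element-wise normalized attention modulation index in [-1, 1].

    Elements where both inputs are zero are flagged invalid (NaN).
    """
    a = np.asarray(power_attend_left, float)
    b = np.asarray(power_attend_right, float)
    if a.shape != b.shape:
        raise ValueError("inputs must be aligned element-wise")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("power values must be nonnegative")
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        ami = np.where(denom > 0, (a - b) / denom, np.nan)
    return ami


@dataclass(frozen=True)
class Cluster:
    elements: tuple  # flat element indices
    sign: int  # +1 or -1
    mass: float  # summed t statistic
    p: float  # Monte-Carlo p, (b+1)/(n+1)

    @property
    def size(self) -> int:
        return len(self.elements)


@dataclass
class ClusterTestResult:
    clusters: list  # Cluster, sorted by |mass| descending
    n_permutations: int
    threshold: float  # cluster-forming |t| threshold
    t_obs: np.ndarray

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p <= alpha]

    def largest(self, sign: int):
        """Largest-mass cluster of the given sign, or None."""
        cands = [c for c in self.clusters if c.sign == sign]
        return max(cands, key=lambda c: abs(c.mass)) if cands else None


def channel_adjacency(layout: ChannelLayout, target_degree: int = 6):
    """Sparse symmetric channel adjacency from the 2-D layout."""
    nb = layout.neighbors(target_degree)
    n = layout.n_channels
    rows, cols = [], []
    for i, name in enumerate(layout.names):
        for other in nb[name]:
            rows.append(i)
            cols.append(layout.index(other))
    m = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return ((m + m.T) > 0).tocsr()


def grid_adjacency(channel_adj, n_bins: int):
    """Adjacency over channel x bin elements: same-bin channel neighbours
    plus consecutive bins of the same channel (flattened channel-major)."""
    bins = sp.diags([1, 1], [-1, 1], shape=(n_bins, n_bins))
    n_ch = channel_adj.shape[0]
    return (
        sp.kron(channel_adj, sp.identity(n_bins)) + sp.kron(sp.identity(n_ch), bins)
    ).tocsr() > 0


def _adjacency_lists(adjacency):
    """Neighbour index lists per element from a sparse adjacency matrix."""
    adj = sp.csr_matrix(adjacency)
    return [adj.indices[adj.indptr[i]:adj.indptr[i + 1]]
            for i in range(adj.shape[0])]


def _clusters_from_t(t, threshold, neighbor_lists):
    """Sign-consistent connected supra-threshold clusters: (indices, mass)."""
    out = []
    for sign in (1, -1):
        mask = (sign * t) > threshold
        seen = ~mask
        for start in np.where(mask)[0]:
            if seen[start]:
                continue
            # breadth-first growth within the supra-threshold set
            members = [start]
            seen[start] = True
            frontier = [start]
            while frontier:
                nxt = []
                for i in frontier:
                    for j in neighbor_lists[i]:
                        if not seen[j]:
                            seen[j] = True
                            members.append(j)
                            nxt.append(j)
                frontier = nxt
            members = np.array(sorted(members))
            out.append((members, sign, float(t[members].sum())))
    return out


def _paired_t(diff):
    """One-sample t over axis 0, zero-variance-safe."""
    n = diff.shape[0]
    mean = diff.mean(0)
    sd = diff.std(0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / math.sqrt(n)), 0.0)
    return t


def cluster_permutation_test(
    cond_a,
    cond_b,
    adjacency,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    cluster_alpha: float = DEFAULT_CLUSTER_ALPHA,
    rng=None,
) -> ClusterTestResult:
    """Paired cluster-based permutation test over elements.

    ``cond_a``/``cond_b``: (n_subjects, n_elements) paired per-subject
    values; ``adjacency``: symmetric sparse matrix over elements. The
    permutation scheme swaps the two condition labels within subjects
    (equivalently, flips the sign of each subject's difference).
    """
    a = np.atleast_2d(np.asarray(cond_a, float))
    b = np.atleast_2d(np.asarray(cond_b, float))
    if a.shape != b.shape:
        raise ValueError("conditions must be paired and aligned")
    n_sub, n_el = a.shape
    if n_sub < 2:
        raise ValueError("at least 2 subjects required")
    if rng is None:
        rng = np.random.default_rng(0)
    adjacency = sp.csr_matrix(adjacency)
    if adjacency.shape != (n_el, n_el):
        raise ValueError("adjacency shape must match the element count")

    diff = a - b
    threshold = float(stats.t.ppf(1 - cluster_alpha / 2, df=n_sub - 1))
    neighbor_lists = _adjacency_lists(adjacency)
    t_obs = _paired_t(diff)
    observed = _clusters_from_t(t_obs, threshold, neighbor_lists)

    # vectorized permutation t statistics (sign flips of subject differences)
    signs = rng.choice((-1.0, 1.0), size=(n_permutations, n_sub))
    null_max = np.zeros(n_permutations)
    chunk = max(1, int(2e6 // max(n_el * n_sub, 1)))
    for start in range(0, n_permutations, chunk):
        s = signs[start:start + chunk]
        flipped = s[:, :, None] * diff[None, :, :]
        mean = flipped.mean(1)
        sd = flipped.std(1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = np.where(sd > 0, mean / (sd / math.sqrt(n_sub)), 0.0)
        for k, t_row in enumerate(t_perm):
            perm_clusters = _clusters_from_t(t_row, threshold, neighbor_lists)
            if perm_clusters:
                null_max[start + k] = max(abs(m) for _, _, m in perm_clusters)

    clusters = []
    for members, sign, mass in observed:
        b_count = int((null_max >= abs(mass)).sum())
        clusters.append(
            Cluster(
                elements=tuple(int(i) for i in members),
                sign=sign,
                mass=mass,
                p=(b_count + 1) / (n_permutations + 1),
            )
        )
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterTestResult(
        clusters=clusters,
        n_permutations=n_permutations,
        threshold=threshold,
        t_obs=t_obs,
    )


@dataclass(frozen=True)
class ROIPair:
    """Ten-channel (by default) left/right hemisphere channel sets."""

    left: tuple  # channel names, most-positive AMI first
    right: tuple  # channel names, most-negative AMI first
    basis: str = "group"  # 'group' | 'individual'

    def __post_init__(self):
        if set(self.left) & set(self.right):
            raise ValueError("left and right ROIs must be disjoint")
        if len(self.left) != len(self.right):
            raise ValueError("ROIs must have equal size")


def select_rois(ami, layout: ChannelLayout, k: int = DEFAULT_ROI_SIZE,
                basis: str = "group") -> ROIPair:
    """k most-positive left-hemisphere / most-negative right-hemisphere
    channels by AMI; midline channels are excluded before sorting. Ties are
    broken by channel name for determinism.
    """
    ami = np.asarray(ami, float)
    if ami.shape != (layout.n_channels,):
        raise ValueError("need one AMI value per channel")

    def pick(hemi, sign):
        names = layout.channels(hemi)
        vals = {n: ami[layout.index(n)] for n in names}
        eligible = [n for n in names if np.isfinite(vals[n])]
        if len(eligible) < k:
            raise ValueError(
                f"fewer than {k} eligible channels in hemisphere {hemi}"
            )
        ordered = sorted(eligible, key=lambda n: (-sign * vals[n], n))
        return tuple(ordered[:k])

    return ROIPair(left=pick("L", +1), right=pick("R", -1), basis=basis)


def roi_size_from_clusters(result: ClusterTestResult,
                           fallback: int = DEFAULT_ROI_SIZE) -> int:
    """ROI size = rounded mean of the largest positive and negative cluster
    sizes (round half up); falls back to ``fallback`` with a warning when a
    cluster of either sign is absent.
    """
    pos = result.largest(+1)
    neg = result.largest(-1)
    if pos is None or neg is None:
        warnings.warn(
            "missing a positive or negative cluster; using fallback ROI size",
            RuntimeWarning,
        )
        return fallback
    return int(math.floor((pos.size + neg.size) / 2 + 0.5))
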