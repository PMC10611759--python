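"""Residue-motion analysis: RMSF, native contacts, correlation networks.

All quantities are computed on C-alpha coordinates and are invariant under
global rigid-body motion of every frame:

* RMSF about the mean structure after least-squares superposition onto the
  reference;
* fraction of native contacts Q, with native pairs defined on the
  reference structure (|i-j| > 3, C-alpha distance <= cutoff);
* the generalized correlation r_MI = sqrt(1 - exp(-2 I / 3)) of
  Lange & Grubmueller, with the mutual information I between two residues'
  3-D displacement vectors estimated by the Kraskov k-nearest-neighbor
  estimator;
* a residue network whose edges connect residues in persistent spatial
  contact, weighted by C_ij with graph distance -log(C_ij) (small distance
  between highly coupled residues), decomposed into communities by
  Girvan-Newman divisive clustering at maximum modularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms.community import modularity
from scipy.spatial import cKDTree
from scipy.special import digamma

from .types import TrajectoryEnsemble, ValidationError

CONTACT_CUTOFF = 8.0          # angstrom, native-contact definition
CONTACT_TOLERANCE = 0.2       # fractional slack when counting per frame
EDGE_CUTOFF = 10.0            # angstrom, network contact filter
EDGE_OCCUPANCY = 0.75         # fraction of frames within EDGE_CUTOFF
CORRELATION_FLOOR = 0.01      # minimum C_ij for a retained edge
MIN_SEQ_SEPARATION = 3        # |i-j| must exceed this for a native contact


@dataclass
class FluctuationProfile:
    residue_ids: list
    rmsf: np.ndarray          # angstrom, >= 0 per residue


@dataclass
class NativeContactProfile:
    contacts: np.ndarray      # (n_pairs, 2) residue indices (0-based)
    q_per_frame: np.ndarray   # in [0, 1]
    subset: np.ndarray | None = None
    q_subset: np.ndarray | None = None

    @property
    def q_mean(self) -> float:
        return float(np.mean(self.q_per_frame))


@dataclass
class CorrelationNetwork:
    residue_ids: list
    correlation: np.ndarray   # symmetric, diagonal 1, values in [0, 1]
    graph: nx.Graph           # nodes are 0-based residue indices


@dataclass
class CommunityPartition:
    labels: dict              # node -> community id
    betweenness: dict         # node -> betweenness centrality
    coupling: dict            # (cid_a, cid_b) -> mean inter-community C_ij
    modularity: float
    n_communities: int
    note: str = ""

    def coupling_weight(self, a: int, b: int) -> float:
        """1 - coupling, the 'weight' convention used for edge thickness."""
        key = (min(a, b), max(a, b))
        return 1.0 - self.coupling[key]


# ---------------------------------------------------------------------------
# Superposition and RMSF
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body superposition of one frame onto target."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return mc @ rot.T + target.mean(axis=0)


def superpose_frames(traj: TrajectoryEnsemble,
                     subset: np.ndarray | None = None) -> np.ndarray:
    """Superpose every frame onto the reference (optionally fitting on a
    residue subset); returns the aligned (n_frames, n_residues, 3) array."""
    ref = traj.reference
    fit_idx = np.arange(traj.n_residues) if subset is None else np.asarray(subset)
    rc = ref[fit_idx] - ref[fit_idx].mean(axis=0)
    if np.linalg.matrix_rank(rc, tol=1e-8) < 2:
        raise ValidationError(
            "degenerate (collinear) reference: superposition is ill-posed")
    aligned = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        frame = traj.frames[f]
        mc = frame[fit_idx] - frame[fit_idx].mean(axis=0)
        tc = rc
        h = mc.T @ tc
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        aligned[f] = (frame - frame[fit_idx].mean(axis=0)) @ rot.T \
            + ref[fit_idx].mean(axis=0)
    return aligned


def rmsf(traj: TrajectoryEnsemble,
         fit_subset: np.ndarray | None = None) -> FluctuationProfile:
    """Per-residue RMSF about the mean structure after superposition.

    RMSF_i = sqrt(mean over frames of |r_i - <r_i>|^2).  Needs >=10 frames.
    """
    if traj.n_frames < 10:
        raise ValidationError("rmsf needs >=10 frames")
    aligned = superpose_frames(traj, fit_subset)
    mean = aligned.mean(axis=0)
    dev = aligned - mean[None]
    vals = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))
    return FluctuationProfile(residue_ids=list(traj.residue_ids), rmsf=vals)


# ---------------------------------------------------------------------------
# Native contacts
# ---------------------------------------------------------------------------

def native_contact_pairs(reference: np.ndarray,
                         cutoff: float = CONTACT_CUTOFF,
                         min_sep: int = MIN_SEQ_SEPARATION) -> np.ndarray:
    """Residue pairs (|i-j| > min_sep) within cutoff on the reference."""
    n = reference.shape[0]
    d = np.linalg.norm(reference[:, None] - reference[None], axis=2)
    ii, jj = np.triu_indices(n, k=min_sep + 1)
    keep = d[ii, jj] <= cutoff
    return np.column_stack([ii[keep], jj[keep]])


def native_contacts(traj: TrajectoryEnsemble,
                    subset: np.ndarray | None = None,
                    cutoff: float = CONTACT_CUTOFF,
                    tolerance: float = CONTACT_TOLERANCE) -> NativeContactProfile:
    """Per-frame fraction of native contacts Q (hard count).

    Native pairs come from the reference structure; a contact is kept in a
    frame when its distance is <= cutoff*(1+tolerance).  ``subset`` is an
    optional explicit (n, 2) pair list (e.g. an interface pair set) scored
    separately as Q_subset.  Q on a frame identical to the reference is
    exactly 1.
    """
    pairs = native_contact_pairs(traj.reference, cutoff)
    if pairs.shape[0] == 0:
        raise ValidationError(
            f"no native contacts at cutoff {cutoff} A; increase the cutoff")
    thresh = cutoff * (1.0 + tolerance)

    def q_of(pair_arr: np.ndarray) -> np.ndarray:
        di = traj.frames[:, pair_arr[:, 0]] - traj.frames[:, pair_arr[:, 1]]
        dist = np.linalg.norm(di, axis=2)
        return np.mean(dist <= thresh, axis=1)

    q = q_of(pairs)
    q_sub = None
    sub = None
    if subset is not None:
        sub = np.asarray(subset, dtype=int)
        if sub.ndim != 2 or sub.shape[1] != 2 or sub.shape[0] == 0:
            raise ValidationError("subset must be a non-empty (n, 2) pair list")
        q_sub = q_of(sub)
    return NativeContactProfile(contacts=pairs, q_per_frame=q,
                                subset=sub, q_subset=q_sub)


# ---------------------------------------------------------------------------
# Generalized correlation (Kraskov mutual information)
# ---------------------------------------------------------------------------

def _ksg_mi(x: np.ndarray, y: np.ndarray, k: int = 6) -> float:
    """Kraskov-Stoegbauer-Grassberger estimator (algorithm 1) of the
    mutual information between two d-dimensional variables, in nats."""
    n = x.shape[0]
    joint = np.hstack([x, y])
    tree = cKDTree(joint)
    # distance to the k-th neighbor in the joint space (max-norm)
    dist, _ = tree.query(joint, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    tx = cKDTree(x)
    ty = cKDTree(y)
    # strictly-within-eps marginal counts, excluding the point itself
    r = eps * (1 - 1e-12)
    nx_ = tx.query_ball_point(x, r, p=np.inf, return_length=True) - 1
    ny_ = ty.query_ball_point(y, r, p=np.inf, return_length=True) - 1
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx_ + 1) + digamma(ny_ + 1))
    return float(max(mi, 0.0))


def r_mi_from_mi(mi: float, dim: int = 3) -> float:
    """Map mutual information to the generalized correlation in [0, 1]."""
    return float(np.sqrt(np.clip(1.0 - np.exp(-2.0 * mi / dim), 0.0, 1.0)))


def generalized_correlation(traj: TrajectoryEnsemble, k: int = 6,
                            pairs: np.ndarray | None = None,
                            rng_jitter: float = 1e-10,
                            seed: int = 0,
                            superpose: bool = True) -> CorrelationNetwork:
    """Pairwise generalized correlation matrix of residue displacements.

    Frames are superposed onto the reference (``superpose=False`` accepts
    pre-aligned frames); each residue's mean position
    is subtracted to obtain 3-D displacement vectors.  For every residue
    pair (or only ``pairs`` when given, leaving the rest zero) the Kraskov
    k-NN estimator gives the mutual information I, mapped to
    r_MI = sqrt(1 - exp(-2I/3)).  A tiny seeded jitter breaks the exact
    distance ties the k-NN estimator cannot handle.  Warns below 500
    frames; errors when frames <= k.
    """
    if traj.n_frames <= k:
        raise ValidationError(f"need more than k+1={k + 1} frames")
    if traj.n_frames < 500:
        warnings.warn("fewer than 500 frames: generalized correlation "
                      "estimates will be noisy", stacklevel=2)
    aligned = superpose_frames(traj) if superpose else traj.frames
    disp = aligned - aligned.mean(axis=0)[None]
    rng = np.random.default_rng(seed)
    disp = disp + rng.normal(0.0, rng_jitter, disp.shape)
    n = traj.n_residues
    corr = np.zeros((n, n))
    np.fill_diagonal(corr, 1.0)
    if pairs is None:
        ii, jj = np.triu_indices(n, k=1)
        pairs = np.column_stack([ii, jj])
    for i, j in pairs:
        mi = _ksg_mi(disp[:, i], disp[:, j], k=k)
        corr[i, j] = corr[j, i] = r_mi_from_mi(mi)
    return CorrelationNetwork(residue_ids=list(traj.residue_ids),
                              correlation=corr, graph=nx.Graph())


# ---------------------------------------------------------------------------
# Network construction and communities
# ---------------------------------------------------------------------------

def build_network(correlation: np.ndarray, traj: TrajectoryEnsemble,
                  contact_cutoff: float = EDGE_CUTOFF,
                  occupancy: float = EDGE_OCCUPANCY,
                  floor: float = CORRELATION_FLOOR) -> CorrelationNetwork:
    """Residue graph with edges for persistently contacting, correlated pairs.

    An edge (i, j) is retained when the C-alpha distance is within
    ``contact_cutoff`` in at least ``occupancy`` of frames and
    C_ij >= ``floor``; its graph distance is -log(C_ij) (>= 0, zero at
    perfect coupling).  Raising the occupancy threshold can only remove
    edges.  A disconnected result triggers a warning with the component
    sizes, not an error.
    """
    c = np.asarray(correlation, dtype=float)
    n = c.shape[0]
    if c.shape != (n, n) or not np.allclose(c, c.T, atol=1e-9):
        raise ValidationError("correlation matrix must be square symmetric")
    occ = np.zeros((n, n))
    for lo in range(0, traj.n_frames, 256):   # chunked to bound memory
        chunk = traj.frames[lo:lo + 256]
        d = np.linalg.norm(chunk[:, :, None, :] - chunk[:, None, :, :], axis=3)
        occ += np.sum(d <= contact_cutoff, axis=0)
    occ /= traj.n_frames
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.triu_indices(n, k=1)
    for i, j in zip(ii, jj):
        cij = min(float(c[i, j]), 1.0)
        if occ[i, j] >= occupancy and cij >= floor:
            g.add_edge(int(i), int(j), correlation=cij,
                       distance=float(-np.log(cij)) if cij < 1.0 else 0.0)
    if g.number_of_edges() and not nx.is_connected(g):
        sizes = sorted((len(comp) for comp in nx.connected_components(g)),
                       reverse=True)
        warnings.warn(f"network is disconnected (component sizes {sizes})",
                      stacklevel=2)
    return CorrelationNetwork(residue_ids=list(traj.residue_ids),
                              correlation=c, graph=g)


def _girvan_newman_best(g: nx.Graph) -> tuple[list[set], float]:
    """Divisive edge-betweenness clustering; returns the partition with
    maximum modularity (computed on the correlation weights).  Ties in edge
    betweenness are broken by the lexicographically smallest edge."""
    work = g.copy()
    best_parts = [set(g.nodes)]
    best_q = modularity(g, best_parts, weight="correlation")
    n_comp = nx.number_connected_components(work)
    while work.number_of_edges():
        eb = nx.edge_betweenness_centrality(work, weight="distance")
        max_b = max(eb.values())
        edge = min(tuple(sorted(e)) for e, b in eb.items()
                   if b >= max_b - 1e-12)
        work.remove_edge(*edge)
        parts = [set(cc) for cc in nx.connected_components(work)]
        if len(parts) > n_comp:
            n_comp = len(parts)
            q = modularity(g, parts, weight="correlation")
            if q > best_q + 1e-12:
                best_q = q
                best_parts = parts
    return best_parts, best_q


def communities(net: CorrelationNetwork) -> CommunityPartition:
    """Community decomposition, betweenness, and inter-community coupling.

    Girvan-Newman divisive clustering on the -log(C) edge distances,
    keeping the partition of maximum modularity; node betweenness is
    computed on the same weighted graph.  The coupling score for a
    community pair is the mean C_ij over the retained edges that cross it
    (1 - coupling matches the edge-thickness convention of community
    diagrams).  A single-community optimum is returned with a note, not an
    error.
    """
    g = net.graph
    if g.number_of_nodes() < 3:
        raise ValidationError("need >=3 nodes for community analysis")
    parts, q = _girvan_newman_best(g)
    parts = sorted(parts, key=lambda s: (-len(s), min(s)))
    labels = {node: cid for cid, members in enumerate(parts) for node in members}
    btw = nx.betweenness_centrality(g, weight="distance", normalized=True)
    coupling: dict[tuple[int, int], list[float]] = {}
    for i, j, data in g.edges(data=True):
        a, b = labels[i], labels[j]
        if a != b:
            coupling.setdefault((min(a, b), max(a, b)), []).append(
                data["correlation"])
    coupling_mean = {k: float(np.mean(v)) for k, v in coupling.items()}
    note = "" if len(parts) > 1 else \
        "maximum modularity at a single community; no finer structure found"
    return CommunityPartition(labels=labels, betweenness=btw,
                              coupling=coupling_mean, modularity=float(q),
                              n_communities=len(parts), note=note)
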