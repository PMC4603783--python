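"""Contact-map spectral clustering of conformational ensembles.

Each frame is reduced to a binary contact fingerprint: a bit per residue
pair (sequence separation ≥ 3 by default) that is 1 iff the main-chain
centres of mass of the two residues are closer than 4.5 Å.  Normalised
Hamming distances between fingerprints are turned into a Gaussian
affinity matrix, whose leading singular vectors (scaled by their singular
values) embed the frames; k-medoids in that embedding yields clusters
whose representatives are actual frames.  The within-cluster
sum-of-distance curve over candidate k supports elbow-based selection of
the cluster number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import Ensemble, Frame, Topology
from .geometry import mainchain_com_all

__all__ = ["ContactParams", "ContactFingerprint", "ClusterResult",
           "ElbowResult", "contact_fingerprint", "fingerprint_matrix",
           "affinity_matrix", "spectral_embed", "cluster", "select_k",
           "medoid_frames"]


@dataclass(frozen=True)
class ContactParams:
    """Contact definition: COM distance cutoff (Å) and minimum sequence
    separation of the residue pairs that enter the fingerprint.

    Pairs closer in sequence than ``min_separation`` are excluded because
    chain connectivity keeps their main-chain COMs permanently within the
    cutoff, producing constant, uninformative bits.
    """

    cutoff: float = 4.5
    min_separation: int = 3

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")


@dataclass
class ContactFingerprint:
    """Binary contact vector for one frame plus its residue-pair map."""

    bits: np.ndarray
    pairs: list[tuple[int, int]]

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (len(self.pairs),):
            raise ValueError("bits and pair map length mismatch")


def residue_pairs(n_residues: int, min_separation: int) -> list[tuple[int, int]]:
    """Lexicographically ordered 1-based pairs (i, j), j − i ≥ separation."""
    return [(i, j)
            for i in range(1, n_residues + 1)
            for j in range(i + min_separation, n_residues + 1)]


def contact_fingerprint(frame: Frame, topology: Topology,
                        params: ContactParams = ContactParams()
                        ) -> ContactFingerprint:
    """Contact fingerprint of one frame.

    Bit for pair (i, j) is 1 iff the Euclidean distance between the
    main-chain COMs of residues i and j is strictly below the cutoff
    (a pair at exactly the cutoff is a non-contact).
    """
    pairs = residue_pairs(topology.n_residues, params.min_separation)
    if not pairs:
        return ContactFingerprint(np.zeros(0, dtype=np.uint8), [])
    coms = mainchain_com_all(frame, topology)
    ii = np.array([p[0] - 1 for p in pairs])
    jj = np.array([p[1] - 1 for p in pairs])
    d = np.linalg.norm(coms[ii] - coms[jj], axis=1)
    return ContactFingerprint((d < params.cutoff).astype(np.uint8), pairs)


def fingerprint_matrix(ensemble: Ensemble,
                       params: ContactParams = ContactParams()) -> np.ndarray:
    """Fingerprints of all frames stacked as an (n_frames, n_pairs) array."""
    topo = ensemble.topology
    pairs = residue_pairs(topo.n_residues, params.min_separation)
    ii = np.array([p[0] - 1 for p in pairs])
    jj = np.array([p[1] - 1 for p in pairs])
    out = np.empty((ensemble.n_frames, len(pairs)), dtype=np.uint8)
    for k, fr in enumerate(ensemble.frames):
        coms = mainchain_com_all(fr, topo)
        d = np.linalg.norm(coms[ii] - coms[jj], axis=1)
        out[k] = d < params.cutoff
    return out


def affinity_matrix(fingerprints: np.ndarray, sigma: float | None = None,
                    mode: str = "gaussian",
                    max_sigma_pairs: int = 2000) -> np.ndarray:
    """Square symmetric affinity matrix from binary fingerprints.

    With ``mode="gaussian"`` (default), ``A[m, n] = exp(-h/(2σ²))`` where
    h is the normalised Hamming distance between fingerprints m and n and
    σ defaults to the square root of the median h over a deterministic
    subsample of at most ``max_sigma_pairs`` pairs.  Because h is the
    squared Euclidean distance between binary vectors (scaled by the
    length), this is a Gaussian radial-basis kernel and the matrix is
    positive semidefinite.  ``mode="similarity"`` uses ``1 − h``
    directly.  If every fingerprint is identical (σ = 0) the matrix
    degenerates to all ones, with a warning.
    """
    F = np.asarray(fingerprints)
    if F.ndim != 2 or F.shape[0] < 2:
        raise ValueError("need >= 2 fingerprints of equal length")
    h = squareform(pdist(F.astype(bool), metric="hamming"))
    if mode == "similarity":
        return 1.0 - h
    if mode != "gaussian":
        raise ValueError(f"unknown affinity mode {mode!r}")
    if sigma is None:
        iu = np.triu_indices_from(h, k=1)
        vals = h[iu]
        if vals.size > max_sigma_pairs:
            rng = np.random.default_rng(0)  # fixed: deterministic subsample
            vals = vals[rng.choice(vals.size, max_sigma_pairs, replace=False)]
        sigma = float(np.sqrt(np.median(vals)))
    if sigma == 0.0:
        warnings.warn("all fingerprints identical; affinity degenerates "
                      "to all ones")
        return np.ones_like(h)
    A = np.exp(-h / (2.0 * sigma * sigma))
    np.fill_diagonal(A, 1.0)
    return A


def spectral_embed(affinity: np.ndarray, n_vectors: int = 7) -> tuple[np.ndarray, np.ndarray]:
    """Embed frames by the leading singular vectors of the affinity matrix.

    Returns ``(embedding, singular_values)`` where the embedding rows are
    the top-``n_vectors`` left singular vectors, each column scaled by its
    singular value.  ``n_vectors`` is capped at the numerical rank.  The
    sign of each vector is fixed so its largest-magnitude entry is
    positive, making the embedding deterministic.
    """
    A = np.asarray(affinity, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("affinity must be symmetric")
    if n_vectors < 1:
        raise ValueError("n_vectors must be >= 1")
    U, s, _ = np.linalg.svd(A, hermitian=True)
    rank = int(np.sum(s > s[0] * max(A.shape) * np.finfo(float).eps)) if s.size else 0
    n = min(n_vectors, max(rank, 1))
    U = U[:, :n].copy()
    for c in range(n):
        col = U[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            U[:, c] = -col
    return U * s[:n], s


@dataclass
class ClusterResult:
    """Outcome of k-medoids in the spectral embedding."""

    labels: np.ndarray
    medoid_indices: np.ndarray
    embedding: np.ndarray
    singular_values: np.ndarray
    k: int
    within_cluster_sum: float
    elbow_ks: np.ndarray | None = None
    elbow_sums: np.ndarray | None = None

    def __post_init__(self):
        if len(self.labels) != self.embedding.shape[0]:
            raise ValueError("label count must equal frame count")
        for m, mi in enumerate(self.medoid_indices):
            if self.labels[mi] != m:
                raise ValueError("medoid label inconsistent with its cluster")


def _kmedoids_once(D: np.ndarray, k: int, rng: np.random.Generator,
                   max_iter: int = 200) -> tuple[np.ndarray, np.ndarray, float]:
    """One k-medoids run: k-means++ style seeding on the distance matrix,
    then alternating assignment / exhaustive medoid update."""
    n = D.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        dmin = D[:, medoids].min(axis=1)
        w = dmin ** 2
        total = w.sum()
        if total <= 0:
            # all remaining points coincide with a medoid: pick any non-medoid
            choices = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(choices[int(rng.integers(choices.size))]))
            continue
        medoids.append(int(rng.choice(n, p=w / total)))
    medoids = np.asarray(medoids)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        labels[medoids] = np.arange(k)  # a medoid always belongs to itself
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.nonzero(labels == c)[0]
            sums = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(sums))]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    labels = np.argmin(D[:, medoids], axis=1)
    labels[medoids] = np.arange(k)
    cost = float(D[np.arange(n), medoids[labels]].sum())
    return labels, medoids, cost


def cluster(embedding: np.ndarray, k: int, seed: int = 0,
            n_restarts: int = 10,
            singular_values: np.ndarray | None = None) -> ClusterResult:
    """k-medoids clustering in the spectral embedding (Euclidean metric).

    Runs ``n_restarts`` seeded restarts and keeps the partition with the
    lowest within-cluster sum of distances to the medoids.  Deterministic
    for fixed ``(seed, n_restarts)``.
    """
    E = np.asarray(embedding, dtype=float)
    n = E.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    D = squareform(pdist(E))
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        labels, medoids, cost = _kmedoids_once(D, k, rng)
        if best is None or cost < best[2] - 1e-12:
            best = (labels, medoids, cost)
    labels, medoids, cost = best
    return ClusterResult(
        labels=labels, medoid_indices=medoids, embedding=E,
        singular_values=(np.asarray(singular_values)
                         if singular_values is not None else np.array([])),
        k=k, within_cluster_sum=cost,
    )


@dataclass
class ElbowResult:
    """Within-cluster sum-of-distance curve and the suggested elbow k."""

    ks: np.ndarray
    sums: np.ndarray
    suggested_k: int


def select_k(embedding: np.ndarray, k_range=range(2, 13), seed: int = 0,
             n_restarts: int = 10) -> ElbowResult:
    """Elbow scan: best within-cluster sum per candidate k.

    The suggested k maximises the discrete curvature of the (monotone
    decreasing) cost curve — the turning point after which extra clusters
    stop paying for themselves.  The suggestion is advisory; callers may
    fix k independently.
    """
    ks = np.asarray(sorted(set(int(k) for k in k_range)))
    if ks.size == 0:
        raise ValueError("k_range must be non-empty")
    sums = np.array([
        cluster(embedding, int(k), seed=seed,
                n_restarts=n_restarts).within_cluster_sum
        for k in ks
    ])
    if ks.size < 3:
        return ElbowResult(ks, sums, int(ks[0]))
    curvature = sums[:-2] - 2.0 * sums[1:-1] + sums[2:]
    suggested = int(ks[1 + int(np.argmax(curvature))])
    return ElbowResult(ks, sums, suggested)


def medoid_frames(ensemble: Ensemble, result: ClusterResult
                  ) -> tuple[list[Frame], np.ndarray]:
    """Representative (medoid) frames with their cluster sizes."""
    frames = [ensemble.frames[int(i)] for i in result.medoid_indices]
    sizes = np.bincount(result.labels, minlength=result.k)
    return frames, sizes
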