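"""From eigenvectors to named compartmental states.

The caller takes the two eigenvectors with the highest sign-bipartition
modularity, scales each by |eigenvalue|, k-means-clusters the bins in that
2-D space (k = 4 by default) and then refines the partition with a
constrained Louvain pass: nodes move, in genomic order, to whichever of the
k seeded communities maximizes the modularity gain, until a full sweep makes
no move. No new communities are created and there is no agglomeration phase,
so the four-state scheme survives refinement.

State naming: the cluster with the highest mean EV1 is A1 and the lowest is
B1 (canonical A/B compartments). Of the remaining two "micro" clusters, the
one with the higher H3K27me3-like signal is B2 (facultative heterochromatin)
and the other A2; without a track the lower-mean-EV1 cluster falls back to
B2 and the call is flagged unoriented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import DegenerateInputError
from .eigen import EigenSystem, ModularityModel, partition_modularity
from .matrix_io import GenomicBinning, SignalTrack

log = logging.getLogger(__name__)

STATE_NAMES = ("A1", "A2", "B1", "B2")

#: transcriptional-activity ranking of the four states, ascending
ACTIVITY_ORDER = {"B1": 0, "B2": 1, "A2": 2, "A1": 3}


@dataclass
class ABCall:
    """Canonical A/B compartments from the sign of one eigenvector."""

    binning: GenomicBinning
    compartments: np.ndarray  # 'A' / 'B' / 'NA' per bin
    ev1: np.ndarray


@dataclass
class CompartmentCall:
    """Four-state compartment call for one chromosome."""

    binning: GenomicBinning
    states: np.ndarray  # per bin, in {A1, A2, B1, B2, NA} (or M* fallback)
    ev1: np.ndarray
    ev2: np.ndarray
    q: float = np.nan
    k: int = 4
    metadata: dict = field(default_factory=dict)

    def labels_valid(self) -> np.ndarray:
        """State names over valid bins only."""
        return self.states[self.binning.valid]

    def ab_states(self) -> np.ndarray:
        """Collapse the four states to the A/B scheme."""
        out = np.array(["NA"] * self.binning.n_bins, dtype=object)
        for s, ab in (("A1", "A"), ("A2", "A"), ("B1", "B"), ("B2", "B")):
            out[self.states == s] = ab
        m = np.char.startswith(self.states.astype(str), "M")
        out[m] = "NA"
        return out


def _orient_by_track(ev: np.ndarray, track: SignalTrack) -> np.ndarray:
    """Flip an eigenvector so its positive side carries the higher signal."""
    t = track.values
    ok = np.isfinite(ev) & np.isfinite(t)
    pos, neg = ok & (ev >= 0), ok & (ev < 0)
    if pos.any() and neg.any() and np.nanmean(t[neg]) > np.nanmean(t[pos]):
        return -ev
    return ev


def ab_compartments(
    es: EigenSystem, orientation_track: SignalTrack = None, vector_index: int = 0
) -> ABCall:
    """A/B compartments from the sign of the (by default leading) eigenvector.

    With an activity track, EV1 is flipped so the positive (A) side has the
    higher track mean; a zero entry is labelled A.
    """
    ev1 = es.vector_full(vector_index)
    if orientation_track is not None:
        ev1 = _orient_by_track(ev1, orientation_track)
    comp = np.array(["NA"] * es.binning.n_bins, dtype=object)
    valid = es.binning.valid
    comp[valid & (ev1 >= 0)] = "A"
    comp[valid & (ev1 < 0)] = "B"
    return ABCall(es.binning.copy(), comp, ev1)


def sse_profile(features: np.ndarray, k_values, seed: int = 0, n_init: int = 10) -> dict:
    """Within-cluster sum of squares (k-means inertia) per candidate k."""
    features = np.asarray(features, dtype=float)
    out = {}
    for k in k_values:
        if k > features.shape[0]:
            raise ValueError(f"k={k} exceeds {features.shape[0]} points")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(features)
        out[int(k)] = float(km.inertia_)
    return out


def eigen_features(es: EigenSystem, ranked_indices) -> np.ndarray:
    """Per-valid-bin feature matrix: each selected eigenvector times |eigenvalue|."""
    cols = [np.abs(es.eigenvalues[i]) * es.vectors[i] for i in ranked_indices]
    return np.column_stack(cols)


def weighted_kmeans(
    es: EigenSystem, ranked, k: int = 4, seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """K-means on the eigenvalue-weighted top-two eigenvectors.

    ``ranked`` is the (vector index, Q_EV) list from
    :func:`~mosaic_hic.eigen.rank_eigenvectors_by_modularity` or a plain pair
    of vector indices. Returns a cluster id per valid bin.
    """
    idx = [t[0] if isinstance(t, (tuple, list)) else int(t) for t in ranked][:2]
    if any(es.eigenvalues[i] == 0 for i in idx):
        raise DegenerateInputError("selected eigenvector has zero eigenvalue")
    feats = eigen_features(es, idx)
    if np.unique(feats, axis=0).shape[0] < k:
        raise DegenerateInputError(f"fewer than k={k} distinct points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(feats)
    return km.labels_.astype(int)


def louvain_refine(
    model: ModularityModel, labels, order: str = "genomic", seed: int = 0
) -> np.ndarray:
    """Constrained Louvain refinement of a seeded partition.

    Repeated sweeps over the nodes (genomic order by default); each node moves
    to the existing community with the largest positive modularity gain. Stops
    when a full sweep makes no move. Q is non-decreasing across moves; a
    community may empty, but no new community is ever created.
    """
    labels = np.asarray(labels, dtype=int).copy()
    B = model.B
    n = B.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels length must match node count")
    k = int(labels.max()) + 1
    # community-affinity sums: S[i, c] = sum_j in c of B[i, j]
    S = np.zeros((n, k))
    for c in range(k):
        members = labels == c
        if members.any():
            S[:, c] = B[:, members].sum(axis=1)
    if order == "random":
        sweep = np.random.default_rng(seed).permutation(n)
    elif order == "genomic":
        sweep = np.arange(n)
    else:
        raise ValueError("order must be 'genomic' or 'random'")
    diag = np.diag(B)
    tol = 1e-12
    improved = True
    while improved:
        improved = False
        for i in sweep:
            c = labels[i]
            # gain of moving i from c to d; staying put gains 0
            gains = 2.0 * (S[i] - S[i, c] + diag[i])
            gains[c] = 0.0
            d = int(np.argmax(gains))
            if gains[d] > tol:
                S[:, c] -= B[:, i]
                S[:, d] += B[:, i]
                labels[i] = d
                improved = True
    return labels


def name_states(
    labels,
    es: EigenSystem,
    ranked,
    h3k27me3: SignalTrack = None,
    activity: SignalTrack = None,
    model: ModularityModel = None,
) -> CompartmentCall:
    """Name refined clusters A1/A2/B1/B2 and assemble the compartment call.

    Naming is independent of input cluster ids. If refinement left a number
    of clusters other than four, the extremes along EV1 are still named
    A1/B1 and the rest fall back to generic M1..Mj with a warning.
    """
    labels = np.asarray(labels, dtype=int)
    idx_pair = [t[0] if isinstance(t, (tuple, list)) else int(t) for t in ranked][:2]
    ev1 = es.vector_full(idx_pair[0])
    ev2 = es.vector_full(idx_pair[1])
    oriented = False
    if activity is not None:
        ev1 = _orient_by_track(ev1, activity)
        oriented = True
    if h3k27me3 is not None:
        ev2 = _orient_by_track(ev2, h3k27me3)

    valid_idx = es.valid_idx
    present = np.unique(labels)
    ev1_valid = ev1[valid_idx]
    means = {c: ev1_valid[labels == c].mean() for c in present}
    order = sorted(present, key=lambda c: means[c])
    naming = {}
    if len(present) == 4:
        naming[order[-1]] = "A1"
        naming[order[0]] = "B1"
        mid = order[1:3]
        if h3k27me3 is not None:
            t = h3k27me3.values[valid_idx]
            h3_means = {c: np.nanmean(t[labels == c]) for c in mid}
            b2 = max(mid, key=lambda c: h3_means[c])
        else:
            b2 = min(mid, key=lambda c: means[c])
        naming[b2] = "B2"
        naming[next(c for c in mid if c != b2)] = "A2"
        micro_oriented = h3k27me3 is not None
    else:
        log.warning("%d clusters after refinement; expected 4 — generic naming", len(present))
        naming[order[-1]] = "A1"
        if len(order) > 1:
            naming[order[0]] = "B1"
        for j, c in enumerate(order[1:-1], start=1):
            naming[c] = f"M{j}"
        micro_oriented = False

    states = np.array(["NA"] * es.binning.n_bins, dtype=object)
    states[valid_idx] = [naming[c] for c in labels]
    q = partition_modularity(model, labels) if model is not None else np.nan
    return CompartmentCall(
        binning=es.binning.copy(),
        states=states,
        ev1=ev1,
        ev2=ev2,
        q=q,
        k=len(present),
        metadata={"oriented": oriented, "micro_oriented": micro_oriented},
    )
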