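"""End-to-end compartment calling for a single chromosome.

Sequence: optional centromere-effect correction of the O/E matrix, symmetric
eigendecomposition, ranking of the top eigenvectors by sign-bipartition
modularity, eigenvalue-weighted k-means on the two best axes, constrained
Louvain refinement, and biological naming of the four states.
"""

from __future__ import annotations

import numpy as np

from . import clustering, eigen
from .clustering import CompartmentCall
from .eigen import ArmAnnotation
from .matrix_io import ContactMatrix, SignalTrack, observed_over_expected


def call_compartments(
    matrix: ContactMatrix,
    arms: ArmAnnotation = None,
    h3k27me3: SignalTrack = None,
    activity: SignalTrack = None,
    k: int = 4,
    seed: int = 7,
    n_top: int = 10,
    resolution: float = 1.0,
    louvain_order: str = "genomic",
    mask_missing_track_bins: bool = True,
) -> CompartmentCall:
    """Call compartmental states from an observed or O/E contact matrix.

    Parameters
    ----------
    matrix
        ``observed`` matrices are O/E-normalised first; ``oe`` matrices are
        used as given.
    arms
        Chromosome-arm layout; enables the centromere-effect correction.
    h3k27me3, activity
        Optional binned tracks used to orient EV2/EV1 and to tell A2 from B2.
    k
        Number of clusters (the four-state scheme assumes 4).
    seed
        Master seed for k-means restarts (and random-order Louvain sweeps).
    n_top
        How many top eigenvectors (by |eigenvalue|) are screened for arm bias
        and ranked by modularity.
    resolution
        Modularity resolution parameter r.
    """
    if matrix.kind == "observed":
        matrix = observed_over_expected(matrix)
    elif matrix.kind != "oe":
        raise ValueError("matrix must be observed or oe")

    if mask_missing_track_bins:
        # bins with missing track data are reported NA rather than guessed
        valid = matrix.binning.valid.copy()
        for track in (h3k27me3, activity):
            if track is not None:
                valid &= np.isfinite(track.values)
        if not valid.all():
            binning = matrix.binning.copy()
            binning.valid = valid
            matrix = ContactMatrix(binning, matrix.values, kind=matrix.kind)

    arm_bias = []
    if arms is not None:
        es0 = eigen.eigendecompose(matrix)
        arm_bias = [
            eigen.arm_bias_index(es0.vector_full(i), arms)
            for i in range(min(n_top, es0.n_valid))
        ]
        matrix = eigen.correct_centromere_effect(matrix, arms, n_top=n_top)

    es = eigen.eigendecompose(matrix)
    model = eigen.modularity_matrix(matrix, r=resolution)
    ranked = eigen.rank_eigenvectors_by_modularity(es, model, n_top=n_top)

    init = clustering.weighted_kmeans(es, ranked, k=k, seed=seed)
    refined = clustering.louvain_refine(model, init, order=louvain_order, seed=seed)
    call = clustering.name_states(
        refined, es, ranked, h3k27me3=h3k27me3, activity=activity, model=model
    )
    call.metadata.update(
        {
            "q_kmeans": eigen.partition_modularity(model, init),
            "q_ev": [(int(i), float(q)) for i, q in ranked],
            "arm_bias": [None if b is None else float(b) for b in arm_bias],
            "chosen_vectors": [int(ranked[0][0]), int(ranked[1][0])],
            "seed": int(seed),
            "k": int(k),
            "resolution": float(resolution),
        }
    )
    return call


def call_ab(
    matrix: ContactMatrix,
    arms: ArmAnnotation = None,
    activity: SignalTrack = None,
    n_top: int = 10,
):
    """Baseline A/B call from the sign of the leading principal component.

    The O/E matrix is mean-centred before decomposition (as PCA implies);
    without centring the leading eigenvector of a non-negative matrix is the
    one-signed coverage vector and carries no compartment signal.
    """
    if matrix.kind == "observed":
        matrix = observed_over_expected(matrix)
    if arms is not None:
        matrix = eigen.correct_centromere_effect(matrix, arms, n_top=n_top)
    sub_mean = float(matrix.valid_submatrix().mean())
    centred = ContactMatrix(matrix.binning.copy(), matrix.values - sub_mean, kind="oe")
    es = eigen.eigendecompose(centred)
    return clustering.ab_compartments(es, orientation_track=activity)
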