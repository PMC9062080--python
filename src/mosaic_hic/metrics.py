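"""Partition-quality metrics for comparing compartment schemes.

Silhouette (cosine distance) and the Calinski–Harabasz variance-ratio score
are computed with scikit-learn on the same eigenvalue-weighted (EV1, EV2)
coordinates the caller clusters on, so external label sets (e.g. from
subcompartment callers) can be scored in the identical feature space.
State-pair interaction summaries average the O/E or correlation matrix over
all between- and within-state bin pairs, excluding self pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .matrix_io import ContactMatrix


@dataclass
class PartitionScore:
    silhouette: float
    calinski_harabasz: float
    modularity: float


def silhouette_mean(features, labels, metric: str = "cosine") -> float:
    """Mean silhouette coefficient S_i = (b_i - a_i)/max(a_i, b_i), cosine
    distance by default. Singleton clusters score 0 (standard convention)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(features, labels, metric=metric))


def calinski_harabasz(features, labels) -> float:
    """Calinski–Harabasz score tr(B_k)/tr(W_k) * (n-k)/(k-1).

    Returns ``inf`` (flagged sentinel) when the within-cluster dispersion is
    exactly zero.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Calinski–Harabasz requires at least 2 clusters")
    tr_w = sum(
        ((features[labels == c] - features[labels == c].mean(axis=0)) ** 2).sum()
        for c in uniq
    )
    if tr_w == 0:
        return math.inf
    return float(calinski_harabasz_score(features, labels))


def state_interaction_summary(m: ContactMatrix, labels) -> pd.DataFrame:
    """Mean matrix value over bin pairs (i in state s, j in state t, i != j).

    ``labels`` is a state name per valid bin. The result is a symmetric
    state-by-state DataFrame; a diagonal entry for a state with fewer than 2
    bins is NaN.
    """
    if m.kind not in ("oe", "correlation"):
        raise ValueError("interaction summary expects an oe or correlation matrix")
    sub = m.valid_submatrix()
    labels = np.asarray(labels)
    if labels.shape[0] != sub.shape[0]:
        raise ValueError("labels must cover the valid bins of the matrix")
    states = sorted(np.unique(labels))
    out = pd.DataFrame(np.nan, index=states, columns=states, dtype=float)
    for a, s in enumerate(states):
        si = np.flatnonzero(labels == s)
        for t in states[a:]:
            ti = np.flatnonzero(labels == t)
            block = sub[np.ix_(si, ti)]
            if s == t:
                if len(si) < 2:
                    continue
                total = block.sum() - np.trace(block)
                mean = total / (len(si) * (len(si) - 1))
            else:
                mean = block.mean()
            out.loc[s, t] = out.loc[t, s] = float(mean)
    return out


def score_partition(features, labels, model=None) -> PartitionScore:
    """Bundle silhouette, Calinski–Harabasz and (optionally) modularity."""
    from .eigen import partition_modularity

    q = np.nan
    if model is not None:
        codes = pd.factorize(np.asarray(labels))[0]
        q = partition_modularity(model, codes)
    return PartitionScore(
        silhouette=silhouette_mean(features, labels),
        calinski_harabasz=calinski_harabasz(features, labels),
        modularity=q,
    )
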