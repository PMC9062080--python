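"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths (and where possible the libraries)
used by the implementation: modularity via the classical sum(e_cc - a_c^2)
community bookkeeping, silhouette via a brute-force double loop, and
Calinski-Harabasz via direct evaluation of the dispersion-matrix formula.
"""

import itertools

import numpy as np


def newman_modularity(adj: np.ndarray, labels) -> float:
    """Q = sum over communities of (e_cc - a_c^2), computed directly from the
    adjacency matrix: e_cc = within-community weight / 2m (both directions,
    diagonal included), a_c = community degree / 2m."""
    labels = np.asarray(labels)
    two_m = adj.sum()
    k = adj.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        members = labels == c
        e_cc = adj[np.ix_(members, members)].sum() / two_m
        a_c = k[members].sum() / two_m
        q += e_cc - a_c**2
    return float(q)


def all_bipartitions(n):
    """Every 2-labelling of n nodes with node 0 fixed in community 0."""
    for bits in itertools.product((0, 1), repeat=n - 1):
        yield np.array((0,) + bits)


def cosine_distance(u, v) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return 1.0 - float(np.dot(u, v) / (nu * nv))


def brute_silhouette(features, labels, distance=cosine_distance) -> float:
    """Mean silhouette by explicit double loops; singletons score 0."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a_i = np.mean([distance(features[i], features[j]) for j in same])
        b_i = min(
            np.mean([distance(features[i], features[j]) for j in range(n) if labels[j] == c])
            for c in np.unique(labels)
            if c != labels[i]
        )
        denom = max(a_i, b_i)
        scores.append(0.0 if denom == 0 else (b_i - a_i) / denom)
    return float(np.mean(scores))


def brute_calinski_harabasz(features, labels) -> float:
    """Direct evaluation of tr(B_k)/tr(W_k) * (n-k)/(k-1)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    centre = features.mean(axis=0)
    clusters = np.unique(labels)
    k = len(clusters)
    tr_b = tr_w = 0.0
    for c in clusters:
        pts = features[labels == c]
        c_q = pts.mean(axis=0)
        tr_b += len(pts) * float(((c_q - centre) ** 2).sum())
        tr_w += float(((pts - c_q) ** 2).sum())
    return tr_b / tr_w * (n - k) / (k - 1)


def two_pass_pearson(x, y) -> float:
    """Plain two-pass Pearson correlation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
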