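"""Independent brute-force oracles: naive loop implementations kept separate
from (and structurally unlike) the vectorized library code."""

import numpy as np


def dcor_naive(x, y):
    """Distance correlation by explicit double-loop double-centering."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = len(x)
    a = np.zeros((m, m))
    b = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            a[i, j] = abs(x[i] - x[j])
            b[i, j] = abs(y[i] - y[j])

    def center(d):
        out = np.zeros_like(d)
        grand = d.mean()
        for i in range(m):
            for j in range(m):
                out[i, j] = d[i, j] - d[i].mean() - d[:, j].mean() + grand
        return out

    A, B = center(a), center(b)
    dcov2 = sum(A[i, j] * B[i, j] for i in range(m) for j in range(m)) / m**2
    dvx = sum(A[i, j] ** 2 for i in range(m) for j in range(m)) / m**2
    dvy = sum(B[i, j] ** 2 for i in range(m) for j in range(m)) / m**2
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return np.sqrt(dcov2 / np.sqrt(dvx * dvy))


def tom_naive(adj):
    """TOM by explicit triple loop."""
    a = np.asarray(adj, float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    t = np.eye(n)
    k = [sum(a[i, u] for u in range(n) if u != i) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            t[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def silhouette_naive(diss, labels):
    """Textbook silhouette over non-zero labels; singleton clusters give 0."""
    d = np.asarray(diss, float)
    idx = [i for i in range(len(labels)) if labels[i] != 0]
    vals = []
    for i in idx:
        own = [j for j in idx if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([d[i, j] for j in own])
        bs = []
        for mod in sorted({labels[j] for j in idx if labels[j] != labels[i]}):
            mem = [j for j in idx if labels[j] == mod]
            bs.append(np.mean([d[i, j] for j in mem]))
        b = min(bs)
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


def dunn_naive(diss, labels):
    d = np.asarray(diss, float)
    idx = [i for i in range(len(labels)) if labels[i] != 0]
    inter = [d[i, j] for i in idx for j in idx if i < j and labels[i] != labels[j]]
    intra = [d[i, j] for i in idx for j in idx if i < j and labels[i] == labels[j]]
    return min(inter) / max(intra)


def mean_connectivity_naive(i, module, adj, labels):
    """Eq-style mean connectivity by explicit loop (literal denominator)."""
    a = np.asarray(adj, float)
    members = [j for j in range(len(labels)) if labels[j] == module]
    total = sum(a[i, j] for j in members if j != i)
    return total / len(members)
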