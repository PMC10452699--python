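"""Independent brute-force reference implementations used only by tests.

Deliberately naive (triple loops, exhaustive relaxation) so they share no
code path with the package.
"""

import numpy as np


def corr_two_pass(x):
    """Two-pass covariance/correlation of the columns of x, diagonal zeroed."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    means = [sum(x[:, j]) / n for j in range(p)]
    cov = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            cov[i, j] = sum((x[t, i] - means[i]) * (x[t, j] - means[j]) for t in range(n))
    out = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i != j:
                out[i, j] = cov[i, j] / np.sqrt(cov[i, i] * cov[j, j])
    return out


def floyd_warshall(a):
    """All-pairs shortest paths by exhaustive relaxation."""
    a = np.asarray(a)
    p = a.shape[0]
    dist = np.full((p, p), np.inf)
    for i in range(p):
        dist[i, i] = 0.0
        for j in range(p):
            if i != j and a[i, j]:
                dist[i, j] = 1.0
    for k in range(p):
        for i in range(p):
            for j in range(p):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def clustering_bruteforce(a):
    """Mean C_i by explicit triangle enumeration."""
    a = np.asarray(a)
    p = a.shape[0]
    cs = []
    for i in range(p):
        nb = [j for j in range(p) if a[i, j]]
        k = len(nb)
        if k < 2:
            cs.append(0.0)
            continue
        t = sum(1 for u in nb for v in nb if u < v and a[u, v])
        cs.append(2.0 * t / (k * (k - 1)))
    return sum(cs) / p


def global_efficiency_bruteforce(a):
    dist = floyd_warshall(a)
    p = len(dist)
    total = sum(1.0 / dist[i, j] for i in range(p) for j in range(p)
                if i != j and np.isfinite(dist[i, j]))
    return total / (p * (p - 1))


def path_length_bruteforce(a):
    dist = floyd_warshall(a)
    p = len(dist)
    finite = [dist[i, j] for i in range(p) for j in range(p)
              if i != j and np.isfinite(dist[i, j])]
    return sum(finite) / len(finite) if finite else 0.0


def local_efficiency_bruteforce(a):
    a = np.asarray(a)
    p = a.shape[0]
    total = 0.0
    for i in range(p):
        nb = [j for j in range(p) if a[i, j]]
        if len(nb) >= 2:
            sub = a[np.ix_(nb, nb)]
            total += global_efficiency_bruteforce(sub)
    return total / p


def random_binary_graph(rng, p, density=None):
    """Symmetric hollow 0/1 adjacency with random density."""
    density = rng.uniform(0.1, 0.9) if density is None else density
    upper = rng.random((p, p)) < density
    a = np.triu(upper, 1)
    return (a | a.T).astype(np.uint8)
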