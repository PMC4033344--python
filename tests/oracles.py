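"""Independent brute-force reference computations used to check the package.

Everything here is written as plainly as possible (explicit loops, the
general ``np.linalg.eig`` solver rather than the symmetric path) and never
calls into :mod:`gaitdiff` itself.
"""

import numpy as np


def pixel_stats(arrays):
    """Element-wise mean and population std over a list of 2-D arrays."""
    H, W = arrays[0].shape
    mean = np.zeros((H, W))
    for a in arrays:
        mean += a
    mean /= len(arrays)
    var = np.zeros((H, W))
    for a in arrays:
        var += (a - mean) ** 2
    var /= len(arrays)
    return mean, np.sqrt(var)


def xor_count(a, b):
    n = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            if a[i, j] != b[i, j]:
                n += 1
    return n


def twodpca_eig(stack):
    """Image covariance, eigenvalues and eigenvectors by the general solver.

    Returns (mean, C, eigenvalues descending, eigenvectors as columns).
    """
    M = stack.shape[0]
    mean = np.zeros(stack.shape[1:])
    for G in stack:
        mean += G
    mean /= M
    n = stack.shape[2]
    C = np.zeros((n, n))
    for G in stack:
        A = G - mean
        C += A.T @ A
    evals, evecs = np.linalg.eig(C)
    evals = evals.real
    evecs = evecs.real
    order = np.argsort(-evals)
    return mean, C, evals[order], evecs[:, order]


def feature_distance_ref(Ya, Yb):
    """Sum over columns of the Euclidean norms of the differences."""
    total = 0.0
    for k in range(Ya.shape[1]):
        total += float(np.sqrt(np.sum((Ya[:, k] - Yb[:, k]) ** 2)))
    return total


def reconstruct_ref(Y, W):
    """Truncated expansion sum_k Y_k W_k^T as an explicit loop of outers."""
    m, d = Y.shape
    n = W.shape[0]
    out = np.zeros((m, n))
    for k in range(d):
        out += np.outer(Y[:, k], W[:, k])
    return out


def flat_pca_eig(stack):
    """Classical PCA on flattened images: mean, covariance eig (descending)."""
    M = stack.shape[0]
    flat = np.array([G.ravel() for G in stack])
    mean = flat.mean(axis=0)
    centered = flat - mean
    C = np.zeros((flat.shape[1], flat.shape[1]))
    for v in centered:
        C += np.outer(v, v)
    evals, evecs = np.linalg.eig(C)
    evals = evals.real
    evecs = evecs.real
    order = np.argsort(-evals)
    return mean, evals[order], evecs[:, order]


def pairwise_rank1(features, labels, probe_features, probe_labels, dist):
    """Exhaustive nearest-neighbour accuracy from an explicit distance matrix."""
    hits = 0
    for P, pl in zip(probe_features, probe_labels):
        best, best_d = None, np.inf
        for F, gl in zip(features, labels):
            d = dist(P, F)
            if d < best_d:
                best, best_d = gl, d
        hits += best == pl
    return hits / len(probe_labels)
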