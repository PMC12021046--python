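"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles — explicit enumeration of
paths, flips and substrings — deliberately sharing no code with the package
implementation it checks.
"""

import itertools

import numpy as np


def genotype_dist_by_flips(a1: int, a2: int, lam: float) -> np.ndarray:
    """P(g | copied alleles a1, a2) by enumerating both miscopy events."""
    dist = np.zeros(3)
    for f1 in (0, 1):
        for f2 in (0, 1):
            b1 = a1 ^ f1
            b2 = a2 ^ f2
            p = (lam if f1 else 1 - lam) * (lam if f2 else 1 - lam)
            dist[b1 + b2] += p
    return dist


def _build_pair_model(alleles: np.ndarray, gl: np.ndarray, rho: np.ndarray,
                      lam: float):
    """Explicit state list, dense transition matrices, emissions and
    per-state genotype conditionals of the diploid copying model."""
    k, s = alleles.shape
    pairs = list(itertools.product(range(k), repeat=2))
    n_states = len(pairs)

    def hop(i, j, r):
        return (1 - r) * (i == j) + r / k

    trans = [np.array([[hop(pairs[a][0], pairs[b][0], rho[t])
                        * hop(pairs[a][1], pairs[b][1], rho[t])
                        for b in range(n_states)] for a in range(n_states)])
             for t in range(s - 1)]

    emit = np.empty((s, n_states))
    cond_g = np.empty((s, n_states, 3))
    for t in range(s):
        for zi, (z1, z2) in enumerate(pairs):
            pg = genotype_dist_by_flips(int(alleles[z1, t]), int(alleles[z2, t]), lam)
            joint = pg * gl[t]
            emit[t, zi] = joint.sum()
            cond_g[t, zi] = joint / joint.sum()
    return pairs, trans, emit, cond_g


def enumerate_diploid_posteriors(alleles: np.ndarray, gl: np.ndarray,
                                 rho: np.ndarray, lam: float):
    """Exhaustive path-sum posteriors of the diploid copying model.

    alleles: K x S reference haplotypes; gl: S x 3 genotype likelihoods;
    rho: S-1 switch probabilities.  Returns (state posterior S x K x K,
    genotype posterior S x 3).
    """
    k, s = alleles.shape
    pairs, trans, emit, cond_g = _build_pair_model(alleles, gl, rho, lam)
    n_states = len(pairs)

    paths = np.array(list(itertools.product(range(n_states), repeat=s)))
    w = np.full(paths.shape[0], 1.0 / n_states)
    for t in range(s):
        w *= emit[t, paths[:, t]]
    for t in range(s - 1):
        w *= trans[t][paths[:, t], paths[:, t + 1]]
    total = w.sum()

    state_post = np.zeros((s, k, k))
    gp = np.zeros((s, 3))
    for t in range(s):
        for zi, (z1, z2) in enumerate(pairs):
            mass = w[paths[:, t] == zi].sum()
            state_post[t, z1, z2] += mass
            gp[t] += mass * cond_g[t, zi]
    return state_post / total, gp / total


def dense_diploid_posteriors(alleles: np.ndarray, gl: np.ndarray,
                             rho: np.ndarray, lam: float):
    """Same posteriors via explicit dense-matrix forward–backward.

    The joint transition matrix over all K^2 ordered pairs is materialised
    and chained directly — no per-haplotype factorisation, no scaling trick —
    so this route is independent of the package's recursion.  Tractable to
    K = 4, S = 6 where full path enumeration is not.
    """
    k, s = alleles.shape
    pairs, trans, emit, cond_g = _build_pair_model(alleles, gl, rho, lam)
    n_states = len(pairs)

    fwd = np.empty((s, n_states))
    fwd[0] = emit[0] / n_states
    for t in range(1, s):
        fwd[t] = (fwd[t - 1] @ trans[t - 1]) * emit[t]
    bwd = np.empty((s, n_states))
    bwd[s - 1] = 1.0
    for t in range(s - 2, -1, -1):
        bwd[t] = trans[t] @ (emit[t + 1] * bwd[t + 1])

    state_post = np.zeros((s, k, k))
    gp = np.zeros((s, 3))
    for t in range(s):
        w = fwd[t] * bwd[t]
        w /= w.sum()
        for zi, (z1, z2) in enumerate(pairs):
            state_post[t, z1, z2] += w[zi]
            gp[t] += w[zi] * cond_g[t, zi]
    return state_post, gp


def pbwt_brute_force(alleles: np.ndarray):
    """Reversed-prefix sorting and divergence by direct comparison."""
    h, s = alleles.shape
    prefix_order = np.empty((s, h), dtype=int)
    divergence = np.empty((s, h), dtype=int)
    for t in range(s):
        keys = [tuple(alleles[i, t::-1]) for i in range(h)]
        order = sorted(range(h), key=lambda i: keys[i])  # stable: ties keep index order
        prefix_order[t] = order
        for rank in range(h):
            if rank == 0:
                divergence[t, 0] = t + 1
                continue
            a, b = order[rank - 1], order[rank]
            d = t + 1
            while d > 0 and alleles[a, d - 1] == alleles[b, d - 1]:
                d -= 1
            divergence[t, rank] = d
    return prefix_order, divergence


def longest_common_contiguous(alleles: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Per-haplotype longest matching substring length, O(H * S^2)."""
    h, s = alleles.shape
    best = np.zeros(h, dtype=int)
    for i in range(h):
        for start in range(s):
            length = 0
            for t in range(start, s):
                if alleles[i, t] == query[t]:
                    length += 1
                    best[i] = max(best[i], length)
                else:
                    break
    return best


def ridge_blup(k_mat: np.ndarray, y: np.ndarray, lam: float):
    """Closed-form GBLUP at fixed lambda by a dense solve.

    mu by GLS with V = K + lam I; blup = K (K + lam I)^-1 (y - mu).
    """
    n = y.size
    v = k_mat + lam * np.eye(n)
    v_inv = np.linalg.inv(v)
    ones = np.ones(n)
    mu = (ones @ v_inv @ y) / (ones @ v_inv @ ones)
    blup = k_mat @ v_inv @ (y - mu)
    return mu, blup
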