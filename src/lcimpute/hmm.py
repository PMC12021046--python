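"""Li–Stephens haplotype-copying forward–backward machinery.

Shared by round-1 imputation (diploid, genotype-likelihood emissions),
panel self-imputation (haploid) and round-2 refinement (diploid, hard-call
emissions).  The hidden state is the reference haplotype (pair) currently
being copied; transitions model recombination with per-interval switch
probability rho = 1 - exp(-4 Ne c d / K), a switch landing uniformly on the
K conditioning haplotypes; emissions allow each copied allele to be
miscopied with probability lambda.

All recursions are scaled per site, so likelihoods never underflow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["switch_probs", "genotype_given_pair", "diploid_forward_backward",
           "haploid_forward_backward", "class_masses", "genotype_posteriors"]


def switch_probs(positions: np.ndarray, ne: float, recomb_rate: float,
                 k: int) -> np.ndarray:
    """Per-interval switch probability between adjacent sites."""
    dist = np.diff(positions.astype(np.float64))
    return -np.expm1(-4.0 * ne * recomb_rate * dist / k)


def genotype_given_pair(miscopy: float) -> np.ndarray:
    """P(g | copied allele sum c) for c, g in {0, 1, 2}.

    Each of the two copied alleles flips independently with probability
    ``miscopy``; rows are the allele-sum class c of the state pair.
    """
    lam = miscopy
    q = 1.0 - lam
    return np.array([
        [q * q, 2 * lam * q, lam * lam],
        [lam * q, q * q + lam * lam, lam * q],
        [lam * lam, 2 * lam * q, q * q],
    ])


def diploid_forward_backward(alleles: np.ndarray, site_weights: np.ndarray,
                             rho: np.ndarray):
    """Posterior over ordered conditioning-haplotype pairs at every site.

    Parameters
    ----------
    alleles
        K x S conditioning haplotypes (0/1, no missing).
    site_weights
        S x 3 emission weight per allele-sum class c:
        w[s, c] = P(data at s | state pair of class c).
    rho
        S-1 switch probabilities.

    Returns
    -------
    posteriors : S x K x K arrays summing to 1 per site
    loglik : float
    """
    post, loglik = _fb_diploid(np.ascontiguousarray(alleles.astype(np.int8)),
                               np.ascontiguousarray(site_weights.astype(np.float64)),
                               np.ascontiguousarray(rho.astype(np.float64)))
    return post, float(loglik)


@njit(cache=True)
def _fb_diploid(alleles, site_weights, rho):  # pragma: no cover - jitted
    k, s = alleles.shape
    fwd = np.empty((s, k, k))
    scale = np.empty(s)

    # forward
    f = np.empty((k, k))
    total = 0.0
    for i in range(k):
        for j in range(k):
            f[i, j] = site_weights[0, alleles[i, 0] + alleles[j, 0]]
            total += f[i, j]
    scale[0] = total / (k * k)
    for i in range(k):
        for j in range(k):
            fwd[0, i, j] = f[i, j] / total
    g = np.empty((k, k))
    col = np.empty(k)
    row = np.empty(k)
    for t in range(1, s):
        stay = 1.0 - rho[t - 1]
        jump = rho[t - 1] / k
        # per-haplotype transition applied to each axis in turn
        for j in range(k):
            acc = 0.0
            for i in range(k):
                acc += fwd[t - 1, i, j]
            col[j] = acc
        for i in range(k):
            acc = 0.0
            for j in range(k):
                v = stay * fwd[t - 1, i, j] + jump * col[j]
                g[i, j] = v
                acc += v
            row[i] = acc
        total = 0.0
        for i in range(k):
            for j in range(k):
                v = (stay * g[i, j] + jump * row[i]) \
                    * site_weights[t, alleles[i, t] + alleles[j, t]]
                f[i, j] = v
                total += v
        scale[t] = total
        for i in range(k):
            for j in range(k):
                fwd[t, i, j] = f[i, j] / total

    # backward, combining into posteriors in place
    post = np.empty((s, k, k))
    b = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            post[s - 1, i, j] = fwd[s - 1, i, j]
    eb = np.empty((k, k))
    for t in range(s - 2, -1, -1):
        stay = 1.0 - rho[t]
        jump = rho[t] / k
        for i in range(k):
            for j in range(k):
                eb[i, j] = site_weights[t + 1, alleles[i, t + 1] + alleles[j, t + 1]] \
                    * b[i, j]
        for j in range(k):
            acc = 0.0
            for i in range(k):
                acc += eb[i, j]
            col[j] = acc
        for i in range(k):
            acc = 0.0
            for j in range(k):
                v = stay * eb[i, j] + jump * col[j]
                g[i, j] = v
                acc += v
            row[i] = acc
        bmax = 0.0
        for i in range(k):
            for j in range(k):
                v = stay * g[i, j] + jump * row[i]
                b[i, j] = v
                if v > bmax:
                    bmax = v
        total = 0.0
        for i in range(k):
            for j in range(k):
                b[i, j] /= bmax
                v = fwd[t, i, j] * b[i, j]
                post[t, i, j] = v
                total += v
        for i in range(k):
            for j in range(k):
                post[t, i, j] /= total

    loglik = 0.0
    for t in range(s):
        loglik += np.log(scale[t])
    return post, loglik


def class_masses(post: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Posterior mass per copied-allele-sum class at every site.

    ``post`` is S x K x K; ``alleles`` K x S.  Returns S x 3 masses over
    classes {0, 1, 2}, exploiting that the emission depends on the state
    pair only through its allele sum.
    """
    a = alleles.T.astype(np.float64)                   # (S, K)
    v = np.matmul(post, a[:, :, None])[:, :, 0]        # (S, K): P_s a
    c1 = v.sum(axis=1)                                 # 1' P a
    m11 = (a * v).sum(axis=1)                          # a' P a
    r1 = (a * post.sum(axis=2)).sum(axis=1)            # a' P 1
    return np.stack([1.0 - r1 - c1 + m11, r1 + c1 - 2.0 * m11, m11], axis=1)


def genotype_posteriors(post: np.ndarray, alleles: np.ndarray,
                        reweight: np.ndarray) -> np.ndarray:
    """Genotype posterior at every site from the state posteriors.

    ``reweight[s, c, g]`` is the genotype distribution given allele-sum
    class c at site s (P(g | c) times the site's genotype likelihood,
    renormalised, when read data informs the site).  Returns S x 3.
    """
    mass = class_masses(post, alleles)
    gp = np.einsum("sc,scg->sg", mass, reweight)
    return gp / gp.sum(axis=1, keepdims=True)


def haploid_forward_backward(ref: np.ndarray, emit: np.ndarray,
                             rho: np.ndarray) -> np.ndarray:
    """Posterior over K copied haplotypes for a single query haplotype.

    ``emit`` is a K x S emission table (already encodes match/mismatch and
    missing-site handling); returns the S x K posterior.
    """
    k, s = ref.shape
    fwd = np.empty((s, k))
    f = emit[:, 0] / k
    fwd[0] = f / f.sum()
    for t in range(1, s):
        r = rho[t - 1]
        f = (1.0 - r) * fwd[t - 1] + r / k
        f = f * emit[:, t]
        fwd[t] = f / f.sum()
    post = np.empty((s, k))
    b = np.ones(k)
    post[s - 1] = fwd[s - 1]
    for t in range(s - 2, -1, -1):
        eb = emit[:, t + 1] * b
        r = rho[t]
        b = (1.0 - r) * eb + r * eb.mean()
        b /= b.max()
        p = fwd[t] * b
        post[t] = p / p.sum()
    return post
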