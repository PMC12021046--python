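"""Reference-panel self-imputation.

Before round 2 the panel must be complete: every missing allele is filled by
a haploid Li–Stephens forward–backward of the incomplete haplotype against
all other panel haplotypes (leave-one-out, against the *original* panel so
the result does not depend on processing order).  Observed alleles are never
altered.
"""

from __future__ import annotations

import logging

import numpy as np

from .hmm import haploid_forward_backward, switch_probs
from .types import MISSING, HaplotypePanel

logger = logging.getLogger(__name__)


def self_impute_panel(panel: HaplotypePanel, params) -> HaplotypePanel:
    """Fill every MISSING panel entry; idempotent on complete panels.

    ``params`` supplies ne, recomb_rate and miscopy_rate (an
    :class:`~lcimpute.phase1.HMMParams` works).  A site missing in all
    haplotypes is uninferable and raises.
    """
    if not panel.has_missing:
        return panel
    obs_per_site = (panel.alleles != MISSING).sum(axis=0)
    if (obs_per_site == 0).any():
        raise ValueError("site(s) missing in every haplotype cannot be self-imputed")
    if (obs_per_site < 2).any():
        raise ValueError("self-imputation requires >= 2 observed alleles per site")

    h, s = panel.alleles.shape
    lam = params.miscopy_rate
    out = panel.alleles.copy()
    k = h - 1
    rho = switch_probs(panel.positions, params.ne, params.recomb_rate, k)
    n_filled = 0
    for i in np.flatnonzero((panel.alleles == MISSING).any(axis=1)):
        others = np.delete(np.arange(h), i)
        ref = panel.alleles[others]                      # (k, s), may hold MISSING
        query = panel.alleles[i]
        miss_q = query == MISSING
        # emission: match 1-lam / mismatch lam where both alleles observed,
        # flat where either the query or the reference row is missing
        ref_obs = ref != MISSING
        match = (ref == query[None, :]) & ref_obs & ~miss_q[None, :]
        mismatch = (ref != query[None, :]) & ref_obs & ~miss_q[None, :]
        emit = np.ones((k, s))
        emit[match] = 1.0 - lam
        emit[mismatch] = lam
        post = haploid_forward_backward(ref, emit, rho)   # (s, k)
        for t in np.flatnonzero(miss_q):
            col = ref[:, t]
            col_obs = col != MISSING
            w = post[t] * col_obs
            p1 = lam + (1.0 - 2.0 * lam) * float(w @ (col == 1)) / w.sum()
            out[i, t] = 1 if p1 > 0.5 else 0
            n_filled += 1
    logger.info("self-imputation filled %d missing alleles", n_filled)
    return HaplotypePanel(chrom=panel.chrom, positions=panel.positions.copy(),
                          alleles=out, hap_ids=list(panel.hap_ids))
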