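"""Round-2 imputation: IBS-conditioned refinement over the complete panel.

Round 1 leaves a set of confidently typed sites per sample.  Round 2 phases
those hard calls into two query haplotypes (reusing the copying states the
round-1 HMM already computed), finds for each query haplotype the reference
haplotypes sharing the longest identical-by-state (IBS) segments at the
typed sites, runs a diploid copying HMM over the typed sites only with those
haplotypes as conditioning states, and interpolates the state posterior in
physical distance to every untyped panel site.  Typed sites keep their
round-1 posteriors; every panel site receives a call (recovery = 100%).

The positional Burrows–Wheeler transform (PBWT) index over the typed sites
is the classic sublinear structure for these long-match queries; it is built
here by the standard prefix/divergence recursion.  The match search itself
is a vectorised contiguous-run scan, which returns the same top-L set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hmm import (class_masses, diploid_forward_backward, genotype_given_pair,
                  switch_probs)
from .types import HaplotypePanel, PosteriorGenotypes, finalize_posteriors

logger = logging.getLogger(__name__)

#: Default conditioning haplotypes per query haplotype.
DEFAULT_L = 48


@dataclass
class PBWTIndex:
    """Positional Burrows–Wheeler transform of a panel at a site subset.

    ``prefix_order[s]`` sorts haplotypes by their reversed prefix ending at
    (typed) site s; ``divergence[s][i]`` is the first site at which
    ``prefix_order[s][i]`` and ``prefix_order[s][i-1]`` agree through s
    (s + 1 if they differ at s itself; index 0 carries the sentinel s + 1).
    """

    prefix_order: np.ndarray   # (S_typed, H) int32
    divergence: np.ndarray     # (S_typed, H) int32
    alleles: np.ndarray        # (H, S_typed) the indexed alleles
    site_subset: np.ndarray    # global panel-site indices


def build_pbwt(panel: HaplotypePanel, site_subset: np.ndarray) -> PBWTIndex:
    """Prefix/divergence construction, left to right over the typed sites."""
    site_subset = np.asarray(site_subset, dtype=np.int64)
    if site_subset.size == 0:
        raise ValueError("cannot build a PBWT over an empty typed set")
    alleles = panel.alleles[:, site_subset]
    if (alleles < 0).any():
        raise ValueError("panel must be complete at the typed sites")
    h, s = alleles.shape
    prefix_order = np.empty((s, h), dtype=np.int32)
    divergence = np.empty((s, h), dtype=np.int32)
    ppa = list(range(h))
    div = [0] * h
    for t in range(s):
        a, b, da, db = [], [], [], []
        p = q = t + 1
        for hap, d in zip(ppa, div):
            p = max(p, d)
            q = max(q, d)
            if alleles[hap, t] == 0:
                a.append(hap)
                da.append(p)
                p = 0
            else:
                b.append(hap)
                db.append(q)
                q = 0
        ppa = a + b
        div = da + db
        prefix_order[t] = ppa
        divergence[t] = div
    return PBWTIndex(prefix_order=prefix_order, divergence=divergence,
                     alleles=alleles, site_subset=site_subset)


def _longest_run_lengths(alleles: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Per-haplotype length of the longest contiguous IBS run with the query."""
    eq = alleles == query[None, :]
    h, s = eq.shape
    run = np.zeros(h, dtype=np.int64)
    best = np.zeros(h, dtype=np.int64)
    for t in range(s):
        run = (run + 1) * eq[:, t]
        np.maximum(best, run, out=best)
    return best


def longest_ibs_matches(index: PBWTIndex, query_hap: np.ndarray,
                        L: int) -> list[tuple[int, int]]:
    """The L haplotypes with the longest IBS match to a query at typed sites.

    Ties break by lower haplotype index.  Returns (haplotype, match length)
    pairs, longest first.
    """
    best = _longest_run_lengths(index.alleles, np.asarray(query_hap))
    h = best.size
    order = np.lexsort((np.arange(h), -best))
    top = order[:min(L, h)]
    return [(int(i), int(best[i])) for i in top]


def _phase_typed(panel: HaplotypePanel, gt_row: np.ndarray, pair_row: np.ndarray,
                 t_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split typed-site hard calls into two query haplotypes.

    Homozygotes are trivially phased.  A heterozygote is oriented by the
    alleles of the round-1 argmax copied pair; when those agree (the state
    cannot resolve the phase) the alt allele goes to the second haplotype.
    """
    q1 = np.empty(t_idx.size, dtype=np.int8)
    q2 = np.empty(t_idx.size, dtype=np.int8)
    for j, t in enumerate(t_idx):
        g = gt_row[t]
        if g == 0:
            q1[j] = q2[j] = 0
        elif g == 2:
            q1[j] = q2[j] = 1
        else:
            z1, z2 = pair_row[t]
            a1 = panel.alleles[z1, t] if z1 >= 0 else 0
            a2 = panel.alleles[z2, t] if z2 >= 0 else 0
            if a1 != a2:
                q1[j], q2[j] = a1, a2
            else:
                q1[j], q2[j] = 0, 1
    return q1, q2


def impute_round2(panel_complete: HaplotypePanel, round1: PosteriorGenotypes,
                  params, L: int = DEFAULT_L) -> PosteriorGenotypes:
    """Refine round-1 posteriors to cover every panel site.

    ``params`` is the round-1 :class:`~lcimpute.phase1.HMMParams`; its
    ``genotype_error`` is the typed-site emission error, ``miscopy_rate``
    the allele-copy error at untyped sites.
    """
    if panel_complete.has_missing:
        raise ValueError("round 2 requires a self-imputed (complete) panel")
    n, s = round1.gp.shape[:2]
    positions = panel_complete.positions
    gp_out = round1.gp.copy()
    eta = params.genotype_error
    pg_c = genotype_given_pair(params.miscopy_rate)

    for i in range(n):
        typed = round1.confident[i]
        t_idx = np.flatnonzero(typed)
        if t_idx.size == 0:
            logger.warning("sample %s has no typed sites; keeping round-1 posteriors",
                           round1.sample_ids[i])
            continue
        u_idx = np.flatnonzero(~typed)
        pair_row = (round1.state_cache[i]["pair"] if round1.state_cache
                    else np.full((s, 2), -1, dtype=np.int32))
        q1, q2 = _phase_typed(panel_complete, round1.gt[i], pair_row, t_idx)

        typed_alleles = panel_complete.alleles[:, t_idx]
        cand = set()
        for q in (q1, q2):
            best = _longest_run_lengths(typed_alleles, q)
            order = np.lexsort((np.arange(best.size), -best))
            cand.update(int(x) for x in order[:min(L, best.size)])
        cond = np.array(sorted(cand), dtype=np.int64)
        if cond.size < 2:
            cond = np.unique(np.concatenate([cond, [0, 1]]))[:2]
        kc = cond.size

        sub = typed_alleles[cond]                       # (kc, S_typed)
        # typed-site emission: observed hard call vs copied allele sum,
        # with symmetric genotype error eta
        g_obs = round1.gt[i, t_idx]
        w = np.full((t_idx.size, 3), eta / 2.0)
        w[np.arange(t_idx.size), g_obs] = 1.0 - eta
        rho = switch_probs(positions[t_idx], params.ne, params.recomb_rate, kc)
        post, _ = diploid_forward_backward(sub, w, rho)  # (S_typed, kc, kc)

        if u_idx.size:
            # linear interpolation of the state posterior in bp distance;
            # class masses are linear in the posterior, so interpolate those
            right = np.searchsorted(positions[t_idx], positions[u_idx])
            left = right - 1
            left_c = np.clip(left, 0, t_idx.size - 1)
            right_c = np.clip(right, 0, t_idx.size - 1)
            pos_l = positions[t_idx][left_c].astype(np.float64)
            pos_r = positions[t_idx][right_c].astype(np.float64)
            pu = positions[u_idx].astype(np.float64)
            with np.errstate(invalid="ignore", divide="ignore"):
                wl = np.where(pos_r > pos_l, (pos_r - pu) / (pos_r - pos_l), 1.0)
            wl[left < 0] = 0.0                  # before the first typed site
            wl[right >= t_idx.size] = 1.0       # past the last typed site
            cond_alleles = panel_complete.alleles[cond][:, u_idx]
            for lo in range(0, u_idx.size, 512):
                sl = slice(lo, min(lo + 512, u_idx.size))
                a_chunk = cond_alleles[:, sl]
                mass = (wl[sl, None] * class_masses(post[left_c[sl]], a_chunk)
                        + (1.0 - wl[sl, None]) * class_masses(post[right_c[sl]], a_chunk))
                gp_u = mass @ pg_c
                gp_out[i, u_idx[sl]] = gp_u / gp_u.sum(axis=1, keepdims=True)

    return finalize_posteriors(round1.sample_ids, gp_out,
                               confident=np.ones((n, s), dtype=bool))
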