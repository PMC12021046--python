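"""Round-1 imputation: diploid haplotype-copying HMM over genotype likelihoods.

The chromosome is chunked into windows with flanking buffers; each window is
imputed independently against K conditioning haplotypes chosen per sample by
read agreement, and windows are ligated by taking every site from the window
in which it lies deepest (furthest from a window edge).  A confidence mask
then selects the "successfully imputed" sites that seed round 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hmm import (diploid_forward_backward, genotype_given_pair,
                  genotype_posteriors, switch_probs)
from .types import (GenotypeLikelihoods, HaplotypePanel, PosteriorGenotypes,
                    RegionSpec, SiteReadCounts, finalize_posteriors)

logger = logging.getLogger(__name__)

#: Default posterior threshold for a "successfully imputed" call.
DEFAULT_TAU = 0.90


@dataclass
class HMMParams:
    """Copying-model and chunking parameters.

    Defaults: K = 48 conditioning haplotypes, Ne = 10,000, recombination
    rate 1e-8 per bp, miscopy 1e-3, 2 Mb windows with 200 kb buffers.
    """

    n_states: int = 48
    ne: float = 10_000.0
    recomb_rate: float = 1e-8
    miscopy_rate: float = 1e-3
    window_bp: int = 2_000_000
    buffer_bp: int = 200_000
    genotype_error: float = 1e-3   # round-2 emission error at typed sites

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("need at least two conditioning haplotypes")
        if self.window_bp <= 2 * self.buffer_bp:
            raise ValueError("window_bp must exceed 2 * buffer_bp")


@dataclass
class WindowPosteriors:
    """Window-local posteriors plus the state bookkeeping round 2 reuses."""

    region: RegionSpec
    site_idx: np.ndarray           # global panel-site indices in this window
    positions: np.ndarray          # bp positions of those sites
    gp: np.ndarray                 # (N, s, 3)
    pair: np.ndarray               # (N, s, 2) argmax ordered state pair
    cond: list[np.ndarray] = field(default_factory=list)  # per-sample hap indices


def select_conditioning_haps(panel: HaplotypePanel, gl: GenotypeLikelihoods,
                             sample: int, k: int) -> np.ndarray:
    """The K panel haplotypes best agreeing with a sample's read evidence.

    Agreement of haplotype h is the summed likelihood, over read-informative
    sites, of the homozygous genotype matching h's allele.  Deterministic;
    ties break toward the lower haplotype index.
    """
    h = panel.n_haplotypes
    if k > h:
        raise ValueError("K cannot exceed the panel haplotype count")
    if k == h:
        return np.arange(h)
    info = gl.informative[sample]
    if not info.any():
        logger.warning("sample %d has no covered sites; using the first %d haplotypes",
                       sample, k)
        return np.arange(k)
    a = panel.alleles[:, info].astype(np.float64)
    g0 = gl.gl[sample, info, 0]
    g2 = gl.gl[sample, info, 2]
    score = a @ g2 + (1.0 - a) @ g0
    order = np.argsort(-score, kind="stable")
    return np.sort(order[:k])


def impute_window(panel: HaplotypePanel, gl: GenotypeLikelihoods,
                  params: HMMParams, region: RegionSpec) -> WindowPosteriors:
    """Forward–backward over ordered conditioning-haplotype pairs in one window."""
    if panel.has_missing:
        raise ValueError("round-1 imputation requires a complete panel "
                         "(run panel self-imputation first)")
    in_win = (panel.positions >= region.start) & (panel.positions <= region.end)
    site_idx = np.flatnonzero(in_win)
    n = gl.gl.shape[0]
    if site_idx.size == 0:
        logger.warning("window %s:%d-%d contains no panel sites",
                       region.chrom, region.start, region.end)
        return WindowPosteriors(region=region, site_idx=site_idx,
                                positions=np.empty(0, dtype=np.int64),
                                gp=np.empty((n, 0, 3)),
                                pair=np.empty((n, 0, 2), dtype=np.int16))

    pos = panel.positions[site_idx]
    k = min(params.n_states, panel.n_haplotypes)
    pg_c = genotype_given_pair(params.miscopy_rate)
    s = site_idx.size
    gp = np.empty((n, s, 3))
    pair = np.empty((n, s, 2), dtype=np.int16)
    cond: list[np.ndarray] = []
    rho = switch_probs(pos, params.ne, params.recomb_rate, k)

    for i in range(n):
        haps = select_conditioning_haps(panel, gl, i, k)
        cond.append(haps)
        sub = panel.alleles[haps][:, site_idx]
        gl_i = gl.gl[i, site_idx]                      # (s, 3)
        w = gl_i @ pg_c.T                              # (s, 3) per-class weights
        post, _ = diploid_forward_backward(sub, w, rho)
        # genotype posterior: P(g | class c) reweighted by the site's gl
        rw = pg_c[None, :, :] * gl_i[:, None, :]       # (s, class, g)
        rw /= rw.sum(axis=2, keepdims=True)
        gp[i] = genotype_posteriors(post, sub, rw)
        flat = post.reshape(s, -1).argmax(axis=1)
        pair[i, :, 0], pair[i, :, 1] = np.divmod(flat, k)
    return WindowPosteriors(region=region, site_idx=site_idx, positions=pos,
                            gp=gp, pair=pair, cond=cond)


def chunk_region(region: RegionSpec, params: HMMParams) -> list[RegionSpec]:
    """Tile a region into windows whose adjacent overlap is 2 * buffer_bp."""
    step = params.window_bp - 2 * params.buffer_bp
    windows = []
    start = region.start
    while True:
        end = min(start + params.window_bp - 1, region.end)
        windows.append(RegionSpec(region.chrom, start, end))
        if end >= region.end:
            break
        start += step
    return windows


def ligate(windows: list[WindowPosteriors], sample_ids: list[str],
           n_sites: int) -> PosteriorGenotypes:
    """Merge window-local posteriors, taking each site from its deepest window.

    For a site covered by several windows, the window in which the site is
    furthest from a window edge wins (its core region).  Every panel site
    must be covered; a coverage gap is a hard error listing the gap.
    """
    if not windows:
        raise ValueError("no windows to ligate")
    n = windows[0].gp.shape[0]
    gp = np.full((n, n_sites, 3), np.nan)
    # copied-haplotype pair per (sample, site), as global panel hap indices
    pair = np.full((n, n_sites, 2), -1, dtype=np.int32)
    best = np.full(n_sites, -1, dtype=np.int64)
    for w in windows:
        if w.site_idx.size == 0:
            continue
        margin = np.minimum(w.positions - w.region.start, w.region.end - w.positions)
        take = margin > best[w.site_idx]
        idx = w.site_idx[take]
        best[idx] = margin[take]
        src = np.flatnonzero(take)
        gp[:, idx] = w.gp[:, src]
        for i in range(n):
            pair[i, idx] = w.cond[i][w.pair[i, src]]
    uncovered = np.flatnonzero(best < 0)
    if uncovered.size:
        raise ValueError(f"ligation gap: panel site indices {uncovered[:10].tolist()} "
                         "are covered by no window")
    cache = [{"pair": pair[i]} for i in range(n)]
    return finalize_posteriors(sample_ids, gp, state_cache=cache)


def select_confident(post: PosteriorGenotypes, counts: SiteReadCounts,
                     tau: float = DEFAULT_TAU) -> PosteriorGenotypes:
    """Mark calls with posterior max >= tau as confidently imputed.

    A site with no read in any sample is dropped from every sample's typed
    set regardless of its posterior: with zero evidence anywhere the call is
    pure prior and cannot anchor round 2.
    """
    if not 0.5 < tau < 1.0:
        raise ValueError("tau must lie in (0.5, 1)")
    confident = post.gp.max(axis=2) >= tau
    covered_anywhere = counts.total.sum(axis=0) > 0
    confident &= covered_anywhere[None, :]
    return PosteriorGenotypes(sample_ids=post.sample_ids, gp=post.gp, ds=post.ds,
                              gt=post.gt, confident=confident,
                              state_cache=post.state_cache)


def impute_round1(panel: HaplotypePanel, gl: GenotypeLikelihoods,
                  counts: SiteReadCounts, params: HMMParams,
                  sample_ids: list[str] | None = None,
                  tau: float = DEFAULT_TAU) -> PosteriorGenotypes:
    """Chunk, impute, ligate and confidence-mask in one call."""
    if sample_ids is None:
        sample_ids = [f"ind{i}" for i in range(gl.gl.shape[0])]
    region = RegionSpec(panel.chrom, int(panel.positions[0]), int(panel.positions[-1]))
    results = []
    for win in chunk_region(region, params):
        logger.info("imputing window %s:%d-%d", win.chrom, win.start, win.end)
        results.append(impute_window(panel, gl, params, win))
    post = ligate(results, sample_ids, panel.n_sites)
    return select_confident(post, counts, tau)
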