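"""Read-evidence simulation for ultra-low-coverage sequencing.

Per (sample, site) cell the read count is Poisson(depth); each read reports
the alternate allele with probability p_g = (g/2)(1-eps) + (1-g/2) eps for
true genotype g and per-base error eps.  Down-sampling is binomial thinning,
so a 0.5x experiment thinned to 0.1x is distributed exactly like a fresh
0.1x experiment — the property the repeated down-sampling protocol relies on.
"""

from __future__ import annotations

import numpy as np

from ._rng import substream
from .types import DiploidTruth, GenotypeLikelihoods, SiteReadCounts

#: Default per-base error (~Q30).
DEFAULT_ERROR_RATE = 0.001


def _p_alt(g: np.ndarray, error_rate: float) -> np.ndarray:
    return (g / 2.0) * (1.0 - error_rate) + (1.0 - g / 2.0) * error_rate


def simulate_reads(truth: DiploidTruth, depth: float,
                   error_rate: float = DEFAULT_ERROR_RATE,
                   seed: int = 0) -> SiteReadCounts:
    """Simulate per-site read counts at a nominal fold-coverage."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = substream(seed, "reads")
    total = rng.poisson(depth, size=truth.genotypes.shape)
    p = _p_alt(truth.genotypes.astype(np.float64), error_rate)
    alt = rng.binomial(total, p)
    return SiteReadCounts(ref_count=(total - alt), alt_count=alt,
                          nominal_depth=float(depth), error_rate=float(error_rate))


def downsample_counts(counts: SiteReadCounts, target_depth: float,
                      seed: int = 0) -> SiteReadCounts:
    """Binomially thin reads to a lower target coverage.

    Different seeds give independent thinning replicates of the same parent
    experiment.
    """
    if target_depth > counts.nominal_depth:
        raise ValueError("target_depth cannot exceed the nominal depth")
    if target_depth == counts.nominal_depth:
        return counts
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    rng = substream(seed, "thin")
    keep = target_depth / counts.nominal_depth
    ref = rng.binomial(counts.ref_count, keep)
    alt = rng.binomial(counts.alt_count, keep)
    return SiteReadCounts(ref_count=ref, alt_count=alt,
                          nominal_depth=float(target_depth),
                          error_rate=counts.error_rate)


def genotype_likelihoods(counts: SiteReadCounts) -> GenotypeLikelihoods:
    """Binomial read-model likelihood triplets, normalised to max 1 per cell.

    Cells without reads get the flat triplet (1, 1, 1): no information.
    Computed in log space so deep cells cannot underflow.
    """
    eps = counts.error_rate
    ref = counts.ref_count[..., None].astype(np.float64)
    alt = counts.alt_count[..., None].astype(np.float64)
    p = _p_alt(np.array([0.0, 1.0, 2.0]), eps)  # (3,)
    with np.errstate(divide="ignore", invalid="ignore"):
        loggl = alt * np.log(p) + ref * np.log1p(-p)
        # eps == 0 makes p exactly 0 or 1; 0 * log(0) is a legitimate 0 there
        loggl = np.where((alt == 0) & np.isneginf(np.log(p)), ref * np.log1p(-p), loggl)
        loggl = np.where((ref == 0) & np.isneginf(np.log1p(-p)), alt * np.log(p), loggl)
    loggl -= loggl.max(axis=2, keepdims=True)
    gl = np.exp(loggl)
    # guard: zero likelihoods (impossible genotypes at eps=0) -> tiny positive
    gl = np.maximum(gl, 1e-300)
    return GenotypeLikelihoods(gl=gl)
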