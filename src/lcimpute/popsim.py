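"""Synthetic haplotype panels and test individuals.

The generator is a mosaic-copying model, not a coalescent: founder
haplotypes are drawn site-wise from a 1/f allele-frequency spectrum, and
every later haplotype is a recombinant mosaic of the haplotypes generated
before it, with per-site mutation.  This produces the block-wise linkage
disequilibrium that haplotype-copying imputation exploits, at desk scale.
"""

from __future__ import annotations

import logging

import numpy as np

from ._rng import substream
from .types import MISSING, DiploidTruth, HaplotypePanel

logger = logging.getLogger(__name__)

_FREQ_LO, _FREQ_HI = 0.01, 0.99


def _founder_frequencies(rng: np.random.Generator, n_sites: int) -> np.ndarray:
    """Per-site allele frequencies from a 1/f spectrum truncated to [0.01, 0.99].

    Inverse-CDF sampling: density ∝ 1/f on [lo, hi] gives f = lo·(hi/lo)^u.
    """
    u = rng.random(n_sites)
    return _FREQ_LO * (_FREQ_HI / _FREQ_LO) ** u


def _mosaic_templates(rng: np.random.Generator, n_source: int, positions: np.ndarray,
                      recomb_rate: float) -> np.ndarray:
    """Template index per site for one mosaic haplotype copied from n_source rows.

    Between adjacent sites the copied template switches with probability
    1 − exp(−recomb_rate · distance); a switch lands uniformly on the sources.
    """
    s = positions.size
    tmpl = np.empty(s, dtype=np.int64)
    tmpl[0] = rng.integers(n_source)
    if s > 1:
        dist = np.diff(positions).astype(float)
        p_switch = -np.expm1(-recomb_rate * dist)
        switches = rng.random(s - 1) < p_switch
        draws = rng.integers(n_source, size=s - 1)
        cur = tmpl[0]
        for i in range(s - 1):
            if switches[i]:
                cur = draws[i]
            tmpl[i + 1] = cur
    return tmpl


def simulate_panel(n_hap: int, n_sites: int, region_len: int, founder_count: int = 20,
                   recomb_rate: float = 1e-6, mut_rate: float = 1e-4,
                   seed: int = 0, chrom: str = "1") -> HaplotypePanel:
    """Simulate a phased biallelic reference panel with LD.

    Parameters
    ----------
    n_hap
        Total haplotypes H (founders + mosaics).
    n_sites
        Number of polymorphic sites S.
    region_len
        Length of the simulated region in bp; positions are drawn uniformly.
    founder_count
        Number of independent founder haplotypes; the remaining
        ``n_hap - founder_count`` rows are recombinant mosaics.
    recomb_rate
        Per-bp probability rate of template switching in mosaics.
    mut_rate
        Per-site allele flip probability in mosaics.
    """
    if n_hap < 2 or n_sites < 1 or region_len < n_sites:
        raise ValueError("non-positive or inconsistent panel dimensions")
    if not 2 <= founder_count <= n_hap:
        raise ValueError("need n_hap >= founder_count >= 2")
    rng = substream(seed, "panel")

    positions = np.sort(rng.choice(region_len, size=n_sites, replace=False)) + 1

    freqs = _founder_frequencies(rng, n_sites)
    alleles = np.zeros((n_hap, n_sites), dtype=np.int8)
    alleles[:founder_count] = rng.random((founder_count, n_sites)) < freqs

    # Record how each mosaic row copies, so monomorphic sites can be
    # resampled at the founders and re-propagated deterministically.
    templates = np.empty((n_hap, n_sites), dtype=np.int64)
    templates[:founder_count] = np.arange(founder_count)[:, None]
    flips = np.zeros((n_hap, n_sites), dtype=bool)
    for h in range(founder_count, n_hap):
        templates[h] = _mosaic_templates(rng, h, positions, recomb_rate)
        flips[h] = rng.random(n_sites) < mut_rate
        alleles[h] = alleles[templates[h], np.arange(n_sites)] ^ flips[h]

    # Resample monomorphic columns: redraw founder alleles and re-propagate
    # through the recorded copying structure until the site is polymorphic.
    for _ in range(1000):
        mono = np.flatnonzero(alleles.min(axis=0) == alleles.max(axis=0))
        if mono.size == 0:
            break
        for s in mono:
            alleles[:founder_count, s] = rng.random(founder_count) < freqs[s]
            for h in range(founder_count, n_hap):
                alleles[h, s] = alleles[templates[h, s], s] ^ flips[h, s]
    else:  # pragma: no cover - would need pathological parameters
        raise RuntimeError("could not make every site polymorphic")

    return HaplotypePanel(chrom=chrom, positions=positions, alleles=alleles)


def sample_offspring(panel: HaplotypePanel, n_ind: int, recomb_rate: float = 1e-6,
                     mut_rate: float = 1e-4, seed: int = 0) -> DiploidTruth:
    """Draw diploid test individuals as pairs of panel-haplotype mosaics."""
    if panel.has_missing:
        raise ValueError("truth sampling requires a panel without missing entries")
    if n_ind < 1:
        raise ValueError("n_ind must be positive")
    rng = substream(seed, "offspring")
    h, s = panel.alleles.shape
    haps = np.empty((n_ind, 2, s), dtype=np.int8)
    cols = np.arange(s)
    for i in range(n_ind):
        for j in range(2):
            tmpl = _mosaic_templates(rng, h, panel.positions, recomb_rate)
            hap = panel.alleles[tmpl, cols].copy()
            flip = rng.random(s) < mut_rate
            hap[flip] ^= 1
            haps[i, j] = hap
    genotypes = haps.sum(axis=1, dtype=np.int8)
    ids = [f"ind{i}" for i in range(n_ind)]
    return DiploidTruth(sample_ids=ids, genotypes=genotypes, hap_pair=haps)


def mask_panel(panel: HaplotypePanel, missing_rate: float, seed: int = 0) -> HaplotypePanel:
    """Independently mask panel entries to MISSING, keeping >= 2 observed per site."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    if missing_rate == 0.0:
        return panel
    rng = substream(seed, "panelmask")
    h, s = panel.alleles.shape
    mask = rng.random((h, s)) < missing_rate
    n_resampled = 0
    # A site must keep at least two observed alleles to stay imputable.
    for col in range(s):
        while mask[:, col].sum() > h - 2:
            mask[:, col] = rng.random(h) < missing_rate
            n_resampled += 1
    if n_resampled:
        logger.warning("resampled the missingness mask at %d site draws to keep "
                       ">= 2 observed alleles per site", n_resampled)
    alleles = panel.alleles.copy()
    alleles[mask] = MISSING
    return HaplotypePanel(chrom=panel.chrom, positions=panel.positions.copy(),
                          alleles=alleles, hap_ids=list(panel.hap_ids))
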