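"""Core in-memory containers shared across the pipeline.

All allele matrices are small integer arrays: 0 = reference allele,
1 = alternate allele, MISSING (-1) = unobserved.  Genotypes are coded as
alternate-allele dosage in {0, 1, 2}; positions are 1-based base pairs,
strictly increasing, matching VCF coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for an unobserved allele / genotype call.
MISSING: int = -1


def _check_positions(positions: np.ndarray) -> None:
    if positions.ndim != 1 or positions.size == 0:
        raise ValueError("positions must be a non-empty 1-D array")
    if np.any(positions < 1):
        raise ValueError("positions are 1-based and must be >= 1")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")


@dataclass
class HaplotypePanel:
    """Phased biallelic reference haplotypes with physical positions.

    ``alleles`` is an H x S int8 matrix over {0, 1, MISSING}; row h is one
    haplotype.  Two consecutive rows (2i, 2i+1) form the phased genome of
    reference individual i when the panel came from diploid samples.
    """

    chrom: str
    positions: np.ndarray  # (S,) int64, 1-based, ascending
    alleles: np.ndarray    # (H, S) int8 over {0, 1, MISSING}
    hap_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        _check_positions(self.positions)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        h, s = self.alleles.shape
        if h < 2:
            raise ValueError("a panel needs at least two haplotypes")
        if s != self.positions.size:
            raise ValueError("alleles and positions disagree on site count")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("panel alleles must be 0, 1 or MISSING")
        if not self.hap_ids:
            self.hap_ids = [f"hap{i}" for i in range(h)]
        if len(self.hap_ids) != h:
            raise ValueError("hap_ids length must match haplotype count")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.alleles == MISSING).any())

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per site from observed (non-missing) alleles."""
        obs = self.alleles != MISSING
        alt = np.where(self.alleles == 1, 1, 0)
        n_obs = obs.sum(axis=0)
        if np.any(n_obs == 0):
            raise ValueError("site with no observed alleles")
        return (alt * obs).sum(axis=0) / n_obs


@dataclass
class DiploidTruth:
    """Ground-truth diploid genotypes with their underlying haplotypes."""

    sample_ids: list[str]
    genotypes: np.ndarray  # (N, S) int8 over {0, 1, 2}
    hap_pair: np.ndarray   # (N, 2, S) int8 over {0, 1}

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.hap_pair = np.asarray(self.hap_pair, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.hap_pair.ndim != 3:
            raise ValueError("genotypes must be N x S and hap_pair N x 2 x S")
        if self.hap_pair.shape != (self.genotypes.shape[0], 2, self.genotypes.shape[1]):
            raise ValueError("hap_pair shape inconsistent with genotypes")
        if not np.array_equal(self.hap_pair.sum(axis=1), self.genotypes):
            raise ValueError("genotypes must equal the sum of the two haplotypes")
        if len(self.sample_ids) != self.genotypes.shape[0]:
            raise ValueError("sample_ids length must match genotype rows")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class SiteReadCounts:
    """Per-sample, per-site reference/alternate read counts."""

    ref_count: np.ndarray  # (N, S) int32
    alt_count: np.ndarray  # (N, S) int32
    nominal_depth: float
    error_rate: float

    def __post_init__(self) -> None:
        self.ref_count = np.asarray(self.ref_count, dtype=np.int32)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int32)
        if self.ref_count.shape != self.alt_count.shape or self.ref_count.ndim != 2:
            raise ValueError("ref_count and alt_count must be equal-shape N x S")
        if (self.ref_count < 0).any() or (self.alt_count < 0).any():
            raise ValueError("read counts must be non-negative")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")

    @property
    def total(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    @property
    def covered(self) -> np.ndarray:
        """Boolean N x S mask of cells with at least one read."""
        return self.total > 0


@dataclass
class GenotypeLikelihoods:
    """P(reads | g) triplets for g in {0, 1, 2}, normalised to max 1 per cell."""

    gl: np.ndarray  # (N, S, 3) float64 in (0, 1], max over g == 1

    def __post_init__(self) -> None:
        self.gl = np.asarray(self.gl, dtype=np.float64)
        if self.gl.ndim != 3 or self.gl.shape[2] != 3:
            raise ValueError("gl must be N x S x 3")
        if (self.gl <= 0).any() or (self.gl > 1).any():
            raise ValueError("likelihoods must lie in (0, 1]")
        if not np.allclose(self.gl.max(axis=2), 1.0):
            raise ValueError("each triplet must be normalised to max 1")

    @property
    def informative(self) -> np.ndarray:
        """Cells whose triplet is not flat (i.e. carries read information)."""
        return ~(np.isclose(self.gl[..., 0], self.gl[..., 1])
                 & np.isclose(self.gl[..., 1], self.gl[..., 2]))


@dataclass
class PosteriorGenotypes:
    """Posterior genotype calls for N samples over S panel sites.

    ``state_cache`` holds, per sample, the conditioning-haplotype indices used
    by the copying model and the per-site argmax ordered state pair — enough
    to phase round-1 heterozygotes in round 2 without keeping full posteriors.
    """

    sample_ids: list[str]
    gp: np.ndarray         # (N, S, 3) posterior triplets, rows sum to 1
    ds: np.ndarray         # (N, S) dosage = gp[...,1] + 2 gp[...,2]
    gt: np.ndarray         # (N, S) hard calls in {0,1,2}
    confident: np.ndarray  # (N, S) bool
    state_cache: list[dict] | None = None

    def __post_init__(self) -> None:
        self.gp = np.asarray(self.gp, dtype=np.float64)
        self.ds = np.asarray(self.ds, dtype=np.float64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.confident = np.asarray(self.confident, dtype=bool)
        n, s, _ = self.gp.shape
        for name, arr in (("ds", self.ds), ("gt", self.gt), ("confident", self.confident)):
            if arr.shape != (n, s):
                raise ValueError(f"{name} shape must match gp")
        if not np.allclose(self.gp.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("posterior triplets must sum to 1")

    @property
    def n_samples(self) -> int:
        return self.gp.shape[0]

    @property
    def n_sites(self) -> int:
        return self.gp.shape[1]


def finalize_posteriors(sample_ids: list[str], gp: np.ndarray,
                        confident: np.ndarray | None = None,
                        state_cache: list[dict] | None = None) -> PosteriorGenotypes:
    """Derive dosage and hard calls from posterior triplets.

    Hard call is argmax of the triplet; ties break toward the smaller dosage.
    """
    gp = np.asarray(gp, dtype=np.float64)
    gp = gp / gp.sum(axis=2, keepdims=True)
    ds = gp[..., 1] + 2.0 * gp[..., 2]
    gt = np.argmax(gp, axis=2).astype(np.int8)  # np.argmax takes the first maximum
    if confident is None:
        confident = np.ones(gp.shape[:2], dtype=bool)
    return PosteriorGenotypes(sample_ids=sample_ids, gp=gp, ds=ds, gt=gt,
                              confident=confident, state_cache=state_cache)


@dataclass
class RegionSpec:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")
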