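"""End-to-end orchestration of the dual-phase imputation pipeline.

The canonical flow is: (optional) panel self-imputation -> round-1 HMM
imputation over genotype likelihoods (chunk, impute, ligate, confidence
mask) -> round-2 IBS-conditioned refinement covering every panel site.
These helpers are what both the command-line interface and the evaluation
scripts drive.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import evalmetrics, panel_refine, phase1, phase2, popsim, seqsim
from .phase1 import HMMParams
from .types import (DiploidTruth, HaplotypePanel, PosteriorGenotypes,
                    SiteReadCounts)

logger = logging.getLogger(__name__)

#: Synthetic benchmark defaults: a 2 Mb region, 200 reference haplotypes,
#: 4,000 SNPs and 20 test individuals — the desk-scale stand-in for the
#: real reference populations the method targets.
BENCH_N_HAP = 200
BENCH_N_SITES = 4000
BENCH_REGION_LEN = 2_000_000
BENCH_N_IND = 20


def simulate_population(seed: int, n_hap: int = BENCH_N_HAP,
                        n_sites: int = BENCH_N_SITES,
                        region_len: int = BENCH_REGION_LEN,
                        n_ind: int = BENCH_N_IND,
                        panel_missing_rate: float = 0.0
                        ) -> tuple[HaplotypePanel, HaplotypePanel, DiploidTruth]:
    """(complete panel, possibly-masked panel, diploid truth) for one seed."""
    panel = popsim.simulate_panel(n_hap=n_hap, n_sites=n_sites,
                                  region_len=region_len, seed=seed)
    truth = popsim.sample_offspring(panel, n_ind=n_ind, seed=seed + 1)
    masked = popsim.mask_panel(panel, panel_missing_rate, seed=seed + 2)
    return panel, masked, truth


def run_dual_phase(panel: HaplotypePanel, counts: SiteReadCounts,
                   params: HMMParams | None = None,
                   tau: float = phase1.DEFAULT_TAU,
                   L: int = phase2.DEFAULT_L,
                   sample_ids: list[str] | None = None
                   ) -> tuple[PosteriorGenotypes, PosteriorGenotypes]:
    """Run both imputation rounds; returns (round-1, round-2) posteriors."""
    params = params or HMMParams()
    if panel.has_missing:
        logger.info("panel has missing entries; self-imputing before round 1")
        panel = panel_refine.self_impute_panel(panel, params)
    gl = seqsim.genotype_likelihoods(counts)
    round1 = phase1.impute_round1(panel, gl, counts, params,
                                  sample_ids=sample_ids, tau=tau)
    round2 = phase2.impute_round2(panel, round1, params, L=L)
    return round1, round2


def round1_calls(round1: PosteriorGenotypes) -> np.ndarray:
    """Round-1 hard calls with non-confident cells set to MISSING."""
    from .types import MISSING
    gt = round1.gt.copy()
    gt[~round1.confident] = MISSING
    return gt


def evaluate_rounds(round1: PosteriorGenotypes, round2: PosteriorGenotypes,
                    truth: DiploidTruth, panel: HaplotypePanel
                    ) -> dict[str, evalmetrics.EvalReport]:
    """MAF-binned evaluation of both rounds against the truth."""
    r1_gt = round1_calls(round1)
    r1 = evalmetrics.maf_bin_report(r1_gt, round1.ds, truth.genotypes, panel)
    r2 = evalmetrics.maf_bin_report(round2.gt, round2.ds, truth.genotypes, panel)
    return {"round1": r1, "round2": r2}


def benchmark_depths(depths: list[float], seed: int,
                     error_rate: float = seqsim.DEFAULT_ERROR_RATE,
                     params: HMMParams | None = None,
                     **pop_kwargs) -> dict[float, evalmetrics.EvalReport]:
    """One population, the coverage ladder; an EvalReport per depth."""
    panel, masked, truth = simulate_population(seed, **pop_kwargs)
    reports = {}
    for depth in depths:
        counts = seqsim.simulate_reads(truth, depth, error_rate, seed=seed + 10)
        _, round2 = run_dual_phase(masked if masked.has_missing else panel,
                                   counts, params, sample_ids=truth.sample_ids)
        reports[depth] = evalmetrics.maf_bin_report(round2.gt, round2.ds,
                                                    truth.genotypes, panel)
        logger.info("depth %gx: total concordance %.4f", depth,
                    reports[depth].total_concordance)
    return reports


def write_manifest(path: Path, *, seed: int, params: HMMParams,
                   stages: dict[str, float], extra: dict | None = None) -> None:
    """Record parameters, seed and per-stage wall times for reproducibility."""
    from importlib.metadata import version
    try:
        ver = version("lcimpute")
    except Exception:  # pragma: no cover
        ver = "unknown"
    manifest = {"seed": seed, "version": ver, "params": asdict(params),
                "stage_seconds": {k: round(v, 3) for k, v in stages.items()},
                "written_at": time.strftime("%Y-%m-%dT%H:%M:%S")}
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2) + "\n")
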