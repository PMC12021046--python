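"""Imputation accuracy metrics.

* Genotype concordance — matches over all truth cells ("total": a missing
  call counts as discordant) and over called cells only ("called").
* Per-site genotypic r² — squared Pearson correlation between imputed
  dosage and true genotype across samples, r² = Cov(X,Y)² / (Var X · Var Y).
* SNP recovery rate — fraction of (sample, panel-site) cells with a call.
* MAF-binned aggregation of all of the above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, HaplotypePanel

#: Default minor-allele-frequency bin edges (left-open, right-closed).
DEFAULT_MAF_EDGES = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class EvalReport:
    total_concordance: float
    called_concordance: float
    recovery_rate: float
    mean_r2: float
    n_sites: int
    n_degenerate_r2: int = 0
    per_bin: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.per_bin)
        rows.append({"maf_low": 0.0, "maf_high": 0.5, "bin": "total",
                     "n_sites": self.n_sites,
                     "concordance": self.total_concordance,
                     "called_concordance": self.called_concordance,
                     "recovery_rate": self.recovery_rate,
                     "mean_r2": self.mean_r2})
        return pd.DataFrame(rows)


def concordance(imputed_gt: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(total, called) genotype concordance; MISSING imputed cells are discordant
    in the total flavour and excluded from the called flavour."""
    imputed_gt = np.asarray(imputed_gt)
    truth = np.asarray(truth)
    if imputed_gt.shape != truth.shape or imputed_gt.size == 0:
        raise ValueError("imputed and truth must be non-empty and equal-shape")
    called = imputed_gt != MISSING
    match = (imputed_gt == truth) & called
    total = match.sum() / truth.size
    called_frac = match.sum() / called.sum() if called.any() else float("nan")
    return float(total), float(called_frac)


def genotypic_r2(imputed_ds: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Per-site r² across samples and its mean.

    Sites where either the dosage or the truth is constant are excluded from
    the mean; returns (per-site r² with NaN at degenerate sites, mean,
    degenerate count).  The mean is NaN if every site is degenerate.
    """
    x = np.asarray(imputed_ds, dtype=np.float64)
    y = np.asarray(truth, dtype=np.float64)
    if x.shape != y.shape or x.shape[0] < 2:
        raise ValueError("need >= 2 samples with matching shapes")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    cov = (xc * yc).mean(axis=0)
    var_x = (xc ** 2).mean(axis=0)
    var_y = (yc ** 2).mean(axis=0)
    degenerate = (var_x == 0) | (var_y == 0)
    r2 = np.full(x.shape[1], np.nan)
    ok = ~degenerate
    r2[ok] = cov[ok] ** 2 / (var_x[ok] * var_y[ok])
    mean = float(np.nanmean(r2)) if ok.any() else float("nan")
    return r2, mean, int(degenerate.sum())


def recovery_rate(imputed_gt: np.ndarray, panel_site_count: int) -> float:
    """Fraction of (sample, panel-site) cells with a non-missing call."""
    imputed_gt = np.asarray(imputed_gt)
    n = imputed_gt.shape[0]
    return float((imputed_gt != MISSING).sum() / (n * panel_site_count))


def maf_bin_report(imputed_gt: np.ndarray, imputed_ds: np.ndarray,
                   truth: np.ndarray, panel: HaplotypePanel,
                   bin_edges: tuple[float, ...] = DEFAULT_MAF_EDGES) -> EvalReport:
    """Aggregate all metrics overall and within panel-MAF bins.

    MAF comes from the panel's observed alleles; each site goes to the bin
    whose interval (left-open, right-closed) contains its MAF.  MAF-0 sites
    are excluded and counted.
    """
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.size < 2 or np.any(np.diff(edges) <= 0) or edges[-1] > 0.5:
        raise ValueError("bin_edges must be ascending within (0, 0.5]")
    freq = panel.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)

    total, called = concordance(imputed_gt, truth)
    r2_site, mean_r2, n_degen = genotypic_r2(imputed_ds, truth)
    rec = recovery_rate(imputed_gt, panel.n_sites)

    per_bin = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (maf > lo) & (maf <= hi)
        row = {"maf_low": float(lo), "maf_high": float(hi),
               "bin": f"({lo:g},{hi:g}]", "n_sites": int(in_bin.sum())}
        if in_bin.any():
            t, c = concordance(imputed_gt[:, in_bin], truth[:, in_bin])
            bin_r2 = r2_site[in_bin]
            row.update(concordance=t, called_concordance=c,
                       recovery_rate=recovery_rate(imputed_gt[:, in_bin], int(in_bin.sum())),
                       mean_r2=float(np.nanmean(bin_r2)) if np.isfinite(bin_r2).any()
                       else float("nan"))
        else:
            row.update(concordance=float("nan"), called_concordance=float("nan"),
                       recovery_rate=float("nan"), mean_r2=float("nan"))
        per_bin.append(row)
    return EvalReport(total_concordance=total, called_concordance=called,
                      recovery_rate=rec, mean_r2=mean_r2, n_sites=panel.n_sites,
                      n_degenerate_r2=n_degen, per_bin=per_bin)
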