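"""VCF and TSV input/output.

Reading goes through cyvcf2 (htslib); writing emits VCF 4.2 text directly,
optionally gzip-compressed when the path ends in ``.gz``.  Only biallelic
SNP records enter the data model; anything else is skipped with a logged
count.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import IO

import numpy as np
from cyvcf2 import VCF

from .types import (MISSING, DiploidTruth, HaplotypePanel, PosteriorGenotypes,
                    SiteReadCounts)

logger = logging.getLogger(__name__)

_HEADER = "##fileformat=VCFv4.2\n"
_COLS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"


def _open_write(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        # mtime pinned to 0 so identical content gives identical bytes
        import io
        return io.TextIOWrapper(gzip.GzipFile(path, "wb", mtime=0))
    return open(path, "w")


def _is_biallelic_snp(variant) -> bool:
    return (len(variant.ALT) == 1 and len(variant.REF) == 1
            and len(variant.ALT[0]) == 1
            and variant.REF in "ACGT" and variant.ALT[0] in "ACGT")


# ---------------------------------------------------------------------------
# reference panel


def read_panel_vcf(path: str | Path) -> HaplotypePanel:
    """Load a phased reference panel from VCF.

    Each sample contributes two haplotype rows.  ``.`` alleles become
    MISSING; unphased non-missing genotypes are a hard error because panel
    rows must be haplotypes.
    """
    vcf = VCF(str(path))
    samples = vcf.samples
    positions: list[int] = []
    rows: list[np.ndarray] = []
    chrom = None
    skipped = 0
    for v in vcf:
        if not _is_biallelic_snp(v):
            skipped += 1
            continue
        if chrom is None:
            chrom = v.CHROM
        gts = np.array(v.genotypes)  # (N, 3): allele_a, allele_b, phased flag
        observed = (gts[:, 0] >= 0) & (gts[:, 1] >= 0)
        het = gts[:, 0] != gts[:, 1]
        if np.any(observed & het & (gts[:, 2] == 0)):
            bad = samples[int(np.flatnonzero(observed & het & (gts[:, 2] == 0))[0])]
            raise ValueError(
                f"unphased panel genotype at {v.CHROM}:{v.POS} sample {bad}; "
                "panels must carry '|'-phased GT")
        col = gts[:, :2].astype(np.int8)
        col[col < 0] = MISSING
        positions.append(v.POS)
        rows.append(col.reshape(-1))
    if skipped:
        logger.info("skipped %d non-biallelic/non-SNP records", skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    alleles = np.stack(rows, axis=1)
    hap_ids = [f"{s}_{k}" for s in samples for k in (0, 1)]
    return HaplotypePanel(chrom=chrom, positions=np.array(positions),
                          alleles=alleles, hap_ids=hap_ids)


def write_panel_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as phased GT ('|'); MISSING alleles become '.'."""
    h = panel.n_haplotypes
    if h % 2:
        raise ValueError("panel must have an even haplotype count to pair into samples")
    names = [panel.hap_ids[2 * i].rsplit("_", 1)[0] if panel.hap_ids[2 * i].endswith("_0")
             else f"s{i}" for i in range(h // 2)]
    with _open_write(path) as fh:
        fh.write(_HEADER)
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(_COLS + "\t" + "\t".join(names) + "\n")
        sym = {0: "0", 1: "1", MISSING: "."}
        for s in range(panel.n_sites):
            col = panel.alleles[:, s]
            gts = "\t".join(f"{sym[int(col[2 * i])]}|{sym[int(col[2 * i + 1])]}"
                            for i in range(h // 2))
            fh.write(f"{panel.chrom}\t{panel.positions[s]}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_truth_vcf(truth: DiploidTruth, positions: np.ndarray, chrom: str,
                    path: str | Path) -> None:
    """Write diploid truth genotypes as unphased GT ('/')."""
    with _open_write(path) as fh:
        fh.write(_HEADER)
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(_COLS + "\t" + "\t".join(truth.sample_ids) + "\n")
        code = {0: "0/0", 1: "0/1", 2: "1/1"}
        for s in range(truth.n_sites):
            gts = "\t".join(code[int(g)] for g in truth.genotypes[:, s])
            fh.write(f"{chrom}\t{positions[s]}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# read counts


def write_counts_vcf(counts: SiteReadCounts, positions: np.ndarray, chrom: str,
                     sample_ids: list[str], path: str | Path) -> None:
    """Write per-sample allelic depths (AD ref,alt) for each site."""
    n, s = counts.ref_count.shape
    with _open_write(path) as fh:
        fh.write(_HEADER)
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(f"##lcimpute_nominal_depth={counts.nominal_depth}\n")
        fh.write(f"##lcimpute_error_rate={counts.error_rate}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(_COLS + "\t" + "\t".join(sample_ids) + "\n")
        for j in range(s):
            cells = "\t".join(
                f"./.:{counts.ref_count[i, j]},{counts.alt_count[i, j]}" for i in range(n))
            fh.write(f"{chrom}\t{positions[j]}\t.\tA\tG\t.\tPASS\t.\tGT:AD\t{cells}\n")


def read_counts_vcf(path: str | Path, nominal_depth: float = 0.0,
                    error_rate: float = 0.001) -> tuple[SiteReadCounts, np.ndarray, list[str]]:
    """Parse allelic depths from a VCF; returns (counts, positions, sample_ids).

    Malformed or missing AD fields are treated as zero reads with a warning.
    Header lines ``##lcimpute_nominal_depth``/``##lcimpute_error_rate`` written
    by :func:`write_counts_vcf` override the defaults.
    """
    vcf = VCF(str(path))
    for line in vcf.raw_header.splitlines():
        if line.startswith("##lcimpute_nominal_depth="):
            nominal_depth = float(line.split("=", 1)[1])
        elif line.startswith("##lcimpute_error_rate="):
            error_rate = float(line.split("=", 1)[1])
    samples = vcf.samples
    positions: list[int] = []
    refs: list[np.ndarray] = []
    alts: list[np.ndarray] = []
    bad_cells = 0
    for v in vcf:
        if not _is_biallelic_snp(v):
            continue
        positions.append(v.POS)
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            bad_cells += len(samples)
            refs.append(np.zeros(len(samples), dtype=np.int32))
            alts.append(np.zeros(len(samples), dtype=np.int32))
            continue
        ad = np.asarray(ad)
        bad = (ad < 0).any(axis=1)
        bad_cells += int(bad.sum())
        ad = np.where(ad < 0, 0, ad)
        refs.append(ad[:, 0].astype(np.int32))
        alts.append(ad[:, 1].astype(np.int32))
    if bad_cells:
        logger.warning("%d cells had malformed/absent AD; treated as zero reads", bad_cells)
    ref = np.stack(refs, axis=1)
    alt = np.stack(alts, axis=1)
    if nominal_depth <= 0:
        nominal_depth = float((ref + alt).mean())
    counts = SiteReadCounts(ref_count=ref, alt_count=alt,
                            nominal_depth=nominal_depth, error_rate=error_rate)
    return counts, np.array(positions), samples


# ---------------------------------------------------------------------------
# imputed output


def write_imputed_vcf(post: PosteriorGenotypes, positions: np.ndarray, chrom: str,
                      path: str | Path) -> None:
    """Emit GT (phased representation), DS and GP to 3 decimals."""
    if not np.allclose(post.gp.sum(axis=2), 1.0, atol=1e-6):
        raise ValueError("posterior triplets must sum to 1 within 1e-6")
    code = {0: "0|0", 1: "0|1", 2: "1|1"}
    with _open_write(path) as fh:
        fh.write(_HEADER)
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior">\n')
        fh.write(_COLS + "\t" + "\t".join(post.sample_ids) + "\n")
        for s in range(post.n_sites):
            cells = []
            for n in range(post.n_samples):
                gp = post.gp[n, s]
                cells.append(f"{code[int(post.gt[n, s])]}:{post.ds[n, s]:.3f}:"
                             f"{gp[0]:.3f},{gp[1]:.3f},{gp[2]:.3f}")
            fh.write(f"{chrom}\t{positions[s]}\t.\tA\tG\t.\tPASS\t.\tGT:DS:GP\t"
                     + "\t".join(cells) + "\n")


def read_imputed_vcf(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Read back (gt, ds, gp, sample_ids) from an imputed VCF."""
    vcf = VCF(str(path))
    samples = vcf.samples
    gts, dss, gps = [], [], []
    for v in vcf:
        g = np.array(v.genotypes)[:, :2].sum(axis=1)
        gts.append(g)
        dss.append(np.asarray(v.format("DS")).reshape(-1))
        gps.append(np.asarray(v.format("GP")))
    gt = np.stack(gts, axis=1).astype(np.int8)
    ds = np.stack(dss, axis=1).astype(np.float64)
    gp = np.stack(gps, axis=1).astype(np.float64)
    return gt, ds, gp, samples


def write_report_tsv(report, path: str | Path) -> None:
    """One row per MAF bin plus a 'total' row; tab-separated with header."""
    df = report.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
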