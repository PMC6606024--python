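"""Two-timepoint allele-frequency-shift scan and windowed summary statistics.

The central statistic is dz2, the squared difference of variance-stabilized
allele frequencies between timepoints: z(q) = 2*arcsin(sqrt(q)) ranges over
[0, pi], so dz2 ranges over [0, pi^2], and one generation of binomial drift
changes z with variance ~ 1/(2*Ne) regardless of the starting frequency.
Windowed statistics tile each chromosome from coordinate 0 in 0-based
half-open intervals; VCF positions (1-based) are converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConsistencyError

logger = logging.getLogger(__name__)

__all__ = [
    "SiteFrequencies",
    "read_genotypes",
    "polarized_freq",
    "delta_z2",
    "window_stats",
    "fst_weir_cockerham",
    "windowed_fst",
    "diversity",
]

PI2 = np.pi**2


@dataclass
class SiteFrequencies:
    """Per-site polarized frequencies at the two timepoints.

    Polarization follows the minor allele at the first timepoint (ties go
    to the alternate allele); dz2 itself is invariant to this choice.
    """

    chroms: np.ndarray
    positions: np.ndarray  # 0-based
    q0: np.ndarray
    q1: np.ndarray
    n0: np.ndarray  # chromosome counts
    n1: np.ndarray


def read_genotypes(vcf_path, samples: list | None = None):
    """Read biallelic SNPs from a VCF into a (samples x sites) 0/1/2 matrix.

    Returns (genotypes int matrix with -1 for missing, chroms, positions
    0-based, sample names).  Multiallelic and non-SNP records are skipped
    and counted in the log.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), samples=samples, gts012=True)
    kept = list(vcf.samples)
    if samples is not None and len(kept) == 0:
        raise ArgumentError("no requested samples found in VCF")
    chroms, pos, rows = [], [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        g = rec.gt_types.astype(np.int8)  # 0/1/2 with gts012, 3 = unknown
        g[g == 3] = -1
        rows.append(g)
        chroms.append(rec.CHROM)
        pos.append(rec.POS - 1)
    vcf.close()
    if skipped:
        logger.info("read_genotypes: skipped %d non-biallelic/non-SNP records", skipped)
    if not rows:
        return (
            np.empty((len(kept), 0), dtype=np.int8),
            np.array([], dtype=object),
            np.array([], dtype=np.int64),
            kept,
        )
    gt = np.vstack(rows).T
    return gt, np.array(chroms), np.array(pos, dtype=np.int64), kept


def _alt_freq(gt: np.ndarray):
    """Alternate-allele frequency and chromosome count per site (missing = -1)."""
    present = gt >= 0
    n_chrom = 2 * present.sum(axis=0)
    alt = np.where(present, gt, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
    return freq, n_chrom


def polarized_freq(gt0, gt1, chroms, positions) -> SiteFrequencies:
    """Polarize on the minor allele at the first timepoint and compute q0, q1.

    Sites with no called genotypes at either timepoint are dropped (logged).
    """
    if gt0.shape[1] != gt1.shape[1]:
        raise ConsistencyError("timepoints must cover the same site set")
    f0, n0 = _alt_freq(gt0)
    f1, n1 = _alt_freq(gt1)
    ok = (n0 > 0) & (n1 > 0)
    if not ok.all():
        logger.info("polarized_freq: dropped %d sites missing in one timepoint", int((~ok).sum()))
    flip = f0 > 0.5  # ties (q = 0.5) stay on the alternate allele
    q0 = np.where(flip, 1 - f0, f0)
    q1 = np.where(flip, 1 - f1, f1)
    return SiteFrequencies(
        chroms=np.asarray(chroms)[ok],
        positions=np.asarray(positions)[ok],
        q0=q0[ok],
        q1=q1[ok],
        n0=n0[ok],
        n1=n1[ok],
    )


def delta_z2(q0, q1):
    """Squared shift of z(q) = 2*arcsin(sqrt(q)); in [0, pi^2]."""
    q0 = np.asarray(q0, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    if np.any((q0 < 0) | (q0 > 1) | (q1 < 0) | (q1 > 1)):
        raise ArgumentError("frequencies must lie in [0, 1]")
    z0 = 2.0 * np.arcsin(np.sqrt(q0))
    z1 = 2.0 * np.arcsin(np.sqrt(q1))
    out = (z1 - z0) ** 2
    return float(out) if out.ndim == 0 else out


def window_stats(
    chroms,
    positions,
    values,
    window: int = 10_000,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Mean per-site statistic in adjacent windows tiling from coordinate 0.

    Returns a frame (chrom, start, end, value, n_snps); windows without
    SNPs carry NaN (missing), not zero.  With ``chrom_lengths`` the tiling
    covers whole chromosomes; otherwise it stops at the last SNP.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    frames = []
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        pos = positions[m]
        val = values[m]
        if chrom_lengths is not None:
            length = chrom_lengths[chrom]
        else:
            length = int(pos.max()) + 1 if pos.size else window
        n_win = int(np.ceil(length / window))
        idx = pos // window  # half-open [k*w, (k+1)*w)
        sums = np.bincount(idx, weights=val, minlength=n_win)
        counts = np.bincount(idx, minlength=n_win)
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        starts = np.arange(n_win, dtype=np.int64) * window
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + window, length),
                    "value": mean,
                    "n_snps": counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def fst_weir_cockerham(gt1: np.ndarray, gt2: np.ndarray):
    """Weir & Cockerham (1984) per-site variance components for two populations.

    Returns (fst, a, b, c) arrays; monomorphic-everywhere sites are NaN.
    Windowed values should be formed as sum(a)/sum(a+b+c).
    """
    comps = []
    for gt in (gt1, gt2):
        present = gt >= 0
        n = present.sum(axis=0).astype(float)  # diploid counts
        alt = np.where(present, gt, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(present, gt == 1, False).sum(axis=0) / np.maximum(n, 1)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ArgumentError("need >= 2 genotyped samples per population at every site")

    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (1 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2

    denom = a + b + c
    mono = (p_bar <= 0) | (p_bar >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(mono | (denom == 0), np.nan, a / denom)
    a = np.where(mono, np.nan, a)
    b = np.where(mono, np.nan, b)
    c = np.where(mono, np.nan, c)
    return fst, a, b, c


def windowed_fst(chroms, positions, a, b, c, window: int = 10_000) -> pd.DataFrame:
    """Ratio-of-sums windowed F_ST from per-site variance components."""
    ok = ~np.isnan(a)
    num = window_stats(chroms[ok], positions[ok], a[ok], window)
    den = window_stats(chroms[ok], positions[ok], (a + b + c)[ok], window)
    out = num[["chrom", "start", "end", "n_snps"]].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["value"] = (num.value * num.n_snps) / (den.value * den.n_snps)
    return out


def diversity(gt: np.ndarray, chroms, positions, window: int = 10_000):
    """(pi per window per bp, observed heterozygosity, segregating-site count).

    Per-site pi uses the unbiased n-chromosome estimator 2*n*q*(1-q)/(n-1).
    """
    if gt.shape[1] == 0:
        raise ArgumentError("empty genotype matrix")
    freq, n_chrom = _alt_freq(gt)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(
            n_chrom > 1, 2.0 * n_chrom * freq * (1 - freq) / np.maximum(n_chrom - 1, 1), np.nan
        )
    win = window_stats(chroms, positions, pi_site, window)
    # convert mean-per-SNP to per-bp over the window
    width = (win.end - win.start).to_numpy()
    win["value"] = win.value * win.n_snps / width
    win.loc[win.n_snps == 0, "value"] = 0.0

    present = gt >= 0
    het = float((gt == 1).sum() / max(present.sum(), 1))
    seg = int(((freq > 0) & (freq < 1)).sum())
    return win, het, seg
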