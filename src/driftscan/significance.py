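"""Simulation-derived significance thresholds, sweep-peak calling and
parallelism statistics.

Critical values come from the distribution of the genome-wide maximum of
the windowed shift statistic over simulated null/selection replicates.
Peaks are grown outward from each significant window in blocks of SNPs
until a block contains no site above the hitchhiking stop level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError
from .scan import PI2

__all__ = [
    "ThresholdSet",
    "SweepPeak",
    "genomewide_max",
    "critical_value",
    "call_peaks",
    "classify_parallelism",
    "parallelism_chisq",
    "profile_correlation",
    "interval_permutation",
]


@dataclass
class ThresholdSet:
    """Critical values keyed by (line, ld_mode, selection); maxima retained."""

    alpha: float
    maxima: dict = field(default_factory=dict)

    def add(self, key, values) -> None:
        self.maxima[key] = np.asarray(values, dtype=float)

    def threshold(self, key) -> float:
        return critical_value(self.maxima[key], self.alpha)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (*key, len(v), self.threshold(key))
            for key, v in self.maxima.items()
        ]
        return pd.DataFrame(rows, columns=["line", "ld_mode", "selection", "n_replicates", "threshold"])


def genomewide_max(profile: pd.DataFrame) -> float:
    """Maximum windowed value over all non-missing windows."""
    vals = profile["value"].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ArgumentError("profile has no non-missing windows")
    return float(vals.max())


def critical_value(maxima, alpha: float = 0.05) -> float:
    """ceil(n*(1-alpha))-th order statistic: exceedance probability <= alpha."""
    maxima = np.sort(np.asarray(maxima, dtype=float))
    n = maxima.size
    if n < 20:
        raise ArgumentError(f"need >= 20 replicate maxima, got {n}")
    if not (0 < alpha < 1):
        raise ArgumentError("alpha must be in (0, 1)")
    k = int(np.ceil(n * (1 - alpha)))
    return float(maxima[k - 1])


@dataclass
class SweepPeak:
    """One called sweep: core = significant windows, span = hitchhiking extent."""

    rank: int
    chrom: str
    span_start: int
    span_end: int
    core_start: int
    core_end: int
    peak_start: int
    peak_value: float


def _extend_side(pos, vals, anchor, stop, ext, direction):
    """Outermost coordinate reached by block-wise extension on one side."""
    if direction > 0:
        idx = np.searchsorted(pos, anchor, side="left")
        limit = anchor
        while idx < pos.size:
            block = slice(idx, min(idx + ext, pos.size))
            limit = int(pos[block.stop - 1]) + 1
            if not np.any(vals[block] > stop):
                break
            idx = block.stop
        return limit
    idx = np.searchsorted(pos, anchor, side="left")
    limit = anchor
    while idx > 0:
        lo = max(idx - ext, 0)
        block = slice(lo, idx)
        limit = int(pos[lo])
        if not np.any(vals[block] > stop):
            break
        idx = lo
    return limit


def call_peaks(
    profile: pd.DataFrame,
    site_chroms,
    site_pos,
    site_vals,
    threshold: float,
    stop: float = 0.2 * PI2,
    extension: int = 100,
) -> list:
    """Call sweep peaks from a windowed profile plus the per-site track.

    Windows at or above ``threshold`` are processed in descending order
    (ties by chrom, start).  Each peak's span grows outward in blocks of
    ``extension`` SNPs per side; a side stops once its latest block holds
    no site above ``stop`` (that final block stays inside the span).
    Windows absorbed by a span are dropped from the candidate list;
    overlapping spans are merged.
    """
    if threshold < stop:
        raise ArgumentError("threshold must be >= stop level")
    site_chroms = np.asarray(site_chroms)
    site_pos = np.asarray(site_pos)
    site_vals = np.asarray(site_vals, dtype=float)

    prof = profile.dropna(subset=["value"]).reset_index(drop=True)
    sig = prof[prof.value >= threshold].copy()
    if sig.empty:
        return []
    sig = sig.sort_values(["value", "chrom", "start"], ascending=[False, True, True], kind="mergesort")

    peaks = []
    taken = np.zeros(len(sig), dtype=bool)
    sig_arr = sig.reset_index(drop=True)
    rank = 0
    for i in range(len(sig_arr)):
        if taken[i]:
            continue
        rank += 1
        row = sig_arr.iloc[i]
        chrom = row.chrom
        m = site_chroms == chrom
        pos_c = site_pos[m]
        val_c = site_vals[m]
        span_lo = _extend_side(pos_c, val_c, int(row.start), stop, extension, -1)
        span_hi = _extend_side(pos_c, val_c, int(row.end), stop, extension, +1)
        span_lo = min(span_lo, int(row.start))
        span_hi = max(span_hi, int(row.end))
        # absorb candidate windows falling inside the span
        inside = (
            (sig_arr.chrom == chrom)
            & (sig_arr.start < span_hi)
            & (sig_arr.end > span_lo)
        ).to_numpy()
        taken |= inside
        # core: contiguous run of significant windows containing the peak
        core_lo, core_hi = _core_run(prof, chrom, int(row.start), threshold)
        peaks.append(
            SweepPeak(
                rank=rank,
                chrom=str(chrom),
                span_start=int(span_lo),
                span_end=int(span_hi),
                core_start=core_lo,
                core_end=core_hi,
                peak_start=int(row.start),
                peak_value=float(row.value),
            )
        )
    return _merge_peaks(peaks)


def _core_run(prof, chrom, peak_start, threshold):
    win = prof[prof.chrom == chrom].sort_values("start")
    starts = win.start.to_numpy()
    ends = win.end.to_numpy()
    sig = win.value.to_numpy() >= threshold
    k = int(np.searchsorted(starts, peak_start))
    lo = k
    while lo > 0 and sig[lo - 1] and ends[lo - 1] == starts[lo]:
        lo -= 1
    hi = k
    while hi + 1 < len(starts) and sig[hi + 1] and starts[hi + 1] == ends[hi]:
        hi += 1
    return int(starts[lo]), int(ends[hi])


def _merge_peaks(peaks):
    merged = []
    for p in sorted(peaks, key=lambda p: (p.chrom, p.span_start)):
        if merged and merged[-1].chrom == p.chrom and p.span_start <= merged[-1].span_end:
            q = merged[-1]
            keep, other = (q, p) if q.peak_value >= p.peak_value else (p, q)
            merged[-1] = SweepPeak(
                rank=min(q.rank, p.rank),
                chrom=q.chrom,
                span_start=min(q.span_start, p.span_start),
                span_end=max(q.span_end, p.span_end),
                core_start=keep.core_start,
                core_end=keep.core_end,
                peak_start=keep.peak_start,
                peak_value=keep.peak_value,
            )
        else:
            merged.append(p)
    merged.sort(key=lambda p: p.rank)
    for new_rank, p in enumerate(merged, start=1):
        p.rank = new_rank
    return merged


def parallelism_chisq(both: int, a_only: int, b_only: int, neither: int):
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table."""
    obs = np.array([[both, a_only], [b_only, neither]], dtype=float)
    n = obs.sum()
    if n == 0:
        raise ArgumentError("empty table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row * col / n
    if np.any(exp == 0):
        return 0.0, 1.0
    if np.any(exp < 1):
        warnings.warn("expected cell count < 1; chi-square approximation is poor", stacklevel=2)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def profile_correlation(profile_a: pd.DataFrame, profile_b: pd.DataFrame):
    """Pearson r of windowed values over shared non-missing windows."""
    a = profile_a.set_index(["chrom", "start"])["value"]
    b = profile_b.set_index(["chrom", "start"])["value"]
    joined = pd.concat([a, b], axis=1, join="inner", keys=["a", "b"]).dropna()
    n = len(joined)
    if n < 10:
        raise ArgumentError(f"need >= 10 shared windows, got {n}")
    if joined["a"].std() == 0 or joined["b"].std() == 0:
        raise ArgumentError("zero variance in a profile; correlation undefined")
    r = float(np.corrcoef(joined["a"], joined["b"])[0, 1])
    return r, n


def classify_parallelism(peaks_by_line, profiles_by_line, thresholds_by_line):
    """Label each peak Parallel or line-specific.

    A peak is Parallel when its full span overlaps at least one
    significant window in every *other* selected line's profile;
    otherwise it is specific to its own line.  Returns a frame with one
    row per (line, peak).
    """
    rows = []
    for line, peaks in peaks_by_line.items():
        others = [l for l in peaks_by_line if l != line]
        for p in peaks:
            parallel = bool(others)
            for other in others:
                prof = profiles_by_line[other]
                thr = thresholds_by_line[other]
                hit = prof[
                    (prof.chrom == p.chrom)
                    & (prof.start < p.span_end)
                    & (prof.end > p.span_start)
                    & (prof.value >= thr)
                ]
                if hit.empty:
                    parallel = False
                    break
            rows.append(
                (line, p.rank, p.chrom, p.span_start, p.span_end, p.core_start,
                 p.core_end, p.peak_start, p.peak_value,
                 "Parallel" if parallel else f"{line}-specific")
            )
    return pd.DataFrame(
        rows,
        columns=["line", "rank", "chrom", "span_start", "span_end", "core_start",
                 "core_end", "peak_start", "peak_value", "type"],
    )


def _overlap_count(spans, features):
    """Number of feature intervals hit by any query span."""
    hit = 0
    for fc, fs, fe in features:
        for qc, qs, qe in spans:
            if qc == fc and qs < fe and qe > fs:
                hit += 1
                break
    return hit


def _mean_nearest_distance(spans, features):
    dists = []
    for qc, qs, qe in spans:
        best = np.inf
        for fc, fs, fe in features:
            if fc != qc:
                continue
            if qs < fe and qe > fs:
                best = 0
                break
            best = min(best, fs - qe + 1 if fs >= qe else qs - fe + 1)
        dists.append(best)
    dists = [d for d in dists if np.isfinite(d)]
    if not dists:
        raise ArgumentError("no feature on any query chromosome; distance undefined")
    return float(np.mean(dists))


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p_value: float
    n_perm: int
    below_resolution: bool


def interval_permutation(
    spans,
    features,
    gmap,
    n_perm: int = 1000,
    mode: str = "overlap_genes",
    rng=None,
    max_retries: int = 1000,
) -> PermutationResult:
    """Empirical p-value from random placement of the query spans.

    Each permutation drops the spans uniformly at random on the genome
    without overlap among themselves.  Statistic: number of features hit
    (``overlap_genes``, upper tail) or mean distance to the nearest
    feature (``nearest_distance``, lower tail).  p is the tie-counting
    quantile rank; values below 1/n_perm are flagged.
    """
    if mode not in ("overlap_genes", "nearest_distance"):
        raise ArgumentError(f"unknown mode: {mode}")
    if not features:
        raise ArgumentError("feature list is empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    spans = [(str(c), int(s), int(e)) for c, s, e in spans]
    for c, s, e in spans:
        if e <= s:
            raise ArgumentError("spans must be non-empty half-open intervals")

    stat = _overlap_count if mode == "overlap_genes" else _mean_nearest_distance
    observed = stat(spans, features)

    chrom_names = gmap.names
    chrom_lens = gmap.physical_lengths
    widths = [e - s for _, s, e in spans]

    permuted = np.empty(n_perm)
    for it in range(n_perm):
        for attempt in range(max_retries):
            placed = []
            ok = True
            for w in widths:
                valid = chrom_lens - w
                usable = np.maximum(valid, 0)
                if usable.sum() == 0:
                    raise ArgumentError("a span is longer than every chromosome")
                ci = rng.choice(len(chrom_names), p=usable / usable.sum())
                start = int(rng.integers(0, valid[ci] + 1))
                cand = (chrom_names[ci], start, start + w)
                if any(c == cand[0] and cand[1] < e and cand[2] > s for c, s, e in placed):
                    ok = False
                    break
                placed.append(cand)
            if ok:
                break
        else:
            raise ArgumentError("could not place spans without overlap within retry cap")
        permuted[it] = stat(placed, features)

    if mode == "overlap_genes":
        count = int((permuted >= observed).sum())
    else:
        count = int((permuted <= observed).sum())
    below = count == 0
    p = max(count, 1) / n_perm if below else count / n_perm
    return PermutationResult(float(observed), permuted, float(p), n_perm, below)
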