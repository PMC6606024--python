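"""Selection-coefficient inference from allele-frequency trajectories and
translation of locus effects into fractions of the selection response.

Selection is genic: each copy of the focal allele has relative fitness
1 + s, so the deterministic per-generation update is
q' = q(1+s) / (1 + s q) and the ln-odds of the allele grow by ln(1+s)
per generation.  The likelihood treats the latent population counts as a
hidden Markov chain with binomial Wright-Fisher transitions and binomial
sampling of the observed chromosome counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError

__all__ = [
    "Trajectory",
    "SEstimate",
    "wf_transition",
    "wf_matrix",
    "estimate_s",
    "drift_envelope",
    "contribution_arithmetic",
    "contribution_simulated",
    "simulate_trajectory",
]

DEFAULT_GRID = np.round(np.arange(-0.5, 1.0 + 1e-9, 0.005), 6)
LL_DROP_95 = 1.92  # asymptotic 95% CI from the likelihood-ratio chi2(1)/2


@dataclass
class Trajectory:
    """Generation-indexed focal-allele counts with sample sizes (chromosomes)."""

    generations: np.ndarray
    counts: np.ndarray
    sample_sizes: np.ndarray
    line: str = ""

    def __post_init__(self):
        self.generations = np.asarray(self.generations, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=int)
        if np.any(np.diff(self.generations) <= 0):
            raise ArgumentError("generations must be strictly increasing")
        if np.any(self.counts > self.sample_sizes) or np.any(self.counts < 0):
            raise ArgumentError("counts must lie in [0, sample size]")
        if self.generations.size < 2:
            raise ArgumentError("need at least 2 observed generations")

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.sample_sizes

    @property
    def delta_q(self) -> float:
        f = self.frequencies
        return float(f[-1] - f[0])

    @classmethod
    def from_tsv(cls, path, line: str = "") -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        return cls(df["generation"], df["focal_count"], df["n_chromosomes"], line)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "generation": self.generations,
                "focal_count": self.counts,
                "n_chromosomes": self.sample_sizes,
            }
        ).to_csv(path, sep="\t", index=False)


def wf_transition(count: int, ne: int, s: float) -> np.ndarray:
    """Distribution of next-generation counts: Binomial(2Ne, q(1+s)/(1+sq))."""
    two_n = 2 * ne
    if not (0 <= count <= two_n):
        raise ArgumentError("count must lie in [0, 2Ne]")
    if s <= -1:
        raise ArgumentError("s must be > -1")
    q = count / two_n
    q_star = q * (1 + s) / (1 + s * q)
    return stats.binom.pmf(np.arange(two_n + 1), two_n, q_star)


def wf_matrix(ne: int, s: float) -> np.ndarray:
    """Full (2Ne+1) x (2Ne+1) transition matrix; rows are current counts."""
    two_n = 2 * ne
    q = np.arange(two_n + 1) / two_n
    q_star = q * (1 + s) / (1 + s * q)
    k = np.arange(two_n + 1)
    return stats.binom.pmf(k[None, :], two_n, q_star[:, None])


@dataclass
class SEstimate:
    s_hat: float
    ci: tuple
    grid: np.ndarray
    loglik: np.ndarray
    delta_q: float
    ne: int
    meta: dict = field(default_factory=dict)


_matrix_cache: dict = {}


def _cached_matrix(ne: int, s: float) -> np.ndarray:
    key = (ne, round(float(s), 6))
    if key not in _matrix_cache:
        _matrix_cache[key] = wf_matrix(ne, s)
    return _matrix_cache[key]


def _loglik_one(traj: Trajectory, ne: int, s: float) -> float:
    two_n = 2 * ne
    counts = np.arange(two_n + 1)
    freqs = counts / two_n
    # prior over the latent state at the first observation: flat, then
    # conditioned on the first binomial sample
    alpha = stats.binom.pmf(traj.counts[0], traj.sample_sizes[0], freqs)
    alpha = alpha / max(alpha.sum(), 1e-300)
    ll = 0.0
    T = _cached_matrix(ne, s)
    for i in range(1, traj.generations.size):
        gap = traj.generations[i] - traj.generations[i - 1]
        for _ in range(gap):  # missing generations: chain the kernel
            alpha = alpha @ T
        emis = stats.binom.pmf(traj.counts[i], traj.sample_sizes[i], freqs)
        alpha = alpha * emis
        tot = alpha.sum()
        if tot <= 0:
            return -np.inf
        ll += np.log(tot)
        alpha = alpha / tot
    return float(ll)


def estimate_s(traj: Trajectory, ne: int = 46, grid=None, alpha: float = 0.05) -> SEstimate:
    """Maximum-likelihood s on a grid, with a likelihood-ratio-drop CI.

    The CI collects grid points within chi2_1(1 - alpha)/2 log-likelihood
    of the maximum (1.92 for the default 95% level).
    """
    if np.all(traj.counts == 0):
        raise ArgumentError("allele absent throughout; s is unidentifiable")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    ll = np.array([_loglik_one(traj, ne, s) for s in grid])
    best = int(np.argmax(ll))
    drop = float(stats.chi2.ppf(1 - alpha, df=1) / 2)
    inside = ll >= ll[best] - drop
    ci = (float(grid[inside].min()), float(grid[inside].max()))
    return SEstimate(
        s_hat=float(grid[best]),
        ci=ci,
        grid=grid,
        loglik=ll,
        delta_q=traj.delta_q,
        ne=ne,
    )


def simulate_trajectory(
    q0: float,
    ne: int,
    s: float,
    generations: int,
    sample_sizes=None,
    rng=None,
) -> Trajectory:
    """Forward-simulate one Wright-Fisher path with binomial sampling noise."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    two_n = 2 * ne
    count = int(round(q0 * two_n))
    counts = [count]
    for _ in range(generations):
        q = count / two_n
        q_star = q * (1 + s) / (1 + s * q)
        count = int(rng.binomial(two_n, q_star))
        counts.append(count)
    counts = np.array(counts)
    gens = np.arange(generations + 1)
    if sample_sizes is None:
        obs = counts
        sizes = np.full(counts.size, two_n)
    else:
        sizes = np.broadcast_to(np.asarray(sample_sizes, dtype=int), counts.shape).copy()
        obs = rng.binomial(sizes, counts / two_n)
    return Trajectory(gens, obs, sizes)


def drift_envelope(
    q0: float,
    ne: int,
    generations: int,
    alpha: float = 0.05,
    rng=None,
    n_paths: int = 100_000,
):
    """Empirical (alpha/2, 1-alpha/2) frequency bands under pure drift.

    Returns a frame (generation, lo, hi, mean); generation 0 collapses to
    the (count-rounded) starting frequency.
    """
    if not (0 < q0 < 1):
        raise ArgumentError("q0 must be in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    two_n = 2 * ne
    counts = np.full(n_paths, int(round(q0 * two_n)))
    rows = [(0, counts[0] / two_n, counts[0] / two_n, counts[0] / two_n)]
    for t in range(1, generations + 1):
        counts = rng.binomial(two_n, counts / two_n)
        freqs = counts / two_n
        lo, hi = np.quantile(freqs, [alpha / 2, 1 - alpha / 2])
        rows.append((t, float(lo), float(hi), float(freqs.mean())))
    return pd.DataFrame(rows, columns=["generation", "lo", "hi", "mean"])


def contribution_arithmetic(per_allele_effect: float, delta_q, total_increase: float) -> float:
    """Percent of the total trait increase explained by one locus.

    ``per_allele_effect`` and ``total_increase`` share units (percent of
    the trait); ``delta_q`` is one or more per-line frequency changes.
    """
    if total_increase <= 0:
        raise ArgumentError("total_increase must be > 0")
    dq = float(np.mean(np.asarray(delta_q, dtype=float)))
    return 100.0 * (2.0 * dq * per_allele_effect) / total_increase


def contribution_simulated(
    make_pedigree,
    gmap,
    model,
    target_delta_q: float = 0.7,
    q0: float = 0.17,
    n_replicates: int = 100,
    n_calibration: int = 24,
    tol: float = 0.02,
    a_bounds: tuple = (0.0, 0.9),
    max_iter: int = 8,
    seed=None,
    run_kwargs: dict | None = None,
):
    """Calibrate a major-locus effect to a target frequency change, then
    report its share of the selection response.

    ``make_pedigree`` is a zero-argument callable returning a fresh
    PedigreeTable (so replicates can share or vary the design).  Bisects
    on the per-copy effect ``a`` until the mean replicate delta-q matches
    ``target_delta_q`` within ``tol``; at the calibrated effect, runs
    ``n_replicates`` replicates and returns a dict with the mean
    contribution percentage, replicate (min, max) limits, the calibrated
    effect and the per-replicate values.  Contribution per replicate is
    2 * a * delta_q / total phenotypic response.
    """
    from .simulate import major_locus_injection

    rng = np.random.default_rng(seed)
    run_kwargs = dict(run_kwargs or {})
    run_kwargs.setdefault("compute_f", False)
    run_kwargs.setdefault("keep_genomes", ())

    def mean_dq(a, n_rep):
        dqs = []
        for _ in range(n_rep):
            sim = major_locus_injection(
                make_pedigree(), None, gmap, model, effect=a, q0=q0,
                rng=rng, **run_kwargs,
            )
            dqs.append(sim.trajectory[-1] - sim.trajectory[0])
        return float(np.mean(dqs))

    if target_delta_q == 0:
        a_star = 0.0
    else:
        lo, hi = a_bounds
        dq_hi = mean_dq(hi, n_calibration)
        if dq_hi < target_delta_q - tol:
            raise ArgumentError(
                f"target delta-q {target_delta_q} unreachable: effect {hi} gives {dq_hi:.3f}"
            )
        a_star = None
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            dq_mid = mean_dq(mid, n_calibration)
            if abs(dq_mid - target_delta_q) <= tol:
                a_star = mid
                break
            if dq_mid < target_delta_q:
                lo = mid
            else:
                hi = mid
        if a_star is None:
            a_star = 0.5 * (lo + hi)

    contribs = []
    dqs = []
    for _ in range(n_replicates):
        sim = major_locus_injection(
            make_pedigree(), None, gmap, model, effect=a_star, q0=q0,
            rng=rng, **run_kwargs,
        )
        dq = float(sim.trajectory[-1] - sim.trajectory[0])
        means = sim.per_generation["mean_trait"].to_numpy()
        total_resp = float(means[-1] - means[0])
        if total_resp <= 0:
            continue
        contribs.append(100.0 * 2.0 * a_star * dq / total_resp)
        dqs.append(dq)
    contribs = np.array(contribs)
    return {
        "mean": float(contribs.mean()),
        "limits": (float(contribs.min()), float(contribs.max())),
        "effect": float(a_star),
        "mean_delta_q": float(np.mean(dqs)),
        "contributions": contribs,
        "n_replicates": int(contribs.size),
    }
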