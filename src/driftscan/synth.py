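"""Synthetic inputs: genome maps, founder haplotype panels and pedigrees.

The founder panel mimics an outbred commercial stock: every founder
chromosome is a mosaic of a small ancestral haplotype pool, which induces
linkage disequilibrium with a tunable length scale.  The pedigree encodes
the breeding design (families per generation, realized litter sizes and
sexes, non-sibling pairings) but leaves the choice of breeders to the
simulator's selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, EmptyPanelError, PedigreeError

__all__ = [
    "GenomeMap",
    "FounderPanel",
    "PedigreeTable",
    "make_genome_map",
    "make_founder_panel",
    "make_pedigree",
    "write_pedigree_tsv",
    "read_pedigree_tsv",
    "write_panel_vcf",
]


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome scaffold: (name, physical length in bp, genetic length in Morgans)."""

    chromosomes: tuple

    def __post_init__(self):
        names = [c[0] for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ArgumentError("chromosome names must be unique")
        for name, bp, morgans in self.chromosomes:
            if bp <= 0:
                raise ArgumentError(f"{name}: physical length must be > 0")
            if morgans < 0:
                raise ArgumentError(f"{name}: genetic length must be >= 0")

    @property
    def names(self):
        return [c[0] for c in self.chromosomes]

    @property
    def physical_lengths(self):
        return np.array([c[1] for c in self.chromosomes], dtype=np.int64)

    @property
    def genetic_lengths(self):
        return np.array([c[2] for c in self.chromosomes], dtype=float)

    @property
    def total_morgans(self) -> float:
        return float(self.genetic_lengths.sum())

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def __len__(self):
        return len(self.chromosomes)


def make_genome_map(n_chrom: int, bp_per_chrom: int, morgans_per_chrom: float) -> GenomeMap:
    """Uniform genome map with ``n_chrom`` chromosomes named chr1..chrN."""
    if n_chrom < 1:
        raise ArgumentError("n_chrom must be >= 1")
    if bp_per_chrom <= 0 or morgans_per_chrom < 0:
        raise ArgumentError("chromosome lengths must be positive")
    chroms = tuple(
        (f"chr{i + 1}", int(bp_per_chrom), float(morgans_per_chrom)) for i in range(n_chrom)
    )
    return GenomeMap(chroms)


@dataclass
class FounderPanel:
    """Phased founder haplotypes over segregating biallelic sites.

    ``haplotypes[chrom]`` has shape (2 * n_founders, n_sites); row 2i and
    2i+1 are the two haplotypes of founder individual i.  Positions are
    0-based internally (converted to 1-based on VCF output).
    """

    positions: dict
    haplotypes: dict
    ancestral_pool_size: int
    seed: int | None = None

    @property
    def n_haplotypes(self) -> int:
        first = next(iter(self.haplotypes.values()))
        return first.shape[0]

    @property
    def n_founders(self) -> int:
        return self.n_haplotypes // 2

    @property
    def n_sites(self) -> int:
        return sum(p.size for p in self.positions.values())

    def frequencies(self, chrom: str) -> np.ndarray:
        """Pooled alternate-allele frequency per site on ``chrom``."""
        return self.haplotypes[chrom].mean(axis=0)

    def validate(self) -> None:
        for chrom, pos in self.positions.items():
            if np.any(np.diff(pos) <= 0):
                raise ArgumentError(f"{chrom}: positions must be strictly increasing")
            hap = self.haplotypes[chrom]
            if not np.isin(hap, (0, 1)).all():
                raise ArgumentError("alleles must be 0/1")
            freq = hap.mean(axis=0)
            if np.any((freq <= 0) | (freq >= 1)):
                raise ArgumentError(f"{chrom}: monomorphic sites present")


def make_founder_panel(
    gmap: GenomeMap,
    n_founders: int,
    snp_density: float,
    ancestral_pool: int = 18,
    block_length: float | None = 500_000.0,
    maf_floor: float = 0.05,
    seed: int | None = None,
) -> FounderPanel:
    """Draw a founder panel whose haplotypes are mosaics of an ancestral pool.

    Per chromosome: site positions are uniform at the requested density;
    each site gets an ancestral-pool frequency from a U-shaped Beta(0.5, 0.5)
    spectrum truncated at ``maf_floor``; pool haplotypes carry i.i.d.
    Bernoulli alleles at those frequencies.  Founder haplotypes copy the
    pool in blocks with exponentially distributed lengths (mean
    ``block_length``; ``None`` or ``inf`` means one block per chromosome).
    Sites monomorphic in the realized panel are dropped.
    """
    if ancestral_pool < 1:
        raise ArgumentError("ancestral_pool must be >= 1")
    # pool size 1 is allowed through: every site is monomorphic and the
    # realized panel fails as empty, which is the informative error
    if snp_density <= 0:
        raise ArgumentError("snp_density must be > 0")
    if not (0 <= maf_floor < 0.5):
        raise ArgumentError("maf_floor must be in [0, 0.5)")
    if n_founders < 1:
        raise ArgumentError("n_founders must be >= 1")

    rng = np.random.default_rng(seed)
    positions: dict[str, np.ndarray] = {}
    haplotypes: dict[str, np.ndarray] = {}
    n_hap = 2 * n_founders

    for name, length, _ in gmap.chromosomes:
        n_sites = int(round(snp_density * length))
        if n_sites == 0:
            positions[name] = np.empty(0, dtype=np.int64)
            haplotypes[name] = np.empty((n_hap, 0), dtype=np.int8)
            continue
        pos = np.sort(rng.choice(length, size=min(n_sites, length), replace=False))

        # U-shaped spectrum, truncated by rejection at the MAF floor.
        freq = rng.beta(0.5, 0.5, size=pos.size)
        bad = (freq < maf_floor) | (freq > 1 - maf_floor)
        while bad.any():
            freq[bad] = rng.beta(0.5, 0.5, size=int(bad.sum()))
            bad = (freq < maf_floor) | (freq > 1 - maf_floor)

        pool = (rng.random((ancestral_pool, pos.size)) < freq).astype(np.int8)

        hap = np.empty((n_hap, pos.size), dtype=np.int8)
        for h in range(n_hap):
            hap[h] = pool[_mosaic_sources(rng, pos, length, ancestral_pool, block_length), np.arange(pos.size)]

        freq_real = hap.mean(axis=0)
        keep = (freq_real > 0) & (freq_real < 1)
        positions[name] = pos[keep].astype(np.int64)
        haplotypes[name] = np.ascontiguousarray(hap[:, keep])

    if sum(p.size for p in positions.values()) == 0:
        raise EmptyPanelError("no segregating sites produced; raise density or pool size")

    panel = FounderPanel(positions, haplotypes, ancestral_pool, seed)
    panel.validate()
    return panel


def _mosaic_sources(rng, pos, length, pool_size, block_length):
    """Ancestral-pool source index for each site of one mosaic haplotype."""
    if block_length is None or not np.isfinite(block_length):
        return np.full(pos.size, rng.integers(pool_size))
    # Block boundaries from an exponential renewal process along the chromosome.
    n_blocks_guess = max(4, int(3 * length / block_length) + 4)
    edges = np.cumsum(rng.exponential(block_length, size=n_blocks_guess))
    while edges[-1] < length:
        edges = np.concatenate([edges, edges[-1] + np.cumsum(rng.exponential(block_length, size=n_blocks_guess))])
    edges = edges[edges < length]
    sources = rng.integers(pool_size, size=edges.size + 1)
    return sources[np.searchsorted(edges, pos, side="right")]


@dataclass
class PedigreeTable:
    """Breeding design: individuals plus per-generation family pairings.

    ``individuals`` columns: id, sire, dam, sex ('M'/'F'), generation,
    line, family (index of the breeding pair that produced the
    individual; founders belong to their own pair).  ``pairings`` maps
    generation g >= 1 to an array of (sire_family, dam_family) giving, for
    each family of generation g, which generation-(g-1) families supply
    the breeding male and female.  Sire/dam ids are filled in by the
    simulator once breeders are chosen.
    """

    individuals: pd.DataFrame
    pairings: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_generations(self) -> int:
        return int(self.individuals["generation"].max()) + 1

    @property
    def n_pairs(self) -> int:
        return int(self.individuals.loc[self.individuals.generation == 0].shape[0] // 2)

    def generation(self, g: int) -> pd.DataFrame:
        return self.individuals.loc[self.individuals.generation == g]

    def validate(self) -> None:
        df = self.individuals
        if df.loc[df.generation == 0, ["sire", "dam"]].to_numpy().max(initial=-1) != -1:
            raise PedigreeError("founders must have no parents")
        filled = df[(df.sire >= 0) | (df.dam >= 0)]
        if len(filled):
            gen_of = df.set_index("id")["generation"]
            for col in ("sire", "dam"):
                parent_gen = gen_of.reindex(filled[col]).to_numpy()
                if np.any(parent_gen != filled["generation"].to_numpy() - 1):
                    raise PedigreeError("parents must come from the previous generation")


def make_pedigree(
    n_pairs: int,
    n_generations: int,
    offspring_per_pair=12,
    seed: int | None = None,
    line: str = "L1",
    max_retries: int = 100,
) -> PedigreeTable:
    """Generate a breeding design with ``n_pairs`` families per generation.

    ``offspring_per_pair`` is either a constant int or ``("poisson", mean)``.
    Each family's sexes are i.i.d. Bernoulli(0.5), regenerated (up to
    ``max_retries``) until both sexes are present, since every family must
    supply one breeding male and one female.  Sibling pairings are excluded
    by drawing a derangement of families each generation.
    """
    if n_pairs < 2:
        raise ArgumentError("n_pairs must be >= 2")
    if n_generations < 1:
        raise ArgumentError("n_generations must be >= 1")
    dist = _offspring_sampler(offspring_per_pair)

    rng = np.random.default_rng(seed)
    rows = []
    next_id = 0
    for j in range(n_pairs):
        for sex in ("M", "F"):
            rows.append((next_id, -1, -1, sex, 0, line, j))
            next_id += 1

    pairings: dict[int, np.ndarray] = {}
    for g in range(1, n_generations + 1):
        perm = _derangement(rng, n_pairs)
        pairings[g] = np.column_stack([np.arange(n_pairs), perm])
        for j in range(n_pairs):
            for attempt in range(max_retries):
                n_off = dist(rng)
                sexes = np.where(rng.random(n_off) < 0.5, "M", "F")
                if (sexes == "M").any() and (sexes == "F").any():
                    break
            else:
                raise PedigreeError(
                    f"family {j} generation {g}: no viable sex split in {max_retries} tries"
                )
            for sex in sexes:
                rows.append((next_id, -2, -2, sex, g, line, j))
                next_id += 1

    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation", "line", "family"])
    ped = PedigreeTable(df, pairings, seed)
    return ped


def _offspring_sampler(spec):
    if isinstance(spec, int):
        if spec < 2:
            raise ArgumentError("constant offspring count must be >= 2")
        return lambda rng: spec
    if isinstance(spec, tuple) and len(spec) == 2 and spec[0] == "poisson":
        mean = float(spec[1])
        if mean < 2:
            raise ArgumentError("offspring distribution mean must be >= 2")
        return lambda rng: max(2, int(rng.poisson(mean)))
    if callable(spec):
        return spec
    raise ArgumentError(f"unrecognized offspring spec: {spec!r}")


def _derangement(rng, n):
    """Permutation of range(n) with no fixed point (mate family != own family)."""
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


# ---------------------------------------------------------------------------
# plain-text interchange


def write_pedigree_tsv(ped: PedigreeTable, path) -> None:
    ped.individuals.to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> PedigreeTable:
    df = pd.read_csv(path, sep="\t")
    return PedigreeTable(df)


def write_panel_vcf(panel: FounderPanel, gmap: GenomeMap, path, sample_prefix: str = "F0_") -> None:
    """Write founder haplotypes as a phased VCF (uncompressed text)."""
    n = panel.n_founders
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=driftscan\n")
        for name, length, _ in gmap.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for name, _, _ in gmap.chromosomes:
            pos = panel.positions.get(name)
            if pos is None or pos.size == 0:
                continue
            hap = panel.haplotypes[name]
            for j in range(pos.size):
                gts = "\t".join(f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(n))
                fh.write(f"{name}\t{pos[j] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
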