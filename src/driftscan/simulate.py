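"""Gene dropping of junction genomes down a pedigree under truncation selection.

A diploid genome is stored per chromosome as two homologs, each an ordered
list of (segment start, founder-haplotype label) pairs.  Crossovers are
uniform along the physical chromosome at a Poisson rate equal to the genetic
map length, with no interference.  The trait is the sum of an infinitesimal
background (a dense grid of loci with i.i.d. Gaussian founder-haplotype
effects, variance ``vg``), a discrete-locus component (``n_discrete_loci``
evenly spaced loci, variance ``vs``) and Gaussian noise (``ve``); genetic
variance is split across chromosomes in proportion to map length.

After the run, SNP genotypes at arbitrary generations are reconstructed by
seeding founder segments with panel haplotypes under one of three
linkage-disequilibrium schemes (``no_ld``, ``min_ld``, ``max_ld``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConsistencyError
from .synth import FounderPanel, GenomeMap, PedigreeTable

__all__ = [
    "JunctionGenome",
    "TraitModel",
    "EffectTables",
    "SimResult",
    "GenotypeData",
    "founder_genome",
    "meiosis",
    "draw_effects",
    "breeding_value",
    "trait_value",
    "composite_trait",
    "estimate_phi",
    "run_experiment",
    "major_locus_injection",
    "seed_snps",
    "seed_snps_groups",
    "inbreeding",
    "inbreeding_series",
    "ne_from_inbreeding",
    "write_genotype_vcf",
]

LD_MODES = ("no_ld", "min_ld", "max_ld")


# ---------------------------------------------------------------------------
# junction genomes


@dataclass
class JunctionGenome:
    """Per chromosome: two homologs, each (starts, labels) int arrays.

    ``starts[0]`` is always 0; labels are founder-haplotype identifiers.
    Homolog tuples are treated as immutable and may be shared between
    individuals (copy-on-write during meiosis).
    """

    chroms: list

    def validate(self, gmap: GenomeMap) -> None:
        for (name, length, _), homs in zip(gmap.chromosomes, self.chroms):
            for starts, labels in homs:
                if starts[0] != 0:
                    raise ArgumentError(f"{name}: first breakpoint must be 0")
                if np.any(np.diff(starts) <= 0) or starts[-1] >= length:
                    raise ArgumentError(f"{name}: breakpoints must increase and stay < length")
                if np.any(labels[1:] == labels[:-1]):
                    raise ArgumentError(f"{name}: adjacent segments share a label")

    def max_label(self) -> int:
        return max(int(labels.max()) for homs in self.chroms for _, labels in homs)


def founder_genome(founder_index: int, gmap: GenomeMap) -> JunctionGenome:
    """Founder i carries its own haplotype labels 2i and 2i+1, unrecombined."""
    zero = np.zeros(1, dtype=np.int64)
    chroms = []
    for _ in gmap.chromosomes:
        h0 = (zero, np.array([2 * founder_index], dtype=np.int64))
        h1 = (zero, np.array([2 * founder_index + 1], dtype=np.int64))
        chroms.append((h0, h1))
    return JunctionGenome(chroms)


def _merge_segments(starts, labels):
    if len(labels) <= 1:
        return starts, labels
    keep = np.empty(len(labels), dtype=bool)
    keep[0] = True
    np.not_equal(labels[1:], labels[:-1], out=keep[1:])
    if keep.all():
        return starts, labels
    return starts[keep], labels[keep]


def recombine(hom0, hom1, xovers, start_homolog: int, length: int):
    """Haploid product given sorted crossover positions and a starting homolog."""
    homs = (hom0, hom1)
    cur = start_homolog
    bounds = np.concatenate([[0], xovers, [length]])
    out_starts, out_labels = [], []
    for k in range(len(bounds) - 1):
        a, b = int(bounds[k]), int(bounds[k + 1])
        if a >= b:
            cur ^= 1
            continue
        starts, labels = homs[cur]
        i = int(np.searchsorted(starts, a, side="right")) - 1
        j = int(np.searchsorted(starts, b, side="left"))
        seg = starts[i:j].copy()
        seg[0] = a
        out_starts.append(seg)
        out_labels.append(labels[i:j])
        cur ^= 1
    starts = np.concatenate(out_starts)
    labels = np.concatenate(out_labels)
    return _merge_segments(starts, labels)


def meiosis(parent: JunctionGenome, gmap: GenomeMap, rng) -> list:
    """One gamete: per chromosome, Poisson(map length) uniform crossovers."""
    gamete = []
    for (_, length, morgans), (hom0, hom1) in zip(gmap.chromosomes, parent.chroms):
        n_x = rng.poisson(morgans) if morgans > 0 else 0
        start = int(rng.integers(2))
        if n_x == 0:
            gamete.append((hom0, hom1)[start])
            continue
        xovers = np.sort(rng.integers(1, length, size=n_x))
        gamete.append(recombine(hom0, hom1, xovers, start, length))
    return gamete


def inbreeding(genome: JunctionGenome, gmap: GenomeMap) -> float:
    """Fraction of the genome where the two homologs carry the same label."""
    ibd = 0
    total = 0
    for (_, length, _), ((s0, l0), (s1, l1)) in zip(gmap.chromosomes, genome.chroms):
        total += length
        bounds = np.union1d(s0, s1)
        a0 = l0[np.searchsorted(s0, bounds, side="right") - 1]
        a1 = l1[np.searchsorted(s1, bounds, side="right") - 1]
        widths = np.diff(np.append(bounds, length))
        ibd += int(widths[a0 == a1].sum())
    return ibd / total


# ---------------------------------------------------------------------------
# trait model and effect tables


@dataclass
class TraitModel:
    """Variance components and locus layout of the composite trait."""

    vg: float = 0.2
    vs: float = 0.2
    ve: float = 0.6
    n_discrete_loci: int = 10_000
    grid_per_morgan: float = 1000.0
    phi: float = -0.57

    def __post_init__(self):
        if min(self.vg, self.vs, self.ve) < 0:
            raise ArgumentError("variance components must be >= 0")

    @property
    def h2(self) -> float:
        tot = self.vg + self.vs + self.ve
        return 0.0 if tot == 0 else (self.vg + self.vs) / tot


@dataclass
class EffectTables:
    """Per component, per chromosome: grid positions and per-label cumulative sums.

    ``tables[comp][c]`` is (positions float array of length L, cumsum array of
    shape (n_labels, L + 1)); a founder segment's contribution is a prefix-sum
    difference, so breeding values cost O(segments) rather than O(loci).
    ``merged`` collapses both components into one sorted grid per chromosome
    and is what breeding_value actually walks.
    """

    tables: dict
    n_labels: int
    merged: list = None

    def component_items(self):
        return self.tables.items()


def _allocate_loci(total: int, gmap: GenomeMap) -> np.ndarray:
    """Largest-remainder allocation of ``total`` loci proportional to map length."""
    gl = gmap.genetic_lengths
    if gl.sum() == 0:
        return np.zeros(len(gl), dtype=int)
    quota = total * gl / gl.sum()
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    return counts


def draw_effects(
    n_labels: int,
    gmap: GenomeMap,
    model: TraitModel,
    rng,
    standardize: bool = True,
) -> EffectTables:
    """I.i.d. Gaussian effects for every founder haplotype at every grid locus.

    Per-chromosome variance targets are proportional to genetic length;
    with ``standardize`` the realized founder-population variance of each
    component is rescaled to hit its target exactly (shares across
    chromosomes keep their sampled proportions).
    """
    specs = {}
    gl = gmap.genetic_lengths
    total_m = gl.sum()
    grid_counts = np.maximum((gl * model.grid_per_morgan).round().astype(int), (gl > 0).astype(int))
    specs["infinitesimal"] = (model.vg, grid_counts)
    specs["discrete"] = (model.vs, _allocate_loci(model.n_discrete_loci, gmap))

    raw = {}
    for comp, (v_target, counts) in specs.items():
        per_chrom = []
        for (name, length, morgans), n_loci in zip(gmap.chromosomes, counts):
            if n_loci == 0 or v_target == 0 or total_m == 0:
                per_chrom.append((np.empty(0), np.zeros((n_labels, 0))))
                continue
            v_c = v_target * morgans / total_m
            sigma = np.sqrt(v_c / (2 * n_loci))
            pos = (np.arange(n_loci) + 0.5) * (length / n_loci)
            eff = rng.normal(0.0, sigma, size=(n_labels, n_loci))
            per_chrom.append((pos, eff))
        if standardize and v_target > 0:
            totals = sum(eff.sum(axis=1) for _, eff in per_chrom)  # per-haplotype sums
            diploid = totals[0::2] + totals[1::2]
            v_real = diploid.var()
            if v_real > 0:
                scale = np.sqrt(v_target / v_real)
                per_chrom = [(pos, eff * scale) for pos, eff in per_chrom]
        raw[comp] = per_chrom

    def _cumulate(pos, eff):
        cum = np.zeros((n_labels, pos.size + 1))
        np.cumsum(eff, axis=1, out=cum[:, 1:])
        return pos, cum

    tables = {comp: [_cumulate(pos, eff) for pos, eff in per_chrom] for comp, per_chrom in raw.items()}
    merged = []
    for c in range(len(gmap.chromosomes)):
        parts = [raw[comp][c] for comp in raw]
        pos = np.concatenate([p for p, _ in parts])
        eff = np.concatenate([e for _, e in parts], axis=1)
        order = np.argsort(pos, kind="stable")
        merged.append(_cumulate(pos[order], eff[:, order]))
    return EffectTables(tables, n_labels, merged)


def breeding_value(genome: JunctionGenome, effects: EffectTables) -> float:
    """Sum of grid-locus effects covered by each founder segment, both homologs."""
    if genome.max_label() >= effects.n_labels:
        raise ConsistencyError("genome carries a label missing from the effect table")
    bv = 0.0
    for (pos, cum), homs in zip(effects.merged, genome.chroms):
        n = pos.size
        if n == 0:
            continue
        for starts, labels in homs:
            idx = np.searchsorted(pos, starts)
            bounds = np.empty(idx.size + 1, dtype=np.intp)
            bounds[:-1] = idx
            bounds[-1] = n
            bv += float((cum[labels, bounds[1:]] - cum[labels, bounds[:-1]]).sum())
    return bv


def trait_value(genome: JunctionGenome, effects: EffectTables, model: TraitModel, rng):
    """(breeding value, phenotype): phenotype adds Normal(0, ve) noise."""
    bv = breeding_value(genome, effects)
    return bv, bv + rng.normal(0.0, np.sqrt(model.ve))


# ---------------------------------------------------------------------------
# composite trait and phi estimation


def composite_trait(T, B, phi: float):
    """Composite score ln(T) + phi * ln(B); ranking proxy for the breeding index."""
    T = np.asarray(T, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(T <= 0) or np.any(B <= 0):
        raise ArgumentError("T and B must be positive")
    out = np.log(T) + phi * np.log(B)
    return float(out) if out.ndim == 0 else out


def estimate_phi(table: pd.DataFrame, grid=None):
    """Grid-search the composite exponent that best recovers realized breeder choices.

    ``table`` columns: T, B, sex, family, chosen (bool); optionally
    generation.  For each (family, sex[, generation]) group the top-ranked
    candidate under the composite score is compared with the actually
    chosen breeder.  Returns (phi_hat, concordance); ties on concordance
    break toward phi closest to 0.
    """
    if grid is None:
        grid = np.round(np.arange(-2.0, 0.0 + 1e-9, 0.01), 10)
    keys = ["family", "sex"] + (["generation"] if "generation" in table.columns else [])
    groups = list(table.groupby(keys, sort=False))
    for key, grp in groups:
        if len(grp) < 2:
            raise ArgumentError(f"group {key} has fewer than 2 candidates")
    best = None
    for phi in grid:
        hits = 0
        total = 0
        for _, grp in groups:
            if not grp["chosen"].any():
                continue
            score = composite_trait(grp["T"].to_numpy(), grp["B"].to_numpy(), phi)
            top = int(np.argmax(score))
            hits += bool(grp["chosen"].to_numpy()[top])
            total += 1
        frac = hits / max(total, 1)
        # strict > keeps the earlier phi on ties; grid runs toward 0, so
        # '>= on equal distance' is handled by preferring later (closer to 0)
        if best is None or frac > best[1] or (frac == best[1] and abs(phi) < abs(best[0])):
            best = (float(phi), frac)
    return best


# ---------------------------------------------------------------------------
# running the experiment


@dataclass
class SimResult:
    """Outcome of one gene-dropping run."""

    individuals: pd.DataFrame
    per_generation: pd.DataFrame
    genomes: dict
    gmap: GenomeMap
    model: TraitModel
    trajectory: np.ndarray | None = None
    locus: tuple | None = None
    meta: dict = field(default_factory=dict)


def _select_breeders(ids, fams, sexes, phen, selection, rng, scope="family"):
    """Ids of the breeding (male, female) per family, keyed by family index."""
    chosen: dict[int, dict] = {}
    uniq_fams = sorted(set(int(f) for f in fams))
    if selection == "random" and scope == "line":
        for sex in ("M", "F"):
            pool = ids[sexes == sex]
            picks = rng.choice(pool, size=len(uniq_fams), replace=False)
            for fam, pick in zip(uniq_fams, picks):
                chosen.setdefault(fam, {})[sex] = int(pick)
        return chosen
    for fam in uniq_fams:
        chosen[fam] = {}
        in_fam = fams == fam
        for sex in ("M", "F"):
            m = in_fam & (sexes == sex)
            if not m.any():
                raise ConsistencyError(f"family {fam} has no {sex} offspring")
            cand_ids = ids[m]
            if selection == "truncation":
                # ties broken toward the lowest id
                order = np.lexsort((cand_ids, -phen[m]))
                chosen[fam][sex] = int(cand_ids[order[0]])
            elif selection == "random":
                chosen[fam][sex] = int(rng.choice(cand_ids))
            else:
                raise ArgumentError(f"unknown selection mode: {selection}")
    return chosen


def _locus_copies(genome, locus):
    c_idx, pos, _, carriers = locus
    copies = 0
    for starts, labels in genome.chroms[c_idx]:
        lab = labels[np.searchsorted(starts, pos, side="right") - 1]
        copies += int(carriers[lab])
    return copies


def run_experiment(
    ped: PedigreeTable,
    panel: FounderPanel | None,
    gmap: GenomeMap,
    model: TraitModel,
    selection: str = "truncation",
    rng=None,
    effects: EffectTables | None = None,
    major_locus: tuple | None = None,
    keep_genomes="all",
    random_scope: str = "family",
    compute_f: bool = True,
) -> SimResult:
    """Drop genomes down the pedigree, selecting breeders per family.

    Under ``truncation`` the male and female with the largest phenotype in
    each family breed; under ``random`` breeders are drawn uniformly
    (per family, or line-wide with ``random_scope='line'``).
    ``major_locus`` is (chrom_index, position, effect_per_copy,
    carrier_mask_over_labels); its additive contribution is added on top
    of the infinitesimal components and its allele frequency is recorded
    per generation.  ``keep_genomes`` is 'all', or an iterable of
    generation indices to retain.
    """
    if selection not in ("truncation", "random"):
        raise ArgumentError(f"unknown selection mode: {selection}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    df = ped.individuals.sort_values(["generation", "id"]).reset_index(drop=True)
    n_founders = int((df.generation == 0).sum())
    if panel is not None and panel.n_founders != n_founders:
        raise ConsistencyError("pedigree founder count does not match panel")
    n_labels = 2 * n_founders
    if effects is None:
        effects = draw_effects(n_labels, gmap, model, rng)

    keep = None if keep_genomes == "all" else set(keep_genomes)
    gen_arr = df.generation.to_numpy()
    id_arr = df.id.to_numpy()
    fam_arr = df.family.to_numpy()
    sex_arr = df.sex.to_numpy()
    sire_arr = df.sire.to_numpy().copy()
    dam_arr = df.dam.to_numpy().copy()
    n_gens = int(gen_arr.max()) + 1
    n_total = len(df)
    bv_arr = np.zeros(n_total)
    phen_arr = np.zeros(n_total)
    sel_arr = np.zeros(n_total, dtype=bool)
    f_arr = np.zeros(n_total)
    idx_of = {int(i): k for k, i in enumerate(id_arr)}

    genomes_kept: dict[int, JunctionGenome] = {}
    per_gen_rows = []
    traj = [] if major_locus is not None else None
    cur: dict[int, JunctionGenome] = {}
    sqrt_ve = np.sqrt(model.ve)

    for g in range(n_gens):
        rows = np.flatnonzero(gen_arr == g)
        gen_ids = id_arr[rows]
        if g == 0:
            for fidx, i in enumerate(gen_ids):
                cur[int(i)] = founder_genome(fidx, gmap)
        bvs = np.empty(gen_ids.size)
        for k, i in enumerate(gen_ids):
            genome = cur[int(i)]
            bv = breeding_value(genome, effects)
            if major_locus is not None:
                bv += major_locus[2] * _locus_copies(genome, major_locus)
            bvs[k] = bv
        phen = bvs + rng.normal(0.0, sqrt_ve, size=gen_ids.size)
        bv_arr[rows] = bvs
        phen_arr[rows] = phen
        if compute_f:
            f_arr[rows] = [inbreeding(cur[int(i)], gmap) for i in gen_ids]
        if traj is not None:
            copies = sum(_locus_copies(cur[int(i)], major_locus) for i in gen_ids)
            traj.append(copies / (2 * gen_ids.size))

        if g < n_gens - 1:
            chosen = _select_breeders(
                gen_ids, fam_arr[rows], sex_arr[rows], phen, selection, rng, random_scope
            )
            for fam in chosen.values():
                for i in fam.values():
                    sel_arr[idx_of[i]] = True

            next_rows = np.flatnonzero(gen_arr == g + 1)
            fam_parent = {}
            for row in ped.pairings[g + 1]:
                fam_parent[int(row[0])] = (chosen[int(row[0])]["M"], chosen[int(row[1])]["F"])
            nxt: dict[int, JunctionGenome] = {}
            for r in next_rows:
                sire_id, dam_id = fam_parent[int(fam_arr[r])]
                sire_arr[r], dam_arr[r] = sire_id, dam_id
                gam_s = meiosis(cur[sire_id], gmap, rng)
                gam_d = meiosis(cur[dam_id], gmap, rng)
                nxt[int(id_arr[r])] = JunctionGenome(list(zip(gam_s, gam_d)))
        else:
            nxt = {}

        # generation summary
        mean_t = float(phen.mean())
        sd_t = float(phen.std())
        sel_mask = sel_arr[rows]
        s_val = np.nan
        if sel_mask.any() and sd_t > 0:
            s_val = (float(phen[sel_mask].mean()) - mean_t) / sd_t
        per_gen_rows.append((g, mean_t, sd_t, s_val, float(f_arr[rows].mean())))

        if keep is None or g in keep:
            genomes_kept.update(cur)
        cur = nxt

    df = df.assign(sire=sire_arr, dam=dam_arr, bv=bv_arr, phenotype=phen_arr,
                   selected=sel_arr, F=f_arr)
    per_gen = pd.DataFrame(per_gen_rows, columns=["generation", "mean_trait", "sd_trait", "S", "mean_F"])
    means = per_gen.mean_trait.to_numpy()
    sds = per_gen.sd_trait.to_numpy()
    resp = np.full(len(per_gen), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        resp[:-1] = np.diff(means) / np.where(sds[:-1] > 0, sds[:-1], np.nan)
    per_gen["R"] = resp

    return SimResult(
        individuals=df,
        per_generation=per_gen,
        genomes=genomes_kept,
        gmap=gmap,
        model=model,
        trajectory=np.array(traj) if traj is not None else None,
        locus=major_locus,
        meta={"selection": selection, "n_founders": n_founders},
    )


def major_locus_injection(
    ped: PedigreeTable,
    panel: FounderPanel | None,
    gmap: GenomeMap,
    model: TraitModel,
    effect: float,
    q0: float,
    position: tuple | None = None,
    rng=None,
    selection: str = "truncation",
    **kwargs,
) -> SimResult:
    """Run with one additive biallelic locus of effect ``effect`` per copy.

    The locus starts at frequency ``q0`` (realized as the closest count of
    carrier founder haplotypes, placed at random) and the infinitesimal
    variance is rescaled so total initial genetic variance is unchanged.
    """
    if not (0 < q0 < 1):
        raise ArgumentError("q0 must be in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_founders = int((ped.individuals.generation == 0).sum())
    n_labels = 2 * n_founders
    n_car = int(round(q0 * n_labels))
    n_car = min(max(n_car, 1), n_labels - 1)
    carriers = np.zeros(n_labels, dtype=bool)
    carriers[rng.choice(n_labels, size=n_car, replace=False)] = True
    q0_real = n_car / n_labels

    v_locus = 2 * q0_real * (1 - q0_real) * effect**2
    v_bg = model.vg + model.vs
    if effect != 0:
        if v_locus > v_bg:
            raise ArgumentError("locus effect too large: background variance would be negative")
        kappa = (v_bg - v_locus) / v_bg if v_bg > 0 else 0.0
    else:
        kappa = 1.0
    scaled = TraitModel(
        vg=model.vg * kappa,
        vs=model.vs * kappa,
        ve=model.ve,
        n_discrete_loci=model.n_discrete_loci,
        grid_per_morgan=model.grid_per_morgan,
        phi=model.phi,
    )
    if position is None:
        name, length, _ = gmap.chromosomes[0]
        position = (name, length // 2)
    c_idx = gmap.names.index(position[0])
    locus = (c_idx, int(position[1]), float(effect), carriers)
    return run_experiment(
        ped, panel, gmap, scaled, selection=selection, rng=rng, major_locus=locus, **kwargs
    )


# ---------------------------------------------------------------------------
# inbreeding and effective size


def inbreeding_series(sim: SimResult) -> np.ndarray:
    """Mean identity-by-descent fraction per generation."""
    return sim.per_generation["mean_F"].to_numpy()


def ne_from_inbreeding(f_series, tol: float = 0.02) -> float:
    """Fit 1 - F_t = (1 - dF)^t through the origin on log(1 - F); Ne = 1/(2 dF)."""
    f = np.asarray(f_series, dtype=float)
    if f.size < 3:
        raise ArgumentError("need at least 3 generations of F")
    if np.any(np.diff(f) < -tol):
        warnings.warn("inbreeding series is non-monotone; fitting anyway", stacklevel=2)
    t = np.arange(f.size)
    y = np.log1p(-np.clip(f, 0.0, 1.0 - 1e-12))
    denom = float((t * t).sum())
    slope = float((t * y).sum()) / denom
    d_f = 1.0 - np.exp(slope)
    if d_f <= 0:
        return float("inf")
    return 1.0 / (2.0 * d_f)


# ---------------------------------------------------------------------------
# SNP seeding


@dataclass
class GenotypeData:
    """Diploid genotype matrices (individuals x sites) per chromosome."""

    positions: dict
    genotypes: dict
    samples: list

    def site_table(self):
        """(chroms, positions, genotype matrix) concatenated over chromosomes."""
        chroms, pos, gts = [], [], []
        for name, p in self.positions.items():
            chroms.extend([name] * p.size)
            pos.append(p)
            gts.append(self.genotypes[name])
        return np.array(chroms), np.concatenate(pos), np.hstack(gts)


def _shared_intervals(genome_list, c_idx, length):
    starts = [homs[c_idx][h][0] for homs in (g.chroms for g in genome_list) for h in (0, 1)]
    bounds = np.unique(np.concatenate(starts))
    return np.append(bounds, length)


def seed_snps(
    genomes: list,
    panel: FounderPanel,
    gmap: GenomeMap,
    ld_mode: str,
    rng,
    samples: list | None = None,
) -> GenotypeData:
    """Reconstruct SNP genotypes from junction mosaics under an LD scheme.

    ``no_ld``: every founder haplotype gets fresh i.i.d. alleles at the
    panel pooled frequency (linkage equilibrium).  ``min_ld``: founder
    diploid genotypes are kept; heterozygous sites are re-phased by a fair
    coin per site.  ``max_ld``: heterozygous sites are phased consistently
    within each shared-ancestry interval (all alternate alleles on one
    homolog).  Homozygous sites are identical under all modes.
    """
    if ld_mode not in LD_MODES:
        raise ArgumentError(f"unknown LD mode: {ld_mode!r} (use one of {LD_MODES})")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_ind = len(genomes)
    n_lab = 2 * panel.n_founders
    max_lab = max(g.max_label() for g in genomes)
    if max_lab >= n_lab:
        raise ConsistencyError("genome labels exceed panel haplotype count")

    positions = {}
    out = {}
    for c_idx, (name, length, _) in enumerate(gmap.chromosomes):
        pos = panel.positions[name]
        positions[name] = pos
        n_sites = pos.size
        gt = np.zeros((n_ind, n_sites), dtype=np.int8)
        if n_sites == 0:
            out[name] = gt
            continue
        H_true = panel.haplotypes[name]
        if ld_mode == "no_ld":
            # linkage equilibrium: heterozygous-site alleles are redrawn
            # independently at the panel frequency; homozygous sites are kept
            # (identical under all modes)
            p = H_true.mean(axis=0)
            H = H_true.copy()
            G = H_true[0::2] + H_true[1::2]
            het = G == 1
            for i in range(panel.n_founders):
                m = het[i]
                k = int(m.sum())
                if k:
                    H[2 * i, m] = rng.random(k) < p[m]
                    H[2 * i + 1, m] = rng.random(k) < p[m]
        elif ld_mode == "min_ld":
            H = H_true.copy()
            G = H_true[0::2] + H_true[1::2]
            het = G == 1
            flip = rng.integers(2, size=het.shape).astype(bool) & het
            for i in range(panel.n_founders):
                f = flip[i]
                H[2 * i, f] = 1 - H_true[2 * i, f]
                H[2 * i + 1, f] = 1 - H_true[2 * i + 1, f]
        else:  # max_ld: built per interval below
            H = None
            G = H_true[0::2] + H_true[1::2]

        bounds = _shared_intervals(genomes, c_idx, length)
        # labels per (individual, homolog, interval)
        lab = np.empty((n_ind, 2, bounds.size - 1), dtype=np.int64)
        for k, g in enumerate(genomes):
            for h in (0, 1):
                starts, labels = g.chroms[c_idx][h]
                lab[k, h] = labels[np.searchsorted(starts, bounds[:-1], side="right") - 1]

        for b in range(bounds.size - 1):
            jlo = int(np.searchsorted(pos, bounds[b]))
            jhi = int(np.searchsorted(pos, bounds[b + 1]))
            if jhi == jlo:
                continue
            if ld_mode == "max_ld":
                Gs = G[:, jlo:jhi]
                alt_first = rng.integers(2, size=panel.n_founders).astype(np.int8)
                hom_alt = (Gs == 2).astype(np.int8)
                het = (Gs == 1).astype(np.int8)
                Hs = np.empty((n_lab, jhi - jlo), dtype=np.int8)
                Hs[0::2] = hom_alt + het * alt_first[:, None]
                Hs[1::2] = hom_alt + het * (1 - alt_first[:, None])
            else:
                Hs = H[:, jlo:jhi]
            gt[:, jlo:jhi] = Hs[lab[:, 0, b]] + Hs[lab[:, 1, b]]
        out[name] = gt

    if samples is None:
        samples = [f"S{i}" for i in range(n_ind)]
    return GenotypeData(positions, out, list(samples))


def seed_snps_groups(
    genome_groups: list,
    panel: FounderPanel,
    gmap: GenomeMap,
    ld_mode: str,
    rng,
    sample_groups: list | None = None,
) -> list:
    """Seed several cohorts (e.g. F0 and F17) under ONE haplotype assignment.

    Shared-ancestry intervals and the per-founder phasing coins are common
    to all groups, as they must be when the groups are timepoints of the
    same line; returns one GenotypeData per group.
    """
    flat = [g for group in genome_groups for g in group]
    if sample_groups is None:
        samples = None
    else:
        samples = [s for group in sample_groups for s in group]
    data = seed_snps(flat, panel, gmap, ld_mode, rng, samples=samples)
    out = []
    lo = 0
    for k, group in enumerate(genome_groups):
        hi = lo + len(group)
        out.append(
            GenotypeData(
                data.positions,
                {c: g[lo:hi] for c, g in data.genotypes.items()},
                data.samples[lo:hi],
            )
        )
        lo = hi
    return out


def write_genotype_vcf(data: GenotypeData, gmap: GenomeMap, path) -> None:
    """Write unphased diploid genotypes as uncompressed VCF text."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=driftscan\n")
        for name, length, _ in gmap.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(data.samples) + "\n")
        code = {0: "0/0", 1: "0/1", 2: "1/1"}
        for name in data.positions:
            pos = data.positions[name]
            gt = data.genotypes[name]
            for j in range(pos.size):
                cells = "\t".join(code[int(g)] for g in gt[:, j])
                fh.write(f"{name}\t{pos[j] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{cells}\n")
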