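import numpy as np
import pandas as pd
import pytest

from driftscan import simulate, synth
from driftscan.errors import ArgumentError, ConsistencyError
from driftscan.simulate import (
    JunctionGenome,
    TraitModel,
    breeding_value,
    composite_trait,
    draw_effects,
    estimate_phi,
    founder_genome,
    inbreeding,
    major_locus_injection,
    meiosis,
    ne_from_inbreeding,
    recombine,
    run_experiment,
    seed_snps,
)

def _het_parent(gmap, a=0, b=1):
    """Parent whose homologs are single segments labeled a and b on every chromosome."""
    zero = np.zeros(1, dtype=np.int64)
    chroms = [
        ((zero, np.array([a])), (zero, np.array([b]))) for _ in gmap.chromosomes
    ]
    return JunctionGenome(chroms)


class TestMeiosis:
    def test_zero_map_copies_one_homolog(self):
        gmap = synth.make_genome_map(1, 1_000_000, 0.0)
        parent = _het_parent(gmap)
        rng = np.random.default_rng(0)
        labels = [int(meiosis(parent, gmap, rng)[0][1][0]) for _ in range(400)]
        assert set(labels) == {0, 1}
        assert abs(np.mean(labels) - 0.5) < 0.1

    def test_crossover_rate_equals_map_length(self):
        gmap = synth.make_genome_map(1, 1_000_000, 1.0)
        parent = _het_parent(gmap)
        rng = np.random.default_rng(1)
        # with two distinct labels, every crossover is a visible junction
        counts = [len(meiosis(parent, gmap, rng)[0][0]) - 1 for _ in range(10_000)]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 1.0) <= 3 * se

    def test_single_crossover_definition(self):
        gmap = synth.make_genome_map(1, 1000, 1.0)
        parent = _het_parent(gmap, a=7, b=9)
        starts, labels = recombine(parent.chroms[0][0], parent.chroms[0][1],
                                   np.array([400]), 0, 1000)
        assert starts.tolist() == [0, 400]
        assert labels.tolist() == [7, 9]

    def test_gamete_satisfies_invariants(self, gmap_small):
        rng = np.random.default_rng(2)
        parent = _het_parent(gmap_small)
        for _ in range(50):
            gam = meiosis(parent, gmap_small, rng)
            for (name, length, _), (starts, labels) in zip(gmap_small.chromosomes, gam):
                assert starts[0] == 0
                assert np.all(np.diff(starts) > 0)
                assert starts[-1] < length
                assert np.all(labels[1:] != labels[:-1])


class TestTraitValue:
    def test_null_heritability(self, gmap_small):
        model = TraitModel(vg=0.0, vs=0.0, ve=1.0)
        rng = np.random.default_rng(3)
        eff = draw_effects(8, gmap_small, model, rng)
        bv = breeding_value(founder_genome(2, gmap_small), eff)
        assert bv == 0.0

    def test_founder_identity(self, gmap_small):
        rng = np.random.default_rng(4)
        model = TraitModel()
        eff = draw_effects(8, gmap_small, model, rng)
        i = 3
        expected = sum(
            float(cum[lab, -1])
            for _, per_chrom in eff.component_items()
            for _, cum in per_chrom
            for lab in (2 * i, 2 * i + 1)
        )
        assert breeding_value(founder_genome(i, gmap_small), eff) == pytest.approx(expected)

    def test_founder_variance_matches_target_raw(self, gmap_small):
        model = TraitModel(vg=0.3, vs=0.2, ve=0.5)
        ratios = []
        for seed in range(20):
            eff = draw_effects(32, gmap_small, model, np.random.default_rng(seed), standardize=False)
            bvs = [breeding_value(founder_genome(i, gmap_small), eff) for i in range(16)]
            ratios.append(np.var(bvs) / (model.vg + model.vs))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_standardized_component_variance_exact(self, gmap_small):
        model = TraitModel(vg=0.25, vs=0.15, ve=0.6)
        eff = draw_effects(16, gmap_small, model, np.random.default_rng(5))
        for comp, target in (("infinitesimal", model.vg), ("discrete", model.vs)):
            totals = sum(cum[:, -1] for _, cum in eff.tables[comp])
            diploid = totals[0::2] + totals[1::2]
            assert np.var(diploid) == pytest.approx(target, rel=1e-9)
        # total differs from vg+vs only by the component cross-covariance
        bvs = [breeding_value(founder_genome(i, gmap_small), eff) for i in range(8)]
        assert np.var(bvs) == pytest.approx(model.vg + model.vs, rel=0.35)

    def test_per_chromosome_share_proportional_to_map(self):
        gmap = synth.GenomeMap((("chr1", 1_000_000, 0.8), ("chr2", 1_000_000, 0.2)))
        model = TraitModel(vg=1.0, vs=0.0, ve=0.0)
        shares = []
        for seed in range(20):
            eff = draw_effects(64, gmap, model, np.random.default_rng(seed), standardize=False)
            per_chrom = eff.tables["infinitesimal"]
            var_c = []
            for pos, cum in per_chrom:
                tot = cum[:, -1]
                var_c.append(np.var(tot[0::2] + tot[1::2]))
            shares.append(var_c[0] / sum(var_c))
        assert np.mean(shares) == pytest.approx(0.8, abs=0.08)

    def test_missing_label_raises(self, gmap_small):
        eff = draw_effects(4, gmap_small, TraitModel(), np.random.default_rng(6))
        with pytest.raises(ConsistencyError):
            breeding_value(founder_genome(5, gmap_small), eff)  # labels 10, 11


class TestCompositeTrait:
    def test_phi_zero_reduces_to_t(self):
        t = np.array([1.0, 2.0, 3.0])
        b = np.array([9.0, 1.0, 4.0])
        score = composite_trait(t, b, 0.0)
        assert np.array_equal(np.argsort(score), np.argsort(t))

    def test_b_one_eliminates_phi(self):
        assert composite_trait(2.0, 1.0, -0.57) == pytest.approx(np.log(2), abs=1e-12)

    def test_worked_example(self):
        assert composite_trait(1.1, 1.2, -0.57) == pytest.approx(
            0.09531018 - 0.57 * 0.18232156, abs=1e-6
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ArgumentError):
            composite_trait(0.0, 1.0, -0.5)
        with pytest.raises(ArgumentError):
            composite_trait(1.0, -1.0, -0.5)


def _phi_table(phi_true, rng, n_families=20):
    rows = []
    for fam in range(n_families):
        for sex in ("M", "F"):
            t = rng.lognormal(0, 0.1, size=5)
            b = rng.lognormal(0, 0.1, size=5)
            score = np.log(t) + phi_true * np.log(b)
            top = int(np.argmax(score))
            for k in range(5):
                rows.append((t[k], b[k], sex, fam, k == top))
    return pd.DataFrame(rows, columns=["T", "B", "sex", "family", "chosen"])


class TestEstimatePhi:
    def test_t_only_selection_gives_zero(self):
        table = _phi_table(0.0, np.random.default_rng(7))
        phi, conc = estimate_phi(table)
        assert phi == 0.0
        assert conc == 1.0

    def test_recovers_true_phi(self):
        # many groups narrow the interval of perfect concordance around the
        # true phi; the tie rule then picks its boundary closest to 0
        table = _phi_table(-0.57, np.random.default_rng(8), n_families=250)
        phi, conc = estimate_phi(table)
        assert phi == pytest.approx(-0.57, abs=0.04)
        assert conc == 1.0

    def test_small_family_rejected(self):
        df = pd.DataFrame(
            {"T": [1.0], "B": [1.0], "sex": ["M"], "family": [0], "chosen": [True]}
        )
        with pytest.raises(ArgumentError):
            estimate_phi(df)


class TestRunExperiment:
    def test_random_selection_no_response(self, gmap_small):
        model = TraitModel()
        rng = np.random.default_rng(9)
        means = []
        for _ in range(40):
            ped = synth.make_pedigree(4, 3, 6, seed=int(rng.integers(2**31)))
            sim = run_experiment(ped, None, gmap_small, model, selection="random",
                                 rng=rng, compute_f=False, keep_genomes=())
            means.append(np.nanmean(sim.per_generation.R))
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 0.01

    def test_zero_heritability_no_response(self, gmap_small):
        model = TraitModel(vg=0.0, vs=0.0, ve=1.0)
        rng = np.random.default_rng(10)
        r_vals, s_vals = [], []
        for _ in range(40):
            ped = synth.make_pedigree(6, 3, 8, seed=int(rng.integers(2**31)))
            sim = run_experiment(ped, None, gmap_small, model, rng=rng,
                                 compute_f=False, keep_genomes=())
            r_vals.append(np.nanmean(sim.per_generation.R))
            s_vals.append(np.nanmean(sim.per_generation.S))
        assert np.mean(s_vals) > 0.5  # selection differential present
        se = np.std(r_vals) / np.sqrt(len(r_vals))
        assert abs(np.mean(r_vals)) < 3 * se + 0.01

    def test_within_family_breeders_equation(self, gmap_small):
        # under within-family truncation the response per generation is
        # S * (Va/2) / (Va/2 + Ve): only the Mendelian-segregation half of
        # the additive variance is visible inside a family
        model = TraitModel(vg=0.2, vs=0.2, ve=0.6)
        h2w = 0.2 / 0.8
        rng = np.random.default_rng(11)
        ratios = []
        for _ in range(50):
            ped = synth.make_pedigree(8, 2, 8, seed=int(rng.integers(2**31)))
            sim = run_experiment(ped, None, gmap_small, model, rng=rng,
                                 compute_f=False, keep_genomes=())
            pg = sim.per_generation
            # generation 0 families hold one individual per sex (S = 0);
            # real truncation starts at generation 1
            if pg.S.iloc[1] > 0:
                ratios.append(pg.R.iloc[1] / pg.S.iloc[1])
        assert np.mean(ratios) == pytest.approx(h2w, abs=0.05)

    def test_selected_flags_one_pair_per_family(self, ped_small, sim_small):
        df = sim_small.individuals
        for g in range(ped_small.n_generations - 1):
            sel = df[(df.generation == g) & df.selected]
            counts = sel.groupby(["family", "sex"]).size()
            assert (counts == 1).all()

    def test_parents_filled_from_previous_generation(self, sim_small):
        df = sim_small.individuals
        gen_of = df.set_index("id")["generation"]
        off = df[df.generation > 0]
        assert (gen_of.loc[off.sire].to_numpy() == off.generation.to_numpy() - 1).all()
        assert (gen_of.loc[off.dam].to_numpy() == off.generation.to_numpy() - 1).all()

    def test_unknown_selection_mode(self, ped_small, gmap_small, model_default):
        with pytest.raises(ArgumentError):
            run_experiment(ped_small, None, gmap_small, model_default, selection="best")


class TestInbreeding:
    def test_founders_have_zero_f(self, gmap_small):
        assert inbreeding(founder_genome(0, gmap_small), gmap_small) == 0.0

    def test_full_sib_recursion(self):
        # F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4 for repeated full-sib mating
        gmap = synth.make_genome_map(2, 1_000_000, 1.0)
        expected = [0.0, 0.0]
        for _ in range(3):
            expected.append((1 + 2 * expected[-1] + expected[-2]) / 4)
        rng = np.random.default_rng(12)
        sims = []
        for _ in range(60):
            ped = _full_sib_pedigree(4, offspring=4)
            sim = run_experiment(ped, None, gmap, TraitModel(), selection="random",
                                 rng=rng, keep_genomes=())
            sims.append(sim.per_generation.mean_F.to_numpy())
        observed = np.mean(sims, axis=0)
        assert observed[:2] == pytest.approx(expected[:2], abs=1e-12)
        assert observed[2:] == pytest.approx(expected[2:], abs=0.04)

    def test_ne_from_exact_series(self):
        f = 1 - (1 - 1 / 92) ** np.arange(18)
        assert ne_from_inbreeding(f) == pytest.approx(46.0, rel=1e-6)

    def test_ne_unbounded_without_drift(self):
        assert ne_from_inbreeding(np.zeros(10)) == np.inf

    def test_ne_warns_on_nonmonotone(self):
        with pytest.warns(UserWarning):
            ne_from_inbreeding(np.array([0.0, 0.2, 0.1, 0.3]))

    @pytest.mark.filterwarnings("ignore:inbreeding series is non-monotone")
    def test_truncation_line_ne_in_range(self, gmap_small):
        rng = np.random.default_rng(13)
        nes = []
        for _ in range(5):
            ped = synth.make_pedigree(16, 17, 6, seed=int(rng.integers(2**31)))
            sim = run_experiment(ped, None, gmap_small, TraitModel(), rng=rng,
                                 keep_genomes=())
            nes.append(ne_from_inbreeding(sim.per_generation.mean_F.to_numpy()))
        assert 32 < np.mean(nes) < 64  # 32 breeders, within-family selection


def _full_sib_pedigree(n_generations, offspring=4):
    rows = [(0, -1, -1, "M", 0, "FS", 0), (1, -1, -1, "F", 0, "FS", 0)]
    nid = 2
    rng = np.random.default_rng(nid)
    pairings = {}
    for g in range(1, n_generations + 1):
        pairings[g] = np.array([[0, 0]])
        sexes = ["M", "F"] + list(np.where(rng.random(offspring - 2) < 0.5, "M", "F"))
        for sex in sexes:
            rows.append((nid, -2, -2, sex, g, "FS", 0))
            nid += 1
    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation", "line", "family"])
    return synth.PedigreeTable(df, pairings)


class TestSeedSnps:
    def _mini_panel(self, hap_rows, positions, gmap):
        hap = np.array(hap_rows, dtype=np.int8)
        return synth.FounderPanel(
            {"chr1": np.array(positions, dtype=np.int64)}, {"chr1": hap}, ancestral_pool_size=2
        )

    def test_homozygous_founders_mode_invariant(self):
        gmap = synth.make_genome_map(1, 1000, 0.0)
        # two founders, each homozygous at every site, sites segregating across founders
        hap = [[0, 1, 0], [0, 1, 0], [1, 0, 1], [1, 0, 1]]
        panel = self._mini_panel(hap, [100, 400, 800], gmap)
        genomes = [founder_genome(0, gmap), founder_genome(1, gmap)]
        outs = {}
        for mode in simulate.LD_MODES:
            data = seed_snps(genomes, panel, gmap, mode, np.random.default_rng(14))
            outs[mode] = data.genotypes["chr1"]
        assert np.array_equal(outs["no_ld"], outs["min_ld"])
        assert np.array_equal(outs["min_ld"], outs["max_ld"])

    def test_max_ld_consistent_within_interval(self):
        gmap = synth.make_genome_map(1, 1000, 0.0)
        # founder 0 heterozygous at 3 sites; IBD carriers of each single
        # haplotype must be all-0 or all-1 across the interval under max LD
        hap = [[0, 0, 0], [1, 1, 1], [0, 1, 0], [0, 1, 0]]
        panel = self._mini_panel(hap, [100, 400, 800], gmap)
        zero = np.zeros(1, dtype=np.int64)
        g_h0 = JunctionGenome([((zero, np.array([0])), (zero, np.array([0])))])
        g_h1 = JunctionGenome([((zero, np.array([1])), (zero, np.array([1])))])
        for seed in range(10):
            data = seed_snps([g_h0, g_h1], panel, gmap, "max_ld", np.random.default_rng(seed))
            gt = data.genotypes["chr1"]
            # each row is double one reconstructed haplotype: constant 0 or 2
            assert set(np.unique(gt[0])) in ({0}, {2}, {0, 2}) and len(np.unique(gt[0])) == 1
            assert len(np.unique(gt[1])) == 1
            assert np.array_equal(gt[0] + gt[1], np.array([2, 2, 2]))

    def test_min_ld_preserves_diploid_genotypes(self, gmap_small, panel_small):
        genomes = [founder_genome(i, gmap_small) for i in range(panel_small.n_founders)]
        data = seed_snps(genomes, panel_small, gmap_small, "min_ld", np.random.default_rng(15))
        for chrom in panel_small.positions:
            hap = panel_small.haplotypes[chrom]
            assert np.array_equal(data.genotypes[chrom], hap[0::2] + hap[1::2])

    def test_unknown_mode(self, gmap_small, panel_small):
        with pytest.raises(ArgumentError):
            seed_snps([founder_genome(0, gmap_small)], panel_small, gmap_small,
                      "mid_ld", np.random.default_rng(0))

    def test_ld_mode_variance_ordering(self):
        # initial LD couples neighbouring sites, inflating the variance of
        # window-averaged frequency shifts: max_ld >= min_ld >= no_ld on
        # matched junction realizations
        from driftscan import scan

        gmap = synth.make_genome_map(1, 2_000_000, 0.2)
        panel = synth.make_founder_panel(gmap, 8, 1 / 10_000, ancestral_pool=4,
                                         block_length=1_000_000.0, seed=16)
        rng = np.random.default_rng(17)
        maxima = {m: [] for m in simulate.LD_MODES}
        for _ in range(40):
            ped = synth.make_pedigree(4, 3, 6, seed=int(rng.integers(2**31)))
            sim = run_experiment(ped, panel, gmap, TraitModel(), selection="random",
                                 rng=rng, compute_f=False)
            g0 = [sim.genomes[int(i)] for i in ped.individuals.loc[ped.individuals.generation == 0, "id"]]
            g3 = [sim.genomes[int(i)] for i in ped.individuals.loc[ped.individuals.generation == 3, "id"]]
            for mode in simulate.LD_MODES:
                d0, d1 = simulate.seed_snps_groups([g0, g3], panel, gmap, mode, rng)
                q0 = d0.genotypes["chr1"].mean(axis=0) / 2
                q1 = d1.genotypes["chr1"].mean(axis=0) / 2
                dz2 = scan.delta_z2(q0, q1)
                prof = scan.window_stats(np.full(q0.size, "chr1"), panel.positions["chr1"],
                                         dz2, window=100_000)
                maxima[mode].append(prof.value.max())
        v = {m: np.mean(maxima[m]) for m in simulate.LD_MODES}
        assert v["max_ld"] >= v["min_ld"] >= v["no_ld"]


class TestMajorLocus:
    def test_null_effect_behaves_neutrally(self, gmap_small):
        rng = np.random.default_rng(18)
        dqs = []
        for _ in range(30):
            ped = synth.make_pedigree(4, 3, 6, seed=int(rng.integers(2**31)))
            sim = major_locus_injection(ped, None, gmap_small, TraitModel(),
                                        effect=0.0, q0=0.25, rng=rng,
                                        compute_f=False, keep_genomes=())
            dqs.append(sim.trajectory[-1] - sim.trajectory[0])
        se = np.std(dqs) / np.sqrt(len(dqs))
        assert abs(np.mean(dqs)) < 3 * se + 0.02

    def test_delta_q_monotone_in_effect(self, gmap_small):
        rng = np.random.default_rng(19)
        means = []
        for a in (0.05, 0.2, 0.5):
            dqs = []
            for _ in range(25):
                ped = synth.make_pedigree(6, 5, 6, seed=int(rng.integers(2**31)))
                sim = major_locus_injection(ped, None, gmap_small, TraitModel(),
                                            effect=a, q0=0.17, rng=rng,
                                            compute_f=False, keep_genomes=())
                dqs.append(sim.trajectory[-1] - sim.trajectory[0])
            means.append(np.mean(dqs))
        assert means[0] < means[1] < means[2]

    def test_effect_too_large_rejected(self, gmap_small):
        ped = synth.make_pedigree(4, 2, 4, seed=20)
        with pytest.raises(ArgumentError):
            major_locus_injection(ped, None, gmap_small, TraitModel(vg=0.01, vs=0.0, ve=0.99),
                                  effect=1.0, q0=0.5, rng=0)

    def test_trajectory_recorded_per_generation(self, gmap_small):
        ped = synth.make_pedigree(4, 4, 6, seed=21)
        sim = major_locus_injection(ped, None, gmap_small, TraitModel(),
                                    effect=0.3, q0=0.25, rng=22,
                                    compute_f=False, keep_genomes=())
        assert sim.trajectory.shape == (5,)
        assert np.all((sim.trajectory >= 0) & (sim.trajectory <= 1))
        assert sim.trajectory[0] == pytest.approx(0.25, abs=1 / 16)


class TestNeutralDriftVariance:
    @pytest.mark.filterwarnings("ignore:inbreeding series is non-monotone")
    def test_variance_matches_ne_from_inbreeding(self, gmap_small):
        # neutral seeded site under random selection: mean dq ~ 0 and
        # Var(dq over T generations) ~ q(1-q) * (1 - (1 - 1/(2Ne))^T)
        # with Ne fitted from the inbreeding series
        rng = np.random.default_rng(23)
        T = 10
        dqs, f_series = [], []
        for _ in range(100):
            ped = synth.make_pedigree(4, T, 6, seed=int(rng.integers(2**31)))
            sim = major_locus_injection(ped, None, gmap_small, TraitModel(),
                                        effect=0.0, q0=0.5, rng=rng,
                                        selection="random", keep_genomes=())
            dqs.append(sim.trajectory[-1] - sim.trajectory[0])
            f_series.append(sim.per_generation.mean_F.to_numpy())
        se = np.std(dqs) / np.sqrt(len(dqs))
        assert abs(np.mean(dqs)) < 3 * se
        ne = ne_from_inbreeding(np.mean(f_series, axis=0))
        expected = 0.25 * (1 - (1 - 1 / (2 * ne)) ** T)
        assert np.var(dqs) == pytest.approx(expected, rel=0.35)
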