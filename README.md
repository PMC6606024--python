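# driftscan

Simulation and analysis toolkit for evolve-and-resequence artificial-selection
experiments in small pedigreed populations. It provides:

- **`driftscan.synth`** — synthetic inputs: genome maps, founder haplotype
  panels (mosaics of a small ancestral pool, so founder linkage
  disequilibrium is tunable) and breeding designs (families per generation,
  realized litter sizes/sexes, non-sibling pairings).
- **`driftscan.simulate`** — a pedigree gene-dropping simulator. Genomes are
  junction lists (segment boundaries labeled by founder haplotype);
  crossovers are uniform at a Poisson rate equal to the genetic map length.
  The trait combines an infinitesimal background, a discrete-locus component
  (10⁴ evenly spaced loci) and Gaussian noise; breeding is within-family
  truncation on the composite score ln T + φ·ln B (or random, for control
  lines). SNP genotypes at any generation are reconstructed by seeding
  founder segments under three LD schemes (`no_ld`, `min_ld`, `max_ld`).
  A single biallelic major locus can be injected on top of the background.
- **`driftscan.scan`** — two-timepoint summary statistics: per-site and
  10 kbp-windowed Δz² (z(q) = 2·arcsin√q), Weir–Cockerham F_ST, π,
  heterozygosity and segregating-site counts, from VCF or in-memory
  matrices.
- **`driftscan.significance`** — critical Δz² values from the distribution
  of simulated genome-wide maxima, hitchhiking-aware peak calling
  (100-SNP block extension with a 0.2·π² stop rule), parallelism χ² and
  profile correlations, and a BED-interval permutation test.
- **`driftscan.inference`** — selection-coefficient estimation from allele
  trajectories (Wright–Fisher hidden Markov model, genic selection,
  likelihood-ratio CIs), neutral drift envelopes, and the translation of a
  locus effect into its share of the total selection response (arithmetic
  and simulation-calibrated).

## Command line

```sh
driftscan simulate --config config.yaml --out runs/demo     # 3 lines, F0/F-last VCFs + report
driftscan scan --vcf0 runs/demo/LS1.F0.vcf --vcf1 runs/demo/LS1.F17.vcf --out runs/ls1
driftscan thresholds --config config.yaml --n-replicates 100 --ld-mode all --out thresholds.tsv
driftscan peaks --windows runs/ls1.windows.tsv --sites runs/ls1.sites.tsv \
    --threshold 3.3 --stop-frac 0.2 --ext-snps 100 --out peaks.tsv
driftscan scan-and-call --dir runs/demo --config config.yaml --threshold 3.3   # all lines + parallelism
driftscan sfit --traj trajectory.tsv --ne 46 --out sfit.yaml
driftscan contribution --effect 0.36 --delta-q 0.68 --delta-q 0.81 --total 12.9
driftscan report --report runs/demo/report.yaml
```

Configuration is YAML (see `driftscan.cli.DEFAULT_CONFIG` for the schema);
all outputs embed the config hash and seed, and identical config + seed
reproduce identical files.

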