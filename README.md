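# allelekit

Allele-aware analyses for haplotype-resolved diploid genomes, exercised
end-to-end on synthetic data with planted ground truth:

- **simulate** — synthetic diploid inputs: a two-haplotype annotation with
  collinear allele pairs plus noise genes, negative-binomial counts over
  7 tissues × 29 samples with planted bias categories, CDS pairs evolved
  to target (Ka, Ks), promoters with planted motif occurrences, TEs at
  controlled distances, Ks mixtures, LTR lifecycle records, and a k-mer
  histogram with known genome size (`allelekit.simulate`)
- **pairing** — translated k-mer homology matching, dynamic-programming
  collinear-block chaining in both orientations, median-Ks removal of
  WGD-derived blocks, allele-pair extraction (`allelekit.pairing`)
- **ase** — TPM normalization, the 0.5-TPM expressed rule, a
  negative-binomial Wald test per tissue with BH adjustment, the
  four-level bias categories (none / smaller ≤2× / larger / largest ≥8×),
  dynamic/stable top-10% ranking, and neighboring/jumping category
  transitions (`allelekit.ase`)
- **kaks** — protein-guided codon alignment and NG86 Ka/Ks with
  Jukes–Cantor correction and the Ks > 5 exclusion flag; a kappa-weighted
  `YN-approx` variant behind a method flag (`allelekit.kaks`)
- **regctx** — PWM scanning of 2-kb promoters with *exact* tail p-values
  (integer-lattice DP, p < 1e−5, pseudocount 1e−8), shared/specific TFBS
  accounting between allele promoters, nearest-TE distances
  (`allelekit.regctx`)
- **coexpr** — unsigned weighted coexpression network (soft power at
  scale-free fit 0.9, TOM, min module size 60, merge cut 0.15), module
  eigengenes, and the coordinated/similar/divergent allele rule at 50% of
  the median maximum eigengene distance (`allelekit.coexpr`)
- **dating** — Ks-distribution KDE peak detection, rate calibration
  time = Ks/(2r), WGD dating, LTR insertion ages at μ = 1.3e−8, and
  k-mer genome-size estimation (`allelekit.dating`)
- **ltr** — intact/solo/truncated classification from Gag-Pol and
  homology evidence, 70%-coverage/60%-identity single-linkage clustering,
  S:I / T:I removal-rate statistics (`allelekit.ltr`)
- **pipeline / cli** — seeded, deterministic orchestration over a working
  directory of plain-text files, with category contrasts
  (Mann–Whitney–Wilcoxon) in the run report (`allelekit.pipeline`,
  `allelekit.cli`)

## CLI

Every subcommand operates on a shared working directory; `simulate`
populates it, later stages read from and write to it.

```sh
# full synthetic run
allelekit run-all --workdir run --seed 1

# or stage by stage
allelekit simulate     --workdir run --seed 1
allelekit pair-alleles --workdir run
allelekit kaks         --workdir run
allelekit ase          --workdir run
allelekit tfbs         --workdir run
allelekit te-dist      --workdir run
allelekit coexpr       --workdir run
allelekit date         --workdir run
allelekit ltr          --workdir run
allelekit report       --workdir run
```

Thresholds and simulation sizes can be set in a flat INI config:

```ini
[pipeline]
seed = 1
wgd_ks_ceiling = 0.15

[simulate]
n_chromosome_pairs = 4
genes_per_chromosome = 40
```

```sh
allelekit run-all --config config.ini --workdir run
```

Exit codes: 0 ok, 2 configuration error, 3 data error. All outputs are
TSV/JSON/FASTA/GFF3/BED; identical config + seed gives byte-identical
reports.

## Layout

```
src/allelekit/      simulate, pairing, ase, kaks, regctx, coexpr,
                    dating, ltr, pipeline, cli, io, stats
tests/              unit + property tests per module and
                    test_acceptance.py (one test per criterion)
scripts/acceptance.py
```
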