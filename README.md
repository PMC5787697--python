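# clipshift

Analysis tools for the RNA-binding landscape of a chromatin protein, built
around two experimental readouts:

1. **PAR-CLIP sequencing.** Photoactivatable-ribonucleoside crosslinking
   leaves diagnostic T-to-C transitions in reads at protein-RNA contact
   sites. `clipshift` groups aligned reads into clusters, filters them into
   binding-site peaks by conversion evidence, partitions peaks over genomic
   features (exon, intron, promoter, UTRs, intergenic — with a 10-kb
   "rescue" of intergenic peaks near annotated coding ends), scores
   positional k-mer enrichment against a shuffled-ORF background, builds
   exon-boundary coverage metaprofiles with two randomized backgrounds, and
   draws positional RNA maps around regulated cassette exons with
   permutation significance.
2. **Gel mobility-shift (EMSA) titrations.** For a single-step reaction in
   which *n* protein monomers bind one ligand, K<sub>n</sub> =
   [P<sub>n</sub>R] / ([R][P]<sup>n</sup>), so
   ln([P<sub>n</sub>R]/[R]) = *n*·ln[P] + ln K<sub>n</sub>: the slope of the
   log-log binding plot is the stoichiometry and the monomer-equivalent
   association constant K = K<sub>n</sub><sup>1/n</sup> is the reciprocal of
   the midpoint protein concentration. For two co-incubated ligands whose
   complexes co-migrate, the relative affinity K_DNA/K_RNA is computed
   per lane from free-band disappearance and extrapolated linearly to zero
   protein.

Every analysis stage is exercisable without external data: the
`clipshift.synthetic` module generates toy genomes with mRNA / lincRNA /
miRNA / snRNA gene structure, crosslink reads of 16–23 nt (modal length
20 nt) with sense-strand T-to-C conversions at planted — optionally
GC-biased and exon-boundary-enriched — binding sites, rMATS-style
cassette-exon tables with planted regulatory classes, and noisy binding
isotherms on a 0.05–2.5 µM protein grid.

## Worked example

Run the whole pipeline on simulated data:

```bash
clipshift run-all --output-dir demo_run
```

With the bundled defaults (20 000 reads over 200 planted sites on a toy
two-chromosome genome) this writes the stage outputs plus `manifest.json`
with a SHA-256 checksum per file; the run reports **140 peaks** from
20 000 reads, splice-event classes `enhanced=90, silenced=105,
background=105`, and an `emsa_fit.json` like

```json
{"n": 1.9031, "K_per_M": 1915643.6, "r_squared": 0.9949, "n_points_used": 4}
```

i.e. a fitted stoichiometry of ~1.9 monomers per RNA and a
monomer-equivalent K of ~1.9×10⁶ M⁻¹ from one noisy simulated titration
(generated at n = 1.75, K = 1.95×10⁶ M⁻¹). Running the same command twice
produces byte-identical outputs.

The same stages are available individually (`simulate`, `callpeaks`,
`annotate`, `kmers`, `boundaries`, `splicemap`, `emsa-fit`,
`emsa-compete`); e.g.

```bash
clipshift callpeaks --reads demo_run/reads.bed --out peaks.tsv
clipshift emsa-fit --titration demo_run/titration.tsv
```

Peak calling applies the three binding-site criteria: T-to-C conversion
frequency ≥ 0.25, more than five converted reads, and at least two distinct
conversion positions (each threshold configurable).

Peaks are written as BED6+ TSV with columns
`chromosome, start, end, name, score, strand, n_reads, n_converted_reads,
conversion_frequency, conversion_sites, anchor` (coordinates 0-based
half-open; `conversion_sites` is a comma-joined `position:count` list and
`anchor` is the leftmost maximally-supported conversion site).

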