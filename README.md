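# mirforge

Genome-wide miRNA discovery with three complementary tracks — homology to
known matures, de novo stem-loop scanning, and small-RNA-read-guided
discovery — sharing one structural filter battery, plus mature 5p/3p arm
inference, strand resolution, cross-track merging with Venn accounting,
seed-family assignment, conservation classification, a precursor-compendium
criteria benchmark, and 3'UTR target scanning.  A deterministic synthetic
data generator plants precursors, reads, reference matures and target sites
with full ground truth, so every stage is testable without downloads.

## The filter battery

Candidate precursors must satisfy, jointly:

* length 50–130 nt,
* exactly one hairpin loop in the MFE structure,
* GC content in [30 %, 70 %],
* more than 55 % of positions base-paired,
* MFE ≤ −0.31·L + 6.00 kcal/mol (L = precursor length),

plus two automated curation checks once a mature is attached (bounded
bulge size, mature outside the hairpin loop).

Folding is a self-contained Zuker-style minimum-free-energy implementation
over the Turner 2004 nearest-neighbor parameters (shipped as JSON in
`mirforge/data/`), with temperature rescaling (used at 18 °C by the homolog
rescan).  It reproduces the energies of the reference thermodynamic folder
exactly on the validation set frozen under `tests/data/`.

## CLI

```bash
mirforge simulate --config sim.toml --seed 17 --outdir sim/
mirforge homology --genome sim/genome.fa --matures sim/matures.fa --max-mm 2 --out homology.tsv
mirforge denovo   --genome sim/genome.fa --mask mask.bed --out denovo.tsv
mirforge smallrna --genome sim/genome.fa --reads sim/reads.fq --out smallrna.tsv
mirforge merge    --in homology.tsv --in denovo.tsv --in smallrna.tsv --out catalog.tsv --venn venn.json
mirforge conserve --catalog catalog.tsv --matrix presence.tsv
mirforge rescan   --matures matures.fa --genome2 other.fa --mm 4 --temp 18
mirforge targets  --matures matures.fa --gff sim/models.gff3 --genome sim/genome.fa --p 0.01 --out targets.tsv
mirforge filter   --in precursors.fa --report report.tsv
mirforge benchmark --hairpins hairpin.fa --out bench.tsv
```

Filter criteria can be overridden with a flat TOML file (`--criteria`),
mirroring the `FilterCriteria` fields.

## Layout

| module | role |
|---|---|
| `mirforge.core_io` | locus-string coordinate model, FASTA/FASTQ/BED/GFF3/TSV readers and writers |
| `mirforge.rna_structure` | MFE folding and structure metrics (loops, paired fraction, GC, threshold) |
| `mirforge.filtration` | filter battery, rejection logging, compendium benchmark |
| `mirforge.homology_track` | mismatch-limited mature scan, window folding/trim, overlap resolution |
| `mirforge.denovo_track` | genome-wide hairpin sweep (60–130 nt), redundancy/repeat clustering |
| `mirforge.smallrna_track` | read mapping, flank folding, expression exclusion, read support |
| `mirforge.mature_strand_merge` | 5p/3p arm inference, strand evidence, track merging/Venn, families, conservation, second-genome rescan |
| `mirforge.target_scan` | 3'UTR extraction, constrained duplex energies, Gumbel-null significance |
| `mirforge.synthetic_data` | deterministic planted-truth generator |
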