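# ssrmine

Reference-free SSR (microsatellite) marker mining from genotyping-by-sequencing
(GBS) reads, plus the codominant-marker statistics layer used to evaluate the
resulting markers.

The pipeline takes demultiplexable single-end reads that begin with an inline
barcode and a restriction-site remnant (`CWGC`, from a G^CWGC cutter such as
ApeKI) and produces:

1. **preprocess** — demultiplexing, remnant verification, sliding-window
   quality filtering, truncation to a uniform length;
2. **catalog** — per-accession collapsing of identical reads into depth-
   annotated stacks, then greedy cross-accession merging into consensus loci;
3. **ssr_detect** — detection of maximal perfect SSR tracts (primitive motifs
   of 2–6 bp, configurable minimum repeat counts), canonical motif-class
   labels, and summary tables;
4. **polymorph** — tract masking, flank-identity clustering of SSR loci across
   accessions, per-locus allele (repeat-count) tables, polymorphism calls, and
   marker-selection filters (accession support, expected product size);
5. **primers** — exhaustive flanking-primer enumeration under hard constraints
   (length 18–23 nt, Tm 52–60 °C, GC 30–67 %, homopolymer and 3'-dimer limits)
   with a nearest-neighbor thermodynamic Tm;
6. **diversity** — Na/MAF/He/Ho/PIC per locus, individual heterozygosity,
   Nei-1972 and shared-allele distances, neighbor-joining trees (Newick),
   principal coordinates analysis, Mantel tests, and a STRUCTURE exporter;
7. **synthsim** — a ground-truthed simulator (planted SSR loci, in-silico
   digestion, configurable depth/error/inbreeding) used by the test suite;
8. **pipeline / CLI** — stage orchestration with machine-readable stage
   reports, checksums, and resumability.

A bundled reference panel of 74 validated SSR markers with per-locus
diversity statistics (`ssrmine/data/marker_panel.tsv`) anchors the validator
tests and the acceptance report.

## Tests

```sh
python -m pytest tests/
```

The suite includes brute-force oracle equivalence for the SSR detector,
property tests (NJ on additive matrices, PCoA reconstruction, Mantel null
uniformity), and a full simulate→mine recovery check.

## CLI

```sh
# generate a ground-truthed synthetic dataset
ssrmine simulate --seed 1 --out sim/

# run the whole pipeline from a YAML config
cat > config.yaml <<EOF
fastq: sim/reads.fastq
barcodes: sim/barcodes.tsv
out_dir: run/
EOF
ssrmine run --config config.yaml

# single stages
ssrmine demux --fastq sim/reads.fastq --barcodes sim/barcodes.tsv --out demux/
ssrmine ssr --fasta run/catalog.fasta --out misa.tsv

# statistics on a codominant genotype table
ssrmine stats --genotypes genotypes.tsv --out-dir stats/ \
    --coords coords.tsv --permutations 999 --seed 1
```

The genotype table format is one row per individual: `individual`, `group`,
then two allele columns per locus (`.` for missing).

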