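# pprfoot

Analysis pipeline for pentatricopeptide-repeat (PPR) protein / RNA-footprint
studies: tandem repeat-motif annotation on proteins, nucleotide-specificity
("PPR code") consensus prediction, degenerate-consensus scanning of plastid
sequences, circular-RT-PCR transcript-termini mapping with footprint-overlap
arithmetic, and conservation profiling of orthologous intergenic regions.
A seeded synthetic-data module generates every input the pipeline consumes,
with recorded ground truth, so the whole chain is testable offline.

## Layout

| module | role |
| --- | --- |
| `pprfoot.seqio` | FASTA/GenBank I/O, signed gene-relative coordinates, reverse complement, molecular mass |
| `pprfoot.motifs` | sliding-profile detection of tandem 31–36 aa repeats; specificity-residue pairs (6, 1′) |
| `pprfoot.code` | (residue6, residue1′) → nucleotide mapping; degenerate consensus parse/format |
| `pprfoot.scan` | consensus matching at fixed offsets and strand-aware whole-sequence scans |
| `pprfoot.termini` | ligation-junction calling from clone reads, termini tallies, overlap/footprint arithmetic |
| `pprfoot.align` | Needleman–Wunsch global alignment and star-alignment conservation profiles |
| `pprfoot.simulate` | seeded generators: planted-motif proteins, genomes with planted sites, clone reads, ortholog families |
| `pprfoot.cli` | `pprfoot` subcommand CLI: annotate, predict, scan, termini, footprint, conserve, simulate, replay-paper |

Package data (`src/pprfoot/data/`) ships the default 35-position motif
profile, the default specificity table, and the printed fixture sequences
(the RNA probe, the competitor probe, and the degenerate binding-consensus
string).

## CLI

```sh
# generate a complete synthetic scenario with ground truth
pprfoot simulate --scenario scenario.yaml --out sim/

# protein -> motifs -> binding consensus
pprfoot predict --fasta sim/protein.fasta --out pred/

# scan a genome for the consensus on both strands
pprfoot scan --pattern "$(python -c 'import json;print(json.load(open("sim/truth.json"))["protein"]["expected_consensus"])')" \
             --target sim/locus.gb --strand both --out scanout/

# clone reads -> junctions -> termini tallies -> overlap -> footprint
pprfoot footprint --genome sim/locus.gb --gene-a geneA --gene-b geneB \
                  --clones sim/clones.fasta --out fp/

# conservation profile of an ortholog family
pprfoot conserve --fasta sim/family.fasta --window 18:40 --out cons/

# replay the printed-fixture analysis chain
pprfoot replay-paper --out replay/
```

Every subcommand writes a `manifest.json` (inputs with SHA-256, effective
config hash, package version) and uses exit codes 0 (ok), 2 (input error),
3 (empty result). Identical config + seed gives byte-identical outputs.

An example scenario file:

```yaml
seed: 5
protein: {n_motifs: 22}
genome: {intergenic_len: 67, strand: "+", end3: 40, end5: -50}
clones:
  n: 14
  noise: 0.01
  dist3: {40: 10, 38: 2, 35: 2}   # weights; normalized to probabilities
  dist5: {-50: 6, -48: 3, -46: 3, -44: 2}
family: {n_species: 7, rate_in: 0.02, rate_out: 0.25}
```

## External data

Two analyses replay published coordinates on real public sequences that are
*not* bundled and cannot be fetched offline. To enable them, place under
`data/external/`:

* `AT4G30825.fasta` — the 904-aa protein sequence of the Arabidopsis
  AT4G30825 locus (TAIR / NCBI);
* `NC_000932_atpFA.gb` — a GenBank slice of the Arabidopsis chloroplast
  genome (NC_000932) containing the annotated `atpF` and `atpA` genes.

With the files present, `pprfoot replay-paper`, the acceptance script and
the corresponding acceptance tests compute the motif architecture, the
mature-chain mass and the intergenic overlap from them. Note that the
bundled motif profile is calibrated on synthetic repeats; reproducing a
specific published motif count on a real protein may require recalibrating
the profile threshold (see `pprfoot annotate --threshold`).
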