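# cysscreen

Cysteine-motif screening of transcriptome assemblies for antimicrobial
and other cysteine-rich peptides.

The pipeline reads a nucleotide FASTA, performs six-frame translation and
Met-initiated ORF extraction, scans each precursor against a database of
cysteine-motif patterns (anchored cysteines separated by bounded
non-cysteine gaps, e.g. `CX{2,4}C`), applies a filtration cascade
(precursor length strictly below the limit, signal-peptide presence via a
pluggable predictor, motif located in the mature region), classifies the
survivors into peptide families (defensins, thionins, cyclotides,
snakins, hevein-like peptides, lipid-transfer proteins) or an artificial
cysteine-rich group, and reports per-family count tables. A null model
estimates per-motif false-positive rates on random sequences, and an
alignment-based reporter derives consensus strings (with `z` marking
unconserved columns) and conservation summaries.

Nine motif patterns ship as the default database
(`src/cysscreen/data/motifs.tsv`); any file in the same three-column
format (`motif_id<TAB>family<TAB>pattern`) can replace it with
`--motif-db`.

Signal-peptide prediction is a transparent built-in heuristic (n-region
charge, Kyte–Doolittle h-region window, (-3,-1) small-residue rule);
any callable returning a `SignalPrediction` can be plugged in instead.

## Command line

```sh
# generate a synthetic transcriptome with planted, ground-truthed genes
cysscreen fixtures --n-per-family 2 --decoys 20 --seed 3 --out-dir fix/

# screen it
cysscreen screen fix/transcriptome.fasta --out-dir out/ --seed 3

# false-positive calibration on random sequences
cysscreen null --n-sequences 500 --seq-length 400 --seed 3

# combined count tables and consensus/conservation from an alignment
cysscreen report --counts out/counts.tsv --alignment aligned.fasta --out-dir rep/
```

`screen` writes `classified.fasta` (header
`<seq_id>|<family>|<motif_id>|<frame>|<nt_start>-<nt_end>`),
`counts.tsv` (one row per transcriptome plus totals), `hits.tsv` and
`rejections.tsv`. Every output begins with a comment header recording
the tool version, config hash and seed; runs with equal headers are
byte-identical below the header. Key flags: `--length-limit`
(default 150, strict `<`), `--motif-db`, `--min-cys`, `--all-starts`,
`--allow-unterminated`, `--no-mature-rule`, `--seed`.

## Library

```python
import cysscreen as cs

db = cs.load_motif_db()
records, manifest = cs.generate_transcriptome(n_planted_per_family=5, n_decoys=50, seed=1)
result = cs.screen_transcriptome(records, db, cs.PipelineConfig(seed=1))
print(result.counts)
```

Coordinates are 0-based half-open on the forward strand; frames are
labelled +1/+2/+3 and -1/-2/-3.

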