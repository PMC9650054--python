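# seppipe

A discovery and quantification pipeline for small-ORF-encoded peptides
(SEPs), built around six stages:

1. **simdata** — synthetic transcripts with planted sORFs (AUG/GUG/UUG
   starts, 8–100 aa), centroided MGF spectra with partial b/y coverage and
   controlled precursor ppm error, PSM tables with planted filter
   violations, an annotated proteome, and 3-vs-3 log-normal intensity
   matrices with planted fold changes — all with machine-readable ground
   truth (`truth.json`) and byte-identical reruns per seed.
2. **sepdb** — three-frame ORF calling (non-AUG starts, bacterial table 11,
   first start per inter-stop segment), 8–100 aa length filter,
   deduplication, deterministic `SEP######` identifiers, FASTA output.
3. **digest** — in-silico proteolysis for trypsin, ArgC, chymotrypsin,
   LysC, LysN and mirror-trypsin with ≤2 missed cleavages, and
   peptide-to-database mapping with uniqueness flags.
4. **ions** — monoisotopic peptide masses with fixed carbamidomethyl-C and
   variable Met-oxidation, singly-charged b/y ladders, spectrum matching at
   0.02 Da, signed precursor ppm error, longest-consecutive-ion runs,
   MGF I/O.
5. **curate** — the PSM funnel (length ≥7, consecutive b/y ions ≥4,
   |ppm| < 2, score > 20), a Smith–Waterman novelty screen (BLOSUM62,
   affine gaps 11/1, exact k-mer prefilter) against an annotated proteome,
   and final SEPome assembly with per-stage counts.
6. **quant** — Student's t-test on log2 intensities, Benjamini–Hochberg
   adjustment, FC >2 / <0.5 classification at adj. p < 0.05, row z-scores,
   2^-ddCt relative qPCR quantification, and GRAVY hydropathy.

## CLI

All stages are exposed through one executable:

```sh
seppipe simulate  --config cfg.json --seed 1 --out simdir
seppipe build-db  --transcripts simdir/transcripts.fasta --out seps.fasta \
                  --min-len 8 --max-len 100 --starts ATG,GTG,TTG
seppipe digest    --db seps.fasta --enzyme trypsin --missed 2 --out peptides.tsv
seppipe annotate  --spectra simdir/spectra.mgf --psms simdir/psms.tsv --out ions.tsv
seppipe curate    --psms simdir/psms.tsv --spectra simdir/spectra.mgf \
                  --db seps.fasta --proteome simdir/proteome.fasta --out curated
seppipe quantify  --matrix simdir/intensities.tsv --groups treatment:3,control:3 \
                  --fc 2 --alpha 0.05 --out quant.tsv
```

`simulate` accepts a JSON config overriding any `SimConfig` field (seeds,
planted sORF counts, start-codon weights, fragment coverage, planted
violation fractions, fold changes, …). `curate` writes
`curation_report.json` (funnel counts, per-PSM verdicts, per-candidate
novelty status), `sepome.fasta` and `evidence.tsv`.

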