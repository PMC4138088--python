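# coatscreen

Domain-signature screening of chloroplast-annotated proteomes for candidate
homologs of vesicle-coat components (clathrin triskelion, AP1–5 adaptor
complexes, B-/F-COPI subcomplexes, and coat GTPases).

The pipeline:

1. **Signature catalog** (`coatscreen.catalog`) — load query-subunit tables
   (one known cytosolic coat protein per row, with its Prosite/Pfam
   accessions) and derive one domain signature per query protein, plus a
   report of domains shared between subunits ("commonly occurring" domains).
2. **PROSITE pattern engine** (`coatscreen.patterns`) — parse PROSITE-syntax
   patterns and scan FASTA sequences, so pattern-type (PS0xxxx) accessions
   can be assigned offline. Profile (PS5xxxx) and Pfam accessions are
   precomputed inputs, supplied via the proteome annotation table.
3. **Candidate screen** (`coatscreen.screen`) — superset-containment matching
   of an annotated proteome against the catalog; partitions hit loci into
   single-subunit and multi-subunit candidates.
4. **Localization integration** (`coatscreen.localization`) — four-level
   chloroplast-support verdicts from consensus predictor scores (reliable at
   ≥ 10) and experimental flags, or from a single-predictor call (rice
   dialect). Verdicts annotate candidates; they never filter them.
5. **Classification** (`coatscreen.classify`) — green / yellow per candidate
   locus (green = vesicle-role keyword + single-subunit + some localization
   support), red / yellow / green per subunit identity, and summary counts.
6. **Synthetic data** (`coatscreen.synth`) — seeded generators for screening
   instances with exact planted ground truth (decoy domains live in a
   reserved PF9xxxx namespace) and for random pattern/sequence instances with
   oracle-computed matches.

Two fixtures ship inside the package (`coatscreen/fixtures/*.tsv`): an
Arabidopsis chloroplast candidate set (29 loci) and a rice set (15 loci),
in the same TSV dialects the CLI consumes.

## CLI

```sh
# full pipeline on a packaged fixture (or --queries/--proteome/--evidence)
coatscreen screen --fixture arabidopsis --out out/
coatscreen screen --queries Q.tsv --proteome P.tsv --evidence E.tsv --out out/

# scan FASTA sequences for PROSITE patterns -> proteome-annotation TSV
coatscreen scan --patterns PAT.tsv --fasta SEQ.fa --out annot.tsv

# synthetic screening instance + ground truth
coatscreen simulate --seed 1 --out sim/

# materialize the packaged fixture TSVs
coatscreen fixtures --name rice --out fixtures/
```

`screen` writes `candidates.tsv`, `verdicts.tsv` and `summary.json` (summary
counts, per-locus support levels, and a provenance block with input
checksums and warning counts). Outputs are byte-stable across runs except
for the provenance timestamp. Options may also be given via a YAML file
(`--config run.yaml`); explicit flags win.

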