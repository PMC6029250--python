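# rxnmetric

Biochemical reaction similarity toolkit.

`rxnmetric` scores the similarity of atom-mapped biochemical reactions at
two levels:

- **Reaction level** — every substrate and product is fingerprinted, the
  molecules of the two reactions are paired side-wise by a greedy
  algorithm that maximizes the selected similarity measure, and the score
  is the mean over all equivalent pairs (unpaired molecules are dropped).
- **Transformation level** — the reaction center (atoms whose bonds are
  formed, broken, or change order, found from atom-atom maps) is expanded
  to a configurable bond-distance degree *k*; the resulting fragments are
  scored with the same pairing procedure.

Four fingerprint types are available (`circular` — radius-1 hashed
environments; `extended` — hashed linear paths plus ring descriptors,
1024 bits by default; `substructure` — 307 bundled SMARTS keys;
`enhanced` — extended plus a dedicated 64-bit block of stereo and
formal-charge signatures) and nine binary similarity measures
(`tanimoto` (default), `dice`, `ochiai`, `simpson`, `russell_rao`,
`sokal_michener`, `faith`, `gower_legendre`, `rogers_tanimoto`).

Scores can be corrected for physicochemical variance: molecular mass and
additive van der Waals volume of the paired molecules feed a generalized
Jaccard distance `Jdist = 1 - mean(min(a,b)/max(a,b))`, and the corrected
score is `Rs = Rf / (1 + Jdist)`. A rule-table pKa model assigns formal
charges at a configurable pH (default 7) before enhanced fingerprinting.

An evaluation module provides EC-number ground-truth labeling (similar =
identical through the third EC field), ROC/AUC with accuracy/precision
versus cutoff, and Pearson correlation between scoring configurations. A
deterministic fixture generator produces small atom-mapped toy reactions
(ester hydrolyses, transaminations, phosphoryl transfers,
dehydrogenations) with EC-style labels, so everything is testable without
external data.

Atom-atom mapping is **required input** for transformation-level scoring;
automatic mapping is out of scope.

## CLI

```bash
# generate the toy reaction set
rxnmetric fixtures --seed 1 --n-per-family 3 --out-dir fx --rxn-files

# all-vs-all scoring (reaction + transformation level, with correction)
rxnmetric score --input fx/reactions.tsv --output scores.tsv \
    --level reaction --level transformation \
    --fp-type enhanced --measure tanimoto \
    --property mass --property volume --degree 1

# comparative assessment along one dimension
rxnmetric sweep --input fx/reactions.tsv --dimension measure \
    --measure tanimoto --measure dice --measure faith --output sweep.tsv

# re-score a subset of a previous run under new parameters
rxnmetric reevaluate --input fx/reactions.tsv --previous scores.tsv \
    --min-score 0.8 --measure dice --output rescored.tsv

# EC-label ROC on a scored pair table (id_a, id_b, score, ec_a, ec_b)
rxnmetric evaluate --input labeled.tsv --output roc.tsv
```

Every run writes a JSON config echo (all defaults resolved) next to its
output; re-running from the echoed configuration reproduces the output
byte-identically. Options can also come from a YAML file via `--config`,
with flags taking precedence.

Input reactions are reaction SMILES (atom maps in brackets, e.g.
`[CH3:1][OH:2]>>[CH3:1][OH:2]`) or MDL RXN V2000, batched in TSV/CSV
tables with columns `id`, `reaction`, optional `ec`.

## Layout

- `src/rxnmetric/chem_io.py` — SMILES/RXN parsing, reaction tables
- `src/rxnmetric/fingerprints.py` — the four fingerprint types
- `src/rxnmetric/measures.py` — the nine binary similarity measures
- `src/rxnmetric/pairing.py` — greedy pairing, reaction-level scores
- `src/rxnmetric/transformation.py` — reaction center, degree-k regions
- `src/rxnmetric/properties.py` — mass, volume, pH charges, Rs correction
- `src/rxnmetric/evaluation.py` — EC labels, ROC/AUC, Pearson matrix
- `src/rxnmetric/fixtures.py` — deterministic toy reaction generator
- `src/rxnmetric/cli.py`, `config.py` — command line and run config
- `src/rxnmetric/data/` — substructure keys, volume parameters, pKa rules
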