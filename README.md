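# minisplice

Analysis toolkit for **minigene splice assays** in clinical variant
interpretation. Given (1) a screening table of candidate splice variants
with SpliceAI delta scores, (2) gel-lane densitometry of the spliced
RT-PCR products of mutant minigene constructs, and (3) a transcript model
of the gene, it prioritizes variants, quantifies splice products,
annotates the aberrant transcripts in HGVS r./p. notation, and applies
gene-specific ACMG splice-assay rules to reclassify variants from the
residual wild-type transcript fraction. It was built around an *RPE65*
minigene cohort (packaged as data fixtures) and is intended for clinical
genetics groups running exon-trapping/minigene screens.

## The method

A variant enters the assay when its prior ACMG class is at most VUS and
any of its four SpliceAI components (acceptor gain/loss, donor gain/loss)
has Δ ≥ 0.1 with the predicted site within ±5000 bp. Each tested variant
yields a lane of RT-PCR products; densitometry turns the lane into band
fractions, and bands are identified by fragment size against the
transcripts predicted from a splice-event algebra (exon skips,
pseudo-exons, truncations/elongations, intron retentions). The decision
variable is the **residual wild-type fraction** `wt%`:

| `wt%`      | criterion           | class  |
|------------|---------------------|--------|
| 0          | PVS1 (very strong)  | P      |
| (0, 5)     | PVS1 (strong)       | LP     |
| [5, 20)    | —                   | as before |
| ≥ 20       | —                   | as before |
| 100, splice-only mechanism (synonymous / NCSS) | BP7 (strong) | B |

Consequences are reported as, e.g., `r.644_725del` /
`p.Asp215Valfs*4` for a frameshifting exon-7 skip (Δlen = −82,
first affected codon 215).

The packaged transcript model uses the cohort-evidenced exon map; its CDS
is a **synthetic, constraint-engineered stand-in** (the biological mRNA
sequence is not redistributed) that reproduces the cohort's printed codon
identities and junction frameshift consequences — see
`docs/methods.md`.

## Worked example

Classify the packaged quantified cohort (59 assays joined with the
73-variant screening table):

```sh
minisplice classify \
  --assays  src/minisplice/data/rpe65_assays.tsv \
  --variants src/minisplice/data/rpe65_variants.tsv \
  --out report.json
```

prints the cohort summary:

```json
{
  "n": 59,
  "bins": {"none": 7, "sub5": 0, "low": 11, "high": 41},
  "criteria": {"PP3:supporting": 32, "PVS1:very_strong": 7,
               "BP7:strong": 9},
  "final_classes": {"P": 7, "VUS": 30, "LB": 13, "B": 9},
  "constructs": {"WT-3": 25, "WT-4": 11, "WT-2": 23},
  "no_effect": 15
}
```

Reading: 7 assays showed **no residual wild-type transcript** and are
reclassified pathogenic via PVS1-very-strong; 11 retained 5–20% wild-type
transcript and 41 kept ≥20% (no splice criterion; class unchanged); 15 of
the latter showed no effect on splicing at all, and the 9 of those with a
splicing-only mechanism are reclassified benign via BP7-strong.
`report.json` additionally lists per-variant criteria and rationales.

The same pipeline runs from Python:

```python
import minisplice as ms
model = ms.load_bundled_model()
report = ms.protein_consequence([ms.SpliceEvent.exon_skip(7)], model)
# ConsequenceReport(r_notation='r.644_725del', delta_len=-82,
#                   frame='frameshift', p_notation='p.Asp215Valfs*4',
#                   first_affected_codon=215)
```

Other subcommands: `minisplice select` (SpliceAI filtering),
`minisplice quantify` (one lane + ladder → sized, identified band
fractions), `minisplice consequence` (events → r./p. notation),
`minisplice simulate` (synthetic model/table/lanes with ground truth).

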