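# Methods

`minisplice` re-implements, as a tested library, the computational chain of
a minigene splice-assay screen: in-silico prioritization of candidate
splice variants, assignment to wild-type minigene constructs, densitometric
quantification of spliced RT-PCR products, HGVS-style annotation of the
aberrant transcripts, and rule-based ACMG reclassification from the
residual wild-type transcript fraction. This note records the models,
parameter choices and their rationale, and what the synthetic tests do and
do not demonstrate.

## Coordinate system and transcript model

All positions are HGVS coding (c.) coordinates: 1-based within the CDS,
with a signed intronic offset (`643+5` = 5 nt into the intron past the
donor of the exon ending at c.643; `1129-293` = 293 nt upstream of the
acceptor of the exon starting at c.1129). Exons are closed intervals that
tile c. space without gaps; interval length is `end − start + 1`. Source
tables mix en-dash, minus-sign and hyphen glyphs; all are normalized to
`-` before parsing.

The packaged RPE65 model encodes a 14-exon, 1602-nt CDS (533 residues plus
stop). Exon boundaries are taken from the RNA-level deletion/insertion
coordinates the assay cohort itself evidences (e.g. the exon-7 span
c.644–725 from its skipping product r.644_725del); boundaries no r. string
pins down (the internal breaks among exons 1–3, the end of exon 14) are
stored with provenance `inferred` and never asserted by tests.

**The packaged CDS is synthetic.** The true RPE65 mRNA sequence is not
redistributed here. Instead `scripts/build_model_fixture.py` constructs,
deterministically and codon by codon, a stand-in sequence that (a) carries
the amino acid the cohort tables print at every referenced codon
(missense/synonymous sites and frameshift anchor residues) and (b)
reproduces, exactly, the junction-spanning protein consequences the cohort
reports for the exon 5, 6+7, 7, 7+8, 10 and 12 skips and the 2-nt exon-13
acceptor elongation (e.g. skipping c.644–725 → p.Asp215Valfs*4). Every
engineered consequence is verified against a brute-force
string-surgery-plus-translation oracle before the fixture is written.
Sequence-level results on this fixture therefore validate the annotation
*machinery*, and the specific consequences listed above, not any other
property of the biological RPE65 sequence.

## Variant selection

A variant is kept when its prior ACMG class is at most a cutoff (default
VUS) and at least one of its four SpliceAI delta scores (acceptor
gain/loss, donor gain/loss) reaches the threshold **with that component's
predicted site inside the analysis window**. Defaults: threshold 0.1
(inclusive ≥, with a strict-`>` flag, since the cohort's operative
restatement of the rule is inclusive), window 5000 bp, cutoff VUS using
the screening-timepoint class column (the follow-up column is carried for
reporting only). Duplicate records from different databases merge to
source `both`, keeping the more severe prior class and recording the
discarded one.

## Densitometry

A lane is a 1-D profile (pixel position, arbitrary intensity). The
quantification chain:

1. **Background**: morphological opening (rolling minimum then maximum)
   over a window wider than the band *multiplet* — the default pipeline
   uses 20 band-sigmas; a window only slightly wider than one band lets
   the baseline intrude between nearby bands and biases their ratio.
2. **Detection**: Gaussian smoothing (2 px by default; set near the band
   sigma for matched-filter detection of faint species), median-floor
   removal, then peak finding with a prominence floor that is the larger
   of 5% of the profile maximum and 5 robust noise sigmas (noise
   estimated from the median absolute first difference of the raw
   profile, which slow baselines and bands barely perturb).
3. **Integration**: trapezoid between flanking valleys, truncated to ±4
   estimated band sigmas around each peak so empty lane stretches add no
   area. Band area is taken proportional to molar fraction directly; no
   mass/size correction is applied, matching how assay product
   percentages are conventionally reported.
4. **Refinement** (optional, used by the synthetic pipeline):
   non-negative least squares of Gaussian amplitudes at the detected
   centres plus a pedestal/ramp term. All products on a gel share one
   band width, so a known width (from the ladder or a control lane)
   should be passed; fitting averages noise over the whole band shape
   and roughly halves the fraction error of plain integration.
5. **Calibration**: least-squares fit of migration against log10(size)
   over ≥3 ladder rungs; band sizes evaluated on the fitted line with the
   fit R² reported.
6. **Identification**: each sized band is greedily (by decreasing area)
   matched to the nearest predicted fragment size among candidate
   transcripts within a bp tolerance; unmatched bands are flagged
   `unidentified`. Predicted sizes are reporter flanks plus the summed
   segment lengths after applying the events to the construct's exon
   window.

Fractions are reported to whole percent in table outputs, matching the
source tables' precision.

## Splice events and consequences

Aberrant products are an event algebra: contiguous exon skips, intronic
pseudo-exons, exon truncations/elongations, intron retentions; a
transcript may carry several events (e.g. skipping exons 7 and 10
together). RNA notation serializes events deterministically
(`r.644_725del`, `r.1338_1339ins1339-2_1339-1`), joins co-occurring
species as `r.[x,y,=]`, and supports both the standard bracketed dialect
and the compound joined style the cohort tables print
(`r.644_725del_999_1128del`); a parser inverts both, and round-trips all
59 packaged r. strings byte-identically.

Protein consequences rebuild the spliced coding sequence segment by
segment, translate it, and locate the first residue differing from
reference. Frameshifts are reported as `p.<Ref><pos><New>fs*N` with N
counting from the first changed residue to the new stop inclusive (`fs*?`
if no stop is reached); in-frame changes as del/ins/delins after maximal
common prefix/suffix trimming. The coordinate-only
`first_affected_codon` is a lower bound: when the junction codon
resynthesizes the reference residue (as in the exon-12 skip, where codon
415 is rebuilt as serine) the sequence-based first *changed* residue sits
one codon downstream — the cohort's printed p.Phe416Leufs*2 reflects the
sequence-based numbering.

Intron-derived insertions need intronic sequence: models may carry full
intron sequences (the synthetic generator always does) or splice-site
flank snippets; the packaged model carries the canonical `AG` acceptor
flank of intron 12, which is all the 2-nt elongation product requires.

## Reclassification rules

Residual wild-type fraction is binned as `none` (exactly 0), `sub5`
(0–5), `low` ([5, 20)) and `high` (≥20); the half-open boundaries
reproduce the cohort's printed 7/11/41 partition. Criteria:

* `none` → PVS1 at very-strong, final class P;
* `sub5` → PVS1 at strong, final class LP;
* 100% wild-type and a synonymous or non-canonical splice-site variant
  (no plausible mechanism other than splicing) → BP7 at strong, final
  class B; a splice-silent missense variant keeps its prior class;
* `low`/`high` otherwise → no splice criterion, class unchanged;
* PP3-supporting is recorded whenever the highest delta score is ≥0.2,
  for reporting only — it never changes a class by itself.

This is intentionally not a full ACMG evidence combiner; only the
splice-assay pathway is implemented. The enzyme-activity PS3 route is
deliberately absent (gene-specific guidance advises against applying it
to splicing assays). An optional baseline-adjustment mode flags aberrant
species that match a construct's constitutive wild-type products (e.g.
39% exon-7 skipping in the exon 6–10 construct) within a fraction
tolerance (default 10 points) and exposes an effective wild-type fraction
that discounts them; it is off by default because the source tables'
printed percentages are raw.

## Synthetic data generator

The generator emulates the statistical shape of the emulated screen, not
any particular chemistry. Defaults (a single seed fixes everything):

* **Gene model**: 13 exons of 63–150 nt (at least one not divisible by 3,
  so single-exon skips can frameshift), introns of 80–300 nt with
  canonical GT…AG ends, a stop-free random CDS, and constructs as sliding
  5-exon windows overlapping by one exon with 150/150-nt reporter flanks.
* **Variant table**: 73 variants (the emulated cohort's size), placed
  exonic/NCSS/deep-intronic at 0.55/0.35/0.10. Above-threshold variants
  (50%) draw their leading score from 0.1 + 0.9·Beta(1.2, 4) — most mass
  in 0.1–0.3 with a high tail, a stylized match to the screen's observed
  spread, not a fit — with the predicted site inside the 5000-bp window
  90% of the time; sub-threshold scores are 0.1·Beta(1, 9) capped at
  0.09 so 2-decimal table rounding cannot cross the cut-off. Ground-truth
  selection labels are computed by the generator's own logic,
  independently of the intake module.
* **Lanes**: one Gaussian band per species (σ = 6 px on a 1200-px lane),
  area proportional to fraction, over a small offset-plus-ramp baseline
  (5% of peak) with additive Gaussian noise at SNR 30 (peak amplitude
  over noise sigma); an 8-rung 100–2000-bp ladder with migration linear
  in log size. Ground truth (centres, sizes, fractions, an overlap
  warning below 1σ separation) accompanies every lane.

The end-to-end cohort simulation draws residual-WT bins at probabilities
0.2/0.25/0.4/0.15 for none/low/high/splice-silent — mirroring the
emulated cohort, which had no assay strictly between 0 and 5% — with true
fractions kept more than 2 points from the 5%/20% cut-offs so the
densitometry tolerance cannot flip a bin, and species fractions of at
least 7 points so every true band clears the detection floor.

Replicate-accuracy tests quantify **duplicate lanes and average them**,
mirroring the assay protocol's duplicate experiments: single-lane NNLS
quantification at SNR 20 has an irreducible fraction noise of ~0.7
points, so duplicate means are what hold the ±2-point recovery bound.

What passing synthetic tests shows: the pipeline's arithmetic, detection
and classification logic are correct under Gaussian bands, log-linear
migration and additive noise. What they do not show: robustness to real
gel artefacts — smears, heteroduplexes, saturation, lane distortion —
none of which the generator attempts to model.

## Numerical choices and degenerate inputs

Fractions over a lane always sum to 100 within rounding; quantification
is invariant to global intensity scaling. Empty profiles yield empty band
lists (not errors); ladders need ≥3 strictly size-decreasing rungs;
assays validate conservation (wild-type plus aberrant totals within
100 ± 1, against the reported aberrant total where per-species
percentages were rounded independently). Tie-breaks: when several
constructs cover a variant, a declared assignment from the input table
wins, else the nearest window centre; band-to-candidate matching is
greedy by decreasing area with each candidate consumed once.

## Known limitations

* Genomic (g.) coordinates, strand handling and multi-transcript models
  are out of scope; everything lives in c. space.
* Protein notation covers the event algebra, not arbitrary SNVs; the
  in-frame delins naming uses prefix/suffix trimming without the full
  HGVS 3'-shifting normalization.
* Intron retention consequences require the intron's sequence; the
  packaged model carries only a 2-nt acceptor flank for intron 12.
* The identity-text parser covers the vocabulary of the packaged cohort
  tables; novel phrasings raise a parse error rather than guessing.
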