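# Methods

## The analysis model

The pipeline treats search-engine output as a table of candidate
correlations between MS/MS spectra and tryptic peptides in a redundant
protein library. Three error sources dominate such tables and each has a
dedicated control:

* **Spectrum re-use.** A spectrum correlated to several peptides or charge
  states inflates counts. The cascade keeps, per spectrum, only the charge
  state whose best p-value is lowest, then only the lowest-p peptide, then a
  single accession — so each spectrum contributes exactly one RANK1
  correlation. Identity of a candidate correlation is the 4-tuple
  (spectrum, charge, peptide, accession); `cascade.complex_key` exposes the
  SHA1 digest over it.
* **Random mis-correlation.** In a null model where assignments are drawn
  with probability proportional to each protein's tryptic-peptide count,
  giant proteins (titin-class) accumulate the most chance hits. Requiring
  ≥ k independent correlations per accession (default k = 5; k = 3 is a
  common lenient choice), comparing the observed peptide-count distribution
  to the null by Pearson χ², and screening against named contaminant lists
  all target this mode.
* **Condition-independent noise.** Source noise and dust hit both treatment
  groups equally, so the run-normalised RT/ICE count ratio with a fivefold
  threshold removes them without needing to know their identity.

Gene-level significance combines the retained peptides' p-values per gene
symbol. The default "cumulative p" is the raw product — not a calibrated
p-value, but monotone in evidence and spanning hundreds of orders of
magnitude, which is the quantity the field reports; Fisher's method
(−2Σln pᵢ against χ² with 2k df) is available where calibration matters.
Benjamini–Hochberg is applied across gene symbols (one value per symbol),
not across peptides. Products of many small p-values underflow double
precision; the combined value is floored at the smallest positive subnormal
so BH stays defined, and the exact magnitude is carried separately as
`log10_cumulative_p`.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| intensity floor | 1000, inclusive | detector counts | physical noise filter on precursor ions; "at least" semantics, a strict (>) mode is a flag |
| min correlations/accession | 5 | RANK1 correlations | robust-identification threshold; counts correlations, not distinct sequences (a distinct-sequence mode exists) |
| RT/ICE fold | 5 | ratio | false positives shared by both conditions sit near ratio 1; fivefold leaves wide margin over sampling noise |
| pseudocount | 1 | counts | keeps genes absent from the ICE group finite (RT-specific genes exist) |
| run normalisation | on | runs | the two groups have 88 vs 82 LC–ESI–MS/MS runs |
| consensus rule | SEQUEST ≥ 5 ∧ X!TANDEM ≥ 1 | peptides | two independent algorithms rarely share a random error |
| χ² bin pooling | expected < 5 | counts | standard validity convention; low-expectation bins merge rightward, the tail folds left |
| log10 intensity bin | 0.25 | log10 counts | fine enough to show the RT/ICE intensity shift |
| proton mass | 1.007276 | Da | m/z ↔ neutral-mass conversion |
| proline rule | on | — | no cleavage at K/R–P, for both terminus checks and missed-cleavage counts; toggleable since conventions differ |

Masses are monoisotopic by default (pyteomics residue table); an
average-mass table is available since ion-trap delta masses span ±2 Da and
isotope choice matters when emulating them.

## Tie-breaking and degenerate inputs

All selections are deterministic: lower charge, then lower p-value, then
lexicographically smaller peptide, then lexicographically smaller accession
(and for representatives, higher correlation count before the lexicographic
fallback). Empty tables flow through every stage and produce zero counts
rather than errors. Records with an empty gene symbol survive all
correlation-level stages, are excluded from the gene rollup, and are counted
separately (`CascadeResult.n_no_symbol`). A combined p-value of zero on
input is rejected as an upstream underflow signal. Zero intensities are
excluded from log histograms with a warning. A delta-mass spread of zero is
flagged degenerate rather than plotted.

## The synthetic-data generator

`simulate.SimulationDesign` fixes the study conditions; all randomness flows
from its single mandatory seed, and the design serialises to JSON next to
its outputs.

* **Library.** Genes carry 1–3 isoform accessions (probabilities
  0.5/0.3/0.2); each protein is a concatenation of tryptic fragments
  (5–14 residues ending in K/R; proline and internal K/R are excluded from
  fragment bodies so every site cleaves). Later isoforms keep ≥ 60% of the
  first isoform's fragments, so isoforms share most tryptic peptides —
  the redundancy the rollup exists to remove. Each accession's symbol is
  blanked with probability 0.26, mirroring real federated libraries where
  only ~74% of accessions have defined symbols.
* **Counts.** Per-gene expected ICE correlation totals are log-normal
  (median 30, σ = 0.4 on the log scale) floored at 20 so every gene is
  quantifiable; RT rates are the ICE rate × degradation fold (10 for the
  15% of genes drawn as degraded, 1 otherwise) × the 88/82 run ratio.
  Realised counts are Poisson.
* **PSMs.** True correlations draw p ~ Beta(0.05, 1) (so per-gene products
  span many orders of magnitude); mis-correlations (2% of events) draw a
  peptide from the whole digest — hitting giant proteins in proportion to
  size — with p ~ U(0,1). Intensities are log-normal (log10 mean 3.5 ICE /
  3.6 RT, σ 0.5, so a realistic fraction falls below the 1000-count floor
  and the RT group is slightly intensity-shifted). Precursor m/z is computed
  from the peptide's theoretical mass plus a N(0, 0.4) delta clipped to
  ±2 Da at charge 2+ or 3+; 5% of peptides carry a phospho modification.
  15% of spectra get a decoy duplicate at the other charge and 10% a
  second, worse-scoring peptide candidate, so the dedup stages have real
  work to do. Each correlation is emitted once per accession containing the
  peptide.
* **Contaminants.** Five catalog genes (TTN as a giant at ~10× median
  length, NEB, ACTB, KRT10, CYCS) are injected at equal normalised rates in
  both treatment groups, never degraded.
* **Null tables.** Random assignment weighted by digest size, uniform
  p-values — a spectrum-free stand-in for a random-spectra generator, which
  is sufficient because the downstream statistic only consumes the count
  distribution.
* **Truth.** Per-gene degraded/fold/contaminant flags plus per-row
  true/contaminant labels aligned row-for-row with both emitted tables.

At the default scale (200 genes, 82 + 88 runs, ~35k X!TANDEM rows) a full
study generates in well under a minute; tests use 6–40-gene designs. These
sizes are the package's chosen working scale: large enough that Poisson
noise on a fold-10 gene with ≥ 20 expected ICE correlations cannot push its
ratio below 5, small enough to iterate on.

**What passing tests do and do not show.** The generator reproduces the
count structure, score mixture, redundancy and contamination patterns the
analysis assumes — so passing tests show the pipeline implements its rules
correctly and recovers planted signals under those assumptions. It does not
emulate retention time, chromatographic co-elution, fragment spectra,
exopeptidase trimming (ragged termini), inter-donor biological variance, or
search-engine score miscalibration; real-data performance depends on those.

**Recovery metrics.** Recall of degraded genes is computed over genes with
at least one symbol-bearing accession: a gene whose accessions all lack a
defined symbol is invisible to any gene-symbol-level rollup, ours included.
The nominal `false_enrichment_rate` (0.05) bounds the probability that an
undegraded gene passes the fivefold filter through sampling noise;
contaminant pass rates are compared against it.

## Design choices that were genuinely open

* **Cumulative-p definition** — raw product chosen as the default (it is
  what the name and the log10 presentation imply), Fisher kept as the
  calibrated alternative; the choice is recorded in output metadata.
* **"Independent peptides"** for the ≥ k filter counts RANK1 correlations,
  which makes the cascade's arithmetic self-consistent; a distinct-sequence
  mode is a flag.
* **Intensity boundary** — inclusive (≥ 1000), since the filter is stated as
  "at least"; a strict flag flips it.
* **FDR level application** — q-values are computed at gene-symbol level;
  thresholds (1%, 0.02%) are parameters, not constants.
* **Fivefold-vs-consensus order** — the CLI applies the fivefold filter to
  the single-algorithm cascade output; consensus filtering is a separate
  composable step, so either order can be scripted.
* **Enrichment null** — hypergeometric upper tail; the multiple-testing
  universe defaults to terms with ≥ 1 observed gene (an `all` mode exists).
  Output metadata labels the method, since network databases do not publish
  their exact internal statistic.

## Known limitations

* The pipeline consumes PSM tables in one strict TSV dialect; it does not
  parse pepXML/mzIdentML/mzML and does not re-score PSMs.
* The product cumulative p is not a calibrated p-value; BH on it controls
  ranking-based FDR only under the usual positive-dependence caveats. Use
  Fisher mode when calibration matters.
* The hypergeometric enrichment p-values are discrete; at small term or set
  sizes they are conservative.
* Time-course kinetics over the 0–72 h incubation are out of scope; both
  treatment groups are pooled.
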