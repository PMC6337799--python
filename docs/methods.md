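# Methods

## Assay model

The package models dsODN-marked break sequencing as a generative process
with four molecule classes:

1. **Nuclease cleavage** at genomic loci resembling a guide's protospacer
   (exact PAM required), cut bluntly 3 bp 5′ of the PAM, with small
   resection offsets before ODN capture.
2. **Spontaneous double-strand breaks**, frequent during cell division and
   biased toward active chromatin; they capture the ODN exactly like
   nuclease cuts and form the background of every run.
3. **Sonication + ligation-mediated nested PCR**: each captured break is
   read out as a fragment from the ODN–genome junction to a random
   sonication breakpoint. Distinct breakpoints mark independent cellular
   isolation events; identical fragments are PCR duplicates.
4. **Mispriming**: the inner ODN primer anneals at genomic loci whose
   sequence resembles it, producing amplicons with the same structure as
   true junction fragments except that the ODN-derived reporter segment is
   absent.

The analysis inverts this process. The reporter check classifies
molecules; alignment recovers `(junction, breakpoint)` per fragment; gap
clustering groups junctions into sites; distinct fragment signatures
quantify abundance; the guide scan annotates sites as on-/off-target; the
flank-score test quantifies residual mispriming; ROC areas relate site
positions to annotation density.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `match_min` | 14 (of 20) | bases | published off-target filter: ≥14/20 protospacer matches |
| PAM policy | exact IUPAC | — | published filter requires a perfect PAM |
| `match_window` | 100 | bp | published site-to-locus assignment window |
| `cut_offset` | −3 | bp | blunt SpCas9 cut between protospacer bases 17/18 |
| `cluster_gap` | 25 | bp | exceeds resection spread, separates nearby loci; no published value, recorded in run metadata |
| `reporter_max_mismatch` | 1 | bases | reporter is short; MiSeq substitutions rare, indels rarer — ungapped Hamming at fixed offset |
| `primer_max_mismatch` | 2 | bases | primer-prefix trim tolerance |
| barcode tolerance | 0 | bases | conservative exact demultiplexing; configurable |
| aligner mismatch budget | 5% of length | — | ungapped seed-and-extend; exact junction recovery is the requirement, not indel tolerance |
| SAM MAPQ floor | 30 | — | a convention for imported alignments, not a published value |
| enrichment windows | 1 kb, 10 kb, 100 kb, 1 Mb | bp | 10 kb is the published comparison interval; the others bracket it because the relevant scale is unknown |
| permutation count | 10 000 | — | resolves p ≈ 1e-4, the smallest starred threshold, with +1 correction |
| null sample size | 1000 | positions | flank-score null per genome/primer |

The dsODN itself, its reporter and the two nested primers are run
configuration. The shipped default is a synthetic 46-nt design
(`primer1[0:16] | primer2[16:34] | reporter[34:46]`) constructed for
self-contained operation and testing; real studies supply their own oligo
set in the YAML configuration.

## Coordinates and conventions

All internal coordinates are 0-based; intervals are half-open; `junction`
and `break` are inclusive base coordinates, so fragment length is
`|break − junction| + 1`. BED output is 0-based half-open; rendered report
positions are 1-based. For a reverse-strand SAM record the junction is the
*last covered reference base* (the 5′ end of the read), mirroring the
forward convention that the junction is the first covered base.

## Quantification choices

- **Abundance** counts distinct `(strand, junction, break)` triples, not
  fragment lengths alone, so equal lengths from different junctions or
  strands never collapse. Abundance is invariant under read duplication.
- **Site position** is the signature-weighted modal junction (ties to the
  smaller coordinate): junctions are discrete, the mode matches pile-up
  intuition, and weighting by distinct signatures keeps PCR jackpots from
  moving the site.
- **Sonication breakpoints** beyond the ODN-side read length are recovered
  from the adapter-side mate (its position-0 base is the break); when no
  single compatible mate placement exists the ODN-side read extent is used.
- **Specificity**: `filtered = 100 × A₀ / A_g` and
  `unfiltered = 100 × A₀ / A_t`, where `A₀` is abundance at sites assigned
  to 0-mismatch matches, `A_g` at all guide-matched sites, `A_t` at all
  sites. `A₀ ≤ A_g ≤ A_t` guarantees filtered ≥ unfiltered. A zero
  `A_g` yields NA with a reason rather than a number.
- **Mispriming score**: positional identity of the `|primer|` bases ending
  at the junction on the priming strand, 3′-anchored — PCR extension
  requires a matched 3′ terminus, so that is the geometry that matters.
  The pipeline scores one flank per *site* (modal junction, majority
  strand); per-event scoring is available as a library primitive. The test
  is the tie-corrected normal-approximation Mann-Whitney U, one-sided
  (sample > null); scores are small integers with heavy ties, which the
  tie correction handles and an exact test would not. Completely tied
  inputs return p = 0.5. A Kolmogorov-Smirnov alternative was considered
  and rejected for its poor behavior under heavy discreteness.
- **ROC area** is the two-sample rank statistic scaled to [0, 1]
  (ties at half credit), so `area(a,b) + area(b,a) = 1` and the area is
  invariant under monotone transforms of density. Significance is a
  two-sided label-permutation test by default (seeded, vectorized over
  pooled ranks); a normal approximation is available. Stars reflect raw
  p-values as is conventional for these heatmaps; a Benjamini-Hochberg
  column (`p_adj`) is emitted alongside.
- **Percent enrichment** is
  `100 × (mean site density − mean control density) / mean control density`,
  emitted with each ROC cell; it is a documented summary of effect size on
  the density scale, not a reproduction of any published statistic.

## The synthetic-data generator

`odnmap.simulate` emulates: i.i.d. genome at configurable GC with a gene
interval track (~30% coverage); planted protospacer+PAM loci with exact
mismatch counts on random strands; spontaneous breaks optionally biased
into genes (default bias 0.8); mispriming loci whose upstream flank is
written to equal the inner primer and whose downstream sequence is
constrained to share fewer than `len(reporter) − tolerance` bases with the
reporter (so filter false-keeps are structurally impossible); fragment
lengths uniform on `[read_len, 3·read_len]`; PCR duplication by exact
fragment reuse at rate `dup_rate`; and the full read grammar
`primer2+reporter+flank` / `barcode+adapter+rc(flank)` with read-through
into the opposite element when the fragment is short.

Default study conditions: 50 mispriming loci and 30% misprimed reads
(mispriming is widespread across adventitious loci in unfiltered data),
50 spontaneous sites, and origin weights 50 : 0.5 : 1
(on-target : per off-target : per spontaneous site), which put ~95–99% of
guide-matched abundance on target and roughly half of total abundance in
the spontaneous background.

What it does **not** model: sequencing errors by default (a uniform
substitution rate is available; exact abundance assertions need noise-free
baselines), quality-score variation (constant Q40), indels, chimeric PCR
products, chromatin-dependent capture efficiency, and real genome
repeat structure. Passing tests therefore demonstrate correctness of the
computation on the modeled process, not robustness to every artifact class
of real MiSeq data; chimera-like artifacts in particular are only removed
insofar as they lack the reporter.

## Numerical and degenerate-input behavior

Ambiguous genome bases (N) never match a protospacer base or a concrete
PAM symbol (pattern N accepts anything). Alignment ties are reported as
non-unique rather than resolved arbitrarily, and non-unique fragments are
excluded from site calling but counted. Clustering is permutation-
invariant (input is sorted internally). Empty inputs: empty FASTQ streams
are valid; an empty site list is an error for enrichment ("no sites");
zero-length null samples are rejected. All TSV output is written with
fixed float formatting and sorted rows, so identical inputs and seed give
byte-identical files.

## Problem sizes

The test suite validates the scanner against brute force on twenty 100 kb
genomes, end-to-end recovery on 50,000 read pairs over a 1 Mb genome, the
mispriming diagnostic over ten seeded 6,000-read simulations, and null
calibration over 200 replicates per test. `scripts/acceptance.py` uses the
50k-pair / 1 Mb design. These sizes exercise every code path at scales
where the binomial/rank asymptotics the tests rely on are accurate.

## Known limitations

- The built-in aligner is ungapped and intended for synthetic genomes;
  real data should be aligned externally and imported as SAM.
- Guide matching is a Hamming criterion; bulge-tolerant or energy-model
  scoring (CFD/MIT) is out of scope.
- Whether sites should merge across strands or report strand-specific
  flanks separately is not settled; sites merge across strands here, and
  per-strand event counts are exported so the other view can be derived.
- Which nested primer drives the mispriming diagnostic is configurable;
  the pipeline reports both.
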