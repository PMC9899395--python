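# Methods

## Scope and model

`gbs3d` models a multi-enzyme reduced-representation sequencing protocol as
four composable stages:

1. **Digestion.** The genome's top strand is scanned for each enzyme's IUPAC
   recognition site; every match contributes a cut at
   `site_start + cut_offset` (the asterisk convention: `CTGCA*G` cuts after
   five bases). Only palindromic sites are accepted, so top-strand scanning
   sees every duplex site and nothing is lost; non-palindromic enzymes are
   rejected rather than half-scanned. Overlapping matches each cut; windows
   containing `N` never match (reference gaps produce no phantom fragments).
   Coordinates are 0-based half-open everywhere in the digestion half of the
   package; VCF positions (1-based) are converted only at the VCF boundary.

2. **Methylation blocking.** A methylation track lists methylated cytosines,
   given either as the top-strand C or as the G whose paired bottom-strand
   base is the methylated C; both encodings normalise to strand-aware
   records. A fully sensitive enzyme (PstI) is blocked whenever *any*
   methylated cytosine falls inside the matched duplex site — the paper-level
   description gives no finer model, and this conservative rule captures
   CpG/CHG blocking within the site. A partially sensitive enzyme (ApeKI) is
   blocked at a methylated site independently with probability
   `partial_block_probability` (default 0.5, seeded). "Partially sensitive"
   is qualitative in the literature, so this probability is an explicit
   modelling knob, not a measured constant; results that depend on it should
   be reported with the value used. Insensitive enzymes (NsiI, MspI) always
   cut.

3. **Library selection.** A fragment is retained iff one end label is in the
   rare set (default {PstI, NsiI}; their common overhang matches the 5′
   adapter), the other end equals the frequent cutter (default MspI, the 3′
   adapter), and `length + adapter_extension` lies in the inclusive size
   window (default [50, 350] bp). Terminus-ended, rare–rare and
   frequent–frequent fragments never receive both adapter types and are
   excluded. The published 50–350 bp window is quoted on the adapter-ligated
   molecule; adapter lengths are platform-specific and not modelled, so
   `adapter_extension` defaults to 0 and is exposed for users who know their
   adapter lengths. A design whose rare set equals the frequent cutter (or an
   empty rare set) denotes the classic single-enzyme protocol, where X–X
   fragments are sequenced — used for ApeKI baselines.

4. **Read budget.** Reads are modelled one per fragment copy (single-end
   short-read sequencing of size-selected inserts), so "depth" is reads per
   fragment, not per base. With N reads over F selected fragments,
   per-fragment depth is λ = N/F. Treating per-fragment counts as Poisson(λ)
   (the large-F limit of the multinomial), dropout is e^(−λ) and
   P(depth < d) = Poisson CDF at d − 1. The default `min_depth` is 2, a
   common minimum for calling a diploid genotype. The inverse mode returns
   ⌈λ*·F⌉ reads for a target depth λ*. `simulate_reads` provides the exact
   multinomial forward model, with optional log-normal fragment weights
   (σ = `bias_dispersion`) emulating amplification bias; the test suite
   verifies the Poisson zero-class against it at F = 10⁴.

Note that a VCF-based "mean depth of coverage" computed over variant
positions (as variant-calling pipelines report) is related but not identical
to λ: λ is per selected fragment, before alignment and calling losses. The
two should agree in order of magnitude, not digit for digit.

## Marker diagnostics

**Filtering.** A record is removed on the first failing rule, in order:
QUAL < 10; MQ < 30 (absent MQ fails, conservatively); chromosome excluded
(by default anything whose name contains "scaffold"; a whitelist can be
given); indel (any allele length ≠ 1); not biallelic; missing-genotype rate
≥ 0.8; site heterozygosity ≥ 0.1 among non-missing calls. The quality pair
is disjunctive by default — the retention sentence "QUAL < 10 and MQ < 30"
reads most naturally as two removal criteria — with a `qual_mq_mode="both"`
option for the conjunctive reading. The missing/het thresholds are strict on
retention ("< 0.8", "< 0.1"). Heterozygosity here is per-site (a site filter);
per-sample heterozygosity appears separately in the diversity summary.

**Densities and gaps.** SNP/Mb = total markers / (total length / 10⁶), and
analogously SNP/cM on total map length. A gap is a distance between
*consecutive* markers on one chromosome strictly greater than the threshold
(5/10 Mb physical, 10/20 cM genetic by default). Distances from chromosome
or map ends to the terminal markers are not gaps by default
(`include_ends=True` adds them); gap counts are anti-monotone in the
threshold by construction and asserted so.

**Genetic positions.** Each marker takes the cM of the consensus-map anchor
with minimal |bp difference| on its chromosome; exact ties resolve to the
smaller-bp anchor; markers on unmapped chromosomes are flagged unplaced
rather than dropped silently.

**Diversity.** Missing rate is over all records × samples; het rate over
non-missing calls; per-site MAF from non-missing allele counts; per-site
nucleotide diversity uses the small-sample-corrected estimator
π = 2p(1−p)·n/(n−1) with n the non-missing allele count. All-missing sites
count toward missingness but are skipped (and logged) for MAF/π. Other
implementations normalise π differently, so values are comparable in
structure across tools, not guaranteed numerically identical.

**Distances.** IBS distance between two samples is 1 minus the mean over
sites with both calls of (shared alleles)/2, where shared alleles is the
multiset intersection of the two diploid genotypes (AA vs AT shares 1).
Published IBS variants differ in heterozygote handling; this definition is
the one stated and tested. Pairs with zero comparable sites are NaN, never
0. Polymorphic-marker counts for a candidate cross require both calls
present and genotypes different.

## Synthetic data

The generators are pure functions of (spec, seed) — byte-identical reruns —
and emulate only what the toolkit consumes:

- **Genomes** are i.i.d. bases at a stated GC fraction (optionally a linear
  gradient along the sequence). Real genomes have repeats, isochores,
  methylation islands and assembly gaps; none are modelled. Consequently
  passing statistical tests shows the *arithmetic* is right (observed
  cutting intervals converge to 1/p, etc.), not that coverage predictions
  transfer quantitatively to any particular species. On uniform DNA the
  default VcfSpec and GenomeSpec values are chosen to exercise both branches
  of every filter rather than to mimic one organism.
- **Methylation** marks each CpG cytosine (both strands) independently with
  a stated fraction; CHG/CHH contexts and spatial autocorrelation are not
  modelled.
- **Consensus maps** place anchors evenly with a linear cM/Mb rate (default
  2.5) plus truncated jitter that cannot break monotonicity, so with zero
  jitter the map is exactly linear — convenient for closed-form checks.
- **VCFs** draw QUAL, MQ, missing rate and MAF from stated ranges and place
  stated fractions of indel, multiallelic and scaffold records. The
  generator emits a truth table computed from its own realised values
  (rounded to the two decimals actually written, so a reader sees the same
  numbers), making filter tests oracle-exact rather than re-derived. No
  linkage disequilibrium or pedigree structure is simulated.

## Numerical and design choices

- GC percent is truncated toward zero (floor) to match the quoting
  convention for 6-bp sites (66%/33%); the exact rational value is exposed
  as `gc_fraction_exact`.
- `percent_reduction` rounds half away from zero, reproducing ~92% (1.2M →
  100K) and ~86% (1.4M → 200K).
- Coincident cuts by two enzymes at one coordinate keep the first-listed
  enzyme's label and log a warning — deterministic and observable.
- Strand symmetry: for a palindromic site with an asymmetric cut offset,
  reverse-complementing the genome shifts every cut by the constant
  2·offset − site_length, so interior fragment lengths are preserved as a
  multiset (and all lengths for blunt cutters); the tests check exactly
  this.
- FASTQ subsampling is uniform without replacement, order-preserving and
  seeded; it is not bit-compatible with any particular external subsampler,
  by contract.
- The run report is validated against the JSON schema shipped in
  `gbs3d/data/design_report.schema.json` by a small structural validator
  (required keys and types) built into the package.
- Enzyme registry: built-ins ship as a packaged TSV
  (`gbs3d/data/enzymes.tsv`) with name, IUPAC site, cut offset and
  methylation class; users can override with `--registry`. Cut offsets for
  the alternative cutters (BglII, BclI, BlnI, BamHI, BfaI, BstUI) follow
  standard REBASE definitions. BfaI's site (CTAG) is 50% GC by arithmetic
  regardless of the class it is sometimes marketed under.

## Problem sizes in the test suite

Statistical digestion checks run on 0.5–2 Mb uniform genomes, where 5%
relative tolerances are comfortably above sampling noise; the end-to-end
arithmetic checks use a 10 Mb genome, 100 × 50 kb genomes for scanner/oracle
equivalence, a 1,000-site VCF for filter truth, and F = 10⁴ fragments for
the dropout comparison. These sizes make the full suite run in seconds on
one core while keeping Monte-Carlo bounds meaningful.

## Known limitations

- Digestion is all-or-none: no partial digestion kinetics, star activity,
  nicking, or buffer effects.
- Type IIS / offset-cutting and non-palindromic enzymes are out of scope.
- PCR duplicates, GC amplification bias curves (beyond the log-normal
  dispersion knob), barcode demultiplexing and base errors are not
  simulated.
- Predicted coverage and depth describe the protocol's in-silico capture;
  alignment losses, repeat collapse and caller behaviour sit between these
  predictions and the numbers a variant-calling pipeline reports.
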