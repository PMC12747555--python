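# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `gseseq`.

## Barcode-pool statistics

A barcode is `L` i.i.d. uniform bases (default `L = 19` over ACGT), so the
sequence space holds `N = 4^L` barcodes, computed in exact integer
arithmetic (never floating point). Pool synthesis is modeled as sampling
**with replacement** — random oligo synthesis draws each molecule
independently — so the expected number of distinct sequences among `n` draws
is `N(1 − (1 − 1/N)^n)` and the expected **collision fraction** (fraction of
draws that repeat an already-drawn sequence) is

```
f(n, N) = 1 − N(1 − (1 − 1/N)^n)/n .
```

It is evaluated with `log1p`/`expm1` so it remains accurate when
`n/N ≪ 1` (at `n = 5×10⁹`, `N = 4^19`, `f ≈ 0.90 %`, close to the
small-ratio approximation `n/2N`). The Monte-Carlo validator measures the
same excess-draw statistic, `(n − #distinct)/n`, per replicate; defining the
empirical fraction instead as "draws whose value occurs ≥ 2 times" would
double-count each collision and sit ~2× above the closed form, so the
excess-draw definition is used for both routes. The statistic quantifying
"error tolerance" of a pool is a design interpretation: the module exposes
both the collision fraction and a realized-pool Levenshtein
distance-profile (exact pair counts within radius ≤ 2 via a
symmetric-deletion index verified by edit distance) so users can apply
either reading.

## Simulator

The generator emulates one mock experiment end to end; all stochastic
choices flow from a single seed (NumPy `default_rng`), making outputs
byte-reproducible.

* **Droplet loading** — entities per occupied droplet are zero-truncated
  Poisson(λ), default λ = 0.1 (≈ 4.9 % doublets among occupied droplets,
  typical of dilute droplet loading). λ = 0 is the documented zero-loading
  limit: exactly one entity per droplet.
* **Barcodes** — each droplet draws a uniform slot from a pool of
  `pool_size` (default 5×10⁹); distinct slots receive i.i.d. random
  barcodes, so pool collisions are reproduced without materializing the
  pool. The read's barcode segment is corrupted by substitutions at
  `barcode_error_rate` (default 0.5 %, representing synthesis/PCR errors on
  top of sequencing error).
* **Amplification bias** — each (droplet, entity) partitions its genome
  into 500 bp windows with log-normal(0, σ) sampling weights (default
  σ = 1.0). The log-normal is the simplest heavy-tailed stand-in for MDA
  bias; σ = 0 recovers uniform coverage.
* **Fragmentation / read length** — a fragment anchors uniformly inside a
  bias-weighted window and extends left or right (equal probability) by a
  log-normal length draw, truncated at the genome ends. Truncation makes
  terminal fragments that start or end exactly at a genome boundary occur at
  a realistic rate, as enzymatic fragmentation of linear amplicons produces
  terminal pieces. Lengths are log-normal with
  `μ = ln(N50_target) − σ_len²`: the length-weighted median of a
  log-normal(μ, σ) is `exp(μ + σ²)`, so the realized N50 lands on the
  target (default 1700 bp, σ_len = 0.45) regardless of σ_len; boundary
  truncation shifts it by ≲ 2 % at 40 kb genomes.
* **Errors** — per-base substitution 10⁻³ and insertion/deletion 3×10⁻⁴
  each (HiFi-like, ≥ Q30 scale), applied to the whole molecule
  (cassette + insert). Reads are emitted in either orientation with equal
  probability; qualities are a constant Q30 placeholder.
* **Ambient contamination** — with probability `ambient_fraction`
  (default 1 %) a read keeps its droplet's barcode but draws its fragment
  from a random other droplet's genome (barcode-correct, insert-foreign —
  what mock-community external contamination measures). Barcode hopping is
  not modeled separately.

What the simulator does **not** emulate: chimeric MDA products, branched
amplification structures, quality-value realism, PacBio subread/CCS
mechanics, and droplet-to-droplet reagent variability. Tests passing on
this generator therefore demonstrate algorithmic correctness and
parameter recovery under controlled noise, not performance on every
artifact of real libraries.

## Cassette parsing

Both anchors are located by infix (semi-global) edit-distance alignment
(edlib) against the read and its reverse complement; a placement is valid
when each anchor is within `max_anchor_edits` (default 2, conservative for
Q30 reads) and the inter-anchor gap is within `barcode_length ±
indel_slack` (default 1). The best joint placement by total edits wins;
ties prefer the plus strand, then the 5′-most placement; ties that yield
different barcode strings are reported `ambiguous` (substitutions at the
anchor/barcode boundary genuinely create such frame ambiguities). The
anchor3 search is restricted to the window implied by the gap constraint,
and anchor5 placements are enumerated at their best edit distance — a
greedy simplification of full joint optimization that the sliding-window
oracle tests bound. In the optional two-cassette layout the second cassette
is parsed from the opposite orientation and the two barcodes must agree
within 1 edit, otherwise the read is ambiguous.

## Barcode clustering

Greedy abundance-descending sphere clustering: barcodes are visited by
descending count (ties lexicographic); each joins the most abundant
existing canonical within Levenshtein `d` (default 2, appropriate for
19-mers at sub-percent error) whose **accumulated** count at merge time is
≥ `ratio` × its own count (default 5), else founds a canonical. Merging is
single-level, so the `≤ d` member guarantee is exact; chaining is
deliberately excluded. Candidates come from a symmetric-deletion index
(strings within edit distance `d` always share a variant after ≤ d
deletions each), with every candidate verified by banded edit distance, so
the result is identical to the all-pairs brute-force greedy — a property
the test suite asserts directly. Clusters with fewer than `min_reads`
(default 10) total reads are dropped and their reads left unassigned; the
threshold is exposed because published cluster counts depend on it.

## Assembly

The built-in assembler is a greedy overlap-layout: repeatedly merge the
pair of contigs (either orientation) with the longest suffix–prefix
overlap ≥ `min_overlap` (default 40) whose edit fraction is ≤
`max_mismatch_frac` (default 2 %), absorbing contained contigs, until no
merge applies. Candidates are discovered by seed k-mers (k = min(16,
min_overlap)) taken near each contig's 5′ end in both orientations and
looked up in a global k-mer index over both orientations of every live
contig; each candidate is verified by banded semi-global alignment, so
indels inside overlaps are handled. Junctions whose seed k-mer was hit by a
sequencing error can be missed (≲ 1 % at HiFi rates). Determinism: reads
are ranked canonically (length, then sequence) before assembly; the merge
order is a total order on (overlap length, resulting length, contig ranks);
mismatched overlap columns take the predecessor's base; final contigs are
reported strand-canonically (min of sequence and reverse complement) and
sorted by length. Contigs shorter than `min_contig` (default 500) are
filtered; size-class counts (">2 kb", ">10 kb") use strict inequality.

DA pools every extracted insert; BCA assembles each barcode cluster
independently; SAGb additionally groups each cluster's contigs into one
genome bin (trivial within-cluster grouping; cross-cluster bin merging is
out of scope). External assemblers substitute per unit via a
`{reads} {outdir}` command template.

The mixed-strain strategy demo (three strains of a 12 kb ancestor at ~1 %
pairwise divergence, 64 droplets at ~4× each) is sized so a desk-scale run
exhibits the mechanism of interest: strain divergence sits below the
assembler's mismatch tolerance, so pooled assembly collapses the strains
into a single consensus mosaic, while per-droplet assembly reconstructs
each strain separately. At this scale both routes reach the full genome
length, so the comparison is directional (barcode-aware max length ≥ DA,
many more ≥ 2 kb contigs); published fold-changes are dataset-dependent
and not asserted.

## Evaluation

Reads and contigs are compared to references by canonical k-mer
containment (k = 21, odd, canonical = min of k-mer and reverse
complement): a read is assigned to the reference containing the largest
fraction of its k-mers if that fraction is ≥ 0.5; ties are unassigned.
This replaces alignment so evaluation is exact and dependency-free on
synthetic data. Purity is the majority-reference share of assigned reads;
external contamination is 1 − purity; the high-purity (> 95 %) and
low-contamination (< 1 %) flags use strict inequalities. Completeness is
the fraction of the majority reference's canonical k-mers covered by the
SAG's sequences; on error-containing reads it carries a small downward
bias of order `k × error-rate` per singly covered k-mer (~1 % at default
rates), which is why parameter-recovery tests compare the population mean
against interval-union ground truth.

Quality tiers: complete (= 100 %), high (> 90 %), medium (50–90 % with
quality score `completeness − 5 × contamination` on the percent scale
≥ 10 — the MIMAG-style convention), draft (10–50 %), else low. Band edges
are lower-inclusive; the medium band closes at exactly 90 % because the
high tier starts strictly above it, keeping the function total. A
50–90 %-complete SAG failing the score requirement falls to low, not
draft, since it is outside the draft band.

## Pipeline

Stages communicate exclusively through files (FASTQ/FASTA/TSV/JSON) under
the run directory so external tools can replace any stage; the report
aggregates per-stage summaries and the strategy fold-change table; reruns
with identical config and seed are byte-identical. Problem sizes in tests
and the acceptance script (300 droplets for demultiplexing/evaluation,
64 deep droplets for the strategy comparison, 10 kb / 10× for assembler
sanity) are desk-scale choices that keep the full suite in minutes while
preserving each phenomenon being measured.

## Known limitations

* The assembler is a testable stand-in, not a production assembler: no
  consensus polishing, no repeat resolution, no scaffolding or circularity
  detection; seed-miss can drop a small fraction of noisy junctions.
* k-mer containment assignment has no mapping-quality model and ignores
  positional information; highly similar references (> ~95 % identity over
  read length) can leave reads tie-unassigned.
* Doublet droplets are simulated but not detected; probabilistic
  demultiplexing and UMI handling are out of scope.
* The simulator's ambient model covers barcode-correct/insert-foreign reads
  only; index hopping and chimeric MDA reads are not modeled.
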