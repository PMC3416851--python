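# Methods

## Model

A sequence tag set is a code over the alphabet {A, C, G, T} evaluated under
one of three metrics:

* **edit** — global unit-cost Levenshtein distance (insertions, deletions,
  substitutions each cost 1), computed by the standard two-row dynamic
  program. This is the design metric: it captures every error class that
  synthesis (n−1 congeners), replication (non-proofreading polymerases), and
  sequencing (indel-prone platforms) introduce.
* **hamming** — positionwise mismatches of equal-length strings; blind to
  indels, retained for auditing published Hamming sets.
* **binary_hamming** — Hamming distance between two-bit encodings of the
  sequences. The default mapping is T=00, G=01, C=10, A=11; any systematic
  bijection may be supplied. Under *every* such bijection exactly 2 of the 6
  unordered base substitutions flip both bits (the pairs mapped across the
  00/11 and 01/10 diagonals), so a single-bit-correcting code leaves 2/6 ≈
  33 % of single-nucleotide substitutions detectable but uncorrectable —
  the quantitative argument against binary-encoded Hamming barcodes.

A code with minimum distance *d* detects *d* − 1 and corrects
⌊(*d* − 1)/2⌋ errors. The assigner uses exactly that radius: exact match
first, otherwise the unique tag within ⌊(*d* − 1)/2⌋ edits, otherwise
unassigned. For a validated distance-*d* set the triangle inequality
guarantees that every corruption of a tag by at most the radius demultiplexes
back to it; the test suite verifies this exhaustively for small *d* = 3 and
*d* = 5 sets over all mixed substitution/indel corruptions.

## Design pipeline

1. **Enumerate** all 4ⁿ candidates of length *n* in lexicographic order with
   A < C < G < T.
2. **Filter** (defaults, all overridable): no single-base run longer than 2;
   GC content within [40 %, 60 %] *inclusive*; no perfect self-complements.
   Inclusive GC bounds are a deliberate choice: odd/short lengths quantize GC
   in steps that land exactly on 40 % and 60 % (e.g. 2 or 3 GC bases in a
   5-mer), and excluding the boundary would empty the 5-mer pool entirely.
3. **Summarize**: for each surviving candidate taken as a key, a summary
   vector counts candidates at each edit distance (index = distance). Only
   these histograms are kept — never an all-pairs matrix, whose storage grows
   quadratically (a 10-mer pool of ~10⁶ candidates would need ~550 billion
   pairwise entries).
4. **Reduce**: keep only keys with the maximum count at the target distance
   *d*. This prunes the expensive stage to a handful of seeds.
5. **Build**: for each surviving key, drop candidates closer than *d* to the
   key, then scan the remainder in lexicographic order, retaining a candidate
   iff it is ≥ *d* from every previously retained tag (greedy lexicode). The
   largest set wins; ties go to the lexicographically smallest key.

Every designed set is validator-clean at *d*, conserves the filters
member-by-member, and is maximal: no filtered candidate outside the set is
≥ *d* from all members (greedy retention guarantees this; the tests confirm
it by brute-force addition for n ≤ 6).

The **subset shortcut** (`extract_subset`) reuses the designed set's members
as both keys and candidates to pull a subset at a higher distance *d′* ≥ *d*.
It is fast but deliberately not optimal: rerunning the full design at *d′*
can return more tags.

### Order sensitivity

A greedy lexicode's output — content *and* size — depends on the candidate
iteration order, which is not part of the method's definition. This package
commits to lexicographic A < C < G < T everywhere, making every result
deterministic and reproducible bit-for-bit regardless of batch sizes or
worker counts (batches are mapped and reassembled in order; the
parallel-equals-serial property is under test). Published counts from other
implementations of the same scheme (e.g. 25/61/211 tags at lengths 5/6/7,
distance 3) were produced under an unstated ordering; this package's
convention yields 28/64/217 for the same parameters — different, equally
valid, maximal sets. The tests compare against the published counts and
report the difference as a warning rather than asserting equality, because
the discrepancy reflects ordering, not correctness: each output set passes
validation with zero violations and admits no further member.

### Performance choices

Distances inside the pipeline are computed by the same dynamic program as the
scalar API, vectorized across the candidate axis with numpy (`_batch.py`);
agreement between the scalar and vectorized paths is under test. Batch sizes
(25,000 candidates for filtering, 500 keys per scoring batch) are throughput
knobs only. Desk-scale runs: length 6 ≈ 1 s, length 7 ≈ 30 s; the test suite
and acceptance script use lengths ≤ 7. Lengths 8–10 use the identical code
path and only more time; the enumeration cap is length 12.

## Tag integration

Primer tagging builds `pigtail + tag + primer[k:]` where *k* (with trimming
enabled) is the length of the longest suffix of the tag equal to a prefix of
the primer, collapsed once. Removing the overlap from the primer side (rather
than the tag side) keeps the full tag sequence intact in the synthesized
oligo, so demultiplexing still sees complete tags; the trimmed and untrimmed
oligos differ by exactly *k* edits (tested). A tag whose overlap swallows the
whole primer is an error. The default pigtail `GTTT` promotes non-templated
+A addition for T/A ligation and is prepended verbatim, with no special case
when the tag begins with G or T.

The structure screen is a **string-complementarity heuristic**, not a
thermodynamic model: the hairpin score is the longest substring whose reverse
complement occurs downstream separated by at least `min_loop` (default 3)
bases; the self-dimer score is the longest substring whose reverse complement
occurs at a different position; flags are raised at `min_stem` (default 4).
Defaults are conventional minima for a stable fold-back stem and loop. The
screen ranks and flags candidates; a thermodynamic evaluator can be plugged
into `tag_all_primers` via the `screen` callable for synthesis-grade
decisions. Adapter tagging records the tag's 0-based half-open slice so the
embedded tags can be re-extracted and re-validated; slice validation of
tagged adapters reproduces the bare tags' distance report exactly (tested).

## Error model

Errors are uniform and independent per base with rate *p*, so the error count
in a length-*L* tag is Binomial(*L*, *p*) and the expected number of reads
with ≥ *k* tag errors among *N* reads is *N* · P(X ≥ *k*) (scipy's binomial
survival function). The Monte-Carlo twin draws per-read error counts with a
seeded generator; at *N* = 10⁶ it must sit within 3 binomial standard
deviations of the closed form (tested). The default threshold is *k* = 1
(reads with at least one tag error): at *p* = 1 %, *L* = 8, *N* = 10⁶ this
gives 77,255 reads ≈ 8 %. The stricter "more than one error" reading is
available as `min_errors=2` and is an order of magnitude smaller; both
readings are exposed rather than silently choosing one. The error mix
(substitution/insertion/deletion proportions, default pure substitution)
affects generated corruptions but not event counts.

The model deliberately omits position-dependent error profiles along reads
and platform-specific error spectra: it quantifies scale, not platform
detail. Likewise the package contains no read-level FASTQ demultiplexer — the
assigner is the minimal correct decision rule for a single observed tag.

## What the synthetic inputs do and do not show

All test inputs are generated: candidate spaces are enumerated, corrupted
observations are exhaustive edit neighborhoods or seeded draws, and primers/
adapters are short synthetic sequences. Passing tests therefore demonstrate
the combinatorial guarantees (distances, maximality, round-trip correction,
format round-trips) — they do not demonstrate wet-lab performance of any
particular oligo, which depends on thermodynamics, synthesis purity, and
platform chemistry outside this model.

## Known limitations

* Greedy construction is not provably maximum; evolutionary search can find
  larger codes at the cost of determinism.
* The boundary between tag and insert is not modelled: edit distance is
  computed on the bare tag, not on tag-plus-context (no sequence-boundary
  correction).
* The structure screen knows string complementarity only — no melting
  temperatures, dangling ends, or salt corrections.
* Validation is all-pairs O(N²·L²) in pure Python for mixed-length sets;
  large published sets (~10³ tags) take seconds, not milliseconds.
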