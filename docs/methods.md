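# Methods

## Counting model

Each template molecule is tagged by a barcode of `r` random bases drawn
independently from a per-position base composition (uniform by default),
interleaved with designed fixed bases. After amplification and sequencing,
every read is an imperfect copy of `barcode + target`. The estimand is the
number of molecules per (template, sample index) before amplification; the
estimator is the number of barcode clusters after error removal.

Two conditions must hold for the estimator to be unbiased, and both are
checked empirically rather than assumed:

* **Variety**: the barcode space `4^r` must dwarf the molecule count `N`, so
  that distinct molecules receive distinct (and, under clustering, well
  separated) barcodes. The expected number of distinct barcodes among `N`
  uniform draws is `K(1 − (1 − 1/K)^N)` with `K = 4^r`; at `r = 24`
  (`K ≈ 2.8 × 10^14`) and `N = 20,000` the expected collision count is ≪ 1.
* **Depth**: every molecule must be read at least once. Under uniform read
  allocation the expected number of detected molecules at `R` reads is
  `N(1 − (1 − 1/N)^R)` (coupon collector), which the coverage-saturation
  curve approaches from below.

Both conditions appear as plateaus: in cluster count versus retained random
bases, and versus subsampled read fraction. Certification means observing
the plateau, not trusting the closed forms — the closed forms serve as
oracles in the test suite.

## Clustering

Bounded single-linkage: two barcodes are related if they differ at no more
than *Distance* of the compared positions; clusters are the connected
components of this relation (transitive closure, order-independent).
Compared positions default to the design's random positions; fixed
positions are excluded because mismatches there are handled by filtering.
When templates of different designs are merged for resolution, comparison
uses the first `k` random bases of each design (`k = 20` by default for
mixed designs) so keys remain comparable.

Implementation: distinct barcode strings are deduplicated (multiplicity is
reattached afterwards), then candidate pairs are generated by pigeonhole
partitioning — the compared positions are split into *Distance* + 1
near-equal contiguous segments, and any pair within the bound must agree
exactly on at least one segment. Candidates are verified with an explicit
mismatch count, so the output is exactly the single-linkage partition; an
O(n²) all-pairs union-find oracle is kept in the package and the test suite
asserts partition equality on instances up to 500 barcodes for
*Distance* 0–3. Cluster ids are the lexicographically smallest member key,
making reports reproducible. The worst case is quadratic (e.g. all keys
identical in a segment), which does not arise at realistic error rates.

## Filtering and resolution rules

Filter order: length window → target mapping → N-in-barcode removal →
fixed-base filter. Reads are never trimmed; each stage keeps or flags.
Quality scores are carried but unused (no quality threshold is part of the
procedure). The default fixed-base selection is positions 16, 21, 24 and
28 of the barcode — fixed in both built-in designs, so one selection serves
all templates; `furthest:k` selects the `k` fixed bases furthest from the
sequencing primer site (largest positions).

Resolution operates on clusters built over merged categories:

* **Index contamination** (indices merged per template): a cluster is
  counted for the index holding the majority of its reads; an exact tie
  gives each of the `m` tied indices `1/m` (0.5 for two).
* **Misidentification** (all templates and indices merged, multi-mapped
  reads retained): a read mapped to `k` templates contributes weight `1/k`
  to each; the cluster goes to the (template, index) category with the
  largest weighted tally, ties split `1/m`. The two-way rule generalizes
  to `1/m` for `m`-way ties.

Majorities are computed on (weighted) read counts, not on distinct
barcodes. Every mode conserves the total: summed counts equal the number
of clusters.

## Target mapping

The native mapper compares the designed target region (8 bases for short,
50 for long templates) against every reference by ungapped fixed-position
mismatch counting; read positions missing due to truncation or upstream
indels count as mismatches. Defaults: ≤ 1 mismatch for targets up to
10 nt, ≤ 5 otherwise. This is deliberate: with a panel of eleven short
references at known coordinates, full alignment adds nothing, and reads
whose target is frame-shifted by a barcode indel are cleanly rejected
(a shifted random-sequence window matches at ~25% per base). Gapped
aligners are supported through SAM import instead; primary plus secondary
alignments of a read form its template set.

## Simulator

The generator emulates the measurement system under the study conditions:

* Copy panel (per sample index): LT1–LT6 at 40,000 / 40,000 / 4,000 / 300 /
  100 / 20 copies; ST1–ST5 at 20,000 / 20,000 / 4,000 / 4,000 / 4,000.
* Per-base substitution rate 0.25% (midpoint of the measured 0.23–0.29%
  window), substitutions uniform over the three alternative bases.
* Total indel rate 0.1% per base, split evenly between insertions and
  deletions; indels shift the remainder of the read without re-padding.
* N-call rate 0.0002 per base (a typical MiSeq N fraction; no published
  value exists for this system).
* Per-molecule read count: negative binomial with mean 15 (inside the
  observed 12.6–20.9 coverage window) and dispersion 8; dispersion `None`
  gives Poisson. `min_reads = 1` clamps the draw to guarantee detection
  where an analysis requires it; the truncation slightly raises realized
  mean coverage and is the stated condition for exact low-copy recovery.
* Index swapping at rate 0.001 per read between the two sample indices
  (covering primer contamination, index sequence errors and index
  hopping collectively; the mechanism is not modelled).

All draws flow from one `numpy` generator seeded by the config, making the
output byte-for-byte reproducible. Every injected event is logged, and the
suite asserts that replaying the log on the true sequence reproduces each
emitted read exactly.

What the simulator does **not** model: amplification-cycle structure (an
error in an early PCR cycle would be shared by many reads; errors here are
i.i.d. per read), polymerase bias, quality-score structure, adapter
read-through, and Read2. Consequently, passing tests demonstrate that the
analysis correctly inverts this error model at the stated rates — not that
it corrects error modes absent from the model (clonal PCR errors in
particular would merge into clusters by design, but are not simulated by
default).

## Saturation analyses

Subsampling is exact-count without replacement (`round(f · N)` reads,
seeded), not Bernoulli, so coverage levels are reproducible across
repeats; the default fraction grid is 100, 32, 10, 3.2, 1, 0.32 and 0.1
percent, with 8 repeats seeded as `seed + repeat index` (single evaluation
and SD 0 at 100%). Barcode truncation keeps the `k` random positions
closest to the 5′ end; which positions the original analysis kept is not
documented, so the choice is exposed as an option. Coverage is reported as
reads entering clustering divided by the resolved cluster count. Relative
curves are normalized to the count at the largest swept value;
`required_random_bases` scans for the smallest grid `k` with relative
count ≥ 0.95 and reports "not reached" when the grid never qualifies.

## Error estimators

The consensus barcode of a cluster is the per-position majority with ties
broken to the lexicographically smallest base. The substitution rate is
the fraction of mismatching bases between members and their cluster
consensus over random positions, excluding singleton clusters (which carry
no mismatch evidence). Fixed-base mismatch rates are computed per position
on reads *before* fixed-base filtering; under pure substitution noise at
rate `e` every fixed position mismatches at rate `e`, while indels make
the rate grow with distance from the primer site — the signature used to
justify the fixed-base filter. Base composition is estimated from one
consensus vote per cluster, so read-count bias per molecule cancels.

## Default parameters

| parameter | default | rationale |
| --- | --- | --- |
| *Distance* | 2 | cluster counts are near-constant from Distance 2 on |
| fixed bases | 16, 21, 24, 28 | counts near-constant from four fixed bases |
| random bases (mixed designs) | 20 | largest common k that plateaus for the panel |
| subsample repeats | 8 | matches the reported mean ± SD convention |
| max index mismatch | 0 | demultiplexing made explicit and exact |
| native mapper mismatches | 1 (short) / 5 (long) | scale with target width |

## Problem sizes used in the checks

The bundled acceptance analyses run the high-copy condition at 20,000
molecules per index over 3 seeds and the low-copy condition at 20
molecules per index over 5 seeds; property tests use 300–2,000 molecules.
These sizes put the binomial sampling error of every asserted quantity
well inside its tolerance while keeping the suite quick to run.

## Known limitations

* The fixed-base letters and exact layouts of the original designs are not
  public; the built-ins are editable stand-ins that preserve the counts,
  spacing, and the shared 16/21/24/28 filtering positions. The bundled
  reference panel's target sequences are likewise synthetic stand-ins.
* Indels in the random region downstream of the last selected fixed base
  are invisible to the filter; they are caught instead by target mapping
  (frame shift) or absorbed by clustering when few key positions change.
* Directional/network UMI collapsing (à la UMI-tools) and edit-distance
  clustering are out of scope: indels are handled by fixed-base filtering,
  not by alignment of barcodes.
* The extrapolated dynamic range (~10^15 molecules) is a linear
  extrapolation in the source analysis and is not certified by this
  package.
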