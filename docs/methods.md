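# Methods

## The measurement

A transposable (Mu-like) phage packages its linear genome together with
host DNA flanking the insertion site: 31–36 bp on the left and a few
hundred bp up to ~2.5 kb on the right. Sequencing virion DNA therefore
samples phage–host junctions, and the host-side coordinate of each
junction is one replicative transposition site. Two read types feed the
pipeline:

* **whole-virion reads** that span the phage left end (host prefix, then
  the terminal `TGT…`), extracted by exact seeding on the terminal 20-mer
  and extension, requiring ≥ 12 bp of host and ≥ 20 bp of phage overlap;
* **enrichment reads** produced by digesting virion DNA with an enzyme
  that cuts the phage genome twice — once 181 bp before the right end —
  and size-selecting the right-end fragment. The valid-read filter keeps
  only reads whose first 181 bases equal the terminal phage fragment
  exactly (either orientation) with ≥ 12 bp of host beyond it. A
  configurable mismatch allowance exists (default 0) because tolerated
  sequencing error is not specified by the strict "starting precisely"
  rule.

**Junction-base convention.** The recorded site is the first host base
adjacent to the phage end, for both ends and both strands. Whether the
annotated "start" is the first host base or the last phage base is an
open representational choice; first-host-base is adopted and used
consistently by the mapper (`junction_side="start"` for right-end
fragments, `"end"` for left-end fragments).

**Orientation.** "forward" means the phage plus strand is co-oriented
with the host reference plus strand. Reverse-orientation events report
their junction coordinate shifted by the target-site duplication offset
(default 5 bp), which reproduces the paired forward/reverse peak geometry
of real single-site hotspots. The duplication length of this phage group
is not established; 5 bp is an inference from the observed peak pairing
and remains a parameter.

**Deduplication.** Left-end junctions are counted one event per read;
how overlapping reads of the same molecule should be collapsed is not
specified upstream, and the simulated libraries carry no PCR duplicates,
so no further deduplication is applied.

## Fragment placement

Fragments as short as 12 bp (left-flank route minimum) up to ~70 bp
(right-flank route at 250 bp reads) are placed on the reference by exact
k-mer seeding (k = 15, sorted-integer index over the plus strand,
wrap-around k-mers included for circular references) and extension.
Acceptance thresholds mirror a conservative short-read mapper
configuration: mismatches ≤ floor(0.02·L), gap bases ≤ floor(0.03·L),
identity ≥ 0.95. Flooring per fragment means a 34 bp flank tolerates zero
mismatches — deliberately strict for short flanks, configurable.
Candidates failing the ungapped check are re-evaluated with a banded
edit-distance alignment (edlib) whose extended cigar is split into
mismatch and gap counts. A fragment is *unique* iff exactly one
best-scoring locus passes (co-optimal gapped loci within the gap budget
of one another are collapsed); *ambiguous* fragments are counted but
excluded from the site table — the upstream convention for multi-mappers
is unstated, and exclusion is the conservative choice for per-position
statistics.

## Coincidence model

For T events uniform on N positions with R = T/N, the expected number of
positions with two coincident events is E₂ = T·R/2 and
E_{i+1} = ln(1/(1−R))·E_i/(i+1). E_i is interpreted as the expected count
of positions with *at least* i events (the balls-in-bins tail); the
observed spectrum reports both exactly-i and at-least-i counts so either
comparison can be made. The approximation is accurate for R < 0.1 and is
only warned about, not refused, beyond that: at R = 0.1 it overshoots the
exact multinomial expectation by ~7%, which the test suite checks
explicitly against the exact closed form. Interval enrichment is
summarised as fold = (events/T) / (length/N); printed fold figures in the
literature for such intervals are not exactly reproducible from the
stated counts, so the ratio definition here is the documented one and no
printed fold value is asserted.

## Hotspots and the adjacent consensus

Positions with ≥ 3000 events (the threshold appropriate to a 13-million
event experiment; `scaled_threshold` keeps the per-event fraction when an
experiment is smaller) are merged within 20 bp into hotspots carrying one
or two peak coordinates. The consensus of the repeat element adjacent to
the hotspots is built from the 280 bp flanks of the called hotspots by a
gapless shared-block procedure: an 8-mer shared by the most flanks
anchors a column-wise extension; a column is conserved iff the bases at
frequency ≥ 0.25 number at most two *and* cover ≥ 90% of the rows (random
columns spread their mass over 3–4 bases and stop the extension). Each
column is emitted as the IUPAC code of its ≥ 25% bases — seven C and
seven T give `Y`. A multiple aligner would do the same job; the gapless
procedure is sufficient because the element aligns without gaps over its
~35 bp core, and it keeps the package dependency-light and deterministic.
The genome scan counts a window as matching when at most `max_mismatches`
(default 3) positions hold a genome base outside the motif code's set;
both strands are scanned and opposite-strand hits overlapping by more
than half the motif (palindromic self-hits) are deduplicated to the
fewer-mismatch hit. Indel-tolerant matching is not implemented: the
reference count this scanner mirrors is described as mismatch-only, and
an edit-distance mode would change the occurrence count in unspecified
ways.

## Coldspots

Event density (events/kb) and GC fraction are computed in 1 kb windows
every 200 bp (both configurable; the reference analysis states region
sizes but not its windowing). Runs of windows below 10 events/kb are
converted to bp spans and *merged when the spans overlap or touch*: a
genuinely cold region at ~6 events/kb still shows occasional single
windows at ≥ 10 by Poisson noise, and window overlap (step < window)
makes the interrupted spans overlap, so merging reconstitutes the region.
A merged region is reported when ≥ 1 kb long and its exact aggregate
density (recomputed per base, not from overlapping windows) stays below
the cutoff. Intermediate regions at ~30 events/kb are never called —
P(window < 10 | λ = 30) ≈ 2·10⁻⁵ — reproducing the separation between
low-GC coldspots and merely cooler rRNA-operon-like regions.

## Self-insertion topology

Events escaping target immunity (probability ε, default 0.004) land in an
already-inserted phage copy. Their per-50-bp profile is segmented at
sharp boundary peaks: a bin exceeding q = 5 times the centred 41-bin
running median, greedily selected with ≥ 10 bins mutual separation. k
peaks delimit k+1 domains (each boundary bin opens the following domain,
so domains tile the genome exactly); the nine-domain layout therefore has
eight boundaries. Exclusion zones (± 1 kb around each restriction site,
whose enrichment creates symmetric artifact peaks) are masked before peak
calling and their events excluded from domain counts and reported
separately. Interior domains (terminals excluded — the genome ends are
held in the transposome) are paired symmetrically into loops, outermost
first, the central domain alone at the apex; per-loop shares are event
fractions. The protected gap search reports maximal zero-event runs of
≥ 30 bp within ± 1 kb of the genome middle; at ~1,300 events/kb the
chance of an empty 37 bp run is ~e⁻⁴⁸, so a recovered gap is a genuine
protected core, while an empty table returns the whole window flagged
uninformative.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not sequencing physics:

* **Sequences** are random with exact (rounded) GC composition per 100 bp
  block. Block-wise composition makes the 500 bp windowed GC track the
  requested island value; with iid bases a 46% island fluctuates ± 2.2%
  and crosses the 0.50 cold threshold in patches, which no real
  AT-rich island (coated as a whole by nucleoid proteins) does.
* **Site selection** multiplies a flat base weight by 0.005 where the
  windowed GC is below 0.50 (puts islands in the < 10 events/kb regime at
  realistic depth) and by 300 within 120 bp of a planted motif (the order
  of the observed insertion bias next to the repeat elements). The boost
  window is broader than a real single-position hotspot peak, so
  flank-consensus recovery at the exact 54–60 bp offsets is exercised on
  constructed flank sets, while the planted-recovery tests assert hotspot
  positions.
* **Virion molecules** carry the phage left-to-right in phage orientation
  with flanks written in virion orientation; left flanks are drawn
  uniformly on 31–36 bp, right flanks uniformly on 170–2,500 bp (the
  size-selection shape is not modelled further). Whole-virion mode always
  emits the two molecule-end reads (ends are overrepresented in sheared
  libraries of linear molecules) plus uniform interior reads;
  enriched-right mode emits reads starting exactly at the cut before the
  terminal fragment, half of them reverse-complemented.
* **Self-insertions** follow a per-base domain profile; the bundled
  study-like profile has nine domains with relative densities
  300/330/800/800/1332/620/709/1049/300 events/kb (terminal-domain values
  are not reported anywhere and are set to a plausible low 300), sharp
  single-peak boundaries, and a 37 bp zero-density gap 150 bp (rescaled)
  right of the middle.
* No sequencing-error, PCR-duplicate or quality model is included: the
  analyses operate on high-identity mappings, and the mapper's error
  tolerance is exercised directly with mutated fragments.

What passing tests show, therefore, is that the pipeline recovers
planted structure from data with the right event statistics — not that it
is robust to base-calling error, chimera rates beyond the modelled PCR
joins, or reference/sample divergence.

## Problem sizes and determinism

Tests and the recovery checks run at reduced scale chosen so each check
retains its statistical meaning: 10⁵ events on a 100 kb host for hotspot
and coldspot recovery (the per-position hotspot threshold auto-scales to
23), 5·10⁴ self-insertions on a 10 kb phage for domain/loop/gap recovery
(the boundary-and-density parameter-recovery check passes at ± 2 bins and
10%), 10⁶ events for immunity-leak recovery (3 binomial SE), and a 6 Mb
genome for the short-fragment uniqueness floor. Every random draw takes
an explicit integer seed; there is no global RNG state, and rerunning any
stage with the same seed is byte-identical in all text outputs.

## Known limitations

* Not a general-purpose read mapper: no paired-end awareness, no base
  qualities, no adapter handling.
* The consensus builder assumes the conserved element aligns without
  gaps; an element with internal indels across hotspot copies would
  truncate the block rather than gap it.
* The coincidence model is an approximation valid for R < 0.1; beyond
  that the code warns and the exact multinomial expectation should be
  used instead.
* Left-end junction counting is per read; molecule-level deduplication
  would require fragment-boundary information the simulator does not
  model.
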