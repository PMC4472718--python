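# Methods

This note documents the models, defaults and design choices behind
`oligoplex`, in the order a user meets them: oligo thermodynamics, in-silico
PCR, APC construct design, panel compatibility, standard-curve analytics,
and the synthetic fixtures the test suite runs on.

## Oligo thermodynamics

**Melting temperature.** `nn_tm` uses the unified nearest-neighbor ΔH/ΔS
parameter set with the Owczarzy salt correction, delegating the arithmetic
to Biopython's `Tm_NN`. Self-complementary (palindromic) oligos are
detected automatically and receive the duplex symmetry correction. Defaults
are molar concentrations typical of a PCR-design run: 50 nM oligo, 50 mM
monovalent cation, 1.5 mM Mg²⁺, 0.6 mM total dNTP. The divalent terms
matter: against the shipped panel's tabulated reference Tm values
(computed by a standard primer-design program), these defaults agree to a
mean of −0.9 °C, whereas a monovalent-only model sits ~6 °C low. The
package treats reference Tm columns as metadata to compare against, not as
values it promises to reproduce exactly — the reference program's version
and settings are not part of the shipped data.

**Dimer scores.** `self_any_score`, `self_end3_score` and
`cross_dimer_score` count whole Watson–Crick base pairs over every ungapped
antiparallel alignment (indexing pairs by `i + j = const`); the 3' variant
restricts to alignments in which the 3'-terminal base of one copy lies
inside the duplex overlap, which makes `self_end3 ≤ self_any` definitional.
G:T wobbles never count. This transparent integer convention is *not* the
weighted alignment score produced by common design programs, whose weights
are version-dependent; the package therefore verifies these scores against
its own brute-force enumeration, and ships the program-reported values as
metadata only.

**Hairpins.** `hairpin_dg` enumerates every single stem-loop: a stem of
p ≥ 2 contiguous pairs closing a loop of ≥ 3 unpaired bases, scored as the
sum of nearest-neighbor stacking ΔG₃₇ terms plus a tabulated loop-closure
penalty (Jacobson–Stockmayer extrapolated beyond 30 nt). No bulges,
internal loops, multibranch structures or dangling ends — it is a screening
surrogate for full secondary-structure folding and its numbers are not
comparable to a folding program's output. A fold is reported only when the
optimum is negative; a weak stem whose best energy is ≥ 0 is "no stable
fold" (absent), which keeps the reported value's sign meaningful.

## In-silico PCR

Coordinates are 1-based inclusive on the plus strand. A binding site needs
≤ `max_mismatch` mismatches overall and zero inside the 3'-terminal
`clamp3` bases (defaults 0 and 3: specificity claims are exact-match;
mismatch tolerance exists for decoy exploration). An amplicon runs from the
forward primer's first base to the reverse primer's last base inclusive.
Probes never act as extension primers. Circular templates are searched on
the doubled sequence with starts restricted to the first copy, which finds
wrap-around products exactly once. Multiple productive pairings are all
reported; callers decide what to do with them. `locate_probe` demands an
exact interior match and, by default, no overlap with either primer
footprint; two interior sites are an ambiguity error rather than a silent
choice. The virtual gel sorts sizes descending and flags adjacent bands
closer than `min_separation` (default 20 bp, comfortably below the 41 bp
smallest designed gap in the shipped panel and coarse enough for 2% agarose
resolution).

## APC construct design

Each target's block orders elements on the plus strand: outer forward,
inner forward, probe, inner reverse (reverse-complemented), outer reverse
(reverse-complemented), with ≥ 2 nt spacers between functional elements and
≥ 10 nt between blocks. Spacer lengths are solved exactly from the
requested product sizes; shared primers (one reverse serving both readouts,
or one pair serving both) collapse the layout accordingly. Probes are
embedded in the plus strand as written, so the probe hybridizes to the
minus strand of the amplicon — a configuration flag is deliberately absent
because either orientation detects; plus-strand embedding keeps the feature
table readable.

**Overlapping primer pairs.** When one primer's exact site is contained in
another element of the same assay (the shipped panel's *L. bostrychophila*
inner reverse contains the outer forward — the pairs overlap in the source
gene), strict nesting would plant a second annealing site inside the outer
amplicon and create a spurious short product. Such assays are laid out as
two side-by-side sub-blocks instead; sizes stay exact and the contained
site ends up downstream of its reverse partner, where it cannot prime a
product.

**Cross-target products.** On any linear construct every upstream forward
primer converges with every downstream reverse primer of other targets, so
"no cross-target product at all" is geometrically impossible — and
harmless: the control is used as a template for *matched* primer sets, and
deliberate cross-set products are a documented feature of such constructs.
What would be harmful is a cross-target product a gel cannot tell from a
designed one. The planner therefore computes all convergent cross-target
pairings from the planned coordinates (scanning element sequences, so
contained sites are seen) and pads inter-block spacers until every such
product differs from every designed size by at least `min_size_gap`
(default 20 bp); verification re-derives the same property from the
realized sequence. Size equality between an assay's APC product and its
genomic product is allowed — the barcodes guarantee sequence
identifiability — but reported as an informational flag.

**Spacers and barcodes.** Spacers are GC-balanced (40–60%) random DNA,
rejected if either strand contains any panel oligo's 3'-terminal 8-mer or
any 12 nt run from any panel oligo (both screens conservative defaults,
configurable). Each block's largest spacer carries an 8 nt barcode, pairwise
Hamming distance ≥ 4, making every amplicon's internal sequence unique.
Synthesis is driven by one `numpy` generator seeded by the caller:
identical inputs and seed give a byte-identical construct. If a junction
accident (spacer–element boundary recreating a site) breaks verification,
the driver resynthesizes with a derived sub-seed; size planning is
deterministic and unaffected.

**Verification** re-runs in-silico PCR on the assembled sequence: exactly
one amplicon per pair at the designed size, probes strictly between
primers, exactly one designed site per oligo (extra sites tolerated only
inside another oligo's footprint, as with overlapping pairs), cross-target
products non-confusable, internal sequences pairwise distinct.

## Panel compatibility

Channel assignment maps each reporter dye to the acquisition channel with
the nearest detection band, requires injectivity, and rejects dye pairs
closer than `min_gap_nm` in emission (default 25 nm, below the 34 nm
smallest gap in the shipped dye set). The default five-channel optics
(green 470/510 through crimson 680/712 nm) are instrument constants shipped
as editable values. Dimer flags consider only oligos that share a reaction
tube (endpoint multiplex vs qPCR multiplex — overlapping primers from
different readouts never meet) and trigger at ¾ of the shorter oligo's
length paired, the point where a stable duplex becomes plausible for the
pair-count metric. Primer Tm is checked against a ±3 °C window around the
shared 60 °C annealing temperature; with the package's Tm defaults one
shipped primer (PeaCo15F, 63.1 °C) sits just outside and is reported as a
finding — findings are report entries, never errors. Exclusivity runs the
full multiplex simulation over designated target templates and decoys and
passes only for a strictly diagonal outcome; the verdict is monotone in the
decoy set by construction (adding templates can only add failures).

## Standard curves

Fits are ordinary least squares of Ct on log₁₀(amount in ng), on replicate
means by default because published tables print means; a `per_replicate`
flag fits all individual Cts (same slope for balanced designs, lower R² —
one plausible source of small discrepancies between printed fits and
refits of rounded means). Efficiency is the fraction 10^(−1/slope) − 1.
Replicate SD is the n−1 sample estimate and is absent, not zero, for a
single replicate. NaN replicates mean "not detected"; the detection limit
is the smallest amount in the contiguous detected range under an
all-replicates (default) or any-replicate criterion. Refits of the shipped
dilution table reproduce the published fast-cycling kit's slopes and
efficiencies to ±0.01; the single-reaction master mix's slopes recompute
~0.01 steeper than printed from the rounded means, so those slopes are
treated as soft references while their efficiencies still agree at two
decimals.

## Synthetic fixtures

The fixture generator emulates the *structure* the assays exploit, not real
CO1 sequence: a planted template carries one target's priming sites nested
at the published genomic product sizes inside screened, GC-balanced random
background; decoys are the same template with 3'-terminal transversions at
primer sites (the near-neighbor situation: similar template, broken clamp);
out-group and host stand-ins are pure screened background. What passing
tests show is that the *method* — site search, orientation logic, size
arithmetic, clamp enforcement — behaves correctly; they cannot show that
the shipped oligos discriminate real near-neighbor genomes, which is an
empirical property of the sequences themselves. Simulated Ct series follow
Ct = intercept + slope·log₁₀(amount) + N(0, σ) with defaults slope −3.32,
σ 0.15, 3 replicates over 1 ng → 1 fg, mirroring the shipped table's
design; real qPCR noise is heteroscedastic near the detection limit, which
the simulator deliberately ignores.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at the scale the
shipped panel defines: 25 oligos, constructs ≈ 1.3 kb, fixture templates
≤ 1.5 kb, 500 fuzzed oracle instances, 200 simulated series — a few
seconds end to end. Brute-force oracles are re-implementations with their
own constants, kept independent of the library paths they check. Floating
comparisons use absolute tolerances stated per test; integer quantities
(scores, sizes, counts) are compared exactly.

## Known limitations

No degenerate (IUPAC) bases; no polymerase kinetics or amplification-curve
modeling (the tool consumes Ct values); hairpin model is single-stem; the
dimer metric is unweighted pair counting; vector context is reduced to
optional adapter strings; accession-based checks against deposited records
require network access and are out of the offline workflow.
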