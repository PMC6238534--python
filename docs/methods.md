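# Methods

## The measurement being modelled

Inverse toeprinting turns ribosome position into fragment length. A
transcript library is translated in vitro; a highly processive 3'→5'
exonuclease (RNase R) then degrades each mRNA until it reaches the leading
ribosome, leaving a fragment whose 3' end reports the ribosome's P-site
codon while preserving the *entire* upstream coding region. After ligation
of a 3' linker, reverse transcription and PCR, fragments are sequenced as
merged single-contig reads of the form

    flank5 (RBS region) + ATG…cleavage position + flank3 (linker)

Ribosomes that reached the designed terminal stop protect a restriction
site that is later cut, so only stalled complexes are amplified. The
quantity of interest is, per 3-aa motif X1X2(X3) (X2 in the P-site, X3 in
the A-site), how often ribosomes stall on it versus translate through it,
and how that changes when a drug (e.g. a macrolide) is added.

## Simulator

`invtoe.simulate` generates the whole experiment so every analysis stage
can be verified against ground truth without any external data.

**Library designs.**
* `nns15` — 15 degenerate NNS codons after the start codon (N uniform over
  ACGT, S uniform over G/C). NNS encodes all 20 amino acids and excludes
  TGA/TAA by construction, so UAG is the only stop that can appear in
  frame — which is precisely what makes stop-codon pausing usable as an
  offset-calibration signal.
* `mutant_library` — every nucleotide of a supplied wild-type region is
  substituted independently with probability `mutation_rate` (default
  0.07) to a uniformly chosen different base; the focused ErmBL-style
  design.
* `fixed` — the wild-type region verbatim.

Templates are assembled as `ATG + variable region + spacer + TGA TGA`.
The four-codon Gly-Ser-Gly-Ser spacer (`GGTAGCGGCTCT`) is a package
choice: the real construct has a fixed four-codon spacer whose sequence is
not among this package's inputs; any stop-free, motif-neutral spacer
serves the same role.

**Sequential stalling.** Each ribosome/template encounter is one walk.
With probability `initiation_fraction` the ribosome never leaves the start
codon (initiation-complex contaminants). Otherwise it steps through
P-site codons p = 2, 3, …, looks up the motif (aa[p−1], aa[p], aa[p+1])
and stalls with that motif's Bernoulli probability (`default_pause` when
unlisted). A-site stop codons are handled by type:

* UAG: stall with `stop_pause` (default 0.4 — chosen to give the mild
  stop-codon enrichment expected when release factor 1 competes with
  pausing); otherwise RF-1 releases the ribosome and the unprotected mRNA
  yields **no** read (`cause=release`).
* UGA/UAA at the designed terminal position: `cause=readthrough`, removed
  by the restriction-digest analogue.
* premature UGA/UAA (possible only in mutagenized libraries): hard stall —
  the translation system contains no RF-2, so nothing releases them.

For focused libraries a peptide-level rule (`variant_pause`, mapping a full
peptide to a (P-site codon, probability) pair) expresses arrest that
depends on nascent-chain context beyond the 3-aa window, e.g. a variant
whose stalling at codon 10 requires a particular residue at position 7.

**Cleavage geometry.** The protected 3' end lies `offset` nucleotides
downstream of the *last* nucleotide of the P-site codon (inclusive), i.e.
at `3·p + offset`; default 17. The documented convention matters: the
physical distance is known to within an anchor choice (first vs last
nucleotide of the P-site codon), and simulator and analysis share this
convention so offsets round-trip exactly. The observed three-nucleotide
peak is modelled as jitter over {offset, offset−1, offset−2} with default
weights (0.70, 0.20, 0.10) — a plausible dominant-phase-plus-shoulders
shape; the true weights are not independently known, so these are
placeholders that tests treat as the ground truth they recover.

**Rendering.** Each non-dropped event becomes one read: flanks
`GTATAAGGAGGAAAAAAT` / `GCGATCTCGGTGTGATG`, constant Phred quality
(default Q37), optional uniform substitution noise, optional fraction of
full-length readthrough contaminants. Events whose cleavage position
exceeds the template (very late stalls) are skipped and counted.
Replicates derive independent child seeds from one master seed
(`numpy.random.SeedSequence.spawn`), so a (config, seed) pair is
byte-reproducible.

## Read processing

Trimming anchors flank5 as a prefix and flank3 as a suffix, each tolerating
up to 2 substitutions (Hamming; the flanks are fixed-length, so no gaps are
modelled). Filters run in a fixed first-fail order so rejection reports
are deterministic: (1) ≥18 'A' within the first 22 nt (poly-A tail
carry-over), (2) missing ATG, (3) any base below Q30 inside the region of
interest, (4) fragment end outside the size window. Coordinates are
1-based with nt 1 = A of ATG. The default window 24–47 keeps the
tri-nucleotide-periodic range (P-site codons 3–10); the input library uses
a 1–48 quality window and no size selection; known-arrest samples use
24–77 with Q60; focused-library samples are variant-called over the full
ORF, so their window is applied to quality only. Permuting filters (1)–(3)
may change which reason a doubly-bad read is charged to, never the pass
set.

## P-site assignment and offset calibration

`assign_psite` inverts the cleavage rule with
`p = ceil((end_pos − offset)/3)`; the ceiling absorbs −1/−2 jitter so all
three jittered ends of one stall event collapse to the same codon (checked
exhaustively). `estimate_offset` calibrates the offset from the data
itself: for every in-frame UAG at codon q ≥ 3 (so the X1 residue exists),
`end_pos − 3(q−1)` is a candidate offset — exact for reads that paused
with that UAG in the A-site, and biased low for UAGs downstream of the
true A-site, which is why the mode (ties broken toward the larger value,
since jitter only shortens fragments) is the estimator. Simulations at
offsets 15–18 with default jitter are recovered exactly at 10⁴ reads.

## Motif statistics

For each read with p ≥ 2 and a complete A-site codon, the protected region
is translated through codon p+1 (A-site UAG → `'*'`); the terminal motif
increments nP and every interior motif increments nB at most once per read
(nB counts *reads* that translated through a motif; an occurrence-level
mode exists behind `bypass_mode="occurrence"` for sensitivity analysis).
`n_total` counts all processed reads, including p < 2 reads that
contribute no motif. `'*'`-A-site motifs are tallied but excluded from
the 8,000-member sense ranking — stop pausing is a calibration signal, not
a peptide motif.

* **Pause strength** PS = nP/(nP+nB): the fraction of observed encounters
  ending in a stall. PS = 1 means no bypass; PS = 0.2 means 80 % of
  ribosomes translated through. Note a conditioning effect inherent to the
  selection: bypasses are only observed when the ribosome later stalls
  inside the size window, so with weak downstream pausing PS is biased
  upward. It remains monotone in the true stall probability (enrichment
  and PS rank-correlate at ρ > 0.95 in simulation), and is unbiased when a
  guaranteed downstream staller makes every bypass observable — the
  configuration the estimator tests use.
* **Counting noise.** Replicate scatter is compared with pure binomial
  partitioning: motifs' two-replicate totals are split with success
  probability proportional to replicate sizes, and the SD of the
  replicate-1 fraction is computed per total-count bin. The SD of a
  150-read total split evenly is 0.5/√150 ≈ 0.041, just under the 0.05
  bound that motivates the 150-count "well-measured" threshold.
* **Enrichment.** Per motif, replicate frequencies are averaged;
  FC = F_fg/F_bg with the inter-replicate difference propagated as
  dFC = sqrt((dF_bg/F_bg)² + (dF_fg/F_fg)²)·FC. Motifs absent from the
  background are flagged undefined rather than pseudo-counted (a
  configurable pseudo-count exists, default off). `well_measured`
  requires > 150 stall counts combined across the compared samples.
* **Classification.** Among well-measured motifs: *intrinsic* if the
  drug-free PS ≥ 0.25; *drug-dependent* if PS with drug ≥ 0.25, at least
  1.5× the drug-free PS, and log2 FC ≥ 0.5.
* **Codon-usage control.** For 3-codon motifs, log2 FC is correlated
  (Pearson) against the usage frequency of each codon position separately;
  a user-supplied codon→frequency TSV is required since usage tables are
  organism-specific.

## Variant analysis (focused libraries)

Reads are translated over the wild-type-length window (reads too short for
the window, or containing a stop, are excluded and counted), grouped into
peptide variants with per-sample counts and the number of distinct
underlying nucleotide sequences. Per-variant FC against the input library
uses frequency ratios. `select_discriminating` keeps variants with ≥ 150
combined reads whose FC reaches the cutoff (default 2.0) in exactly one
condition (XOR — "enriched in one but not the other" operationalised as
the other side falling below the same cutoff). Per-(position, residue)
over/under-representation between two read sets uses
log2((f_fg+ε)/(f_bg+ε)) with ε = 1/(n_bg+20) — the smoothing keeps
zero-count cells finite while shrinking as data grow — plus an uncorrected
two-sided binomial p-value per cell, labelled descriptive: the statistic
ranks cells, it does not test hypotheses.

## What the simulator does and does not establish

Passing tests show the analysis correctly inverts the generative model it
assumes: sequential first-stall-wins pausing, a single cleavage offset
with short-range jitter, substitution-only sequencing error, binomial
replicate noise. Real data add effects outside this model — ribosome
queuing, sequence-dependent RNase R pause sites, ligation and PCR bias,
indels, heterogeneous per-position quality — so agreement here validates
the *software*, not those biochemical assumptions. Known limitations: PS
conditioning bias (above); no modelling of tRNA kinetics, drug-binding
thermodynamics or EF-P mechanism; multi-round selection is represented
only by dropping readthrough reads.

## Numerical and design choices

* Problem sizes in the test suite (10⁴ reads for offset recovery, 2×10⁴
  encounters per PS oracle point, ~10⁶ reads for the enrichment–PS
  correlation, 2×10⁵ encounters per condition for variant recovery) were
  chosen so closed-form 3-SE bounds are decisive at a few minutes of
  runtime.
* Mode ties in offset estimation break toward the larger offset; ceil
  rounding in P-site assignment; both follow from jitter only shortening
  fragments.
* Degenerate inputs: empty read sets raise; zero-variance usage vectors
  and motifs never encountered give flagged NaNs rather than silent zeros;
  single-replicate conditions propagate NaN errors with a logged warning.
* All randomness flows from explicit seeds; replicate and condition seeds
  are spawned from the master seed in sorted-name order.
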