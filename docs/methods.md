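# Methods

## Model

`senscan` treats each database's missense variants as a point pattern on
the residues of one protein and estimates a smoothed positional density
for each source with a truncated Gaussian rolling average. The two
density estimates are put on a common scale by max-normalization and
subtracted; spans where the clinical density exceeds the population
density (negative delta) are reported as sensitive regions.

The assumptions this encodes:

- **One substitution, one event.** Variants are deduplicated on
  (gene, position, ref, alt, consequence). Allele frequency, submission
  counts and carrier numbers are deliberately ignored: the question is
  *where* variation is observed or absent, not how common it is. A
  variant present in both databases contributes to both curves.
- **Missense only.** Nonsense/frameshift variants abolish or truncate
  the protein and are handled by the separate truncation analysis;
  mixing them into the density curves would conflate loss-of-expression
  with local structural sensitivity.
- **Locality.** A variant is evidence about its neighbourhood, with
  Gaussian-decaying weight over roughly ±15 residues (window 31). This
  is a smoothing bandwidth, not a biological estimate of domain size.
- **Relative, not absolute, signal.** After max-normalization the curves
  carry no information about absolute mutation burden. A gene with a
  single clinical variant will still show a maximal clinical peak; the
  delta is only meaningful where at least one source has data, and
  region calls on sparse inputs should be read together with the
  per-region variant counts (`n_clinical`, `n_population`) that
  accompany every call.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `window` | 31 | residues | the span of the rolling average; odd so it centres on a residue |
| `sigma` | (window−1)/6 = 5 | residues | the window then covers ±3σ, ≈99.7% of an untruncated Gaussian, so truncating at the window edge discards almost no mass |
| `min_region_length` | 1 | residues | region calls are maximal negative runs with no smoothing of their own; no gap merging is applied |
| `t_pop` | 10 | variants | minimum population NMD-predicted truncations for a *tolerant* call |
| `pop_to_clinical_ratio` | 3.0 | — | population truncations must exceed this multiple of the clinical truncating count for *tolerant* |
| `intolerant_max_pop` / `intolerant_min_clinical` | 5 / 1 | variants | *intolerant* needs few population early truncations alongside clinical ones |
| `male_fraction_flag` | 0.2 | — | male share of population pre-last-exon carriers below which the rationale notes a female-carrier bias |
| `intron_scale` | per gene | ratio | a single divisor applied to every intron's drawn width in exon maps |

The kernel is truncated at the window and renormalized to unit sum
*before* the edge correction. The alternative order (correct first,
renormalize after) differs only by a constant factor per curve, which
cancels under max-normalization — the choice is therefore documented
rather than load-bearing.

## Numerical choices

- **Edge correction as division.** The correction for windows that
  overhang the protein ends is implemented as division of each residue's
  raw value by the in-range kernel mass m(i) (equivalently,
  multiplication by its reciprocal). For a uniform unit density this
  makes the curve exactly constant across the whole protein, including
  both termini — the property the test suite checks to 1e−10. Edge
  residues (within (window−1)/2 of a terminus) are flagged
  `edge_flag=1` in every output because their values rest on upweighted
  partial windows; they are never dropped.
- **Delta orientation.** delta = population_norm − clinical_norm, so
  negative values always mean clinical enrichment. Swapping the two
  inputs negates delta exactly (tested).
- **Zero curves.** A source with no missense variants yields an all-zero
  curve, which max-normalization passes through unchanged (no division
  by zero). The delta then degenerates to ± the other curve, which is
  the honest reading: with an empty clinical set, nothing is sensitive;
  with an empty population set, everything clinical is.
- **Strictness of the region threshold.** Sensitive regions are runs of
  strictly negative delta. Residues where the curves tie (commonly 0−0
  far from all variants) are not sensitive.
- **Masking.** Masked residue intervals (e.g. an alternatively spliced
  insert absent from the population database's transcript, such as the
  NLGN1 splice-insert span 165–205) drop the configured source's
  variants in the interval and set `masked_flag=1`; masking can be
  applied per source or to both.
- **Coordinates.** 1-based closed residue intervals everywhere (HGVS
  convention) except BED output, where residue r becomes the 0-based
  half-open interval [r−1, r).
- **Frameshift position.** `p.X123Yfs*N` is parsed but only the first
  affected residue (123) is kept; the downstream stop extension is
  dropped. At the CDS level a truncating variant without an explicit
  nucleotide coordinate is marked at the first nucleotide of its codon,
  3·(pos−1)+1.
- **NMD boundary.** A stop whose marked nucleotide is the first
  nucleotide of the last exon belongs to the last exon and escapes the
  NMD prediction. Only the last-exon criterion is implemented; the
  50-nt-from-last-junction refinement is out of scope by design.
- **Ambiguous reference residues.** The parser preserves notation as
  printed and does not validate reference residues against a sequence —
  curated lists occasionally carry conflicting refs at one position
  (e.g. NLGN3 P77S alongside I77M), and both are retained as distinct
  events.

## Haploinsufficiency call

The tolerance call compares the population's NMD-predicted
(before-last-exon) truncation count with the clinical truncating total
under the thresholds above. The published neuroligin tallies — NLGN1
53 population / 3 clinical, NLGN2 64 / 2, NLGN3 11 pre-last-exon of 20 /
3, NLGN4X 4 pre-last-exon of 5 / 6 — reproduce under the defaults as
tolerant, tolerant, tolerant (with a female-carrier-bias note: 18 of 20
NLGN3 population truncation carriers are female, a pattern consistent
with intolerance in hemizygous males), and intolerant. The thresholds
are explicitly heuristic: the underlying inference is qualitative, and
the defaults were chosen to express it, not fitted. Sex bias never flips
a call on its own — for X-linked genes the counts and rationale are the
product, and the call should be read with them.

The bundled per-gene exon models behind these tallies are synthetic
stand-ins (toy exon counts and lengths); only the before-last/last exon
split and carrier sex split are faithful to the published summaries, and
those are the only inputs the call consumes. The NLGN4X clinical
truncations carry no published exon breakdown and are placed before the
last exon, consistent with their description as early truncations; the
call does not depend on this placement.

## Synthetic data

`senscan.synthetic` draws variant tables with known ground truth: a
per-residue Poisson background of population missense variants
(optionally zeroed in depleted windows), Gaussian clinical clusters
(rounded, clipped — not rejected — at the bounds so each cluster's count
stays exact), and nonsense variants placed per exon for truncation
tests. Amino acids come from a random reference sequence with distinct
alternates forced at repeated positions, so deduplication never erodes
the specified counts. One integer seed drives a single generator stream.

What the generator does *not* emulate: mutational signatures and codon
structure (positions are uniform within their distributions), allele
frequencies, carrier counts, submission noise, shared variants between
the two sources, and annotation errors. Passing the recovery test
therefore shows the pipeline detects positional clustering against a
diffuse background at realistic densities — not that it is robust to
every artefact of real database exports.

The standard recovery study uses an 800-residue protein, one clinical
cluster of 20 variants with sd 5 at residue 400 (mid-protein, clear of
edge effects), a population background of 0.05 variants/residue (≈40
variants, the order of a moderately covered gene), window 31, and 100
seeded replicates; the acceptance criterion is that ≥95 replicates call
a sensitive region containing the implanted center. These problem sizes
run in about a second.

## Known limitations

- No statistical significance is attached to a region call: the method
  is a density comparison, not a test, and narrow regions driven by one
  or two clinical variants are only as trustworthy as those records.
- Max-normalization makes curves comparable within a gene but not
  between genes; cross-gene comparisons should use the raw curves and
  matched database snapshots.
- Residue numbering must be consistent between the two exports and the
  stated protein length; isoform mismatches (e.g. splice inserts that
  shift numbering by ~20 residues between MANE and literature
  conventions for NLGN3) must be resolved upstream or handled with
  masks.
- The clinical-significance filter defaults to *all* records, because
  published region counts include uncharacterized entries; an allow-list
  (e.g. pathogenic/likely-pathogenic only) is available and changes the
  clinical curve accordingly.
- GFF3 reading expects a single-transcript annotation; multi-transcript
  files must be pre-filtered.
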