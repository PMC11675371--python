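# senscan

Residue-level missense-tolerance profiling for disease-gene analysis.

`senscan` compares where missense variants fall along a protein in a
clinical variant repository (ClinVar) against an unimpacted-population
repository (gnomAD), and calls **sensitive regions** — spans of residues
relatively enriched in disease-associated variation and depleted of
benign variation. It also classifies truncating variants (nonsense,
frameshift) under the last-exon nonsense-mediated-decay (NMD) rule and
summarizes a gene's apparent **tolerance to haploinsufficiency** from the
relative incidence of early truncations in the two databases. The package
was developed around the neuroligin (*NLGN*) gene family — postsynaptic
adhesion molecules strongly associated with autism spectrum disorder —
and ships the NLGN variant lists as worked examples, but applies to any
gene with protein-level variant exports.

## The method

For one gene of protein length *L*, each database's deduplicated missense
variants (one event per distinct substitution, unweighted by carrier
counts) define a per-residue "tolerance value":

1. **Rolling Gaussian average.** The variant indicator counts
   *c(p)* are convolved with a truncated, unit-sum Gaussian kernel *w* of
   odd window *W* (default 31 residues, σ = (W−1)/6):
   raw(i) = Σₚ c(p) · w(i−p).
2. **Edge correction.** Near the termini part of the window leaves
   [1, L] and would contribute false zeros; each value is divided by the
   kernel mass in range, m(i) = Σ_{1≤i+k≤L} w(k). Edge residues (within
   (W−1)/2 of a terminus) are flagged, not dropped.
3. **Max-normalization.** Both curves are rescaled so their maxima equal
   1, putting databases of very different sizes on one footing.
4. **Delta.** Δ(i) = population_norm(i) − clinical_norm(i). Maximal runs
   of Δ < 0 are reported as sensitive regions; positive spans are
   well-tolerated.

Truncating variants are marked at a CDS nucleotide (the first nucleotide
of the affected codon, 3·(pos−1)+1, unless an explicit coordinate is
given); NMD is predicted exactly when that nucleotide lies before the
transcript's last exon. A gene is called *tolerant* to haploinsufficiency
when many NMD-predicted truncations circulate in the population relative
to the clinical count, *intolerant* when the population count is low and
clinical truncations exist, and *indeterminate* otherwise; sex-linked
carrier bias (female-dominated population truncations on X-linked genes)
is surfaced in the rationale, never as an automatic call.

## Worked example

The NLGN4X ClinVar missense lists for its two best-described sensitive
spans (the N-terminal surface-trafficking hotspot around residue 100 and
the juxtamembrane cleavage region) against a small gnomAD background:

```python
from senscan.examples import (REGION1_CLINVAR, JUXTAMEMBRANE_VARIANTS,
                              PROTEIN_LENGTHS, variant_table)
from senscan.tolerance import tolerance_profile
from senscan.variant_model import SourceLabel

clinical = variant_table(
    REGION1_CLINVAR["NLGN4X"] + JUXTAMEMBRANE_VARIANTS[("NLGN4X", SourceLabel.CLINICAL)],
    "NLGN4X", SourceLabel.CLINICAL)
population = variant_table(
    ["p.V54L", "p.A283T", "p.T287M", "p.S329L", "p.V403M",
     "p.R547C", "p.A712V", "p.R766Q"], "NLGN4X", SourceLabel.POPULATION)

profile = tolerance_profile(clinical, population,
                            PROTEIN_LENGTHS["NLGN4X"], gene="NLGN4X")
for r in profile.regions:
    print(f"{r.start:>4}-{r.end:<4} min_delta={r.min_delta:+.3f} "
          f"clinvar={r.n_clinical} gnomad={r.n_population}")
```

prints

```
  69-129  min_delta=-0.917 clinvar=11 gnomad=0
 605-648  min_delta=-1.000 clinvar=6 gnomad=0
```

Two sensitive regions are called. The first (residues 69–129) contains
the 11 ClinVar variants of the N-terminal hotspot — the span around the
N102 glycosylation site whose variants impair NLGN4X surface trafficking;
the second (605–648) contains the six juxtamembrane ClinVar variants.
`min_delta` is the most negative value of the collapsed curve inside the
region: −1.0 means clinical density peaked there with no offsetting
population density.

The same analysis from a shell, on any generic CSV with a `hgvs_p`
column (plus ClinVar variant_summary TSV and gnomAD CSV export dialects):

```sh
senscan profile --clinical clinvar.csv --population gnomad.csv \
    --gene NLGN4X --length 816 --window 31 --out nlgn4x
# -> nlgn4x.curve.tsv  nlgn4x.regions.bed  nlgn4x.png
senscan truncations --clinical clinvar.csv --population gnomad.csv \
    --transcript nlgn4x.json --out report.json
senscan exonmap --transcript nlgn4x.json --population gnomad.csv --out map.png
senscan simulate --spec spec.json --out sim      # seeded synthetic data
```

HGVS protein notation is accepted with or without the `p.` prefix, in
one- or three-letter codes, with `*` or `Ter` stops, `fs`/`fs*N`
frameshifts, and `=`/ref==alt synonymous forms: `p.R451C`, `R451C`,
`p.Arg451Cys`, `p.L25*`, `p.Leu25Ter`, `p.T271fs`, `p.K123Rfs*17`.

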