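"""Bundled neuroligin (NLGN) worked-example data.

Small, curated variant lists for the NLGN gene family — postsynaptic
adhesion molecules strongly associated with autism spectrum disorder —
compiled from public ClinVar and gnomAD entries.  They cover the
published sensitive regions of the family (the N-terminal ~100-residue
trafficking hotspot and the juxtamembrane O-glycosylated cleavage span)
plus summary early-truncation counts per gene, and serve as the README's
worked example and the regression anchors in the test suite.

The per-gene exon models returned by :func:`truncation_fixture` are
synthetic stand-ins: exon counts and lengths are toy values chosen only
so that "before last exon" vs "last exon" placement matches the published
per-gene truncation tallies; they are not the real MANE exon structures.
"""

from __future__ import annotations

from .io import TranscriptModel, VariantTable
from .synthetic import SyntheticSpec, TruncationSpec, generate_transcript, generate_variants
from .variant_model import (
    ProteinVariant,
    SourceLabel,
    ZygosityCounts,
    dedupe_variants,
    parse_hgvs_p,
)

__all__ = [
    "PROTEIN_LENGTHS",
    "REGION1_CLINVAR",
    "REGION1_INTERVALS",
    "JUXTAMEMBRANE_VARIANTS",
    "JUXTAMEMBRANE_INTERVALS",
    "NLGN1_REPORTED",
    "variant_table",
    "truncation_fixture",
]

#: Approximate canonical protein lengths (literature residue numbering;
#: MANE numbering of NLGN3 differs by an alternatively spliced insert).
PROTEIN_LENGTHS = {"NLGN1": 873, "NLGN2": 835, "NLGN3": 848, "NLGN4X": 816}

#: ClinVar missense variants in the N-terminal sensitive region (the
#: surface-trafficking hotspot around residue 100 of NLGN4X and its
#: paralogous spans in NLGN1/NLGN3).
REGION1_CLINVAR = {
    "NLGN1": ["p.A87S", "p.P88S", "p.P89L", "p.T90R", "p.R93H", "p.E99Q", "p.P100S", "p.P103S"],
    "NLGN3": ["p.A76T", "p.P77S", "p.I77M", "p.E81K", "p.K82Q", "p.R83C", "p.L85V"],
    "NLGN4X": [
        "p.P81A", "p.T83P", "p.G84R", "p.R87W", "p.P90A", "p.P94L",
        "p.T98A", "p.T103A", "p.T104S", "p.A108G", "p.L114P",
    ],
}

#: Closed residue intervals spanning each gene's Region-1 variant list.
REGION1_INTERVALS = {"NLGN1": (87, 103), "NLGN3": (76, 85), "NLGN4X": (81, 114)}

#: Variants across the juxtamembrane O-glycosylated cleavage span:
#: ClinVar missense lists for all four genes, plus the gnomAD missense
#: list for NLGN1 (a span otherwise notably sparse in population
#: variation — 12 variants across residues 673–699).
JUXTAMEMBRANE_VARIANTS = {
    ("NLGN1", SourceLabel.CLINICAL): ["p.T667K", "p.Q675R", "p.P678A", "p.T694A"],
    ("NLGN1", SourceLabel.POPULATION): [
        "p.T674I", "p.V678I", "p.A681S", "p.A681V", "p.V682A", "p.L686M",
        "p.N690H", "p.I691M", "p.L692M", "p.A695T", "p.Y698F", "p.Y698C",
    ],
    ("NLGN2", SourceLabel.CLINICAL): ["p.R641P", "p.R642W", "p.P645L", "p.E654K", "p.P655T"],
    ("NLGN3", SourceLabel.CLINICAL): ["p.T652A", "p.T659N", "p.R671W", "p.I674T", "p.N680D"],
    ("NLGN4X", SourceLabel.CLINICAL): ["p.S620L", "p.T625I", "p.T625N", "p.R626Q", "p.R627Q", "p.W633R"],
}

JUXTAMEMBRANE_INTERVALS = {
    "NLGN1": (673, 699),
    "NLGN2": (641, 659),
    "NLGN3": (652, 680),
    "NLGN4X": (620, 633),
}

#: Ten NLGN1 variants reported in patients (ASD/ID/speech disorder/AD
#: cohorts) — a mixed-consequence list exercising the parser: one
#: nonsense, one frameshift, eight missense.
NLGN1_REPORTED = [
    "p.L25*", "p.P89L", "p.T90I", "p.T90R", "p.D140Y",
    "p.I158K", "p.L269P", "p.T271fs", "p.G297E", "p.H795Y",
]


def variant_table(
    notations: list[str], gene: str, source: SourceLabel
) -> VariantTable:
    """Parse a notation list into a deduplicated VariantTable."""
    records = [parse_hgvs_p(n, gene=gene, source=source) for n in notations]
    return VariantTable(
        records=dedupe_variants(records),
        source=source,
        provenance=f"bundled {gene} example list",
    )


# Published per-gene early-truncation tallies:
#   gene: (population total, population before-last-exon,
#          clinical total, clinical before-last-exon,
#          population (n_female, n_male) carrier split or None)
_TRUNCATION_COUNTS = {
    "NLGN1": (53, 53, 3, 3, None),
    "NLGN2": (64, 64, 2, 2, None),
    "NLGN3": (20, 11, 3, 2, (18, 2)),
    "NLGN4X": (5, 4, 6, 6, (5, 0)),
}

# Toy exon lengths per gene (synthetic; sum = 3 * (protein_length + 1)).
_TOY_EXONS = {
    "NLGN1": [300, 400, 400, 400, 400, 400, 322],
    "NLGN2": [358, 400, 400, 350, 400, 300, 300],
    "NLGN3": [347, 300, 300, 300, 300, 300, 300, 400],
    "NLGN4X": [400, 500, 450, 400, 350, 351],
}


def truncation_fixture(
    gene: str, seed: int = 0
) -> tuple[VariantTable, VariantTable, TranscriptModel]:
    """Clinical/population truncation tables matching a gene's published tally.

    Builds a synthetic exon model and draws nonsense variants so that the
    before-last-exon / last-exon split and the female/male carrier split
    of the population set match the published summary counts for the
    gene.  Variant positions within exons are synthetic.
    """
    pop_total, pop_before, clin_total, clin_before, sex_split = _TRUNCATION_COUNTS[gene]
    exon_lengths = _TOY_EXONS[gene]
    transcript = generate_transcript(len(exon_lengths), exon_lengths, gene=gene)
    n_exons = transcript.n_exons

    truncs = []
    # spread before-last-exon counts over the penultimate exon; last-exon
    # counts in the final exon
    truncs.append(TruncationSpec(SourceLabel.POPULATION, n_exons - 1, pop_before))
    if pop_total > pop_before:
        truncs.append(TruncationSpec(SourceLabel.POPULATION, n_exons, pop_total - pop_before))
    if clin_before:
        truncs.append(TruncationSpec(SourceLabel.CLINICAL, n_exons - 1, clin_before))
    if clin_total > clin_before:
        truncs.append(TruncationSpec(SourceLabel.CLINICAL, n_exons, clin_total - clin_before))

    spec = SyntheticSpec(
        protein_length=transcript.protein_length,
        truncations=tuple(truncs),
        seed=seed,
        gene=gene,
    )
    clinical, population, _ = generate_variants(spec, transcript=transcript)

    if sex_split is not None:
        n_female, n_male = sex_split
        records = []
        for i, v in enumerate(population.records):
            zyg = ZygosityCounts(
                het=1,
                n_female=1 if i < n_female else 0,
                n_male=0 if i < n_female else 1,
            )
            records.append(ProteinVariant(
                gene=v.gene, position=v.position, ref_aa=v.ref_aa, alt_aa=v.alt_aa,
                consequence=v.consequence, source=v.source, zygosity=zyg,
                raw_hgvs=v.raw_hgvs,
            ))
        population = VariantTable(records, SourceLabel.POPULATION, population.provenance)
    return clinical, population, transcript
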