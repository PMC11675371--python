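"""Early-truncation classification, the last-exon NMD rule, and the
haploinsufficiency report.

Transcripts carrying a premature stop codon are typically degraded by
nonsense-mediated decay (NMD), so a truncating variant whose stop lies
before the final exon is predicted to abolish expression from that allele.
Comparing how many such alleles circulate in an unimpacted population
(gnomAD) against how many are reported clinically (ClinVar) supports a
qualitative call on whether a gene tolerates the loss of one copy:

* many population early truncations and few clinical ones → tolerant;
* few or no population early truncations alongside clinical ones →
  intolerant to haploinsufficiency.

For X-linked genes the sex of carriers matters — loss of the single allele
in hemizygous males is not buffered — so the report surfaces any
female/male carrier bias in its rationale but never converts it into an
automatic call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ._errors import ConsequenceError, RangeError
from .io import TranscriptModel, VariantTable
from .variant_model import ConsequenceClass, ProteinVariant, dedupe_variants

__all__ = [
    "TruncationCall",
    "HaploThresholds",
    "HaploinsufficiencyReport",
    "TRUNCATING",
    "mark_truncation_site",
    "classify_truncation",
    "haploinsufficiency_report",
]

#: Consequence classes that terminate translation early.
TRUNCATING = (ConsequenceClass.NONSENSE, ConsequenceClass.FRAMESHIFT)


@dataclass(frozen=True)
class TruncationCall:
    """NMD prediction for one truncating variant on one transcript."""

    variant: ProteinVariant
    cds_position: int
    exon_index: int
    is_last_exon: bool

    @property
    def predicted_nmd(self) -> bool:
        """True iff the marked stop lies before the transcript's last exon."""
        return not self.is_last_exon


@dataclass(frozen=True)
class HaploThresholds:
    """Configurable cutoffs behind the qualitative tolerance call.

    The defaults are heuristic: ``tolerant`` needs at least ``t_pop``
    population before-last-exon truncations and a population excess of
    ``pop_to_clinical_ratio`` over the clinical truncation count;
    ``intolerant`` needs at most ``intolerant_max_pop`` population
    before-last-exon truncations alongside at least
    ``intolerant_min_clinical`` clinical truncating variants.
    ``male_fraction_flag`` is the male share of population pre-last-exon
    carriers below which the rationale notes a female-carrier bias.
    """

    t_pop: int = 10
    pop_to_clinical_ratio: float = 3.0
    intolerant_max_pop: int = 5
    intolerant_min_clinical: int = 1
    male_fraction_flag: float = 0.2


@dataclass
class SourceTruncationCounts:
    total: int = 0
    before_last_exon: int = 0
    last_exon: int = 0
    het: int = 0
    hom: int = 0
    hemi: int = 0
    n_female: int = 0
    n_male: int = 0


@dataclass
class HaploinsufficiencyReport:
    """Early-truncation tally per source plus a rule-based tolerance call."""

    gene: str
    clinical: SourceTruncationCounts
    population: SourceTruncationCounts
    tolerance_call: str = "indeterminate"
    rationale: str = ""
    thresholds: HaploThresholds = field(default_factory=HaploThresholds)

    def to_dict(self) -> dict:
        def counts(c: SourceTruncationCounts) -> dict:
            return {
                "total_truncating": c.total,
                "before_last_exon": c.before_last_exon,
                "last_exon": c.last_exon,
                "het": c.het,
                "hom": c.hom,
                "hemi": c.hemi,
                "n_female": c.n_female,
                "n_male": c.n_male,
            }

        return {
            "gene": self.gene,
            "clinical": counts(self.clinical),
            "population": counts(self.population),
            "tolerance_call": self.tolerance_call,
            "rationale": self.rationale,
        }


def mark_truncation_site(
    variant: ProteinVariant,
    transcript: TranscriptModel,
    cds_hint: Optional[int] = None,
) -> int:
    """CDS nucleotide index marking a truncating variant.

    An explicit nucleotide coordinate (``cds_hint`` — the mutated
    nucleotide for a nonsense variant, the first inserted/deleted
    nucleotide for a frameshift) is passed through when given; otherwise
    the site is derived from the protein position as the first nucleotide
    of the affected codon, ``3·(pos − 1) + 1``.
    """
    if variant.consequence not in TRUNCATING:
        raise ConsequenceError(
            f"{variant.raw_hgvs or variant}: expected a truncating variant, "
            f"got {variant.consequence.value}"
        )
    nt = cds_hint if cds_hint is not None else 3 * (variant.position - 1) + 1
    if not (1 <= nt <= transcript.cds_length):
        raise RangeError(
            f"CDS position {nt} outside [1, {transcript.cds_length}] "
            f"for {variant.raw_hgvs or variant}"
        )
    return nt


def classify_truncation(
    variant: ProteinVariant,
    transcript: TranscriptModel,
    cds_hint: Optional[int] = None,
) -> TruncationCall:
    """Locate a truncating variant's exon and apply the last-exon NMD rule.

    ``predicted_nmd`` is true exactly when the marked nucleotide falls in
    any exon but the transcript's final one; a stop at the first
    nucleotide of the last exon already escapes NMD (the boundary belongs
    to the last exon).
    """
    nt = mark_truncation_site(variant, transcript, cds_hint)
    exon = transcript.exon_of_cds_position(nt)
    return TruncationCall(
        variant=variant,
        cds_position=nt,
        exon_index=exon,
        is_last_exon=exon == transcript.n_exons,
    )


def _tally(table: VariantTable, transcript: TranscriptModel) -> SourceTruncationCounts:
    c = SourceTruncationCounts()
    for v in dedupe_variants(table.records):
        if v.consequence not in TRUNCATING:
            continue
        call = classify_truncation(v, transcript)
        c.total += 1
        if call.is_last_exon:
            c.last_exon += 1
        else:
            c.before_last_exon += 1
        if v.zygosity is not None:
            c.het += v.zygosity.het
            c.hom += v.zygosity.hom
            c.hemi += v.zygosity.hemi
            c.n_female += v.zygosity.n_female
            c.n_male += v.zygosity.n_male
    return c


def haploinsufficiency_report(
    clinical: VariantTable,
    population: VariantTable,
    transcript: TranscriptModel,
    thresholds: HaploThresholds = HaploThresholds(),
) -> HaploinsufficiencyReport:
    """Assemble truncation counts and a rule-based haploinsufficiency call.

    Tables may contain any consequence classes; only truncating variants
    are tallied.  The call compares the population's before-last-exon
    (NMD-predicted) truncation count with the clinical truncating total;
    sex-linked carrier bias is reported in the rationale only.
    """
    clin = _tally(clinical, transcript)
    pop = _tally(population, transcript)
    th = thresholds

    call = "indeterminate"
    reasons: list[str] = []
    if (
        pop.before_last_exon >= th.t_pop
        and pop.before_last_exon >= th.pop_to_clinical_ratio * max(clin.total, 1)
    ):
        call = "tolerant"
        reasons.append(
            f"{pop.before_last_exon} population truncations before the last exon "
            f"(NMD-predicted) vs {clin.total} clinical truncating variants: "
            f"loss of one allele circulates in the unimpacted population"
        )
    elif pop.before_last_exon <= th.intolerant_max_pop and clin.total >= th.intolerant_min_clinical:
        call = "intolerant"
        reasons.append(
            f"only {pop.before_last_exon} population truncation(s) before the last exon "
            f"against {clin.total} clinical truncating variant(s): "
            f"loss of an allele is depleted from the unimpacted population"
        )
    else:
        reasons.append(
            f"{pop.before_last_exon} population before-last-exon truncations and "
            f"{clin.total} clinical truncating variants do not meet either rule"
        )

    sexed = pop.n_female + pop.n_male
    if sexed > 0 and pop.before_last_exon > 0:
        male_frac = pop.n_male / sexed
        if male_frac <= th.male_fraction_flag:
            reasons.append(
                f"population carriers are predominantly female "
                f"({pop.n_female} female vs {pop.n_male} male): pattern consistent "
                f"with intolerance in hemizygous males and tolerance in "
                f"heterozygous female carriers (not an automatic call)"
            )

    return HaploinsufficiencyReport(
        gene=transcript.gene,
        clinical=clin,
        population=pop,
        tolerance_call=call,
        rationale="; ".join(reasons),
        thresholds=th,
    )
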