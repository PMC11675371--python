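"""Core domain types and the HGVS protein-notation parser.

Every other module consumes the :class:`ProteinVariant` record defined here.
Variants are protein-level events: a residue position, reference and
alternate amino acids, and a consequence class (missense, nonsense,
frameshift, synonymous, other).  Notation such as ``p.R451C`` (one-letter)
or ``p.Arg451Cys`` (three-letter, the ClinVar dialect) is canonicalized to
one-letter codes on input.

Counting convention: a distinct protein-level substitution is one event,
regardless of how many individuals or database submissions carry it.
Distinct substitutions at the same residue (e.g. T625I and T625N) are
separate events.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from ._errors import HgvsParseError, RangeError

__all__ = [
    "AA_ONE_LETTER",
    "ConsequenceClass",
    "SourceLabel",
    "ZygosityCounts",
    "ProteinVariant",
    "parse_hgvs_p",
    "classify_consequence",
    "format_hgvs_p",
    "dedupe_variants",
    "count_region_variants",
]

#: The 20 standard amino acids, one-letter codes.
AA_ONE_LETTER = frozenset("ACDEFGHIKLMNPQRSTVWY")

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Xaa": "?",
}


class ConsequenceClass(str, Enum):
    """Protein-level consequence of a variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class SourceLabel(str, Enum):
    """Which database a variant record came from.

    ``CLINICAL`` corresponds to a disease-associated repository (ClinVar);
    ``POPULATION`` to an unimpacted-population repository (gnomAD).
    """

    CLINICAL = "clinical"
    POPULATION = "population"


@dataclass(frozen=True)
class ZygosityCounts:
    """Genotype and sex breakdown of carriers of one variant."""

    het: int = 0
    hom: int = 0
    hemi: int = 0
    n_female: int = 0
    n_male: int = 0

    def __post_init__(self) -> None:
        for name in ("het", "hom", "hemi", "n_female", "n_male"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ProteinVariant:
    """One protein-level variant.

    ``position`` is the 1-based residue index of the first affected residue.
    ``ref_aa`` is a one-letter code or ``"?"`` when unknown; ``alt_aa`` is a
    one-letter code, ``"*"`` for a stop gain, or ``""`` for a frameshift
    (whose eventual downstream stop is not a substitution at this residue).
    """

    gene: str
    position: int
    ref_aa: str
    alt_aa: str
    consequence: ConsequenceClass
    source: Optional[SourceLabel] = None
    significance: Optional[str] = None
    zygosity: Optional[ZygosityCounts] = None
    raw_hgvs: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise RangeError(f"residue position must be >= 1, got {self.position}")
        if self.consequence is ConsequenceClass.MISSENSE:
            if self.ref_aa not in AA_ONE_LETTER or self.alt_aa not in AA_ONE_LETTER:
                raise ValueError(
                    f"missense requires standard amino acids, got {self.ref_aa}->{self.alt_aa}"
                )
            if self.ref_aa == self.alt_aa:
                raise ValueError("missense requires ref_aa != alt_aa")
        if self.consequence is ConsequenceClass.NONSENSE and self.alt_aa != "*":
            raise ValueError("nonsense requires alt_aa == '*'")
        if self.consequence is ConsequenceClass.FRAMESHIFT and "fs" not in self.raw_hgvs:
            raise ValueError("frameshift requires 'fs' in raw_hgvs")

    @property
    def key(self) -> tuple:
        """Identity for deduplication: one distinct substitution = one event."""
        return (self.gene, self.position, self.ref_aa, self.alt_aa, self.consequence)

    def with_source(self, source: SourceLabel) -> "ProteinVariant":
        return replace(self, source=source)


# Grammar: optional "p." prefix, optional parentheses (ClinVar prediction
# style), ref residue (1- or 3-letter), position, then either an alt residue
# (1- or 3-letter, "*"/"Ter"), "=" (synonymous), or a frameshift suffix
# "fs" / "fs*N" / "fsTer<N>", optionally after an alt residue.
_RES = r"(?:[A-Z][a-z]{2}|[A-Z*?])"
_HGVS_RE = re.compile(
    rf"^(?:p\.)?\(?"
    rf"(?P<ref>{_RES})"
    rf"(?P<pos>\d+)"
    rf"(?P<alt>{_RES}|=)?"
    rf"(?P<fs>fs(?:\*\d+|Ter\d+)?)?"
    rf"\)?$"
)


def _canon_residue(token: str, notation: str) -> str:
    """Canonicalize a residue token to a one-letter code."""
    if len(token) == 3:
        try:
            return _THREE_TO_ONE[token]
        except KeyError:
            raise HgvsParseError(notation, token, "unknown three-letter amino-acid code")
    if token in ("*", "?") or token in AA_ONE_LETTER:
        return token
    raise HgvsParseError(notation, token, "unknown amino-acid code")


def parse_hgvs_p(
    notation: str,
    *,
    gene: str = "",
    source: Optional[SourceLabel] = None,
    significance: Optional[str] = None,
    zygosity: Optional[ZygosityCounts] = None,
) -> ProteinVariant:
    """Parse an HGVS protein notation into a :class:`ProteinVariant`.

    Accepts ``p.X123Y``, ``X123Y``, three-letter forms (``p.Arg451Cys``),
    stop gains (``p.L25*``, ``p.Leu25Ter``), synonymous (``p.T90T`` or
    ``p.T90=``) and frameshifts (``p.T271fs``, ``p.X123Yfs*17``).  Parsing
    is canonicalizing and idempotent: ``format_hgvs_p(parse_hgvs_p(x))``
    re-parses to an identical record.

    Raises
    ------
    HgvsParseError
        If the notation does not match the grammar; the error names the
        offending token.
    RangeError
        If the residue position is zero (HGVS positions are 1-based).
    """
    s = notation.strip()
    m = _HGVS_RE.match(s)
    if m is None:
        # Identify the most informative offending token for the message.
        stripped = re.sub(r"^p\.", "", s)
        tok = stripped if stripped else "<empty>"
        raise HgvsParseError(notation, tok, "does not match HGVS protein grammar")

    ref = _canon_residue(m.group("ref"), notation)
    pos = int(m.group("pos"))
    if pos < 1:
        raise RangeError(f"HGVS residue position must be >= 1, got {pos} in {notation!r}")
    if ref == "*":
        raise HgvsParseError(notation, m.group("ref"), "reference residue cannot be a stop")

    alt_tok = m.group("alt")
    fs_tok = m.group("fs")

    if fs_tok is not None:
        # Frameshift: only the first-affected residue position is retained;
        # any downstream-stop extension ("fs*17") is accepted but dropped.
        alt = ""
        consequence = ConsequenceClass.FRAMESHIFT
        raw = f"p.{ref}{pos}fs"
    elif alt_tok is None:
        raise HgvsParseError(notation, s, "missing alternate residue")
    else:
        alt = ref if alt_tok == "=" else _canon_residue(alt_tok, notation)
        raw = f"p.{ref}{pos}{'*' if alt == '*' else alt}"
        if alt == "*":
            consequence = ConsequenceClass.NONSENSE
        elif alt == ref:
            consequence = ConsequenceClass.SYNONYMOUS
        elif ref in AA_ONE_LETTER and alt in AA_ONE_LETTER:
            consequence = ConsequenceClass.MISSENSE
        else:
            consequence = ConsequenceClass.OTHER

    return ProteinVariant(
        gene=gene,
        position=pos,
        ref_aa=ref,
        alt_aa=alt,
        consequence=consequence,
        source=source,
        significance=significance,
        zygosity=zygosity,
        raw_hgvs=raw,
    )


def format_hgvs_p(variant: ProteinVariant) -> str:
    """Canonical one-letter HGVS protein notation for a variant."""
    if variant.consequence is ConsequenceClass.FRAMESHIFT:
        return f"p.{variant.ref_aa}{variant.position}fs"
    return f"p.{variant.ref_aa}{variant.position}{variant.alt_aa}"


def classify_consequence(variant: ProteinVariant) -> ConsequenceClass:
    """Deterministically classify a parsed variant.

    Missense only when a single-residue substitution between two distinct
    standard amino acids; anything unrecognized falls back to ``OTHER``.
    """
    if "fs" in variant.raw_hgvs and variant.alt_aa == "":
        return ConsequenceClass.FRAMESHIFT
    if variant.alt_aa == "*":
        return ConsequenceClass.NONSENSE
    if variant.ref_aa in AA_ONE_LETTER and variant.alt_aa in AA_ONE_LETTER:
        if variant.ref_aa == variant.alt_aa:
            return ConsequenceClass.SYNONYMOUS
        return ConsequenceClass.MISSENSE
    return ConsequenceClass.OTHER


def dedupe_variants(variants: Iterable[ProteinVariant]) -> list[ProteinVariant]:
    """Collapse to one record per distinct substitution.

    Identity is ``(gene, position, ref_aa, alt_aa, consequence)``; distinct
    substitutions at the same residue are retained separately.  The first
    record seen for each key wins (so its annotations are kept) and the
    result is ordered by ``(position, alt_aa)``.  Idempotent.
    """
    seen: dict[tuple, ProteinVariant] = {}
    for v in variants:
        seen.setdefault(v.key, v)
    return sorted(seen.values(), key=lambda v: (v.position, v.alt_aa, v.ref_aa, v.gene))


def count_region_variants(
    variants: Sequence[ProteinVariant],
    interval: tuple[int, int],
    consequence_filter: ConsequenceClass | None = ConsequenceClass.MISSENSE,
) -> int:
    """Count deduplicated variants of one class inside a closed residue range.

    ``interval`` is 1-based inclusive on both ends.  Pass
    ``consequence_filter=None`` to count every class.
    """
    start, end = interval
    if start > end:
        raise RangeError(f"inverted interval [{start}, {end}]")
    deduped = dedupe_variants(variants)
    return sum(
        1
        for v in deduped
        if start <= v.position <= end
        and (consequence_filter is None or v.consequence is consequence_filter)
    )
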