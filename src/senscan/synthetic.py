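"""Seeded generator of variant tables and toy transcripts with known truth.

The generator emulates the positional structure the real databases
exhibit for a constrained gene: clinical (disease-associated) missense
variants clustered over a handful of critical subdomains, population
variants spread as a diffuse background with optional locally depleted
windows, and truncating variants distributed over exons.  Amino-acid
identities are drawn from a fixed random reference sequence; carrier
counts, allele frequencies and mutational-signature realism are out of
scope — positions are the object of study.

A single integer seed drives one NumPy generator stream, so every draw is
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._errors import SpecError
from .io import TranscriptModel, VariantTable
from .variant_model import (
    ConsequenceClass,
    ProteinVariant,
    SourceLabel,
    dedupe_variants,
)

__all__ = ["Cluster", "TruncationSpec", "SyntheticSpec", "generate_variants", "generate_transcript"]

_AAS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Cluster:
    """An implanted Gaussian cluster of missense variants."""

    center: int
    sd: float
    n: int
    source: SourceLabel = SourceLabel.CLINICAL


@dataclass(frozen=True)
class TruncationSpec:
    """``n`` nonsense variants placed in one exon for one source."""

    source: SourceLabel
    exon_index: int
    n: int


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth description of one synthetic gene's variant landscape."""

    protein_length: int
    background_rate: float = 0.0  # population variants per residue
    clusters: tuple[Cluster, ...] = ()
    depleted_windows: tuple[tuple[int, int], ...] = ()
    truncations: tuple[TruncationSpec, ...] = ()
    seed: int = 0
    gene: str = "SYN1"

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise SpecError("protein_length must be >= 1")
        if self.background_rate < 0:
            raise SpecError("background_rate must be >= 0")
        for c in self.clusters:
            if not (1 <= c.center <= self.protein_length):
                raise SpecError(f"cluster center {c.center} outside [1, {self.protein_length}]")
            if c.n > 0 and c.sd <= 0:
                raise SpecError(f"cluster with n={c.n} requires sd > 0, got {c.sd}")
            if c.n < 0:
                raise SpecError("cluster n must be >= 0")


def _draw_substitution(
    rng: np.random.Generator,
    pos: int,
    ref_seq: str,
    used: set,
    gene: str,
    source: SourceLabel,
) -> Optional[ProteinVariant]:
    """A missense variant at ``pos`` with an alt not yet used there."""
    ref = ref_seq[pos - 1]
    alts = [a for a in _AAS if a != ref and (pos, a) not in used]
    if not alts:
        return None
    alt = alts[rng.integers(len(alts))]
    used.add((pos, alt))
    return ProteinVariant(
        gene=gene,
        position=pos,
        ref_aa=ref,
        alt_aa=alt,
        consequence=ConsequenceClass.MISSENSE,
        source=source,
        raw_hgvs=f"p.{ref}{pos}{alt}",
    )


def generate_variants(
    spec: SyntheticSpec,
    transcript: Optional[TranscriptModel] = None,
) -> tuple[VariantTable, VariantTable, list[tuple[int, int]]]:
    """Draw clinical and population variant tables plus truth intervals.

    Background positions are Poisson per residue at ``background_rate``
    (zero inside depleted windows); cluster positions are rounded normal
    draws clipped — not rejected — at the protein bounds, so each cluster
    contributes exactly ``n`` variants.  Distinct alternates are forced at
    repeated positions, keeping counts exact after deduplication.  Truth
    records each cluster's span as ``center ± 2·sd``.  Truncation entries
    need a transcript to resolve exon boundaries.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.protein_length
    ref_seq = "".join(_AAS[i] for i in rng.integers(0, len(_AAS), size=L))

    depleted = np.zeros(L, dtype=bool)
    for s, e in spec.depleted_windows:
        depleted[max(s, 1) - 1 : min(e, L)] = True

    by_source: dict[SourceLabel, list[ProteinVariant]] = {
        SourceLabel.CLINICAL: [],
        SourceLabel.POPULATION: [],
    }
    used: dict[SourceLabel, set] = {SourceLabel.CLINICAL: set(), SourceLabel.POPULATION: set()}

    # population background
    if spec.background_rate > 0:
        counts = rng.poisson(spec.background_rate, size=L)
        counts[depleted] = 0
        for pos0 in np.nonzero(counts)[0]:
            for _ in range(int(counts[pos0])):
                v = _draw_substitution(
                    rng, int(pos0) + 1, ref_seq, used[SourceLabel.POPULATION],
                    spec.gene, SourceLabel.POPULATION,
                )
                if v is not None:
                    by_source[SourceLabel.POPULATION].append(v)

    # implanted clusters
    truth: list[tuple[int, int]] = []
    for c in spec.clusters:
        if c.n == 0:
            continue
        draws = np.rint(rng.normal(c.center, c.sd, size=c.n)).astype(int)
        draws = np.clip(draws, 1, L)
        for pos in draws:
            v = _draw_substitution(
                rng, int(pos), ref_seq, used[c.source], spec.gene, c.source
            )
            if v is not None:
                by_source[c.source].append(v)
        half = int(round(2 * c.sd))
        truth.append((max(1, c.center - half), min(L, c.center + half)))

    # truncating variants, placed exon by exon
    if spec.truncations:
        if transcript is None:
            raise SpecError("truncation entries require a transcript")
        for t in spec.truncations:
            rng_range = transcript.cds_codon_range_in_exon(t.exon_index)
            if rng_range is None:
                raise SpecError(f"exon {t.exon_index} contains no coding codons")
            lo, hi = rng_range
            stop_used = used[t.source]
            for _ in range(t.n):
                for _attempt in range(1000):
                    pos = int(rng.integers(lo, hi + 1))
                    if (pos, "*") not in stop_used:
                        break
                else:
                    raise SpecError(
                        f"cannot place {t.n} distinct stops in exon {t.exon_index}"
                    )
                stop_used.add((pos, "*"))
                ref = ref_seq[pos - 1]
                by_source[t.source].append(
                    ProteinVariant(
                        gene=spec.gene,
                        position=pos,
                        ref_aa=ref,
                        alt_aa="*",
                        consequence=ConsequenceClass.NONSENSE,
                        source=t.source,
                        raw_hgvs=f"p.{ref}{pos}*",
                    )
                )

    clinical = VariantTable(
        records=dedupe_variants(by_source[SourceLabel.CLINICAL]),
        source=SourceLabel.CLINICAL,
        provenance=f"synthetic seed={spec.seed}",
    )
    population = VariantTable(
        records=dedupe_variants(by_source[SourceLabel.POPULATION]),
        source=SourceLabel.POPULATION,
        provenance=f"synthetic seed={spec.seed}",
    )
    return clinical, population, truth


def generate_transcript(
    n_exons: int,
    exon_lengths: Sequence[int],
    gene: str = "SYN1",
    intron_length: int = 100,
) -> TranscriptModel:
    """A contiguous plus-strand toy transcript whose CDS spans every exon.

    Exon lengths must sum to a multiple of 3 (the last codon is the stop),
    so a transcript of total length ``3·(L+1)`` encodes ``L`` residues.
    """
    exon_lengths = list(exon_lengths)
    if n_exons != len(exon_lengths) or n_exons < 1:
        raise SpecError(
            f"n_exons ({n_exons}) must match exon_lengths ({len(exon_lengths)}) and be >= 1"
        )
    if any(ln < 1 for ln in exon_lengths):
        raise SpecError("exon lengths must be >= 1")
    total = sum(exon_lengths)
    if total % 3 != 0:
        raise SpecError(f"CDS length {total} is not a multiple of 3")
    exons = []
    pos = 1
    for ln in exon_lengths:
        exons.append((pos, pos + ln - 1))
        pos += ln + intron_length
    return TranscriptModel(
        gene=gene,
        exons=tuple(exons),
        cds_start=1,
        cds_end=total,
        strand="+",
    )
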