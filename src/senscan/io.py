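"""Readers and writers for variant tables, transcript models, curves and regions.

Three tabular variant dialects are supported:

``generic_csv``
    Columns ``gene, hgvs_p, significance, het, hom, hemi, sex`` (only
    ``hgvs_p`` is required; ``sex`` holds ``M``/``F`` per record, or use
    explicit ``n_male``/``n_female`` count columns).
``clinvar_summary``
    ClinVar variant_summary-style TSV with ``Name``, ``GeneSymbol`` and
    ``ClinicalSignificance`` columns; the protein change is extracted from
    the ``(p.…)`` suffix of ``Name``.
``gnomad_export``
    gnomAD CSV export with a ``Protein Consequence`` column and optional
    ``Allele Count`` / ``Homozygote Count`` / ``Hemizygote Count`` columns.

Residue coordinates are 1-based closed everywhere except BED output, which
is 0-based half-open (residue ``r`` maps to ``[r-1, r)``).
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd

from ._errors import RangeError, SchemaError, TranscriptValidationError
from .variant_model import (
    ProteinVariant,
    SourceLabel,
    ZygosityCounts,
    dedupe_variants,
    parse_hgvs_p,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VariantTable",
    "TranscriptModel",
    "read_variant_table",
    "read_transcript",
    "write_regions_bed",
    "read_regions_bed",
    "write_curve_tsv",
]


@dataclass
class VariantTable:
    """A list of protein variants from one database source."""

    records: list[ProteinVariant]
    source: SourceLabel
    provenance: str = ""

    def __post_init__(self) -> None:
        for r in self.records:
            if r.source is not None and r.source is not self.source:
                raise ValueError(
                    f"record {r.raw_hgvs} has source {r.source}, table declares {self.source}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinVariant]:
        return iter(self.records)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of a single (MANE-style) transcript.

    ``exons`` are genomic 1-based closed intervals in 5'→3' transcript
    order (ascending for ``+`` strand, descending for ``-``).
    ``cds_start``/``cds_end`` are 1-based positions in spliced-transcript
    coordinates; the CDS includes the stop codon, so the protein length is
    one codon less than ``cds length / 3``.
    """

    gene: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise TranscriptValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise TranscriptValidationError("transcript must have at least one exon")
        for s, e in self.exons:
            if s > e:
                raise TranscriptValidationError(f"exon interval inverted: ({s}, {e})")
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise TranscriptValidationError("exons are not ordered 5'->3' for the declared strand")
        # non-overlap check in genomic space
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise TranscriptValidationError(f"exons overlap: ({s1},{e1}) and ({s2},{e2})")
        if not (1 <= self.cds_start <= self.cds_end <= self.transcript_length):
            raise TranscriptValidationError(
                f"CDS [{self.cds_start}, {self.cds_end}] outside transcript "
                f"of length {self.transcript_length}"
            )
        if self.cds_length % 3 != 0:
            raise TranscriptValidationError(
                f"CDS length {self.cds_length} is not a multiple of 3"
            )

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def protein_length(self) -> int:
        """Residues encoded, excluding the stop codon."""
        return self.cds_length // 3 - 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_of_transcript_position(self, t: int) -> int:
        """1-based exon index containing spliced-transcript position ``t``."""
        if not (1 <= t <= self.transcript_length):
            raise RangeError(f"transcript position {t} outside [1, {self.transcript_length}]")
        cum = 0
        for i, ln in enumerate(self.exon_lengths, start=1):
            cum += ln
            if t <= cum:
                return i
        raise AssertionError("unreachable")

    def exon_of_cds_position(self, nt: int) -> int:
        """1-based exon index containing CDS nucleotide ``nt`` (1-based)."""
        if not (1 <= nt <= self.cds_length):
            raise RangeError(f"CDS position {nt} outside [1, {self.cds_length}]")
        return self.exon_of_transcript_position(self.cds_start + nt - 1)

    def cds_codon_range_in_exon(self, exon_index: int) -> Optional[tuple[int, int]]:
        """Residues whose codon *starts* in the given exon, or None.

        Only residues (not the stop codon) are reported; used for placing
        synthetic truncating variants exon by exon.
        """
        if not (1 <= exon_index <= self.n_exons):
            raise RangeError(f"exon index {exon_index} outside [1, {self.n_exons}]")
        cum = [0]
        for ln in self.exon_lengths:
            cum.append(cum[-1] + ln)
        # transcript interval of this exon intersected with the CDS
        lo = max(cum[exon_index - 1] + 1, self.cds_start)
        hi = min(cum[exon_index], self.cds_end)
        if lo > hi:
            return None
        # CDS-relative nucleotides; codon r occupies nts 3(r-1)+1 .. 3r.
        # Report codons whose first nucleotide lies within this exon.
        nt_lo, nt_hi = lo - self.cds_start + 1, hi - self.cds_start + 1
        first = -(-(nt_lo - 1) // 3) + 1  # smallest r with 3(r-1)+1 >= nt_lo
        last = (nt_hi - 1) // 3 + 1  # largest r with 3(r-1)+1 <= nt_hi
        first = max(first, 1)
        last = min(last, self.protein_length)
        if first > last:
            return None
        return (first, last)


# ---------------------------------------------------------------------------
# variant tables

_PAREN_P_RE = re.compile(r"\((p\.[^)\s]+)\)")

_DIALECTS = ("generic_csv", "clinvar_summary", "gnomad_export")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _zygosity_from_row(row: pd.Series) -> Optional[ZygosityCounts]:
    def geti(*names: str) -> int:
        for n in names:
            if n in row.index and pd.notna(row[n]) and str(row[n]).strip() != "":
                return int(row[n])
        return 0

    het = geti("het", "Allele Count")  # gnomAD allele count stands in for het+hom*2
    hom = geti("hom", "Homozygote Count")
    hemi = geti("hemi", "Hemizygote Count")
    n_f = geti("n_female")
    n_m = geti("n_male")
    sex = str(row.get("sex", "") or "").strip().upper()
    if sex == "F":
        n_f += 1
    elif sex == "M":
        n_m += 1
    if het or hom or hemi or n_f or n_m:
        if "Allele Count" in row.index:
            # gnomAD reports alleles; carriers counted as het = AC - 2*hom - hemi
            het = max(het - 2 * hom - hemi, 0)
        return ZygosityCounts(het=het, hom=hom, hemi=hemi, n_female=n_f, n_male=n_m)
    return None


def read_variant_table(
    path,
    dialect: str = "generic_csv",
    gene: Optional[str] = None,
    source: SourceLabel = SourceLabel.CLINICAL,
    significance_allowlist: Optional[Sequence[str]] = None,
) -> VariantTable:
    """Read, parse, classify and deduplicate a variant export file.

    Rows whose notation fails HGVS parsing are logged and skipped, with a
    summary count; a file with zero parseable rows yields an empty table and
    a warning, not an error.  By default no clinical-significance filter is
    applied; pass ``significance_allowlist`` to keep only listed classes.
    Unknown columns are ignored.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    sep = "\t" if dialect == "clinvar_summary" or path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str).rename(columns=lambda c: c.strip())

    if dialect == "generic_csv":
        _require_columns(df, ["hgvs_p"], path)
        hgvs_col, gene_col, sig_col = "hgvs_p", "gene", "significance"
    elif dialect == "clinvar_summary":
        _require_columns(df, ["Name", "GeneSymbol"], path)
        hgvs_col, gene_col, sig_col = "Name", "GeneSymbol", "ClinicalSignificance"
    else:  # gnomad_export
        _require_columns(df, ["Protein Consequence"], path)
        hgvs_col, gene_col, sig_col = "Protein Consequence", "gene", None

    records: list[ProteinVariant] = []
    n_failed = 0
    for _, row in df.iterrows():
        raw = row.get(hgvs_col)
        if pd.isna(raw) or str(raw).strip() == "":
            n_failed += 1
            continue
        raw = str(raw).strip()
        row_gene = str(row[gene_col]).strip() if gene_col in df.columns and pd.notna(row.get(gene_col)) else ""
        if gene and row_gene and row_gene != gene:
            continue
        if dialect == "clinvar_summary":
            m = _PAREN_P_RE.search(raw)
            if m is None:
                n_failed += 1
                logger.warning("%s: no (p.…) protein change in Name %r; row skipped", path, raw)
                continue
            raw = m.group(1)
        sig = None
        if sig_col and sig_col in df.columns and pd.notna(row.get(sig_col)):
            sig = str(row[sig_col]).strip()
        if significance_allowlist is not None and (
            sig is None or sig.lower() not in {s.lower() for s in significance_allowlist}
        ):
            continue
        try:
            v = parse_hgvs_p(
                raw,
                gene=row_gene or (gene or ""),
                source=source,
                significance=sig,
                zygosity=_zygosity_from_row(row),
            )
        except Exception as exc:  # parse failures are skipped, never fatal
            n_failed += 1
            logger.warning("%s: skipping unparseable row %r (%s)", path, raw, exc)
            continue
        records.append(v)

    if n_failed:
        logger.info("%s: %d row(s) skipped as unparseable", path, n_failed)
    if not records:
        warnings.warn(f"{path}: no parseable variant rows", stacklevel=2)
    return VariantTable(
        records=dedupe_variants(records),
        source=source,
        provenance=f"{path.name} dialect={dialect}",
    )


# ---------------------------------------------------------------------------
# transcripts

def _transcript_from_exons_cds(
    gene: str,
    exons_genomic: list[tuple[int, int]],
    cds_genomic: tuple[int, int],
    strand: str,
) -> TranscriptModel:
    """Build a model from genomic exon intervals and a genomic CDS span."""
    exons_sorted = sorted(exons_genomic)
    order = exons_sorted if strand == "+" else list(reversed(exons_sorted))

    def to_transcript(g: int) -> int:
        t = 0
        for s, e in order:
            if s <= g <= e:
                return t + (g - s + 1 if strand == "+" else e - g + 1)
            t += e - s + 1
        raise TranscriptValidationError(f"genomic position {g} falls outside every exon")

    g5, g3 = (cds_genomic if strand == "+" else (cds_genomic[1], cds_genomic[0]))
    return TranscriptModel(
        gene=gene,
        exons=tuple(order),
        cds_start=to_transcript(g5),
        cds_end=to_transcript(g3),
        strand=strand,
    )


def read_transcript(path, format: Optional[str] = None) -> TranscriptModel:
    """Read a single-transcript annotation (GFF3 or a simple JSON exon table).

    The JSON form is ``{"gene", "strand", "exons": [[start, end], …],
    "cds_start", "cds_end"}`` with exons as genomic intervals and the CDS in
    spliced-transcript coordinates.  The GFF3 form takes ``exon`` and ``CDS``
    features of one transcript; minus-strand annotations are normalized to
    the same internal plus-strand CDS space.
    """
    path = Path(path)
    if format is None:
        format = "exon_json" if path.suffix.lower() == ".json" else "gff3"
    if format == "exon_json":
        data = json.loads(path.read_text())
        return TranscriptModel(
            gene=data.get("gene", path.stem),
            exons=tuple((int(s), int(e)) for s, e in data["exons"]),
            cds_start=int(data["cds_start"]),
            cds_end=int(data["cds_end"]),
            strand=data.get("strand", "+"),
        )
    if format != "gff3":
        raise ValueError(f"unknown transcript format {format!r}")

    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    exons = [(f.start, f.end, f.strand) for f in db.features_of_type("exon")]
    cds = [(f.start, f.end) for f in db.features_of_type("CDS")]
    if not exons:
        raise TranscriptValidationError(f"{path}: no exon features")
    if not cds:
        raise TranscriptValidationError(f"{path}: no CDS features")
    strand = exons[0][2] or "+"
    gene = path.stem
    for ftype in ("gene", "mRNA", "transcript"):
        feats = list(db.features_of_type(ftype))
        if feats:
            attrs = feats[0].attributes
            for key in ("gene_name", "Name", "gene", "ID"):
                if key in attrs:
                    gene = attrs[key][0]
                    break
            break
    cds_genomic = (min(s for s, _ in cds), max(e for _, e in cds))
    return _transcript_from_exons_cds(gene, [(s, e) for s, e, _ in exons], cds_genomic, strand)


# ---------------------------------------------------------------------------
# curve / region output

def write_regions_bed(regions, protein_length: int, path, header_comments: Sequence[str] = ()) -> None:
    """Write called regions as BED (0-based half-open residue coordinates).

    A 1-based closed region ``[s, e]`` becomes the BED interval
    ``s-1 .. e``.  The chrom column carries the gene symbol (or ``region``
    when a region has no gene attribute).
    """
    lines = [f"# {c}" for c in header_comments]
    for i, r in enumerate(regions, start=1):
        start, end = r.start, r.end
        if not (1 <= start <= end <= protein_length):
            raise RangeError(
                f"region [{start}, {end}] outside protein [1, {protein_length}]"
            )
        name = getattr(r, "gene", "") or "region"
        score = getattr(r, "min_delta", 0.0)
        lines.append(f"{name}\t{start - 1}\t{end}\tsensitive_region_{i}\t{score:.6g}\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def read_regions_bed(path) -> list[tuple[int, int]]:
    """Read a regions BED back to 1-based closed residue intervals."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        out.append((int(fields[1]) + 1, int(fields[2])))
    return out


def write_curve_tsv(profile, path, header_comments: Sequence[str] = ()) -> None:
    """Write a per-residue curve table.

    Columns: residue, clinical_raw, population_raw, clinical_norm,
    population_norm, delta, edge_flag, masked_flag.  Output is
    deterministic (fixed float formatting) so identical inputs produce
    byte-identical files.
    """
    import numpy as np

    L = len(profile.delta)
    cols = {
        "residue": np.arange(1, L + 1),
        "clinical_raw": profile.clinical_raw,
        "population_raw": profile.population_raw,
        "clinical_norm": profile.clinical_norm,
        "population_norm": profile.population_norm,
        "delta": profile.delta,
        "edge_flag": profile.edge_flag.astype(int),
        "masked_flag": profile.masked.astype(int),
    }
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
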