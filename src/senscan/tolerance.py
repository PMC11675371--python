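"""Smoothed per-residue missense-tolerance curves and sensitive-region calling.

The method compares the positional density of missense variants from a
clinical database (ClinVar) against a population database (gnomAD) along
the span of one protein:

1. Each deduplicated missense variant contributes a Gaussian bump centred
   at its residue, truncated to a fixed odd window (default 31 residues)
   and normalized to unit mass — a rolling weighted average of nearby
   variant counts, unweighted by carrier numbers.
2. Near the protein termini part of the window falls outside ``[1, L]``
   and would contribute false zeros; each residue's value is divided by
   the fraction of the kernel's mass that falls in range (edge
   correction).  Edge residues are flagged, not dropped: values there are
   upweighted and should be interpreted with caution.
3. Both curves are rescaled so their maxima coincide at 1.
4. The per-residue difference ``delta = population − clinical`` collapses
   the pair into one profile.  Negative delta marks residues relatively
   enriched in clinical variants — "sensitive regions"; positive delta
   marks well-tolerated spans.

Maximal runs of strictly negative delta are reported as
:class:`SensitiveRegion` intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.signal.windows import gaussian as _gaussian_window

from ._errors import ConfigError, RangeError
from .io import VariantTable
from .variant_model import ConsequenceClass, ProteinVariant, SourceLabel, dedupe_variants

__all__ = [
    "KernelConfig",
    "ToleranceCurve",
    "SensitiveRegion",
    "DeltaProfile",
    "gaussian_window_kernel",
    "density_curve",
    "normalize_pair",
    "delta_profile",
    "call_sensitive_regions",
    "tolerance_profile",
]

Intervals = Sequence[tuple[int, int]]
#: Mask spec: plain intervals apply to both sources; a mapping keyed by
#: "clinical"/"population" applies per source.
MaskSpec = Union[Intervals, Mapping[str, Intervals], None]


@dataclass(frozen=True)
class KernelConfig:
    """Smoothing-kernel settings.

    ``window`` is the odd residue count of the truncated Gaussian (31 by
    default); ``sigma`` defaults to ``(window - 1) / 6`` so the window
    spans ±3σ and captures ≈99.7% of the untruncated Gaussian mass.
    """

    window: int = 31
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigError(f"window must be odd and >= 1, got {self.window}")
        if self.sigma is not None and self.sigma <= 0:
            raise ConfigError(f"sigma must be > 0, got {self.sigma}")

    @property
    def effective_sigma(self) -> float:
        if self.sigma is not None:
            return self.sigma
        if self.window == 1:
            return 1.0  # degenerate; kernel is [1.0] regardless
        return (self.window - 1) / 6

    @property
    def half_width(self) -> int:
        return (self.window - 1) // 2


@dataclass
class ToleranceCurve:
    """Per-residue smoothed, edge-corrected variant density for one source."""

    gene: str
    source: SourceLabel
    values: np.ndarray
    edge_flag: np.ndarray
    masked: np.ndarray
    positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SensitiveRegion:
    """A maximal run of strictly negative delta (1-based closed interval)."""

    start: int
    end: int
    min_delta: float
    mean_delta: float
    n_clinical: int
    n_population: int
    low_confidence: bool = False
    gene: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass
class DeltaProfile:
    """The collapsed population-minus-clinical profile for one gene."""

    gene: str
    delta: np.ndarray
    clinical_norm: np.ndarray
    population_norm: np.ndarray
    clinical_raw: np.ndarray
    population_raw: np.ndarray
    edge_flag: np.ndarray
    masked: np.ndarray
    clinical_positions: np.ndarray
    population_positions: np.ndarray
    regions: list[SensitiveRegion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.delta)


def gaussian_window_kernel(config: KernelConfig) -> np.ndarray:
    """Truncated, unit-sum Gaussian weight vector of length ``config.window``.

    Symmetric and unimodal with its maximum at the centre tap; truncation
    at the window edge is followed by renormalization so the weights sum
    to 1, which makes the edge correction (division by in-range mass)
    well defined.
    """
    w = _gaussian_window(config.window, std=config.effective_sigma, sym=True)
    return w / w.sum()


def _resolve_mask(mask: MaskSpec, source: SourceLabel) -> list[tuple[int, int]]:
    if mask is None:
        return []
    if isinstance(mask, Mapping):
        return list(mask.get(source.value, ()))
    return list(mask)


def _mask_vector(intervals: Intervals, length: int) -> np.ndarray:
    out = np.zeros(length, dtype=bool)
    for s, e in intervals:
        if s > e:
            raise RangeError(f"inverted mask interval [{s}, {e}]")
        out[max(s, 1) - 1 : min(e, length)] = True
    return out


def density_curve(
    variants: VariantTable | Sequence[ProteinVariant],
    protein_length: int,
    config: KernelConfig = KernelConfig(),
    mask: Optional[Intervals] = None,
    consequence: Optional[ConsequenceClass] = ConsequenceClass.MISSENSE,
) -> ToleranceCurve:
    """Smoothed, edge-corrected per-residue density of one variant set.

    Input variants are deduplicated and (by default) filtered to missense.
    ``raw[i]`` sums the kernel weight each variant position contributes to
    residue ``i`` (taps beyond the window contribute nothing); the value is
    then divided by the kernel mass falling inside ``[1, L]`` at ``i``, so
    interior residues are unchanged (mass 1) and terminal residues are
    rescaled rather than rolled off.  Masked intervals drop their variants
    and flag their residues.  Variants beyond ``protein_length`` are
    excluded with a warning.
    """
    import warnings

    if protein_length < 1:
        raise RangeError(f"protein_length must be >= 1, got {protein_length}")
    records = list(variants.records if isinstance(variants, VariantTable) else variants)
    source = variants.source if isinstance(variants, VariantTable) else SourceLabel.CLINICAL
    gene = records[0].gene if records else ""

    deduped = dedupe_variants(records)
    if consequence is not None:
        deduped = [v for v in deduped if v.consequence is consequence]

    out_of_range = [v for v in deduped if v.position > protein_length]
    if out_of_range:
        warnings.warn(
            f"{len(out_of_range)} variant(s) beyond protein length {protein_length} "
            f"excluded (e.g. {out_of_range[0].raw_hgvs})",
            stacklevel=2,
        )
        deduped = [v for v in deduped if v.position <= protein_length]

    mask_intervals = list(mask or [])
    masked_vec = _mask_vector(mask_intervals, protein_length)
    deduped = [v for v in deduped if not masked_vec[v.position - 1]]

    counts = np.zeros(protein_length, dtype=float)
    for v in deduped:
        counts[v.position - 1] += 1.0

    kernel = gaussian_window_kernel(config)
    raw = np.convolve(counts, kernel, mode="same")
    in_range_mass = np.convolve(np.ones(protein_length), kernel, mode="same")
    values = raw / in_range_mass

    hw = config.half_width
    edge = np.zeros(protein_length, dtype=bool)
    if hw > 0:
        edge[: min(hw, protein_length)] = True
        edge[max(protein_length - hw, 0) :] = True

    return ToleranceCurve(
        gene=gene,
        source=source,
        values=values,
        edge_flag=edge,
        masked=masked_vec,
        positions=np.array(sorted(v.position for v in deduped), dtype=int),
    )


def normalize_pair(
    clinical: ToleranceCurve, population: ToleranceCurve
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each curve so its maximum is 1; all-zero curves pass through.

    Equal-maximum scaling puts the two databases — whose absolute variant
    counts differ by orders of magnitude — on a comparable footing.
    """
    if len(clinical) != len(population):
        raise ValueError(
            f"curve length mismatch: {len(clinical)} vs {len(population)}"
        )

    def norm(values: np.ndarray) -> np.ndarray:
        m = values.max(initial=0.0)
        return values / m if m > 0 else values.copy()

    return norm(clinical.values), norm(population.values)


def delta_profile(
    clinical_norm: np.ndarray, population_norm: np.ndarray
) -> np.ndarray:
    """Pointwise ``population − clinical`` difference of the normalized curves.

    Negative values mark residues relatively enriched in clinical
    (disease-associated) variants.
    """
    clinical_norm = np.asarray(clinical_norm, dtype=float)
    population_norm = np.asarray(population_norm, dtype=float)
    if clinical_norm.shape != population_norm.shape:
        raise ValueError(
            f"shape mismatch: {clinical_norm.shape} vs {population_norm.shape}"
        )
    return population_norm - clinical_norm


def call_sensitive_regions(
    profile: DeltaProfile,
    min_length: int = 1,
    ignore_edges: bool = False,
) -> list[SensitiveRegion]:
    """Maximal runs of strictly negative delta, sorted by start.

    Runs shorter than ``min_length`` are dropped.  With ``ignore_edges``,
    a region lying entirely within edge-flagged residues is annotated
    ``low_confidence`` (values there rest on upweighted partial windows)
    but is never removed.
    """
    delta = profile.delta
    neg = delta < 0
    regions: list[SensitiveRegion] = []
    i = 0
    L = len(delta)
    while i < L:
        if not neg[i]:
            i += 1
            continue
        j = i
        while j + 1 < L and neg[j + 1]:
            j += 1
        start, end = i + 1, j + 1  # 1-based closed
        if end - start + 1 >= min_length:
            seg = delta[i : j + 1]
            n_clin = int(np.sum((profile.clinical_positions >= start) & (profile.clinical_positions <= end)))
            n_pop = int(np.sum((profile.population_positions >= start) & (profile.population_positions <= end)))
            low_conf = bool(ignore_edges and profile.edge_flag[i : j + 1].all())
            regions.append(
                SensitiveRegion(
                    start=start,
                    end=end,
                    min_delta=float(seg.min()),
                    mean_delta=float(seg.mean()),
                    n_clinical=n_clin,
                    n_population=n_pop,
                    low_confidence=low_conf,
                    gene=profile.gene,
                )
            )
        i = j + 1
    return regions


def tolerance_profile(
    clinical: VariantTable,
    population: VariantTable,
    protein_length: int,
    config: KernelConfig = KernelConfig(),
    mask: MaskSpec = None,
    min_region_length: int = 1,
    ignore_edges: bool = False,
    gene: str = "",
) -> DeltaProfile:
    """Full pipeline: two density curves → normalize → delta → regions.

    Deterministic for fixed inputs.  ``mask`` may be a plain interval list
    (applied to both sources) or a mapping with ``"clinical"`` /
    ``"population"`` keys for per-source masking (e.g. excluding
    population variants across an alternatively spliced insert).
    """
    c_curve = density_curve(
        clinical, protein_length, config, mask=_resolve_mask(mask, SourceLabel.CLINICAL)
    )
    p_curve = density_curve(
        population, protein_length, config, mask=_resolve_mask(mask, SourceLabel.POPULATION)
    )
    c_norm, p_norm = normalize_pair(c_curve, p_curve)
    delta = delta_profile(c_norm, p_norm)
    profile = DeltaProfile(
        gene=gene or c_curve.gene or p_curve.gene,
        delta=delta,
        clinical_norm=c_norm,
        population_norm=p_norm,
        clinical_raw=c_curve.values,
        population_raw=p_curve.values,
        edge_flag=c_curve.edge_flag,
        masked=c_curve.masked | p_curve.masked,
        clinical_positions=c_curve.positions,
        population_positions=p_curve.positions,
    )
    profile.regions = call_sensitive_regions(
        profile, min_length=min_region_length, ignore_edges=ignore_edges
    )
    return profile
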