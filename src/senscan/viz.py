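"""Figure rendering: tolerance-curve overlays with a delta panel, and
exon maps with truncation lollipops.

Conventions follow the field's usual encodings: clinical (ClinVar) in
red, population (gnomAD) in blue (curves) or black (exon-map marks);
sensitive regions shaded red in the delta panel; masked intervals shaded
pink; an optional protein domain track beneath the curves.

All numeric placement logic is pure (:func:`exon_map_layout`,
:func:`mark_x`) and unit-testable without drawing; the plotting
functions only draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from ._errors import ConfigError, RangeError
from .io import TranscriptModel
from .tolerance import DeltaProfile
from .truncation import TruncationCall
from .variant_model import SourceLabel

__all__ = [
    "DomainTrack",
    "exon_map_layout",
    "mark_x",
    "plot_profile",
    "plot_exon_map",
]

CLINICAL_COLOR = "#c0392b"  # red
POPULATION_COLOR = "#2e6da4"  # blue
MASK_COLOR = "#f8c8dc"  # pink
REGION_COLOR = "#e74c3c"


@dataclass(frozen=True)
class DomainTrack:
    """Labelled protein features drawn beneath a curve figure.

    ``features`` is a list of ``(label, start, end, color)`` with 1-based
    closed residue intervals (signal peptide, transmembrane span, binding
    domains, …).
    """

    features: tuple[tuple[str, int, int, str], ...]
    protein_length: int

    def __post_init__(self) -> None:
        for label, s, e, _ in self.features:
            if not (1 <= s <= e <= self.protein_length):
                raise RangeError(
                    f"domain {label!r} [{s}, {e}] outside [1, {self.protein_length}]"
                )

    @classmethod
    def from_csv(cls, path, protein_length: int) -> "DomainTrack":
        """Read a ``label,start,end,color`` CSV (header optional)."""
        feats = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.lower().startswith("label,"):
                continue
            label, s, e, color = [f.strip() for f in line.split(",")]
            feats.append((label, int(s), int(e), color))
        return cls(features=tuple(feats), protein_length=protein_length)


# ---------------------------------------------------------------------------
# exon-map placement (pure)

def exon_map_layout(
    transcript: TranscriptModel, intron_scale: float
) -> list[tuple[float, float]]:
    """x-extents of each exon box with introns shrunk by ``intron_scale``.

    Exons keep true scale; each intron's drawn width is its genomic length
    divided by ``intron_scale`` (a single per-gene ratio).  Returns one
    ``(x_start, x_end)`` pair per exon in 5'→3' order, starting at 0.
    """
    if intron_scale <= 0:
        raise ConfigError(f"intron_scale must be > 0, got {intron_scale}")
    layout = []
    x = 0.0
    prev_end: Optional[int] = None
    for s, e in transcript.exons:
        lo, hi = min(s, e), max(s, e)
        if prev_end is not None:
            intron = abs(lo - prev_end) - 1 if transcript.strand == "+" else abs(prev_end - hi) - 1
            x += max(intron, 0) / intron_scale
        width = hi - lo + 1
        layout.append((x, x + width))
        x += width
        prev_end = hi if transcript.strand == "+" else lo
    return layout


def mark_x(
    transcript: TranscriptModel,
    layout: Sequence[tuple[float, float]],
    cds_position: int,
) -> float:
    """Drawn x-coordinate of a CDS nucleotide under an exon-map layout."""
    t = transcript.cds_start + cds_position - 1
    exon = transcript.exon_of_transcript_position(t)
    offset_in_exon = t - sum(transcript.exon_lengths[: exon - 1]) - 1
    x0, _ = layout[exon - 1]
    return x0 + offset_in_exon + 0.5


# ---------------------------------------------------------------------------
# figures

def plot_profile(
    profile: DeltaProfile,
    path,
    track: Optional[DomainTrack] = None,
    title: Optional[str] = None,
) -> None:
    """Two-panel figure: curve overlay (top) and delta with regions (bottom).

    Clinical curve red, population blue; sensitive regions shaded red in
    the delta panel; masked intervals shaded pink in both panels; domain
    track appended beneath when given.  Output format follows the file
    extension (SVG/PNG).
    """
    import numpy as np

    L = len(profile)
    residues = np.arange(1, L + 1)
    nrows = 3 if track is not None else 2
    heights = [3, 2] + ([0.5] if track is not None else [])
    fig, axes = plt.subplots(
        nrows, 1, sharex=True, figsize=(10, sum(heights) + 1),
        gridspec_kw={"height_ratios": heights},
    )
    ax_curves, ax_delta = axes[0], axes[1]

    ax_curves.plot(residues, profile.clinical_norm, color=CLINICAL_COLOR, label="clinical (ClinVar)")
    ax_curves.plot(residues, profile.population_norm, color=POPULATION_COLOR, label="population (gnomAD)")
    ax_curves.set_ylabel("normalized tolerance value")
    ax_curves.legend(loc="upper right", frameon=False)

    ax_delta.plot(residues, profile.delta, color="black", linewidth=1)
    ax_delta.axhline(0.0, color="gray", linewidth=0.5)
    for region in profile.regions:
        ax_delta.axvspan(region.start, region.end, color=REGION_COLOR, alpha=0.25)
    ax_delta.set_ylabel("delta (pop − clin)")
    ax_delta.set_xlabel("residue")

    masked_runs = _runs(profile.masked)
    for ax in (ax_curves, ax_delta):
        for s, e in masked_runs:
            ax.axvspan(s, e, color=MASK_COLOR, alpha=0.6)

    if track is not None:
        ax_track = axes[2]
        for label, s, e, color in track.features:
            ax_track.axvspan(s, e, color=color)
            ax_track.text((s + e) / 2, 0.5, label, ha="center", va="center", fontsize=7)
        ax_track.set_ylim(0, 1)
        ax_track.set_yticks([])

    if title:
        fig.suptitle(title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def _runs(flags) -> list[tuple[int, int]]:
    """1-based closed runs of True in a boolean vector."""
    runs, i, L = [], 0, len(flags)
    while i < L:
        if flags[i]:
            j = i
            while j + 1 < L and flags[j + 1]:
                j += 1
            runs.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return runs


def plot_exon_map(
    transcript: TranscriptModel,
    calls: Sequence[TruncationCall],
    path,
    intron_scale: float = 1.0,
    title: Optional[str] = None,
) -> None:
    """Exon boxes to scale with truncation lollipops.

    Population marks sit above the exon track (black), clinical marks
    below (red), each at its marked nucleotide position.  Marks stacking
    at one position are jittered vertically.  Introns are shrunk by the
    single per-gene ``intron_scale`` ratio.
    """
    layout = exon_map_layout(transcript, intron_scale)
    fig, ax = plt.subplots(figsize=(10, 2.5))

    for x0, x1 in layout:
        ax.add_patch(plt.Rectangle((x0, -0.15), x1 - x0, 0.3, facecolor="#bcd2e8", edgecolor="black"))

    seen: dict[tuple[float, bool], int] = {}
    for call in calls:
        x = mark_x(transcript, layout, call.cds_position)
        above = call.variant.source is not SourceLabel.CLINICAL
        stack = seen.get((x, above), 0)
        seen[(x, above)] = stack + 1
        jitter = 0.12 * stack
        if above:
            y0, y1, color = 0.15, 0.55 + jitter, "black"
        else:
            y0, y1, color = -0.15, -0.55 - jitter, CLINICAL_COLOR
        ax.plot([x, x], [y0, y1], color=color, linewidth=1)
        ax.plot([x], [y1], marker="o", color=color, markersize=4)

    total_width = layout[-1][1]
    ax.set_xlim(-0.01 * total_width, 1.01 * total_width)
    ax.set_ylim(-1.2, 1.2)
    ax.set_yticks([])
    ax.set_xlabel("nucleotide (introns not to scale)" if intron_scale != 1 else "nucleotide")
    if title:
        ax.set_title(title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
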