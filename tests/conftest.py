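"""Shared fixtures and the independent brute-force smoothing oracle."""

from __future__ import annotations

import math

import pytest
from hypothesis import settings

from senscan.io import TranscriptModel, VariantTable
from senscan.variant_model import ConsequenceClass, ProteinVariant, SourceLabel

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def brute_force_curve(positions, protein_length, window=31, sigma=None):
    """Direct O(L·W) per-residue summation with explicit Gaussian weights.

    Independent of the package's convolution path: weights, truncation,
    normalization and the in-range-mass edge correction are all recomputed
    from first principles here.
    """
    if sigma is None:
        sigma = (window - 1) / 6 if window > 1 else 1.0
    hw = (window - 1) // 2
    weights = [math.exp(-0.5 * (k / sigma) ** 2) for k in range(-hw, hw + 1)]
    total = sum(weights)
    weights = [w / total for w in weights]

    values = []
    for i in range(1, protein_length + 1):
        raw = 0.0
        mass = 0.0
        for k in range(-hw, hw + 1):
            tap = i + k
            if 1 <= tap <= protein_length:
                mass += weights[k + hw]
        for p in positions:
            k = i - p
            if -hw <= k <= hw:
                raw += weights[k + hw]
        values.append(raw / mass)
    return values


def make_missense(position, gene="GENE", ref="A", alt="C", source=None):
    return ProteinVariant(
        gene=gene, position=position, ref_aa=ref, alt_aa=alt,
        consequence=ConsequenceClass.MISSENSE, source=source,
        raw_hgvs=f"p.{ref}{position}{alt}",
    )


def table_at(positions, source=SourceLabel.CLINICAL, gene="GENE"):
    """A VariantTable with one A→C missense per listed position."""
    return VariantTable(
        records=[make_missense(p, gene=gene, source=source) for p in positions],
        source=source,
    )


@pytest.fixture
def toy_transcript():
    """3 exons of 300/300/402 CDS nt: a 333-residue protein."""
    return TranscriptModel(
        gene="TOY",
        exons=((1, 300), (401, 700), (801, 1202)),
        cds_start=1,
        cds_end=1002,
        strand="+",
    )
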