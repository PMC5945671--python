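"""Construction of 96-channel mutational catalogues from somatic variant calls.

Single-base substitutions are classified by the pyrimidine-strand substitution
and the two flanking reference bases, pooled per sample into a 96 x m count
matrix, optionally rescaled for the trinucleotide content of the sequencing
target relative to the whole genome. Small insertions/deletions are counted
per sample within a configurable length band.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BASES",
    "SUBSTITUTIONS",
    "CHANNELS",
    "CHANNEL_INDEX",
    "PYRIMIDINE_TRIPLETS",
    "FUNCTIONAL_CLASSES",
    "VariantCall",
    "StrandBiasReport",
    "classify_snv",
    "channel_triplet",
    "strand_bias_filter",
    "functional_filter",
    "build_catalogue",
    "triplet_correction",
    "count_small_indels",
]

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Substitution-major channel order: pyrimidine substitutions, then 5' base,
#: then 3' base, each in alphabetical order.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
CHANNEL_INDEX: Mapping[str, int] = {label: i for i, label in enumerate(CHANNELS)}

#: The 32 pyrimidine-centered trinucleotides, in the order of first appearance
#: in the channel list.
PYRIMIDINE_TRIPLETS: tuple[str, ...] = tuple(
    f"{five}{center}{three}"
    for center in "CT"
    for five in BASES
    for three in BASES
)

FUNCTIONAL_CLASSES = frozenset({"nonsynonymous", "splice_site", "stopgain", "stoploss"})
KNOWN_CLASSES = FUNCTIONAL_CLASSES | {"synonymous", "other"}


@dataclass
class VariantCall:
    """One somatic variant (SNV or indel) in one sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    context5: str | None = None
    context3: str | None = None
    alt_fwd: int | None = None
    alt_rev: int | None = None
    depth: int | None = None
    func_class: str | None = None
    gene: str | None = None

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    def channel(self) -> str:
        if not self.is_snv:
            raise ValueError(f"not an SNV: {self.ref}>{self.alt}")
        if self.context5 is None or self.context3 is None:
            raise ValueError(
                f"flanking context missing for {self.chrom}:{self.pos}; "
                "provide context in the input or a reference FASTA"
            )
        return classify_snv(self.ref, self.alt, self.context5, self.context3)


def _check_base(b: str) -> str:
    if not isinstance(b, str) or b.upper() not in _COMPLEMENT:
        raise ValueError(f"invalid base {b!r}; expected one of A, C, G, T")
    return b.upper()


def classify_snv(ref: str, alt: str, context5: str, context3: str) -> str:
    """Map an SNV plus flanking bases to its canonical 96-channel label.

    Purine-reference substitutions are reverse-complemented (ref, alt and both
    flanks, flanks swapped) so every channel has a pyrimidine reference base.
    """
    ref, alt = _check_base(ref), _check_base(alt)
    context5, context3 = _check_base(context5), _check_base(context3)
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context5, context3 = _COMPLEMENT[context3], _COMPLEMENT[context5]
    return f"{context5}[{ref}>{alt}]{context3}"


def channel_triplet(label: str) -> str:
    """Central pyrimidine trinucleotide of a channel label, e.g. A[C>A]A -> ACA."""
    return label[0] + label[2] + label[6]


@dataclass
class StrandBiasReport:
    """Per-channel pooled strand counts and the filtering outcome."""

    channel: str
    fwd: int
    rev: int
    pvalue: float
    biased: bool
    n_removed: int = 0


def strand_bias_filter(
    variants: Sequence[VariantCall],
    alpha: float = 0.05,
    min_pooled: int = 10,
    min_opposite: int = 2,
) -> tuple[list[VariantCall], list[StrandBiasReport]]:
    """Remove variants with weak opposite-strand support in strand-biased channels.

    For each 96-channel class, pooled alt-supporting read counts on the two
    sequencing strands are tested against a symmetric binomial; in channels
    called biased (two-sided p < ``alpha`` with at least ``min_pooled`` pooled
    reads), variants with fewer than ``min_opposite`` alt reads on the
    minority strand are dropped.
    """
    by_channel: dict[str, list[VariantCall]] = {}
    for v in variants:
        if v.alt_fwd is None or v.alt_rev is None:
            raise ValueError(
                f"per-strand alt counts missing for {v.chrom}:{v.pos}; "
                "cannot assess strand bias"
            )
        by_channel.setdefault(v.channel(), []).append(v)

    kept: list[VariantCall] = []
    reports: list[StrandBiasReport] = []
    for channel, group in by_channel.items():
        fwd = sum(v.alt_fwd for v in group)
        rev = sum(v.alt_rev for v in group)
        total = fwd + rev
        if total > 0:
            pvalue = stats.binomtest(fwd, total, 0.5).pvalue
        else:
            pvalue = 1.0
        biased = pvalue < alpha and total >= min_pooled
        report = StrandBiasReport(channel, fwd, rev, pvalue, biased)
        if biased:
            # opposite strand = the strand with the smaller pooled alt count
            opposite = "rev" if fwd >= rev else "fwd"
            for v in group:
                support = v.alt_rev if opposite == "rev" else v.alt_fwd
                if support < min_opposite:
                    report.n_removed += 1
                else:
                    kept.append(v)
        else:
            kept.extend(group)
        reports.append(report)
    return kept, reports


def functional_filter(variants: Iterable[VariantCall]) -> list[VariantCall]:
    """Retain nonsynonymous, splice-site, stop-gain and stop-loss variants."""
    out = []
    for v in variants:
        if v.func_class is None:
            raise ValueError(
                f"func_class missing for {v.chrom}:{v.pos}; refusing to keep "
                "an unclassified variant"
            )
        if v.func_class in FUNCTIONAL_CLASSES:
            out.append(v)
    return out


def build_catalogue(
    variants: Iterable[VariantCall], sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Count SNVs per channel and sample into a 96 x m catalogue."""
    sample_ids = list(sample_ids)
    col = {s: j for j, s in enumerate(sample_ids)}
    counts = np.zeros((96, len(sample_ids)))
    for v in variants:
        if v.sample_id not in col:
            raise KeyError(f"unknown sample_id {v.sample_id!r}")
        counts[CHANNEL_INDEX[v.channel()], col[v.sample_id]] += 1
    return pd.DataFrame(counts, index=list(CHANNELS), columns=sample_ids)


def triplet_correction(
    catalogue: pd.DataFrame,
    genome_freq: Mapping[str, float],
    target_freq: Mapping[str, float],
) -> pd.DataFrame:
    """Rescale channel counts for triplet content of the capture vs the genome.

    Each channel is multiplied by the ratio of relative genome frequency to
    relative target frequency of its central trinucleotide, then every column
    is rescaled to its original total so exposures stay in mutation-count
    units.
    """
    missing = [t for t in PYRIMIDINE_TRIPLETS if t not in genome_freq or t not in target_freq]
    if missing:
        raise ValueError(f"triplet frequencies missing for {missing}")
    g_sum = float(sum(genome_freq[t] for t in PYRIMIDINE_TRIPLETS))
    t_sum = float(sum(target_freq[t] for t in PYRIMIDINE_TRIPLETS))
    factors = np.empty(96)
    for i, label in enumerate(catalogue.index):
        trip = channel_triplet(label)
        if target_freq[trip] <= 0:
            if catalogue.iloc[i].sum() > 0:
                raise ValueError(f"target frequency of {trip} is zero but counts exist")
            factors[i] = 0.0
        else:
            factors[i] = (genome_freq[trip] / g_sum) / (target_freq[trip] / t_sum)
    scaled = catalogue.mul(factors, axis=0)
    orig_totals = catalogue.sum(axis=0)
    new_totals = scaled.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rescale = np.where(new_totals > 0, orig_totals / new_totals, 1.0)
    return scaled.mul(rescale, axis=1)


def count_small_indels(
    indels: Iterable[VariantCall],
    sample_ids: Sequence[str] | None = None,
    min_len: int = 2,
    max_len: int = 10,
) -> pd.Series:
    """Per-sample counts of indels with net length change in [min_len, max_len]."""
    counts: dict[str, int] = {s: 0 for s in (sample_ids or [])}
    for v in indels:
        counts.setdefault(v.sample_id, 0)
        if min_len <= v.indel_length <= max_len:
            counts[v.sample_id] += 1
    return pd.Series(counts, dtype=int).sort_index()


def enumerate_snv_contexts():
    """All 192 (ref, alt, 5', 3') combinations with ref != alt. Test helper."""
    for ref, alt, five, three in itertools.product(BASES, repeat=4):
        if ref != alt:
            yield ref, alt, five, three
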