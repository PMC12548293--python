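"""Somatic-variant filtering and SBS96/ID83 mutation-matrix classification.

Filtering applies fixed post-calling rules to tumor-normal variant calls:
total depth >= 10 in both tumor and normal, >= 3 variant-supporting reads in
the tumor and none in the normal, autosomes only (chromosomes X, Y and M
excluded), not present in dbSNP, and not shared by two or more tumors.
dbSNP membership and shared-tumor counts arrive as precomputed flags.

Single-base substitutions are classified into the standard 96 trinucleotide
channels using the pyrimidine convention: when the reference base is a
purine, the substitution and its immediate 5'/3' context are reverse-
complemented so every channel is keyed on C or T.  Small indels are
classified into the standard 83 channels: 1-bp events by base (T for A/T,
C for C/G) and homopolymer run length, longer events by tandem-repeat copy
number of the inserted/deleted unit, and deletions without a tandem copy by
the longest microhomology between the deleted sequence and its flanks.
Indels are left-aligned before classification.  For deletions the repeat
category counts the copies remaining besides the deleted one (0-5+); for
insertions it counts the copies already present in the reference (0-5+).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SomaticVariant",
    "FILTER_RULES",
    "filter_somatic",
    "classify_sbs96",
    "classify_id83",
    "left_align",
    "build_matrices",
    "SBS96_CLASSES",
    "ID83_CLASSES",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SomaticVariant:
    """One tumor-normal variant call with the read support and flags the
    downstream filters consume.  ``pos`` is 1-based (VCF convention); ``ref``
    and ``alt`` are VCF-style alleles (indels carry the anchor base)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    tumor_depth: int
    normal_depth: int
    tumor_alt_reads: int
    normal_alt_reads: int
    in_dbsnp: bool = False
    shared_tumor_count: int = 1

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")
        if self.tumor_alt_reads > self.tumor_depth or self.normal_alt_reads > self.normal_depth:
            raise ValueError("alt reads exceed depth")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def norm_chrom(self) -> str:
        c = self.chrom
        return c[3:] if c.lower().startswith("chr") else c


# rule name -> predicate returning True when the variant PASSES the rule
FILTER_RULES: "OrderedDict[str, callable]" = OrderedDict(
    [
        ("tumor_depth", lambda v: v.tumor_depth >= 10),
        ("normal_depth", lambda v: v.normal_depth >= 10),
        ("tumor_alt_reads", lambda v: v.tumor_alt_reads >= 3),
        ("normal_alt_reads", lambda v: v.normal_alt_reads == 0),
        ("autosome", lambda v: v.norm_chrom.upper() not in {"X", "Y", "M", "MT"}),
        ("dbsnp", lambda v: not v.in_dbsnp),
        ("shared_tumors", lambda v: v.shared_tumor_count < 2),
    ]
)


def filter_somatic(
    variants: Iterable[SomaticVariant],
) -> tuple[list[SomaticVariant], dict[str, int], list[SomaticVariant]]:
    """Apply all retention rules; returns (retained, tally, rejected).

    The tally counts rejections by the FIRST failed rule in the fixed rule
    order; the retained set itself is order-independent (a variant passes
    iff it passes every rule).
    """
    retained, rejected = [], []
    tally = {name: 0 for name in FILTER_RULES}
    for v in variants:
        for name, rule in FILTER_RULES.items():
            if not rule(v):
                tally[name] += 1
                rejected.append(v)
                break
        else:
            retained.append(v)
    return retained, tally, rejected


# ---------------------------------------------------------------------------
# SBS96
# ---------------------------------------------------------------------------

_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Fixed channel order: substitution-major, then 5' and 3' context alphabetical.
SBS96_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in _SUBS for five in _BASES for three in _BASES
)


def classify_sbs96(ref: str, alt: str, five_prime: str, three_prime: str) -> str:
    """Map one substitution with context to its 96-channel label.

    Purine references are reverse-complemented (together with the context)
    onto the pyrimidine strand, e.g. G>A with context T_T becomes A[C>T]A.

    Raises
    ------
    ValueError
        For non-SNV alleles or ambiguous (non-ACGT) context bases.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    tri = five_prime + ref + three_prime
    if any(b not in _BASES for b in tri + alt):
        raise ValueError(f"ambiguous base in context {tri!r} or alt {alt!r}")
    if ref in "AG":
        tri = _revcomp(tri)
        alt = alt.translate(_COMPLEMENT)
    label = f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"
    return label


def classify_sbs96_at(variant: SomaticVariant, reference: Mapping[str, str]) -> str:
    """Classify an SNV using the reference sequence for context (pos is 1-based)."""
    seq = reference[variant.chrom]
    i = variant.pos - 1
    if not 1 <= i <= len(seq) - 2:
        raise ValueError("variant too close to the sequence edge for trinucleotide context")
    if seq[i] != variant.ref:
        raise ValueError(f"reference mismatch at {variant.chrom}:{variant.pos}")
    return classify_sbs96(variant.ref, variant.alt, seq[i - 1], seq[i + 1])


# ---------------------------------------------------------------------------
# ID83
# ---------------------------------------------------------------------------


def _id83_channels() -> tuple[str, ...]:
    chans: list[str] = []
    for base in ("C", "T"):
        chans += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in ("C", "T"):
        chans += [f"1:Ins:{base}:{i}" for i in range(6)]
    for size in (2, 3, 4, 5):
        chans += [f"{size}:Del:R:{i}" for i in range(6)]
    for size in (2, 3, 4, 5):
        chans += [f"{size}:Ins:R:{i}" for i in range(6)]
    chans += ["2:Del:M:1"]
    chans += [f"3:Del:M:{i}" for i in (1, 2)]
    chans += [f"4:Del:M:{i}" for i in (1, 2, 3)]
    chans += [f"5:Del:M:{i}" for i in (1, 2, 3, 4, 5)]
    return tuple(chans)


#: The 83 indel channels in SigProfiler order ("5" size/category means 5+).
ID83_CLASSES: tuple[str, ...] = _id83_channels()
assert len(ID83_CLASSES) == 83


def left_align(pos: int, ref: str, alt: str, seq: str) -> tuple[int, str, str]:
    """Left-align a VCF-style indel (1-based ``pos``, anchor-base alleles).

    Shifts the event left while the trailing base of the alleles matches the
    base preceding the anchor.  SNVs and already-normalized indels are
    returned unchanged.
    """
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise ValueError("indel cannot be normalized at the sequence start")
                prev = seq[pos - 2]
                ref, alt = prev + ref, prev + alt
                pos -= 1
            continue
        break
    return pos, ref, alt


def _tandem_copies_after(seq: str, start: int, unit: str) -> int:
    """Number of consecutive copies of ``unit`` in ``seq`` starting at ``start``."""
    n, k = 0, len(unit)
    while seq[start + n * k : start + (n + 1) * k] == unit:
        n += 1
    return n


def classify_id83(pos: int, ref: str, alt: str, seq: str) -> str:
    """Map one VCF-style indel to its 83-channel label.

    ``pos`` is 1-based; ``ref``/``alt`` carry the shared anchor base.  The
    event is left-aligned first.  For 1-bp events the homopolymer run of the
    affected base is counted in the reference, INCLUDING the deleted base
    for deletions (so category 5 means a run of 6+ before deletion) and
    EXCLUDING the inserted base for insertions.  Longer deletions are
    repeat-type when at least one additional tandem copy of the deleted
    sequence flanks it, with category = additional copies capped at 5+;
    otherwise microhomology length at the deletion boundary is used when
    positive, else repeat category 0.  Insertions count existing reference
    copies of the inserted unit (capped 5+).
    """
    pos, ref, alt = left_align(pos, ref, alt, seq)
    if len(ref) == len(alt):
        raise ValueError(f"not an indel: {ref}>{alt}")
    if not (ref[0] == alt[0] and (len(ref) == 1 or len(alt) == 1)):
        raise ValueError(f"complex allele pair {ref}>{alt}; anchor-base indels only")
    if seq[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ValueError(f"reference mismatch at position {pos}")

    if len(ref) > len(alt):  # deletion
        deleted = ref[len(alt) :]
        size = len(deleted)
        after = pos - 1 + len(ref)  # first reference index past the deleted tract
        if size == 1:
            base = deleted[0]
            run = 1 + _tandem_copies_after(seq, after, base)
            i = pos  # index of the deleted base is pos (0-based: anchor at pos-1)
            j = i - 1
            while j >= 0 and seq[j] == base:
                run += 1
                j -= 1
            pyr = base if base in "CT" else base.translate(_COMPLEMENT)
            return f"1:Del:{pyr}:{min(run - 1, 5)}"
        size_cat = min(size, 5)
        extra = _tandem_copies_after(seq, after, deleted)
        # copies to the left of the deleted tract
        left = pos  # 0-based start of deleted tract
        while left >= size and seq[left - size : left] == deleted:
            extra += 1
            left -= size
        if extra > 0:
            return f"{size_cat}:Del:R:{min(extra, 5)}"
        # microhomology: longest prefix of the deleted tract shared with the
        # right flank (after left-alignment a left-side match cannot occur)
        mh = 0
        for m in range(size - 1, 0, -1):
            if seq[after : after + m] == deleted[:m]:
                mh = m
                break
        if mh > 0:
            return f"{size_cat}:Del:M:{min(mh, 5)}"
        return f"{size_cat}:Del:R:0"

    # insertion
    inserted = alt[len(ref) :]
    size = len(inserted)
    after = pos  # 0-based index just past the anchor base
    if size == 1:
        base = inserted[0]
        run = _tandem_copies_after(seq, after, base)
        j = after - 1
        while j >= 0 and seq[j] == base:
            run += 1
            j -= 1
        pyr = base if base in "CT" else base.translate(_COMPLEMENT)
        return f"1:Ins:{pyr}:{min(run, 5)}"
    size_cat = min(size, 5)
    copies = _tandem_copies_after(seq, after, inserted)
    left = after
    while left >= size and seq[left - size : left] == inserted:
        copies += 1
        left -= size
    return f"{size_cat}:Ins:R:{min(copies, 5)}"


def classify_id83_at(variant: SomaticVariant, reference: Mapping[str, str]) -> str:
    return classify_id83(variant.pos, variant.ref, variant.alt, reference[variant.chrom])


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

SBS6_CLASSES = _SUBS


@dataclass
class MatrixCounts:
    """Per-sample SBS96 and ID83 count vectors plus summary splits."""

    sbs96: pd.DataFrame  # 96 x samples
    id83: pd.DataFrame  # 83 x samples
    sbs6: pd.DataFrame  # 6 x samples (collapsed substitution spectrum)
    burden: pd.DataFrame  # rows BS / indel, columns samples
    unclassifiable: dict[str, int] = field(default_factory=dict)


def build_matrices(
    variants: Sequence[SomaticVariant], reference: Mapping[str, str]
) -> MatrixCounts:
    """Count classified variants into per-sample SBS96/ID83 matrices.

    Also emits the 6-class collapsed substitution spectrum and the
    substitution-vs-indel burden split.  Variants with ambiguous context are
    tallied separately, not dropped silently.
    """
    samples = sorted({v.sample_id for v in variants})
    sbs = pd.DataFrame(0, index=list(SBS96_CLASSES), columns=samples, dtype=int)
    idm = pd.DataFrame(0, index=list(ID83_CLASSES), columns=samples, dtype=int)
    unclassifiable: dict[str, int] = {}
    for v in variants:
        try:
            if v.is_snv:
                sbs.loc[classify_sbs96_at(v, reference), v.sample_id] += 1
            else:
                idm.loc[classify_id83_at(v, reference), v.sample_id] += 1
        except ValueError:
            unclassifiable[v.sample_id] = unclassifiable.get(v.sample_id, 0) + 1
    sbs6 = pd.DataFrame(0, index=list(SBS6_CLASSES), columns=samples, dtype=int)
    for sub in SBS6_CLASSES:
        mask = [lbl[2:5] == sub for lbl in SBS96_CLASSES]
        sbs6.loc[sub] = sbs.loc[mask].sum(axis=0)
    burden = pd.DataFrame(
        {"BS": sbs.sum(axis=0), "indel": idm.sum(axis=0)}
    ).T
    return MatrixCounts(sbs96=sbs, id83=idm, sbs6=sbs6, burden=burden,
                        unclassifiable=unclassifiable)


def normalize_profile(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize a count matrix to proportions (empty columns stay 0)."""
    totals = matrix.sum(axis=0)
    out = matrix.astype(float)
    for col in out.columns:
        if totals[col] > 0:
            out[col] /= totals[col]
    return out
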