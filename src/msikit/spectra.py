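"""Per-locus allele spectra from aligned reads.

A spectrum is the histogram of repeat-unit counts observed across the reads
spanning one microsatellite locus.  The repeat length carried by a read is
measured by pattern matching between flanking anchor sequences rather than
from the CIGAR, because aligners place indels within repeats ambiguously:
a read contributes an observation only when it contains, in order, at least
``min_flank`` reference-matching bases on BOTH sides of the tract, and the
unit count is the number of consecutive motif copies found between those
anchors in the read sequence itself.

The on-disk dialect is a documented TSV ("``.dis``-like"): one row per
(sample, locus) with the spectrum serialized as comma-separated
``units:count`` pairs sorted by units.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .catalog import MicrosatelliteLocus, read_fasta

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleSpectrum",
    "measure_read_repeat_length",
    "extract_spectra",
    "write_spectra",
    "read_spectra",
]


@dataclass
class AlleleSpectrum:
    """Histogram of observed repeat-unit counts at one locus in one sample."""

    locus_id: str
    sample_id: str
    counts: dict[int, int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("spectrum counts must be >= 1 for present keys")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def proportions(self) -> dict[int, float]:
        total = self.total_reads
        return {units: c / total for units, c in self.counts.items()}


def measure_read_repeat_length(
    read_seq: str,
    locus: MicrosatelliteLocus,
    ref_seq: str,
    min_flank: int = 5,
) -> int | None:
    """Count motif copies carried by one read at ``locus``; None if not spanning.

    The left anchor is the ``min_flank`` reference bases preceding the tract
    and the right anchor the ``min_flank`` bases following it.  Starting at
    each occurrence of the left anchor in the read, consecutive motif copies
    are counted and the right anchor must follow immediately; the first
    consistent parse wins.  Reads lacking either anchor (e.g. ending inside
    the tract), or with mismatches/Ns in the anchors, yield no observation.
    """
    if locus.start < min_flank or locus.end + min_flank > len(ref_seq):
        return None  # tract too close to a reference edge to anchor
    left = ref_seq[locus.start - min_flank : locus.start]
    right = ref_seq[locus.end : locus.end + min_flank]
    motif = locus.motif
    k = len(motif)
    read_seq = read_seq.upper()
    idx = read_seq.find(left)
    while idx != -1:
        p = idx + min_flank
        units = 0
        while read_seq[p : p + k] == motif:
            p += k
            units += 1
        if read_seq[p : p + min_flank] == right:
            return units
        idx = read_seq.find(left, idx + 1)
    return None


@dataclass
class SpectrumExtraction:
    """Result bundle from :func:`extract_spectra`."""

    spectra: dict[str, AlleleSpectrum]
    insufficient: dict[str, int] = field(default_factory=dict)  # locus_id -> depth seen


def _locus_lookup(catalog: Sequence[MicrosatelliteLocus]):
    """Index loci per chromosome for overlap queries against read spans."""
    per_chrom: dict[str, list[MicrosatelliteLocus]] = {}
    for loc in catalog:
        per_chrom.setdefault(loc.chrom, []).append(loc)
    starts: dict[str, list[int]] = {}
    for chrom, loci in per_chrom.items():
        loci.sort(key=lambda l: l.start)
        starts[chrom] = [l.start for l in loci]
    max_span = max((loc.end - loc.start for loc in catalog), default=0)

    def overlapping(chrom: str, begin: int, end: int) -> list[MicrosatelliteLocus]:
        loci = per_chrom.get(chrom)
        if not loci:
            return []
        lo = bisect_right(starts[chrom], begin - max_span - 1)
        out = []
        for loc in loci[lo:]:
            if loc.start >= end:
                break
            if loc.end > begin:
                out.append(loc)
        return out

    return overlapping


def extract_spectra(
    alignments: str | Path | pysam.AlignmentFile,
    catalog: Sequence[MicrosatelliteLocus],
    reference: Mapping[str, str] | str | Path,
    sample_id: str,
    min_flank: int = 5,
    min_mapq: int = 20,
    min_depth: int = 10,
) -> SpectrumExtraction:
    """Build per-locus allele spectra from a SAM/BAM file.

    Duplicate-marked, secondary, supplementary, unmapped and low-MAPQ reads
    are ignored.  Loci with fewer than ``min_depth`` spanning observations
    are flagged insufficient and excluded from the returned spectra.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    if isinstance(reference, (str, Path)):
        reference = read_fasta(reference)
    own_handle = isinstance(alignments, (str, Path))
    af = (
        pysam.AlignmentFile(str(alignments), check_sq=False)
        if own_handle
        else alignments
    )
    overlapping = _locus_lookup(catalog)
    tallies: dict[str, Counter] = {loc.locus_id: Counter() for loc in catalog}
    try:
        for read in af:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.mapping_quality < min_mapq
                or read.query_sequence is None
            ):
                continue
            chrom = read.reference_name
            begin = read.reference_start
            end = read.reference_end or begin + len(read.query_sequence)
            seq = read.query_sequence
            # permissive window: indels shift the read's reference span, so the
            # authoritative spanning test is the anchor parse, not coordinates
            for loc in overlapping(chrom, begin - min_flank - 20, end + min_flank + 20):
                if loc.chrom not in reference:
                    continue
                units = measure_read_repeat_length(
                    seq, loc, reference[loc.chrom], min_flank
                )
                if units is not None:
                    tallies[loc.locus_id][units] += 1
    finally:
        if own_handle:
            af.close()

    spectra: dict[str, AlleleSpectrum] = {}
    insufficient: dict[str, int] = {}
    for loc in catalog:
        tally = tallies[loc.locus_id]
        depth = sum(tally.values())
        if depth >= min_depth:
            spectra[loc.locus_id] = AlleleSpectrum(
                locus_id=loc.locus_id, sample_id=sample_id, counts=dict(sorted(tally.items()))
            )
        elif depth > 0:
            insufficient[loc.locus_id] = depth
    if not spectra:
        warnings.warn(f"no locus reached min_depth={min_depth} for sample {sample_id}")
    return SpectrumExtraction(spectra=spectra, insufficient=insufficient)


_DIS_COLUMNS = [
    "sample_id",
    "locus_id",
    "chrom",
    "start",
    "motif",
    "canonical_motif",
    "ref_units",
    "spectrum",
]


def write_spectra(
    spectra: Iterable[AlleleSpectrum],
    catalog: Mapping[str, MicrosatelliteLocus],
    path: str | Path,
) -> None:
    """Serialize spectra to the TSV dialect (one row per sample x locus)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_DIS_COLUMNS) + "\n")
        for sp in spectra:
            loc = catalog[sp.locus_id]
            packed = ",".join(f"{u}:{c}" for u, c in sorted(sp.counts.items()))
            fh.write(
                f"{sp.sample_id}\t{sp.locus_id}\t{loc.chrom}\t{loc.start}\t"
                f"{loc.motif}\t{loc.canonical_motif}\t{loc.unit_count}\t{packed}\n"
            )


def read_spectra(path: str | Path) -> list[AlleleSpectrum]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            sample_id, locus_id = fields[0], fields[1]
            counts = {}
            for pair in fields[7].split(","):
                units, count = pair.split(":")
                counts[int(units)] = int(count)
            out.append(AlleleSpectrum(locus_id=locus_id, sample_id=sample_id, counts=counts))
    return out
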