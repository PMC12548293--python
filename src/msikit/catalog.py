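"""Microsatellite catalog: discovery of perfect short tandem repeats.

Scans reference sequences for maximal perfect mono-, di- and trinucleotide
repeats and assigns each locus a canonical (strand-combined) motif.  The
catalog is the substrate for allele-spectrum extraction and for the
entropy-based instability statistics: stratification by exact unit count
requires perfect, unambiguous tracts, so interrupted repeats are never
reported.

Canonicalization merges a motif with its reverse complement (the two
strands of one physical tract) but deliberately does NOT merge rotations:
GA/TC and AG/CT describe differently phased tracts and are kept distinct.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "MicrosatelliteLocus",
    "canonicalize_motif",
    "scan_sequence",
    "scan_reference",
    "read_fasta",
    "write_catalog",
    "read_catalog",
    "DEFAULT_MIN_UNITS",
]

_VALID = frozenset("ACGT")

#: Minimum number of complete units for a tract to be cataloged, per motif size.
DEFAULT_MIN_UNITS: Mapping[int, int] = {1: 5, 2: 3, 3: 3}


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """One perfect tandem-repeat tract on the reference forward strand.

    Coordinates are 0-based half-open; ``motif`` is the repeat unit as read
    from ``start``, and ``canonical_motif`` is the lexicographic minimum of
    the motif and its reverse complement.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    motif: str
    canonical_motif: str
    unit_count: int

    @property
    def tract_length_bp(self) -> int:
        return self.unit_count * len(self.motif)

    def __post_init__(self) -> None:
        if self.end - self.start != self.unit_count * len(self.motif):
            raise ValueError(
                f"{self.locus_id}: span {self.end - self.start} != "
                f"{self.unit_count} x {len(self.motif)}"
            )


def canonicalize_motif(motif: str) -> str:
    """Return the strand-combined representative of ``motif``.

    The representative is ``min(motif, revcomp(motif))`` lexicographically,
    so a tract read as (TG)n on one strand and (CA)n on the other is always
    reported as CA.  Rotations are not merged: ``canonicalize_motif("TC")``
    is ``"GA"`` while ``canonicalize_motif("CT")`` is ``"AG"``.

    Raises
    ------
    ValueError
        If the motif is empty, longer than 6 bp, or contains non-ACGT bases.
    """
    if not motif or len(motif) > 6:
        raise ValueError(f"motif must be 1-6 bases, got {motif!r}")
    if not _VALID.issuperset(motif):
        raise ValueError(f"motif contains non-ACGT characters: {motif!r}")
    return min(motif, reverse_complement(motif))


def _is_primitive(motif: str) -> bool:
    """True if no smaller period generates the motif (e.g. 'AA' is not primitive)."""
    k = len(motif)
    for p in range(1, k):
        if k % p == 0 and motif == motif[:p] * (k // p):
            return False
    return True


def scan_sequence(
    chrom: str, seq: str, min_units: Mapping[int, int] | None = None
) -> list[MicrosatelliteLocus]:
    """Find every maximal perfect repeat in one sequence.

    For each configured motif size k the sequence is scanned for maximal
    period-k runs; a run is emitted once, phased at its leftmost base, when
    it contains at least ``min_units[k]`` complete units and its unit is
    primitive (a homopolymer is never reported as a dinucleotide repeat).
    Ambiguous bases (anything outside ACGT) terminate runs.  Tracts of
    different motif sizes may overlap; tracts of the same size cannot.
    """
    if min_units is None:
        min_units = DEFAULT_MIN_UNITS
    for k, m in min_units.items():
        if m < 2:
            raise ValueError(f"minimum unit count for size {k} must be >= 2, got {m}")
    seq = seq.upper()
    n = len(seq)
    out: list[MicrosatelliteLocus] = []
    for k, min_u in sorted(min_units.items()):
        i = 0
        while i + k * min_u <= n:
            motif = seq[i : i + k]
            if not _VALID.issuperset(motif) or not _is_primitive(motif):
                i += 1
                continue
            # leftmost phase only: a run extendable to the left was already seen
            if i > 0 and seq[i - 1] == seq[i + k - 1] and seq[i - 1] in _VALID:
                i += 1
                continue
            j = i + k
            while j < n and seq[j] in _VALID and seq[j] == seq[j - k]:
                j += 1
            units = (j - i) // k
            if units >= min_u:
                end = i + units * k
                out.append(
                    MicrosatelliteLocus(
                        locus_id=f"{chrom}:{i}:{motif}",
                        chrom=chrom,
                        start=i,
                        end=end,
                        motif=motif,
                        canonical_motif=canonicalize_motif(motif),
                        unit_count=units,
                    )
                )
            # advance by one: the leftmost-phase guard above already ensures
            # each maximal run is emitted exactly once, and two phase-shifted
            # maximal runs of the same period may overlap by a few bases
            i += 1
    out.sort(key=lambda loc: (loc.chrom, loc.start, len(loc.motif)))
    return out


def scan_reference(
    reference: Mapping[str, str] | str | Path,
    min_units: Mapping[int, int] | None = None,
) -> list[MicrosatelliteLocus]:
    """Scan a whole reference (FASTA path or name→sequence mapping).

    Returns loci sorted by (chrom, start).  An empty sequence yields an
    empty catalog.
    """
    if isinstance(reference, (str, Path)):
        reference = read_fasta(reference)
    out: list[MicrosatelliteLocus] = []
    for chrom in reference:
        out.extend(scan_sequence(chrom, str(reference[chrom]), min_units))
    out.sort(key=lambda loc: (loc.chrom, loc.start, len(loc.motif)))
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (possibly gzipped) multi-record FASTA into a name→sequence dict."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as handle:
            records = list(SeqIO.parse(handle, "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    return {rec.id: str(rec.seq).upper() for rec in records}


_BED_COLUMNS = ["chrom", "start", "end", "locus_id", "motif", "canonical_motif", "unit_count"]


def write_catalog(catalog: Iterable[MicrosatelliteLocus], path: str | Path) -> None:
    """Write the catalog as BED-like TSV (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_BED_COLUMNS) + "\n")
        for loc in catalog:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}\t"
                f"{loc.motif}\t{loc.canonical_motif}\t{loc.unit_count}\n"
            )


def read_catalog(path: str | Path) -> list[MicrosatelliteLocus]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, locus_id, motif, canonical, units = line.rstrip("\n").split("\t")
            out.append(
                MicrosatelliteLocus(
                    locus_id=locus_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    motif=motif,
                    canonical_motif=canonical,
                    unit_count=int(units),
                )
            )
    return out


def catalog_by_id(catalog: Iterable[MicrosatelliteLocus]) -> dict[str, MicrosatelliteLocus]:
    return {loc.locus_id: loc for loc in catalog}
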