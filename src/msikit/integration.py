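"""Transgene integration-site detection from discordant read pairs.

A multi-copy tandem plasmid insertion leaves a characteristic signal in
host-aligned paired-end data: fragments spanning a junction have one mate
mapped to the host genome and the other mate unmapped (it derives from
plasmid sequence the aligner has never seen).  The procedure is:

1. select pairs with exactly one confidently host-mapped mate and one
   unmapped mate;
2. re-align the unmapped mates to the plasmid reference with a seed-and-
   extend local aligner (exact 15-mer seeds, banded Smith-Waterman-style
   extension; match +1, mismatch -2, gap -3 — declared constants), keeping
   hits scoring at least a fraction of the maximum attainable score;
3. cluster the host-side positions of the resulting chimeric evidence
   (single linkage, gap <= window) and call clusters with enough support.

Pairs internal to the tandem array have both mates unmapped and carry no
host position; they are examined by the reciprocal pass (both-unmapped
pairs where exactly one mate hits the plasmid have their partner re-checked
against the host) when a host reference is supplied.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .catalog import read_fasta

__all__ = [
    "ChimericEvidence",
    "IntegrationCall",
    "SeedExtendAligner",
    "find_chimeric_pairs",
    "cluster_evidence",
    "detect_integration",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ChimericEvidence:
    """One read pair linking a host position to the plasmid."""

    read_id: str
    host_chrom: str
    host_pos: int
    host_strand: str  # "+" or "-"
    plasmid_pos: int
    plasmid_strand: str
    score: int


@dataclass(frozen=True)
class IntegrationCall:
    host_chrom: str
    start: int
    end: int
    n_supporting: int
    mean_score: float
    max_score: int
    n_forward: int  # host mates on the forward strand
    n_reverse: int


class SeedExtendAligner:
    """Gapped local aligner: exact k-mer seeds + banded extension.

    Scores are fixed (match +1, mismatch -2, gap -3).  The best-scoring
    seed diagonal on either strand is extended with a banded local DP; the
    reported position is the reference offset of the best-scoring cell.
    """

    def __init__(self, reference: str, k: int = 15, band: int = 12,
                 match: int = 1, mismatch: int = -2, gap: int = -3):
        self.reference = reference.upper()
        self.k = k
        self.band = band
        self.match, self.mismatch, self.gap = match, mismatch, gap
        self.index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(self.reference) - k + 1):
            self.index[self.reference[i : i + k]].append(i)

    def _banded_local(self, q: str, off: int) -> tuple[int, int]:
        """Banded local DP of query against the reference around diagonal
        ``off`` (ref_pos ~= query_pos + off); returns (score, ref_end_pos)."""
        r = self.reference
        m, n = len(q), len(r)
        w = self.band
        prev: dict[int, int] = {}
        best, best_j = 0, max(0, min(off, n - 1))
        for i in range(m):
            cur: dict[int, int] = {}
            lo = max(0, i + off - w)
            hi = min(n - 1, i + off + w)
            qi = q[i]
            for j in range(lo, hi + 1):
                diag = prev.get(j - 1, 0) + (self.match if qi == r[j] else self.mismatch)
                up = prev.get(j, 0) + self.gap
                left = cur.get(j - 1, 0) + self.gap
                h = max(0, diag, up, left)
                if h:
                    cur[j] = h
                    if h > best:
                        best, best_j = h, j
            prev = cur
        return best, best_j

    def align(self, query: str) -> tuple[int, int, str] | None:
        """Best local hit of ``query`` on either strand.

        Returns (score, ref_position, strand) or None when no seed matches.
        """
        query = query.upper()
        best: tuple[int, int, str] | None = None
        for strand, q in (("+", query), ("-", _revcomp(query))):
            if len(q) < self.k:
                continue
            diagonals: dict[int, int] = defaultdict(int)
            for i in range(0, len(q) - self.k + 1):
                for pos in self.index.get(q[i : i + self.k], ()):
                    diagonals[pos - i] += 1
            if not diagonals:
                continue
            off = max(diagonals, key=lambda d: (diagonals[d], -d))
            score, ref_j = self._banded_local(q, off)
            if score > 0 and (best is None or score > best[0]):
                best = (score, ref_j, strand)
        return best

    def max_score(self, query: str) -> int:
        return len(query) * self.match


def _iter_primary_pairs(af: pysam.AlignmentFile):
    """Yield (read1, read2) primary records grouped by query name."""
    pending: dict[str, pysam.AlignedSegment] = {}
    for read in af:
        if read.is_secondary or read.is_supplementary:
            continue
        mate = pending.pop(read.query_name, None)
        if mate is None:
            pending[read.query_name] = read
        else:
            yield (mate, read) if mate.is_read1 else (read, mate)


def find_chimeric_pairs(
    alignments: str | Path | pysam.AlignmentFile,
    plasmid: Mapping[str, str] | str | Path,
    host: Mapping[str, str] | str | Path | None = None,
    min_mapq: int = 20,
    min_score_frac: float = 0.8,
    k: int = 15,
) -> list[ChimericEvidence]:
    """Extract chimeric host/plasmid read pairs from host-aligned data.

    ``plasmid`` must contain exactly one sequence.  When ``host`` is given,
    the reciprocal pass re-checks the partners of plasmid-hitting mates in
    both-unmapped pairs against the host genome and merges the evidence.
    """
    if isinstance(plasmid, (str, Path)):
        plasmid = read_fasta(plasmid)
    if len(plasmid) != 1:
        raise ValueError("plasmid reference must contain exactly one sequence")
    (plasmid_seq,) = plasmid.values()
    if not plasmid_seq:
        raise ValueError("plasmid reference is empty")
    aligner = SeedExtendAligner(plasmid_seq, k=k)
    host_aligners: dict[str, SeedExtendAligner] = {}
    if host is not None:
        if isinstance(host, (str, Path)):
            host = read_fasta(host)
        host_aligners = {name: SeedExtendAligner(seq, k=k) for name, seq in host.items()}

    own = isinstance(alignments, (str, Path))
    af = pysam.AlignmentFile(str(alignments), check_sq=False) if own else alignments
    evidence: list[ChimericEvidence] = []
    try:
        for r1, r2 in _iter_primary_pairs(af):
            mapped = [r for r in (r1, r2) if not r.is_unmapped and r.mapping_quality >= min_mapq]
            unmapped = [r for r in (r1, r2) if r.is_unmapped]
            if len(mapped) == 1 and len(unmapped) == 1:
                seq = unmapped[0].query_sequence
                if not seq:
                    continue
                hit = aligner.align(seq)
                if hit is None or hit[0] < min_score_frac * aligner.max_score(seq):
                    continue
                anchor = mapped[0]
                evidence.append(
                    ChimericEvidence(
                        read_id=anchor.query_name,
                        host_chrom=anchor.reference_name,
                        host_pos=anchor.reference_start,
                        host_strand="-" if anchor.is_reverse else "+",
                        plasmid_pos=hit[1],
                        plasmid_strand=hit[2],
                        score=hit[0],
                    )
                )
            elif len(unmapped) == 2 and host_aligners:
                hits = []
                for r in unmapped:
                    seq = r.query_sequence or ""
                    h = aligner.align(seq) if seq else None
                    ok = h is not None and h[0] >= min_score_frac * aligner.max_score(seq)
                    hits.append((r, h, ok))
                plasmid_side = [t for t in hits if t[2]]
                other_side = [t for t in hits if not t[2]]
                if len(plasmid_side) == 1 and other_side:
                    r, _, _ = other_side[0]
                    seq = r.query_sequence or ""
                    if not seq:
                        continue
                    best = None
                    for chrom, ha in host_aligners.items():
                        h = ha.align(seq)
                        if h and h[0] >= min_score_frac * ha.max_score(seq):
                            if best is None or h[0] > best[1][0]:
                                best = (chrom, h)
                    if best is not None:
                        _, ph, _ = plasmid_side[0]
                        chrom, (score, pos, strand) = best
                        evidence.append(
                            ChimericEvidence(
                                read_id=r.query_name,
                                host_chrom=chrom,
                                host_pos=pos,
                                host_strand=strand,
                                plasmid_pos=ph[1],
                                plasmid_strand=ph[2],
                                score=score,
                            )
                        )
    finally:
        if own:
            af.close()
    return evidence


def cluster_evidence(
    evidence: Sequence[ChimericEvidence],
    window: int = 1000,
    min_support: int = 3,
) -> list[IntegrationCall]:
    """Single-linkage clustering of chimeric evidence into integration calls.

    Evidence records on one chromosome whose host positions are within
    ``window`` bp of a neighbour join one cluster; clusters supported by at
    least ``min_support`` pairs become calls spanning min..max host position.
    """
    calls: list[IntegrationCall] = []
    by_chrom: dict[str, list[ChimericEvidence]] = defaultdict(list)
    for ev in evidence:
        by_chrom[ev.host_chrom].append(ev)
    for chrom in sorted(by_chrom):
        records = sorted(by_chrom[chrom], key=lambda e: e.host_pos)
        cluster: list[ChimericEvidence] = []
        for ev in records:
            if cluster and ev.host_pos - cluster[-1].host_pos > window:
                calls.extend(_emit(cluster, min_support))
                cluster = []
            cluster.append(ev)
        calls.extend(_emit(cluster, min_support))
    return calls


def _emit(cluster: list[ChimericEvidence], min_support: int) -> list[IntegrationCall]:
    if len(cluster) < min_support:
        return []
    scores = [ev.score for ev in cluster]
    fwd = sum(1 for ev in cluster if ev.host_strand == "+")
    return [
        IntegrationCall(
            host_chrom=cluster[0].host_chrom,
            start=min(ev.host_pos for ev in cluster),
            end=max(ev.host_pos for ev in cluster) + 1,
            n_supporting=len(cluster),
            mean_score=sum(scores) / len(scores),
            max_score=max(scores),
            n_forward=fwd,
            n_reverse=len(cluster) - fwd,
        )
    ]


def detect_integration(
    alignments: str | Path,
    plasmid: Mapping[str, str] | str | Path,
    host: Mapping[str, str] | str | Path | None = None,
    window: int = 1000,
    min_support: int = 3,
    min_mapq: int = 20,
    min_score_frac: float = 0.8,
) -> tuple[list[IntegrationCall], list[ChimericEvidence]]:
    """End-to-end convenience wrapper: extract evidence, then cluster."""
    evidence = find_chimeric_pairs(
        alignments, plasmid, host=host, min_mapq=min_mapq, min_score_frac=min_score_frac
    )
    return cluster_evidence(evidence, window=window, min_support=min_support), evidence
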