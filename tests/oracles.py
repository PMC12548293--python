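"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own algorithms: the scanner oracle
tests every start position and motif size exhaustively, and the filter
oracle applies each retention rule independently.
"""

from __future__ import annotations

import numpy as np

_VALID = set("ACGT")


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def _primitive(motif: str) -> bool:
    k = len(motif)
    return not any(k % p == 0 and motif == motif[:p] * (k // p) for p in range(1, k))


def oracle_scan(chrom: str, seq: str, min_units: dict[int, int]) -> set:
    """Every maximal perfect repeat, found by exhaustive start-position search."""
    seq = seq.upper()
    n = len(seq)
    found = set()
    for k, min_u in min_units.items():
        for i in range(n - k * min_u + 1):
            motif = seq[i : i + k]
            if len(motif) < k or not _VALID.issuperset(motif) or not _primitive(motif):
                continue
            units = 1
            while seq[i + units * k : i + (units + 1) * k] == motif:
                units += 1
            if units < min_u:
                continue
            # leftmost phase of a maximal run only
            if i > 0 and seq[i - 1] in _VALID and seq[i - 1] == seq[i + k - 1]:
                continue
            found.add((chrom, i, motif, units))
    return found


def oracle_filter(variants) -> set:
    """Retention decided by applying every rule independently (order-free)."""
    keep = set()
    for v in variants:
        ok = (
            v.tumor_depth >= 10
            and v.normal_depth >= 10
            and v.tumor_alt_reads >= 3
            and v.normal_alt_reads == 0
            and v.norm_chrom.upper() not in {"X", "Y", "M", "MT"}
            and not v.in_dbsnp
            and v.shared_tumor_count < 2
        )
        if ok:
            keep.add(id(v))
    return keep


def oracle_at_run_length(seq: str, pos: int) -> int:
    """Run length of the maximal same-base run containing pos, by re-scanning."""
    base = seq[pos]
    i = pos
    while i > 0 and seq[i - 1] == base:
        i -= 1
    j = pos
    while j + 1 < len(seq) and seq[j + 1] == base:
        j += 1
    return j - i + 1
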