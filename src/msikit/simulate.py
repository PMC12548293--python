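"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes —
not realistic sequencing noise.  The slippage model gives each read at a
microsatellite locus a chance of carrying a contracted or expanded allele,

    p(n) = min(0.5, p0 * (n - n_min + 1)^gamma) * genotype_multiplier,

rising with the repeat unit count n, so that longer repeats are less
stable; the "MMR-deficient" condition simply multiplies the rate.  Steps
are single units most of the time (contraction-biased, d1 > i1) with a
geometric tail of larger jumps.  PCR-stutter-like jitter is a separate,
default-off knob so instability and noise can be tested independently.

Every generator is a pure function of (parameters, seed).  Randomness is
derived per locus/sample/fragment from the global seed combined with a
stable key (CRC32 of the identifier), so adding a locus or sample never
perturbs the draws of the others.  Each generator returns a truth log
sufficient to reconstruct the expected downstream output exactly when
noise is off.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .catalog import DEFAULT_MIN_UNITS, MicrosatelliteLocus, canonicalize_motif
from .reporter import AssayCounts, ReporterMutation, ReporterReference
from .spectra import AlleleSpectrum

__all__ = [
    "SlippageModel",
    "simulate_reference",
    "random_plants",
    "synthetic_catalog",
    "simulate_locus_spectra",
    "simulate_msi_cohort",
    "simulate_reporter_colonies",
    "simulate_integration_readset",
    "SYNTHETIC_REPORTER",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _rng(seed: int, *keys: str | int) -> np.random.Generator:
    """Child generator keyed on (seed, stable hashes of keys)."""
    entropy = [int(seed)] + [
        zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k) for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Slippage model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlippageModel:
    """Length-dependent replication-slippage model for one condition.

    ``p0`` is the per-read slippage probability at the minimum cataloged
    length; ``gamma`` the length exponent; ``d1``/``i1`` the single-unit
    contraction/expansion step probabilities (remaining mass is geometric
    over steps of two or more units); ``genotype_multiplier`` scales the
    rate for the mismatch-repair-deficient condition; ``stutter`` adds
    PCR-like +/-1 jitter independent of true instability (off by default).
    """

    p0: float = 0.002
    gamma: float = 1.5
    d1: float = 0.7
    i1: float = 0.2
    geometric_p: float = 0.5
    genotype_multiplier: float = 1.0
    stutter: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= 1.0 and 0.0 <= self.stutter <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.d1 < 0 or self.i1 < 0 or self.d1 + self.i1 > 1.0:
            raise ValueError("d1 + i1 must not exceed 1")
        if self.genotype_multiplier < 1.0:
            raise ValueError("genotype_multiplier must be >= 1")

    def slip_probability(self, unit_count: int, n_min: int) -> float:
        # ceiling applied after the genotype multiplier: at most half the
        # reads slip, so the rate never saturates to certainty and entropy
        # keeps rising with repeat length in the deficient condition
        rate = self.p0 * self.genotype_multiplier * max(unit_count - n_min + 1, 0) ** self.gamma
        return min(0.5, rate)

    def draw_steps(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Unit-count steps for ``n`` slipped reads (never zero)."""
        steps = np.zeros(n, dtype=int)
        u = rng.random(n)
        steps[u < self.d1] = -1
        steps[(u >= self.d1) & (u < self.d1 + self.i1)] = 1
        tail = u >= self.d1 + self.i1
        k = int(tail.sum())
        if k:
            mags = rng.geometric(self.geometric_p, size=k) + 1
            contract = self.d1 / (self.d1 + self.i1) if self.d1 + self.i1 > 0 else 0.5
            signs = np.where(rng.random(k) < contract, -1, 1)
            steps[tail] = signs * mags
        return steps


#: Conditions used throughout: a microsatellite-stable baseline and an
#: MMR-deficient condition with a five-fold elevated slippage rate.
STABLE_MODEL = SlippageModel()
MMR_DEFICIENT_MODEL = replace(SlippageModel(), genotype_multiplier=5.0)


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------


def _constrained_base(rng: np.random.Generator, seq: list[str], i: int,
                      forbidden: set[str]) -> str:
    """Draw a base that cannot complete a cataloged-size repeat run.

    Forbids extending a mononucleotide run to 3, a period-2 run to 5 bases
    or a period-3 run to 7 bases, keeping random background far below the
    scan thresholds (mono >= 5, di/tri >= 3 units).
    """
    bad = set(forbidden)
    if i >= 2 and seq[i - 1] == seq[i - 2]:
        bad.add(seq[i - 1])
    if i >= 4 and seq[i - 1] == seq[i - 3] and seq[i - 2] == seq[i - 4]:
        bad.add(seq[i - 2])
    if i >= 6 and seq[i - 1] == seq[i - 4] and seq[i - 2] == seq[i - 5] and seq[i - 3] == seq[i - 6]:
        bad.add(seq[i - 3])
    choices = [b for b in "ACGT" if b not in bad]
    return choices[int(rng.integers(len(choices)))]


def simulate_reference(
    n_chrom: int,
    length: int,
    plants: Sequence[tuple[int, int, str, int]],
    seed: int,
    min_units: Mapping[int, int] | None = None,
) -> tuple[dict[str, str], list[MicrosatelliteLocus]]:
    """Random background with planted perfect repeats at known coordinates.

    ``plants`` is a sequence of (chrom_index, start, motif, unit_count).
    The background is constrained so it can never reach the scan
    thresholds, and breaker bases at each tract boundary prevent the
    planted run from extending; scanning the output therefore recovers
    exactly the planted loci that meet the thresholds.  Identical seeds
    give byte-identical output.

    Raises
    ------
    ValueError
        If plants overlap or run outside their chromosome.
    """
    if min_units is None:
        min_units = DEFAULT_MIN_UNITS
    chroms = [f"chr{c + 1}" for c in range(n_chrom)]
    per_chrom: dict[int, list[tuple[int, str, int]]] = {c: [] for c in range(n_chrom)}
    for chrom_idx, start, motif, units in plants:
        end = start + len(motif) * units
        if start < 1 or end > length - 1:
            raise ValueError(f"plant at {start} does not fit in chromosome of length {length}")
        per_chrom[chrom_idx].append((start, motif.upper(), units))
    sequences: dict[str, str] = {}
    truth: list[MicrosatelliteLocus] = []
    for c, chrom in enumerate(chroms):
        rng = _rng(seed, "ref", chrom)
        sites = sorted(per_chrom[c])
        for (s1, m1, u1), (s2, _, _) in zip(sites, sites[1:]):
            if s1 + len(m1) * u1 + 1 > s2 - 1:
                raise ValueError(f"plants overlap on {chrom} near {s2}")
        seq: list[str] = []
        plant_at = {s: (m, u) for s, m, u in sites}
        i = 0
        while i < length:
            if i in plant_at:
                motif, units = plant_at[i]
                # left breaker: the previous base must not extend the run
                if seq and seq[-1] == motif[-1]:
                    seq[-1] = _constrained_base(rng, seq, i - 1, {motif[-1]})
                tract = motif * units
                seq.extend(tract)
                i += len(tract)
                truth.append(
                    MicrosatelliteLocus(
                        locus_id=f"{chrom}:{len(seq) - len(tract)}:{motif}",
                        chrom=chrom,
                        start=len(seq) - len(tract),
                        end=len(seq),
                        motif=motif,
                        canonical_motif=canonicalize_motif(motif),
                        unit_count=units,
                    )
                )
                if i < length:  # right breaker
                    seq.append(_constrained_base(rng, seq, i, {motif[0]}))
                    i += 1
            else:
                seq.append(_constrained_base(rng, seq, i, set()))
                i += 1
        sequences[chrom] = "".join(seq)
    truth = [
        loc
        for loc in truth
        if loc.unit_count >= min_units.get(len(loc.motif), 10**9)
    ]
    truth.sort(key=lambda loc: (loc.chrom, loc.start, len(loc.motif)))
    return sequences, truth


def random_plants(
    n: int,
    n_chrom: int,
    length: int,
    seed: int,
    motifs: Sequence[str] = ("A", "C", "CA", "GA", "AAC"),
    unit_range: tuple[int, int] = (5, 15),
    margin: int = 30,
) -> list[tuple[int, int, str, int]]:
    """Non-overlapping random plant specifications for simulate_reference."""
    rng = _rng(seed, "plants")
    out: list[tuple[int, int, str, int]] = []
    occupied: dict[int, list[tuple[int, int]]] = {c: [] for c in range(n_chrom)}
    attempts = 0
    while len(out) < n and attempts < 100 * n:
        attempts += 1
        c = int(rng.integers(n_chrom))
        motif = str(motifs[int(rng.integers(len(motifs)))])
        units = int(rng.integers(unit_range[0], unit_range[1] + 1))
        span = len(motif) * units
        start = int(rng.integers(margin, length - span - margin))
        if all(start + span + margin < s or start > e + margin for s, e in occupied[c]):
            occupied[c].append((start, start + span))
            out.append((c, start, motif, units))
    if len(out) < n:
        raise ValueError("could not place the requested number of plants")
    return out


def synthetic_catalog(
    motifs: Mapping[str, Sequence[int]],
    loci_per_unit_count: int = 1,
    chrom: str = "chrS",
) -> list[MicrosatelliteLocus]:
    """Catalog of virtual loci (no backing sequence) for spectrum-level
    simulations: ``motifs`` maps motif -> iterable of unit counts."""
    out = []
    pos = 0
    for motif, unit_counts in motifs.items():
        for units in unit_counts:
            for r in range(loci_per_unit_count):
                start = pos
                end = start + len(motif) * units
                out.append(
                    MicrosatelliteLocus(
                        locus_id=f"{chrom}:{start}:{motif}",
                        chrom=chrom,
                        start=start,
                        end=end,
                        motif=motif,
                        canonical_motif=canonicalize_motif(motif),
                        unit_count=units,
                    )
                )
                pos = end + 1000
    return out


# ---------------------------------------------------------------------------
# Spectrum simulation
# ---------------------------------------------------------------------------


def simulate_locus_spectra(
    catalog: Sequence[MicrosatelliteLocus],
    model: SlippageModel,
    seed: int,
    depth: int = 50,
    sample_id: str = "sim",
    min_units: Mapping[int, int] | None = None,
) -> tuple[dict[str, AlleleSpectrum], dict[str, dict[int, int]]]:
    """Draw per-locus allele spectra under the slippage model.

    Returns (spectra keyed by locus, truth log of allele histograms).  The
    truth log equals the emitted spectra by construction; it is kept
    separate so SAM round-trips can be checked against it.
    """
    if min_units is None:
        min_units = DEFAULT_MIN_UNITS
    spectra: dict[str, AlleleSpectrum] = {}
    truth: dict[str, dict[int, int]] = {}
    for loc in catalog:
        rng = _rng(seed, sample_id, loc.locus_id)
        n_min = min_units.get(len(loc.motif), 2)
        p = model.slip_probability(loc.unit_count, n_min)
        alleles = np.full(depth, loc.unit_count, dtype=int)
        slipped = rng.random(depth) < p
        k = int(slipped.sum())
        if k:
            alleles[slipped] += model.draw_steps(rng, k)
        if model.stutter > 0:
            jitter = rng.random(depth) < model.stutter
            j = int(jitter.sum())
            if j:
                alleles[jitter] += np.where(rng.random(j) < 0.5, -1, 1)
        np.clip(alleles, 1, None, out=alleles)
        values, counts = np.unique(alleles, return_counts=True)
        hist = {int(v): int(c) for v, c in zip(values, counts)}
        truth[loc.locus_id] = dict(hist)
        spectra[loc.locus_id] = AlleleSpectrum(
            locus_id=loc.locus_id, sample_id=sample_id, counts=hist
        )
    return spectra, truth


def write_spectra_sam(
    spectra: Mapping[str, AlleleSpectrum],
    catalog: Sequence[MicrosatelliteLocus],
    reference: Mapping[str, str],
    path: str | Path,
    flank: int = 20,
) -> None:
    """Emit each spectrum observation as a mapped read with intact flanks.

    Reads carry ``flank`` reference bases on both sides of the tract so an
    anchor-based extraction reproduces the spectra exactly.
    """
    by_id = {loc.locus_id: loc for loc in catalog}
    chrom_order = sorted(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in chrom_order],
    }
    tid = {c: i for i, c in enumerate(chrom_order)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for lid in sorted(spectra):
            sp = spectra[lid]
            loc = by_id[lid]
            ref = reference[loc.chrom]
            left = ref[loc.start - flank : loc.start]
            right = ref[loc.end : loc.end + flank]
            serial = 0
            for units in sorted(sp.counts):
                for _ in range(sp.counts[units]):
                    read = pysam.AlignedSegment()
                    read.query_name = f"{lid.replace(':', '_')}:{serial}"
                    serial += 1
                    seq = left + loc.motif * units + right
                    read.query_sequence = seq
                    read.reference_id = tid[loc.chrom]
                    read.reference_start = loc.start - flank
                    read.mapping_quality = 60
                    k = len(loc.motif)
                    common = min(units, loc.unit_count) * k
                    cigar = [(0, len(left) + common)]
                    if units > loc.unit_count:
                        cigar.append((1, (units - loc.unit_count) * k))
                    elif units < loc.unit_count:
                        cigar.append((2, (loc.unit_count - units) * k))
                    cigar.append((0, len(right)))
                    read.cigartuples = cigar
                    read.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                    out.write(read)


def simulate_msi_cohort(
    catalog: Sequence[MicrosatelliteLocus],
    n_normal: int,
    n_tumor: int,
    stable_model: SlippageModel,
    unstable_model: SlippageModel,
    seed: int,
    depth: int = 50,
) -> tuple[dict[str, dict[str, AlleleSpectrum]], dict]:
    """Cohort of stable normals and unstable tumors over a shared catalog."""
    cohort: dict[str, dict[str, AlleleSpectrum]] = {}
    truth: dict = {"normal_samples": [], "tumor_samples": []}
    for i in range(n_normal):
        sid = f"normal{i + 1}"
        cohort[sid], _ = simulate_locus_spectra(
            catalog, stable_model, seed, depth=depth, sample_id=sid
        )
        truth["normal_samples"].append(sid)
    for i in range(n_tumor):
        sid = f"tumor{i + 1}"
        cohort[sid], _ = simulate_locus_spectra(
            catalog, unstable_model, seed, depth=depth, sample_id=sid
        )
        truth["tumor_samples"].append(sid)
    return cohort, truth


# ---------------------------------------------------------------------------
# Reporter-colony simulation
# ---------------------------------------------------------------------------

# Synthetic stand-in for the rpsL reporter coding sequence (the real CDS is
# not distributed here).  Constructed so the adenine-run structure matches
# the assay's context classes: runs of length 2-6 with (A)6 the longest.
_SYNTH_SEGMENTS = [
    "ATGGCTACGGTCAACCAGCTC",  # (A)2
    "GGTACCAAAGTC",  # (A)3
    "CGCTGGATCTCGAC",
    "GTCAAAAGGCTG",  # (A)4
    "CATCGGAAAAACTG",  # (A)5
    "CGGTCAAAAAAGCG",  # (A)6 — the longest adenine run
    "GACTTGGCCTGAGCGGTCACATGGC",  # (T)2
    "GTATACCGGCGTGACCGCGTGA",
]
SYNTHETIC_REPORTER = ReporterReference("synthetic_rpsl", "".join(_SYNTH_SEGMENTS))


def _at_runs(reference: ReporterReference, min_run: int = 2) -> list[tuple[int, int]]:
    """(start, length) of every maximal A- or T-run of length >= min_run."""
    seq = reference.sequence
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if seq[i] in "AT" and j - i >= min_run:
            runs.append((i, j - i))
        i = j
    return runs


DEFAULT_REPORTER_CLASS_RATES: Mapping[str, float] = {
    "G:C>A:T": 0.09,
    "A:T>G:C": 0.03,
    "G:C>T:A": 0.012,
    "G:C>C:G": 0.005,
    "A:T>T:A": 0.007,
    "A:T>C:G": 0.016,
    "1-indel": 0.04,
    "1-indel_(A)n": 0.77,
    "2-indel_(A)n": 0.01,
    ">2bp_indel": 0.02,
}


def _make_mutation(
    rng: np.random.Generator,
    label: str,
    reference: ReporterReference,
    colony_id: str,
    runlength_power: float,
    deletion_bias: float = 0.9,
) -> ReporterMutation:
    seq = reference.sequence
    if ">" in label and "indel" not in label:  # substitution class
        purine = label[0]  # G or A of the pair notation
        alt_purine = label.split(">")[1][0]
        candidates = [i for i, b in enumerate(seq) if b in (purine, purine.translate(_COMPLEMENT))]
        pos = candidates[int(rng.integers(len(candidates)))]
        ref_b = seq[pos]
        alt_b = alt_purine if ref_b == purine else alt_purine.translate(_COMPLEMENT)
        return ReporterMutation(colony_id, "substitution", pos, ref_b, alt_b)
    if label in ("1-indel_(A)n", "2-indel_(A)n"):
        width = 1 if label.startswith("1") else 2
        runs = [(s, ln) for s, ln in _at_runs(reference) if ln >= width]
        weights = np.array([ln**runlength_power for _, ln in runs], dtype=float)
        weights /= weights.sum()
        s, ln = runs[int(rng.choice(len(runs), p=weights))]
        base = seq[s]
        if rng.random() < deletion_bias:
            return ReporterMutation(colony_id, "deletion", s, base * width, "")
        return ReporterMutation(colony_id, "insertion", s, "", base * width)
    if label == "1-indel":
        candidates = [i for i, b in enumerate(seq) if b in "CG"]
        pos = candidates[int(rng.integers(len(candidates)))]
        return ReporterMutation(colony_id, "deletion", pos, seq[pos], "")
    if label == ">2bp_indel":
        pos = int(rng.integers(0, len(seq) - 3))
        return ReporterMutation(colony_id, "deletion", pos, seq[pos : pos + 3], "")
    # "other": a 2-bp deletion outside A/T-run context
    for _ in range(1000):
        pos = int(rng.integers(0, len(seq) - 2))
        double = seq[pos : pos + 2]
        if double not in ("AA", "TT"):
            return ReporterMutation(colony_id, "deletion", pos, double, "")
    raise RuntimeError("could not place an 'other' mutation")


def simulate_reporter_colonies(
    reference: ReporterReference,
    class_rates: Mapping[str, float],
    mice: Sequence[tuple[str, str, int]],
    mutant_rate: float,
    seed: int,
    runlength_power: float = 4.0,
    n_colonies: int | None = None,
) -> tuple[list[AssayCounts], dict[str, list[ReporterMutation]], dict]:
    """Simulate the colony assay for a set of mice.

    ``mice`` is (mouse_id, group, n_km) per mouse; each mouse's mutant
    count is Binomial(n_km, mutant_rate) unless ``n_colonies`` forces it.
    Mutant classes are drawn from the normalized ``class_rates``; adenine-
    run indel positions are drawn with probability proportional to
    run_length ** runlength_power.  Returns (per-mouse counts, mutation
    calls per mouse, truth log of drawn classes).
    """
    labels = list(class_rates)
    probs = np.array([class_rates[l] for l in labels], dtype=float)
    probs /= probs.sum()
    counts: list[AssayCounts] = []
    mutations: dict[str, list[ReporterMutation]] = {}
    truth: dict = {"classes": {}, "mutant_rate": mutant_rate}
    for mouse_id, group, n_km in mice:
        rng = _rng(seed, "reporter", mouse_id)
        n_kmsm = int(rng.binomial(n_km, mutant_rate)) if n_colonies is None else n_colonies
        counts.append(AssayCounts(mouse_id=mouse_id, group=group, n_km=n_km, n_kmsm=n_kmsm))
        drawn = [labels[i] for i in rng.choice(len(labels), size=n_kmsm, p=probs)]
        truth["classes"][mouse_id] = list(drawn)
        mutations[mouse_id] = [
            _make_mutation(rng, label, reference, f"{mouse_id}_c{j}", runlength_power)
            for j, label in enumerate(drawn)
        ]
    return counts, mutations, truth


# ---------------------------------------------------------------------------
# Integration read-set simulation
# ---------------------------------------------------------------------------


def simulate_integration_readset(
    host: Mapping[str, str],
    plasmid_seq: str,
    insertion: tuple[str, int] | None,
    copies: int,
    seed: int,
    path: str | Path,
    fragment_mean: float = 350.0,
    fragment_sd: float = 30.0,
    read_len: int = 100,
    depth: float = 30.0,
) -> dict:
    """Paired-end reads over a genome with a tandem plasmid insertion.

    The modified genome carries ``copies`` tandem plasmid units at the
    insertion point (``copies`` 0 or ``insertion`` None leaves the host
    untouched).  Reads are emitted as a host-referenced SAM: reads lying
    entirely in host sequence are mapped at their host coordinate; reads
    touching plasmid sequence or a junction are emitted unmapped, paired
    with their mates.  Returns the truth log (junction coordinate, counts).
    """
    host = {c: s.upper() for c, s in host.items()}
    plasmid_seq = plasmid_seq.upper()
    if insertion is None or copies == 0:
        ins_chrom, ins_pos, plen = None, None, 0
    else:
        ins_chrom, ins_pos = insertion
        plen = copies * len(plasmid_seq)
    chrom_order = sorted(host)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(host[c])} for c in chrom_order],
    }
    tid = {c: i for i, c in enumerate(chrom_order)}
    truth = {
        "junction": {"chrom": ins_chrom, "pos": ins_pos},
        "copies": copies,
        "n_pairs": 0,
        "n_junction_pairs": 0,
    }

    def host_coord(chrom: str, x: int, span: int) -> int | None:
        """Host coordinate of a modified-genome interval, None if chimeric."""
        if chrom != ins_chrom or plen == 0:
            return x
        if x + span <= ins_pos:
            return x
        if x >= ins_pos + plen:
            return x - plen
        return None

    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for chrom in chrom_order:
            seq = host[chrom]
            if chrom == ins_chrom and plen:
                seq = seq[:ins_pos] + plasmid_seq * copies + seq[ins_pos:]
            glen = len(seq)
            rng = _rng(seed, "tg", chrom)
            n_frags = int(depth * glen / (2 * read_len))
            frag_lens = np.maximum(
                rng.normal(fragment_mean, fragment_sd, n_frags).astype(int), read_len + 20
            )
            starts = rng.integers(0, np.maximum(glen - frag_lens, 1))
            for idx in range(n_frags):
                s = int(starts[idx])
                flen = int(frag_lens[idx])
                e = min(s + flen, glen)
                if e - s < read_len + 10:
                    continue
                r1_seq = seq[s : s + read_len]
                r2_seq = _revcomp(seq[e - read_len : e])
                pos1 = host_coord(chrom, s, read_len)
                pos2 = host_coord(chrom, e - read_len, read_len)
                name = f"frag_{chrom}_{idx}"
                truth["n_pairs"] += 1
                if (pos1 is None) != (pos2 is None):
                    truth["n_junction_pairs"] += 1
                _write_pair(out, name, tid[chrom], pos1, r1_seq, pos2, r2_seq, read_len)
    return truth


def _write_pair(out, name, ref_id, pos1, seq1, pos2, seq2, read_len):
    a = pysam.AlignedSegment()
    b = pysam.AlignedSegment()
    for read, seq, pos, mate_pos, first, reverse in (
        (a, seq1, pos1, pos2, True, False),
        (b, seq2, pos2, pos1, False, True),
    ):
        read.query_name = name
        read.query_sequence = seq
        read.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        read.is_paired = True
        read.is_read1 = first
        read.is_read2 = not first
        if pos is None:
            read.is_unmapped = True
            read.reference_id = ref_id if mate_pos is not None else -1
            read.reference_start = mate_pos if mate_pos is not None else -1
        else:
            read.reference_id = ref_id
            read.reference_start = pos
            read.mapping_quality = 60
            read.cigartuples = [(0, read_len)]
            read.is_reverse = reverse
        if mate_pos is None:
            read.mate_is_unmapped = True
            read.next_reference_id = read.reference_id
            read.next_reference_start = read.reference_start
        else:
            read.next_reference_id = ref_id
            read.next_reference_start = mate_pos
            read.mate_is_reverse = first  # the mate of read1 is the reverse read
    out.write(a)
    out.write(b)
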