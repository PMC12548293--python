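"""Reporter-gene (rpsL) mutation-frequency calculus.

In the rpsL transgenic assay, mutant frequency (MF) is the number of
Km/Sm-resistant colonies divided by the total Km-resistant colonies
screened; each sequenced mutant is assigned one class from a fixed scheme
(six Watson-Crick substitution pair classes plus indel classes keyed on
adenine/thymine homopolymer context), and the per-class MF apportions the
overall MF by the class's share of classified mutations.

Both A-runs and T-runs count as "(A)n" context: the assay reads one strand
of a double-stranded tract.  A run length of >= 2 qualifies; an indel at an
isolated base is a plain 1-indel.  Indel positions are normalized to the
leftmost base of their run, since placement inside a homopolymer is
ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "ReporterReference",
    "ReporterMutation",
    "MutationClass",
    "SUBSTITUTION_CLASSES",
    "INDEL_CLASSES",
    "classify_reporter_mutation",
    "AssayCounts",
    "compute_assay_mf",
    "adenine_indel_by_runlength",
    "hotspot_profile",
    "read_published_mf_table",
    "read_published_runlength_table",
    "indel_bs_ratio",
    "mf_fold_change",
    "compare_groups",
]

SUBSTITUTION_CLASSES = ("G:C>A:T", "A:T>G:C", "G:C>T:A", "G:C>C:G", "A:T>T:A", "A:T>C:G")
INDEL_CLASSES = ("1-indel", "1-indel_(A)n", "2-indel_(A)n", ">2bp_indel", "other")
ALL_CLASSES = SUBSTITUTION_CLASSES + INDEL_CLASSES

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class MutationClass:
    """One reporter-scheme class; (A)n classes carry the run length."""

    label: str
    run_length: int | None = None

    def __post_init__(self) -> None:
        if self.label not in ALL_CLASSES:
            raise ValueError(f"unknown class label {self.label!r}")
        if self.label.endswith("(A)n") and (self.run_length is None or self.run_length < 2):
            raise ValueError("(A)n classes require run_length >= 2")


class ReporterReference:
    """Reporter coding sequence plus its homopolymer-run map."""

    def __init__(self, name: str, sequence: str):
        sequence = sequence.upper()
        if set(sequence) - set("ACGT"):
            raise ValueError("reporter sequence must be over ACGT")
        self.name = name
        self.sequence = sequence
        # run_length[i] = length of the maximal same-base run containing i
        self.run_length = np.zeros(len(sequence), dtype=int)
        self.run_start = np.zeros(len(sequence), dtype=int)
        i = 0
        while i < len(sequence):
            j = i
            while j < len(sequence) and sequence[j] == sequence[i]:
                j += 1
            self.run_length[i:j] = j - i
            self.run_start[i:j] = i
            i = j

    def at_run(self, pos: int) -> tuple[int, int]:
        """(run start, run length) of the A/T homopolymer at ``pos``; (pos, 0) if none."""
        if self.sequence[pos] in "AT":
            return int(self.run_start[pos]), int(self.run_length[pos])
        return pos, 0


@dataclass(frozen=True)
class ReporterMutation:
    colony_id: str
    kind: str  # substitution | deletion | insertion
    position: int  # 0-based offset in the coding sequence
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("substitution requires single-base alleles")
            if self.ref_allele == self.alt_allele:
                raise ValueError("ref and alt are identical")
        elif self.kind == "deletion":
            if not self.ref_allele or self.alt_allele:
                raise ValueError("deletion has non-empty ref and empty alt")
        elif self.kind == "insertion":
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion has empty ref and non-empty alt")
        else:
            raise ValueError(f"unknown mutation kind {self.kind!r}")


def _pair_class(ref: str, alt: str) -> str:
    """Map a strand-specific substitution to its Watson-Crick pair class."""
    if ref in "CT":  # normalize to the purine strand
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    pair = {"G": "G:C", "A": "A:T"}[ref]
    alt_pair = {"A": "A:T", "G": "G:C", "T": "T:A", "C": "C:G"}[alt]
    return f"{pair}>{alt_pair}"


def classify_reporter_mutation(
    mutation: ReporterMutation, reference: ReporterReference
) -> MutationClass:
    """Assign the reporter-scheme class to one mutation.

    Substitutions fall into the six pair classes.  A 1-bp indel of A or T
    inside an A/T run of length >= 2 is ``1-indel_(A)n`` with that run
    length; a 2-bp indel of AA or TT within such a run is ``2-indel_(A)n``;
    other 1-bp indels are ``1-indel``; indels over 2 bp are ``>2bp_indel``;
    anything else is ``other``.
    """
    seq = reference.sequence
    pos = mutation.position
    if not 0 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside reference of length {len(seq)}")
    if mutation.kind == "substitution":
        if seq[pos] != mutation.ref_allele:
            raise ValueError(
                f"ref allele {mutation.ref_allele} does not match reference "
                f"{seq[pos]} at {pos}"
            )
        return MutationClass(_pair_class(mutation.ref_allele, mutation.alt_allele))
    if mutation.kind == "deletion":
        allele = mutation.ref_allele
        if seq[pos : pos + len(allele)] != allele:
            raise ValueError(f"deleted sequence {allele} not present at {pos}")
        if len(allele) == 1 and allele in "AT":
            _, run = reference.at_run(pos)
            if run >= 2:
                return MutationClass("1-indel_(A)n", run_length=run)
        if len(allele) == 2 and allele in ("AA", "TT"):
            _, run = reference.at_run(pos)
            if run >= 2:
                return MutationClass("2-indel_(A)n", run_length=run)
        if len(allele) == 1:
            return MutationClass("1-indel")
        if len(allele) > 2:
            return MutationClass(">2bp_indel")
        return MutationClass("other")
    # insertion: run context is the reference run adjacent to the insertion point
    allele = mutation.alt_allele
    base = allele[0]
    if len(allele) in (1, 2) and base in "AT" and set(allele) == {base}:
        run = 0
        if pos < len(seq) and seq[pos] == base:
            run = max(run, reference.at_run(pos)[1])
        if pos > 0 and seq[pos - 1] == base:
            run = max(run, reference.at_run(pos - 1)[1])
        if run >= 2:
            label = "1-indel_(A)n" if len(allele) == 1 else "2-indel_(A)n"
            return MutationClass(label, run_length=run)
    if len(allele) == 1:
        return MutationClass("1-indel")
    if len(allele) > 2:
        return MutationClass(">2bp_indel")
    return MutationClass("other")


def normalized_position(mutation: ReporterMutation, reference: ReporterReference) -> int:
    """Indel position shifted to the leftmost base of its homopolymer run."""
    if mutation.kind == "substitution":
        return mutation.position
    pos = min(mutation.position, len(reference.sequence) - 1)
    start, run = reference.at_run(pos)
    return start if run >= 2 else mutation.position


# ---------------------------------------------------------------------------
# Mutant-frequency tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayCounts:
    """Colony counts for one mouse: screened (Km) and mutant (Km/Sm)."""

    mouse_id: str
    group: str
    n_km: int
    n_kmsm: int

    def __post_init__(self) -> None:
        if self.n_km <= 0:
            raise ValueError("n_km must be positive")
        if self.n_kmsm > self.n_km:
            raise ValueError("n_kmsm cannot exceed n_km")

    @property
    def overall_mf(self) -> float:
        return self.n_kmsm / self.n_km


def _class_key(cls: MutationClass) -> str:
    return cls.label


def compute_assay_mf(
    counts: Sequence[AssayCounts],
    classes_by_mouse: Mapping[str, Sequence[MutationClass]],
    scale: float = 1e5,
    mode: str = "per_mouse",
) -> pd.DataFrame:
    """Per-class mutant-frequency table (rows: classes; columns: groups).

    Per mouse, overall MF = n_kmsm / n_km and each class receives
    MF x (class count / classified mutations).  Group values are per-mouse
    means (``mode="per_mouse"``) or, with ``mode="pooled"``, the group mean
    overall MF apportioned by the group's pooled class counts.  Rows
    ``BS_total``, ``Indel_total`` and ``mean_overall`` summarize the six
    substitution classes, the four indel classes plus ``other``, and the
    overall MF.  Values are on the ``scale`` display scale (1e5 by default,
    i.e. MF x 10^-5 units).
    """
    if mode not in ("per_mouse", "pooled"):
        raise ValueError("mode must be 'per_mouse' or 'pooled'")
    groups = sorted({c.group for c in counts})
    rows = ["BS_total", *SUBSTITUTION_CLASSES, "Indel_total", *INDEL_CLASSES, "mean_overall"]
    table = pd.DataFrame(0.0, index=rows, columns=groups)
    for group in groups:
        mice = [c for c in counts if c.group == group]
        overall = np.array([m.overall_mf for m in mice]) * scale
        per_class = pd.DataFrame(0.0, index=list(ALL_CLASSES), columns=[m.mouse_id for m in mice])
        for m in mice:
            muts = classes_by_mouse.get(m.mouse_id, [])
            if not muts:
                if m.n_kmsm > 0:
                    per_class[m.mouse_id] = np.nan  # mutants seen but none classified
                continue
            share = pd.Series(0.0, index=list(ALL_CLASSES))
            for cls in muts:
                share[_class_key(cls)] += 1
            share /= len(muts)
            per_class[m.mouse_id] = share * m.overall_mf * scale
        if mode == "per_mouse":
            class_mf = per_class.mean(axis=1)
        else:
            pooled = pd.Series(0.0, index=list(ALL_CLASSES))
            for m in mice:
                for cls in classes_by_mouse.get(m.mouse_id, []):
                    pooled[_class_key(cls)] += 1
            share = pooled / pooled.sum() if pooled.sum() else pooled
            class_mf = share * overall.mean()
        table.loc[list(ALL_CLASSES), group] = class_mf
        table.loc["BS_total", group] = class_mf[list(SUBSTITUTION_CLASSES)].sum()
        table.loc["Indel_total", group] = class_mf[list(INDEL_CLASSES)].sum()
        table.loc["mean_overall", group] = overall.mean()
    return table


def adenine_indel_by_runlength(
    counts: Sequence[AssayCounts],
    classes_by_mouse: Mapping[str, Sequence[MutationClass]],
    scale: float = 1e5,
    max_run: int | None = None,
) -> pd.DataFrame:
    """Partition the 1-indel_(A)n MF by homopolymer run length.

    Rows are run lengths 2..max; columns are groups; the column sums equal
    the group's total 1-indel_(A)n MF exactly (conservation).
    """
    lengths = [
        cls.run_length
        for muts in classes_by_mouse.values()
        for cls in muts
        if cls.label == "1-indel_(A)n"
    ]
    if max_run is None:
        max_run = max(lengths, default=2)
    groups = sorted({c.group for c in counts})
    out = pd.DataFrame(0.0, index=range(2, max_run + 1), columns=groups)
    out.index.name = "run_length"
    for group in groups:
        mice = [c for c in counts if c.group == group]
        for run in out.index:
            vals = []
            for m in mice:
                muts = classes_by_mouse.get(m.mouse_id, [])
                if not muts:
                    vals.append(0.0)
                    continue
                k = sum(
                    1 for cls in muts if cls.label == "1-indel_(A)n" and cls.run_length == run
                )
                vals.append(m.overall_mf * scale * k / len(muts))
            out.loc[run, group] = float(np.mean(vals)) if vals else 0.0
    return out


def hotspot_profile(
    counts: Sequence[AssayCounts],
    mutations_by_mouse: Mapping[str, Sequence[ReporterMutation]],
    reference: ReporterReference,
    scale: float = 1e5,
) -> pd.DataFrame:
    """Per-position deletion/insertion MF along the reporter sequence.

    Indel positions are normalized to the leftmost base of their run; each
    position row carries its homopolymer-run context.  Column sums conserve
    the per-kind MF totals.
    """
    mice = list(counts)
    del_mf = np.zeros(len(reference.sequence) + 1)
    ins_mf = np.zeros(len(reference.sequence) + 1)
    n_mice = len(mice)
    for m in mice:
        muts = mutations_by_mouse.get(m.mouse_id, [])
        if not muts:
            continue
        per_mut = m.overall_mf * scale / len(muts)
        for mut in muts:
            if mut.kind == "substitution":
                continue
            pos = normalized_position(mut, reference)
            if mut.kind == "deletion":
                del_mf[pos] += per_mut / n_mice
            else:
                ins_mf[pos] += per_mut / n_mice
    runs = np.append(reference.run_length, 0)
    bases = list(reference.sequence) + [""]
    return pd.DataFrame(
        {
            "base": bases,
            "run_length": runs,
            "deletion_mf": del_mf,
            "insertion_mf": ins_mf,
        }
    )


def compare_groups(
    counts: Sequence[AssayCounts], group_a: str, group_b: str
) -> tuple[float, float]:
    """Mann-Whitney U test on per-mouse overall MFs between two groups."""
    a = [c.overall_mf for c in counts if c.group == group_a]
    b = [c.overall_mf for c in counts if c.group == group_b]
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Published-table readers and worked-value helpers
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(str(resources.files("msikit").joinpath("data", name)))


def read_published_mf_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the published per-class MF table (x1e-5 scale; NA = not detected)."""
    if path is None:
        path = _data_path("rpsl_mf_table.tsv")
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def read_published_runlength_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the published adenine 1-indel MF by run length (x1e-5 scale)."""
    if path is None:
        path = _data_path("rpsl_adenine_runlength_mf.tsv")
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def indel_bs_ratio(table: pd.DataFrame, group: str) -> float:
    """Indel-total over substitution-total MF ratio for one group column."""
    return float(table.loc["Indel_total", group] / table.loc["BS_total", group])


def mf_fold_change(table: pd.DataFrame, treated: str, control: str) -> float:
    """Ratio of mean overall MFs between two group columns."""
    return float(table.loc["mean_overall", treated] / table.loc["mean_overall", control])
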