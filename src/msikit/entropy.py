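"""Shannon-entropy instability statistics and baseline-calibrated MSI scoring.

The central quantity is the Shannon entropy (SE) of a locus's allele-length
spectrum,

    SE = -sum_i p_i * log2(p_i)

over the proportions p_i of reads carrying each distinct repeat-unit count.
SE = 0 means complete stability (all reads share one length); higher values
mean several lengths coexist, i.e. greater instability.  SE is reported in
bits throughout.

Per-sample summaries stratify loci by (canonical motif, reference unit
count), combining complementary strands, and the motif-level trend is an
ordinary least-squares fit of per-locus SE on repeat unit count with a 95%
confidence interval on the slope.

Tumor-only MSI scoring calibrates against a normal cohort: the baseline
stores each locus's pooled normal spectrum and an instability threshold tau
derived leave-one-out from the normals (mean + 3 SD of the total-variation
distance to the pool, with a configurable floor).  A sample locus is called
unstable when its total-variation distance to the pooled baseline exceeds
max(tau, tau_floor) strictly; the MSI score is the proportion of unstable
loci among those evaluated.
"""

from __future__ import annotations

import json
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .catalog import MicrosatelliteLocus
from .spectra import AlleleSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "LocusEntropy",
    "StratumSummary",
    "MotifTrend",
    "MsiBaseline",
    "MsiResult",
    "shannon_entropy",
    "compute_entropies",
    "summarize_strata",
    "fit_motif_trend",
    "build_baseline",
    "score_msi",
]

#: Default floor on the per-locus instability threshold.
TAU_FLOOR = 0.05
#: Threshold used when the baseline has a single normal sample (no LOO spread).
TAU_SINGLE_NORMAL = 0.1
#: Strata with fewer loci than this are dropped for exome (WES) data.
MIN_STRATUM_LOCI_WES = 10


def shannon_entropy(spectrum: AlleleSpectrum | Mapping[int, int]) -> float:
    """Shannon entropy, in bits, of an allele-length spectrum.

    Zero-probability lengths contribute nothing; a single-length spectrum has
    exactly zero entropy.

    Raises
    ------
    ValueError
        If the spectrum is empty (entropy is undefined without reads).
    """
    counts = spectrum.counts if isinstance(spectrum, AlleleSpectrum) else dict(spectrum)
    total = sum(counts.values())
    if total < 1:
        raise ValueError("entropy undefined for an empty spectrum")
    se = 0.0
    for c in counts.values():
        if c > 0:
            p = c / total
            se -= p * math.log2(p)
    return max(se, 0.0)


@dataclass(frozen=True)
class LocusEntropy:
    locus_id: str
    sample_id: str
    se: float  # bits
    depth: int


@dataclass(frozen=True)
class StratumSummary:
    canonical_motif: str
    unit_count: int
    mean_se: float
    sd_se: float
    n_loci: int


@dataclass(frozen=True)
class MotifTrend:
    canonical_motif: str
    slope: float  # SE (bits) per repeat unit
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    n_points: int


def compute_entropies(
    spectra: Iterable[AlleleSpectrum],
) -> list[LocusEntropy]:
    return [
        LocusEntropy(
            locus_id=sp.locus_id,
            sample_id=sp.sample_id,
            se=shannon_entropy(sp),
            depth=sp.total_reads,
        )
        for sp in spectra
    ]


def summarize_strata(
    entropies: Sequence[LocusEntropy],
    catalog: Mapping[str, MicrosatelliteLocus],
    assay_kind: str = "WGS",
    min_stratum_loci: int = MIN_STRATUM_LOCI_WES,
) -> list[StratumSummary]:
    """Mean/SD of SE per (canonical motif, reference unit count) stratum.

    Complementary motifs are combined through canonicalization.  For exome
    data (``assay_kind="WES"``) strata with fewer than ``min_stratum_loci``
    loci are excluded (and logged); whole-genome strata are always kept.
    """
    if assay_kind not in ("WES", "WGS"):
        raise ValueError(f"assay_kind must be WES or WGS, got {assay_kind!r}")
    groups: dict[tuple[str, int], list[float]] = defaultdict(list)
    for ent in entropies:
        loc = catalog.get(ent.locus_id)
        if loc is None:
            raise KeyError(f"locus {ent.locus_id} not in catalog (catalog/spectra mismatch)")
        groups[(loc.canonical_motif, loc.unit_count)].append(ent.se)
    out = []
    for (motif, units), values in sorted(groups.items()):
        if assay_kind == "WES" and len(values) < min_stratum_loci:
            logger.info(
                "stratum (%s, %d) excluded: %d loci < %d",
                motif, units, len(values), min_stratum_loci,
            )
            continue
        arr = np.asarray(values)
        out.append(
            StratumSummary(
                canonical_motif=motif,
                unit_count=units,
                mean_se=float(arr.mean()),
                sd_se=float(arr.std(ddof=0)),
                n_loci=len(values),
            )
        )
    return out


def fit_motif_trend(
    entropies: Sequence[LocusEntropy],
    catalog: Mapping[str, MicrosatelliteLocus],
    canonical_motif: str,
) -> MotifTrend:
    """OLS fit of per-locus SE against repeat unit count for one motif group.

    Requires at least three distinct unit-count values; the 95% CI on the
    slope uses the t distribution on the residual degrees of freedom.
    """
    xs, ys = [], []
    for ent in entropies:
        loc = catalog.get(ent.locus_id)
        if loc is None:
            raise KeyError(f"locus {ent.locus_id} not in catalog")
        if loc.canonical_motif == canonical_motif:
            xs.append(loc.unit_count)
            ys.append(ent.se)
    if len(set(xs)) < 3:
        raise ValueError(
            f"motif {canonical_motif}: need >= 3 distinct unit counts, got {len(set(xs))}"
        )
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return MotifTrend(
        canonical_motif=canonical_motif,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci_low=float(ci[1][0]),
        slope_ci_high=float(ci[1][1]),
        n_points=len(xs),
    )


# ---------------------------------------------------------------------------
# MSI scoring against a normal-cohort baseline
# ---------------------------------------------------------------------------


@dataclass
class MsiBaseline:
    """Pooled normal spectra and per-locus instability thresholds.

    ``proportions[locus_id]`` maps unit count to pooled proportion (sums to
    one per locus); ``tau[locus_id]`` is the leave-one-out mean + 3 SD
    threshold on the total-variation distance.
    """

    proportions: dict[str, dict[int, float]]
    tau: dict[str, float]
    normal_sample_ids: list[str] = field(default_factory=list)
    tau_floor: float = TAU_FLOOR

    def save(self, path: str | Path) -> None:
        payload = {
            "se_unit": "bits",
            "instability_metric": "total_variation_distance",
            "threshold_rule": "leave_one_out_mean_plus_3sd",
            "tau_floor": self.tau_floor,
            "normal_sample_ids": self.normal_sample_ids,
            "loci": {
                lid: {
                    "proportions": {str(u): p for u, p in props.items()},
                    "tau": self.tau[lid],
                }
                for lid, props in self.proportions.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "MsiBaseline":
        with open(path) as fh:
            payload = json.load(fh)
        props = {
            lid: {int(u): p for u, p in entry["proportions"].items()}
            for lid, entry in payload["loci"].items()
        }
        tau = {lid: entry["tau"] for lid, entry in payload["loci"].items()}
        return cls(
            proportions=props,
            tau=tau,
            normal_sample_ids=payload.get("normal_sample_ids", []),
            tau_floor=payload.get("tau_floor", TAU_FLOOR),
        )


@dataclass(frozen=True)
class MsiResult:
    sample_id: str
    n_evaluated: int
    n_unstable: int
    msi_score: float
    per_locus_distance: Mapping[str, float] = field(hash=False, default_factory=dict)


def total_variation(p: Mapping[int, float], q: Mapping[int, float]) -> float:
    """Total-variation distance between two unit-count distributions."""
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


def _pool(spectra: Sequence[AlleleSpectrum]) -> dict[int, float]:
    tally: dict[int, int] = defaultdict(int)
    for sp in spectra:
        for units, c in sp.counts.items():
            tally[units] += c
    total = sum(tally.values())
    return {u: c / total for u, c in sorted(tally.items())}


def build_baseline(
    normal_spectra: Mapping[str, Mapping[str, AlleleSpectrum]],
    tau_floor: float = TAU_FLOOR,
    tau_single_normal: float = TAU_SINGLE_NORMAL,
) -> MsiBaseline:
    """Construct the tumor-only scoring baseline from normal samples.

    ``normal_spectra`` maps sample_id -> {locus_id -> AlleleSpectrum}.  Only
    loci covered in every contributing sample are retained (drops logged).
    Per locus, read counts are pooled across normals into the reference
    proportion vector, and tau is mean + 3 SD of each normal's
    total-variation distance to the pool built from the remaining normals.
    With identical normals the distances collapse to zero and tau falls to
    the floor; with a single normal sample tau is ``tau_single_normal``.
    """
    if not normal_spectra:
        raise ValueError("at least one normal sample is required")
    sample_ids = sorted(normal_spectra)
    common = set.intersection(*(set(normal_spectra[s]) for s in sample_ids))
    dropped = set().union(*(set(normal_spectra[s]) for s in sample_ids)) - common
    if dropped:
        logger.info("baseline: dropped %d loci missing from >=1 normal", len(dropped))
    proportions: dict[str, dict[int, float]] = {}
    tau: dict[str, float] = {}
    for lid in sorted(common):
        per_sample = [normal_spectra[s][lid] for s in sample_ids]
        proportions[lid] = _pool(per_sample)
        if len(per_sample) == 1:
            tau[lid] = tau_single_normal
            continue
        dists = []
        for i, sp in enumerate(per_sample):
            loo_pool = _pool([q for j, q in enumerate(per_sample) if j != i])
            dists.append(total_variation(sp.proportions(), loo_pool))
        arr = np.asarray(dists)
        tau[lid] = float(arr.mean() + 3.0 * arr.std(ddof=0))
    return MsiBaseline(
        proportions=proportions,
        tau=tau,
        normal_sample_ids=sample_ids,
        tau_floor=tau_floor,
    )


def score_msi(
    sample_spectra: Mapping[str, AlleleSpectrum],
    baseline: MsiBaseline,
    sample_id: str | None = None,
) -> MsiResult:
    """Score one sample against the baseline.

    A locus is unstable iff its total-variation distance to the pooled
    baseline strictly exceeds max(tau_locus, tau_floor); ties are stable.
    The MSI score is n_unstable / n_evaluated over loci present in both the
    sample and the baseline.
    """
    shared = sorted(set(sample_spectra) & set(baseline.proportions))
    if not shared:
        raise ValueError("no loci shared between sample and baseline")
    if sample_id is None:
        sample_id = next(iter(sample_spectra.values())).sample_id
    distances: dict[str, float] = {}
    n_unstable = 0
    for lid in shared:
        d = total_variation(sample_spectra[lid].proportions(), baseline.proportions[lid])
        distances[lid] = d
        if d > max(baseline.tau[lid], baseline.tau_floor):
            n_unstable += 1
    return MsiResult(
        sample_id=sample_id,
        n_evaluated=len(shared),
        n_unstable=n_unstable,
        msi_score=n_unstable / len(shared),
        per_locus_distance=distances,
    )
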