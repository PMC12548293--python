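# msikit

Repeat-instability analytics for mismatch-repair (MMR) deficiency studies:
microsatellite cataloging, per-locus allele spectra, a Shannon-entropy
instability statistic, baseline-calibrated tumor-only MSI scoring,
reporter-gene (rpsL) mutant-frequency spectra, somatic-variant filtering with
SBS96/ID83 classification, and transgene integration-site detection from
discordant read pairs. A seeded synthetic-data generator produces every input
the pipeline consumes, so the whole stack is testable without sequencing data.

## Who it is for

Groups quantifying microsatellite instability (MSI) and mutation spectra in
MMR-deficient model organisms — e.g. *Msh2*-knockout mice under oxidative
stress — from exome/genome sequencing and reporter-gene assays.

## The statistics at the core

**Per-locus instability.** For a microsatellite locus with allele-length
proportions *p₁ … p_k* across spanning reads, the Shannon entropy

SE = −Σᵢ pᵢ log₂ pᵢ   (bits)

is 0 when every read shares one repeat length (complete stability) and grows
as more lengths coexist. Loci are stratified by canonical motif
(complementary strands combined: A/T, C/G, CA/TG, GA/TC, AG/CT, …) and repeat
unit count *n*; the motif-level trend is the OLS slope of SE on *n* with a
95% CI — MMR-deficient samples show markedly steeper slopes.

**MSI score.** A baseline is built from normal samples: per locus, the pooled
allele distribution and a threshold τ = mean + 3·SD of the leave-one-out
total-variation distances among normals. A sample locus is *unstable* when
its total-variation distance to the pooled baseline exceeds max(τ, 0.05);
the MSI score is the fraction of unstable loci.

**Reporter calculus.** Mutant frequency MF = (Km/Sm-resistant colonies) /
(Km-resistant colonies); per-class MF apportions it by each class's share of
sequenced mutations (six Watson–Crick substitution pair classes plus
(A)n-context indel classes), with the adenine 1-indel MF further partitioned
by homopolymer run length.

**Mutation matrices.** Somatic calls are filtered (depth ≥ 10 in tumor and
normal, ≥ 3 tumor alt reads, 0 normal alt reads, autosomes only, no dbSNP,
not shared between tumors) and classified into the standard 96 trinucleotide
substitution channels (pyrimidine convention) and 83 indel channels
(homopolymer / repeat-unit / microhomology context).

## Worked example

Simulate a 121-locus mono-A catalog (unit counts 5–15), a 20-normal stable
cohort and one MMR-deficient tumor (5× slippage), then score the tumor
against the normal baseline and fit the SE-vs-length trend:

```python
from msikit.catalog import catalog_by_id
from msikit.entropy import build_baseline, compute_entropies, fit_motif_trend, score_msi
from msikit.simulate import (MMR_DEFICIENT_MODEL, STABLE_MODEL,
                             simulate_msi_cohort, synthetic_catalog)

catalog = synthetic_catalog({"A": range(5, 16)}, loci_per_unit_count=11)
cohort, _ = simulate_msi_cohort(catalog, 20, 1, STABLE_MODEL, MMR_DEFICIENT_MODEL,
                                seed=1, depth=50)
normals = {s: v for s, v in cohort.items() if s.startswith("normal")}
baseline = build_baseline(normals)
tumor = score_msi(cohort["tumor1"], baseline)
print(f"tumor MSI score: {tumor.msi_score:.3f} "
      f"({tumor.n_unstable}/{tumor.n_evaluated} unstable loci)")
byid = catalog_by_id(catalog)
for name, sample in (("tumor", cohort["tumor1"]), ("normal1", cohort["normal1"])):
    trend = fit_motif_trend(compute_entropies(sample.values()), byid, "A")
    print(f"{name}: SE-vs-length slope {trend.slope:.3f} bits/unit "
          f"(95% CI {trend.slope_ci_low:.3f}-{trend.slope_ci_high:.3f})")
```

Output:

```
tumor MSI score: 0.686 (83/121 unstable loci)
tumor: SE-vs-length slope 0.145 bits/unit (95% CI 0.134-0.155)
normal1: SE-vs-length slope 0.044 bits/unit (95% CI 0.036-0.051)
```

The tumor's score (0.686) says 83 of 121 loci drifted measurably from the
normal baseline, and its entropy rises ~3× faster with repeat length than a
stable sample's — the characteristic MMR-deficient pattern.

The same operations are exposed on the command line
(`msikit scan | spectra | entropy | strata | trend | baseline | msi |
reporter … | somatic … | tglocate`); see `msikit --help`.

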