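"""Per-variant summaries: MAF, Hardy-Weinberg test, deleterious heuristic.

The Hardy-Weinberg test is the standard asymptotic 1-df Pearson
chi-square of observed genotype counts against p^2 / 2pq / q^2
expectation with allele frequencies estimated from the same sample, no
continuity correction. Departures are reported but never used to drop
variants: in a case-only cohort a low HWE p-value can reflect the
sampling design rather than genotyping error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort_io import CohortDataset, VariantAnnotation


@dataclass
class VariantSummary:
    label: str
    maf: float
    hwe_chi2: float
    hwe_p: float
    deleterious: bool
    rs_id: Optional[str] = None
    codon_change: Optional[str] = None
    monomorphic: bool = False


def compute_maf(dosages: Sequence[float]) -> float:
    """Minor-allele frequency from 0/1/2 dosages, missing excluded.

    The result is folded to <= 0.5 so it is invariant to which allele
    the dosage happens to count.
    """
    d = np.asarray(dosages, dtype=float)
    ok = np.isfinite(d)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("all dosages missing; MAF undefined")
    freq = float(d[ok].sum()) / (2 * n)
    return min(freq, 1.0 - freq)


def hwe_test(counts: tuple[int, int, int]) -> tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg proportions.

    ``counts`` are (n_AA, n_Aa, n_aa) genotype counts. Returns
    ``(chi2, p)`` with p from the upper tail of chi-square(1). A
    monomorphic sample is degenerate: (0.0, 1.0).
    """
    n_aa_hom, n_het, n_bb_hom = (int(c) for c in counts)
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_bb_hom
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    p = (2 * n_aa_hom + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa_hom, n_het, n_bb_hom], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def classify_deleterious_heuristic(annotation: VariantAnnotation) -> bool:
    """Label-grammar heuristic for the deleterious flag.

    Frameshift-prone indels (any ``del``/``ins`` label) and nonsense
    substitutions (codon change ending in ``X``) are treated as
    deleterious; other substitutions are not. An explicit flag on the
    annotation is authoritative and simply returned.
    """
    if annotation.deleterious:
        return True
    if annotation.variant_class in ("deletion", "insertion"):
        return True
    if annotation.codon_change and annotation.codon_change.endswith("X"):
        return True
    return False


def summarize_variants(dataset: CohortDataset) -> list[VariantSummary]:
    """One summary per variant column, in input order."""
    out: list[VariantSummary] = []
    for label in dataset.genotypes.variant_labels:
        ann = dataset.annotation_for(label)
        col = dataset.genotypes.column(label)
        ok = np.isfinite(col)
        maf = compute_maf(col)
        d = col[ok].astype(int)
        counts = (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
        chi2, p = hwe_test(counts)
        out.append(
            VariantSummary(
                label=label,
                maf=maf,
                hwe_chi2=chi2,
                hwe_p=p,
                deleterious=ann.deleterious,
                rs_id=ann.rs_id,
                codon_change=ann.codon_change,
                monomorphic=maf == 0.0,
            )
        )
    return out
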