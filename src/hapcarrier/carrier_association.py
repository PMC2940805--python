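"""Carrier vs non-carrier association testing and the omnibus combination.

Each common variant (and each haplotype) is tested by comparing allele
counts between deleterious-mutation carriers and non-carriers with a
label-permutation test: the observed statistic is the Pearson
chi-square of the 2x2 table (allele count vs other alleles, carrier vs
non-carrier), and its p-value is the proportion of label shuffles whose
statistic is at least as large. Haplotype counts enter the table as
EM-posterior expected (fractional) counts per individual.

Per-test permutation p-values are then combined: each p is
back-transformed to the 1-df chi-square deviate with that upper-tail
probability, the deviates are summed, and the sum is referred to a
chi-square with the relevant degrees of freedom (the number of variant
tests, or the number of haplotypes minus one since frequencies sum
to 1). No other multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort_io import CohortDataset
from .ld_phasing import (
    HaplotypeDistribution,
    binomial_se,
    em_haplotype_frequencies,
    expected_haplotype_counts,
)

__all__ = [
    "VariantAssociation",
    "HaplotypeAssociation",
    "OmnibusResult",
    "permutation_test",
    "p_to_chisq1",
    "omnibus_combine",
    "degrees_of_freedom",
    "associate_variants",
    "associate_haplotypes",
]


@dataclass
class VariantAssociation:
    label: str
    freq_noncarriers: float
    freq_carriers: float
    chi2_perm: float
    p_perm: float
    rs_id: Optional[str] = None
    codon_change: Optional[str] = None


@dataclass
class HaplotypeAssociation:
    haplotype: str
    freq_noncarriers: float
    se_noncarriers: float
    freq_carriers: float
    se_carriers: float
    freq_all: float
    se_all: float
    chi2_perm: float
    p_perm: float


@dataclass
class OmnibusResult:
    chi2_sum: float
    df: int
    p: float


def _chi2_2x2(s_w, s_d, t_w, t_d):
    """Pearson chi-square of the 2x2 allele-count table, vectorized.

    Cells: carriers (s_w, s_d - s_w) vs non-carriers
    (t_w - s_w, (t_d - s_d) - (t_w - s_w)). Zero-margin tables give 0.
    """
    s_w = np.asarray(s_w, dtype=float)
    s_d = np.asarray(s_d, dtype=float)
    r1, r2 = s_d, t_d - s_d
    c1, c2 = t_w, t_d - t_w
    a = s_w
    b = s_d - s_w
    c = t_w - s_w
    d = (t_d - s_d) - (t_w - s_w)
    denom = r1 * r2 * c1 * c2
    num = t_d * (a * d - b * c) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return chi2


def permutation_test(
    success_weights: Sequence[float],
    denominators: Sequence[float],
    labels: Sequence[bool],
    n_perm: int = 10000,
    seed: int = 0,
    perm_labels: Optional[np.ndarray] = None,
    small_sample_correction: bool = False,
) -> float:
    """Label-permutation p-value for a 2x2 allele-count comparison.

    ``success_weights`` is each individual's contribution to the allele
    (or haplotype) count, ``denominators`` their chromosome count (0 to
    exclude an individual, e.g. missing genotype), ``labels`` the
    carrier flags. Permutations shuffle the labels across individuals
    keeping each individual's weights intact; a pre-built boolean
    ``perm_labels`` matrix (n_perm, n) can be shared across tests. The
    p-value is the raw proportion of permuted statistics >= observed
    (optionally the (+1)/(+1) small-sample version); an observed
    proportion of zero is stored as 1/(2 n_perm), i.e. "< 1/n_perm".
    """
    w = np.asarray(success_weights, dtype=float)
    d = np.asarray(denominators, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if w.shape != d.shape or w.shape != lab.shape:
        raise ValueError("weights, denominators and labels must align")
    if not lab.any() or lab.all():
        raise ValueError("need at least one carrier and one non-carrier")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    t_w, t_d = w.sum(), d.sum()
    observed = float(_chi2_2x2(w[lab].sum(), d[lab].sum(), t_w, t_d))

    if perm_labels is None:
        perm_labels = permutation_label_matrix(lab, n_perm, seed)
    elif perm_labels.shape != (n_perm, lab.size):
        raise ValueError("perm_labels shape must be (n_perm, n_individuals)")
    s_w = perm_labels.astype(float) @ w
    s_d = perm_labels.astype(float) @ d
    perm_stats = _chi2_2x2(s_w, s_d, t_w, t_d)
    count = int((perm_stats >= observed - 1e-12).sum())
    if small_sample_correction:
        p = (count + 1) / (n_perm + 1)
    else:
        p = count / n_perm
    if p == 0.0:
        p = 1.0 / (2 * n_perm)
    return float(p)


def permutation_label_matrix(
    labels: Sequence[bool], n_perm: int, seed: int
) -> np.ndarray:
    """(n_perm, n) boolean matrix of independently shuffled carrier labels."""
    lab = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    out = np.tile(lab, (n_perm, 1))
    rng.permuted(out, axis=1, out=out)
    return out


def p_to_chisq1(p: float) -> float:
    """1-df chi-square deviate with upper-tail probability ``p``."""
    if p <= 0.0:
        raise ValueError(
            "p must be > 0; a permutation p of zero should be substituted "
            "with 1/(2 n_perm), i.e. reported as < 1/n_perm"
        )
    if p > 1.0:
        raise ValueError(f"p={p} exceeds 1")
    return float(stats.chi2.isf(p, df=1))


def omnibus_combine(chi2_values: Sequence[float], df: int) -> OmnibusResult:
    """Sum per-test chi-square(1) deviates; refer to chi-square(df)."""
    vals = np.asarray(chi2_values, dtype=float)
    if vals.size == 0:
        raise ValueError("no chi-square values to combine")
    if (vals < 0).any():
        raise ValueError("chi-square values must be non-negative")
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    total = float(vals.sum())
    return OmnibusResult(chi2_sum=total, df=df, p=float(stats.chi2.sf(total, df)))


def degrees_of_freedom(test_kind: str, m: int) -> int:
    """df for the omnibus: m for variant tests, m - 1 for haplotypes."""
    if test_kind == "variants":
        if m < 1:
            raise ValueError("need at least one variant test")
        return m
    if test_kind == "haplotypes":
        if m < 2:
            raise ValueError("need at least two haplotypes (frequencies sum to 1)")
        return m - 1
    raise ValueError(f"unknown test kind {test_kind!r}")


# ---------------------------------------------------------------------------
# cohort-level drivers


def associate_variants(
    dataset: CohortDataset,
    labels: Sequence[str],
    n_perm: int = 10000,
    seed: int = 0,
    small_sample_correction: bool = False,
) -> tuple[list[VariantAssociation], OmnibusResult]:
    """Permutation tests for each listed variant plus the omnibus."""
    carriers = dataset.carrier_status
    if not carriers.any() or carriers.all():
        raise ValueError("association needs both carriers and non-carriers")
    perm = permutation_label_matrix(carriers, n_perm, seed)
    out: list[VariantAssociation] = []
    for label in labels:
        ann = dataset.annotation_for(label)
        col = dataset.genotypes.column(label)
        ok = np.isfinite(col)
        w = np.where(ok, col, 0.0)
        d = np.where(ok, 2.0, 0.0)
        p = permutation_test(
            w, d, carriers, n_perm=n_perm, seed=seed, perm_labels=perm,
            small_sample_correction=small_sample_correction,
        )
        fn = w[~carriers].sum() / max(d[~carriers].sum(), 1.0)
        fc = w[carriers].sum() / max(d[carriers].sum(), 1.0)
        out.append(
            VariantAssociation(
                label=label,
                freq_noncarriers=float(fn),
                freq_carriers=float(fc),
                chi2_perm=p_to_chisq1(p),
                p_perm=p,
                rs_id=ann.rs_id,
                codon_change=ann.codon_change,
            )
        )
    omnibus = omnibus_combine(
        [a.chi2_perm for a in out], degrees_of_freedom("variants", len(out))
    )
    return out, omnibus


def associate_haplotypes(
    dataset: CohortDataset,
    tag_labels: Sequence[str],
    n_perm: int = 10000,
    seed: int = 0,
    reestimate_per_perm: bool = False,
    small_sample_correction: bool = False,
    em_kwargs: Optional[dict] = None,
) -> tuple[list[HaplotypeAssociation], OmnibusResult, dict[str, HaplotypeDistribution]]:
    """Per-haplotype permutation tests over the tag-SNP block.

    Group frequencies (and their binomial SEs on the group's own
    chromosome count) come from EM run separately in non-carriers,
    carriers, and the pooled sample. The permutation statistic uses
    per-individual expected haplotype counts from the pooled EM,
    computed once; ``reestimate_per_perm`` instead re-runs the groupwise
    EM for every permutation (slow, Haploview-faithful alternative).
    """
    carriers = dataset.carrier_status
    if not carriers.any() or carriers.all():
        raise ValueError("association needs both carriers and non-carriers")
    em_kwargs = dict(em_kwargs or {})
    cols = np.column_stack([dataset.genotypes.column(l) for l in tag_labels])
    alleles = [
        dataset.genotypes.alleles.get(l, ("1", "0")) for l in tag_labels
    ]
    em_kwargs.setdefault("alleles", alleles)

    pooled = em_haplotype_frequencies(cols, markers=list(tag_labels), **em_kwargs)
    dist_nc = em_haplotype_frequencies(
        cols, markers=list(tag_labels), subset=~carriers, **em_kwargs
    )
    dist_c = em_haplotype_frequencies(
        cols, markers=list(tag_labels), subset=carriers, **em_kwargs
    )

    counts = expected_haplotype_counts(cols, pooled)  # (n, H)
    d = counts.sum(axis=1)  # 2 per phase-consistent individual, else 0
    perm = permutation_label_matrix(carriers, n_perm, seed)

    out: list[HaplotypeAssociation] = []
    for h_idx, hap in enumerate(pooled.haplotypes):
        w = counts[:, h_idx]
        if reestimate_per_perm:
            p = _reestimate_permutation_p(
                cols, tag_labels, hap, carriers, perm, em_kwargs,
                small_sample_correction,
            )
        else:
            p = permutation_test(
                w, d, carriers, n_perm=n_perm, seed=seed, perm_labels=perm,
                small_sample_correction=small_sample_correction,
            )
        fn = dist_nc.frequency_of(hap)
        fc = dist_c.frequency_of(hap)
        fa = float(pooled.frequencies[h_idx])
        out.append(
            HaplotypeAssociation(
                haplotype=hap,
                freq_noncarriers=fn,
                se_noncarriers=binomial_se(fn, dist_nc.n_chromosomes),
                freq_carriers=fc,
                se_carriers=binomial_se(fc, dist_c.n_chromosomes),
                freq_all=fa,
                se_all=binomial_se(fa, pooled.n_chromosomes),
                chi2_perm=p_to_chisq1(p),
                p_perm=p,
            )
        )
    omnibus = omnibus_combine(
        [a.chi2_perm for a in out],
        degrees_of_freedom("haplotypes", len(out)),
    )
    groups = {"all": pooled, "noncarriers": dist_nc, "carriers": dist_c}
    return out, omnibus, groups


def _reestimate_permutation_p(
    cols: np.ndarray,
    tag_labels: Sequence[str],
    hap: str,
    carriers: np.ndarray,
    perm: np.ndarray,
    em_kwargs: dict,
    small_sample_correction: bool,
) -> float:
    """Permutation p with groupwise EM re-fit for every shuffle."""

    def stat(lab: np.ndarray) -> float:
        f_c = em_haplotype_frequencies(
            cols, markers=list(tag_labels), subset=lab, **em_kwargs
        )
        f_n = em_haplotype_frequencies(
            cols, markers=list(tag_labels), subset=~lab, **em_kwargs
        )
        s_w = f_c.frequency_of(hap) * f_c.n_chromosomes
        s_d = f_c.n_chromosomes
        t_w = s_w + f_n.frequency_of(hap) * f_n.n_chromosomes
        t_d = s_d + f_n.n_chromosomes
        return float(_chi2_2x2(s_w, s_d, t_w, t_d))

    observed = stat(carriers)
    n_perm = perm.shape[0]
    count = sum(stat(perm[r]) >= observed - 1e-12 for r in range(n_perm))
    if small_sample_correction:
        p = (count + 1) / (n_perm + 1)
    else:
        p = count / n_perm
    if p == 0.0:
        p = 1.0 / (2 * n_perm)
    return float(p)
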