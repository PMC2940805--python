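"""Greedy pairwise tag-SNP selection.

Common variants (MAF >= ``maf_min``, never deleterious-flagged) are
covered by a small panel of tags so that every common variant has
r^2 >= ``r2_min`` with at least one selected tag. Selection is a greedy
set cover: repeatedly pick the variant capturing the most uncovered
common variants, breaking ties toward higher MAF and then earlier input
order, which makes the output deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import CohortDataset
from .ld_phasing import em_gamete_frequencies, ld_statistics
from .variant_stats import compute_maf


@dataclass
class TagSet:
    """Selected tags plus, for each non-tag common variant, its best tag."""

    tags: list[str]
    covered_by: dict[str, tuple[str, float]] = field(default_factory=dict)
    common_variants: list[str] = field(default_factory=list)
    r2_min: float = 0.8
    maf_min: float = 0.05


def pairwise_r2_matrix(
    dataset: CohortDataset, labels: list[str]
) -> np.ndarray:
    """Symmetric r^2 matrix over the given variant columns (EM-based)."""
    k = len(labels)
    r2 = np.eye(k)
    cols = [dataset.genotypes.column(l) for l in labels]
    for i in range(k):
        for j in range(i + 1, k):
            stats = ld_statistics(em_gamete_frequencies(cols[i], cols[j]))
            val = stats.r2 if np.isfinite(stats.r2) else 0.0
            r2[i, j] = r2[j, i] = val
    return r2


def select_tag_snps(
    dataset: CohortDataset, maf_min: float = 0.05, r2_min: float = 0.8
) -> TagSet:
    """Greedy minimal cover of common variants at pairwise r^2 >= r2_min.

    Deleterious variants are excluded both as candidates and as targets:
    the rare deleterious class defines carrier status and must not leak
    into the common-variation panel.
    """
    common: list[str] = []
    mafs: dict[str, float] = {}
    for label in dataset.genotypes.variant_labels:
        ann = dataset.annotation_for(label)
        if ann.deleterious:
            continue
        maf = compute_maf(dataset.genotypes.column(label))
        if maf >= maf_min:
            common.append(label)
            mafs[label] = maf
    if not common:
        warnings.warn("no common variants at the given MAF threshold",
                      RuntimeWarning)
        return TagSet(tags=[], common_variants=[], r2_min=r2_min, maf_min=maf_min)

    r2 = pairwise_r2_matrix(dataset, common)
    order = {l: i for i, l in enumerate(common)}
    uncovered = set(common)
    tags: list[str] = []
    while uncovered:
        def score(label: str) -> tuple[int, float, int]:
            i = order[label]
            captured = sum(
                1 for u in uncovered if r2[i, order[u]] >= r2_min
            )
            return (captured, mafs[label], -order[label])

        best = max(common, key=score)
        captured, _, _ = score(best)
        if captured == 0:  # remaining variants tag only themselves
            best = min(uncovered, key=lambda l: order[l])
        tags.append(best)
        i = order[best]
        uncovered = {u for u in uncovered if r2[i, order[u]] < r2_min}

    covered_by: dict[str, tuple[str, float]] = {}
    for label in common:
        if label in tags:
            continue
        i = order[label]
        best_tag = max(tags, key=lambda t: r2[i, order[t]])
        covered_by[label] = (best_tag, float(r2[i, order[best_tag]]))
    return TagSet(
        tags=tags,
        covered_by=covered_by,
        common_variants=common,
        r2_min=r2_min,
        maf_min=maf_min,
    )
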