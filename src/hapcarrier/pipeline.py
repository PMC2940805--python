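"""End-to-end orchestration: classify, summarize, tag, phase, associate.

``run_full_analysis`` drives the whole comparison on one cohort and
writes the report bundle: a variant summary table, the tag-SNP report,
per-group haplotype frequency tables, the variant and haplotype
association tables (each with an Overall omnibus row), and a
machine-readable run manifest recording the seed, thresholds, carrier
counts and EM diagnostics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .carrier_association import (
    HaplotypeAssociation,
    OmnibusResult,
    VariantAssociation,
    associate_haplotypes,
    associate_variants,
)
from .cohort_io import CohortDataset, read_annotation, read_linkage
from .ld_phasing import HaplotypeDistribution
from .tag_selection import TagSet, select_tag_snps
from .variant_stats import summarize_variants

logger = logging.getLogger("hapcarrier")


class PipelineAbort(RuntimeError):
    """Clean abort: the analysis is undefined on this input."""


@dataclass
class RunConfig:
    seed: int
    genotypes_path: Optional[str] = None
    annotations_path: Optional[str] = None
    dialect: str = "linkage"
    maf_min: float = 0.05
    r2_min: float = 0.8
    n_perm: int = 10000
    reestimate_per_perm: bool = False
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must be in (0, 0.5)")
        if not 0.0 < self.r2_min <= 1.0:
            raise ValueError("r2_min must be in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class RunResult:
    variant_summary: pd.DataFrame
    tag_report: pd.DataFrame
    tag_set: TagSet
    haplotype_tables: dict[str, pd.DataFrame]
    variant_association: pd.DataFrame
    haplotype_association: pd.DataFrame
    variant_omnibus: OmnibusResult
    haplotype_omnibus: OmnibusResult
    distributions: dict[str, HaplotypeDistribution]
    manifest: dict = field(default_factory=dict)


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def variant_summary_frame(dataset: CohortDataset) -> pd.DataFrame:
    rows = []
    for s in summarize_variants(dataset):
        rows.append(
            {
                "Variant": s.label,
                "rs number": s.rs_id or "",
                "Codon": s.codon_change or "",
                "MAF": _fmt(s.maf),
                "HWE": _fmt(s.hwe_p),
                "Deleterious mutation?": "Yes" if s.deleterious else "No",
            }
        )
    return pd.DataFrame(rows)


def tag_report_frame(tag_set: TagSet) -> pd.DataFrame:
    rows = []
    for tag in tag_set.tags:
        captured = [
            (v, r2) for v, (t, r2) in tag_set.covered_by.items() if t == tag
        ]
        rows.append(
            {
                "Tag": tag,
                "Captures": ";".join(v for v, _ in captured),
                "Worst r2": _fmt(min((r2 for _, r2 in captured), default=1.0)),
            }
        )
    return pd.DataFrame(rows)


def variant_association_frame(
    assoc: list[VariantAssociation], omnibus: OmnibusResult
) -> pd.DataFrame:
    rows = [
        {
            "Variant": a.label,
            "rs number": a.rs_id or "",
            "CodonChange": a.codon_change or "",
            "Deleterious mutation non-carriers": _fmt(a.freq_noncarriers),
            "Deleterious mutation carriers": _fmt(a.freq_carriers),
            "Chi square (Permutation)": _fmt(a.chi2_perm),
            "P value (Permutation)": _fmt(a.p_perm),
        }
        for a in assoc
    ]
    rows.append(
        {
            "Variant": "Overall",
            "rs number": "",
            "CodonChange": "",
            "Deleterious mutation non-carriers": "",
            "Deleterious mutation carriers": "",
            "Chi square (Permutation)": _fmt(omnibus.chi2_sum),
            "P value (Permutation)": _fmt(omnibus.p),
        }
    )
    return pd.DataFrame(rows)


def haplotype_association_frame(
    assoc: list[HaplotypeAssociation], omnibus: OmnibusResult
) -> pd.DataFrame:
    rows = [
        {
            "Haplotype": a.haplotype,
            "Deleterious mutation noncarriers (standard error)":
                f"{_fmt(a.freq_noncarriers)} ({_fmt(a.se_noncarriers)})",
            "Deleterious mutation carriers (standard error)":
                f"{_fmt(a.freq_carriers)} ({_fmt(a.se_carriers)})",
            "All (standard error)": f"{_fmt(a.freq_all)} ({_fmt(a.se_all)})",
            "Chi square (Permutation)": _fmt(a.chi2_perm),
            "P value (Permutation)": _fmt(a.p_perm),
        }
        for a in assoc
    ]
    rows.append(
        {
            "Haplotype": "Overall",
            "Deleterious mutation noncarriers (standard error)": "",
            "Deleterious mutation carriers (standard error)": "",
            "All (standard error)": "",
            "Chi square (Permutation)": _fmt(omnibus.chi2_sum),
            "P value (Permutation)": _fmt(omnibus.p),
        }
    )
    return pd.DataFrame(rows)


def haplotype_table_frame(dist: HaplotypeDistribution) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Haplotype": dist.haplotypes,
            "Frequency (standard error)": [
                f"{_fmt(f)} ({_fmt(s)})"
                for f, s in zip(dist.frequencies, dist.se)
            ],
        }
    )


def load_dataset(config: RunConfig) -> CohortDataset:
    if config.genotypes_path is None or config.annotations_path is None:
        raise ValueError("genotype and annotation paths are required")
    matrix = read_linkage(config.genotypes_path, dialect=config.dialect)
    annotations = read_annotation(config.annotations_path)
    return CohortDataset.from_parts(matrix, annotations)


def run_full_analysis(
    config: RunConfig, dataset: Optional[CohortDataset] = None
) -> RunResult:
    """Run the complete carrier/non-carrier comparison on one cohort."""
    if dataset is None:
        dataset = load_dataset(config)
    n = dataset.genotypes.n_individuals
    n_car = dataset.n_carriers
    logger.info("cohort: %d individuals, %d carriers", n, n_car)
    if n_car == 0:
        raise PipelineAbort(
            "no deleterious-mutation carriers in the cohort; the "
            "carrier/non-carrier comparison is undefined"
        )
    if n_car == n:
        raise PipelineAbort("every individual is a carrier; no comparison group")

    summary = variant_summary_frame(dataset)
    tag_set = select_tag_snps(dataset, maf_min=config.maf_min, r2_min=config.r2_min)
    if not tag_set.tags:
        raise PipelineAbort("no common variants to tag at the given MAF threshold")

    var_assoc, var_omni = associate_variants(
        dataset, tag_set.tags, n_perm=config.n_perm, seed=config.seed
    )
    hap_assoc, hap_omni, dists = associate_haplotypes(
        dataset,
        tag_set.tags,
        n_perm=config.n_perm,
        seed=config.seed,
        reestimate_per_perm=config.reestimate_per_perm,
        em_kwargs={"seed": config.seed},
    )

    # self-consistency: every Overall p must be the chi-square tail of its sum
    for omni in (var_omni, hap_omni):
        assert abs(omni.p - float(sps.chi2.sf(omni.chi2_sum, omni.df))) < 1e-12

    manifest = {
        "seed": config.seed,
        "n_perm": config.n_perm,
        "maf_min": config.maf_min,
        "r2_min": config.r2_min,
        "n_individuals": n,
        "n_carriers": n_car,
        "tags": tag_set.tags,
        "em": {
            name: {
                "n_chromosomes": d.n_chromosomes,
                "log_likelihood": d.log_likelihood,
                "iterations": len(d.loglik_trace),
                "n_haplotypes": len(d.haplotypes),
            }
            for name, d in dists.items()
        },
        "variant_omnibus": {
            "chi2_sum": var_omni.chi2_sum, "df": var_omni.df, "p": var_omni.p,
        },
        "haplotype_omnibus": {
            "chi2_sum": hap_omni.chi2_sum, "df": hap_omni.df, "p": hap_omni.p,
        },
    }

    result = RunResult(
        variant_summary=summary,
        tag_report=tag_report_frame(tag_set),
        tag_set=tag_set,
        haplotype_tables={k: haplotype_table_frame(d) for k, d in dists.items()},
        variant_association=variant_association_frame(var_assoc, var_omni),
        haplotype_association=haplotype_association_frame(hap_assoc, hap_omni),
        variant_omnibus=var_omni,
        haplotype_omnibus=hap_omni,
        distributions=dists,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_bundle(result, Path(config.out_dir))
    return result


def write_bundle(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.variant_summary.to_csv(out_dir / "variant_summary.tsv", sep="\t", index=False)
    result.tag_report.to_csv(out_dir / "tag_report.tsv", sep="\t", index=False)
    for name, table in result.haplotype_tables.items():
        table.to_csv(out_dir / f"haplotypes_{name}.tsv", sep="\t", index=False)
    result.variant_association.to_csv(
        out_dir / "variant_association.tsv", sep="\t", index=False
    )
    result.haplotype_association.to_csv(
        out_dir / "haplotype_association.tsv", sep="\t", index=False
    )
    (out_dir / "run_manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=float) + "\n"
    )
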