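"""Cohort input/output and the carrier/non-carrier data model.

Genotypes are stored as minor-allele dosages (0, 1, 2, or missing) in a
dense matrix with one row per individual and one column per variant.
Variants are opaque labeled columns (cDNA-style labels, no genomic
coordinates). An individual is a *carrier* when they have at least one
minor allele at at least one variant flagged deleterious; missing
genotypes never create carriers.

Two text dialects are supported, declared explicitly rather than
sniffed:

* ``linkage`` — PED-like: family id, individual id, then two allele
  columns per variant; ``0`` is the missing code. A leading ``#`` header
  line may carry variant labels.
* ``dosage`` — CSV with an ``individual_id`` column and one 0/1/2 column
  per variant; empty cells are missing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

MISSING_ALLELE = "0"

_DELETERIOUS_TRUE = {"yes", "true", "1", "y"}
_DELETERIOUS_FALSE = {"no", "false", "0", "n"}


class ParseError(ValueError):
    """Malformed input file (message names the offending line/column)."""


@dataclass
class VariantAnnotation:
    """One annotated variant: label, optional identifiers, deleterious flag.

    ``variant_class`` is one of ``substitution``, ``deletion``,
    ``insertion``, inferred from the label when not given.
    """

    label: str
    rs_id: Optional[str] = None
    codon_change: Optional[str] = None
    variant_class: Optional[str] = None
    deleterious: bool = False

    def __post_init__(self) -> None:
        if self.variant_class is None:
            self.variant_class = infer_variant_class(self.label)


def infer_variant_class(label: str) -> str:
    """Classify a cDNA-style variant label by its tokens.

    ``"2800 del AAG"`` -> deletion, ``"5382 ins C"`` -> insertion,
    ``"3232 A > G"`` -> substitution.
    """
    tokens = label.lower().split()
    if "del" in tokens:
        return "deletion"
    if "ins" in tokens:
        return "insertion"
    if ">" in tokens or ">" in label:
        return "substitution"
    raise ParseError(
        f"cannot infer variant class from label {label!r}; expected a "
        "'del', 'ins' or 'X > Y' token (e.g. '2800 del AAG', '5382 ins C', "
        "'3232 A > G')"
    )


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix.

    ``dosages`` is float with ``nan`` marking missing genotypes; every
    non-missing entry is 0, 1 or 2. ``alleles`` maps each variant label
    to its ``(minor, major)`` allele characters when known (used to
    round-trip linkage files).
    """

    individual_ids: list[str]
    variant_labels: list[str]
    dosages: np.ndarray
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, k = self.dosages.shape
        if n != len(self.individual_ids) or k != len(self.variant_labels):
            raise ValueError(
                f"dosage matrix is {self.dosages.shape} but there are "
                f"{len(self.individual_ids)} individuals and "
                f"{len(self.variant_labels)} variant labels"
            )
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids are not unique")
        if len(set(self.variant_labels)) != k:
            raise ValueError("variant labels are not unique")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_labels)

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.variant_labels.index(label)
        except ValueError:
            raise KeyError(f"no variant column labeled {label!r}") from None
        return self.dosages[:, j]


@dataclass
class CohortDataset:
    """Genotypes plus annotations plus derived per-individual carrier flags."""

    genotypes: GenotypeMatrix
    annotations: list[VariantAnnotation]
    carrier_status: np.ndarray

    def __post_init__(self) -> None:
        labels = [a.label for a in self.annotations]
        if len(set(labels)) != len(labels):
            dupes = {l for l in labels if labels.count(l) > 1}
            raise ValueError(f"duplicate annotation labels: {sorted(dupes)}")
        missing = set(self.genotypes.variant_labels) - set(labels)
        if missing:
            raise ValueError(
                f"annotations do not cover genotype columns: {sorted(missing)}"
            )
        self.carrier_status = np.asarray(self.carrier_status, dtype=bool)
        if self.carrier_status.shape != (self.genotypes.n_individuals,):
            raise ValueError("carrier_status length does not match individuals")

    @classmethod
    def from_parts(
        cls,
        genotypes: GenotypeMatrix,
        annotations: Sequence[VariantAnnotation],
    ) -> "CohortDataset":
        """Attach annotations and derive carrier status."""
        status = derive_carrier_status(genotypes, annotations)
        return cls(genotypes, list(annotations), status)

    @property
    def n_carriers(self) -> int:
        return int(self.carrier_status.sum())

    def annotation_for(self, label: str) -> VariantAnnotation:
        for ann in self.annotations:
            if ann.label == label:
                return ann
        raise KeyError(f"no annotation for variant {label!r}")


def derive_carrier_status(
    genotypes: GenotypeMatrix, annotations: Iterable[VariantAnnotation]
) -> np.ndarray:
    """Flag individuals with >= 1 minor allele at >= 1 deleterious variant.

    Missing genotypes count as dosage 0 (missing is never evidence of a
    mutation).
    """
    status = np.zeros(genotypes.n_individuals, dtype=bool)
    for ann in annotations:
        if not ann.deleterious:
            continue
        if ann.label not in genotypes.variant_labels:
            raise ValueError(
                f"deleterious annotation {ann.label!r} has no genotype column"
            )
        col = genotypes.column(ann.label)
        status |= np.nan_to_num(col, nan=0.0) >= 1
    return status


# ---------------------------------------------------------------------------
# linkage (PED-like) dialect


def read_linkage(path: Union[str, Path], dialect: str = "linkage") -> GenotypeMatrix:
    """Read a genotype file in the declared dialect.

    ``linkage`` rows are ``fam ind a1 b1 a2 b2 ...``; allele code ``0``
    is missing (a half-missing genotype is treated as fully missing).
    The minor allele of each variant is determined from the pooled
    sample; an exact 0.5 tie is broken toward the alphabetically smaller
    allele. ``dosage`` delegates to :func:`read_dosage_csv`.
    """
    if dialect == "dosage":
        return read_dosage_csv(path)
    if dialect != "linkage":
        raise ValueError(f"unknown dialect {dialect!r}; use 'linkage' or 'dosage'")

    path = Path(path)
    labels: Optional[list[str]] = None
    rows: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                labels = line.lstrip("#").strip().split("\t")
                continue
            fields = line.split()
            if len(fields) < 4 or len(fields) % 2 != 0:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 'fam ind' plus an even "
                    f"number of allele columns, got {len(fields)} fields"
                )
            rows.append((fields[1], fields[2:]))

    if not rows:
        raise ParseError(f"{path.name}: no genotype rows")
    k = len(rows[0][1]) // 2
    for i, (_, alleles) in enumerate(rows):
        if len(alleles) != 2 * k:
            raise ParseError(
                f"{path.name}: row {i + 1} has {len(alleles) // 2} variants, "
                f"expected {k}"
            )
    if labels is None:
        labels = [f"V{j + 1}" for j in range(k)]
    elif len(labels) != k:
        raise ParseError(
            f"{path.name}: header names {len(labels)} variants but rows have {k}"
        )

    ids = [ind for ind, _ in rows]
    n = len(ids)
    dosages = np.full((n, k), np.nan)
    allele_map: dict[str, tuple[str, str]] = {}
    for j in range(k):
        pairs = [(rows[i][1][2 * j], rows[i][1][2 * j + 1]) for i in range(n)]
        counts: dict[str, int] = {}
        for a, b in pairs:
            for al in (a, b):
                if al != MISSING_ALLELE:
                    counts[al] = counts.get(al, 0) + 1
        if len(counts) > 2:
            raise ParseError(
                f"{path.name}: variant {labels[j]!r} has more than two alleles: "
                f"{sorted(counts)}"
            )
        if not counts:
            allele_map[labels[j]] = (MISSING_ALLELE, MISSING_ALLELE)
            continue
        alleles_sorted = sorted(counts)  # alphabetical
        if len(alleles_sorted) == 1:
            major = alleles_sorted[0]
            minor = major  # monomorphic: MAF 0, dosage stays 0
            allele_map[labels[j]] = (minor, major)
            for i, (a, b) in enumerate(pairs):
                if MISSING_ALLELE in (a, b):
                    continue
                dosages[i, j] = 0.0
            continue
        a1, a2 = alleles_sorted
        # tie -> alphabetically smaller allele is "minor"
        minor = a1 if counts[a1] <= counts[a2] else a2
        major = a2 if minor == a1 else a1
        allele_map[labels[j]] = (minor, major)
        for i, (a, b) in enumerate(pairs):
            if MISSING_ALLELE in (a, b):
                continue
            dosages[i, j] = float((a == minor) + (b == minor))
    return GenotypeMatrix(ids, labels, dosages, allele_map)


def write_linkage(matrix: GenotypeMatrix, path: Union[str, Path]) -> None:
    """Write the ``linkage`` dialect with a ``#`` label header.

    Allele characters come from ``matrix.alleles``; variants without a
    recorded pair are written with ``A`` (minor) / ``B`` (major).
    """
    path = Path(path)
    lines = ["#" + "\t".join(matrix.variant_labels)]
    for i, ind in enumerate(matrix.individual_ids):
        fields = ["FAM", ind]
        for j, label in enumerate(matrix.variant_labels):
            minor, major = matrix.alleles.get(label, ("A", "B"))
            d = matrix.dosages[i, j]
            if not np.isfinite(d):
                fields += [MISSING_ALLELE, MISSING_ALLELE]
            else:
                d = int(d)
                fields += [minor] * d + [major] * (2 - d)
        lines.append(" ".join(fields))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# dosage-CSV dialect


def read_dosage_csv(path: Union[str, Path]) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "individual_id":
        raise ParseError(
            f"{Path(path).name}: first column must be 'individual_id', "
            f"got {df.columns[0]!r}"
        )
    ids = df["individual_id"].astype(str).tolist()
    labels = list(df.columns[1:])
    dosages = df[labels].to_numpy(dtype=float)
    return GenotypeMatrix(ids, labels, dosages)


def write_dosage_csv(matrix: GenotypeMatrix, path: Union[str, Path]) -> None:
    df = pd.DataFrame(matrix.dosages, columns=matrix.variant_labels)
    df.insert(0, "individual_id", matrix.individual_ids)
    # dosages as ints where present, empty cells for missing
    out = df.copy()
    for c in matrix.variant_labels:
        out[c] = out[c].map(lambda v: "" if not np.isfinite(v) else str(int(v)))
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# annotation tables


def read_annotation(source: Union[str, Path, io.StringIO]) -> list[VariantAnnotation]:
    """Read a variant annotation table (CSV or TSV, header required).

    Required columns: ``label`` and ``deleterious`` (Yes/No); optional
    ``rs_id`` and ``codon_change``. The variant class is inferred from
    the label.
    """
    if isinstance(source, (str, Path)):
        header = Path(source).read_text().splitlines()[0]
    else:
        header = source.getvalue().splitlines()[0]
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    if "label" not in df.columns:
        raise ParseError("annotation table needs a 'label' column")
    if "deleterious" not in df.columns:
        raise ParseError(
            "annotation table needs a 'deleterious' column (Yes/No); to fill "
            "it from the label grammar use "
            "variant_stats.classify_deleterious_heuristic"
        )
    records: list[VariantAnnotation] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        label = row["label"].strip()
        if label in seen:
            raise ParseError(f"duplicate annotation label {label!r}")
        seen.add(label)
        flag_raw = row["deleterious"].strip().lower()
        if flag_raw in _DELETERIOUS_TRUE:
            flag = True
        elif flag_raw in _DELETERIOUS_FALSE:
            flag = False
        else:
            raise ParseError(
                f"unrecognized deleterious flag {row['deleterious']!r} for "
                f"{label!r} (use Yes/No)"
            )
        rs = row.get("rs_id", "").strip() or None
        codon = row.get("codon_change", "").strip() or None
        records.append(
            VariantAnnotation(
                label=label, rs_id=rs, codon_change=codon, deleterious=flag
            )
        )
    return records


def write_annotation(
    annotations: Sequence[VariantAnnotation], path: Union[str, Path]
) -> None:
    df = pd.DataFrame(
        {
            "label": [a.label for a in annotations],
            "rs_id": [a.rs_id or "" for a in annotations],
            "codon_change": [a.codon_change or "" for a in annotations],
            "deleterious": ["Yes" if a.deleterious else "No" for a in annotations],
        }
    )
    df.to_csv(path, index=False)
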