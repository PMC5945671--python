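"""Primary-tumor vs thrombus mutation sharing and indel/signature association.

Gene-level mutation presence is compared between the two compartments of each
patient: a gene is compartment-specific if it is mutated in at least one
sample of one compartment and in no sample of the other. Cohort totals sum
gene-per-patient events. The association between exposure to the
homologous-recombination-deficiency signature and small-indel burden is
tested with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SharingSummary",
    "AssociationReport",
    "classify_sharing",
    "ac3_indel_association",
]

TUMOR = "tumor"
THROMBUS = "thrombus"


@dataclass
class SharingSummary:
    """Gene-sharing counts, per patient and cohort-wide."""

    per_patient: pd.DataFrame     # rows: patients; cols: n_genes, n_shared, ...
    gene_classes: pd.DataFrame    # rows: (patient, gene); col: class

    @property
    def n_genes_total(self) -> int:
        return int(self.per_patient["n_genes"].sum())

    @property
    def n_shared(self) -> int:
        return int(self.per_patient["n_shared"].sum())

    @property
    def n_tumor_only(self) -> int:
        return int(self.per_patient["n_tumor_only"].sum())

    @property
    def n_thrombus_only(self) -> int:
        return int(self.per_patient["n_thrombus_only"].sum())

    @property
    def n_heterogeneous(self) -> int:
        return self.n_tumor_only + self.n_thrombus_only

    @property
    def heterogeneous_fraction(self) -> float:
        return self.n_heterogeneous / self.n_genes_total if self.n_genes_total else 0.0


def classify_sharing(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    min_alt_reads: int = 1,
) -> SharingSummary:
    """Classify mutated genes as shared / tumor-only / thrombus-only per patient.

    ``variants`` needs columns (sample, gene) and optionally alt_reads;
    ``samples`` needs (sample, patient, compartment). Patients lacking one of
    the two compartments are excluded with a warning. Normal samples are
    ignored.
    """
    for col in ("sample", "gene"):
        if col not in variants.columns:
            raise ValueError(f"variants table lacks column {col!r}")
    for col in ("sample", "patient", "compartment"):
        if col not in samples.columns:
            raise ValueError(f"sample sheet lacks column {col!r}")
    if samples["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")

    if "alt_reads" in variants.columns:
        variants = variants[variants["alt_reads"] >= min_alt_reads]
    sheet = samples.set_index("sample")
    unknown = set(variants["sample"]) - set(sheet.index)
    if unknown:
        raise KeyError(f"variants reference unknown samples: {sorted(unknown)}")

    rows = []
    per_patient = []
    for patient, psheet in sheet.groupby("patient"):
        compartments = set(psheet["compartment"]) & {TUMOR, THROMBUS}
        if compartments != {TUMOR, THROMBUS}:
            warnings.warn(
                f"patient {patient!r} lacks a tumor or thrombus sample; excluded",
                stacklevel=2,
            )
            continue
        pvars = variants[variants["sample"].isin(psheet.index)]
        pvars = pvars.assign(
            compartment=sheet.loc[pvars["sample"], "compartment"].to_numpy()
        )
        pvars = pvars[pvars["compartment"].isin((TUMOR, THROMBUS))]
        counts = {"n_genes": 0, "n_shared": 0, "n_tumor_only": 0, "n_thrombus_only": 0}
        for gene, gvars in pvars.groupby("gene"):
            comps = set(gvars["compartment"])
            if comps == {TUMOR}:
                cls = "tumor_only"
            elif comps == {THROMBUS}:
                cls = "thrombus_only"
            else:
                cls = "shared"
            counts["n_genes"] += 1
            counts[f"n_{cls}"] = counts.get(f"n_{cls}", 0) + 1
            rows.append({"patient": patient, "gene": gene, "class": cls})
        counts["n_shared"] = counts.get("n_shared", 0)
        counts["n_heterogeneous"] = counts["n_tumor_only"] + counts["n_thrombus_only"]
        per_patient.append({"patient": patient, **counts})

    per_patient_df = pd.DataFrame(
        per_patient,
        columns=[
            "patient", "n_genes", "n_shared", "n_tumor_only",
            "n_thrombus_only", "n_heterogeneous",
        ],
    ).set_index("patient")
    gene_df = pd.DataFrame(rows, columns=["patient", "gene", "class"])
    return SharingSummary(per_patient=per_patient_df, gene_classes=gene_df)


@dataclass
class AssociationReport:
    """Wilcoxon rank-sum comparison of indel counts between exposure groups."""

    n_positive: int
    n_negative: int
    median_positive: float
    median_negative: float
    statistic: float
    pvalue: float
    method: str
    testable: bool = True


def ac3_indel_association(
    indel_counts: Sequence[float],
    ac3_exposures: Sequence[float],
    exact_max_n: int = 25,
) -> AssociationReport:
    """Two-sided Wilcoxon rank-sum test of indel counts by signature presence.

    Samples with exposure > 0 form the positive group. The exact null
    distribution is used for combined sample sizes up to ``exact_max_n``,
    the tie-corrected normal approximation otherwise.
    """
    indels = np.asarray(indel_counts, dtype=float)
    expo = np.asarray(ac3_exposures, dtype=float)
    if indels.shape != expo.shape:
        raise ValueError("indel counts and exposures must be aligned")
    pos = indels[expo > 0]
    neg = indels[expo <= 0]
    if len(pos) == 0 or len(neg) == 0:
        return AssociationReport(
            n_positive=len(pos), n_negative=len(neg),
            median_positive=float(np.median(pos)) if len(pos) else np.nan,
            median_negative=float(np.median(neg)) if len(neg) else np.nan,
            statistic=np.nan, pvalue=np.nan, method="none", testable=False,
        )
    has_ties = len(np.unique(np.concatenate([pos, neg]))) < len(pos) + len(neg)
    if len(pos) + len(neg) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    return AssociationReport(
        n_positive=len(pos),
        n_negative=len(neg),
        median_positive=float(np.median(pos)),
        median_negative=float(np.median(neg)),
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method=method,
    )
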