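"""Simulators producing every input of the pipeline with known ground truth.

Catalogues are drawn multinomially from planted signature exposures, segmented
genomes emit noisy coverage ratios and binomial B-allele read counts under a
known (TCC, ploidy, karyotype), and multiregion cohorts plant shared and
compartment-specific gene mutations with indel burdens coupled to the
presence of the homologous-recombination-deficiency signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalogue import CHANNELS
from .cna_purity import Segment, SnpSite, expected_coverage_ratio
from .signatures import SignatureSet

__all__ = [
    "KaryotypeEvent",
    "GenomeTruth",
    "simulate_catalogue",
    "simulate_genome",
    "simulate_multiregion",
    "TOY_CHROM_LENGTHS",
]

#: 2-chromosome toy genome used by default to keep simulations fast.
TOY_CHROM_LENGTHS = {"chr1": 120_000_000, "chr2": 80_000_000}


def simulate_catalogue(
    signatures: SignatureSet,
    exposures: np.ndarray,
    mutations_per_sample: Sequence[int],
    rng: np.random.Generator,
    sample_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial catalogue draws from planted exposures.

    ``exposures`` is a k x m matrix of non-negative relative weights; each
    sample's channel probabilities are W @ h normalized. Returns the
    catalogue and the true absolute exposure matrix (weights scaled to the
    per-sample mutation count).
    """
    exposures = np.asarray(exposures, dtype=float)
    if np.any(exposures < 0):
        raise ValueError("exposures must be non-negative")
    if exposures.shape[0] != signatures.k:
        raise ValueError("exposure rows must match the number of signatures")
    m = exposures.shape[1]
    if sample_ids is None:
        sample_ids = [f"S{j + 1:03d}" for j in range(m)]
    counts = np.zeros((96, m))
    truth = np.zeros_like(exposures)
    for j in range(m):
        n = int(mutations_per_sample[j])
        h = exposures[:, j]
        if h.sum() > 0:
            p = signatures.W @ (h / h.sum())
            if n > 0:
                counts[:, j] = rng.multinomial(n, p / p.sum())
            truth[:, j] = n * h / h.sum()
    cat = pd.DataFrame(counts, index=list(CHANNELS), columns=list(sample_ids))
    true_h = pd.DataFrame(truth, index=signatures.names, columns=list(sample_ids))
    return cat, true_h


@dataclass(frozen=True)
class KaryotypeEvent:
    """Planted allele-specific copy-number state over an interval."""

    chrom: str
    start: int
    end: int
    a_cn: int
    b_cn: int

    def __post_init__(self) -> None:
        if not (self.a_cn >= self.b_cn >= 0):
            raise ValueError("karyotype events need A >= B >= 0")

    @property
    def total_cn(self) -> int:
        return self.a_cn + self.b_cn


@dataclass
class GenomeTruth:
    tcc: float
    ploidy: float
    events: list[KaryotypeEvent]
    expected_ratios: list[float] = field(default_factory=list)
    expected_bafs: list[float] = field(default_factory=list)


def simulate_genome(
    karyotype: Sequence[KaryotypeEvent],
    tcc: float,
    ploidy: float,
    rng: np.random.Generator,
    read_depth: float = 60.0,
    snps_per_segment: int = 200,
    coverage_noise_sd: float = 0.0,
    n_somatic_snvs: int = 200,
    sample_id: str = "SIM",
) -> tuple[list[Segment], dict[str, list[SnpSite]], list[float], GenomeTruth]:
    """Segments, het-SNP read counts and somatic MAFs for one simulated tumor.

    Coverage ratios follow the mixture model with multiplicative lognormal
    noise; het-SNP B-allele reads are binomial at the mixture allele fraction;
    somatic MAFs are binomial around the clonal heterozygous-diploid fraction
    tcc / 2. Returns (segments, snps per segment key, somatic MAFs, truth).
    """
    truth = GenomeTruth(tcc=tcc, ploidy=ploidy, events=list(karyotype))
    segments: list[Segment] = []
    snps: dict[str, list[SnpSite]] = {}
    for ev in karyotype:
        ratio = expected_coverage_ratio(ev.total_cn, tcc, ploidy)
        truth.expected_ratios.append(ratio)
        if coverage_noise_sd > 0:
            ratio *= float(np.exp(rng.normal(0.0, coverage_noise_sd)))
        seg = Segment(
            chrom=ev.chrom, start=ev.start, end=ev.end,
            coverage_ratio=ratio, sample_id=sample_id,
        )
        denom = tcc * ev.total_cn + 2.0 * (1.0 - tcc)
        p_b = (tcc * ev.a_cn + (1.0 - tcc)) / denom if denom > 0 else 0.5
        truth.expected_bafs.append(max(p_b, 1.0 - p_b))
        key = f"{ev.chrom}:{ev.start}-{ev.end}"
        sites = []
        positions = np.sort(
            rng.integers(ev.start, ev.end + 1, size=snps_per_segment)
        )
        for pos in positions:
            depth = max(1, int(rng.poisson(read_depth * max(denom, 0.1) / 2.0)))
            # the designated allele sits on the A-haplotype in half the SNPs
            if rng.random() < 0.5:
                p = p_b
            else:
                p = 1.0 - p_b
            b_reads = int(rng.binomial(depth, min(max(p, 0.0), 1.0)))
            sites.append(
                SnpSite(
                    chrom=ev.chrom, pos=int(pos), normal_af=0.5,
                    tumor_depth=depth, tumor_b_reads=b_reads,
                )
            )
        snps[key] = sites
        segments.append(seg)

    mafs: list[float] = []
    for _ in range(n_somatic_snvs):
        depth = max(1, int(rng.poisson(read_depth)))
        mafs.append(rng.binomial(depth, tcc / 2.0) / depth)
    return segments, snps, mafs, truth


def simulate_multiregion(
    rng: np.random.Generator,
    n_patients: int = 5,
    samples_per_compartment: int = 3,
    n_gene_events: int = 100,
    fractions: tuple[float, float, float] = (0.78, 0.13, 0.09),
    indel_rate_pos: float = 24.0,
    indel_rate_neg: float = 8.0,
    ac3_positive_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series, dict]:
    """Cohort with planted shared/tumor-only/thrombus-only gene events.

    ``fractions`` = (shared, tumor_only, thrombus_only); counts per class are
    fixed by rounding (remainder to shared) and distributed round-robin over
    patients so totals are exact. Per-sample small-indel counts are Poisson
    with a rate chosen by each sample's planted signature-presence label.

    Returns (variants, sample sheet, indel counts, AC3 exposures, truth).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("sharing fractions must sum to 1")
    n_tumor_only = int(round(fractions[1] * n_gene_events))
    n_thrombus_only = int(round(fractions[2] * n_gene_events))
    n_shared = n_gene_events - n_tumor_only - n_thrombus_only

    sheet_rows = []
    var_rows = []
    classes = (
        ["shared"] * n_shared
        + ["tumor_only"] * n_tumor_only
        + ["thrombus_only"] * n_thrombus_only
    )
    samples_by_patient: dict[str, dict[str, list[str]]] = {}
    for i in range(n_patients):
        patient = f"P{i + 1}"
        comp = {"tumor": [], "thrombus": []}
        for c in ("tumor", "thrombus"):
            for j in range(samples_per_compartment):
                sid = f"{patient}_{c}_{j + 1}"
                comp[c].append(sid)
                sheet_rows.append(
                    {"sample": sid, "patient": patient, "compartment": c}
                )
        samples_by_patient[patient] = comp

    for g, cls in enumerate(classes):
        patient = f"P{(g % n_patients) + 1}"
        gene = f"GENE{g + 1:04d}"
        comp = samples_by_patient[patient]
        if cls == "shared":
            pick = [rng.choice(comp["tumor"]), rng.choice(comp["thrombus"])]
        elif cls == "tumor_only":
            pick = [rng.choice(comp["tumor"])]
        else:
            pick = [rng.choice(comp["thrombus"])]
        for sid in pick:
            var_rows.append(
                {"patient": patient, "sample": sid, "gene": gene, "alt_reads": 10}
            )

    sheet = pd.DataFrame(sheet_rows)
    variants = pd.DataFrame(var_rows)
    sample_ids = sheet["sample"].tolist()
    labels = rng.random(len(sample_ids)) < ac3_positive_fraction
    rates = np.where(labels, indel_rate_pos, indel_rate_neg)
    indels = pd.Series(rng.poisson(rates), index=sample_ids, name="indels")
    exposures = pd.Series(
        np.where(labels, rng.uniform(20.0, 120.0, len(sample_ids)), 0.0),
        index=sample_ids,
        name="ac3",
    )
    truth = {
        "n_shared": n_shared,
        "n_tumor_only": n_tumor_only,
        "n_thrombus_only": n_thrombus_only,
        "ac3_positive": {s: bool(l) for s, l in zip(sample_ids, labels)},
    }
    return variants, sheet, indels, exposures, truth
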