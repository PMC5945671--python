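"""Readers and writers for the interchange formats of the pipeline.

All tabular files are tab-separated with a header row. Genomic coordinates in
TSVs are 1-based inclusive (VCF convention); BED output is 0-based half-open.
"""

from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .catalogue import CHANNELS, PYRIMIDINE_TRIPLETS, VariantCall
from .cna_purity import Segment, SnpSite
from .genome_scars import Arm, CnSegment
from .signatures import SignatureSet

__all__ = [
    "read_vcf_somatic",
    "read_maf_table",
    "read_signature_matrix",
    "load_packaged_signatures",
    "load_packaged_arms",
    "read_catalogue",
    "write_catalogue",
    "read_triplet_frequencies",
    "read_segments",
    "read_snp_sites",
    "read_cn_profile",
    "write_cn_profile",
    "read_arm_map",
    "read_sample_sheet",
    "write_exposures",
]

_DATA = importlib.resources.files("scarsig") / "data"


# ---------------------------------------------------------------------------
# variants

def read_vcf_somatic(
    path: str | Path,
    sample_id: str | None = None,
    strand_keys: tuple[str, str] = ("SAF", "SAR"),
    dp4_key: str = "DP4",
    context_key: str = "TNC",
    func_key: str = "FUNC",
    fasta: str | Path | None = None,
) -> list[VariantCall]:
    """Load somatic SNVs and indels from a VCF into variant records.

    Per-strand alt read depths are taken from the per-allele INFO keys in
    ``strand_keys`` or, failing that, from a samtools-style ``DP4`` field
    (then only meaningful for biallelic records). Flanking context comes from
    a trinucleotide INFO key or a reference FASTA; if neither is present the
    context fields stay unset. Multi-allelic records are split.
    """
    ref_fa = pysam.FastaFile(str(fasta)) if fasta else None
    calls: list[VariantCall] = []
    vf = pysam.VariantFile(str(path))
    if sample_id is None:
        samples = list(vf.header.samples)
        sample_id = samples[0] if samples else Path(path).stem
    for rec in vf:
        info = rec.info
        alts = rec.alts or ()
        for ai, alt in enumerate(alts):
            alt_fwd = alt_rev = None
            if strand_keys[0] in info and strand_keys[1] in info:
                saf, sar = info[strand_keys[0]], info[strand_keys[1]]
                saf = saf if isinstance(saf, tuple) else (saf,)
                sar = sar if isinstance(sar, tuple) else (sar,)
                alt_fwd, alt_rev = int(saf[ai]), int(sar[ai])
            elif dp4_key in info and len(alts) == 1:
                dp4 = info[dp4_key]
                alt_fwd, alt_rev = int(dp4[2]), int(dp4[3])
            c5 = c3 = None
            if context_key in info:
                tnc = info[context_key]
                tnc = tnc[ai] if isinstance(tnc, tuple) else tnc
                if len(tnc) == 3:
                    c5, c3 = tnc[0], tnc[2]
            elif ref_fa is not None and len(rec.ref) == 1:
                seq = ref_fa.fetch(rec.chrom, rec.pos - 2, rec.pos + 1).upper()
                if len(seq) == 3:
                    c5, c3 = seq[0], seq[2]
            func = info.get(func_key) if func_key in info else None
            if isinstance(func, tuple):
                func = func[ai]
            calls.append(
                VariantCall(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    sample_id=sample_id, context5=c5, context3=c3,
                    alt_fwd=alt_fwd, alt_rev=alt_rev,
                    depth=int(info["DP"]) if "DP" in info else None,
                    func_class=func,
                    gene=str(info["GENE"]) if "GENE" in info else None,
                )
            )
    if ref_fa is not None:
        ref_fa.close()
    return calls


_MAF_COLUMNS = {
    "sample": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "context": "CONTEXT",
}


def read_maf_table(
    path: str | Path,
    min_snvs: int = 25,
    columns: Mapping[str, str] | None = None,
) -> dict[str, list[VariantCall]]:
    """Per-sample SNV lists from a MAF-style TSV, dropping low-load samples.

    Samples with at most ``min_snvs`` SNVs are removed (strictly-greater
    rule). ``columns`` remaps the default MAF column names.
    """
    colmap = dict(_MAF_COLUMNS)
    if columns:
        colmap.update(columns)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty variant table", stacklevel=2)
        return {}
    if df.empty:
        warnings.warn(f"{path}: empty variant table", stacklevel=2)
        return {}
    missing = [c for c in ("sample", "chrom", "pos", "ref", "alt") if colmap[c] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {[colmap[c] for c in missing]}")
    out: dict[str, list[VariantCall]] = {}
    for _, row in df.iterrows():
        ref, alt = str(row[colmap["ref"]]), str(row[colmap["alt"]])
        ctx = row.get(colmap["context"])
        c5 = c3 = None
        if isinstance(ctx, str) and len(ctx) == 3:
            c5, c3 = ctx[0], ctx[2]
        sample = str(row[colmap["sample"]])
        out.setdefault(sample, []).append(
            VariantCall(
                chrom=str(row[colmap["chrom"]]), pos=int(row[colmap["pos"]]),
                ref=ref, alt=alt, sample_id=sample, context5=c5, context3=c3,
            )
        )
    dropped = [s for s, vs in out.items() if sum(v.is_snv for v in vs) <= min_snvs]
    for s in dropped:
        del out[s]
    if dropped:
        warnings.warn(
            f"{path}: dropped {len(dropped)} sample(s) with <= {min_snvs} SNVs",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# signatures and catalogues

def read_signature_matrix(path: str | Path) -> SignatureSet:
    """COSMIC-style signature TSV -> validated, canonically ordered SignatureSet."""
    df = pd.read_csv(path, sep="\t")
    sub_col = next((c for c in df.columns if c.lower().startswith("substitution")), None)
    tri_col = next((c for c in df.columns if c.lower().startswith("trinucleotide")), None)
    if sub_col is None or tri_col is None:
        raise ValueError(f"{path}: need 'Substitution Type' and 'Trinucleotide' columns")
    labels = [
        f"{t[0]}[{s}]{t[2]}" for s, t in zip(df[sub_col], df[tri_col])
    ]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate channel rows")
    missing = set(CHANNELS) - set(labels)
    if missing:
        raise ValueError(f"{path}: missing channels, e.g. {sorted(missing)[:3]}")
    df = df.assign(_channel=labels).set_index("_channel").drop(columns=[sub_col, tri_col])
    df = df.loc[list(CHANNELS)]
    return SignatureSet(W=df.to_numpy(float), names=list(df.columns))


def load_packaged_signatures() -> SignatureSet:
    """The 30-signature fixture matrix shipped with the package."""
    with importlib.resources.as_file(_DATA / "signatures30.tsv") as p:
        return read_signature_matrix(p)


def write_catalogue(catalogue: pd.DataFrame, path: str | Path) -> None:
    catalogue.rename_axis("Channel").to_csv(path, sep="\t")


def read_catalogue(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if list(df.index) != list(CHANNELS):
        if set(df.index) == set(CHANNELS):
            df = df.loc[list(CHANNELS)]
        else:
            raise ValueError(f"{path}: rows are not the 96 canonical channels")
    return df


def read_triplet_frequencies(path: str | Path) -> dict[str, float]:
    """TSV with columns (triplet, count) covering the 32 pyrimidine triplets."""
    df = pd.read_csv(path, sep="\t")
    freq = dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))
    missing = [t for t in PYRIMIDINE_TRIPLETS if t not in freq]
    if missing:
        raise ValueError(f"{path}: missing triplets {missing}")
    return freq


def write_exposures(exposures, path_abs: str | Path, path_rel: str | Path | None = None) -> None:
    exposures.H.rename_axis("Signature").to_csv(path_abs, sep="\t")
    if path_rel is not None:
        exposures.relative.rename_axis("Signature").to_csv(path_rel, sep="\t")


# ---------------------------------------------------------------------------
# copy number

def read_segments(path: str | Path) -> list[Segment]:
    """SEG-like TSV (sample, chrom, start, end, ratio) -> segments."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "chrom", "start", "end", "ratio"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return [
        Segment(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            coverage_ratio=float(r.ratio), sample_id=str(r.sample),
        )
        for r in df.itertuples()
    ]


def read_snp_sites(path: str | Path) -> list[SnpSite]:
    """TSV (chrom, pos, normal_af, tumor_depth, tumor_b_reads) -> SNP sites."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "normal_af", "tumor_depth", "tumor_b_reads"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return [
        SnpSite(
            chrom=str(r.chrom), pos=int(r.pos), normal_af=float(r.normal_af),
            tumor_depth=int(r.tumor_depth), tumor_b_reads=int(r.tumor_b_reads),
        )
        for r in df.itertuples()
    ]


def read_cn_profile(path: str | Path) -> list[CnSegment]:
    """TSV (chrom, start, end, total, A, B[, real]) -> copy-number profile."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "total", "A", "B"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return [
        CnSegment(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            total_cn=int(r.total), a_cn=int(r.A), b_cn=int(r.B),
            real_cn=float(getattr(r, "real", r.total)),
        )
        for r in df.itertuples()
    ]


def write_cn_profile(profile: Sequence[CnSegment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": s.chrom, "start": s.start, "end": s.end,
                "total": s.total_cn, "A": s.a_cn, "B": s.b_cn,
                "real": s.real_cn,
            }
            for s in profile
        ]
    ).to_csv(path, sep="\t", index=False)


def read_arm_map(path: str | Path) -> tuple[list[Arm], dict[str, int]]:
    """Arm TSV (chrom, length, p_end, q_start) -> (arms, chromosome lengths)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "length", "p_end", "q_start"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    arms: list[Arm] = []
    lengths: dict[str, int] = {}
    for r in df.itertuples():
        chrom = str(r.chrom)
        lengths[chrom] = int(r.length)
        arms.append(Arm(chrom=chrom, name="p", start=1, end=int(r.p_end)))
        arms.append(Arm(chrom=chrom, name="q", start=int(r.q_start), end=int(r.length)))
    return arms, lengths


def load_packaged_arms() -> tuple[list[Arm], dict[str, int]]:
    """Built-in GRCh37 chromosome-arm map."""
    with importlib.resources.as_file(_DATA / "grch37_arms.tsv") as p:
        return read_arm_map(p)


def read_sample_sheet(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Sample sheet TSV (sample, patient, compartment[, file columns])."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "patient", "compartment"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    bad = set(df["compartment"]) - {"tumor", "thrombus", "normal"}
    if bad:
        raise ValueError(f"{path}: unknown compartments {sorted(bad)}")
    if check_files:
        for col in df.columns:
            if col.endswith(("_file", "_path")):
                for p in df[col].dropna():
                    if not Path(p).exists():
                        raise FileNotFoundError(f"{path}: referenced file missing: {p}")
    return df
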