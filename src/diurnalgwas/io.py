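"""Readers and writers: VCF dosages, sample tables, summary statistics.

Clock times travel in files as HH:MM:SS strings; internally they are seconds
since midnight plus the day fraction t = seconds/86400.  Dosages travel in
the VCF FORMAT/DS field (expected alternate-allele count), with GT hard
calls as a fallback.  Summary-statistic files carry a self-describing
``# key=value`` header block (version, seed, config hash) so any output can
be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import warnings

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import __version__
from .simulate import DAY_SECONDS, GenotypeMatrix

__all__ = [
    "write_vcf",
    "write_samples",
    "write_cohort",
    "read_genotypes",
    "read_samples",
    "write_sumstats",
    "read_sumstats",
    "config_hash",
    "seconds_to_hms",
    "hms_to_seconds",
]

MISSING = "."


def seconds_to_hms(seconds: float) -> str:
    s = int(round(seconds))
    return f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}"


def hms_to_seconds(text: str) -> float:
    parts = str(text).split(":")
    if len(parts) != 3:
        raise ValueError(f"bad time {text!r}: expected HH:MM:SS")
    hh, mm, ss = (float(p) for p in parts)
    if not (0 <= hh < 24 and 0 <= mm < 60 and 0 <= ss < 60):
        raise ValueError(f"bad time {text!r}: fields out of range")
    return hh * 3600 + mm * 60 + ss


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with FORMAT fields GT and DS (4 decimals)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=diurnalgwas {__version__}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n'
        )
        fh.write("##contig=<ID=1>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(header + list(genotypes.sample_ids)) + "\n")
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, var in genotypes.variants.iterrows():
            dose = genotypes.dosages[:, j]
            fields = [
                str(var["chrom"]),
                str(int(var["pos"])),
                str(var["id"]),
                str(var["ref"]),
                str(var["alt"]),
                MISSING,
                "PASS",
                f"MAF={var['maf']:.4g}",
                "GT:DS",
            ]
            cells = [
                f"{gts.get(int(round(d)), './.')}:{d:.4f}" for d in dose
            ]
            fh.write("\t".join(fields + cells) + "\n")


def write_samples(samples: pd.DataFrame, path) -> None:
    """Sample table TSV; draw time serialized as HH:MM:SS, missing as '.'."""
    out = samples.copy()
    if "draw_time" in out.columns:
        out["draw_time"] = out["draw_time"].map(seconds_to_hms)
    out = out.drop(columns=[c for c in ("t",) if c in out.columns])
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING, float_format="%.6g")


def write_cohort(genotypes: GenotypeMatrix, samples: pd.DataFrame, out_prefix: str):
    """Emit ``<prefix>.vcf`` and ``<prefix>.samples.tsv``."""
    vcf_path = f"{out_prefix}.vcf"
    tsv_path = f"{out_prefix}.samples.tsv"
    write_vcf(genotypes, vcf_path)
    write_samples(samples, tsv_path)
    return vcf_path, tsv_path


def read_genotypes(path, fmt: str = "vcf", sample_ids=None) -> GenotypeMatrix:
    """Load a dosage matrix from VCF (DS, falling back to GT) or a TSV.

    The dosage TSV layout is variants as rows: columns ``id chrom pos ref
    alt`` then one column per sample.  With ``sample_ids`` given, samples
    are intersected and reordered to match; zero overlap is an error.
    """
    if fmt == "vcf":
        vcf = VCF(str(path), gts012=True)
        file_samples = list(vcf.samples)
        rows, meta = [], []
        has_ds_warned = False
        for k, variant in enumerate(vcf):
            try:
                ds = variant.format("DS")
            except KeyError:  # DS absent from the header entirely
                ds = None
            if ds is not None:
                dose = np.asarray(ds, dtype=float).reshape(-1)
            else:
                if not has_ds_warned:
                    warnings.warn(
                        f"{path}: no DS field, using GT hard calls", UserWarning
                    )
                    has_ds_warned = True
                gt = np.asarray(variant.gt_types, dtype=float)
                dose = np.where(gt == 3, np.nan, gt)
            if dose.size != len(file_samples):
                raise ValueError(f"{path}: malformed record at line ~{k + 1}")
            rows.append(dose)
            meta.append(
                {
                    "id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                    "chrom": variant.CHROM,
                    "pos": variant.POS,
                    "ref": variant.REF,
                    "alt": variant.ALT[0] if variant.ALT else MISSING,
                    "maf": float(np.nanmean(dose) / 2.0),
                }
            )
        dosages = np.array(rows).T if rows else np.empty((len(file_samples), 0))
        geno = GenotypeMatrix(dosages, pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt", "maf"]), file_samples)
    elif fmt == "dosage_tsv":
        df = pd.read_csv(path, sep="\t", na_values=[MISSING])
        meta_cols = ["id", "chrom", "pos", "ref", "alt"]
        missing = [c for c in meta_cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: dosage TSV lacks columns {missing}")
        file_samples = [c for c in df.columns if c not in meta_cols]
        dosages = df[file_samples].to_numpy(dtype=float).T
        meta = df[meta_cols].copy()
        meta["maf"] = np.nanmean(dosages, axis=0) / 2.0
        geno = GenotypeMatrix(dosages, meta, file_samples)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")

    if sample_ids is not None:
        wanted = [s for s in sample_ids if s in set(geno.sample_ids)]
        if not wanted:
            raise ValueError("zero overlapping samples between genotypes and phenotypes")
        if len(wanted) < len(sample_ids):
            warnings.warn(
                f"{len(sample_ids) - len(wanted)} phenotype samples absent from genotypes",
                UserWarning,
            )
        idx = [geno.sample_ids.index(s) for s in wanted]
        geno = GenotypeMatrix(geno.dosages[idx], geno.variants, wanted)
    return geno


def read_samples(path, required=("sample_id", "glucose_raw", "draw_time")) -> pd.DataFrame:
    """Sample table TSV -> typed DataFrame with draw_time (s) and t columns.

    Rows whose draw time fails to parse (or leaves t outside [0,1)) are
    dropped with a warning; missing required columns raise ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "draw_time" in df.columns:
        seconds = []
        bad = 0
        for value in df["draw_time"]:
            try:
                seconds.append(hms_to_seconds(value))
            except (ValueError, TypeError):
                seconds.append(np.nan)
                bad += 1
        df["draw_time"] = seconds
        if bad:
            warnings.warn(f"{path}: dropped {bad} rows with unparseable draw times", UserWarning)
        df = df[np.isfinite(df["draw_time"])].reset_index(drop=True)
        df["t"] = df["draw_time"] / DAY_SECONDS
    return df


def config_hash(config: dict) -> str:
    """Stable short hash of a canonicalised configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_sumstats(results: pd.DataFrame, path, analysis: str, seed=None, config=None) -> None:
    """Summary-statistics TSV with a self-describing '# key=value' header."""
    with open(path, "w") as fh:
        fh.write(f"# tool=diurnalgwas\n# version={__version__}\n")
        fh.write(f"# analysis={analysis}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if config is not None:
            fh.write(f"# config_hash={config_hash(config)}\n")
        results.to_csv(fh, sep="\t", index=False, na_rep=MISSING, float_format="%.12g")


def read_sumstats(path) -> tuple[pd.DataFrame, dict]:
    """Read a summary-statistics TSV; returns (table, header metadata)."""
    meta = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                key, _, value = line[2:].strip().partition("=")
                meta[key] = value
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t", na_values=[MISSING])
    return df, meta
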