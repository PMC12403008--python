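"""Readers and writers for the interchange formats the pipeline owns.

Formats: 012 genotype matrix (TSV, rows = individuals, columns = loci,
missing = NA) with locus- and individual-metadata sidecars, a minimal VCF
subset (CHROM POS ID REF ALT + GT), pedigree CSV, captures CSV, MARK-style
.inp capture histories, and JSON reports.  Every writer/reader pair
round-trips losslessly for the fields the pipeline uses.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree


# ---------------------------------------------------------------------------
# 012 matrix
# ---------------------------------------------------------------------------


def write_genotypes_012(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write calls to <prefix>.012.tsv plus loci/individuals sidecars."""
    prefix = Path(prefix)
    df = pd.DataFrame(g.calls, index=g.individual_ids, columns=g.locus_ids)
    df.index.name = "id"
    with np.errstate(invalid="ignore"):
        out = df.where(~df.isna(), other=np.nan)
    out = out.astype("Int64")
    out.to_csv(Path(str(prefix) + ".012.tsv"), sep="\t", na_rep="NA")
    pd.DataFrame(
        {"locus": g.locus_ids, "chrom": g.chrom, "pos_bp": g.pos_bp}
    ).to_csv(Path(str(prefix) + ".loci.tsv"), sep="\t", index=False)
    pd.DataFrame({"id": g.individual_ids, "site": g.site_labels}).to_csv(
        Path(str(prefix) + ".individuals.tsv"), sep="\t", index=False
    )


def read_genotypes_012(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    df = pd.read_csv(
        Path(str(prefix) + ".012.tsv"), sep="\t", index_col="id", dtype={"id": str}
    )
    loci = pd.read_csv(Path(str(prefix) + ".loci.tsv"), sep="\t")
    ind = pd.read_csv(
        Path(str(prefix) + ".individuals.tsv"), sep="\t", dtype={"id": str}
    )
    if list(loci["locus"].astype(str)) != list(df.columns):
        raise ValueError("loci sidecar does not match 012 matrix columns")
    site = dict(zip(ind["id"].astype(str), ind["site"].astype(str)))
    return GenotypeMatrix(
        individual_ids=df.index.astype(str).to_numpy(dtype=object),
        locus_ids=np.array(df.columns, dtype=object),
        calls=df.to_numpy(dtype=float),
        chrom=loci["chrom"].astype(str).to_numpy(dtype=object),
        pos_bp=loci["pos_bp"].to_numpy(dtype=int),
        site_labels=np.array(
            [site.get(i, "") for i in df.index.astype(str)], dtype=object
        ),
    )


# ---------------------------------------------------------------------------
# minimal VCF
# ---------------------------------------------------------------------------

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Minimal diploid VCF: CHROM POS ID REF ALT QUAL FILTER INFO FORMAT GT."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for ch in pd.unique(g.chrom):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in g.individual_ids)
            + "\n"
        )
        for l in range(g.n_loci):
            gts = [
                "./." if np.isnan(c) else _GT_CODE[int(c)] for c in g.calls[:, l]
            ]
            fh.write(
                f"{g.chrom[l]}\t{g.pos_bp[l]}\t{g.locus_ids[l]}\tA\tT\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str | Path, site_labels: dict | None = None) -> GenotypeMatrix:
    """Read the GT field of a diploid VCF (cyvcf2 when available)."""
    path = str(path)
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 is an extra
        raise ImportError("reading VCF requires the cyvcf2 extra") from exc
    vcf = VCF(path)
    samples = list(vcf.samples)
    chrom, pos, lid, rows = [], [], [], []
    for var in vcf:
        chrom.append(var.CHROM)
        pos.append(var.POS)
        lid.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = np.array(var.gt_types, dtype=float)
        calls = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(calls)
    calls = np.column_stack(rows) if rows else np.zeros((len(samples), 0))
    site_labels = site_labels or {}
    return GenotypeMatrix(
        individual_ids=np.array(samples, dtype=object),
        locus_ids=np.array(lid, dtype=object),
        calls=calls,
        chrom=np.array(chrom, dtype=object),
        pos_bp=np.array(pos, dtype=int),
        site_labels=np.array([site_labels.get(s, "") for s in samples], dtype=object),
    )


# ---------------------------------------------------------------------------
# pedigree and captures CSV
# ---------------------------------------------------------------------------

PEDIGREE_COLUMNS = [
    "id", "dam", "sire", "sex", "birth_year", "byr_min", "byr_max",
    "genotyped", "dummy", "site",
]


def write_pedigree_csv(p: Pedigree, path: str | Path) -> None:
    p.table[PEDIGREE_COLUMNS].to_csv(path, index=False)


def read_pedigree_csv(path: str | Path) -> Pedigree:
    """Read and validate (referential integrity, sex, acyclicity) a pedigree."""
    t = pd.read_csv(path, dtype={"id": str, "dam": str, "sire": str})
    return Pedigree(t)


def write_captures_csv(captures: pd.DataFrame, path: str | Path) -> None:
    captures.to_csv(path, index=False)


def read_captures_csv(path: str | Path) -> pd.DataFrame:
    cap = pd.read_csv(path, dtype={"id": str, "site": str})
    missing = {"id", "site", "year"} - set(cap.columns)
    if missing:
        raise ValueError(f"captures CSV missing columns: {sorted(missing)}")
    cap["year"] = cap["year"].astype(int)
    if "svl_cm" in cap.columns and (cap["svl_cm"].dropna() <= 0).any():
        raise ValueError("svl_cm must be positive where present")
    return cap


# ---------------------------------------------------------------------------
# MARK-style .inp
# ---------------------------------------------------------------------------


def write_mark_inp(h, path: str | Path) -> None:
    """Export histories as '/* id */ 110.01 1;' with '.' for unsurveyed."""
    with open(Path(path), "w") as fh:
        for i in range(h.n_individuals):
            chars = [
                "." if not h.surveyed[i, t] else str(int(h.y[i, t]))
                for t in range(h.n_occasions)
            ]
            fh.write(f"/* {h.individual_ids[i]} */ {''.join(chars)} 1;\n")


# ---------------------------------------------------------------------------
# JSON report
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def write_report_json(report: dict, path: str | Path) -> None:
    """Deterministic JSON (sorted keys, no timestamps) for run reports."""
    with open(Path(path), "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True, allow_nan=False)
        fh.write("\n")
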