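"""File readers/writers and the multi-method comparison report.

Formats are deliberately plain: p-values as one- or two-column delimited
text, LD maps as square delimited numeric text (optional header row/column
of SNP ids), genotypes as delimited 0/1/2 tables or minimal VCF.  All
indices in outputs are 1-based SNP ordinals within the gene; genomic
positions from VCF are carried through as labels only.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .combine import combine
from .datatypes import GenotypeMatrix, InputError, LDMatrix, PValueSet
from .dependent import brown, strube
from .empirical import empirical_combine
from .neff import combine_keff, estimate_keff

__all__ = [
    "read_pvalues",
    "write_pvalues",
    "read_ld",
    "write_ld",
    "read_genotypes",
    "write_genotypes_table",
    "write_genotypes_vcf",
    "report_gene",
    "write_report",
]

_SPLIT = re.compile(r"[,\t ]+")


def _tokens(line: str):
    return [t for t in _SPLIT.split(line.strip()) if t]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_pvalues(path, gene_id: Optional[str] = None) -> PValueSet:
    """Read SNP p-values from one-column (p) or two-column (snp_id, p)
    delimited text; a header line is detected and skipped.  SNP order is
    preserved."""
    path = Path(path)
    lines = path.read_text().splitlines()
    ps, ids = [], []
    first_data = True
    for lineno, line in enumerate(lines, start=1):
        toks = _tokens(line)
        if not toks:
            continue
        if first_data and not _is_number(toks[-1]):
            first_data = False  # header
            continue
        first_data = False
        if len(toks) == 1:
            sid, tok = None, toks[0]
        elif len(toks) == 2:
            sid, tok = toks
        else:
            raise InputError(f"{path}:{lineno}: expected 1 or 2 columns, got {len(toks)}")
        if not _is_number(tok):
            raise InputError(f"{path}:{lineno}: non-numeric p-value {tok!r}")
        val = float(tok)
        if not (0.0 < val <= 1.0):
            raise InputError(f"{path}:{lineno}: p-value {val} outside (0, 1]")
        ps.append(val)
        ids.append(sid)
    if not ps:
        raise InputError(f"{path}: no p-values found")
    snp_ids = tuple(ids) if all(i is not None for i in ids) else None
    return PValueSet(gene_id=gene_id or path.stem, p=np.array(ps), snp_ids=snp_ids)


def write_pvalues(pset: PValueSet, path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(pset.p):
            sid = pset.snp_ids[i] if pset.snp_ids else f"snp{i + 1}"
            fh.write(f"{sid}\t{float(p)!r}\n")


def read_ld(path, expected_k: Optional[int] = None) -> LDMatrix:
    """Read a square LD matrix from delimited numeric text.

    A header row and/or a leading column of SNP ids is detected and used as
    labels.  ``expected_k`` enforces a strict dimension check against a
    companion p-value file.
    """
    path = Path(path)
    raw = [_tokens(l) for l in path.read_text().splitlines()]
    raw = [r for r in raw if r]
    if not raw:
        raise InputError(f"{path}: empty LD matrix file")
    header_ids = None
    if not all(_is_number(t) for t in raw[0]):
        header_ids = [t for t in raw[0]]
        raw = raw[1:]
    has_id_col = bool(raw) and not _is_number(raw[0][0])
    rows, row_ids = [], []
    for lineno, toks in enumerate(raw, start=1):
        if has_id_col:
            row_ids.append(toks[0])
            toks = toks[1:]
        if not all(_is_number(t) for t in toks):
            raise InputError(f"{path}: non-numeric matrix entry in data row {lineno}")
        rows.append([float(t) for t in toks])
    M = np.array(rows, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise InputError(f"{path}: LD matrix is not square (shape {M.shape})")
    if header_ids is not None and len(header_ids) == M.shape[0] + 1:
        header_ids = header_ids[1:]  # header included a corner label
    ids = tuple(row_ids) if row_ids else (tuple(header_ids) if header_ids else None)
    if ids is not None and len(ids) != M.shape[0]:
        ids = None
    if expected_k is not None and M.shape[0] != expected_k:
        raise InputError(
            f"{path}: LD matrix is {M.shape[0]}x{M.shape[0]} but {expected_k} SNP p-values were supplied"
        )
    return LDMatrix(M, snp_ids=ids)


def write_ld(R: LDMatrix, path) -> None:
    ids = R.snp_ids or tuple(f"snp{i + 1}" for i in range(R.k))
    with open(path, "w") as fh:
        fh.write("\t".join(ids) + "\n")
        for i in range(R.k):
            fh.write(ids[i] + "\t" + "\t".join(repr(float(v)) for v in R.R[i]) + "\n")


def read_genotypes(path, format: str = "table") -> GenotypeMatrix:
    """Read genotypes as a delimited 0/1/2 table (rows = individuals) or a
    diploid VCF.

    VCF sites are mapped to minor-allele dosage: the ALT-allele count per
    individual, flipped when the ALT allele is the major one, so that code 2
    is always the minor-allele homozygote.  Missing genotypes, non-biallelic
    sites and non-diploid calls are rejected with the offending record
    named.
    """
    if format == "table":
        return _read_genotype_table(path)
    if format == "vcf":
        return _read_genotype_vcf(path)
    raise InputError(f"unknown genotype format {format!r}")


def _read_genotype_table(path) -> GenotypeMatrix:
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if _tokens(l)]
    if not lines:
        raise InputError(f"{path}: empty genotype file")
    toks0 = _tokens(lines[0])
    ids = None
    if not all(_is_number(t) for t in toks0):
        ids = tuple(toks0)
        lines = lines[1:]
    rows = []
    for lineno, line in enumerate(lines, start=1):
        toks = _tokens(line)
        if not all(t in ("0", "1", "2") for t in toks):
            raise InputError(f"{path}: genotype codes must be 0/1/2 (data row {lineno})")
        rows.append([int(t) for t in toks])
    G = np.array(rows, dtype=np.int8)
    freq = G.mean(axis=0) / 2.0
    flip = freq > 0.5
    if np.any(flip):
        G = G.copy()
        G[:, flip] = 2 - G[:, flip]
    return GenotypeMatrix(G, snp_ids=ids)


def _read_genotype_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    cols, ids = [], []
    vcf = VCF(str(path))
    try:
        for v in vcf:
            label = v.ID or f"{v.CHROM}:{v.POS}"
            if len(v.ALT) != 1:
                raise InputError(f"{path}: site {label} is not biallelic")
            dosages = []
            for gt in v.genotypes:
                alleles = gt[:-1]
                if len(alleles) != 2:
                    raise InputError(f"{path}: site {label} has ploidy {len(alleles)} != 2")
                if any(a < 0 for a in alleles):
                    raise InputError(f"{path}: missing genotype at site {label}")
                dosages.append(sum(1 for a in alleles if a == 1))
            cols.append(dosages)
            ids.append(label)
    finally:
        vcf.close()
    if not cols:
        raise InputError(f"{path}: no variant records found")
    G = np.array(cols, dtype=np.int8).T  # individuals x SNPs
    freq = G.mean(axis=0) / 2.0
    flip = freq > 0.5
    G[:, flip] = 2 - G[:, flip]
    return GenotypeMatrix(G, snp_ids=tuple(ids))


def write_genotypes_table(G: GenotypeMatrix, path) -> None:
    ids = G.snp_ids or tuple(f"snp{i + 1}" for i in range(G.k))
    with open(path, "w") as fh:
        fh.write("\t".join(ids) + "\n")
        for row in G.G:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def write_genotypes_vcf(G: GenotypeMatrix, path, chrom: str = "1") -> None:
    """Write a minimal diploid VCF; positions are 1-based SNP ordinals and
    the minor allele is written as ALT, so round-tripping preserves codes."""
    ids = G.snp_ids or tuple(f"snp{i + 1}" for i in range(G.k))
    n = G.n
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"ind{j + 1}" for j in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i in range(G.k):
            gts = "\t".join(gt_map[int(v)] for v in G.G[:, i])
            fh.write(f"{chrom}\t{i + 1}\t{ids[i]}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


_KEFF_COLS = ("nyholt", "liji", "gao", "galwey")
_REPORT_COLS = ("unadjusted",) + _KEFF_COLS + ("empirical", "dependence")


def report_gene(
    pset: PValueSet,
    R: LDMatrix,
    alpha_p: float = 0.05,
    s: int = 100_000,
    seed=None,
    gao_C: float = 0.995,
) -> pd.DataFrame:
    """Combined p-values for one gene under every method/adjustment pair.

    Rows are the five base methods; columns are the unadjusted method, the
    four keff adjustments, the empirical (pseudo-permutation) calibration
    and the dependence-aware analytic form — the latter only for Fisher
    (Brown's method) and Stouffer (Strube's method).  The SNP count, the
    four keff estimates, the empirical sample count and seed are attached
    as ``DataFrame.attrs``.
    """
    if R.k != pset.k:
        raise InputError(f"LD matrix is {R.k}x{R.k} but the p-value set has {pset.k} SNPs")
    keffs = {est: estimate_keff(R, est, C=gao_C) for est in _KEFF_COLS}
    methods = ("bonferroni", "tippett", "binomial", "fisher", "stouffer")
    table = pd.DataFrame(index=list(methods), columns=list(_REPORT_COLS), dtype=float)
    repaired = False
    for m in methods:
        table.loc[m, "unadjusted"] = combine(pset, m, alpha_p=alpha_p).p
        for est in _KEFF_COLS:
            table.loc[m, est] = combine_keff(pset, keffs[est], m, alpha_p=alpha_p).p
        emp = empirical_combine(pset, R, m, s=s, seed=seed, alpha_p=alpha_p)
        repaired = repaired or emp.info["repaired"]
        table.loc[m, "empirical"] = emp.p
    table.loc["fisher", "dependence"] = brown(pset, R).p
    table.loc["stouffer", "dependence"] = strube(pset, R).p
    table.attrs.update(
        {
            "gene_id": pset.gene_id,
            "k": pset.k,
            "keff": {est: keffs[est].keff for est in _KEFF_COLS},
            "s": int(s),
            "seed": seed,
            "ld_repaired": repaired,
        }
    )
    return table


def write_report(table: pd.DataFrame, path) -> None:
    """Write a report table as tab-separated text with '.' for
    not-applicable cells and a commented header echoing k and the keff
    estimates."""
    with open(path, "w") as fh:
        a = table.attrs
        if a:
            keffs = " ".join(f"keff_{k}={v!r}" for k, v in a.get("keff", {}).items())
            fh.write(f"# gene={a.get('gene_id')} k={a.get('k')} {keffs}\n")
            fh.write(f"# empirical: s={a.get('s')} seed={a.get('seed')} ld_repaired={a.get('ld_repaired')}\n")
        fh.write("method\t" + "\t".join(table.columns) + "\n")
        for m, row in table.iterrows():
            cells = [("." if pd.isna(v) else repr(float(v))) for v in row]
            fh.write(m + "\t" + "\t".join(cells) + "\n")
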