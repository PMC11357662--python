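"""Readers and writers for the pipeline's file formats.

Formats: PGS-Catalog-style scoring file (TSV: variant_id, effect_allele,
other_allele, effect_weight), a plain dosage matrix TSV (participants x
variants), VCF 4.2 with a DS FORMAT field (GT fallback on read), and the
phenotype/covariate CSV with colonoscopy findings stored as a JSON column.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ScoringFileError
from .prs import GenotypeMatrix, VariantWeight

SCORING_COLUMNS = ("variant_id", "effect_allele", "other_allele", "effect_weight")


def read_scoring_file(path) -> list[VariantWeight]:
    """Parse a variant scoring file into an ordered list of weights.

    Raises :class:`ScoringFileError` naming the offending line on a missing
    column, a duplicated variant ID or a non-numeric weight.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ScoringFileError(f"{path}: empty file") from None
        missing = [c for c in SCORING_COLUMNS if c not in header]
        if missing:
            raise ScoringFileError(
                f"{path}, line 1: missing required column(s) {', '.join(missing)}"
            )
        idx = {c: header.index(c) for c in SCORING_COLUMNS}
        weights: list[VariantWeight] = []
        seen: dict[str, int] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            vid = row[idx["variant_id"]]
            if vid in seen:
                raise ScoringFileError(
                    f"{path}, line {lineno}: duplicate variant ID {vid} "
                    f"(first seen on line {seen[vid]})"
                )
            seen[vid] = lineno
            raw = row[idx["effect_weight"]]
            try:
                w = float(raw)
            except ValueError:
                raise ScoringFileError(
                    f"{path}, line {lineno}: non-numeric weight {raw!r}"
                ) from None
            if not math.isfinite(w):
                raise ScoringFileError(
                    f"{path}, line {lineno}: non-finite weight {raw!r}"
                )
            weights.append(
                VariantWeight(vid, row[idx["effect_allele"]],
                              row[idx["other_allele"]], w)
            )
    return weights


def write_scoring_file(weights, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SCORING_COLUMNS)
        for w in weights:
            writer.writerow(
                [w.variant_id, w.effect_allele, w.other_allele, repr(w.weight)]
            )


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Participants x variants dosage TSV; header row holds variant IDs."""
    df = pd.DataFrame(genotypes.dosages, index=genotypes.participant_ids,
                      columns=genotypes.variant_ids)
    df.to_csv(path, sep="\t", index_label="participant_id")


def read_dosage_tsv(path, counted_alleles=None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="participant_id",
                     float_precision="round_trip")
    return GenotypeMatrix(df.index.astype(str), df.columns, df.to_numpy(float),
                          counted_alleles=counted_alleles)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a VCF 4.2 with per-sample DS dosage (and GT for hard calls).

    REF is the variant's other allele and ALT its counted allele, so the DS
    field is the counted-allele dosage. Continuous (imputed) dosages get
    GT ``./.``.
    """
    if genotypes.counted_alleles is None:
        raise ValueError("VCF output requires allele information per variant")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, genotypes.participant_ids)) + "\n")
        for j, vid in enumerate(genotypes.variant_ids):
            counted, other = genotypes.counted_alleles[vid]
            fields = ["1", str(j + 1), vid, other, counted, ".", "PASS", ".", "GT:DS"]
            for g in genotypes.dosages[:, j]:
                if np.isnan(g):
                    fields.append("./.:.")
                elif float(g).is_integer():
                    k = int(g)
                    gt = ["0/0", "0/1", "1/1"][k]
                    fields.append(f"{gt}:{g:g}")
                else:
                    fields.append(f"./.:{g:.6g}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read dosages from a VCF: DS FORMAT field preferred, GT fallback.

    The counted allele is the ALT allele; multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variant_ids, columns, alleles = [], [], {}
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"{v.ID}: multi-allelic records are not supported")
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).ravel()
            col = np.where(col < -0.5, np.nan, col)  # cyvcf2 encodes '.' as negative
        else:
            gts = np.asarray([g[:2] for g in v.genotypes])
            col = np.where((gts < 0).any(axis=1), np.nan,
                           (gts > 0).sum(axis=1)).astype(float)
        variant_ids.append(v.ID)
        columns.append(col)
        alleles[v.ID] = (v.ALT[0], v.REF)
    return GenotypeMatrix(samples, variant_ids, np.column_stack(columns),
                          counted_alleles=alleles)


def write_phenotypes(table: pd.DataFrame, path) -> None:
    """Phenotype/covariate CSV; the findings list serialises to a JSON column."""
    out = table.copy()
    if "findings" in out.columns:
        out["findings"] = [
            json.dumps(f) if isinstance(f, (list, tuple)) else f
            for f in out["findings"]
        ]
    out.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "findings" in df.columns:
        df["findings"] = [
            json.loads(s) if isinstance(s, str) else [] for s in df["findings"]
        ]
    return df
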