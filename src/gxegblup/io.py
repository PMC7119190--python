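"""Plain-text interchange formats.

Canonical formats are TSV for matrices and tables and JSON/YAML for
configuration and reports:

- genotypes: first column ``line``, header row of marker ids, cells in
  {0, 1, 2, NA} (biallelic) or {0, 1, NA} (dominant);
- phenotypes: long table with columns ``line``, ``env``, optional ``rep``
  and ``block``, ``value``;
- kinship: symmetric matrix with line ids as header and first column;
- PC scores: ``line``, ``PC1..PCc`` plus a JSON sidecar with eigenvalues
  and variance proportions.

VCF is accepted as an input-only convenience (diploid biallelic records;
multiallelic sites are skipped and counted).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import GenomicRelationship, PCProjection
from .markers import Coding, MarkerMatrix
from .model import PhenotypeTable

logger = logging.getLogger("gxegblup")

__all__ = [
    "read_genotypes_tsv", "write_genotypes_tsv", "read_genotypes_vcf",
    "read_phenotypes_tsv", "write_phenotypes_tsv",
    "read_kinship_tsv", "write_kinship_tsv",
    "write_pca_tsv", "read_family_map_tsv", "write_family_map_tsv",
]

_NA = {"", "NA", "NaN", "nan", ".", "-9"}


def read_genotypes_tsv(path, coding: Coding | None = None,
                       sep: str = "\t") -> MarkerMatrix:
    """Read a lines x markers dosage table; coding is inferred if omitted."""
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(_NA),
                     keep_default_na=False)
    dosages = df.to_numpy(dtype=float)
    if coding is None:
        vals = dosages[~np.isnan(dosages)]
        coding = Coding.BIALLELIC_012 if (vals == 2).any() else Coding.DOMINANT_01
    return MarkerMatrix(tuple(df.index.astype(str)),
                        tuple(df.columns.astype(str)), dosages, coding)


def write_genotypes_tsv(m: MarkerMatrix, path, sep: str = "\t") -> None:
    d = np.where(m.missing_mask, np.nan, m.dosages)
    df = pd.DataFrame(d, index=list(m.line_ids), columns=list(m.marker_ids))
    df.index.name = "line"
    df.to_csv(path, sep=sep, na_rep="NA", float_format="%.6g")


def read_genotypes_vcf(path) -> MarkerMatrix:
    """Convert diploid biallelic VCF genotypes to 0/1/2 dosages.

    Multiallelic records are skipped (a count is logged); missing calls
    become NA.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path), gts012=True)
    samples = tuple(vcf.samples)
    rows, ids, skipped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gt = var.gt_types.astype(float)  # 0,1,2 and 3 = unknown
        gt[gt == 3] = np.nan
        rows.append(gt)
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
    if skipped:
        logger.info("skipped %d multiallelic VCF records", skipped)
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return MarkerMatrix(samples, tuple(ids), dosages, Coding.BIALLELIC_012)


def read_phenotypes_tsv(path, sep: str = "\t", line_col: str = "line",
                        env_col: str = "env", value_col: str = "value",
                        rep_col: str | None = "rep",
                        block_col: str | None = "block") -> PhenotypeTable:
    df = pd.read_csv(path, sep=sep)
    for col, name in ((line_col, "line"), (env_col, "env"),
                      (value_col, "value")):
        if col not in df.columns:
            raise ValueError(f"phenotype file lacks the {name} column "
                             f"{col!r} (columns: {list(df.columns)})")
    return PhenotypeTable.from_dataframe(
        df, line_col=line_col, env_col=env_col, value_col=value_col,
        rep_col=rep_col if rep_col in df.columns else None,
        block_col=block_col if block_col in df.columns else None)


def write_phenotypes_tsv(pheno: PhenotypeTable, path, sep: str = "\t") -> None:
    pheno.df.to_csv(path, sep=sep, index=False)


def read_kinship_tsv(path, sep: str = "\t") -> GenomicRelationship:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("kinship file rows and columns disagree")
    return GenomicRelationship(tuple(df.index.astype(str)),
                               df.to_numpy(dtype=float))


def write_kinship_tsv(g: GenomicRelationship, path, sep: str = "\t") -> None:
    df = pd.DataFrame(g.K, index=list(g.line_ids), columns=list(g.line_ids))
    df.index.name = "line"
    df.to_csv(path, sep=sep, float_format="%.10g")


def write_pca_tsv(pc: PCProjection, path, sidecar_path=None,
                  sep: str = "\t") -> None:
    ncomp = pc.scores.shape[1]
    df = pd.DataFrame(pc.scores, index=list(pc.line_ids),
                      columns=[f"PC{i + 1}" for i in range(ncomp)])
    df.index.name = "line"
    df.to_csv(path, sep=sep, float_format="%.10g")
    if sidecar_path is None:
        sidecar_path = Path(path).with_suffix(".json")
    with open(sidecar_path, "w") as fh:
        json.dump({"eigenvalues": pc.eigenvalues.tolist(),
                   "prop_var": pc.prop_var.tolist()}, fh, indent=1)


def read_family_map_tsv(path, sep: str = "\t") -> dict:
    df = pd.read_csv(path, sep=sep)
    if not {"line", "family"} <= set(df.columns):
        raise ValueError("family map needs columns 'line' and 'family'")
    return dict(zip(df["line"].astype(str), df["family"].astype(str)))


def write_family_map_tsv(labels: dict, path, sep: str = "\t") -> None:
    pd.DataFrame(sorted(labels.items()),
                 columns=["line", "family"]).to_csv(path, sep=sep,
                                                    index=False)
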