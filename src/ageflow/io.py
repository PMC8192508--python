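"""Readers and writers for every on-disk artifact.

All tables are plain TSV. Coordinates are 0-based half-open on disk and in
memory. Regulatory-edge signs are normalized to integers {-1, +1} at parse
time; duplicate parallel edges keep the first occurrence and log the rest.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CohortTable,
    ExpressionMatrix,
    FormatError,
    GeneAnnotation,
    MethylationMatrix,
    PerturbationProfiles,
)

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_counts",
    "write_counts",
    "read_cohort",
    "write_cohort",
    "read_annotation",
    "write_annotation",
    "read_grn_edges",
    "write_grn_edges",
    "read_perturbation_profiles",
    "write_perturbation_profiles",
]

logger = logging.getLogger(__name__)

_SIGN_TOKENS = {
    "+1": 1, "1": 1, "+": 1, "activates": 1, "activation": 1,
    "-1": -1, "-": -1, "inhibits": -1, "inhibition": -1,
}


def read_beta_matrix(path: str | Path, one_based: bool = False) -> MethylationMatrix:
    """Beta-value TSV: header row of sample ids after chrom, pos columns.

    ``one_based=True`` converts incoming 1-based positions to the package's
    0-based convention; this is the only place 1-based input is accepted.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3 or list(df.columns[:2]) != ["chrom", "pos"]:
        raise FormatError(f"{path}: expected columns chrom, pos, <samples...>")
    pos = df["pos"].to_numpy(int) - (1 if one_based else 0)
    beta = df.iloc[:, 2:].astype(float)
    bad = np.argwhere((beta.to_numpy() < 0) | (beta.to_numpy() > 1))
    if bad.size:
        row = int(bad[0][0])
        raise FormatError(f"{path}: beta outside [0,1] at data row {row + 1}")
    if df.duplicated(subset=["chrom", "pos"]).any():
        dup = df.loc[df.duplicated(subset=["chrom", "pos"]), ["chrom", "pos"]].iloc[0]
        raise FormatError(f"{path}: duplicate position {dup['chrom']}:{dup['pos']}")
    return MethylationMatrix.from_beta(df["chrom"].to_numpy(), pos, beta)


def write_beta_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    out = matrix.positions.copy()
    out[matrix.beta.columns] = matrix.beta
    out.to_csv(path, sep="\t", index=False)  # default repr round-trips floats


def read_counts(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be gene_id")
    counts = df.set_index("gene_id").rename_axis(None)
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or (vals < 0).any():
        raise FormatError(f"{path}: counts must be non-negative numbers")
    if not np.allclose(vals, np.round(vals)):
        raise FormatError(f"{path}: counts must be integers")
    return ExpressionMatrix(counts.astype(int))


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_cohort(path: str | Path) -> CohortTable:
    return CohortTable(pd.read_csv(path, sep="\t"))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> GeneAnnotation:
    """BED6+2-style annotation: chrom, start, end, gene_id, score, strand,
    tss, is_tf. Start/end become the 0-based half-open gene body."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "body_start", "body_end", "gene_id", "score", "strand", "tss", "is_tf"],
        header=0,
    )
    df["is_tf"] = df["is_tf"].astype(int).astype(bool)
    return GeneAnnotation(
        df[["gene_id", "chrom", "tss", "body_start", "body_end", "strand", "is_tf"]]
    )


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    t = annotation.table
    out = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "body_start": t["body_start"],
            "body_end": t["body_end"],
            "gene_id": t["gene_id"],
            "score": 0,
            "strand": t["strand"],
            "tss": t["tss"],
            "is_tf": t["is_tf"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def _parse_sign(token) -> int:
    key = str(token).strip().lower()
    if key in _SIGN_TOKENS:
        return _SIGN_TOKENS[key]
    # numeric forms like 1.0 / -1.0
    try:
        val = float(key)
    except ValueError:
        raise FormatError(f"unknown sign token {token!r}") from None
    if val in (1.0, -1.0):
        return int(val)
    raise FormatError(f"unknown sign token {token!r}")


def read_grn_edges(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Canonical GRN edge list, TSV (source, target[, sign]) or SIF
    (source, relation, target) with relation in {activates, inhibits}.

    Parallel duplicate edges collapse to the first occurrence (logged);
    self-loops are retained here and removed during subnetwork extraction.
    """
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if dialect == "sif":
                if len(parts) != 3:
                    raise FormatError(f"{path}:{line_no}: SIF line needs 3 fields")
                src, rel, tgt = parts
                rows.append((src, tgt, _parse_sign(rel)))
            else:
                if line_no == 1 and parts[0].lower() in ("source", "src"):
                    continue
                if len(parts) == 2:
                    rows.append((parts[0], parts[1], np.nan))
                elif len(parts) == 3:
                    rows.append((parts[0], parts[1], _parse_sign(parts[2])))
                else:
                    raise FormatError(f"{path}:{line_no}: expected 2 or 3 fields")
    df = pd.DataFrame(rows, columns=["source", "target", "sign"])
    dup = df.duplicated(subset=["source", "target"])
    if dup.any():
        for _, r in df[dup].iterrows():
            logger.warning("duplicate edge %s->%s dropped (first kept)", r["source"], r["target"])
        df = df[~dup]
    return df.reset_index(drop=True)


def write_grn_edges(edges: pd.DataFrame, path: str | Path) -> None:
    out = edges.copy()
    if "sign" in out.columns:
        out["sign"] = out["sign"].map(lambda s: "" if pd.isna(s) else str(int(s)))
    out.to_csv(path, sep="\t", index=False)


def read_perturbation_profiles(path: str | Path) -> PerturbationProfiles:
    """GCT-like TSV: gene_id column then one column per condition, each
    labelled ``drug|dose|time``, holding modZ scores."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be gene_id")
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows / missing modZ values")
    modz = df.set_index("gene_id").rename_axis(None).astype(float)
    return PerturbationProfiles.from_modz(modz)


def write_perturbation_profiles(profiles: PerturbationProfiles, path: str | Path) -> None:
    profiles.modz.rename_axis("gene_id").to_csv(path, sep="\t")
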