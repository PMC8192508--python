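"""In-memory containers shared across the pipeline.

All genomic coordinates are 0-based, half-open. Methylation is stored as
beta values (fraction methylated) in [0, 1]; expression as non-negative
integer counts with size-factor normalization computed on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "GeneAnnotation",
    "MethylationMatrix",
    "ExpressionMatrix",
    "PerturbationProfiles",
    "SignedGRN",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its schema or invariants."""


SEXES = ("male", "female")
SMOKING = ("smoker", "non_smoker", "unknown")


@dataclass
class CohortTable:
    """Sample metadata: one row per sample with age, sex and smoking status."""

    table: pd.DataFrame  # columns: sample_id, age, sex, smoking

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample_id", "age", "sex", "smoking"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FormatError(f"cohort table missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        if t["age"].isna().any() or t["sex"].isna().any():
            raise FormatError("missing age or sex")
        ages = t["age"].to_numpy(float)
        if not ((ages > 0) & (ages < 120)).all():
            raise FormatError("ages must lie in (0, 120)")
        bad = set(t["sex"]) - set(SEXES)
        if bad:
            raise FormatError(f"unknown sex labels: {sorted(bad)}")
        bad = set(t["smoking"]) - set(SMOKING)
        if bad:
            raise FormatError(f"unknown smoking labels: {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def ages(self) -> pd.Series:
        return pd.Series(
            self.table["age"].to_numpy(float),
            index=self.table["sample_id"].to_numpy(),
            name="age",
        )

    @property
    def sexes(self) -> pd.Series:
        return pd.Series(
            self.table["sex"].to_numpy(),
            index=self.table["sample_id"].to_numpy(),
            name="sex",
        )

    def __len__(self) -> int:
        return len(self.table)

    def summary(self) -> dict:
        """Composition summary: counts, percentages and age statistics."""
        t = self.table
        n = len(t)
        n_male = int((t["sex"] == "male").sum())
        n_smoker = int((t["smoking"] == "smoker").sum())
        ages = t["age"].to_numpy(float)
        return {
            "n": n,
            "n_male": n_male,
            "n_female": n - n_male,
            "pct_male": 100.0 * n_male / n,
            "pct_female": 100.0 * (n - n_male) / n,
            "n_smoker": n_smoker,
            "age_mean": float(ages.mean()),
            "age_sd": float(ages.std(ddof=1)),
            "age_min": float(ages.min()),
            "age_max": float(ages.max()),
        }


@dataclass
class GeneAnnotation:
    """Gene coordinates (BED-like, 0-based half-open body) plus TF flags."""

    table: pd.DataFrame  # columns: gene_id, chrom, tss, body_start, body_end, strand, is_tf

    def __post_init__(self) -> None:
        t = self.table
        required = ["gene_id", "chrom", "tss", "body_start", "body_end", "strand", "is_tf"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FormatError(f"gene annotation missing columns: {missing}")
        if t["gene_id"].duplicated().any():
            raise FormatError("duplicate gene_id in annotation")
        if not (t["body_start"] < t["body_end"]).all():
            raise FormatError("body_start must be < body_end")
        bad = set(t["strand"]) - {"+", "-"}
        if bad:
            raise FormatError(f"unknown strand symbols: {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    @property
    def tf_ids(self) -> list[str]:
        t = self.table
        return list(t.loc[t["is_tf"].astype(bool), "gene_id"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MethylationMatrix:
    """CpG beta values: ``positions`` (chrom, pos per row) and ``beta``
    (positions x samples), sharing a ``chrom:pos`` string index."""

    positions: pd.DataFrame  # index: position_id; columns: chrom, pos
    beta: pd.DataFrame  # index: position_id; columns: sample ids

    def __post_init__(self) -> None:
        if not self.positions.index.equals(self.beta.index):
            raise FormatError("positions and beta indexes differ")
        if self.positions.index.duplicated().any():
            dup = self.positions.index[self.positions.index.duplicated()][0]
            raise FormatError(f"duplicate position {dup}")
        vals = self.beta.to_numpy(float)
        if np.isnan(vals).any():
            raise FormatError("missing beta values")
        if (vals < 0).any() or (vals > 1).any():
            bad = np.argwhere((vals < 0) | (vals > 1))[0]
            raise FormatError(
                f"beta value outside [0,1] at row {self.beta.index[bad[0]]!r}, "
                f"sample {self.beta.columns[bad[1]]!r}"
            )
        order = self.positions.sort_values(["chrom", "pos"]).index
        self.positions = self.positions.loc[order]
        self.beta = self.beta.loc[order]

    @property
    def position_ids(self) -> list[str]:
        return list(self.positions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    @staticmethod
    def position_id(chrom: str, pos: int) -> str:
        return f"{chrom}:{pos}"

    @classmethod
    def from_beta(cls, chrom: np.ndarray, pos: np.ndarray, beta: pd.DataFrame) -> "MethylationMatrix":
        ids = [cls.position_id(c, p) for c, p in zip(chrom, pos)]
        positions = pd.DataFrame({"chrom": chrom, "pos": pos}, index=ids)
        beta = beta.set_axis(ids, axis=0)
        return cls(positions, beta)


@dataclass
class ExpressionMatrix:
    """Raw gene expression counts (genes x samples) with DESeq-style
    median-of-ratios size factors and log2 normalized values on demand."""

    counts: pd.DataFrame  # index: gene ids; columns: sample ids
    _size_factors: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise FormatError("negative counts")
        if self.counts.index.duplicated().any():
            raise FormatError("duplicate gene ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def size_factors(self) -> pd.Series:
        """Median-of-ratios size factors over genes expressed in every sample."""
        if self._size_factors is None:
            vals = self.counts.to_numpy(float)
            with np.errstate(divide="ignore"):
                logs = np.log(vals)
            ref = logs.mean(axis=1)  # log geometric mean per gene
            usable = np.isfinite(ref)
            if not usable.any():
                sf = np.ones(vals.shape[1])
            else:
                ratios = logs[usable] - ref[usable, None]
                sf = np.exp(np.median(ratios, axis=0))
            self._size_factors = pd.Series(sf, index=self.counts.columns, name="size_factor")
        return self._size_factors

    def normalized(self) -> pd.DataFrame:
        return self.counts / self.size_factors()

    def log_normalized(self) -> pd.DataFrame:
        return np.log2(self.normalized() + 1.0)


@dataclass
class PerturbationProfiles:
    """Drug perturbation modZ scores: genes x conditions, each condition a
    (drug, dose, time) triple with a ``drug|dose|time`` column label."""

    modz: pd.DataFrame  # index: gene ids; columns: condition labels "drug|dose|time"
    conditions: pd.DataFrame  # index: condition labels; columns: drug, dose, time

    def __post_init__(self) -> None:
        if list(self.modz.columns) != list(self.conditions.index):
            raise FormatError("modZ columns and condition metadata disagree")
        for col in ("drug", "dose", "time"):
            if col not in self.conditions.columns:
                raise FormatError(f"condition metadata missing {col!r}")

    @property
    def drugs(self) -> list[str]:
        return list(dict.fromkeys(self.conditions["drug"]))

    @classmethod
    def from_modz(cls, modz: pd.DataFrame) -> "PerturbationProfiles":
        meta = []
        for label in modz.columns:
            parts = str(label).split("|")
            if len(parts) != 3:
                raise FormatError(
                    f"condition label {label!r} is not of the form drug|dose|time"
                )
            meta.append(parts)
        conditions = pd.DataFrame(meta, columns=["drug", "dose", "time"], index=modz.columns)
        return cls(modz, conditions)


ROLES = ("input", "intermediate", "output")


@dataclass
class SignedGRN:
    """Directed TF->target regulatory graph with per-edge mode of action.

    Edge attribute ``sign`` is -1 (inhibition) or +1 (activation); optional
    ``partial_r``/``partial_p`` carry the statistics the sign came from.
    Node attribute ``role`` is input / intermediate / output.
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        loops = list(nx.nodes_with_selfloops(self.graph))
        if loops:
            raise FormatError(f"self-loops not allowed in a signed GRN: {loops[:3]}")
        for u, v, d in self.graph.edges(data=True):
            if d.get("sign") not in (-1, 1):
                raise FormatError(f"edge {u}->{v} missing sign in {{-1,+1}}")

    def _role(self, role: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("role") == role]

    @property
    def inputs(self) -> list[str]:
        return self._role("input")

    @property
    def outputs(self) -> list[str]:
        return self._role("output")

    @property
    def intermediates(self) -> list[str]:
        return self._role("intermediate")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_sign(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["sign"]

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, **d} for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "sign", "pearson_r",
                                           "pearson_p", "partial_r", "partial_p"])

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str, int]],
        inputs: set[str] | list[str] = (),
        outputs: set[str] | list[str] = (),
    ) -> "SignedGRN":
        g = nx.DiGraph()
        inputs, outputs = set(inputs), set(outputs)
        for u, v, s in edges:
            g.add_edge(u, v, sign=int(s))
        for n in g.nodes:
            if n in inputs:
                g.nodes[n]["role"] = "input"
            elif n in outputs:
                g.nodes[n]["role"] = "output"
            else:
                g.nodes[n]["role"] = "intermediate"
        return cls(g)
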