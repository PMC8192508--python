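"""Aging marker identification.

DMPs are CpG positions whose beta value correlates with age (Pearson, raw
two-sided P < 0.05; no multiple-testing correction — the test count dwarfs
the sample count and the positions feed a downstream network filter). DEGs
are genes whose counts change per year of age under a negative-binomial GLM
(log link, design intercept + age + sex, library-size offset), with
Benjamini-Hochberg adjustment. DMPs are linked to transcription-factor
genes whose TSS or gene body lies within a 5 kb window, via the Pearson
correlation of beta with log2 normalized expression; per TF the most
significant link is the representative. Marker panels are compared with a
hypergeometric upper-tail overlap test.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CohortTable, ExpressionMatrix, GeneAnnotation, MethylationMatrix

__all__ = [
    "adjust_sex",
    "call_dmps",
    "call_degs",
    "link_dmp_to_tf",
    "overlap_enrichment",
    "pearson_p_from_r",
]

logger = logging.getLogger(__name__)


def pearson_p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided P for a Pearson correlation via the t transform,
    t = r sqrt(n-2) / sqrt(1 - r^2) on n-2 degrees of freedom."""
    r = np.clip(np.asarray(r, float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def _pearson_rows(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson correlation of a matrix against one vector."""
    vc = values - values.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((vc * vc).sum(axis=1) * (yc * yc).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (vc @ yc) / denom
    return r, denom


def adjust_sex(matrix: MethylationMatrix, cohort: CohortTable) -> MethylationMatrix:
    """Remove the additive sex offset per position.

    Each sex group's mean is shifted to the pooled mean (a two-level,
    location-only batch adjustment); output is clipped back to [0, 1].
    Skipped with a warning when either sex has fewer than 2 samples.
    """
    sexes = cohort.sexes.reindex(matrix.sample_ids)
    if sexes.isna().any():
        raise ValueError("samples in matrix missing from cohort")
    groups = sexes.value_counts()
    if groups.reindex(["male", "female"]).fillna(0).min() < 2:
        warnings.warn("a sex group has < 2 samples; sex adjustment skipped", stacklevel=2)
        return matrix
    vals = matrix.beta.to_numpy(float).copy()
    pooled = vals.mean(axis=1, keepdims=True)
    for sex in ("male", "female"):
        cols = (sexes == sex).to_numpy()
        group_mean = vals[:, cols].mean(axis=1, keepdims=True)
        vals[:, cols] += pooled - group_mean
    vals = np.clip(vals, 0.0, 1.0)
    beta = pd.DataFrame(vals, index=matrix.beta.index, columns=matrix.beta.columns)
    return MethylationMatrix(matrix.positions.copy(), beta)


def call_dmps(
    matrix: MethylationMatrix,
    cohort: CohortTable,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-position Pearson correlation of beta with age.

    Returns a frame with feature_id, r, p, direction and an ``is_dmp`` flag
    (raw p < threshold). Zero-variance positions are untestable and excluded;
    their count is in ``.attrs['n_untestable']``.
    """
    if len(cohort) < 4:
        raise ValueError("at least 4 samples required")
    ages = cohort.ages.reindex(matrix.sample_ids).to_numpy(float)
    vals = matrix.beta.to_numpy(float)
    r, denom = _pearson_rows(vals, ages)
    testable = denom > 0
    r = r[testable]
    p = pearson_p_from_r(r, len(ages))
    out = pd.DataFrame(
        {
            "feature_id": matrix.beta.index[testable],
            "r": r,
            "p": p,
            "direction": np.sign(r).astype(int),
            "is_dmp": p < p_threshold,
        }
    ).reset_index(drop=True)
    out.attrs["n_untestable"] = int((~testable).sum())
    return out


def _mom_dispersion(q: np.ndarray) -> float:
    """Method-of-moments NB2 dispersion from normalized counts, floored."""
    m = q.mean()
    if m <= 0:
        return 1e-8
    v = q.var(ddof=1)
    return max((v - m) / (m * m), 1e-8)


def call_degs(
    counts: ExpressionMatrix,
    cohort: CohortTable,
    alpha_adj: float = 0.05,
) -> pd.DataFrame:
    """Differential expression over age by per-gene negative-binomial GLM.

    Design: intercept + age + sex, log link, log size-factor offset; Wald
    test on the age coefficient; BH adjustment across tested genes.
    ``lfc_per_year`` is the age coefficient converted to log2 units.
    All-zero genes are excluded; a gene whose NB fit fails falls back to a
    Gaussian fit on log2(normalized + 1), flagged in the output.
    """
    import statsmodels.api as sm

    if len(cohort) < 6:
        raise ValueError("at least 6 samples required")
    samples = counts.sample_ids
    ages = cohort.ages.reindex(samples).to_numpy(float)
    sex_male = (cohort.sexes.reindex(samples) == "male").to_numpy(float)
    X = np.column_stack([np.ones_like(ages), ages, sex_male])
    sf = counts.size_factors().to_numpy(float)
    offset = np.log(sf)
    raw = counts.counts.to_numpy(float)
    norm = raw / sf
    logn = np.log2(norm + 1.0)

    records = []
    for gi, gene in enumerate(counts.gene_ids):
        y = raw[gi]
        if y.max() == 0:
            continue
        disp = _mom_dispersion(norm[gi])
        fallback = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(
                    y, X, family=sm.families.NegativeBinomial(alpha=disp), offset=offset
                )
                res = model.fit(maxiter=100)
            if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
                raise ValueError("non-finite NB fit")
            beta_age = res.params[1]
            p = res.pvalues[1]
        except Exception:
            fallback = True
            ols = sm.OLS(logn[gi], X).fit()
            beta_age = ols.params[1] * np.log(2.0)  # back to natural-log scale
            p = ols.pvalues[1]
            logger.info("NB fit failed for %s; Gaussian fallback used", gene)
        records.append(
            {
                "gene_id": gene,
                "lfc_per_year": beta_age / np.log(2.0),
                "p": float(min(max(p, 0.0), 1.0)),
                "fallback": fallback,
            }
        )
    out = pd.DataFrame(records)
    if out.empty:
        out["p_adj"] = out.get("p", pd.Series(dtype=float))
        out["is_deg"] = pd.Series(dtype=bool)
        return out
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["is_deg"] = out["p_adj"] < alpha_adj
    return out


def _cpg_gene_distance(pos: int, tss: int, body_start: int, body_end: int) -> int:
    """Min of distance to the TSS and distance to the half-open body interval."""
    d_tss = abs(pos - tss)
    if body_start <= pos < body_end:
        d_body = 0
    elif pos < body_start:
        d_body = body_start - pos
    else:
        d_body = pos - (body_end - 1)
    return min(d_tss, d_body)


def link_dmp_to_tf(
    dmps: pd.DataFrame,
    annotation: GeneAnnotation,
    matrix: MethylationMatrix,
    expression: ExpressionMatrix,
    window: int = 5000,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Link DMPs to TF genes within ``window`` bp and correlate beta with
    log2 normalized expression; per TF the smallest-p link is representative
    (p ties broken by larger |r|, then lexicographic DMP id)."""
    dmp_ids = set(dmps.loc[dmps["is_dmp"], "feature_id"])
    tf_table = annotation.table[annotation.table["is_tf"].astype(bool)]
    logn = expression.log_normalized()
    shared = [s for s in matrix.sample_ids if s in logn.columns]
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared samples between matrices")
    beta = matrix.beta[shared]
    logn = logn[shared]
    pos_info = matrix.positions

    rows = []
    for _, tf in tf_table.iterrows():
        gene = tf["gene_id"]
        if gene not in logn.index:
            warnings.warn(f"TF {gene} has no expression row; skipped", stacklevel=2)
            continue
        same_chrom = pos_info[pos_info["chrom"] == tf["chrom"]]
        expr = logn.loc[gene].to_numpy(float)
        if expr.std() == 0:
            continue
        for pid, prow in same_chrom.iterrows():
            if pid not in dmp_ids:
                continue
            d = _cpg_gene_distance(
                int(prow["pos"]), int(tf["tss"]), int(tf["body_start"]), int(tf["body_end"])
            )
            if d > window:
                continue
            b = beta.loc[pid].to_numpy(float)
            if b.std() == 0:
                continue
            r = float(np.corrcoef(b, expr)[0, 1])
            p = float(pearson_p_from_r(np.array([r]), len(shared))[0])
            if p < p_threshold:
                rows.append(
                    {"dmp_id": pid, "tf_gene_id": gene, "distance": d, "r": r, "p": p}
                )
    links = pd.DataFrame(rows, columns=["dmp_id", "tf_gene_id", "distance", "r", "p"])
    links["representative"] = False
    for gene, grp in links.groupby("tf_gene_id"):
        best = grp.sort_values(
            ["p", "r", "dmp_id"],
            key=lambda s: -s.abs() if s.name == "r" else s,
        ).index[0]
        links.loc[best, "representative"] = True
    return links.reset_index(drop=True)


def overlap_enrichment(
    population_n: int, marker_n: int, selected_n: int, overlap_k: int
) -> dict:
    """Upper-tail hypergeometric overlap test.

    P(X >= k) where X counts the overlap between ``marker_n`` known markers
    and ``selected_n`` selected features drawn from ``population_n``.
    """
    N, K, n, k = population_n, marker_n, selected_n, overlap_k
    if not (0 <= k <= min(K, n) and n <= N and K <= N):
        raise ValueError("inconsistent enrichment counts")
    logp = stats.hypergeom.logsf(k - 1, N, K, n)
    return {
        "population_n": N,
        "marker_n": K,
        "selected_n": n,
        "overlap_k": k,
        "p": float(np.exp(logp)),
        "log10_p": float(logp / np.log(10.0)),
    }
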