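"""Synthetic aging multi-omics study generator.

Emulates a blood aging cohort: ages uniform on 20-74 years, CpG beta
trajectories that drift with age at planted DMPs, negative-binomial RNA-seq
counts with per-year log-fold-change trends at planted DEGs, a ground-truth
signed TF->target regulatory network through which DMP-coupled TF activity
propagates into expression, and drug perturbation profiles containing
planted signature-reversing compounds. Every planted quantity is recorded
in a :class:`GroundTruth` so recovery by the analysis modules is testable.

Methylation noise lives on the logit scale so beta stays in (0, 1); the
configured DMP slope is in beta-units per year and is mapped to the logit
scale with the canonical factor 4 (the inverse-logit derivative at 0.5).
Expression is generated through the same linear propagation rule the
inference assumes, with independent basal-activity noise at every TF node
so that edge modes of action are identifiable from partial correlations;
a config switch adds model-mismatch noise for robustness checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    CohortTable,
    ExpressionMatrix,
    GeneAnnotation,
    MethylationMatrix,
    PerturbationProfiles,
    SignedGRN,
)
from . import sfa

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "generate_cohort",
    "generate_true_network",
    "simulate_methylation",
    "simulate_expression",
    "simulate_perturbation_profiles",
    "simulate_all",
]

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for the generator. Defaults are the package's
    reference conditions (see docs/methods.md for rationale)."""

    seed: int
    n_samples: int = 100
    age_range: tuple[float, float] = (20.0, 74.0)
    n_cpg: int = 1500
    frac_dmp: float = 0.10
    dmp_slope_range: tuple[float, float] = (0.004, 0.004)  # beta-units / year
    methyl_noise_sd: float = 0.3  # logit scale
    n_genes: int = 300
    n_tf: int = 40
    n_input_tf: int = 10
    frac_deg: float = 0.15
    deg_lfc_range: tuple[float, float] = (0.02, 0.02)  # log2 / year
    nb_dispersion: float = 0.05
    network_model: str = "scale_free"
    frac_negative_edges: float = 0.3
    coupling_r: float = 0.8
    n_drugs: int = 20
    n_reverser_drugs: int = 1
    alpha: float = 0.5
    basal_activity_sd: float = 1.0  # per-TF basal input noise, activity units
    expr_signal_scale: float = 2.0  # log2 units of expression per activity unit
    sex_offset_methyl: float = 0.3  # logit offset for males, affected positions
    sex_offset_expr: float = 0.2  # log2 offset for males, affected genes
    sex_affected_frac: float = 0.3
    model_mismatch_sd: float = 0.0  # extra log2 noise breaking the linear rule
    simulate_smoking: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("frac_dmp", "frac_deg", "frac_negative_edges", "sex_affected_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_tf > self.n_genes:
            raise ValueError("n_tf must be <= n_genes")
        if self.n_input_tf < 2 or self.n_input_tf >= self.n_tf:
            raise ValueError("need 2 <= n_input_tf < n_tf")
        if self.n_reverser_drugs > self.n_drugs:
            raise ValueError("n_reverser_drugs must be <= n_drugs")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Everything planted by the generator, for recovery scoring."""

    annotation: GeneAnnotation
    true_dmp_ids: list[str]
    dmp_slopes: dict[str, float]  # beta-units/year, signed; 0 for nulls
    dmp_positions: pd.DataFrame  # index: position id; columns chrom, pos, tf (or "")
    driver_dmp: dict[str, str]  # input TF -> driving DMP id
    coupling_sign: dict[str, int]  # input TF -> sign of beta-expression coupling
    true_deg_ids: list[str]
    deg_effects: dict[str, float]  # gene -> signed log2 lfc per year
    true_edge_signs: dict[tuple[str, str], int]
    planted_reverser_nodes: list[str]
    planted_reverser_drugs: list[str]
    reverser_condition: dict[str, str]  # drug -> condition label (filled later)
    sex_affected_positions: list[str] = field(default_factory=list)
    sex_affected_genes: list[str] = field(default_factory=list)


@dataclass
class SimulatedStudy:
    cohort: CohortTable
    network: SignedGRN
    truth: GroundTruth
    methylation: MethylationMatrix
    expression: ExpressionMatrix
    profiles: PerturbationProfiles


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((int(config.seed) * 1_000_003 + salt) % (2**31))


def generate_cohort(config: SimulationConfig) -> CohortTable:
    """Ages uniform on the configured range; sexes Bernoulli(1/2); smokers,
    when simulated, only among males (about a third of them)."""
    if config.n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    rng = _rng(config, 1)
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, config.n_samples)
    sexes = np.where(rng.random(config.n_samples) < 0.5, "male", "female")
    if config.simulate_smoking:
        smoking = np.where(
            (sexes == "male") & (rng.random(config.n_samples) < 1.0 / 3.0),
            "smoker",
            "non_smoker",
        )
    else:
        smoking = np.full(config.n_samples, "unknown")
    table = pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(config.n_samples)],
            "age": np.round(ages, 2),
            "sex": sexes,
            "smoking": smoking,
        }
    )
    return CohortTable(table)


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    tfs = [f"TF{i:03d}" for i in range(config.n_tf)]
    others = [f"G{i:04d}" for i in range(config.n_genes - config.n_tf)]
    return tfs, others


def _make_annotation(config: SimulationConfig, rng: np.random.Generator) -> GeneAnnotation:
    tfs, others = _gene_ids(config)
    genes = tfs + others
    rows = []
    per_chrom = int(np.ceil(len(genes) / 5))
    for i, g in enumerate(genes):
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        body_start = 100_000 + slot * 50_000
        body_end = body_start + 10_000
        strand = "+" if rng.random() < 0.5 else "-"
        tss = body_start if strand == "+" else body_end - 1
        rows.append(
            {
                "gene_id": g,
                "chrom": chrom,
                "tss": tss,
                "body_start": body_start,
                "body_end": body_end,
                "strand": strand,
                "is_tf": g in set(tfs),
            }
        )
    return GeneAnnotation(pd.DataFrame(rows))


def _build_topology(
    config: SimulationConfig,
    rng: np.random.Generator,
    inputs: list[str],
    mids: list[str],
    outputs: list[str],
    background: list[str],
) -> list[tuple[str, str]]:
    """Layered digraph: path intermediates chain back to inputs and feed the
    outputs; the other half of the intermediates are off-path regulators
    that drive the background genes, so background expression carries no
    aging signal. Scale-free mode uses preferential attachment on
    out-degree."""
    edges: list[tuple[str, str]] = []
    out_deg: dict[str, int] = {t: 0 for t in inputs + mids}
    n_path = max(len(mids) // 2, 1)
    path_mids, null_tfs = mids[:n_path], mids[n_path:]

    def pick(pool: list[str], k: int, preferential: bool) -> list[str]:
        if preferential and config.network_model == "scale_free":
            w = np.array([out_deg[p] + 1.0 for p in pool])
            w = w / w.sum()
            idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False, p=w)
        else:
            idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        return [pool[i] for i in idx]

    # scale-free hub structure lives in the TF->TF regulatory core; target
    # genes choose regulators uniformly
    for j, m in enumerate(path_mids[:-1]):
        pool = inputs + path_mids[:j]
        for p in pick(pool, int(rng.integers(1, 3)), preferential=True):
            edges.append((p, m))
            out_deg[p] += 1
    # the planted reverser is fed directly by an input TF, so no scanned
    # intermediate sits upstream of it
    reverser = path_mids[-1]
    p = inputs[int(rng.integers(len(inputs)))]
    edges.append((p, reverser))
    out_deg[p] += 1
    # every input TF must sit on a path: give idle inputs one intermediate target
    for t in inputs:
        if out_deg[t] == 0:
            m = path_mids[int(rng.integers(0, max(len(path_mids) - 1, 1)))]  # not reverser
            edges.append((t, m))
            out_deg[t] += 1
    for o in outputs:
        for p in pick(path_mids, int(rng.integers(2, 4)), preferential=False):
            edges.append((p, o))
            out_deg[p] += 1
    for b in background:
        pool = null_tfs if null_tfs else mids
        for p in pick(pool, int(rng.integers(1, 3)), preferential=False):
            edges.append((p, b))
            out_deg[p] += 1
    return edges


def generate_true_network(
    config: SimulationConfig, max_retries: int = 50
) -> tuple[SignedGRN, GroundTruth]:
    """Ground-truth signed network plus all planted effects.

    Only TF nodes have out-edges. The last intermediate TF is planted as a
    reverser: it gets direct edges into most output DEGs with signs opposing
    the propagated aging effect, verified by the signal-flow solver
    (a +1 input at the reverser must reverse >= 60% of planted DEGs).
    """
    if config.n_tf < 2:
        raise ValueError("n_tf must be >= 2")
    rng = _rng(config, 2)
    annotation = _make_annotation(config, rng)
    tfs, others = _gene_ids(config)
    inputs = tfs[: config.n_input_tf]
    mids = tfs[config.n_input_tf :]
    n_deg = max(int(round(config.frac_deg * config.n_genes)), 1)
    outputs = others[:n_deg]
    background = others[n_deg:]
    reverser = mids[max(len(mids) // 2, 1) - 1]  # last on-path intermediate

    # planted DMPs: each assigned to an input TF, first per TF is the driver
    n_dmp = max(int(round(config.frac_dmp * config.n_cpg)), config.n_input_tf)
    slope_lo, slope_hi = config.dmp_slope_range
    ann = annotation.table.set_index("gene_id")
    dmp_rows, dmp_slopes, driver_dmp = [], {}, {}
    # round-robin assignment guarantees every input TF gets >= 1 DMP
    tf_for_dmp = [inputs[i % len(inputs)] for i in range(n_dmp)]
    for i, tf in enumerate(tf_for_dmp):
        g = ann.loc[tf]
        pos = int(rng.integers(g["body_start"] - 4500, g["body_end"] + 4500))
        pid = f"{g['chrom']}:{pos}"
        while any(r["pos"] == pos and r["chrom"] == g["chrom"] for r in dmp_rows):
            pos += 1
            pid = f"{g['chrom']}:{pos}"
        slope = float(rng.uniform(slope_lo, slope_hi)) * (1 if rng.random() < 0.5 else -1)
        dmp_rows.append({"chrom": g["chrom"], "pos": pos, "tf": tf, "id": pid})
        dmp_slopes[pid] = slope
        if tf not in driver_dmp:
            driver_dmp[tf] = pid
    # null CpGs: intergenic, > 5 kb from every gene
    n_null = config.n_cpg - n_dmp
    gene_rows = annotation.table
    anchors = gene_rows.sample(n=n_null, replace=True, random_state=int(rng.integers(2**31)))
    for (_, g), jit in zip(anchors.iterrows(), rng.integers(20_000, 25_000, n_null)):
        pos = int(g["body_end"] + jit)
        pid = f"{g['chrom']}:{pos}"
        while pid in dmp_slopes or any(r["pos"] == pos and r["chrom"] == g["chrom"] for r in dmp_rows[n_dmp:]):
            pos += 1
            pid = f"{g['chrom']}:{pos}"
        dmp_rows.append({"chrom": g["chrom"], "pos": pos, "tf": "", "id": pid})
        dmp_slopes[pid] = 0.0
    dmp_positions = pd.DataFrame(dmp_rows).set_index("id").rename_axis(None)
    true_dmp_ids = list(dmp_positions.index[:n_dmp])
    coupling_sign = {tf: int(1 if rng.random() < 0.5 else -1) for tf in inputs}

    for attempt in range(max_retries):
        topo = _build_topology(config, rng, inputs, mids, outputs, background)
        signs = {
            e: int(-1 if rng.random() < config.frac_negative_edges else 1) for e in topo
        }
        # add direct reverser edges into 80% of outputs (signs set below)
        rev_targets = [o for o in outputs if rng.random() < 0.8]
        if len(rev_targets) < max(1, int(0.6 * len(outputs))) + 1:
            rev_targets = outputs[: max(1, int(0.8 * len(outputs)))]
        for o in rev_targets:
            signs.setdefault((reverser, o), 1)
        # trend of each input TF's activity with age has sign coupling * slope
        b_trend = {
            tf: coupling_sign[tf] * np.sign(dmp_slopes[driver_dmp[tf]]) for tf in inputs
        }

        def solve_signs(sign_map: dict) -> pd.Series:
            net = SignedGRN.from_edges(
                [(u, v, s) for (u, v), s in sign_map.items()], inputs, outputs
            )
            prob = sfa.build_weight_matrix(net, alpha=config.alpha)
            res = sfa.solve_steady_state(prob.with_b({t: float(b_trend[t]) for t in inputs}))
            return res.x

        # fix reverser edge signs against the propagated aging direction,
        # iterating because flipping them feeds back into the trend itself;
        # outputs whose parent trends cancel exactly get a parent edge sign
        # re-rolled so every planted DEG has a definite aging direction
        ok = False
        for _ in range(40):
            x = solve_signs(signs)
            degenerate = [o for o in outputs if abs(x[o]) < 1e-6]
            if degenerate:
                # drop one parent edge to break the exact cancellation;
                # keeps the configured sign distribution intact
                fixed = False
                for o in degenerate:
                    parents = [u for (u, v) in signs if v == o and u != reverser]
                    if len(parents) >= 2:
                        edge = (parents[int(rng.integers(len(parents)))], o)
                        del signs[edge]
                        fixed = True
                if not fixed:
                    break
                continue
            s_out = np.sign(x[outputs])
            new = dict(signs)
            for o in rev_targets:
                new[(reverser, o)] = int(-s_out[o])
            if new == signs:
                ok = True
                break
            signs = new
        if not ok:
            continue
        x = solve_signs(signs)
        s_out = np.sign(x[outputs])
        if (np.abs(x[outputs]) < 1e-6).any():
            continue
        network = SignedGRN.from_edges(
            [(u, v, s) for (u, v), s in signs.items()], inputs, outputs
        )
        # oracle verification: +1 at the reverser must reverse >= 60% of DEGs
        prob = sfa.build_weight_matrix(network, alpha=config.alpha)
        pert = sfa.solve_steady_state(prob.with_b({reverser: 1.0})).x
        reversed_n = int(
            ((np.sign(pert[outputs]) == -s_out) & (np.abs(pert[outputs]) > 1e-9)).sum()
        )
        if reversed_n < 0.6 * len(outputs):
            logger.info("retry %d: reverser covers only %d DEGs", attempt, reversed_n)
            continue
        lfc_lo, lfc_hi = config.deg_lfc_range
        deg_effects = {
            o: float(s_out[o]) * float(rng.uniform(lfc_lo, lfc_hi)) for o in outputs
        }
        truth = GroundTruth(
            annotation=annotation,
            true_dmp_ids=true_dmp_ids,
            dmp_slopes=dmp_slopes,
            dmp_positions=dmp_positions,
            driver_dmp=driver_dmp,
            coupling_sign=coupling_sign,
            true_deg_ids=list(outputs),
            deg_effects=deg_effects,
            true_edge_signs=dict(signs),
            planted_reverser_nodes=[reverser],
            planted_reverser_drugs=[f"drug{d:02d}" for d in range(config.n_reverser_drugs)],
            reverser_condition={},
        )
        return network, truth
    raise RuntimeError(f"no valid network after {max_retries} retries")


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(
    cohort: CohortTable, config: SimulationConfig, truth: GroundTruth
) -> MethylationMatrix:
    """Beta = inverse-logit(intercept + slope*(age - midpoint) + sex offset
    + logit-scale noise); slope is nonzero exactly at planted DMPs."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rng = _rng(config, 3)
    ages = cohort.ages.to_numpy()
    male = (cohort.sexes == "male").to_numpy(float)
    mid = float(np.mean(config.age_range))
    pos = truth.dmp_positions
    n_pos, n_samp = len(pos), len(cohort)
    intercepts = rng.uniform(-1.5, 1.5, n_pos)
    slopes_beta = np.array([truth.dmp_slopes[p] for p in pos.index])
    slopes_logit = slopes_beta * 4.0  # beta-units/yr -> logit-units/yr at 0.5
    sex_mask = rng.random(n_pos) < config.sex_affected_frac
    sex_off = np.where(sex_mask, config.sex_offset_methyl, 0.0) * np.where(
        rng.random(n_pos) < 0.5, 1.0, -1.0
    )
    noise = rng.normal(0.0, config.methyl_noise_sd, (n_pos, n_samp))
    logit = (
        intercepts[:, None]
        + slopes_logit[:, None] * (ages - mid)[None, :]
        + sex_off[:, None] * male[None, :]
        + noise
    )
    beta = np.clip(_invlogit(logit), 1e-6, 1.0 - 1e-6)
    frame = pd.DataFrame(beta, index=pos.index, columns=cohort.sample_ids)
    truth.sex_affected_positions = list(pos.index[sex_mask])
    positions = pos[["chrom", "pos"]].copy()
    return MethylationMatrix(positions, frame)


def simulate_expression(
    cohort: CohortTable,
    network: SignedGRN,
    methylation: MethylationMatrix,
    config: SimulationConfig,
    truth: GroundTruth,
) -> ExpressionMatrix:
    """Counts from TF activity propagated through the true network.

    Input-TF activity is the coupling sign times the cohort Z-score of the
    TF's driving DMP (scaled x2 against unit basal noise); every TF node
    additionally receives independent basal-activity noise. Activities are
    propagated with the same damped linear rule the inference assumes; the
    log2 count mean adds the propagated activity, the planted per-year lfc
    for true DEGs, and a sex offset for affected genes.
    """
    missing = [n for n in network.nodes if n not in set(truth.annotation.table["gene_id"])]
    if missing:
        raise ValueError(f"network nodes outside gene universe: {missing[:5]}")
    rng = _rng(config, 4)
    ages = cohort.ages.to_numpy()
    male = (cohort.sexes == "male").to_numpy(float)
    mid = float(np.mean(config.age_range))
    n_samp = len(cohort)

    problem = sfa.build_weight_matrix(network, alpha=config.alpha)
    tf_nodes = [n for n in problem.nodes if n.startswith("TF")]
    B = np.zeros((len(problem.nodes), n_samp))
    for tf in tf_nodes:
        B[problem.node_index(tf), :] = rng.normal(0.0, config.basal_activity_sd, n_samp)
    for tf, dmp in truth.driver_dmp.items():
        if tf not in problem._index:
            continue
        b = methylation.beta.loc[dmp].to_numpy(float)
        z = (b - b.mean()) / b.std(ddof=1)
        B[problem.node_index(tf), :] += 2.0 * truth.coupling_sign[tf] * z
    X = sfa.solve_many(problem, B)  # nodes x samples activity
    activity = pd.DataFrame(X, index=problem.nodes, columns=cohort.sample_ids)

    tfs, others = _gene_ids(config)
    genes = tfs + others
    baselines = rng.uniform(3.0, 8.0, len(genes))
    sex_mask = rng.random(len(genes)) < config.sex_affected_frac
    sex_off = np.where(sex_mask, config.sex_offset_expr, 0.0) * np.where(
        rng.random(len(genes)) < 0.5, 1.0, -1.0
    )
    truth.sex_affected_genes = [g for g, m in zip(genes, sex_mask) if m]
    lib = np.exp(rng.normal(0.0, 0.2, n_samp))  # per-sample library depth

    log2_mu = np.tile(baselines[:, None], (1, n_samp))
    for gi, g in enumerate(genes):
        if g in activity.index:
            log2_mu[gi] += config.expr_signal_scale * activity.loc[g].to_numpy()
        if g in truth.deg_effects:
            log2_mu[gi] += truth.deg_effects[g] * (ages - mid)
        log2_mu[gi] += sex_off[gi] * male
    if config.model_mismatch_sd > 0:
        log2_mu += rng.normal(0.0, config.model_mismatch_sd, log2_mu.shape)
    mu = np.power(2.0, log2_mu) * lib[None, :]
    size = 1.0 / max(config.nb_dispersion, 1e-12)
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)
    frame = pd.DataFrame(counts, index=genes, columns=cohort.sample_ids)
    return ExpressionMatrix(frame)


def simulate_perturbation_profiles(
    truth: GroundTruth, config: SimulationConfig
) -> PerturbationProfiles:
    """Noise modZ profiles for every drug condition; each planted reverser
    drug gets exactly one condition in which every planted DEG's modZ
    opposes its aging direction with extreme magnitude."""
    if config.n_drugs < config.n_reverser_drugs:
        raise ValueError("n_drugs must be >= n_reverser_drugs")
    rng = _rng(config, 5)
    tfs, others = _gene_ids(config)
    genes = tfs + others
    doses = ["10nM", "100nM", "1uM", "10uM"]
    times = ["6h", "24h"]
    columns, data = [], []
    for d in range(config.n_drugs):
        drug = f"drug{d:02d}"
        n_cond = int(rng.integers(2, 5))
        picked = rng.choice(len(doses) * len(times), size=n_cond, replace=False)
        for c in picked:
            dose, time = doses[c % len(doses)], times[c // len(doses)]
            columns.append(f"{drug}|{dose}|{time}")
            data.append(rng.normal(0.0, 1.0, len(genes)))
    modz = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    deg_sign = {g: np.sign(e) for g, e in truth.deg_effects.items()}
    for drug in truth.planted_reverser_drugs:
        conds = [c for c in columns if c.startswith(drug + "|")]
        best = conds[int(rng.integers(len(conds)))]
        for g, s in deg_sign.items():
            modz.loc[g, best] = -s * float(rng.uniform(3.0, 6.0))
        truth.reverser_condition[drug] = best
    return PerturbationProfiles.from_modz(modz)


def simulate_all(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generator: cohort, network/truth, methylation,
    expression, perturbation profiles."""
    cohort = generate_cohort(config)
    network, truth = generate_true_network(config)
    methylation = simulate_methylation(cohort, config, truth)
    expression = simulate_expression(cohort, network, methylation, config, truth)
    profiles = simulate_perturbation_profiles(truth, config)
    return SimulatedStudy(cohort, network, truth, methylation, expression, profiles)
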