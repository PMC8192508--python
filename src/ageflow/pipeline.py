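"""End-to-end analysis orchestration.

Chains the stages on in-memory objects: sex adjustment and marker calling,
DMP-TF linking, subnetwork extraction and sign assignment, per-sample
signal flow, DAC classification, reverse-target ranking, and the
perturbagen screen. The CLI and the reproduction script are thin layers
over :func:`run_analysis`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import markers as mk
from . import network as net
from . import screen as scr
from . import targets as tg
from .containers import (
    CohortTable,
    ExpressionMatrix,
    GeneAnnotation,
    MethylationMatrix,
    PerturbationProfiles,
    SignedGRN,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    dmp_p: float = 0.05
    deg_alpha_adj: float = 0.05
    link_window: int = 5000
    link_p: float = 0.05
    variance_fraction: float = 0.05
    edge_p: float = 0.05
    alpha: float = 0.5
    dac_p: float = 0.05
    top_fraction: float = 0.05
    epsilon: float = 1e-9


@dataclass
class AnalysisResult:
    dmps: pd.DataFrame
    degs: pd.DataFrame
    links: pd.DataFrame
    network: SignedGRN | None
    activities: pd.DataFrame | None
    dacs: pd.DataFrame | None
    influence: pd.DataFrame | None
    target_scores: pd.DataFrame | None
    ranked_targets: pd.DataFrame | None
    screen: pd.DataFrame | None
    notes: dict = field(default_factory=dict)


def run_analysis(
    methylation: MethylationMatrix,
    expression: ExpressionMatrix,
    cohort: CohortTable,
    annotation: GeneAnnotation,
    canonical_edges: pd.DataFrame,
    profiles: PerturbationProfiles | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisResult:
    cfg = config or AnalysisConfig()
    notes: dict = {}

    adjusted = mk.adjust_sex(methylation, cohort)
    dmps = mk.call_dmps(adjusted, cohort, p_threshold=cfg.dmp_p)
    notes["n_dmp"] = int(dmps["is_dmp"].sum())
    degs = mk.call_degs(expression, cohort, alpha_adj=cfg.deg_alpha_adj)
    notes["n_deg"] = int(degs["is_deg"].sum())
    links = mk.link_dmp_to_tf(
        dmps, annotation, adjusted, expression, window=cfg.link_window, p_threshold=cfg.link_p
    )
    notes["n_links"] = int(len(links))

    reps = links[links["representative"]]
    input_tfs = set(reps["tf_gene_id"])
    # network outputs are regulated endpoints: DEGs that are not themselves
    # TFs (TF DEGs act inside the network as regulators, not as outputs)
    tf_genes = set(annotation.tf_ids)
    output_degs = set(degs.loc[degs["is_deg"], "gene_id"]) - tf_genes
    result = AnalysisResult(dmps, degs, links, None, None, None, None, None, None, None, notes)
    if not input_tfs or not output_degs:
        logger.warning("no input TFs or no DEGs; downstream stages skipped")
        return result
    try:
        sub = net.extract_subnetwork(canonical_edges, input_tfs, output_degs)
    except ValueError as exc:
        logger.warning("subnetwork extraction failed: %s", exc)
        return result
    keep = net.variance_filter(expression, set(sub.nodes), fraction=cfg.variance_fraction)
    dropped = set(sub.nodes) - keep
    if dropped:
        sub.remove_nodes_from(dropped)
        notes["n_variance_dropped"] = len(dropped)
    try:
        signed = net.assign_edge_signs(sub, expression, p_threshold=cfg.edge_p)
    except ValueError as exc:
        logger.warning("edge sign assignment failed: %s", exc)
        return result
    result.network = signed
    notes["n_network_nodes"] = len(signed.nodes)
    notes["n_network_edges"] = signed.n_edges

    rep_in_net = reps[reps["tf_gene_id"].isin(signed.inputs)]
    activities = tg.compute_sample_dacs(signed, adjusted, rep_in_net, cohort, alpha=cfg.alpha)
    result.activities = activities
    net_degs = degs[degs["gene_id"].isin(signed.outputs) & degs["is_deg"]]
    dacs = tg.dac_age_association(activities, cohort, net_degs, p_threshold=cfg.dac_p)
    result.dacs = dacs
    notes["n_dac_consistent"] = int((dacs["class"] == "consistent").sum())
    try:
        result.influence = tg.input_influence(
            signed, adjusted, rep_in_net, cohort, outputs=list(net_degs["gene_id"]), alpha=cfg.alpha
        )
    except Exception as exc:  # influence is reporting-only
        logger.warning("input influence failed: %s", exc)
    validated = dacs[dacs["class"] == "consistent"]
    if len(validated) and signed.intermediates:
        scores = tg.perturb_node_scan(signed, dacs, alpha=cfg.alpha, epsilon=cfg.epsilon)
        result.target_scores = scores
        result.ranked_targets = tg.rank_targets(scores, top_fraction=cfg.top_fraction)
        notes["n_candidate_targets"] = int(result.ranked_targets["candidate"].sum())

    if profiles is not None and len(validated):
        signature = validated.set_index("gene_id")["dac_direction"].astype(int)
        result.screen = scr.screen_drugs(profiles, signature)
        notes["n_candidate_drugs"] = int(result.screen["candidate"].sum())
    return result
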