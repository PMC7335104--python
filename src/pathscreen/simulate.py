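"""Seeded synthetic-data generators with a planted-truth record.

Every generator is a pure function of its arguments including the seed, and
emulates the statistical structure the pipeline assumes: per-gene bimodal
gamma-mixture expression (an exponential-like low component and a
larger-mean gamma for the expressed state), matched noisy platforms sharing
a latent signal, activator/inhibitor pathway libraries, response matrices
with associations planted in the activity tails of chosen pathways, and
tumor/normal cohorts with pathway-level shifts.  The accompanying
``SyntheticTruth`` records everything needed to verify recovery without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import ActivityMatrix, Interaction, PathwayLibrary
from .io import ExpressionMatrix, ResponseMatrix

# Default mixture components: means 1 vs 12.5 — clearly separated so that
# EM-recovery checks are sharp.  Weak-separation presets for stress tests.
DOWN_COMPONENT = (1.0, 1.0)      # (shape, scale), exponential-like
UP_COMPONENT = (25.0, 0.5)
UP_COMPONENT_WEAK = (6.0, 0.5)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    seed: int
    mixture_params: dict[str, dict] = field(default_factory=dict)
    planted_associations: list[dict] = field(default_factory=list)
    tumor_shift_pathways: list[str] = field(default_factory=list)


def generate_pathway_library(
    n_pathways: int,
    gene_pool: int,
    seed: int,
    interactions_per_pathway: tuple[int, int] = (3, 15),
    inputs_per_interaction: tuple[int, int] = (1, 4),
    inhibitor_prob: float = 0.2,
) -> PathwayLibrary:
    """Random activator/inhibitor pathway library over a shared gene pool."""
    if gene_pool < inputs_per_interaction[1]:
        raise ValueError("gene pool smaller than the largest interaction")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(gene_pool)]
    pathways: dict[str, tuple[str, list[Interaction]]] = {}
    for p in range(n_pathways):
        pid = f"P{p:04d}"
        n_inter = int(rng.integers(interactions_per_pathway[0], interactions_per_pathway[1] + 1))
        inters = []
        for i in range(n_inter):
            n_in = int(rng.integers(inputs_per_interaction[0], inputs_per_interaction[1] + 1))
            members = rng.choice(gene_pool, size=n_in, replace=False)
            inputs = [
                (genes[g], "inhibitor" if rng.random() < inhibitor_prob else "activator")
                for g in members
            ]
            inters.append(Interaction(interaction_id=f"{pid}_I{i:03d}", inputs=inputs))
        pathways[pid] = (f"pathway {p}", inters)
    return PathwayLibrary(pathways=pathways)


def _draw_gene(rng, n, params) -> np.ndarray:
    if params["bimodal"]:
        up = rng.random(n) < params["weight_up"]
        vals = np.where(
            up,
            rng.gamma(params["shape_up"], params["scale_up"], size=n),
            rng.gamma(params["shape_down"], params["scale_down"], size=n),
        )
    else:
        vals = rng.gamma(params["shape_up"], params["scale_up"], size=n)
    return np.maximum(vals, 1e-9)


def _gene_params(rng, bimodal: bool, up_component=UP_COMPONENT) -> dict:
    if bimodal:
        return {
            "bimodal": True,
            "weight_up": float(rng.uniform(0.2, 0.8)),
            "shape_down": DOWN_COMPONENT[0],
            "scale_down": DOWN_COMPONENT[1],
            "shape_up": up_component[0],
            "scale_up": up_component[1],
        }
    return {
        "bimodal": False,
        "weight_up": 1.0,
        "shape_down": np.nan,
        "scale_down": np.nan,
        "shape_up": float(rng.uniform(2.0, 10.0)),
        "scale_up": float(rng.uniform(0.5, 2.0)),
    }


def generate_expression_cohort(
    library: PathwayLibrary,
    n_samples_per_tissue: dict[str, int],
    bimodal_fraction: float = 0.4,
    seed: int = 0,
    up_component: tuple[float, float] = UP_COMPONENT,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression cohort over the library's gene pool.

    A ``bimodal_fraction`` of genes mixes the low and high components with a
    per-gene up-weight uniform on (0.2, 0.8); the rest are single-gamma.
    """
    rng = np.random.default_rng(seed)
    genes = library.gene_pool()
    samples, annotations = [], {}
    for tissue, n in n_samples_per_tissue.items():
        for i in range(n):
            sid = f"{tissue}_S{i:03d}"
            samples.append(sid)
            annotations[sid] = {"tissue": tissue, "state": "unknown"}
    truth = SyntheticTruth(seed=seed)
    values = np.empty((len(genes), len(samples)))
    for gi, gene in enumerate(genes):
        params = _gene_params(rng, rng.random() < bimodal_fraction, up_component)
        truth.mixture_params[gene] = params
        values[gi] = _draw_gene(rng, len(samples), params)
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        platform="synthetic_platform_a",
        sample_annotations=annotations,
    )
    return expr, truth


def generate_matched_platform(
    expr: ExpressionMatrix,
    noise_sd: float = 0.2,
    seed: int = 0,
    transform: tuple[float, float] = (1.2, 0.9),
) -> ExpressionMatrix:
    """Second "platform": monotone power transform of the shared latent
    values plus multiplicative log-scale noise, same gene and sample ids."""
    rng = np.random.default_rng(seed)
    a, b = transform
    x = expr.values.to_numpy(dtype=float)
    noise = rng.normal(0.0, noise_sd, size=x.shape) if noise_sd > 0 else 0.0
    y = a * np.power(x, b) * np.exp(noise)
    return ExpressionMatrix(
        values=pd.DataFrame(y, index=expr.gene_ids, columns=expr.sample_ids),
        platform="synthetic_platform_b",
        sample_annotations={s: dict(v) for s, v in expr.sample_annotations.items()},
    )


def _tail_lines(
    activity: ActivityMatrix, pathway: str, lines: list[str],
    direction: str, tail_fraction: float,
) -> list[str]:
    vals = activity.values.loc[pathway, lines]
    n_tail = max(1, int(round(tail_fraction * len(lines))))
    order = vals.sort_values(kind="stable")
    if direction == "low_activity_sensitive":
        return list(order.index[:n_tail])
    return list(order.index[-n_tail:])


def generate_drug_screen(
    activity: ActivityMatrix,
    tissue_of: dict[str, str],
    n_compounds: int,
    planted: list[tuple[str, str, str]],
    seed: int = 0,
    auc_sensitive_mean: float = 4.0,
    auc_resistant_mean: float = 12.0,
    auc_sd: float = 1.0,
    tail_fraction: float = 0.3,
) -> tuple[ResponseMatrix, SyntheticTruth]:
    """Drug screen with associations planted in pathway-activity tails.

    ``planted`` lists (tissue, pathway_id, direction) triples; each gets its
    own compound whose cell lines in the implicated 30% activity tail of that
    tissue draw dr-AUC from the sensitive distribution and all other lines
    from the resistant one.  Unplanted compounds are pure null (all lines
    resistant).  dr-AUC is clipped to the [0, 16] scale.
    """
    if len(planted) > n_compounds:
        raise ValueError("more planted associations than compounds")
    rng = np.random.default_rng(seed)
    lines = activity.sample_ids
    for tissue, pathway, _ in planted:
        if pathway not in activity.values.index:
            raise ValueError(f"planted pathway {pathway!r} not in activity matrix")
        if tissue not in set(tissue_of.values()):
            raise ValueError(f"planted tissue {tissue!r} unknown")
    compounds = [f"D{i:03d}" for i in range(n_compounds)]
    truth = SyntheticTruth(seed=seed)
    values = rng.normal(auc_resistant_mean, auc_sd, size=(n_compounds, len(lines)))
    for ci, (tissue, pathway, direction) in enumerate(planted):
        t_lines = [c for c in lines if tissue_of[c] == tissue]
        sens = set(_tail_lines(activity, pathway, t_lines, direction, tail_fraction))
        for li, line in enumerate(lines):
            if line in sens:
                values[ci, li] = rng.normal(auc_sensitive_mean, auc_sd)
        truth.planted_associations.append(
            dict(tissue=tissue, pathway_id=pathway, entity_id=compounds[ci],
                 direction=direction, sensitive_lines=sorted(sens),
                 effect=f"dr-AUC N({auc_sensitive_mean},{auc_sd}) vs "
                        f"N({auc_resistant_mean},{auc_sd})")
        )
    values = np.clip(values, 0.0, 16.0)
    resp = ResponseMatrix(
        values=pd.DataFrame(values, index=compounds, columns=lines),
        kind="drug",
        tissue_of=dict(tissue_of),
    )
    return resp, truth


def generate_essentiality_screen(
    activity: ActivityMatrix,
    tissue_of: dict[str, str],
    n_genes: int,
    planted: list[tuple[str, str, str]],
    seed: int = 0,
    essential_mean: float = -2.5,
    essential_sd: float = 0.5,
    tail_fraction: float = 0.3,
) -> tuple[ResponseMatrix, SyntheticTruth]:
    """Gene-essentiality screen: z-like fitness scores, planted-essential
    lines ~ N(-2.5, 0.5), all others ~ N(0, 1)."""
    if len(planted) > n_genes:
        raise ValueError("more planted associations than genes")
    rng = np.random.default_rng(seed)
    lines = activity.sample_ids
    gene_entities = [f"E{i:04d}" for i in range(n_genes)]
    truth = SyntheticTruth(seed=seed)
    values = rng.normal(0.0, 1.0, size=(n_genes, len(lines)))
    for gi, (tissue, pathway, direction) in enumerate(planted):
        t_lines = [c for c in lines if tissue_of[c] == tissue]
        sens = set(_tail_lines(activity, pathway, t_lines, direction, tail_fraction))
        for li, line in enumerate(lines):
            if line in sens:
                values[gi, li] = rng.normal(essential_mean, essential_sd)
        truth.planted_associations.append(
            dict(tissue=tissue, pathway_id=pathway, entity_id=gene_entities[gi],
                 direction=direction, sensitive_lines=sorted(sens),
                 effect=f"essentiality N({essential_mean},{essential_sd}) vs N(0,1)")
        )
    resp = ResponseMatrix(
        values=pd.DataFrame(values, index=gene_entities, columns=lines),
        kind="essentiality",
        tissue_of=dict(tissue_of),
    )
    return resp, truth


def generate_tumor_normal_cohort(
    library: PathwayLibrary,
    n_per_group: int,
    shifted_pathways: list[str],
    shift: float,
    seed: int = 0,
    bimodal_fraction: float = 0.4,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Tumor/normal cohort where tumor samples up-shift chosen pathways.

    Member genes of ``shifted_pathways`` are forced bimodal; in tumor
    samples their up-component weight is raised by ``shift`` (clipped below
    0.95), producing a pathway-level activity difference between states.
    """
    for pid in shifted_pathways:
        if pid not in library.pathways:
            raise ValueError(f"shifted pathway {pid!r} not in library")
    rng = np.random.default_rng(seed)
    genes = library.gene_pool()
    shifted_genes: set[str] = set()
    for pid in shifted_pathways:
        for inter in library.pathways[pid][1]:
            shifted_genes.update(inter.genes())
    samples, annotations = [], {}
    for state in ("tumor", "normal"):
        for i in range(n_per_group):
            sid = f"{state}_S{i:03d}"
            samples.append(sid)
            annotations[sid] = {"tissue": "tissueA", "state": state}
    n_tumor = n_per_group
    truth = SyntheticTruth(seed=seed, tumor_shift_pathways=list(shifted_pathways))
    values = np.empty((len(genes), len(samples)))
    for gi, gene in enumerate(genes):
        bimodal = gene in shifted_genes or rng.random() < bimodal_fraction
        params = _gene_params(rng, bimodal)
        truth.mixture_params[gene] = params
        if gene in shifted_genes:
            tumor_params = dict(params)
            tumor_params["weight_up"] = min(params["weight_up"] + shift, 0.95)
            values[gi, :n_tumor] = _draw_gene(rng, n_tumor, tumor_params)
            values[gi, n_tumor:] = _draw_gene(rng, n_per_group, params)
        else:
            values[gi] = _draw_gene(rng, len(samples), params)
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        platform="synthetic_tumor_normal",
        sample_annotations=annotations,
    )
    return expr, truth
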