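"""The biomarker screen: classification, filters, testing, FDR, intersection.

Per-entity response values are z-scored across all cell lines; z <= -1.5
labels a line sensitive and z >= 0 not sensitive, with the in-between band
excluded so intermediate responders do not dilute either group.  Drug
screens drop promiscuous cell lines (sensitive to more than 20% of
compounds) and, per tissue, compounds whose minimal dr-AUC exceeds 8 (no
real response anywhere).  Pathways with activity range <= 0.1 are
non-variable and skipped.  Every remaining (pathway, entity) pair is tested
by a two-sided Mann-Whitney U comparing pathway activity between the
sensitive and not-sensitive lines, and Benjamini-Hochberg correction is
applied per tissue: q <= 0.05 is significant, 0.05 < q <= 0.25
near-significant.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .activity import ActivityMatrix
from .config import ScreenConfig
from .io import ResponseMatrix, ResultsTable, RESULTS_COLUMNS

logger = logging.getLogger("pathscreen")

SENSITIVE, NOT_SENSITIVE, EXCLUDED = "sensitive", "not_sensitive", "excluded"


@dataclass
class SensitivityLabels:
    """Entity x cell-line labels in {sensitive, not_sensitive, excluded}."""

    labels: pd.DataFrame
    thresholds: dict = field(default_factory=dict)
    flagged_entities: dict[str, str] = field(default_factory=dict)

    @property
    def entity_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.labels.columns)


def zscore_transform(values: np.ndarray) -> np.ndarray:
    """Center and scale to z-scores with sample sd (n-1); NaN stays NaN."""
    x = np.asarray(values, dtype=float)
    obs = x[np.isfinite(x)]
    if len(obs) < 2:
        raise ValueError("need at least 2 non-missing values to z-score")
    sd = float(np.std(obs, ddof=1))
    if sd == 0:
        raise ValueError("zero spread, z-scores undefined")
    return (x - float(np.mean(obs))) / sd


def classify_sensitivity(
    z: pd.DataFrame | np.ndarray,
    sensitive_max: float = -1.5,
    resistant_min: float = 0.0,
) -> np.ndarray:
    """Map z-scores to labels: z <= sensitive_max sensitive, z >= resistant_min
    not sensitive, the band between (and missing values) excluded."""
    if not sensitive_max < resistant_min:
        raise ValueError("sensitive_max must be below resistant_min")
    arr = np.asarray(z, dtype=float)
    out = np.full(arr.shape, EXCLUDED, dtype=object)
    out[arr <= sensitive_max] = SENSITIVE
    out[arr >= resistant_min] = NOT_SENSITIVE
    return out


def label_response_matrix(
    response_values: pd.DataFrame, config: ScreenConfig
) -> SensitivityLabels:
    """z-score each entity across all cell lines and label every cell.

    Entities with fewer than two observations or zero spread are flagged and
    fully excluded rather than failing the screen.
    """
    labels = pd.DataFrame(
        EXCLUDED, index=response_values.index, columns=response_values.columns, dtype=object
    )
    flagged: dict[str, str] = {}
    for entity, row in response_values.iterrows():
        try:
            z = zscore_transform(row.to_numpy(dtype=float))
        except ValueError as exc:
            flagged[entity] = str(exc)
            logger.warning("entity %s excluded: %s", entity, exc)
            continue
        labels.loc[entity] = classify_sensitivity(
            z, config.sensitive_max, config.resistant_min
        )
    return SensitivityLabels(
        labels=labels,
        thresholds={
            "sensitive_max": config.sensitive_max,
            "resistant_min": config.resistant_min,
        },
        flagged_entities=flagged,
    )


def filter_promiscuous_cell_lines(
    labels: SensitivityLabels, max_fraction: float = 0.20
) -> tuple[SensitivityLabels, list[str]]:
    """Drop cell lines sensitive to more than ``max_fraction`` of entities."""
    n_entities = len(labels.entity_ids)
    removed = []
    if n_entities:
        frac = (labels.labels == SENSITIVE).sum(axis=0) / n_entities
        removed = [c for c in labels.cell_line_ids if frac[c] > max_fraction]
    if removed:
        logger.info("promiscuity filter removed %d cell lines: %s", len(removed), removed)
    kept = labels.labels.drop(columns=removed)
    return (
        SensitivityLabels(kept, labels.thresholds, labels.flagged_entities),
        removed,
    )


def filter_low_variance_pathways(
    activity: ActivityMatrix, min_range: float = 0.1
) -> tuple[ActivityMatrix, list[str]]:
    """Drop pathways whose activity range (max - min) is <= ``min_range``."""
    rng = activity.values.max(axis=1) - activity.values.min(axis=1)
    dropped = [p for p in activity.pathway_ids if rng[p] <= min_range]
    kept = activity.values.drop(index=dropped)
    cov = {p: c for p, c in activity.coverage.items() if p not in dropped}
    return ActivityMatrix(values=kept, coverage=cov), dropped


def filter_nonresponsive_compounds(
    response: ResponseMatrix, tissue: str, max_min_auc: float | None = 8.0
) -> list[str]:
    """Entities retained in a tissue: minimal AUC over its lines must be <= 8.

    A compound that never drops below the cut-off in any of the tissue's cell
    lines produced no actual response there.
    """
    lines = [c for c in response.cell_line_ids if response.tissue_of[c] == tissue]
    if max_min_auc is None:
        return list(response.entity_ids)
    sub = response.values[lines]
    retained = []
    for entity, row in sub.iterrows():
        vals = row.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) and vals.min() <= max_min_auc:
            retained.append(entity)
    return retained


# ---------------------------------------------------------------------------
# Statistics


def _u_statistic(pooled_ranks: np.ndarray, idx1: tuple[int, ...], n1: int) -> float:
    return float(pooled_ranks[list(idx1)].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_association(
    activity_values: np.ndarray, sensitive_mask: np.ndarray
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U of activity between sensitive and not-sensitive.

    ``sensitive_mask`` is boolean over ``activity_values``.  Both group sizes
    <= 8 triggers exact enumeration of all group assignments (midranks handle
    ties correctly); larger groups use the normal approximation with tie and
    continuity correction.  Returns (U of the sensitive group, p, direction)
    where direction is ``low_activity_sensitive`` when the sensitive group's
    median activity is below the not-sensitive median.
    """
    x = np.asarray(activity_values, dtype=float)
    mask = np.asarray(sensitive_mask, dtype=bool)
    sens, rest = x[mask], x[~mask]
    n1, n2 = len(sens), len(rest)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([sens, rest]))
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    if n1 <= 8 and n2 <= 8:
        dev = abs(u_obs - mu)
        count = total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            total += 1
            u = _u_statistic(ranks, combo, n1)
            if abs(u - mu) >= dev - 1e-9:
                count += 1
        p = count / total
    else:
        _, p = stats.mannwhitneyu(
            sens, rest, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(min(p, 1.0))
    direction = (
        "low_activity_sensitive"
        if float(np.median(sens)) < float(np.median(rest))
        else "high_activity_sensitive"
    )
    return u_obs, p, direction


def bh_fdr(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotone enforcement.

    ``m`` overrides the family size (defaults to the vector length), for the
    case where tested hypotheses are a subset of a declared family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m_eff = len(p) if m is None else int(m)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_eff / np.arange(1, len(p) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def assign_tiers(q: np.ndarray, q_sig: float = 0.05, q_near: float = 0.25) -> np.ndarray:
    tier = np.full(len(q), "none", dtype=object)
    tier[q <= q_near] = "near_significant"
    tier[q <= q_sig] = "significant"
    return tier


# ---------------------------------------------------------------------------
# The full screen


def run_screen(
    activity: ActivityMatrix,
    response: ResponseMatrix,
    config: ScreenConfig | None = None,
) -> ResultsTable:
    """Run the per-tissue pathway-by-entity association screen.

    Drug screens apply the promiscuity and minimal-AUC filters; essentiality
    screens reuse the same z-score classification without them.  BH
    correction is applied per tissue over all of that tissue's tests.
    """
    config = config or ScreenConfig()
    common = [s for s in activity.sample_ids if s in set(response.cell_line_ids)]
    if not common:
        raise ValueError("activity samples and response cell lines do not overlap")

    act_vals, _ = filter_low_variance_pathways(
        ActivityMatrix(activity.values[common], activity.coverage),
        config.pathway_min_range,
    )
    resp_vals = response.values[common]
    labels = label_response_matrix(resp_vals, config)
    if response.kind == "drug":
        labels, removed = filter_promiscuous_cell_lines(
            labels, config.promiscuity_max_fraction
        )
        if removed and config.reclassify_after_promiscuity_filter:
            labels = label_response_matrix(resp_vals.drop(columns=removed), config)
    lines = labels.cell_line_ids

    rows: list[dict] = []
    tissues = sorted({response.tissue_of[c] for c in lines})
    for tissue in tissues:
        t_lines = [c for c in lines if response.tissue_of[c] == tissue]
        if response.kind == "drug":
            entities = filter_nonresponsive_compounds(
                ResponseMatrix(resp_vals[t_lines], response.kind, response.tissue_of),
                tissue,
                config.compound_max_min_auc,
            )
        else:
            entities = list(resp_vals.index)
        t_rows: list[dict] = []
        for entity in entities:
            lab = labels.labels.loc[entity, t_lines]
            sens_lines = [c for c in t_lines if lab[c] == SENSITIVE]
            not_lines = [c for c in t_lines if lab[c] == NOT_SENSITIVE]
            if len(sens_lines) < config.min_group_size or len(not_lines) < config.min_group_size:
                continue
            for pathway in act_vals.pathway_ids:
                vals = act_vals.values.loc[pathway, sens_lines + not_lines].to_numpy(float)
                mask = np.zeros(len(vals), dtype=bool)
                mask[: len(sens_lines)] = True
                u, p, direction = mann_whitney_association(vals, mask)
                t_rows.append(
                    dict(
                        tissue=tissue,
                        pathway_id=pathway,
                        entity_id=entity,
                        n_sensitive=len(sens_lines),
                        n_not_sensitive=len(not_lines),
                        u_statistic=u,
                        p_value=p,
                        direction=direction,
                    )
                )
        if t_rows:
            q = bh_fdr(np.array([r["p_value"] for r in t_rows]))
            tiers = assign_tiers(q, config.q_significant, config.q_near_significant)
            for r, qv, tv in zip(t_rows, q, tiers):
                r["q_value"] = float(qv)
                r["tier"] = tv
            rows.extend(t_rows)

    df = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    return ResultsTable(
        results=df,
        provenance={
            "parameters": config.to_dict(),
            "kind": response.kind,
            "n_cell_lines": len(lines),
            "n_pathways": len(act_vals.pathway_ids),
            "n_tests": len(df),
            "seed": config.seed,
        },
    )


def cross_platform_intersect(
    results_a: ResultsTable, results_b: ResultsTable, tier_threshold: float = 0.25
) -> ResultsTable:
    """Keep (tissue, pathway, entity) hits replicated across both platforms.

    A hit must meet the q-value threshold in both tables with the same
    direction; a biomarker flipping sign across platforms is not a
    replication.  Per-platform and overlap counts land in the provenance.
    """
    keys = ["tissue", "pathway_id", "entity_id"]
    a, b = results_a.results, results_b.results
    hits_a = a[a["q_value"] <= tier_threshold]
    hits_b = b[b["q_value"] <= tier_threshold]
    universe_shared = not pd.merge(a[keys], b[keys], on=keys).empty
    if not universe_shared and (len(a) or len(b)):
        logger.warning("result tables share no (tissue, pathway, entity) triples")
    merged = pd.merge(hits_a, hits_b, on=keys, suffixes=("", "_b"))
    merged = merged[merged["direction"] == merged["direction_b"]]
    out = merged[RESULTS_COLUMNS].copy()
    return ResultsTable(
        results=out,
        provenance={
            "n_a": int(len(hits_a)),
            "n_b": int(len(hits_b)),
            "n_overlap": int(len(out)),
            "tier_threshold": tier_threshold,
        },
    )
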