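"""Interaction- and pathway-level activity scores from UDP values.

An interaction's activity is the product of the up-probabilities of its
activator inputs and the complements (1 - UDP) of its inhibitor inputs, so a
score of 1 means every positive regulator is expressed and no inhibitor is.
A pathway's activity is the arithmetic mean of its interaction activities.
Genes not present in the UDP matrix contribute a neutral factor 1 (coverage
is reported per pathway so thinly measured pathways can be filtered); an
interaction with no measured input at all is excluded from the mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("pathscreen")

NO_DATA = None  # marker returned for an interaction with zero measured inputs

VALID_ROLES = ("activator", "inhibitor")


@dataclass
class Interaction:
    """One pathway interaction: gene inputs labelled activator or inhibitor."""

    interaction_id: str
    inputs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError(f"interaction {self.interaction_id!r} has zero inputs")
        seen = set()
        for gene, role in self.inputs:
            if role not in VALID_ROLES:
                raise ValueError(
                    f"interaction {self.interaction_id!r}: role {role!r} "
                    f"not in {VALID_ROLES}"
                )
            if (gene, role) in seen:
                raise ValueError(
                    f"interaction {self.interaction_id!r}: duplicate input ({gene}, {role})"
                )
            seen.add((gene, role))

    def genes(self) -> list[str]:
        return [g for g, _ in self.inputs]


@dataclass
class PathwayLibrary:
    """pathway_id -> (name, interactions)."""

    pathways: dict[str, tuple[str, list[Interaction]]]

    def __post_init__(self) -> None:
        for pid, (_, interactions) in self.pathways.items():
            if not interactions:
                raise ValueError(f"pathway {pid!r} has no interactions")
            ids = [i.interaction_id for i in interactions]
            if len(ids) != len(set(ids)):
                raise ValueError(f"pathway {pid!r} has duplicate interaction ids")

    def __len__(self) -> int:
        return len(self.pathways)

    def gene_pool(self) -> list[str]:
        pool: set[str] = set()
        for _, interactions in self.pathways.values():
            for inter in interactions:
                pool.update(inter.genes())
        return sorted(pool)


@dataclass
class ActivityMatrix:
    """Pathways x samples activity scores in [0, 1] with per-pathway coverage."""

    values: pd.DataFrame
    coverage: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if ((arr < -1e-12) | (arr > 1 + 1e-12)).any():
            raise ValueError("activity scores must lie in [0, 1]")

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def interaction_activity(
    interaction: Interaction, udp_row: Mapping[str, float]
) -> float | None:
    """Product of activator UDPs and inhibitor complements for one sample.

    Missing genes contribute a neutral factor 1; with no measured input at
    all the no-data marker (``None``) is returned.
    """
    prod = 1.0
    measured = 0
    for gene, role in interaction.inputs:
        if gene not in udp_row:
            continue
        p = udp_row[gene]
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"UDP for gene {gene!r} outside [0,1]: {p}")
        measured += 1
        prod *= p if role == "activator" else (1.0 - p)
    if measured == 0:
        return NO_DATA
    return prod


def _interaction_activity_vec(interaction: Interaction, udp: pd.DataFrame) -> np.ndarray | None:
    # vectorised over samples; same contract as interaction_activity
    prod = np.ones(udp.shape[1])
    measured = 0
    for gene, role in interaction.inputs:
        if gene not in udp.index:
            continue
        p = udp.loc[gene].to_numpy(dtype=float)
        measured += 1
        prod *= p if role == "activator" else (1.0 - p)
    return prod if measured else None


def pathway_activity_matrix(library: PathwayLibrary, udp) -> ActivityMatrix:
    """Score every pathway in every sample: mean over measured interactions.

    Pathways with zero measured interactions are dropped with a warning;
    ``coverage`` records, per retained pathway, the fraction of its
    interactions that had at least one measured gene.
    """
    if len(library) == 0:
        raise ValueError("empty pathway library")
    udp_df = udp.values if hasattr(udp, "values") and isinstance(udp.values, pd.DataFrame) else udp
    rows, index, coverage = [], [], {}
    for pid, (_, interactions) in library.pathways.items():
        acts = [_interaction_activity_vec(i, udp_df) for i in interactions]
        measured = [a for a in acts if a is not None]
        if not measured:
            logger.warning("pathway %s: no measured interactions, dropped", pid)
            continue
        rows.append(np.mean(measured, axis=0))
        index.append(pid)
        coverage[pid] = len(measured) / len(interactions)
    arr = np.array(rows) if rows else np.empty((0, udp_df.shape[1]))
    values = pd.DataFrame(arr, index=index, columns=list(udp_df.columns))
    return ActivityMatrix(values=values, coverage=coverage)


def ddct_relative_expression(
    ct_gene: float, ct_ref: float, ct_gene_cal: float, ct_ref_cal: float
) -> float:
    """Fold change by the delta-delta-Ct method.

    Normalises the target gene's cycle threshold to a reference gene (GAPDH
    in the assays this mirrors) within each sample, subtracts the calibrator
    sample's normalised value, and returns 2**(-ddCt).
    """
    vals = (ct_gene, ct_ref, ct_gene_cal, ct_ref_cal)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"non-finite Ct value in {vals}")
    ddct = (ct_gene - ct_ref) - (ct_gene_cal - ct_ref_cal)
    return 2.0 ** (-ddct)


def qpcr_pathway_activity(
    fold_changes: pd.DataFrame, library: PathwayLibrary
) -> ActivityMatrix:
    """Pathway activity from qPCR fold changes (genes x conditions).

    Each gene's log2 fold changes are min-max rescaled across conditions into
    [0, 1] as a pseudo-UDP (0.5 when the gene shows zero range), then the
    ordinary pathway scoring applies.  At least two conditions are required
    for the rescaling to be defined.
    """
    if fold_changes.shape[1] < 2:
        raise ValueError("qPCR activity needs at least two conditions")
    measured = set(fold_changes.index)
    if not any(set(i.genes()) & measured
               for _, inters in library.pathways.values() for i in inters):
        raise ValueError("no pathway gene measured in the fold-change table")
    logf = np.log2(fold_changes.to_numpy(dtype=float))
    lo = logf.min(axis=1, keepdims=True)
    rng = logf.max(axis=1, keepdims=True) - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        pseudo = np.where(rng > 0, (logf - lo) / np.where(rng > 0, rng, 1.0), 0.5)
    pseudo_udp = pd.DataFrame(pseudo, index=fold_changes.index, columns=fold_changes.columns)
    return pathway_activity_matrix(library, pseudo_udp)
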