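"""Robustness analyses: cross-platform distances, membership randomization,
cluster-validity indices, QQ data, and down-sampling power.

The cross-platform comparison asks whether pathway activity profiles agree
better between two measurement platforms than single-gene profiles do: each
shared feature is (optionally) z-scored within each dataset and the
Euclidean distance between its two profiles is recorded, then the gene and
pathway distance distributions are compared by a two-sided Mann-Whitney U.
Shuffling gene identities while keeping pathway structure intact provides
the negative control: randomized memberships should erase the agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .activity import ActivityMatrix, Interaction, PathwayLibrary
from .config import ScreenConfig
from .io import ResponseMatrix
from .screen import mann_whitney_association, run_screen

logger = logging.getLogger("pathscreen")


def paired_feature_distances(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    normalize: bool = True,
    feature_class: str = "gene",
) -> pd.DataFrame:
    """Per-feature Euclidean distance between two datasets' profiles.

    Features and samples are intersected and order-aligned.  With
    ``normalize`` each feature is z-scored within each matrix first, putting
    genes and pathways on one scale; zero-variance features are skipped with
    a note.  Returns columns feature_id / feature_class / euclidean_distance.
    """
    feats = [f for f in matrix_a.index if f in set(matrix_b.index)]
    samples = [s for s in matrix_a.columns if s in set(matrix_b.columns)]
    if len(samples) < 2:
        raise ValueError("need at least 2 shared samples")
    a = matrix_a.loc[feats, samples].to_numpy(dtype=float)
    b = matrix_b.loc[feats, samples].to_numpy(dtype=float)
    rows = []
    for i, feat in enumerate(feats):
        va, vb = a[i], b[i]
        if normalize:
            if va.std(ddof=1) == 0 or vb.std(ddof=1) == 0:
                logger.info("feature %s skipped: zero variance", feat)
                continue
            va = (va - va.mean()) / va.std(ddof=1)
            vb = (vb - vb.mean()) / vb.std(ddof=1)
        rows.append((feat, feature_class, float(np.linalg.norm(va - vb))))
    return pd.DataFrame(rows, columns=["feature_id", "feature_class", "euclidean_distance"])


def compare_distance_distributions(
    report: pd.DataFrame,
    class_a: str = "gene",
    class_b: str = "pathway",
) -> float:
    """Two-sided Mann-Whitney p between two feature classes' ED distributions."""
    present = set(report["feature_class"])
    if class_a not in present or class_b not in present:
        raise ValueError(f"need both classes {class_a!r} and {class_b!r} present")
    da = report.loc[report["feature_class"] == class_a, "euclidean_distance"].to_numpy()
    db = report.loc[report["feature_class"] == class_b, "euclidean_distance"].to_numpy()
    pooled = np.concatenate([da, db])
    mask = np.zeros(len(pooled), dtype=bool)
    mask[: len(da)] = True
    _, p, _ = mann_whitney_association(pooled, mask)
    return p


def randomize_pathway_membership(library: PathwayLibrary, seed: int) -> PathwayLibrary:
    """Shuffle gene identities globally, keeping every pathway's structure.

    A single seeded permutation of the library's gene pool relabels all
    inputs, so interaction topology, roles, and per-pathway gene counts are
    untouched while the biological identity of every membership is destroyed.
    """
    pool = library.gene_pool()
    rng = np.random.default_rng(seed)
    mapping = dict(zip(pool, rng.permutation(pool)))
    pathways = {}
    for pid, (name, interactions) in library.pathways.items():
        new = [
            Interaction(
                interaction_id=i.interaction_id,
                inputs=[(mapping[g], role) for g, role in i.inputs],
            )
            for i in interactions
        ]
        pathways[pid] = (name, new)
    return PathwayLibrary(pathways=pathways)


def _dunn_index(x: np.ndarray, labels: np.ndarray) -> float:
    groups = [x[labels == g] for g in np.unique(labels)]
    diameters = [pdist(g).max() if len(g) > 1 else 0.0 for g in groups]
    max_diam = max(diameters)
    min_sep = np.inf
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            d = np.linalg.norm(groups[i][:, None, :] - groups[j][None, :, :], axis=2)
            min_sep = min(min_sep, float(d.min()))
    if max_diam == 0:
        return np.inf
    return float(min_sep / max_diam)


def cluster_validity_indices(
    features: pd.DataFrame, labels: dict[str, str] | pd.Series
) -> dict[str, float]:
    """Silhouette, Calinski-Harabasz and Dunn indices for labelled samples.

    Computed in the original feature space (features x samples, Euclidean
    metric) with the given class labels — never on a 2-D embedding.  Dunn
    uses minimum pairwise inter-cluster separation over maximum intra-cluster
    diameter.
    """
    lab = pd.Series(labels)
    samples = [s for s in features.columns if s in lab.index]
    y = lab.loc[samples].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    x = features[samples].to_numpy(dtype=float).T  # samples x features
    return {
        "silhouette": float(silhouette_score(x, y, metric="euclidean")),
        "calinski_harabasz": float(calinski_harabasz_score(x, y)),
        "dunn": _dunn_index(x, y),
    }


def qq_points(p_values: np.ndarray, floor: float = 1e-300) -> pd.DataFrame:
    """Expected vs observed -log10 p quantiles for a QQ plot.

    Observed p are sorted ascending and paired with expected quantiles
    (i - 0.5)/m under the uniform null; p = 0 is clamped to ``floor``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    observed = np.sort(np.maximum(p, floor))
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(observed)}
    )


@dataclass
class PowerPoint:
    subset_size: int
    replicate: int
    seed: int
    n_significant: int


def downsampling_power_curve(
    activity: ActivityMatrix,
    response: ResponseMatrix,
    sizes: list[int],
    reps: int = 10,
    seed: int = 0,
    config: ScreenConfig | None = None,
    q_threshold: float = 0.25,
) -> pd.DataFrame:
    """Significant-pathway counts on random cell-line subsets of each size.

    For each subset size and replicate, cell lines are sampled without
    replacement (seeded), the full screen re-runs on the subset, and the
    number of pathways with q below the threshold is recorded.  Power should
    rise with cohort size when real associations are present.
    """
    config = config or ScreenConfig()
    lines = [c for c in activity.sample_ids if c in set(response.cell_line_ids)]
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > len(lines):
            raise ValueError(f"subset size {size} exceeds cohort of {len(lines)}")
        for rep in range(reps):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            sub = list(np.random.default_rng(rep_seed).choice(lines, size=size, replace=False))
            sub_act = ActivityMatrix(activity.values[sub], activity.coverage)
            sub_resp = ResponseMatrix(response.values[sub], response.kind, response.tissue_of)
            try:
                res = run_screen(sub_act, sub_resp, config)
                hits = res.results[res.results["q_value"] < q_threshold]
                n_sig = int(hits["pathway_id"].nunique())
            except ValueError:
                n_sig = 0
            rows.append(PowerPoint(size, rep, rep_seed, n_sig))
    return pd.DataFrame([vars(r) for r in rows])
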