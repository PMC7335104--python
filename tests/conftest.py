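import numpy as np
import pytest

import pathscreen as ps


@pytest.fixture(scope="session")
def tiny_library() -> ps.PathwayLibrary:
    """One pathway, two interactions: I1{A:act}, I2{B:act, C:inh}."""
    return ps.PathwayLibrary(
        pathways={
            "P1": (
                "toy pathway",
                [
                    ps.Interaction("I1", [("A", "activator")]),
                    ps.Interaction("I2", [("B", "activator"), ("C", "inhibitor")]),
                ],
            )
        }
    )


@pytest.fixture(scope="session")
def planted_pipeline():
    """Small end-to-end pipeline shared by screen/robustness/acceptance tests.

    30 pathways over 300 genes, one tissue of 40 cell lines; UDP and activity
    computed once per session.
    """
    library = ps.generate_pathway_library(30, 300, seed=1)
    expr, truth = ps.generate_expression_cohort(library, {"tissueA": 40}, seed=2)
    udp = ps.compute_udp_matrix(expr)
    act = ps.pathway_activity_matrix(library, udp)
    return dict(library=library, expr=expr, truth=truth, udp=udp, activity=act)


@pytest.fixture(scope="session")
def matched_platforms():
    """Two synthetic platforms sharing one latent cohort.

    120 samples mirror (at desk scale) a many-hundred-line cross-platform
    comparison: per-gene model selection needs a cohort this size to be
    stable across platforms.
    """
    library = ps.generate_pathway_library(30, 300, seed=1)
    expr_a, truth = ps.generate_expression_cohort(library, {"tissueA": 120}, seed=2)
    udp_a = ps.compute_udp_matrix(expr_a)
    act_a = ps.pathway_activity_matrix(library, udp_a)
    expr_b = ps.generate_matched_platform(expr_a, noise_sd=0.2, seed=21)
    udp_b = ps.compute_udp_matrix(expr_b)
    act_b = ps.pathway_activity_matrix(library, udp_b)
    return dict(
        library=library, truth=truth,
        expr_a=expr_a, udp_a=udp_a, act_a=act_a,
        expr_b=expr_b, udp_b=udp_b, act_b=act_b,
    )


@pytest.fixture(scope="session")
def null_screen_config() -> ps.ScreenConfig:
    """Config for pure-null screens: the minimal-AUC compound filter is
    disabled because a null screen has no responsive compound by
    construction and the filter would empty it."""
    return ps.ScreenConfig(compound_max_min_auc=None)
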