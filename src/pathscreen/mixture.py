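"""Per-gene two-component gamma-mixture state inference.

Across samples a gene is modelled as a mixture of a low-mean "down"
(unexpressed) gamma component — initialised as an exponential, i.e. shape 1 —
and a higher-mean "up" (expressed) gamma component.  An EM fit against a
single-gamma fit is compared by BIC; for mixture genes the posterior
probability of the up component at each observed value is the UDP
(up/down probability) used downstream for pathway activity.

The M-step is weighted maximum likelihood per component: the scale has a
closed form and the shape solves ln(k) - psi(k) = ln(weighted mean) -
weighted mean of ln(x) by Newton iteration on ln(k).  This keeps the
observed-data log-likelihood non-decreasing across EM iterations, which a
moments-based M-step would not guarantee.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger("pathscreen")


def _gamma_logpdf(x: np.ndarray, shape: float, scale: float) -> np.ndarray:
    return (
        (shape - 1.0) * np.log(x)
        - x / scale
        - shape * np.log(scale)
        - special.gammaln(shape)
    )


class DegenerateInputError(ValueError):
    """Raised when a gene's expression vector cannot support a mixture fit."""


@dataclass
class EMConfig:
    """Settings for the per-gene EM fit.

    min_samples: fewest observations accepted for a fit.
    max_iter / tol: EM stops when the relative log-likelihood change drops
    below ``tol`` or after ``max_iter`` iterations.
    down_init_shape: initial shape of the low component (1 = exponential);
    the shape is free during EM.
    """

    min_samples: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    down_init_shape: float = 1.0
    single_component_rule: str = "cohort_median"  # or "half"


@dataclass
class MixtureFit:
    n_components: int
    weight_up: float
    shape_down: float
    scale_down: float
    shape_up: float
    scale_up: float
    loglik: float
    bic_1: float
    bic_2: float
    converged: bool
    n_iter: int
    loglik_path: list[float] = field(default_factory=list)

    @property
    def mean_down(self) -> float:
        return self.shape_down * self.scale_down

    @property
    def mean_up(self) -> float:
        return self.shape_up * self.scale_up


@dataclass
class UDPMatrix:
    """Genes x samples posterior up-probabilities in [0, 1]."""

    values: pd.DataFrame
    fit_summary: dict[str, MixtureFit] = field(default_factory=dict)
    flagged_genes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("UDP values must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# Weighted gamma maximum likelihood


def _weighted_gamma_mle(
    x: np.ndarray,
    w: np.ndarray,
    shape_init: float | None = None,
    max_newton: int = 50,
) -> tuple[float, float]:
    """MLE (shape, scale) of a gamma under observation weights ``w``.

    Solves ln(k) - psi(k) = s where s = ln(mean_w(x)) - mean_w(ln x), by
    Newton iteration on u = ln(k); the objective is monotone in k so the
    iteration is safe from any positive start.
    """
    wsum = w.sum()
    mean = float(np.dot(w, x) / wsum)
    mean_log = float(np.dot(w, np.log(x)) / wsum)
    s = np.log(mean) - mean_log
    if s <= 0:  # numerically constant data
        raise DegenerateInputError("zero weighted dispersion in gamma MLE")
    # Minka's closed-form start unless the caller supplies one
    k = shape_init if shape_init is not None else (3 - s + np.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)
    k = float(np.clip(k, 1e-6, 1e6))
    u = np.log(k)
    for _ in range(max_newton):
        k = np.exp(u)
        f = np.log(k) - special.digamma(k) - s
        fprime = k * (1.0 / k - special.polygamma(1, k))
        step = f / fprime
        u_new = u - step
        if not np.isfinite(u_new):
            break
        if abs(u_new - u) < 1e-12:
            u = u_new
            break
        u = u_new
    k = float(np.clip(np.exp(u), 1e-6, 1e6))
    return k, mean / k


def fit_gamma_single(x: np.ndarray) -> tuple[float, float, float]:
    """Unweighted gamma MLE; returns (shape, scale, loglik)."""
    k, theta = _weighted_gamma_mle(x, np.ones_like(x))
    ll = float(_gamma_logpdf(x, k, theta).sum())
    return k, theta, ll


# ---------------------------------------------------------------------------
# EM


def _moment_fit(x: np.ndarray) -> tuple[float, float]:
    m, v = float(np.mean(x)), float(np.var(x))
    v = max(v, 1e-12)
    return max(m * m / v, 1e-3), max(v / m, 1e-12)


def select_model_bic(
    loglik_1: float, k_params_1: int, loglik_2: float, k_params_2: int, n: int
) -> int:
    """Pick 1 or 2 components by BIC = -2*loglik + k*ln(n); ties favour 1."""
    if not (np.isfinite(loglik_1) and np.isfinite(loglik_2)):
        raise ValueError("non-finite log-likelihood")
    bic1 = -2.0 * loglik_1 + k_params_1 * np.log(n)
    bic2 = -2.0 * loglik_2 + k_params_2 * np.log(n)
    return 1 if bic1 <= bic2 else 2


def fit_gene_mixture(x: np.ndarray, config: EMConfig | None = None) -> MixtureFit:
    """Fit the two-gamma mixture to one gene's expression vector by EM.

    Returns the mean-ordered fit with both single- and two-component BIC
    populated; ``n_components`` is the BIC-selected model.  Constant input
    raises :class:`DegenerateInputError`; shorter than ``min_samples`` raises
    ``ValueError``.
    """
    config = config or EMConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < config.min_samples:
        raise ValueError(f"need at least {config.min_samples} observations, got {len(x)}")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("expression values must be positive and finite")
    if np.ptp(x) < 1e-12 * max(1.0, abs(float(x[0]))):
        raise DegenerateInputError("constant expression vector")

    n = len(x)
    # single-component reference fit
    k1, th1, ll_single = fit_gamma_single(x)

    # deterministic initialisation: split at the median, moments per half
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if len(hi) < 2 or len(lo) < 2:
        order = np.argsort(x)
        lo, hi = x[order[: n // 2]], x[order[n // 2:]]
    k_dn, th_dn = config.down_init_shape, max(float(np.mean(lo)) / config.down_init_shape, 1e-12)
    k_up, th_up = _moment_fit(hi)
    w_up = 0.5

    ll_prev = -np.inf
    ll = -np.inf
    ll_path: list[float] = []
    converged = False
    it = 0
    resp_up = np.full(n, 0.5)
    for it in range(1, config.max_iter + 1):
        # E-step in log space
        log_dn = np.log1p(-w_up) + _gamma_logpdf(x, k_dn, th_dn)
        log_up = np.log(w_up) + _gamma_logpdf(x, k_up, th_up)
        m = np.maximum(log_dn, log_up)
        log_norm = m + np.log(np.exp(log_dn - m) + np.exp(log_up - m))
        ll = float(log_norm.sum())
        ll_path.append(ll)
        resp_up = np.exp(log_up - log_norm)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= config.tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll
        # M-step
        w_up = float(np.clip(resp_up.mean(), 1e-6, 1 - 1e-6))
        resp_dn = 1.0 - resp_up
        try:
            k_dn, th_dn = _weighted_gamma_mle(x, resp_dn + 1e-12, shape_init=k_dn)
            k_up, th_up = _weighted_gamma_mle(x, resp_up + 1e-12, shape_init=k_up)
        except DegenerateInputError:
            # a component collapsed onto a point mass; keep previous params
            break

    # order components by mean so "up" is the larger-mean component
    if k_dn * th_dn > k_up * th_up:
        k_dn, th_dn, k_up, th_up = k_up, th_up, k_dn, th_dn
        w_up = 1.0 - w_up

    bic_1 = -2.0 * ll_single + 2 * np.log(n)
    bic_2 = -2.0 * ll + 5 * np.log(n)
    n_comp = select_model_bic(ll_single, 2, ll, 5, n)
    return MixtureFit(
        n_components=n_comp,
        weight_up=w_up,
        shape_down=k_dn,
        scale_down=th_dn,
        shape_up=k_up,
        scale_up=th_up,
        loglik=ll if n_comp == 2 else ll_single,
        bic_1=bic_1,
        bic_2=bic_2,
        converged=converged,
        n_iter=it,
        loglik_path=ll_path,
    )


def posterior_up(x: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """Posterior probability of the up component at each value of ``x``."""
    log_dn = np.log1p(-fit.weight_up) + _gamma_logpdf(x, fit.shape_down, fit.scale_down)
    log_up = np.log(fit.weight_up) + _gamma_logpdf(x, fit.shape_up, fit.scale_up)
    m = np.maximum(log_dn, log_up)
    log_norm = m + np.log(np.exp(log_dn - m) + np.exp(log_up - m))
    return np.exp(log_up - log_norm)


def shift_nonpositive(x: np.ndarray) -> np.ndarray:
    """Shift values <= 0 up by half the smallest positive value of the gene.

    Gamma support is (0, inf); RNA-seq RPKM-like data contain exact zeros
    while RMA microarray values are already positive and pass through
    unchanged.
    """
    if np.all(x > 0):
        return x
    pos = x[x > 0]
    if len(pos) == 0:
        raise DegenerateInputError("no positive values")
    eps = 0.5 * float(pos.min())
    out = x.copy()
    out[out <= 0] += eps
    return out


def compute_udp_matrix(expr, config: EMConfig | None = None) -> UDPMatrix:
    """Fit every gene and assemble the UDP matrix.

    Mixture-selected genes get the component posterior.  Single-component
    genes are uniformly 1 when the fitted gene mean exceeds the cohort-wide
    median of per-gene means and uniformly 0 otherwise (the gene is "up" or
    "down" across all samples).  Genes whose fit fails are flagged, assigned
    by the same mean-vs-cohort rule, and never abort the run.
    """
    config = config or EMConfig()
    values = expr.values.to_numpy(dtype=float)
    gene_ids = expr.gene_ids
    udp = np.zeros_like(values)
    fits: dict[str, MixtureFit] = {}
    flagged: dict[str, str] = {}
    gene_means = values.mean(axis=1)
    cohort_median = float(np.median(gene_means))

    for i, gene in enumerate(gene_ids):
        x = values[i]
        uniform = None
        try:
            x = shift_nonpositive(x)
            fit = fit_gene_mixture(x, config)
        except (DegenerateInputError, ValueError) as exc:
            flagged[gene] = str(exc)
            logger.warning("gene %s: fit refused (%s)", gene, exc)
            uniform = 1.0 if gene_means[i] > cohort_median else 0.0
        else:
            fits[gene] = fit
            if fit.n_components == 2:
                udp[i] = posterior_up(x, fit)
                continue
            if config.single_component_rule == "half":
                uniform = 0.5
            else:
                uniform = 1.0 if gene_means[i] > cohort_median else 0.0
        udp[i] = uniform
    return UDPMatrix(
        values=pd.DataFrame(udp, index=gene_ids, columns=expr.sample_ids),
        fit_summary=fits,
        flagged_genes=flagged,
    )
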