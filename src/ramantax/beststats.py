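"""Bayesian comparison of two models' accuracy distributions (BEST) with a
Metropolis-Hastings sampler, plus FDR control for many pairwise comparisons.

Each group's per-fold accuracies are modelled as Normal(mean, sd) with
normal priors on the mean and on the (positivity-truncated) sd.  A
random-walk Metropolis-Hastings chain samples the four parameters jointly;
the first ``burn_in`` iterations (default 1,000 of 11,000) are discarded.
The "null is true" probability is the posterior mass of
``|mean_A - mean_B| <= rope``, a region of practical equivalence (default
half-width 0.005, i.e. half an accuracy percentage point).  Unlike a t-test
this can *accept* the null, not only fail to reject it.

Multiple comparisons are corrected with Benjamini-Hochberg FDR
(via statsmodels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests


class BESTError(ValueError):
    pass


@dataclass(frozen=True)
class BESTConfig:
    """Sampler settings.

    ``proposal_sd`` is a (mean_step, sd_step) pair; None auto-scales both to
    the pooled posterior scale ``pooled_sd / sqrt(n)``.  ``prior`` is a dict
    with keys mean_center/mean_sd/sd_center/sd_sd; None centres the priors
    on the pooled sample statistics with weakly informative spreads
    (mean_sd = 0.5, sd_sd = 0.5).
    """

    n_iter: int = 11_000
    burn_in: int = 1_000
    proposal_sd: tuple[float, float] | None = None
    prior: dict | None = None
    rope: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise BESTError("need 0 <= burn_in < n_iter")
        if self.proposal_sd is not None and any(s <= 0 for s in self.proposal_sd):
            raise BESTError("proposal_sd entries must be positive")
        if self.rope < 0:
            raise BESTError("rope must be nonnegative")


@dataclass
class BESTResult:
    """Posterior samples (post burn-in) and the null probability."""

    samples: dict[str, np.ndarray]  # mean_a, sd_a, mean_b, sd_b
    p_null: float
    acceptance_rate: float
    config: BESTConfig
    degenerate: bool = False

    @property
    def n_samples(self) -> int:
        return self.samples["mean_a"].size


@dataclass
class ChainDiagnostics:
    acceptance_rate: float
    flagged: bool
    summary: dict[str, tuple[float, float]]  # parameter -> (post. mean, post. sd)


def _validate_group(acc, name: str) -> np.ndarray:
    a = np.asarray(acc, dtype=float).ravel()
    if a.size < 3:
        raise BESTError(f"group {name} needs >= 3 accuracy values, got {a.size}")
    if np.any(~np.isfinite(a)) or a.min() < 0 or a.max() > 1:
        raise BESTError(f"group {name} accuracies must be finite and in [0, 1]")
    return a


def best_compare(acc_a, acc_b, cfg: BESTConfig | None = None) -> BESTResult:
    """Posterior comparison of two accuracy samples; deterministic per seed."""
    cfg = cfg or BESTConfig()
    a = _validate_group(acc_a, "A")
    b = _validate_group(acc_b, "B")

    n_keep = cfg.n_iter - cfg.burn_in
    if a.std() == 0.0 and b.std() == 0.0:
        # no within-group spread: the comparison is decided analytically
        diff = abs(a.mean() - b.mean())
        p = 1.0 if diff <= cfg.rope else 0.0
        samples = {
            "mean_a": np.full(n_keep, a.mean()),
            "sd_a": np.zeros(n_keep),
            "mean_b": np.full(n_keep, b.mean()),
            "sd_b": np.zeros(n_keep),
        }
        return BESTResult(samples=samples, p_null=p, acceptance_rate=1.0,
                          config=cfg, degenerate=True)

    pooled = np.concatenate([a, b])
    pooled_mean = float(pooled.mean())
    pooled_sd = max(float(pooled.std(ddof=1)), 1e-4)

    prior = cfg.prior or {}
    pm = prior.get("mean_center", pooled_mean)
    pm_sd = prior.get("mean_sd", 0.5)
    ps = prior.get("sd_center", pooled_sd)
    ps_sd = prior.get("sd_sd", 0.5)

    if cfg.proposal_sd is not None:
        step_m, step_s = cfg.proposal_sd
    else:
        # within-group spread sets the posterior scale; the pooled spread
        # would overshoot badly when the two groups are far apart
        within = max(0.5 * (a.std(ddof=1) + b.std(ddof=1)), 1e-4)
        step_m = step_s = within / math.sqrt(min(a.size, b.size))

    # sufficient statistics make each likelihood evaluation O(1)
    stats = [(a.size, float(a.sum()), float((a ** 2).sum())),
             (b.size, float(b.sum()), float((b ** 2).sum()))]

    def logpost(theta) -> float:
        lp = 0.0
        for g, (n, sy, syy) in enumerate(stats):
            m, s = theta[2 * g], theta[2 * g + 1]
            if s <= 0.0:
                return -math.inf
            lp += -n * math.log(s) - 0.5 * (syy - 2 * m * sy + n * m * m) / (s * s)
            lp += -0.5 * ((m - pm) / pm_sd) ** 2
            lp += -0.5 * ((s - ps) / ps_sd) ** 2
        return lp

    rng = np.random.default_rng(cfg.seed)
    steps = rng.standard_normal((cfg.n_iter, 4)) * np.array(
        [step_m, step_s, step_m, step_s])
    log_u = np.log(rng.random(cfg.n_iter))

    theta = np.array([a.mean(), max(a.std(ddof=1), 1e-4),
                      b.mean(), max(b.std(ddof=1), 1e-4)])
    lp = logpost(theta)
    chain = np.empty((cfg.n_iter, 4))
    accepted = 0
    for i in range(cfg.n_iter):
        prop = theta + steps[i]
        lp_prop = logpost(prop)
        if log_u[i] < lp_prop - lp:
            theta, lp = prop, lp_prop
            accepted += 1
        chain[i] = theta

    kept = chain[cfg.burn_in:]
    samples = {"mean_a": kept[:, 0], "sd_a": kept[:, 1],
               "mean_b": kept[:, 2], "sd_b": kept[:, 3]}
    p_null = float(np.mean(np.abs(kept[:, 0] - kept[:, 2]) <= cfg.rope))
    return BESTResult(samples=samples, p_null=p_null,
                      acceptance_rate=accepted / cfg.n_iter, config=cfg)


def fdr_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, reject flags at ``alpha``).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise BESTError("empty p-value sequence")
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise BESTError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, reject


def chain_diagnostics(result: BESTResult) -> ChainDiagnostics:
    """Acceptance-rate sanity check plus a posterior trace summary.

    Flags chains whose acceptance rate falls outside [0.1, 0.7] — a
    symptom of a proposal that is too small (rate near 1, slow mixing) or
    too large (rate near 0, a stuck chain).
    """
    rate = result.acceptance_rate
    flagged = not (0.1 <= rate <= 0.7)
    summary = {
        name: (float(s.mean()), float(s.std(ddof=0)))
        for name, s in result.samples.items()
    }
    return ChainDiagnostics(acceptance_rate=rate, flagged=flagged,
                            summary=summary)
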