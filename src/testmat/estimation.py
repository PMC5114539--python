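"""Person-parameter estimation for the testlet model.

Three estimators live here:

* :func:`bayes_modal` — posterior-mode scoring of the stacked
  ``(theta, gamma)`` vector under a multivariate normal prior, iterated by
  Fisher scoring with step halving.  Used for the provisional estimates
  inside an adaptive test, where speed matters.
* :func:`mcmc_scale` — Metropolis-within-Gibbs sampling of abilities,
  testlet effects, the ability covariance (conjugate inverse-Wishart block)
  and the testlet-effect variances (conjugate inverse-Gamma blocks), with a
  Geweke-controlled burn-in and expected-a-posteriori (EAP) point estimates
  from the retained window.  Used for the final scaling of a completed
  assessment, where the many gamma dimensions make modal estimation
  unattractive.
* :func:`mml_calibrate_difficulties` — marginal maximum likelihood (EM with
  Gauss-Hermite quadrature) re-calibration of item difficulties under the
  ordinary MIRT model, one dimension at a time.  Used to quantify the
  shrinkage of the difficulty scale when testlet-generated data are scaled
  with a model that ignores the testlet effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit, logsumexp
from scipy.stats import invwishart, norm

from .information import ExpandedPrior
from .model import EXPONENT_CLIP, Item, ItemPool

__all__ = [
    "EstimationError",
    "bayes_modal",
    "PriorSpec",
    "ChainConfig",
    "ConvergenceReport",
    "EAPResult",
    "ResponseSet",
    "mcmc_scale",
    "mml_calibrate_difficulties",
    "geweke_z",
]


#: support of the testlet-variance prior, truncated for numerical stability:
#: with a vague inverse-Gamma prior a variance informed by one or two
#: persons is nearly flat in log-sigma and would otherwise random-walk to
#: overflow; the bounds are far outside any substantively possible value
SIGMA2_BOUNDS = (1e-8, 1e4)


class EstimationError(RuntimeError):
    """Raised on non-convergence; carries the last iterate in ``last_iterate``."""

    def __init__(self, message: str, last_iterate: np.ndarray):
        super().__init__(message)
        self.last_iterate = last_iterate


# ---------------------------------------------------------------------------
# Bayes modal (Fisher scoring)
# ---------------------------------------------------------------------------

def _posterior_pieces(A, b, c, S, slot, u, x, P_dim, v):
    """Log posterior kernel, gradient and Fisher matrix at ``x``.

    ``slot`` maps each answered item to its gamma coordinate (-1 = none).
    The Fisher matrix is the prior precision plus the expected information,
    which keeps the scoring step well defined even for 3PL items.
    """
    theta, gamma = x[:P_dim], x[P_dim:]
    if v:
        gam_item = np.where(slot >= 0, gamma[np.clip(slot, 0, None)], 0.0)
    else:
        gam_item = 0.0
    lin = A @ theta - (b + gam_item) * S
    s = expit(np.clip(lin, -EXPONENT_CLIP, EXPONENT_CLIP))
    p = c + (1.0 - c) * s
    loglik = float(np.sum(u * np.log(p) + (1.0 - u) * np.log1p(-p)))
    slope = (1.0 - c) * s * (1.0 - s)
    pq = p * (1.0 - p)
    w_grad = (u - p) / pq * slope
    w_info = slope**2 / pq

    grad = np.empty(P_dim + v)
    grad[:P_dim] = A.T @ w_grad
    info = np.zeros((P_dim + v, P_dim + v))
    info[:P_dim, :P_dim] = (A * w_info[:, None]).T @ A
    if v:
        valid = slot >= 0
        sv = slot[valid]
        grad[P_dim:] = -np.bincount(sv, weights=(w_grad * S)[valid], minlength=v)
        info[P_dim:, P_dim:][np.arange(v), np.arange(v)] = np.bincount(
            sv, weights=(w_info * S**2)[valid], minlength=v
        )
        cross = np.zeros((v, P_dim))
        np.add.at(cross, sv, -((w_info * S)[valid, None] * A[valid]))
        info[P_dim:, :P_dim] = cross
        info[:P_dim, P_dim:] = cross.T
    return loglik, grad, info


def _bayes_modal_arrays(
    A: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    slot: np.ndarray,
    u: np.ndarray,
    precision: np.ndarray,
    x0: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[np.ndarray, bool, int]:
    """Array-level Fisher scoring; returns ``(x_hat, converged, n_iter)``."""
    n = precision.shape[0]
    P_dim = A.shape[1] if A.size else n
    v = n - P_dim
    x = np.zeros(n) if x0 is None else np.array(x0, dtype=float)
    if u.size == 0:
        return x, True, 0
    S = A.sum(axis=1)

    def objective(xx):
        ll, _, _ = _posterior_pieces(A, b, c, S, slot, u, xx, P_dim, v)
        return ll - 0.5 * xx @ precision @ xx

    obj = objective(x)
    for it in range(1, max_iter + 1):
        _, grad_ll, info = _posterior_pieces(A, b, c, S, slot, u, x, P_dim, v)
        grad_post = grad_ll - precision @ x
        W = precision + info
        try:
            step = np.linalg.solve(W, grad_post)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(W, grad_post, rcond=None)[0]
        alpha = 1.0
        for _ in range(12):
            cand = x + alpha * step
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                break
            alpha *= 0.5
        else:
            return x, False, it
        x, obj = cand, cand_obj
        if np.max(np.abs(step)) < tol:
            return x, True, it
    return x, False, max_iter


def bayes_modal(
    responses: Sequence[int],
    items: Sequence[Item],
    prior: ExpandedPrior,
    testlet_order: Sequence[str] | None = None,
    start: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[np.ndarray, dict[str, float]]:
    """Posterior mode of ``(theta, gamma)`` given answered items.

    Parameters
    ----------
    responses, items
        Parallel sequences of binary responses and the answered items.
    prior
        Expanded prior covariance; its ``testlet_variances`` correspond,
        in order, to ``testlet_order`` (answered-testlet order inferred from
        ``items`` when omitted).  A prior with ``v = 0`` scores under the
        plain MIRT model.
    start
        Optional warm start for the stacked vector.

    Returns
    -------
    theta_hat, gamma_hat
        The ability mode and a testlet-id -> effect mapping.

    Raises
    ------
    EstimationError
        If Fisher scoring fails to converge; the error carries the last
        iterate.
    """
    if len(responses) != len(items):
        raise ValueError("responses and items differ in length")
    if testlet_order is None:
        testlet_order = []
        for it in items:
            if it.testlet_id not in testlet_order:
                testlet_order.append(it.testlet_id)
        testlet_order = testlet_order[: prior.v]
    if len(testlet_order) != prior.v:
        raise ValueError(
            f"testlet_order has {len(testlet_order)} entries, prior expects {prior.v}"
        )
    slots = {tid: m for m, tid in enumerate(testlet_order)}
    if not items:
        return np.zeros(prior.P), {tid: 0.0 for tid in testlet_order}
    A = np.array([it.a for it in items], dtype=float)
    b = np.array([it.b for it in items], dtype=float)
    c = np.array([it.c for it in items], dtype=float)
    slot = np.array([slots.get(it.testlet_id, -1) for it in items], dtype=np.intp)
    u = np.asarray(responses, dtype=float)
    x, converged, n_iter = _bayes_modal_arrays(
        A, b, c, slot, u, prior.precision(), start, tol, max_iter
    )
    if not converged:
        raise EstimationError(
            f"Fisher scoring did not converge within {max_iter} iterations", x
        )
    theta_hat = x[: prior.P]
    gamma_hat = {tid: float(x[prior.P + m]) for tid, m in slots.items()}
    return theta_hat, gamma_hat


# ---------------------------------------------------------------------------
# response container for the final scaling
# ---------------------------------------------------------------------------

@dataclass
class ResponseSet:
    """Responses of ``N`` persons to (possibly person-specific) item sets.

    ``item_idx[j, l]`` is the pool index of the ``l``-th item answered by
    person ``j``; ``slot[j, l]`` the position of that item's testlet in the
    person's answered-testlet list; ``person_testlets[j, m]`` the pool-level
    testlet index of that slot (-1 pads unused slots).
    """

    pool: ItemPool
    item_idx: np.ndarray
    responses: np.ndarray
    slot: np.ndarray
    person_testlets: np.ndarray

    def __post_init__(self) -> None:
        self.item_idx = np.asarray(self.item_idx, dtype=np.intp)
        self.responses = np.asarray(self.responses, dtype=float)
        self.slot = np.asarray(self.slot, dtype=np.intp)
        self.person_testlets = np.asarray(self.person_testlets, dtype=np.intp)
        if self.item_idx.shape != self.responses.shape or self.item_idx.shape != self.slot.shape:
            raise ValueError("item_idx, responses and slot must share a shape")

    @property
    def n_persons(self) -> int:
        return self.item_idx.shape[0]

    @property
    def n_slots(self) -> int:
        return self.person_testlets.shape[1]

    @classmethod
    def full_matrix(cls, responses: np.ndarray, pool: ItemPool) -> "ResponseSet":
        """Every person answered every pool item (non-adaptive full data)."""
        responses = np.asarray(responses)
        N, n_items = responses.shape
        if n_items != len(pool):
            raise ValueError("response matrix width does not match pool size")
        tindex = {tid: k for k, tid in enumerate(pool.testlet_ids)}
        item_testlet = np.array([tindex[it.testlet_id] for it in pool.items], dtype=np.intp)
        item_idx = np.tile(np.arange(n_items, dtype=np.intp), (N, 1))
        slot = np.tile(item_testlet, (N, 1))
        person_testlets = np.tile(np.arange(pool.n_testlets, dtype=np.intp), (N, 1))
        return cls(pool, item_idx, responses, slot, person_testlets)

    def testlet_exposure(self) -> np.ndarray:
        """Number of persons who answered each pool testlet."""
        flat = self.person_testlets[self.person_testlets >= 0]
        return np.bincount(flat, minlength=self.pool.n_testlets)


# ---------------------------------------------------------------------------
# MCMC final scaling
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Hyperpriors for the final scaling.

    Ability means are fixed at zero.  The ability covariance gets an
    inverse-Wishart prior (identity scale, ``wishart_df`` degrees of
    freedom); each testlet-effect variance an inverse-Gamma prior with both
    parameters near zero (vague but proper).  Setting ``estimate_phi`` to
    False fixes the ability covariance at ``phi_fixed``.
    """

    wishart_df: float = 9.0
    wishart_scale: np.ndarray | None = None
    ig_shape: float = 1e-3
    ig_scale: float = 1e-3
    estimate_phi: bool = True
    phi_fixed: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ig_shape <= 0 or self.ig_scale <= 0:
            raise ValueError("inverse-Gamma hyperparameters must be positive")


@dataclass
class ChainConfig:
    """Sampler schedule: burn-in control, adaptation and the retained window."""

    min_burn_in: int = 1000
    burn_in_cap: int = 5000
    check_interval: int = 500
    retain: int = 500
    adapt_interval: int = 100
    theta_scale: float = 0.5
    #: inflation of the Laplace proposal width for the effect updates
    #: (1 = exact Laplace); not adapted — independence proposals are kept
    #: close to the conditional posterior by construction
    gamma_scale: float = 1.2
    sigma_scale: float = 2.0
    #: repetitions of the per-block sweeps within one iteration; extra
    #: ability sweeps cut the Monte-Carlo noise of the retained-window EAPs
    #: (the random walk is the slowest-mixing block left), and the variance
    #: machinery keeps one interweaved sweep per iteration
    theta_sweeps: int = 2
    gamma_sweeps: int = 1
    interweave_sweeps: int = 1
    n_sentinel_theta: int = 10
    #: testlet-variance traces are monitored for convergence only when the
    #: testlet was answered by at least this many persons (the same traces
    #: that inform the reported summaries)
    monitor_min_exposure: int = 20
    geweke_threshold: float = 1.96
    #: convergence is declared when at most this fraction of monitored
    #: parameters exceeds the threshold (the nominal false-positive rate of
    #: the criterion under stationarity), or when no score exceeds the
    #: Bonferroni-corrected familywise threshold — with dozens of monitored
    #: parameters, requiring every score under the nominal threshold has a
    #: familywise false-alarm probability near one
    geweke_fail_fraction: float = 0.05
    familywise_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.burn_in_cap < self.min_burn_in:
            raise ValueError("burn_in_cap must be at least min_burn_in")


@dataclass
class ConvergenceReport:
    """Geweke diagnostics at the adopted burn-in point."""

    geweke_z: dict[str, float]
    burn_in: int
    passed: bool
    fraction_failed: float


@dataclass
class EAPResult:
    """Posterior summaries from the retained window of the final scaling."""

    theta: np.ndarray
    theta_sd: np.ndarray
    gamma: np.ndarray
    sigma2: dict[str, float]
    sigma2_sd: dict[str, float]
    phi_mean: np.ndarray
    testlet_exposure: dict[str, int]
    n_retained: int

    def mean_sigma2(self, min_exposure: int = 20) -> float:
        """Average posterior-mean testlet effect variance across testlets.

        Testlet variances are averaged with weights proportional to the
        number of persons who answered the testlet, and testlets below
        ``min_exposure`` persons are left out entirely: with a vague
        inverse-Gamma prior, a variance informed by only a handful of
        persons is dominated by small-sample skew rather than by data.
        Under uniform exposure (random administration, or any design at
        full scale) this reduces to the plain mean across testlets.
        """
        pairs = [
            (v, self.testlet_exposure[tid])
            for tid, v in self.sigma2.items()
            if self.testlet_exposure[tid] >= min_exposure
        ]
        if not pairs:
            raise ValueError("no testlet reaches the exposure threshold")
        vals, wts = zip(*pairs)
        return float(np.average(vals, weights=wts))


def geweke_z(trace: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence score for one trace.

    Compares the means of the first ``first`` and last ``last`` fractions of
    the trace, with the variance of each segment mean estimated by batch
    means (robust to autocorrelation).
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[0]
    a = trace[: max(int(first * n), 2)]
    b = trace[-max(int(last * n), 2):]
    denom = _mean_variance_ips(a) + _mean_variance_ips(b)
    if denom <= 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(denom))


def _mean_variance_ips(x: np.ndarray) -> float:
    """Variance of the mean of an autocorrelated series.

    Uses Geyer's initial-positive-sequence estimator: autocovariances are
    summed in adjacent pairs until a pair goes non-positive, which is
    consistent for reversible chains and conservative in practice.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    xc = x - x.mean()
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    s = acov[0]
    k = 1
    while k + 1 < n:
        pair = acov[k] + acov[k + 1]
        if pair <= 0:
            break
        s += 2.0 * pair
        k += 2
    return max(s, 0.0) / n


def phi_conditional_params(
    theta: np.ndarray, prior: PriorSpec
) -> tuple[float, np.ndarray]:
    """Inverse-Wishart full-conditional ``(df, scale)`` for the ability covariance."""
    theta = np.asarray(theta, dtype=float)
    P_dim = theta.shape[1]
    V0 = np.eye(P_dim) if prior.wishart_scale is None else np.asarray(prior.wishart_scale)
    return prior.wishart_df + theta.shape[0], V0 + theta.T @ theta


def sigma2_conditional_params(
    gamma_values: np.ndarray, prior: PriorSpec
) -> tuple[float, float]:
    """Inverse-Gamma full-conditional ``(shape, scale)`` for one testlet variance."""
    g = np.asarray(gamma_values, dtype=float)
    return prior.ig_shape + g.size / 2.0, prior.ig_scale + float(g @ g) / 2.0


def _sample_invwishart(
    df: float, scale: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One inverse-Wishart draw via the Bartlett decomposition.

    Equivalent in distribution to ``scipy.stats.invwishart.rvs`` but without
    the per-call overhead, which matters inside the sampler loop.
    """
    p = scale.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((p, p))
    A[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    A[np.tril_indices(p, -1)] = rng.standard_normal(p * (p - 1) // 2)
    LA = L @ A
    return np.linalg.inv(LA @ LA.T)


class _GibbsState:
    """Internal vectorised sampler state over persons."""

    def __init__(
        self,
        data: ResponseSet,
        prior: PriorSpec,
        model: str,
        rng: np.random.Generator,
    ):
        pool = data.pool
        self.rng = rng
        self.prior = prior
        self.model = model
        self.u = data.responses
        self.N, self.L = self.u.shape
        self.P = pool.P
        self.A_g = pool.A[data.item_idx]  # (N, L, P)
        self.S_g = self.A_g.sum(axis=2)
        self.b_g = pool.b[data.item_idx]
        self.c_g = pool.c[data.item_idx]
        # simple structure (one loading per item) admits a gather instead of
        # the general einsum in the inner likelihood sweep
        nz = (pool.A != 0).sum(axis=1)
        self._simple = bool(np.all(nz == 1))
        if self._simple:
            dim_of_item = np.argmax(pool.A != 0, axis=1)
            # flat gather indices into theta.ravel() / gamma.ravel()
            row_offset = np.arange(self.N)[:, None]
            self._dim_flat = dim_of_item[data.item_idx] + row_offset * self.P
            self._a_g = pool.A[np.arange(len(pool)), dim_of_item][data.item_idx]
        self._u_bool = self.u > 0.5
        self._all_rasch = bool(np.all(pool.c == 0.0))
        self.slot = data.slot
        self.glob = data.person_testlets
        self.slot_mask = self.glob >= 0
        self.n_slots = data.n_slots
        self._slot_flat = self.slot + np.arange(self.N)[:, None] * max(self.n_slots, 1)
        self.D = pool.n_testlets
        flat = self.glob[self.slot_mask]
        self.exposure = np.bincount(flat, minlength=self.D)
        self.answered = self.exposure > 0

        # fast path for per-slot log-likelihood sums: administration appends
        # whole testlets, so slots are contiguous equal-sized blocks
        block = self.L // self.n_slots if self.n_slots else 0
        pattern = np.repeat(np.arange(self.n_slots), block) if block else None
        self._contig = (
            self.n_slots > 0
            and self.L == block * self.n_slots
            and bool(np.all(self.slot == pattern[None, :]))
        )

        self.theta = np.zeros((self.N, self.P))
        # start the effects dispersed at the initial variance: starting them
        # at zero collapses the conjugate variance draw toward zero early in
        # the chain, which then takes long to recover from
        sigma2_init = 1.0
        self.gamma = np.where(
            self.slot_mask,
            rng.normal(0.0, np.sqrt(sigma2_init), size=(self.N, self.n_slots)),
            0.0,
        ) if model == "MTIRT" else np.zeros((self.N, self.n_slots))
        if prior.estimate_phi:
            self.phi = np.eye(self.P)
        else:
            if prior.phi_fixed is None:
                raise ValueError("estimate_phi=False requires phi_fixed")
            self.phi = np.asarray(prior.phi_fixed, dtype=float)
        self.lam = np.linalg.inv(self.phi)
        self.sigma2 = np.full(self.D, sigma2_init)
        self.terms = self._loglik_items(self.theta, self.gamma)
        self.ll = self.terms.sum(axis=1)

    # -- likelihood kernels ------------------------------------------------
    def _loglik_items(self, theta: np.ndarray, gamma: np.ndarray) -> np.ndarray:
        gam_item = (
            gamma.ravel()[self._slot_flat] if self.model == "MTIRT" else 0.0
        )
        if self._simple:
            lin = self._a_g * (theta.ravel()[self._dim_flat] - self.b_g - gam_item)
        else:
            lin = (
                np.einsum("nlp,np->nl", self.A_g, theta)
                - (self.b_g + gam_item) * self.S_g
            )
        # log P(u) in one pass: flip the sign of the exponent for wrong
        # answers, then a single log-logistic (exact for c = 0)
        np.clip(lin, -EXPONENT_CLIP, EXPONENT_CLIP, out=lin)
        if self._all_rasch:
            signed = np.where(self._u_bool, lin, -lin)
            return -np.log1p(np.exp(-signed))
        s = expit(lin)
        p = self.c_g + (1.0 - self.c_g) * s
        return np.log(np.where(self._u_bool, p, 1.0 - p))

    def _slot_sums(self, terms: np.ndarray) -> np.ndarray:
        if self._contig:
            return terms.reshape(self.N, self.n_slots, -1).sum(axis=2)
        out = np.zeros((self.N, self.n_slots))
        np.add.at(
            out,
            (np.repeat(np.arange(self.N), self.L), self.slot.ravel()),
            terms.ravel(),
        )
        return out

    # -- update blocks -----------------------------------------------------
    def update_theta(self, scale: float) -> float:
        prop = self.theta + scale * self.rng.standard_normal(self.theta.shape)
        prop_terms = self._loglik_items(prop, self.gamma)
        ll_prop = prop_terms.sum(axis=1)
        pr_cur = -0.5 * np.einsum("np,pq,nq->n", self.theta, self.lam, self.theta)
        pr_prop = -0.5 * np.einsum("np,pq,nq->n", prop, self.lam, prop)
        log_ratio = ll_prop + pr_prop - self.ll - pr_cur
        accept = np.log(self.rng.random(self.N)) < log_ratio
        self.theta[accept] = prop[accept]
        self.terms[accept] = prop_terms[accept]
        self.ll[accept] = ll_prop[accept]
        return float(accept.mean())

    def _gamma_slot_derivatives(
        self, gamma: np.ndarray, th_minus_b: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-slot score and Fisher curvature of the log likelihood in gamma.

        ``th_minus_b`` may carry the gamma-independent part of the exponent
        (per-item ``a'theta - b*sum(a)``), which is constant across Newton
        steps within one update.
        """
        gam_item = gamma.ravel()[self._slot_flat]
        if th_minus_b is None:
            th_minus_b = self._gamma_free_exponent()
        lin = th_minus_b - gam_item * self.S_g
        np.clip(lin, -EXPONENT_CLIP, EXPONENT_CLIP, out=lin)
        s = expit(lin)
        if self._all_rasch:
            # p = s, pq = s(1-s) = slope: score and curvature collapse
            d1 = self._slot_sums((s - self.u) * self.S_g)
            fisher = self._slot_sums(s * (1.0 - s) * self.S_g**2)
        else:
            p = self.c_g + (1.0 - self.c_g) * s
            pq = p * (1.0 - p)
            slope = (1.0 - self.c_g) * s * (1.0 - s)
            d1 = self._slot_sums(-(self.u - p) / pq * slope * self.S_g)
            fisher = self._slot_sums(slope**2 / pq * self.S_g**2)
        return d1, fisher

    def _gamma_free_exponent(self) -> np.ndarray:
        """Per-item exponent at gamma = 0 for the current theta."""
        if self._simple:
            return self._a_g * (self.theta.ravel()[self._dim_flat] - self.b_g)
        return (
            np.einsum("nlp,np->nl", self.A_g, self.theta) - self.b_g * self.S_g
        )

    def update_gamma(self, scale: float) -> float:
        """Independence Metropolis from per-slot Laplace approximations.

        Given theta, the effects of one person are conditionally
        independent across slots, each informed by only a few items.  A
        random walk mixes those weakly identified coordinates slowly and,
        worse, lets the variance chains chase the effect dispersion far
        past equilibrium before recovering.  Instead, each sweep finds the
        1-D conditional mode per slot by Newton steps and proposes from a
        normal at the mode with curvature-matched, slightly inflated scale;
        acceptance rates are near one and successive draws are almost
        independent.  ``scale`` inflates the proposal width (1 = exact
        Laplace).
        """
        var = np.where(self.slot_mask, self.sigma2[np.clip(self.glob, 0, None)], 1.0)
        var = np.maximum(var, 1e-12)
        # Newton from zero with a fixed step count, so the proposal depends
        # only on (theta, sigma2) and the kernel is a true independence
        # sampler (exactly reversible); two steps land close enough to the
        # mode for high acceptance, and the last curvature doubles as the
        # proposal width
        mode = np.zeros_like(self.gamma)
        th_minus_b = self._gamma_free_exponent()
        for _ in range(2):
            d1, fisher = self._gamma_slot_derivatives(mode, th_minus_b)
            curv = fisher + 1.0 / var
            step = (d1 - mode / var) / curv
            mode = np.where(self.slot_mask, mode + step, 0.0)
        prop_sd = scale / np.sqrt(curv)
        prop = mode + prop_sd * self.rng.standard_normal(self.gamma.shape)
        prop_terms = self._loglik_items(self.theta, prop)
        cur_slot = self._slot_sums(self.terms)
        prop_slot = self._slot_sums(prop_terms)
        log_post_diff = (
            prop_slot - cur_slot - 0.5 * (prop**2 - self.gamma**2) / var
        )
        log_q_diff = (
            -0.5 * ((self.gamma - mode) / prop_sd) ** 2
            + 0.5 * ((prop - mode) / prop_sd) ** 2
        )
        log_ratio = log_post_diff + log_q_diff
        accept = (np.log(self.rng.random(self.gamma.shape)) < log_ratio) & self.slot_mask
        self.gamma[accept] = prop[accept]
        acc_items = accept.ravel()[self._slot_flat]
        self.terms = np.where(acc_items, prop_terms, self.terms)
        self.ll = self.terms.sum(axis=1)
        return float(accept[self.slot_mask].mean()) if self.slot_mask.any() else 1.0

    def update_gamma_rw(self, scale: float) -> float:
        prop = self.gamma + scale * self.rng.standard_normal(self.gamma.shape)
        prop_terms = self._loglik_items(self.theta, prop)
        cur_slot = self._slot_sums(self.terms)
        prop_slot = self._slot_sums(prop_terms)
        var = np.where(self.slot_mask, self.sigma2[np.clip(self.glob, 0, None)], 1.0)
        var = np.maximum(var, 1e-12)
        log_ratio = (
            prop_slot
            - cur_slot
            - 0.5 * (prop**2 - self.gamma**2) / var
        )
        accept = (np.log(self.rng.random(self.gamma.shape)) < log_ratio) & self.slot_mask
        self.gamma[accept] = prop[accept]
        acc_items = accept.ravel()[self._slot_flat]
        self.terms = np.where(acc_items, prop_terms, self.terms)
        self.ll = self.terms.sum(axis=1)
        return float(accept[self.slot_mask].mean()) if self.slot_mask.any() else 1.0

    def update_sigma2_interweaved(self, scale: float) -> float:
        """Joint rescaling of ``(gamma_d, sigma2_d)`` per testlet.

        Random-walk Metropolis on ``eta_d = log sigma_d`` in the ancillary
        parameterization (``gamma = sigma * gamma_tilde`` with
        ``gamma_tilde`` held fixed), interleaved with the conjugate draw.
        Each person's effects are weakly identified by a handful of items,
        so the sufficient-parameterization Gibbs step alone moves the
        variances very slowly; the interweaved move rescales a testlet's
        effects and its variance together and restores fast mixing.
        """
        if not self.answered.any():
            return 1.0
        eta = 0.5 * np.log(np.maximum(self.sigma2, 1e-300))
        # posterior width of log sigma_d shrinks like 1/sqrt(exposure), so
        # proposals are scaled per testlet around a globally adapted base
        per_testlet = scale / np.sqrt(self.exposure + 1.0)
        prop_eta = eta + per_testlet * self.rng.standard_normal(self.D)
        lo, hi = SIGMA2_BOUNDS
        in_support = (prop_eta > 0.5 * np.log(lo)) & (prop_eta < 0.5 * np.log(hi))
        prop_eta = np.where(in_support, prop_eta, eta)
        factor = np.exp(prop_eta - eta)
        fac_slot = np.where(self.slot_mask, factor[np.clip(self.glob, 0, None)], 1.0)
        prop_gamma = self.gamma * fac_slot
        prop_terms = self._loglik_items(self.theta, prop_gamma)
        d_slot = self._slot_sums(prop_terms - self.terms)
        dll = np.bincount(
            self.glob[self.slot_mask],
            weights=d_slot[self.slot_mask],
            minlength=self.D,
        )
        k, s = self.prior.ig_shape, self.prior.ig_scale
        s2_prop = np.exp(2.0 * prop_eta)
        # inverse-Gamma prior on sigma2 plus the d(sigma2)/d(eta) Jacobian
        log_ratio = dll - 2.0 * k * (prop_eta - eta) - s * (1.0 / s2_prop - 1.0 / self.sigma2)
        accept = (np.log(self.rng.random(self.D)) < log_ratio) & self.answered
        if accept.any():
            acc_slot = accept[np.clip(self.glob, 0, None)] & self.slot_mask
            self.gamma = np.where(acc_slot, prop_gamma, self.gamma)
            acc_items = acc_slot.ravel()[self._slot_flat]
            self.terms = np.where(acc_items, prop_terms, self.terms)
            self.ll = self.terms.sum(axis=1)
            self.sigma2[accept] = s2_prop[accept]
        return float(accept[self.answered].mean())

    def update_phi(self) -> None:
        if not self.prior.estimate_phi:
            return
        df_post, scale_post = phi_conditional_params(self.theta, self.prior)
        self.phi = _sample_invwishart(df_post, scale_post, self.rng)
        self.lam = np.linalg.inv(self.phi)

    def update_sigma2(self) -> None:
        flat_idx = self.glob[self.slot_mask]
        ssq = np.bincount(flat_idx, weights=(self.gamma**2)[self.slot_mask], minlength=self.D)
        a_post = self.prior.ig_shape + self.exposure / 2.0
        scale_post = self.prior.ig_scale + ssq / 2.0
        draws = scale_post[self.answered] / self.rng.gamma(a_post[self.answered])
        self.sigma2[self.answered] = np.clip(draws, *SIGMA2_BOUNDS)


def mcmc_scale(
    data: ResponseSet,
    prior_spec: PriorSpec | None = None,
    chain: ChainConfig | None = None,
    model: Literal["MTIRT", "MIRT"] = "MTIRT",
    rng: np.random.Generator | int | None = None,
    trace_path: "str | None" = None,
) -> tuple[EAPResult, ConvergenceReport]:
    """Final scaling of a completed assessment by Metropolis-within-Gibbs.

    Item parameters are fixed at their pool values.  Person abilities and
    testlet effects are updated by random-walk Metropolis (proposal scales
    adapted to a 0.2-0.5 acceptance rate during the minimum burn-in and
    frozen afterwards); the ability covariance and the testlet-effect
    variances are drawn from their conjugate full conditionals.  Burn-in is
    extended in blocks until the Geweke criterion passes on the monitored
    parameters (all answered testlet variances, the ability covariance
    entries and sentinel abilities) or the cap is reached; point estimates
    are means over the retained window.

    Under ``model="MIRT"`` the gamma machinery is dropped and only abilities
    and the ability covariance are sampled.

    When ``trace_path`` is given, the monitored traces (testlet variances,
    ability-covariance entries, sentinel abilities) are written there as a
    tidy CSV (iteration, parameter, value) for external MCMC diagnostics.
    """
    prior_spec = prior_spec or PriorSpec()
    chain = chain or ChainConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    state = _GibbsState(data, prior_spec, model, rng)

    theta_scale = chain.theta_scale
    gamma_scale = chain.gamma_scale
    sigma_scale = chain.sigma_scale
    monitor_sigma: list[np.ndarray] = []
    monitor_phi: list[np.ndarray] = []
    monitor_theta: list[np.ndarray] = []
    n_sent = min(chain.n_sentinel_theta, state.N)
    iu = np.triu_indices(state.P)
    sigma_monitored = state.answered & (state.exposure >= chain.monitor_min_exposure)
    if not sigma_monitored.any():
        sigma_monitored = state.answered.copy()

    acc_theta: list[float] = []
    acc_gamma: list[float] = []
    acc_sigma: list[float] = []

    def one_iteration(adapting: bool) -> None:
        nonlocal theta_scale, sigma_scale
        for _ in range(chain.theta_sweeps):
            acc_theta.append(state.update_theta(theta_scale))
        if model == "MTIRT":
            for _ in range(chain.gamma_sweeps):
                acc_gamma.append(state.update_gamma(gamma_scale))
            state.update_sigma2()
            for _ in range(chain.interweave_sweeps):
                acc_sigma.append(state.update_sigma2_interweaved(sigma_scale))
        state.update_phi()
        monitor_sigma.append(state.sigma2[sigma_monitored].copy())
        monitor_phi.append(state.phi[iu].copy())
        monitor_theta.append(state.theta[:n_sent, 0].copy())
        if adapting and len(acc_theta) % chain.adapt_interval == 0:
            recent = np.mean(acc_theta[-chain.adapt_interval:])
            theta_scale *= float(np.exp(np.clip(recent - 0.35, -0.5, 0.5)))
            if acc_sigma:
                recent_s = np.mean(acc_sigma[-chain.adapt_interval:])
                sigma_scale *= float(np.exp(np.clip(recent_s - 0.35, -0.5, 0.5)))

    def geweke_snapshot(start: int) -> dict[str, float]:
        zs: dict[str, float] = {}
        sig = np.asarray(monitor_sigma[start:])
        if model == "MTIRT" and sig.size:
            # variances are monitored on the log scale: the conjugate draws
            # are heavy-tailed and raw segment means compare poorly
            log_sig = np.log(np.maximum(sig, 1e-300))
            for k in range(log_sig.shape[1]):
                zs[f"sigma2_{k}"] = geweke_z(log_sig[:, k])
        ph = np.asarray(monitor_phi[start:])
        for k in range(ph.shape[1]):
            zs[f"phi_{k}"] = geweke_z(ph[:, k])
        th = np.asarray(monitor_theta[start:])
        for k in range(th.shape[1]):
            zs[f"theta_{k}"] = geweke_z(th[:, k])
        return zs

    it = 0
    passed = False
    zs: dict[str, float] = {}
    frac_failed = 1.0
    while True:
        block = min(chain.check_interval, chain.burn_in_cap - it)
        for _ in range(block):
            one_iteration(adapting=it < chain.min_burn_in)
            it += 1
        if it >= chain.min_burn_in:
            zs = geweke_snapshot(it // 2)
            n_bad = sum(abs(z) > chain.geweke_threshold for z in zs.values())
            frac_failed = n_bad / max(len(zs), 1)
            bonferroni = norm.isf(chain.familywise_alpha / (2 * max(len(zs), 1)))
            max_z = max((abs(z) for z in zs.values()), default=0.0)
            if frac_failed <= chain.geweke_fail_fraction or max_z < bonferroni:
                passed = True
                break
        if it >= chain.burn_in_cap:
            break
    report = ConvergenceReport(
        geweke_z=zs, burn_in=it, passed=passed, fraction_failed=frac_failed
    )
    if not passed:
        import warnings

        warnings.warn(
            f"burn-in cap {chain.burn_in_cap} reached with {frac_failed:.0%} of "
            "monitored parameters failing the Geweke criterion; results are "
            "emitted anyway",
            stacklevel=2,
        )

    # retained window
    theta_sum = np.zeros_like(state.theta)
    theta_sq = np.zeros_like(state.theta)
    gamma_sum = np.zeros_like(state.gamma)
    sigma_draws = np.zeros((chain.retain, state.D))
    phi_sum = np.zeros_like(state.phi)
    for r in range(chain.retain):
        one_iteration(adapting=False)
        theta_sum += state.theta
        theta_sq += state.theta**2
        gamma_sum += state.gamma
        sigma_draws[r] = state.sigma2
        phi_sum += state.phi
    nr = chain.retain
    theta_eap = theta_sum / nr
    theta_sd = np.sqrt(np.maximum(theta_sq / nr - theta_eap**2, 0.0))
    pool = data.pool
    sigma2 = {}
    sigma2_sd = {}
    exposure = {}
    for k, tid in enumerate(pool.testlet_ids):
        exposure[tid] = int(state.exposure[k])
        if state.answered[k] and model == "MTIRT":
            # near-unexposed testlets have essentially prior-only variances
            # whose draws can be astronomically large; their summaries are
            # reported as-is (and excluded from mean_sigma2 by exposure)
            with np.errstate(over="ignore"):
                sigma2[tid] = float(sigma_draws[:, k].mean())
                sigma2_sd[tid] = float(sigma_draws[:, k].std(ddof=1))
    if trace_path is not None:
        import pandas as pd

        names: list[str] = []
        if model == "MTIRT":
            names += [
                f"sigma2[{pool.testlet_ids[k]}]"
                for k in np.flatnonzero(sigma_monitored)
            ]
        names += [f"phi[{r},{s}]" for r, s in zip(*iu)]
        names += [f"theta[{j},1]" for j in range(n_sent)]
        rows = np.hstack(
            [np.asarray(monitor_sigma), np.asarray(monitor_phi), np.asarray(monitor_theta)]
            if model == "MTIRT"
            else [np.asarray(monitor_phi), np.asarray(monitor_theta)]
        )
        tidy = pd.DataFrame(rows, columns=names)
        tidy.insert(0, "iteration", np.arange(len(tidy)))
        tidy.melt(id_vars="iteration", var_name="parameter", value_name="value").to_csv(
            trace_path, index=False
        )

    result = EAPResult(
        theta=theta_eap,
        theta_sd=theta_sd,
        gamma=gamma_sum / nr,
        sigma2=sigma2,
        sigma2_sd=sigma2_sd,
        phi_mean=phi_sum / nr,
        testlet_exposure=exposure,
        n_retained=nr,
    )
    return result, report


# ---------------------------------------------------------------------------
# MML difficulty calibration (shrinkage rescaling)
# ---------------------------------------------------------------------------

def mml_calibrate_difficulties(
    responses: np.ndarray,
    pool: ItemPool,
    n_nodes: int = 21,
    max_iter: int = 200,
    tol: float = 1e-5,
    boundary: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """MIRT difficulty re-calibration by marginal maximum likelihood.

    Requires simple structure (each item loads on exactly one dimension) and
    known loadings; the marginal ability distribution per dimension is taken
    as standard normal, so each dimension is calibrated as a unidimensional
    model by EM with Gauss-Hermite quadrature.

    Parameters
    ----------
    responses
        Full ``(N, n_items)`` binary matrix in pool item order.
    pool
        Pool with fixed loadings; ``c`` must be zero for all items.

    Returns
    -------
    b_hat, flagged
        Estimated difficulties per item and a boolean flag marking items
        with all-zero or all-one response vectors (their estimates are set
        to the +/- ``boundary``).
    """
    responses = np.asarray(responses, dtype=float)
    N, n_items = responses.shape
    if n_items != len(pool):
        raise ValueError("response matrix width does not match pool size")
    if np.any(pool.c != 0.0):
        raise ValueError("MML calibration assumes pseudo-guessing fixed at zero")
    nz_counts = (pool.A != 0).sum(axis=1)
    if np.any(nz_counts != 1):
        raise ValueError("MML calibration requires simple structure (one loading per item)")
    dim_of_item = np.argmax(pool.A != 0, axis=1)
    a_scalar = pool.A[np.arange(n_items), dim_of_item]

    # Gauss-Hermite nodes for a standard normal
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_nodes)
    nodes = gh_x * np.sqrt(2.0)
    log_pi = np.log(gh_w / np.sqrt(np.pi))

    b_hat = np.zeros(n_items)
    totals = responses.sum(axis=0)
    flagged = (totals == 0) | (totals == N)
    b_hat[totals == 0] = boundary
    b_hat[totals == N] = -boundary

    for p in range(pool.P):
        cols = np.where((dim_of_item == p) & ~flagged)[0]
        if cols.size == 0:
            continue
        U = responses[:, cols]
        a_p = a_scalar[cols]
        b_p = np.zeros(cols.size)
        for _ in range(max_iter):
            lin = a_p[None, :] * (nodes[:, None] - b_p[None, :])  # (nq, nI)
            s = expit(np.clip(lin, -EXPONENT_CLIP, EXPONENT_CLIP))
            log_s = np.log(s)
            log_q = np.log1p(-s)
            # posterior weights over nodes per person
            ll = U @ log_s.T + (1.0 - U) @ log_q.T + log_pi[None, :]
            W = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
            n_q = W.sum(axis=0)  # (nq,)
            r_qi = W.T @ U  # (nq, nI)
            # M-step: a few Newton steps per item (vectorised)
            b_new = b_p.copy()
            for _ in range(4):
                lin = a_p[None, :] * (nodes[:, None] - b_new[None, :])
                s = expit(np.clip(lin, -EXPONENT_CLIP, EXPONENT_CLIP))
                f = (r_qi - n_q[:, None] * s).sum(axis=0) * a_p
                fp = (n_q[:, None] * s * (1.0 - s)).sum(axis=0) * a_p**2
                b_new = b_new - f / np.maximum(fp, 1e-10)
            delta = np.max(np.abs(b_new - b_p))
            b_p = b_new
            if delta < tol:
                break
        b_hat[cols] = b_p
    return b_hat, flagged
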