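"""Adaptive testlet administration: D-optimal and random selection.

The engine administers whole testlets.  Under the D-optimality rule the next
testlet maximises

    det( Phi_v^{-1} + I_v(theta_hat, gamma_hat) + I_v(theta_hat, candidate) )

over the not-yet-administered testlets, where ``Phi_v`` is the prior
covariance expanded by one effect dimension per answered testlet, the middle
term is the accumulated information of the answered items, and the candidate
term is the testlet information at effect zero (ability block only — a
candidate's effect dimension is not yet instantiated).  Because the
candidate touches only the ability block, the determinant factorises as

    det(M) * det(I_P + Delta G),   G = (M^{-1})[:P, :P],

with ``M`` the candidate-free sum and ``Delta`` the candidate's ability
information; the engine scores candidates through this identity, which is
a strictly monotone transform of the raw determinant (the ``det(M)`` factor
and the logarithm do not reorder candidates).

Provisional ``(theta, gamma)`` estimates are refreshed by Bayes modal
scoring after each testlet; the known generating testlet-effect variances
populate the expanding prior (the usual known-item-parameter assumption of
operational adaptive testing).  The random (RAN) baseline draws whole
testlets uniformly without replacement and re-estimates on the same
schedule, so its records are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .estimation import ResponseSet, _bayes_modal_arrays
from .information import ExpandedPrior, ability_info_weights, expand_prior
from .model import ItemPool, response_probability

__all__ = [
    "CATConfig",
    "PersonState",
    "AdministrationRecord",
    "select_next_testlet_mat",
    "select_next_testlet_ran",
    "administer",
    "build_response_set",
]


@dataclass
class CATConfig:
    """Settings of one adaptive administration.

    ``max_items`` must be a multiple of the (uniform) testlet size; a pool
    whose testlets cannot fill the test length exactly is rejected rather
    than truncated.
    """

    max_items: int = 54
    selection: Literal["MAT", "RAN"] = "MAT"
    model: Literal["MTIRT", "MIRT"] = "MTIRT"
    info_mode: Literal["sum", "mean"] = "sum"
    estimator_tol: float = 1e-4
    estimator_max_iter: int = 100

    def __post_init__(self) -> None:
        if self.max_items <= 0:
            raise ValueError("max_items must be positive")
        if self.selection not in ("MAT", "RAN"):
            raise ValueError(f"unknown selection rule {self.selection!r}")
        if self.model not in ("MTIRT", "MIRT"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class PersonState:
    """Mutable per-person trajectory during an adaptive test."""

    pool: ItemPool
    prior: ExpandedPrior
    theta_hat: np.ndarray
    gamma_hat: np.ndarray
    administered: list[str] = field(default_factory=list)
    item_indices: list[int] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)
    # parallel arrays of answered items for fast re-estimation
    _A: list[np.ndarray] = field(default_factory=list)
    _b: list[float] = field(default_factory=list)
    _c: list[float] = field(default_factory=list)
    _slot: list[int] = field(default_factory=list)

    @property
    def n_answered(self) -> int:
        return len(self.responses)

    def remaining_testlets(self) -> list[str]:
        given = set(self.administered)
        return [tid for tid in self.pool.testlet_ids if tid not in given]


@dataclass
class AdministrationRecord:
    """Complete trajectory of one simulated adaptive test."""

    person_id: str
    testlets: list[str]
    item_indices: list[int]
    responses: list[int]
    provisional_theta: list[np.ndarray]
    provisional_gamma: list[np.ndarray]
    theta_hat: np.ndarray
    gamma_hat: np.ndarray
    estimation_flags: list[str] = field(default_factory=list)


def _accumulated_matrix(state: PersonState) -> np.ndarray:
    """``Phi_v^{-1} + I_v`` of the answered items at the provisional estimates."""
    precision = state.prior.precision()
    if not state._A:
        return precision
    A = np.asarray(state._A)
    b = np.asarray(state._b)
    c = np.asarray(state._c)
    slot = np.asarray(state._slot, dtype=np.intp)
    P_dim = state.pool.P
    v = state.prior.v
    gam = state.gamma_hat[slot] if v else np.zeros(len(b))
    w = ability_info_weights(A, b, c, state.theta_hat, gam)
    M = precision.copy()
    M[:P_dim, :P_dim] += (A * w[:, None]).T @ A
    if v:
        S = A.sum(axis=1)
        M[P_dim:, P_dim:][np.arange(v), np.arange(v)] += np.bincount(
            slot, weights=w * S**2, minlength=v
        )
        cross = np.zeros((v, P_dim))
        np.add.at(cross, slot, -((w * S)[:, None] * A))
        M[P_dim:, :P_dim] += cross
        M[:P_dim, P_dim:] += cross.T
    return M


def _all_testlet_infos(state: PersonState, info_mode: str) -> np.ndarray:
    """``(D, P, P)`` ability informations of every pool testlet at effect zero.

    One vectorised pass over the pool: per-item information weights times the
    cached loading outer products, segment-summed by testlet.
    """
    pool = state.pool
    w = ability_info_weights(pool.A, pool.b, pool.c, state.theta_hat, 0.0)
    weighted = pool.loading_outer_products() * w[:, None, None]
    out = np.zeros((pool.n_testlets, pool.P, pool.P))
    np.add.at(out, pool.item_testlet_index, weighted)
    if info_mode == "mean":
        out /= pool.testlet_sizes[:, None, None]
    return out


def select_next_testlet_mat(
    state: PersonState, info_mode: str = "sum"
) -> tuple[str, np.ndarray]:
    """D-optimal choice among the remaining testlets.

    Returns the selected testlet id and the log scores of all pool testlets
    (``log det(I_P + Delta G)``; the shared ``log det(M)`` offset is omitted
    since it does not affect the ranking; administered testlets and
    candidates whose score cannot be evaluated sit at ``-inf``).  Ties break
    to the candidate earliest in pool order, i.e. the lowest testlet id for
    the generated difficulty-ranked pools.
    """
    pool = state.pool
    if len(state.administered) >= pool.n_testlets:
        raise ValueError("no candidate testlets remain")
    P_dim = pool.P
    M = _accumulated_matrix(state)
    try:
        G = np.linalg.inv(M)[:P_dim, :P_dim]
    except np.linalg.LinAlgError as err:  # structurally PD; defensive
        raise np.linalg.LinAlgError(f"accumulated matrix is singular: {err}") from err
    deltas = _all_testlet_infos(state, info_mode)
    inner = np.eye(P_dim)[None, :, :] + deltas @ G
    sign, logdet = np.linalg.slogdet(inner)
    scores = np.where(sign > 0, logdet, -np.inf)
    tpos = {tid: k for k, tid in enumerate(pool.testlet_ids)}
    for tid in state.administered:
        scores[tpos[tid]] = -np.inf
    best = int(np.argmax(scores))  # argmax takes the first maximum: lowest id
    return pool.testlet_ids[best], scores


def select_next_testlet_ran(
    state: PersonState, rng: np.random.Generator
) -> str:
    """Uniform draw (without replacement) among the remaining testlets."""
    candidates = state.remaining_testlets()
    if not candidates:
        raise ValueError("testlet pool exhausted")
    return candidates[int(rng.integers(len(candidates)))]


def _reestimate(state: PersonState, config: CATConfig) -> bool:
    """Refresh provisional estimates by Bayes modal; returns convergence flag."""
    P_dim = state.pool.P
    v = state.prior.v
    x0 = np.concatenate([state.theta_hat, state.gamma_hat])
    if x0.shape[0] < P_dim + v:  # a testlet was just added: warm-start its gamma at 0
        x0 = np.concatenate([x0, np.zeros(P_dim + v - x0.shape[0])])
    x, converged, _ = _bayes_modal_arrays(
        np.asarray(state._A),
        np.asarray(state._b),
        np.asarray(state._c),
        np.asarray(state._slot, dtype=np.intp),
        np.asarray(state.responses, dtype=float),
        state.prior.precision(),
        x0,
        config.estimator_tol,
        config.estimator_max_iter,
    )
    state.theta_hat = x[:P_dim]
    state.gamma_hat = x[P_dim:]
    return converged


def administer(
    person_truth: tuple[np.ndarray, Mapping[str, float]],
    pool: ItemPool,
    config: CATConfig,
    prior_phi: np.ndarray,
    testlet_variances: Mapping[str, float],
    rng: np.random.Generator,
    person_id: str = "p0",
    response_pool: ItemPool | None = None,
) -> AdministrationRecord:
    """Simulate one adaptive (or random) test for one person.

    Parameters
    ----------
    person_truth
        ``(theta_true, gamma_true)`` — the generating ability vector and a
        testlet-id -> effect mapping used to draw responses.  Responses are
        always generated under the testlet model; ``config.model`` only
        controls the scoring/selection model.
    prior_phi
        Ability covariance used as prior information (known from
        calibration).
    testlet_variances
        Generating testlet-effect variances, used to expand the prior as
        testlets are answered (ignored under the MIRT scoring model).
    rng
        Drives the first (random) testlet, the RAN selections and the
        response draws; seeded runs are bit-reproducible.
    response_pool
        Item parameters used to draw the responses, when they differ from
        the scoring pool ``pool`` — e.g. scoring a misspecified model with
        shrinkage-rescaled difficulties while the data keep the generating
        ones.  Must list the same items in the same order; defaults to
        ``pool``.
    """
    theta_true, gamma_true = person_truth
    if response_pool is None:
        response_pool = pool
    elif len(response_pool) != len(pool) or response_pool.item_ids != pool.item_ids:
        raise ValueError("response_pool must list the same items as the scoring pool")
    sizes = {pool.testlet_size(tid) for tid in pool.testlet_ids}
    if len(sizes) == 1:
        (size,) = sizes
        if config.max_items % size != 0:
            raise ValueError(
                f"max_items={config.max_items} is not a multiple of the testlet "
                f"size {size}; truncating a testlet is not supported"
            )
    use_gamma = config.model == "MTIRT"
    state = PersonState(
        pool=pool,
        prior=expand_prior(prior_phi),
        theta_hat=np.zeros(pool.P),
        gamma_hat=np.zeros(0),
    )
    record = AdministrationRecord(
        person_id=person_id,
        testlets=[],
        item_indices=[],
        responses=[],
        provisional_theta=[],
        provisional_gamma=[],
        theta_hat=np.zeros(pool.P),
        gamma_hat=np.zeros(0),
    )
    while state.n_answered < config.max_items:
        if not state.administered:
            tid = select_next_testlet_ran(state, rng)
        elif config.selection == "MAT":
            tid, _ = select_next_testlet_mat(state, config.info_mode)
        else:
            tid = select_next_testlet_ran(state, rng)
        ix = pool.testlet_members[tid]
        if state.n_answered + ix.size > config.max_items:
            raise ValueError(
                f"testlet {tid!r} ({ix.size} items) would exceed max_items="
                f"{config.max_items}"
            )
        gamma_d = gamma_true.get(tid, 0.0)
        probs = response_probability(
            response_pool.A[ix], response_pool.b[ix], response_pool.c[ix],
            theta_true, gamma_d,
        )
        u = (rng.random(ix.size) < probs).astype(int)

        slot = len(state.administered) if use_gamma else -1
        state.administered.append(tid)
        state.item_indices.extend(int(i) for i in ix)
        state.responses.extend(int(r) for r in u)
        for i in ix:
            state._A.append(pool.A[i])
            state._b.append(float(pool.b[i]))
            state._c.append(float(pool.c[i]))
            state._slot.append(slot)
        if use_gamma:
            state.prior = state.prior.expanded(testlet_variances[tid])
        converged = _reestimate(state, config)
        if not converged:
            record.estimation_flags.append(
                f"non-convergence after testlet {tid!r} (kept last iterate)"
            )
        record.testlets.append(tid)
        record.item_indices.extend(int(i) for i in ix)
        record.responses.extend(int(r) for r in u)
        record.provisional_theta.append(state.theta_hat.copy())
        record.provisional_gamma.append(state.gamma_hat.copy())
    record.theta_hat = state.theta_hat.copy()
    record.gamma_hat = state.gamma_hat.copy()
    return record


def build_response_set(
    records: Sequence[AdministrationRecord], pool: ItemPool
) -> ResponseSet:
    """Stack per-person administration records into a :class:`ResponseSet`.

    All records must contain the same number of items and testlets (the
    fixed-length design of the study); item order within a record follows
    the administration order, so items of one testlet are contiguous.
    """
    if not records:
        raise ValueError("no records given")
    L = len(records[0].responses)
    n_slots = len(records[0].testlets)
    for rec in records:
        if len(rec.responses) != L or len(rec.testlets) != n_slots:
            raise ValueError("records differ in length; cannot stack")
    tindex = {tid: k for k, tid in enumerate(pool.testlet_ids)}
    N = len(records)
    item_idx = np.empty((N, L), dtype=np.intp)
    responses = np.empty((N, L), dtype=float)
    slot = np.empty((N, L), dtype=np.intp)
    person_testlets = np.empty((N, n_slots), dtype=np.intp)
    for j, rec in enumerate(records):
        item_idx[j] = rec.item_indices
        responses[j] = rec.responses
        person_testlets[j] = [tindex[tid] for tid in rec.testlets]
        pos = 0
        for m, tid in enumerate(rec.testlets):
            z = pool.testlet_size(tid)
            slot[j, pos : pos + z] = m
            pos += z
    return ResponseSet(pool, item_idx, responses, slot, person_testlets)
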