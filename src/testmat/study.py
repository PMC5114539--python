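"""Synthetic data generation and the Monte-Carlo study driver.

The study emulates a three-dimensional large-scale assessment: abilities are
multivariate normal with unit variances and latent correlations of 0.80;
the pool holds 324 Rasch items (108 per dimension, simple structure) with
difficulties uniform on (-4, 4); items are grouped into testlets of a fixed
size by their difficulty rank within a dimension, so testlet-mates are
homogeneous in difficulty and share a dimension.  Testlet effects are
i.i.d. normal with a condition-specific variance in {0, 0.5, 1.0, 1.5}.

The full factorial design crosses testlet-effect variance, testlet size
(3/6/9), scoring model (testlet model vs. plain MIRT with shrinkage-rescaled
difficulties) and selection algorithm (D-optimal adaptive vs. random).  Each
cell administers 54 items per person, final-scales the collected responses
by MCMC and summarises ability recovery by the dimension-averaged mean
squared error and testlet-effect-variance recovery by posterior means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import AdministrationRecord, CATConfig, administer, build_response_set
from .estimation import (
    ChainConfig,
    EAPResult,
    PriorSpec,
    mcmc_scale,
    mml_calibrate_difficulties,
)
from .model import Item, ItemPool, response_probability

__all__ = [
    "STUDY_PHI",
    "GeneratedPool",
    "ConditionSpec",
    "ConditionResult",
    "study_phi",
    "generate_abilities",
    "generate_pool",
    "generate_testlet_effects",
    "simulate_responses",
    "rescale_difficulties",
    "compute_shrinkage",
    "shrinkage_closed_form",
    "compute_mse",
    "run_condition",
    "run_study",
]

#: generating ability covariance: unit variances, latent correlations 0.80
STUDY_PHI = np.array(
    [
        [1.00, 0.80, 0.80],
        [0.80, 1.00, 0.80],
        [0.80, 0.80, 1.00],
    ]
)


def study_phi() -> np.ndarray:
    """A fresh copy of the generating ability covariance matrix."""
    return STUDY_PHI.copy()


def generate_abilities(
    N: int, Phi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``N`` ability vectors from ``MVN(0, Phi)``."""
    Phi = np.asarray(Phi, dtype=float)
    try:
        L = np.linalg.cholesky(Phi)
    except np.linalg.LinAlgError as err:
        raise ValueError("ability covariance must be positive definite") from err
    return rng.standard_normal((N, Phi.shape[0])) @ L.T


@dataclass(frozen=True)
class GeneratedPool:
    """Item parameters of the study pool, partitionable into testlet sizes.

    ``difficulties[p]`` holds the 108 difficulties of dimension ``p``; the
    same draws are reused for every testlet size so that conditions differ
    only in the partition.
    """

    difficulties: np.ndarray  # (P, n_per_dim)

    @property
    def P(self) -> int:
        return self.difficulties.shape[0]

    def pool(self, testlet_size: int) -> ItemPool:
        """Partition into testlets of ``testlet_size`` by difficulty rank.

        Within each dimension items are sorted by difficulty and chunked
        into consecutive groups, so a testlet's difficulty range is disjoint
        from the next and all its items load on the same dimension.  Item
        and testlet ids are zero-padded, making pool order and id order
        coincide.
        """
        P, n_per_dim = self.difficulties.shape
        if n_per_dim % testlet_size != 0:
            raise ValueError(
                f"{n_per_dim} items per dimension cannot form testlets of "
                f"size {testlet_size}"
            )
        items: list[Item] = []
        for p in range(P):
            order = np.argsort(self.difficulties[p], kind="stable")
            a = np.zeros(P)
            a[p] = 1.0
            for rank, idx in enumerate(order):
                t = rank // testlet_size
                items.append(
                    Item(
                        id=f"d{p + 1}_i{idx + 1:03d}",
                        a=a.copy(),
                        b=float(self.difficulties[p, idx]),
                        c=0.0,
                        testlet_id=f"d{p + 1}_t{t + 1:02d}",
                    )
                )
        return ItemPool(items)


def generate_pool(
    rng: np.random.Generator,
    n_per_dim: int = 108,
    P: int = 3,
    b_range: tuple[float, float] = (-4.0, 4.0),
) -> GeneratedPool:
    """Draw the study pool: ``n_per_dim`` Rasch items per dimension, b ~ U(b_range)."""
    lo, hi = b_range
    return GeneratedPool(rng.uniform(lo, hi, size=(P, n_per_dim)))


def generate_testlet_effects(
    N: int, D: int, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. ``N(0, sigma2)`` testlet effects for ``N`` persons and ``D`` testlets."""
    if sigma2 < 0:
        raise ValueError("testlet effect variance must be non-negative")
    if sigma2 == 0:
        return np.zeros((N, D))
    return rng.normal(0.0, np.sqrt(sigma2), size=(N, D))


def simulate_responses(
    theta: np.ndarray,
    gamma: np.ndarray,
    pool: ItemPool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli responses of all persons to all pool items under the testlet model.

    ``gamma`` has one column per pool testlet in ``pool.testlet_ids`` order;
    pass zeros to generate under plain MIRT.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    if theta.shape[1] != pool.P:
        raise ValueError("ability dimension does not match pool")
    if gamma.shape[1] != pool.n_testlets:
        raise ValueError("gamma must have one column per pool testlet")
    tindex = {tid: k for k, tid in enumerate(pool.testlet_ids)}
    item_testlet = np.array([tindex[it.testlet_id] for it in pool.items], dtype=np.intp)
    probs = response_probability(
        pool.A, pool.b, pool.c, theta, gamma[:, item_testlet]
    )
    return (rng.random(probs.shape) < probs).astype(np.int8)


# ---------------------------------------------------------------------------
# shrinkage rescaling
# ---------------------------------------------------------------------------

def shrinkage_closed_form(sigma2: float, logistic_constant: float = 1.7) -> float:
    """Closed-form attenuation factor ``(1 + sigma2 / 1.7^2)^(-1/2)``.

    Marginalising a logistic item response over a normal nuisance effect is
    approximately another logistic with its scale attenuated by this factor
    (the classical logit-probit bridge).  Serves as an independent check on
    the simulation-based factors.
    """
    return float((1.0 + sigma2 / logistic_constant**2) ** -0.5)


def compute_shrinkage(
    pool: ItemPool,
    sigma2: float,
    N: int,
    rng: np.random.Generator,
    Phi: np.ndarray | None = None,
    return_difficulties: bool = False,
):
    """Scaling factor turning testlet-model difficulties into MIRT difficulties.

    Generates a full response matrix under the testlet model, re-calibrates
    difficulties under plain MIRT by MML, and regresses the calibrated
    difficulties on the generating ones (OLS with intercept, pooling all
    items).  The slope is the factor: multiplying the generating
    difficulties by it yields difficulties correct under the MIRT model.
    """
    Phi = STUDY_PHI if Phi is None else np.asarray(Phi)
    theta = generate_abilities(N, Phi, rng)
    gamma = generate_testlet_effects(N, pool.n_testlets, sigma2, rng)
    responses = simulate_responses(theta, gamma, pool, rng)
    b_hat, flagged = mml_calibrate_difficulties(responses, pool)
    if flagged.any():
        raise RuntimeError(
            f"{int(flagged.sum())} items had degenerate (all-0/all-1) responses; "
            "increase N"
        )
    slope, _intercept = np.polyfit(pool.b, b_hat, 1)
    if return_difficulties:
        return float(slope), b_hat
    return float(slope)


def rescale_difficulties(pool: ItemPool, factor: float) -> ItemPool:
    """Pool with every difficulty multiplied by the shrinkage factor."""
    items = [replace(it, b=it.b * factor) for it in pool.items]
    return ItemPool(items)


def compute_mse(
    theta_hat: np.ndarray, theta_true: np.ndarray
) -> tuple[float, np.ndarray]:
    """Dimension-averaged mean squared error of ability estimates.

    ``MSE = (1/P) sum_p (1/N) sum_j (theta_hat_jp - theta_jp)^2``; returns
    the average and the per-dimension values.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float)
    if theta_hat.shape != theta_true.shape:
        raise ValueError(
            f"shape mismatch: {theta_hat.shape} vs {theta_true.shape}"
        )
    per_dim = np.mean((theta_hat - theta_true) ** 2, axis=0)
    return float(per_dim.mean()), per_dim


# ---------------------------------------------------------------------------
# condition runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the factorial design."""

    sigma2_gamma: float
    testlet_size: int
    model: Literal["MTIRT", "MIRT"] = "MTIRT"
    algorithm: Literal["MAT", "RAN"] = "MAT"
    n_persons: int = 5000
    replications: int = 10
    max_items: int = 54

    def __post_init__(self) -> None:
        if self.sigma2_gamma < 0:
            raise ValueError("testlet effect variance must be non-negative")
        if self.n_persons < 1 or self.replications < 1:
            raise ValueError("n_persons and replications must be at least 1")

    def label(self) -> str:
        return (
            f"{self.algorithm}-{self.model} size={self.testlet_size} "
            f"sigma2={self.sigma2_gamma}"
        )


@dataclass
class ReplicationResult:
    """Raw outcome of one replication of one condition."""

    mse: float
    mse_per_dim: np.ndarray
    mean_sigma2: float | None
    eap: EAPResult
    theta_true: np.ndarray
    records: list[AdministrationRecord]
    converged: bool
    n_flagged_persons: int


@dataclass
class ConditionResult:
    """Across-replication summary of one design cell."""

    spec: ConditionSpec
    mse_mean: float
    mse_se: float
    sigma2_mean: float | None
    sigma2_se: float | None
    shrinkage_factor: float
    replications: list[ReplicationResult] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "size": self.spec.testlet_size,
            "sigma2": self.spec.sigma2_gamma,
            "model": self.spec.model,
            "algorithm": self.spec.algorithm,
            "mse": self.mse_mean,
            "mse_se": self.mse_se,
            "var_hat": self.sigma2_mean,
            "var_hat_se": self.sigma2_se,
            "shrinkage_factor": self.shrinkage_factor,
            "n_reps": len(self.replications),
        }


def _se_across(values: Sequence[float]) -> float:
    vals = np.asarray(values, dtype=float)
    return float(vals.std(ddof=1)) if vals.size > 1 else 0.0


def run_condition(
    spec: ConditionSpec,
    generated_pool: GeneratedPool,
    seed_seq: np.random.SeedSequence,
    prior_spec: PriorSpec | None = None,
    chain: ChainConfig | None = None,
    shrinkage_n: int = 5000,
    shrinkage_factor: float | None = None,
    min_exposure: int = 20,
    keep_records: bool = False,
) -> ConditionResult:
    """Run all replications of one design cell.

    Responses are always generated under the testlet model.  In MIRT cells
    the scoring pool carries shrinkage-rescaled difficulties (the factor is
    computed by :func:`compute_shrinkage` at ``shrinkage_n`` persons unless
    supplied) and the final scaling drops the testlet machinery.  A
    replication whose final scaling fails outright is excluded with a count;
    per-person modal non-convergence is only flagged.
    """
    prior_spec = prior_spec or PriorSpec()
    chain = chain or ChainConfig()
    pool = generated_pool.pool(spec.testlet_size)
    shrink_seq, *rep_seqs = seed_seq.spawn(spec.replications + 1)

    if spec.model == "MIRT":
        if shrinkage_factor is None:
            shrinkage_factor = (
                1.0
                if spec.sigma2_gamma == 0.0
                else compute_shrinkage(
                    pool, spec.sigma2_gamma, shrinkage_n, np.random.default_rng(shrink_seq)
                )
            )
        scoring_pool = rescale_difficulties(pool, shrinkage_factor)
    else:
        shrinkage_factor = 1.0
        scoring_pool = pool

    true_variances = {tid: spec.sigma2_gamma for tid in pool.testlet_ids}
    config = CATConfig(
        max_items=spec.max_items, selection=spec.algorithm, model=spec.model
    )
    reps: list[ReplicationResult] = []
    for rep_seq in rep_seqs:
        rng = np.random.default_rng(rep_seq)
        theta_true = generate_abilities(spec.n_persons, STUDY_PHI, rng)
        gamma_true = generate_testlet_effects(
            spec.n_persons, pool.n_testlets, spec.sigma2_gamma, rng
        )
        records = []
        n_flagged = 0
        for j in range(spec.n_persons):
            gmap = dict(zip(pool.testlet_ids, gamma_true[j]))
            rec = administer(
                (theta_true[j], gmap),
                scoring_pool,
                config,
                STUDY_PHI,
                true_variances,
                rng,
                person_id=f"p{j}",
                response_pool=pool,
            )
            if rec.estimation_flags:
                n_flagged += 1
            records.append(rec)
        data = build_response_set(records, scoring_pool)
        eap, report = mcmc_scale(
            data, prior_spec, chain, model=spec.model, rng=rng
        )
        mse, per_dim = compute_mse(eap.theta, theta_true)
        mean_s2 = (
            eap.mean_sigma2(min_exposure) if spec.model == "MTIRT" else None
        )
        reps.append(
            ReplicationResult(
                mse=mse,
                mse_per_dim=per_dim,
                mean_sigma2=mean_s2,
                eap=eap,
                theta_true=theta_true,
                records=records if keep_records else [],
                converged=report.passed,
                n_flagged_persons=n_flagged,
            )
        )
    mses = [r.mse for r in reps]
    s2s = [r.mean_sigma2 for r in reps if r.mean_sigma2 is not None]
    return ConditionResult(
        spec=spec,
        mse_mean=float(np.mean(mses)),
        mse_se=_se_across(mses),
        sigma2_mean=float(np.mean(s2s)) if s2s else None,
        sigma2_se=_se_across(s2s) if s2s else None,
        shrinkage_factor=shrinkage_factor,
        replications=reps,
    )


def run_study(
    conditions: Sequence[ConditionSpec],
    seed: int,
    prior_spec: PriorSpec | None = None,
    chain: ChainConfig | None = None,
    shrinkage_n: int = 5000,
    shrinkage_factors: Mapping[tuple[int, float], float] | None = None,
    min_exposure: int = 20,
) -> tuple[pd.DataFrame, list[ConditionResult]]:
    """Run a set of design cells from one root seed.

    A single pool is generated once and shared by every condition; each
    condition and replication receives a deterministic child stream of the
    root seed, so the result table is reproducible bit for bit.
    ``shrinkage_factors`` may pre-supply factors keyed by
    ``(testlet_size, sigma2)`` to avoid re-calibration.

    Returns a tidy summary DataFrame (one row per cell) plus the full
    per-condition results.
    """
    root = np.random.SeedSequence(seed)
    pool_seq, cond_root = root.spawn(2)
    generated_pool = generate_pool(np.random.default_rng(pool_seq))
    cond_seqs = cond_root.spawn(len(conditions))
    results = []
    for spec, cseq in zip(conditions, cond_seqs):
        factor = None
        if shrinkage_factors is not None:
            factor = shrinkage_factors.get((spec.testlet_size, spec.sigma2_gamma))
        results.append(
            run_condition(
                spec,
                generated_pool,
                cseq,
                prior_spec=prior_spec,
                chain=chain,
                shrinkage_n=shrinkage_n,
                shrinkage_factor=factor,
                min_exposure=min_exposure,
            )
        )
    table = pd.DataFrame([r.as_row() for r in results])
    return table, results
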