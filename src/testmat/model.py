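"""Multidimensional random-effects testlet IRT model (MTIRT).

The response model is a multidimensional 3PL in which every item belongs to
exactly one testlet (a set of items sharing a stimulus) and each person
carries one scalar random effect per testlet.  For person ability vector
``theta`` (length ``P``), item loading vector ``a``, difficulty ``b``,
pseudo-guessing ``c`` and testlet effect ``gamma``::

    P(U = 1) = c + (1 - c) * logistic(a' (theta - b*1 - gamma*1))

i.e. the difficulty and the testlet effect enter every dimension the item
loads on, so the exponent reduces to ``a'theta - (b + gamma) * sum(a)``.
Setting every ``gamma`` to zero recovers the ordinary multidimensional 3PL
(MIRT); additionally restricting loadings to 0/1 and ``c = 0`` gives the
multidimensional Rasch testlet model used in the simulation study.

The testlet effects model local item dependence (LID): residual correlation
between items of one testlet after conditioning on ability.  Their variance
``sigma^2_gamma`` per testlet indexes the severity of the dependence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "Item",
    "ItemPool",
    "prob_mtirt",
    "prob_mirt",
    "grad_log_likelihood",
    "response_probability",
    "linear_predictor",
    "read_pool",
    "write_pool",
]

#: exponent arguments are clipped here before exponentiation; keeps the
#: probability strictly inside (c, 1) and monotone at extreme abilities
EXPONENT_CLIP = 35.0


def _clipped_logistic(x: np.ndarray | float) -> np.ndarray | float:
    return expit(np.clip(x, -EXPONENT_CLIP, EXPONENT_CLIP))


@dataclass(frozen=True)
class Item:
    """One binary item: loading vector, difficulty, guessing, testlet membership."""

    id: str
    a: np.ndarray
    b: float
    c: float = 0.0
    testlet_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "a", a)
        if a.ndim != 1:
            raise ValueError("loading vector a must be one-dimensional")
        if not (0.0 <= self.c < 1.0):
            raise ValueError(f"pseudo-guessing c must lie in [0, 1), got {self.c}")
        if not np.any(a != 0.0):
            warnings.warn(
                f"item {self.id!r} has an all-zero loading vector; its response "
                "probability is constant at c + (1 - c)/2",
                stacklevel=2,
            )

    @property
    def n_dim(self) -> int:
        return self.a.shape[0]


class ItemPool:
    """An ordered collection of items partitioned into testlets.

    Internally stores parameters as dense arrays (``A`` of shape ``(n, P)``,
    ``b``, ``c`` of shape ``(n,)``) so that the adaptive engine and the
    samplers can evaluate all items at once.

    Parameters
    ----------
    items
        Items with loading vectors of a common length ``P``.  Each item must
        name a testlet; testlets partition the pool (mutually exclusive and
        exhaustive, no empty testlets by construction).
    """

    def __init__(self, items: Sequence[Item]):
        if len(items) == 0:
            raise ValueError("item pool must contain at least one item")
        P = items[0].n_dim
        for it in items:
            if it.n_dim != P:
                raise ValueError(
                    f"item {it.id!r} has {it.n_dim} loading entries, expected {P}"
                )
            if it.testlet_id == "":
                raise ValueError(f"item {it.id!r} does not reference a testlet")
        self.items: tuple[Item, ...] = tuple(items)
        self.P: int = P
        self.A: np.ndarray = np.array([it.a for it in items], dtype=float)
        self.b: np.ndarray = np.array([it.b for it in items], dtype=float)
        self.c: np.ndarray = np.array([it.c for it in items], dtype=float)
        self.item_ids: list[str] = [it.id for it in items]
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate item ids in pool")
        # testlets in first-appearance order
        self.testlet_ids: list[str] = []
        members: dict[str, list[int]] = {}
        for idx, it in enumerate(items):
            if it.testlet_id not in members:
                members[it.testlet_id] = []
                self.testlet_ids.append(it.testlet_id)
            members[it.testlet_id].append(idx)
        self.testlet_members: dict[str, np.ndarray] = {
            tid: np.asarray(ix, dtype=np.intp) for tid, ix in members.items()
        }
        self._item_index = {iid: i for i, iid in enumerate(self.item_ids)}
        tpos = {tid: k for k, tid in enumerate(self.testlet_ids)}
        self.item_testlet_index: np.ndarray = np.array(
            [tpos[it.testlet_id] for it in items], dtype=np.intp
        )
        self.testlet_sizes: np.ndarray = np.array(
            [self.testlet_members[tid].size for tid in self.testlet_ids], dtype=np.intp
        )
        self._outer_cache: np.ndarray | None = None

    def loading_outer_products(self) -> np.ndarray:
        """Cached per-item ``a a'`` outer products, shape ``(n, P, P)``."""
        if self._outer_cache is None:
            self._outer_cache = self.A[:, :, None] * self.A[:, None, :]
        return self._outer_cache

    def __len__(self) -> int:
        return len(self.items)

    @property
    def n_testlets(self) -> int:
        return len(self.testlet_ids)

    def item_index(self, item_id: str) -> int:
        return self._item_index[item_id]

    def testlet_size(self, testlet_id: str) -> int:
        return int(self.testlet_members[testlet_id].size)

    def to_frame(self) -> pd.DataFrame:
        cols = {"id": self.item_ids}
        for p in range(self.P):
            cols[f"a_{p + 1}"] = self.A[:, p]
        cols["b"] = self.b
        cols["c"] = self.c
        cols["testlet_id"] = [it.testlet_id for it in self.items]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemPool":
        a_cols = sorted(
            (c for c in df.columns if c.startswith("a_")),
            key=lambda c: int(c.split("_")[1]),
        )
        required = {"id", "b", "c", "testlet_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"pool table is missing columns: {sorted(missing)}")
        if not a_cols:
            raise ValueError("pool table has no loading columns a_1..a_P")
        expected = [f"a_{p + 1}" for p in range(len(a_cols))]
        if a_cols != expected:
            raise ValueError(f"loading columns must be contiguous a_1..a_P, got {a_cols}")
        items = [
            Item(
                id=str(row["id"]),
                a=np.array([row[c] for c in a_cols], dtype=float),
                b=float(row["b"]),
                c=float(row["c"]),
                testlet_id=str(row["testlet_id"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(items)


def read_pool(path: str | Path) -> ItemPool:
    """Read an item pool from CSV or JSON (schema: id, a_1..a_P, b, c, testlet_id)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path)
    return ItemPool.from_frame(df)


def write_pool(pool: ItemPool, path: str | Path) -> None:
    path = Path(path)
    df = pool.to_frame()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# array kernels (used throughout the engine and the samplers)
# ---------------------------------------------------------------------------

def linear_predictor(
    A: np.ndarray, b: np.ndarray, theta: np.ndarray, gamma: np.ndarray | float = 0.0
) -> np.ndarray:
    """Exponent ``a'(theta - b*1 - gamma*1) = a'theta - (b + gamma) * sum(a)``.

    ``A`` is ``(n, P)``; ``theta`` is ``(P,)`` or ``(..., P)``; ``b`` and
    ``gamma`` broadcast against the leading item axis.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    row_sum = A.sum(axis=1)
    return np.asarray(theta, dtype=float) @ A.T - (np.asarray(b) + gamma) * row_sum


def response_probability(
    A: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    theta: np.ndarray,
    gamma: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Vectorised MTIRT correct-response probability for a block of items."""
    x = linear_predictor(A, b, theta, gamma)
    return np.asarray(c) + (1.0 - np.asarray(c)) * _clipped_logistic(x)


def prob_mtirt(theta: np.ndarray, item: Item, gamma_d: float = 0.0) -> float:
    """Correct-response probability under the testlet model for one item.

    With ``gamma_d = 0`` this is exactly the multidimensional 3PL probability.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (item.n_dim,):
        raise ValueError(
            f"ability vector has shape {theta.shape}, item expects ({item.n_dim},)"
        )
    p = response_probability(item.a[None, :], item.b, item.c, theta, gamma_d)
    return float(p[0] if p.ndim else p)


def prob_mirt(theta: np.ndarray, item: Item) -> float:
    """Multidimensional 3PL probability: the testlet model with its effect at zero."""
    return prob_mtirt(theta, item, 0.0)


def _prob_and_slope(
    A: np.ndarray, b: np.ndarray, c: np.ndarray, theta: np.ndarray, gamma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``P`` and the logistic slope ``(1 - c) * s * (1 - s)`` per item."""
    x = linear_predictor(A, b, theta, gamma)
    s = _clipped_logistic(x)
    c = np.asarray(c)
    return c + (1.0 - c) * s, (1.0 - c) * s * (1.0 - s)


def grad_log_likelihood(
    theta: np.ndarray,
    gamma: Mapping[str, float],
    items: Sequence[Item],
    responses: Sequence[int],
) -> np.ndarray:
    """Gradient of the response log likelihood in the stacked ``(theta, gamma)``.

    The gamma block follows the key order of the ``gamma`` mapping.  Each
    answered item contributes ``(u - P)/(P Q)`` times the derivative of its
    probability; items whose testlet is absent from ``gamma`` are treated as
    having a zero (MIRT) effect.

    Returns a vector of length ``P + len(gamma)``.  With no responses the
    likelihood is flat: a zero vector of length ``P`` is returned.
    """
    theta = np.asarray(theta, dtype=float)
    P_dim = theta.shape[0]
    slots = {tid: m for m, tid in enumerate(gamma)}
    if not items:
        return np.zeros(P_dim)

    A = np.array([it.a for it in items], dtype=float)
    b = np.array([it.b for it in items], dtype=float)
    c = np.array([it.c for it in items], dtype=float)
    g = np.array([gamma.get(it.testlet_id, 0.0) for it in items], dtype=float)
    u = np.asarray(responses, dtype=float)
    if u.shape[0] != len(items):
        raise ValueError("responses and items differ in length")

    prob, slope = _prob_and_slope(A, b, c, theta, g)
    w = (u - prob) / (prob * (1.0 - prob))  # d lnL / dP per item

    grad = np.zeros(P_dim + len(gamma))
    # d P / d theta_r = slope * a_r ; d P / d gamma_m = -slope * sum(a)
    grad[:P_dim] = (w * slope) @ A
    row_sum = A.sum(axis=1)
    for i, it in enumerate(items):
        m = slots.get(it.testlet_id)
        if m is not None:
            grad[P_dim + m] -= w[i] * slope[i] * row_sum[i]
    return grad
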