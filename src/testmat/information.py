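"""Fisher information for abilities and testlet effects, and the expanding prior.

For one item the information contribution in any coordinate pair ``(x, y)`` of
the stacked parameter ``(theta_1..theta_P, gamma_1..gamma_v)`` is

    I_xy = (dP/dx)(dP/dy) / (P * Q),        Q = 1 - P,

the negative expected Hessian of the Bernoulli log likelihood.  Because the
testlet effect enters the exponent as ``-gamma * sum(a)`` while ability ``r``
enters as ``+a_r``, cross entries between a testlet effect and an ability
carry a negative sign for positively loading items; diagonal entries are
always non-negative.  Items of different testlets never share a gamma, so the
testlet block is diagonal.

As testlets are answered, the prior covariance of the ability vector is
expanded by one row/column per testlet (the effect's variance on the
diagonal, zero covariance elsewhere), and the information matrix grows the
same way.  Candidate testlets that have not been answered contribute only to
the ability block, with their effect fixed at its prior expectation of zero —
so candidate information under the testlet model coincides with ordinary
MIRT item information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .model import Item, _prob_and_slope

__all__ = [
    "ExpandedPrior",
    "ability_info_weights",
    "item_info_ability",
    "testlet_block_info",
    "assemble_expanded_info",
    "testlet_information",
    "expand_prior",
]

#: variance floor applied when inverting the expanded prior; keeps the
#: machinery defined in the zero-LID condition where it must mimic MIRT
VARIANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class ExpandedPrior:
    """Prior covariance over ``(theta, gamma_1..gamma_v)`` after ``v`` testlets.

    Block diagonal: the ability covariance ``Phi`` in the upper-left corner
    and the answered testlets' effect variances on the remaining diagonal.
    """

    Phi: np.ndarray
    testlet_variances: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        Phi = np.asarray(self.Phi, dtype=float)
        object.__setattr__(self, "Phi", Phi)
        if Phi.ndim != 2 or Phi.shape[0] != Phi.shape[1]:
            raise ValueError("ability covariance must be square")
        if not np.allclose(Phi, Phi.T, atol=1e-10):
            raise ValueError("ability covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(Phi) <= 0):
            raise ValueError("ability covariance must be positive definite")
        if any(v < 0 for v in self.testlet_variances):
            raise ValueError("testlet effect variances must be non-negative")

    @property
    def P(self) -> int:
        return self.Phi.shape[0]

    @property
    def v(self) -> int:
        return len(self.testlet_variances)

    @property
    def size(self) -> int:
        return self.P + self.v

    def matrix(self) -> np.ndarray:
        """The full ``(P+v) x (P+v)`` block-diagonal covariance."""
        out = np.zeros((self.size, self.size))
        out[: self.P, : self.P] = self.Phi
        if self.v:
            out[self.P :, self.P :] = np.diag(self.testlet_variances)
        return out

    def precision(self) -> np.ndarray:
        """Inverse covariance; zero testlet variances are floored first."""
        out = np.zeros((self.size, self.size))
        out[: self.P, : self.P] = np.linalg.inv(self.Phi)
        for m, var in enumerate(self.testlet_variances):
            out[self.P + m, self.P + m] = 1.0 / max(var, VARIANCE_FLOOR)
        return out

    def expanded(self, variance: float) -> "ExpandedPrior":
        """Prior after answering one more testlet with effect variance ``variance``."""
        return ExpandedPrior(self.Phi, self.testlet_variances + (float(variance),))


def expand_prior(
    Phi: np.ndarray, testlet_variances: Sequence[float] = ()
) -> ExpandedPrior:
    """Build the expanded prior covariance for ``v`` answered testlets."""
    return ExpandedPrior(np.asarray(Phi, dtype=float), tuple(float(v) for v in testlet_variances))


# ---------------------------------------------------------------------------
# information blocks
# ---------------------------------------------------------------------------

def ability_info_weights(
    A: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    theta: np.ndarray,
    gamma: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Per-item scalar ``(dP*/dx)^2 / (P Q)`` so that item info = w * outer(a, a).

    The full ability-block contribution of item ``i`` is ``w_i * a_i a_i'``;
    its gamma-diagonal contribution is ``w_i * sum(a_i)^2`` and the cross
    entry with ability ``r`` is ``-w_i * sum(a_i) * a_ir``.
    """
    prob, slope = _prob_and_slope(
        np.atleast_2d(A), np.asarray(b), np.asarray(c), np.asarray(theta), gamma
    )
    return slope**2 / (prob * (1.0 - prob))


def item_info_ability(theta_hat: np.ndarray, item: Item, gamma_d: float = 0.0) -> np.ndarray:
    """``P x P`` ability information of a single item (rank one)."""
    w = ability_info_weights(item.a[None, :], item.b, item.c, np.asarray(theta_hat), gamma_d)
    return float(w[0]) * np.outer(item.a, item.a)


def testlet_block_info(
    theta_hat: np.ndarray,
    gamma_hat: Mapping[str, float],
    items: Sequence[Item],
    responses_testlets: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Testlet-effect blocks of the information of answered items.

    Returns ``(diag, cross)``: the ``v``-vector of gamma-diagonal entries
    (off-diagonals are exactly zero — distinct testlets share no parameter)
    and the ``v x P`` cross block with the abilities, in the key order of
    ``gamma_hat``.
    """
    slots = {tid: m for m, tid in enumerate(gamma_hat)}
    P_dim = np.asarray(theta_hat).shape[0]
    diag = np.zeros(len(slots))
    cross = np.zeros((len(slots), P_dim))
    if not items:
        return diag, cross
    for it in items:
        if it.testlet_id not in slots:
            raise ValueError(
                f"item {it.id!r} references testlet {it.testlet_id!r} which has no "
                "gamma entry (testlet not answered)"
            )
    A = np.array([it.a for it in items], dtype=float)
    b = np.array([it.b for it in items], dtype=float)
    c = np.array([it.c for it in items], dtype=float)
    g = np.array([gamma_hat[it.testlet_id] for it in items], dtype=float)
    w = ability_info_weights(A, b, c, np.asarray(theta_hat), g)
    row_sum = A.sum(axis=1)
    for i, it in enumerate(items):
        m = slots[it.testlet_id]
        diag[m] += w[i] * row_sum[i] ** 2
        cross[m, :] -= w[i] * row_sum[i] * A[i, :]
    return diag, cross


def assemble_expanded_info(
    ability_block: np.ndarray,
    testlet_diag: np.ndarray,
    cross_block: np.ndarray,
) -> np.ndarray:
    """Assemble the ``(P+v) x (P+v)`` information from its three blocks.

    The fourth block is the transpose of the cross block.  Raises if the
    result is asymmetric beyond 1e-10 (would indicate an assembly bug).
    """
    ability_block = np.asarray(ability_block, dtype=float)
    testlet_diag = np.asarray(testlet_diag, dtype=float).ravel()
    cross_block = np.atleast_2d(np.asarray(cross_block, dtype=float))
    P_dim = ability_block.shape[0]
    v = testlet_diag.shape[0]
    if v == 0:
        out = ability_block.copy()
    else:
        if cross_block.shape != (v, P_dim):
            raise ValueError(
                f"cross block has shape {cross_block.shape}, expected {(v, P_dim)}"
            )
        out = np.zeros((P_dim + v, P_dim + v))
        out[:P_dim, :P_dim] = ability_block
        out[P_dim:, P_dim:] = np.diag(testlet_diag)
        out[P_dim:, :P_dim] = cross_block
        out[:P_dim, P_dim:] = cross_block.T
    if not np.allclose(out, out.T, atol=1e-10):
        raise AssertionError("assembled information matrix is not symmetric")
    return out


def expanded_information(
    theta_hat: np.ndarray,
    gamma_hat: Mapping[str, float],
    items: Sequence[Item],
) -> np.ndarray:
    """Full information of answered items over ``(theta, gamma)`` coordinates."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    P_dim = theta_hat.shape[0]
    if not items:
        return np.zeros((P_dim + len(gamma_hat), P_dim + len(gamma_hat)))
    A = np.array([it.a for it in items], dtype=float)
    b = np.array([it.b for it in items], dtype=float)
    c = np.array([it.c for it in items], dtype=float)
    g = np.array([gamma_hat.get(it.testlet_id, 0.0) for it in items], dtype=float)
    w = ability_info_weights(A, b, c, theta_hat, g)
    ability = (A * w[:, None]).T @ A
    diag, cross = testlet_block_info(theta_hat, gamma_hat, items)
    return assemble_expanded_info(ability, diag, cross)


def testlet_information(
    theta_hat: np.ndarray,
    candidate_items: Sequence[Item],
    mode: Literal["sum", "mean"] = "sum",
) -> np.ndarray:
    """Ability-block information of a candidate testlet at effect zero.

    Sums (default) or averages the item informations of the testlet's items.
    The mean variant avoids favouring large testlets in pools of mixed size.
    A candidate has no instantiated effect dimension, so only the ability
    block is populated.
    """
    if not candidate_items:
        raise ValueError("candidate testlet is empty")
    A = np.array([it.a for it in candidate_items], dtype=float)
    b = np.array([it.b for it in candidate_items], dtype=float)
    c = np.array([it.c for it in candidate_items], dtype=float)
    w = ability_info_weights(A, b, c, np.asarray(theta_hat), 0.0)
    info = (A * w[:, None]).T @ A
    if mode == "mean":
        info = info / len(candidate_items)
    elif mode != "sum":
        raise ValueError(f"info mode must be 'sum' or 'mean', got {mode!r}")
    return info
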