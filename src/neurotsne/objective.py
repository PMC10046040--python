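"""Neighbor-probability distributions and the KL embedding loss.

t-SNE matches two distributions over ordered pairs of batch examples: a
high-dimensional neighbor distribution P and a low-dimensional Student-t
distribution Q, by minimizing KL(P || Q).

Two constructions of P are provided:

* :func:`rank_neighbor_probs` — the simplified rank-distance distribution
  used with the CNN encoder.  Distances in the encoder's latent space are
  ranked per example; the ``n`` nearest examples share high probability mass
  ``1 - eps`` and all others share the small remainder ``eps``, so the KL
  divergence stays finite.  ``n`` plays the role perplexity plays in
  classic t-SNE.  Because the latent space changes during training, P is
  recomputed for every batch (and treated as a constant within a step —
  ranking is piecewise constant, so there is no useful gradient through it).
* :func:`gaussian_neighbor_probs` — the classic Gaussian conditional
  distribution with per-point bandwidths calibrated by bisection to a target
  perplexity, used by the feature-based (STFT/CWT) baselines where the
  high-dimensional representation is fixed.

Both are symmetrized and jointly normalized following the original t-SNE
convention, p_ij = (p(j|i) + p(i|j)) / 2B, so the matrix sums to one over
ordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PROB_FLOOR = 1e-12


@dataclass
class NeighborDistribution:
    """A B x B matrix of pairwise neighbor probabilities.

    Invariants: zero diagonal, non-negative entries, entries sum to 1 over
    all ordered pairs (joint normalization).
    """

    probs: np.ndarray
    kind: str  # one of {"rank", "gaussian", "student_t"}

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[0] != self.probs.shape[1]:
            raise ValueError("probs must be a square matrix")


@dataclass
class RankSpec:
    """Parameters of the rank-distance distribution.

    ``n_neighbors`` examples get the high probability; ``low_mass_fraction``
    (eps) is the total conditional mass spread over non-neighbors.
    ``symmetrize`` selects the t-SNE joint convention (default) versus raw
    row-conditional probabilities normalized by B.
    """

    n_neighbors: int = 5
    low_mass_fraction: float = 0.01
    symmetrize: bool = True

    def validate(self, batch_size: int) -> None:
        if not (1 <= self.n_neighbors <= batch_size - 1):
            raise ValueError("need 1 <= n_neighbors <= B - 1")
        if not (0 < self.low_mass_fraction < 1):
            raise ValueError("low_mass_fraction must be in (0, 1)")
        if batch_size <= self.n_neighbors + 1:
            raise ValueError(
                f"batch size {batch_size} too small for n_neighbors="
                f"{self.n_neighbors}; reduce n_neighbors or enlarge the batch"
            )


@dataclass
class PerplexitySpec:
    """Target perplexity and bisection settings for the Gaussian P."""

    perplexity: float = 5.0
    tol: float = 1e-5
    max_iter: int = 100

    def validate(self, batch_size: int) -> None:
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if self.perplexity >= batch_size:
            raise ValueError("perplexity must be smaller than the batch size")


def pairwise_sq_distances(X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between all rows of X (B x D)."""
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a B x D matrix with B >= 2")
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return d2


def _joint_from_conditional(cond: np.ndarray, symmetrize: bool) -> np.ndarray:
    B = cond.shape[0]
    if symmetrize:
        return (cond + cond.T) / (2.0 * B)
    return cond / B


def rank_neighbor_probs(Z: np.ndarray, spec: RankSpec | None = None) -> NeighborDistribution:
    """Rank-distance neighbor distribution over a batch of latent vectors.

    Per row i, the n examples with the smallest distance to i (ties broken by
    smaller index; i itself excluded) receive conditional probability
    (1 - eps)/n each; every other example receives eps/(B - 1 - n).  Rows sum
    to one; the returned joint matrix sums to one over ordered pairs.

    The result depends only on the ordering of distances, so any monotone
    transform of the latent space leaves P unchanged.
    """
    spec = spec or RankSpec()
    Z = np.asarray(Z, dtype=np.float64)
    B = Z.shape[0]
    spec.validate(B)
    d2 = pairwise_sq_distances(Z)
    np.fill_diagonal(d2, np.inf)  # self is never a neighbor
    n = spec.n_neighbors
    eps = spec.low_mass_fraction
    # stable argsort => distance ties broken by ascending index
    order = np.argsort(d2, axis=1, kind="stable")
    cond = np.full((B, B), eps / (B - 1 - n))
    rows = np.repeat(np.arange(B), n)
    cond[rows, order[:, :n].ravel()] = (1.0 - eps) / n
    np.fill_diagonal(cond, 0.0)
    return NeighborDistribution(_joint_from_conditional(cond, spec.symmetrize), "rank")


def gaussian_conditionals(
    X: np.ndarray, spec: PerplexitySpec | None = None
) -> np.ndarray:
    """Row-conditional Gaussian neighbor probabilities p(j|i).

    For each row i, p(j|i) ∝ exp(-d²_ij / 2σ_i²) over j ≠ i, with σ_i found
    by bisection on the precision β_i = 1/(2σ_i²) so that the conditional
    entropy H satisfies 2**H = perplexity within ``spec.tol``.
    """
    spec = spec or PerplexitySpec()
    X = np.asarray(X, dtype=np.float64)
    B = X.shape[0]
    if B <= 2:
        raise ValueError("need at least 3 points")
    spec.validate(B)
    d2 = pairwise_sq_distances(X)
    target = np.log2(spec.perplexity)
    cond = np.zeros((B, B))
    mask = ~np.eye(B, dtype=bool)
    worst_err, worst_row = 0.0, -1
    for i in range(B):
        di = d2[i][mask[i]]
        beta, lo, hi = 1.0, 0.0, np.inf
        p = None
        for _ in range(spec.max_iter):
            w = np.exp(-beta * (di - di.min()))  # shift for stability
            p = w / w.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                h = -np.sum(p * np.log2(p, where=p > 0, out=np.zeros_like(p)))
            err = h - target
            if abs(err) < spec.tol:
                break
            if err > 0:  # entropy too high -> narrow the kernel
                lo = beta
                beta = beta * 2.0 if not np.isfinite(hi) else (beta + hi) / 2.0
            else:
                hi = beta
                beta = beta / 2.0 if lo == 0.0 else (beta + lo) / 2.0
        else:
            if abs(err) > worst_err:
                worst_err, worst_row = abs(err), i
        cond[i][mask[i]] = p
    if worst_row >= 0 and worst_err > 1e-2:
        raise RuntimeError(
            f"perplexity bisection failed to converge; worst row {worst_row}, "
            f"entropy error {worst_err:.3g} bits"
        )
    return cond


def gaussian_neighbor_probs(
    X: np.ndarray, spec: PerplexitySpec | None = None
) -> NeighborDistribution:
    """Symmetrized, jointly normalized Gaussian neighbor distribution.

    Conditionals from :func:`gaussian_conditionals` combined by the t-SNE
    convention p_ij = (p(j|i) + p(i|j)) / 2B.
    """
    cond = gaussian_conditionals(X, spec)
    return NeighborDistribution(_joint_from_conditional(cond, True), "gaussian")


def student_t_probs(Y: np.ndarray) -> NeighborDistribution:
    """Student-t (1 degree of freedom) embedding distribution.

    q_ij = (1 + ||y_i - y_j||²)^-1 normalized over all ordered pairs i ≠ j.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite values in embedding")
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 points")
    w = 1.0 / (1.0 + pairwise_sq_distances(Y))
    np.fill_diagonal(w, 0.0)
    return NeighborDistribution(w / w.sum(), "student_t")


def kl_loss(P: NeighborDistribution, Q: NeighborDistribution) -> float:
    """KL(P || Q) over ordered pairs, with 0·log(0/q) = 0 and q floored.

    Non-negative; zero iff P == Q.  Differentiable with respect to the
    parameters producing Q (P is a constant target).
    """
    p, q = P.probs, Q.probs
    if p.shape != q.shape:
        raise ValueError("P and Q must have the same shape")
    q = np.maximum(q, PROB_FLOOR)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def kl_loss_grad_y(P: NeighborDistribution, Y: np.ndarray) -> tuple[float, np.ndarray]:
    """KL loss and its analytic gradient with respect to the embedding Y.

    Uses the standard t-SNE gradient
    dC/dy_i = 4 Σ_j (p_ij - q_ij) (1 + ||y_i - y_j||²)^-1 (y_i - y_j).
    """
    Y = np.asarray(Y, dtype=np.float64)
    Q = student_t_probs(Y)
    loss = kl_loss(P, Q)
    w = 1.0 / (1.0 + pairwise_sq_distances(Y))
    np.fill_diagonal(w, 0.0)
    # symmetrizing P here keeps the gradient exact even for a row-conditional P
    p_sym = (P.probs + P.probs.T) / 2.0
    pq = (p_sym - Q.probs) * w
    grad = 4.0 * ((pq.sum(axis=1)[:, None] * Y) - pq @ Y)
    return loss, grad
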