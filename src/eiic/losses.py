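"""Mutual-information contrastive losses.

The objective of invariant information clustering (IIC) is to maximize the
mutual information between the soft class assignments of a data pair
(x, x').  With softmax outputs Phi(x), Phi(x') of width C, the empirical
joint assignment over a batch of n pairs is

    P = (1/n) sum_i Phi(x_i) Phi(x_i')^T            (C x C, sums to 1)

with marginals P_c (row sums) and P_c' (column sums).  The entropy-weighted
mutual information

    I_lambda = sum_{c,c'} P_cc' * ln( P_cc' / (P_c^lambda * P_c'^lambda) )
             = I_1 + (lambda - 1) * (H(z) + H(z'))

up-weights the marginal-entropy terms by lambda (default 5.0), discouraging
the degenerate solution that assigns every input to one cluster.  The IIC
loss is -I_lambda divided by ln C so the ideal two-class value is bounded.

For two-class output the elementwise complement 1 - Phi(x) is itself a valid
distribution and represents assignment to the opposite class; pairs with
*different* labels are pushed apart by maximizing MI between Phi(x1) and the
complement of Phi(x2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IicConfig",
    "joint_assignment",
    "marginal_entropy",
    "mutual_information_lambda",
    "iic_loss",
    "complement_distribution",
    "cross_entropy",
    "prior_pair_loss",
]

EPS = 1e-12


@dataclass
class IicConfig:
    """Loss hyperparameters: entropy weight lambda, head widths, log epsilon."""

    lambda_weight: float = 5.0
    c_main: int = 2
    c_oc: int = 10
    eps: float = EPS

    def __post_init__(self) -> None:
        if self.lambda_weight < 1:
            raise ValueError("lambda_weight must be >= 1")
        if self.c_main != 2:
            raise ValueError("the main head is two-class")
        if self.c_oc <= 2:
            raise ValueError("the overclustering head must have more than 2 classes")


def _check_distributions(phis: np.ndarray, name: str) -> np.ndarray:
    phis = np.atleast_2d(np.asarray(phis, dtype=float))
    if np.any(phis < -1e-9):
        raise ValueError(f"{name} has negative entries")
    sums = phis.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError(f"{name} rows must sum to 1 (max deviation {np.max(np.abs(sums - 1)):.2e})")
    return phis


def joint_assignment(
    phis_1: np.ndarray,
    phis_2: np.ndarray,
    symmetrize: bool = True,
) -> np.ndarray:
    """Empirical joint class-assignment matrix P = (1/n) sum Phi_1 Phi_2^T.

    With ``symmetrize`` (default), P <- (P + P^T)/2 and is renormalized to
    total mass 1; the symmetrized joint treats the pair order as exchangeable.
    """
    p1 = _check_distributions(phis_1, "phis_1")
    p2 = _check_distributions(phis_2, "phis_2")
    if p1.shape != p2.shape:
        raise ValueError(f"shape mismatch: {p1.shape} vs {p2.shape}")
    n = p1.shape[0]
    joint = p1.T @ p2 / n
    if symmetrize:
        joint = 0.5 * (joint + joint.T)
    joint = np.clip(joint, 0.0, None)
    return joint / joint.sum()


def marginal_entropy(p: np.ndarray, eps: float = EPS) -> float:
    """Shannon entropy -sum p ln(p + eps) of a probability vector (nats)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12):
        raise ValueError("probability vector has negative entries")
    p = np.clip(p, 0.0, None)
    return float(-(p * np.log(p + eps)).sum())


def mutual_information_lambda(
    joint: np.ndarray,
    lambda_weight: float = 5.0,
    eps: float = EPS,
) -> float:
    """I_lambda = I_1(P) + (lambda - 1) (H(z) + H(z')).

    Computed as sum P ln(P) + lambda (H_rows + H_cols) with eps-stabilized
    logs; lambda = 1 recovers the ordinary mutual information of P.
    """
    p = np.asarray(joint, dtype=float)
    h_rows = marginal_entropy(p.sum(axis=1), eps)
    h_cols = marginal_entropy(p.sum(axis=0), eps)
    neg_joint_entropy = float((p * np.log(p + eps)).sum())
    return neg_joint_entropy + lambda_weight * (h_rows + h_cols)


def iic_loss(joint: np.ndarray, lambda_weight: float = 5.0, c: int | None = None) -> float:
    """-I_lambda(P) / ln(c): the minimized training objective."""
    p = np.asarray(joint, dtype=float)
    if c is None:
        c = p.shape[0]
    if c < 2:
        raise ValueError("class count must be at least 2")
    return -mutual_information_lambda(p, lambda_weight) / np.log(c)


def complement_distribution(phi: np.ndarray) -> np.ndarray:
    """1 - Phi for two-class outputs: the opposite-class distribution.

    For C = 2 the elementwise complement equals swapping the two entries, so
    the result is again a valid distribution.  Defined only for C = 2.
    """
    p = np.asarray(phi, dtype=float)
    if p.shape[-1] != 2:
        raise ValueError("complement_distribution is defined only for two-class outputs")
    return 1.0 - p


def cross_entropy(pred: np.ndarray, label: int, eps: float = EPS) -> float:
    """-ln(pred[label] + eps) for a one-hot target."""
    p = np.asarray(pred, dtype=float)
    if label not in (0, 1) or label >= p.shape[-1]:
        raise ValueError(f"invalid label {label!r}")
    return float(-np.log(p[..., label] + eps))


def prior_pair_loss(same_pairs, diff_pairs, heads, config: IicConfig) -> float:
    """Total contrastive objective over labeled pairs.

    ``same_pairs``/``diff_pairs`` are ``(X1, X2)`` tuples of feature batches
    (or None/empty).  ``heads`` maps ``"iic"`` and ``"iic_oc"`` to callables
    producing softmax batches.  Same-label pairs contribute the IIC loss at
    both heads; different-label pairs contribute the IIC loss at the main
    head with the second member's output complemented (the two-class trick
    does not extend to the overclustering head).
    """
    terms = []
    lam = config.lambda_weight
    if same_pairs is not None and len(same_pairs[0]) > 0:
        x1, x2 = same_pairs
        terms.append(iic_loss(joint_assignment(heads["iic"](x1), heads["iic"](x2)), lam))
        terms.append(
            iic_loss(joint_assignment(heads["iic_oc"](x1), heads["iic_oc"](x2)), lam)
        )
    if diff_pairs is not None and len(diff_pairs[0]) > 0:
        x1, x2 = diff_pairs
        phi2c = complement_distribution(heads["iic"](x2))
        terms.append(iic_loss(joint_assignment(heads["iic"](x1), phi2c), lam))
    if not terms:
        raise ValueError("need at least one same-label or different-label pair")
    return float(sum(terms))


def _iic_pair_loss_grads(phi1: np.ndarray, phi2: np.ndarray, lam: float, eps: float = EPS):
    """Loss and gradients w.r.t. the softmax outputs of a pair batch.

    Uses the symmetrized joint.  The gradient treats the eps inside the logs
    and the (numerically unit) renormalization as constants, the standard
    approximation for this objective.
    """
    n, c = phi1.shape
    raw = phi1.T @ phi2 / n
    p = 0.5 * (raw + raw.T)
    p = p / p.sum()
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    log_p = np.log(p + eps)
    log_r = np.log(pr + eps)
    log_c = np.log(pc + eps)
    log_norm = np.log(c)
    info = np.sum(p * (log_p - lam * log_r[:, None] - lam * log_c[None, :]))
    loss = -info / log_norm
    d_info = log_p + 1.0 - lam * (log_r[:, None] + 1.0) - lam * (log_c[None, :] + 1.0)
    d_p = -d_info / log_norm
    g_raw = 0.5 * (d_p + d_p.T)
    d_phi1 = phi2 @ g_raw.T / n
    d_phi2 = phi1 @ g_raw / n
    return float(loss), d_phi1, d_phi2
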