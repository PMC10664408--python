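"""Deep embedded clustering: autoencoder pretraining, Student's-t soft
assignment, the sharpened target distribution and KL self-training.

The default encoder is input -> 500 -> 500 -> 2000 -> 20 (ReLU, biased);
the decoder is its exact mirror with a linear output.
Hidden widths are configurable so the network can be scaled to the input
dimensionality.

Given embeddings ``z_i`` and centroids ``mu_j``, the soft assignment uses a
Student's-t kernel with ``alpha`` degrees of freedom,

    q_ij ∝ (1 + ||z_i - mu_j||^2 / alpha) ^ (-(alpha+1)/2),

rows normalised to 1.  The target distribution sharpens Q while correcting
for cluster size,

    p_ij = (q_ij^2 / f_j) / sum_j' (q_ij'^2 / f_j'),   f_j = sum_i q_ij,

and self-training minimises ``KL(P || Q)`` (natural log) over encoder
weights and centroids, refreshing P periodically and stopping when hard
assignments stabilise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .fusion import FusedFeatures
from .nn import MLP, Adam

log = logging.getLogger("gdec")

__all__ = [
    "EncoderSpec",
    "DecState",
    "SoftAssignment",
    "TargetDistribution",
    "PretrainConfig",
    "DecFitConfig",
    "pretrain_autoencoder",
    "encode",
    "init_centroids",
    "soft_assign",
    "target_distribution",
    "kl_loss",
    "dec_fit",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Encoder layer plan: ``input_dim`` -> hidden... -> ``latent_dim``.

    Defaults are 500/500/2000 hidden with a 20-d latent layer,
    ReLU on every encoder layer, biases on.
    """

    input_dim: int
    hidden: tuple[int, ...] = (500, 500, 2000)
    latent_dim: int = 20

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.latent_dim < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("all layer sizes must be positive")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.input_dim, *self.hidden, self.latent_dim]


@dataclass
class DecState:
    """Encoder/decoder weights plus cluster centroids.

    ``centroids`` is None until :func:`init_centroids`; ``alpha`` is the
    Student's-t degrees of freedom.
    """

    encoder: MLP
    decoder: MLP
    spec: EncoderSpec
    alpha: float = 1.0
    centroids: np.ndarray | None = None
    pretrain_loss: list[float] = field(default_factory=list)
    kl_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.centroids is not None and self.centroids.shape[1] != self.spec.latent_dim:
            raise ValueError("centroid dimension must equal the latent dimension")

    @property
    def k(self) -> int | None:
        return None if self.centroids is None else self.centroids.shape[0]

    def copy(self) -> "DecState":
        return DecState(
            self.encoder.copy(),
            self.decoder.copy(),
            self.spec,
            self.alpha,
            None if self.centroids is None else self.centroids.copy(),
            list(self.pretrain_loss),
            list(self.kl_history),
        )


@dataclass
class SoftAssignment:
    """Cells x k matrix Q of strictly positive rows summing to 1."""

    Q: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if (self.Q <= 0).any():
            raise ValueError("soft assignments must be strictly positive")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("soft-assignment rows must sum to 1")

    def hard(self) -> np.ndarray:
        return self.Q.argmax(axis=1)

    def max_q(self) -> np.ndarray:
        return self.Q.max(axis=1)


@dataclass
class TargetDistribution:
    """Sharpened target P with the per-cluster soft frequencies f."""

    P: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("target rows must sum to 1")


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, FusedFeatures):
        return x.values
    return np.asarray(x, dtype=float)


def _build_networks(spec: EncoderSpec, seed: int) -> tuple[MLP, MLP]:
    rng = np.random.default_rng(seed)
    sizes = spec.layer_sizes
    encoder = MLP.init(sizes, ["relu"] * (len(sizes) - 1), rng)
    dec_sizes = sizes[::-1]
    dec_act = ["relu"] * (len(dec_sizes) - 2) + ["identity"]
    decoder = MLP.init(dec_sizes, dec_act, rng)
    return encoder, decoder


@dataclass(frozen=True)
class PretrainConfig:
    """Autoencoder pretraining settings.

    The default learning rate is 3e-4: with ReLU on the embedding layer a
    larger rate (e.g. 1e-3) reliably drives every latent unit into the dead
    regime and collapses the embedding to a constant.
    """

    epochs: int = 100
    lr: float = 3e-4
    batch_size: int = 256
    seed: int = 0


def pretrain_autoencoder(
    I: FusedFeatures | np.ndarray, spec: EncoderSpec, cfg: PretrainConfig = PretrainConfig()
) -> DecState:
    """Train the mirrored autoencoder on mean-squared reconstruction error.

    Returns a :class:`DecState` with centroids unset; the per-epoch loss
    curve is stored in ``pretrain_loss``.
    """
    X = _as_matrix(I)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite autoencoder input")
    if X.shape[1] != spec.input_dim:
        raise ValueError(f"input width {X.shape[1]} != spec input_dim {spec.input_dim}")
    encoder, decoder = _build_networks(spec, cfg.seed)
    state = DecState(encoder, decoder, spec)
    if cfg.epochs == 0:
        return state
    n = X.shape[0]
    bs = min(cfg.batch_size, n)
    rng = np.random.default_rng(cfg.seed + 1)
    params = encoder.params() + decoder.params()
    opt = Adam(params, lr=cfg.lr)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            batch = X[order[start : start + bs]]
            z = encoder.forward(batch, remember=True)
            recon = decoder.forward(z, remember=True)
            diff = recon - batch
            loss = float(np.mean(diff**2))
            epoch_loss += loss * len(batch)
            g = 2.0 * diff / diff.size
            gz = decoder.backward(g)
            encoder.backward(gz)
            opt.step(encoder.grads() + decoder.grads())
        state.pretrain_loss.append(epoch_loss / n)
    return state


def encode(state: DecState, I: FusedFeatures | np.ndarray) -> np.ndarray:
    """Deterministic encoder forward pass -> cells x latent_dim embeddings."""
    X = _as_matrix(I)
    if X.shape[1] != state.spec.input_dim:
        raise ValueError(f"input width {X.shape[1]} != spec input_dim {state.spec.input_dim}")
    return state.encoder.forward(X)


def init_centroids(Z: np.ndarray, k: int, seed: int = 0, n_init: int = 20) -> np.ndarray:
    """K-means(++) centroids in the embedding space."""
    Z = np.asarray(Z, dtype=float)
    distinct = np.unique(Z, axis=0).shape[0]
    if k > distinct:
        raise ValueError(f"k={k} exceeds {distinct} distinct embedding rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(Z)
    return km.cluster_centers_.astype(float)


def _t_kernel(Z: np.ndarray, mu: np.ndarray, alpha: float):
    d2 = ((Z[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    if not np.all(np.isfinite(d2)):
        raise ValueError("non-finite embedding-to-centroid distances")
    K = (1.0 + d2 / alpha) ** (-(alpha + 1.0) / 2.0)
    return K, d2


def soft_assign(Z: np.ndarray, mu: np.ndarray, alpha: float = 1.0) -> SoftAssignment:
    """Student's-t soft assignment of each cell to each centroid."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    Z = np.asarray(Z, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if Z.shape[1] != mu.shape[1]:
        raise ValueError("embedding and centroid dimensions differ")
    K, _ = _t_kernel(Z, mu, alpha)
    return SoftAssignment(K / K.sum(axis=1, keepdims=True))


def target_distribution(Q: SoftAssignment) -> TargetDistribution:
    """Frequency-corrected sharpening of the soft assignment."""
    q = Q.Q
    f = q.sum(axis=0)
    w = q**2 / f
    return TargetDistribution(w / w.sum(axis=1, keepdims=True), f)


def kl_loss(P: TargetDistribution | np.ndarray, Q: SoftAssignment | np.ndarray) -> float:
    """KL(P || Q) summed over all cells and clusters (natural log)."""
    p = P.P if isinstance(P, TargetDistribution) else np.asarray(P, dtype=float)
    q = Q.Q if isinstance(Q, SoftAssignment) else np.asarray(Q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("P and Q shapes differ")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


@dataclass(frozen=True)
class DecFitConfig:
    max_iters: int = 150
    update_interval: int = 30
    lr: float = 1e-4
    tol: float = 1e-3
    seed: int = 0
    prior_weight: float = 1.0
    confidence_gate: float | None = None


def _kl_grad_wrt_Z_mu(Z, mu, P, alpha, extra_target=None, extra_weight=1.0,
                      confidence_gate=None):
    """Gradients of sum-KL (plus optional auxiliary one-hot term) wrt Z and mu.

    d KL / d z_i = sum_j (alpha+1)/(alpha+d_ij) (p_ij - q_ij) (z_i - mu_j);
    the centroid gradient is its negative, summed over cells.  A cross-entropy
    prior on labelled cells is the same expression with a one-hot target, so
    it is folded in by adjusting the (p - q) coefficient on those rows.
    """
    K, d2 = _t_kernel(Z, mu, alpha)
    q = K / K.sum(axis=1, keepdims=True)
    coef = (alpha + 1.0) / (alpha + d2) * (P - q)
    if confidence_gate is not None:
        # open-set safeguard: ambiguous cells do not drive self-training,
        # so clusters sharpen without absorbing far-from-centroid cells
        coef[q.max(axis=1) < confidence_gate] = 0.0
    if extra_target is not None:
        rows, onehot = extra_target
        coef[rows] += extra_weight * (alpha + 1.0) / (alpha + d2[rows]) * (onehot - q[rows])
    # note the loss decreases along -grad; coef rows broadcast over latent dims
    diff = Z[:, None, :] - mu[None, :, :]
    gZ = (coef[:, :, None] * diff).sum(axis=1)
    gmu = -(coef[:, :, None] * diff).sum(axis=0)
    return gZ, gmu, q


def dec_fit(
    state: DecState,
    I: FusedFeatures | np.ndarray,
    cfg: DecFitConfig = DecFitConfig(),
    prior: tuple[np.ndarray, np.ndarray] | None = None,
    frozen_layers: tuple[int, ...] = (),
) -> tuple[DecState, SoftAssignment]:
    """KL self-training of encoder weights and centroids.

    Every ``update_interval`` steps the target P is refreshed and the run
    stops early once the fraction of cells changing hard assignment between
    consecutive refreshes falls below ``tol``.  ``prior`` is an optional
    ``(cell_row_indices, one_hot_targets)`` pair adding a cross-entropy term
    anchoring labelled cells to their known clusters; ``frozen_layers`` lists
    encoder layer indices excluded from updates.  Returns the fitted state
    and the final soft assignment; the KL value at each refresh is appended
    to ``state.kl_history``.
    """
    if state.centroids is None:
        raise RuntimeError("centroids must be initialised before dec_fit")
    X = _as_matrix(I)
    state = state.copy()
    encoder, mu = state.encoder, state.centroids
    Z = encoder.forward(X)
    Q = soft_assign(Z, mu, state.alpha)
    if cfg.max_iters == 0:
        return state, Q
    params = encoder.params() + [mu]
    mask = []
    for li in range(len(encoder.layers)):
        trainable = li not in frozen_layers
        mask += [trainable, trainable]
    mask.append(True)  # centroids
    opt = Adam(params, lr=cfg.lr)
    P = target_distribution(Q).P
    state.kl_history.append(kl_loss(P, Q.Q))
    prev_hard = Q.hard()
    for it in range(1, cfg.max_iters + 1):
        Z = encoder.forward(X, remember=True)
        gZ, gmu, q = _kl_grad_wrt_Z_mu(
            Z, mu, P, state.alpha,
            extra_target=prior, extra_weight=cfg.prior_weight,
            confidence_gate=cfg.confidence_gate,
        )
        encoder.backward(gZ)
        opt.step(encoder.grads() + [gmu], mask=mask)
        if it % cfg.update_interval == 0 or it == cfg.max_iters:
            Z = encoder.forward(X)
            Q = soft_assign(Z, mu, state.alpha)
            hard = Q.hard()
            changed = float(np.mean(hard != prev_hard))
            P = target_distribution(Q).P
            state.kl_history.append(kl_loss(P, Q.Q))
            if changed < cfg.tol and it < cfg.max_iters:
                log.debug("dec_fit converged at iter %d (changed=%.4f)", it, changed)
                break
            prev_hard = hard
    Z = encoder.forward(X)
    Q = soft_assign(Z, mu, state.alpha)
    state.centroids = mu
    return state, Q
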