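"""Deep generalized CCA: per-view feedforward networks trained to maximize
the top-k eigenvalue sum of the summed-projector matrix built on network
outputs.

The loss maximized is ``L = sum_{i<=k} lambda_i(sum_j O_j (O_j^T O_j)^-1 O_j^T)``
where ``O_j`` is view j passed through its own network; training minimizes
``J*k - L``. The gradient w.r.t. each output block has the closed form

    dL/dO_j = 2 [I - O_j (O_j^T O_j)^-1 O_j^T] G G^T O_j (O_j^T O_j)^-1

with ``G`` the top-k eigenvectors, treated as fixed within a step; parameter
gradients follow by ordinary backpropagation. Networks, dropout, Adam and
backprop are implemented here directly (no autodiff dependency): full-batch
updates at these sample sizes are cheap and exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .gcca import fit_gcca, fix_eigenvector_signs, project_view, standardize_views

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "DgccaModel",
    "MLP",
    "dgcca_loss",
    "loss_gradient",
    "train_dgcca",
    "embed",
    "EarlyStopper",
]


@dataclass
class NetworkSpec:
    """Architecture of one view's network: affine->ReLU(->dropout) hidden
    layers followed by a linear output layer."""

    input_dim: int
    hidden_dims: tuple[int, ...] = (96, 96)
    dropout_prob: float = 0.1
    output_dim: int | None = None  # defaults to input_dim

    def __post_init__(self) -> None:
        if self.output_dim is None:
            self.output_dim = self.input_dim
        if self.input_dim < 1 or self.output_dim < 1:
            raise ValueError("dimensions must be >= 1")
        if any(h < 1 for h in self.hidden_dims):
            raise ValueError("hidden dims must be >= 1")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must lie in [0, 1)")


@dataclass
class TrainConfig:
    k: int = 20
    learning_rate: float = 5e-4
    weight_decay: float = 0.01
    max_epochs: int = 200
    patience: int = 5
    early_stop_frac: float = 5e-4  # 0.05% of the max validation loss
    train_frac: float = 0.8
    seed: int = 0
    ridge: float = 1e-6
    restore_best: bool = True  # rewind to the best-validation-loss weights

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class MLP:
    """Minimal feedforward net with manual forward/backward passes.

    Parameters are He-initialized from ``rng``. Dropout (inverted scaling)
    is active only when ``train_mode`` is requested on the forward pass.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        dims = [spec.input_dim, *spec.hidden_dims, spec.output_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / d_in)
            self.weights.append(rng.normal(0.0, scale, size=(d_in, d_out)))
            self.biases.append(np.zeros(d_out))
        self._cache = None

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    def forward(
        self,
        X: np.ndarray,
        train_mode: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"input width {X.shape[1]} != spec input_dim {self.spec.input_dim}"
            )
        if train_mode and self.spec.dropout_prob > 0 and rng is None:
            raise ValueError("train_mode with dropout requires an rng")
        acts = [X]
        relu_masks, drop_masks = [], []
        h = X
        n_hidden = len(self.spec.hidden_dims)
        for i in range(n_hidden):
            z = h @ self.weights[i] + self.biases[i]
            mask = z > 0
            h = z * mask
            relu_masks.append(mask)
            if train_mode and self.spec.dropout_prob > 0:
                keep = 1.0 - self.spec.dropout_prob
                dmask = (rng.random(h.shape) < keep) / keep
                h = h * dmask
                drop_masks.append(dmask)
            else:
                drop_masks.append(None)
            acts.append(h)
        out = h @ self.weights[n_hidden] + self.biases[n_hidden]
        self._cache = (acts, relu_masks, drop_masks)
        return out

    def backward(self, d_out: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients of a scalar w.r.t. weights/biases given d(scalar)/d(output).

        Uses caches from the most recent :meth:`forward` call.
        """
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        acts, relu_masks, drop_masks = self._cache
        n_hidden = len(self.spec.hidden_dims)
        dW = [None] * len(self.weights)
        db = [None] * len(self.biases)
        g = d_out
        dW[n_hidden] = acts[n_hidden].T @ g
        db[n_hidden] = g.sum(axis=0)
        g = g @ self.weights[n_hidden].T
        for i in range(n_hidden - 1, -1, -1):
            if drop_masks[i] is not None:
                g = g * drop_masks[i]
            g = g * relu_masks[i]
            dW[i] = acts[i].T @ g
            db[i] = g.sum(axis=0)
            g = g @ self.weights[i].T
        return dW, db


def _whitened_blocks(outputs: list[np.ndarray], ridge: float) -> list[np.ndarray]:
    """Return ``C_j = O_j L_j^{-T}`` with ``L_j L_j^T = O_j^T O_j + ridge*I``,
    so ``C_j C_j^T`` is view j's (ridged) projector."""
    blocks = []
    for j, O in enumerate(outputs):
        S = O.T @ O
        if ridge > 0:
            S = S + ridge * np.eye(S.shape[0])
        try:
            L = sla.cholesky(S, lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"view {j}: O^T O is rank deficient and ridge=0"
            ) from exc
        blocks.append(sla.solve_triangular(L, O.T, lower=True).T)
    return blocks


def dgcca_loss(
    outputs: list[np.ndarray], k: int, ridge: float = 0.0
) -> tuple[float, np.ndarray]:
    """Top-k eigenvalue sum of the summed projector matrix, and its
    eigenvectors ``G``.

    Eigenvalues are obtained from the singular values of the horizontal
    stack of whitened output blocks, which is exact and avoids forming the
    N x N matrix.
    """
    N = outputs[0].shape[0]
    if any(O.shape[0] != N for O in outputs):
        raise ValueError("all outputs must share the same number of rows")
    if k > N:
        raise ValueError(f"k={k} exceeds N={N}")
    C = np.hstack(_whitened_blocks(outputs, ridge))
    Gfull, svals, _ = sla.svd(C, full_matrices=False)
    evals = svals**2
    n_avail = min(k, evals.shape[0])
    L = float(evals[:n_avail].sum())
    if n_avail < k:  # rank(M) < k: remaining eigenvalues are 0
        G = np.zeros((N, k))
        G[:, :n_avail] = Gfull[:, :n_avail]
    else:
        G = Gfull[:, :k]
    return L, fix_eigenvector_signs(G)


def loss_gradient(O_j: np.ndarray, G: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Closed-form ``dL/dO_j`` given the current top-k eigenvectors ``G``."""
    if O_j.shape[0] != G.shape[0]:
        raise ValueError("O_j and G must share the sample dimension")
    S = O_j.T @ O_j
    if ridge > 0:
        S = S + ridge * np.eye(S.shape[0])
    cho = sla.cho_factor(S, lower=True)
    # T = G G^T O_j S^{-1}
    T = G @ sla.cho_solve(cho, O_j.T @ G).T
    # subtract the projection of T onto col(O_j)
    PT = O_j @ sla.cho_solve(cho, O_j.T @ T)
    return 2.0 * (T - PT)


class EarlyStopper:
    """Patience-based stop on the validation loss.

    An epoch counts toward patience when the loss fails to improve on the
    best seen so far by more than ``frac`` times the running maximum of the
    validation loss; ``patience`` consecutive such epochs trigger the stop.
    """

    def __init__(self, patience: int, frac: float):
        self.patience = patience
        self.frac = frac
        self.best = np.inf
        self.max_seen = -np.inf
        self.stale = 0

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; return True to stop."""
        self.max_seen = max(self.max_seen, val_loss)
        threshold = self.frac * self.max_seen
        if val_loss < self.best - threshold:
            self.best = val_loss
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


@dataclass
class DgccaModel:
    specs: list[NetworkSpec]
    networks: list[MLP] = field(repr=False)
    U: list[np.ndarray] = field(repr=False)
    G_train: np.ndarray = field(repr=False)
    history: list[dict] = field(repr=False)
    epochs_ran: int
    config: TrainConfig
    train_indices: np.ndarray = field(repr=False)
    val_indices: np.ndarray = field(repr=False)
    view_means: list[np.ndarray] = field(repr=False)
    view_stds: list[np.ndarray] = field(repr=False)

    @property
    def trained(self) -> bool:
        return len(self.U) > 0


class _Adam:
    """Adam with coupled L2 weight decay (gradient += wd * param)."""

    def __init__(self, params: list[np.ndarray], lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.wd:
                g = g + self.wd * p
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_dgcca(
    views: list[np.ndarray],
    specs: list[NetworkSpec],
    config: TrainConfig,
) -> DgccaModel:
    """Train per-view networks by full-batch Adam on ``J*k - L``.

    Views are z-scored with training-split statistics before entering the
    networks; the final ``U_j`` and ``G`` come from a linear GCCA fit on the
    eval-mode outputs of the training split.
    """
    if len(views) != len(specs):
        raise ValueError("one NetworkSpec per view required")
    J = len(views)
    N = views[0].shape[0]
    rng = np.random.Generator(np.random.PCG64(config.seed))

    perm = rng.permutation(N)
    n_train = int(round(config.train_frac * N))
    train_idx, val_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    if len(train_idx) < 2 or len(val_idx) < 2:
        raise ValueError("each split needs at least 2 samples")
    if config.k > min(len(train_idx), len(val_idx)):
        raise ValueError("k exceeds a split size")

    raw_train = [np.asarray(X, dtype=float)[train_idx] for X in views]
    raw_val = [np.asarray(X, dtype=float)[val_idx] for X in views]
    train_views, means, stds = standardize_views(raw_train)
    val_views, _, _ = standardize_views(raw_val, means, stds)

    nets = [MLP(spec, rng) for spec in specs]
    opt = _Adam(
        [p for net in nets for p in net.params],
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    stopper = EarlyStopper(config.patience, config.early_stop_frac)
    upper = J * config.k

    history: list[dict] = []
    epochs_ran = 0
    best_val = np.inf
    best_params: list[np.ndarray] | None = None
    for epoch in range(1, config.max_epochs + 1):
        outputs = [
            net.forward(X, train_mode=True, rng=rng)
            for net, X in zip(nets, train_views)
        ]
        L, G = dgcca_loss(outputs, config.k, config.ridge)
        train_loss = upper - L
        if not np.isfinite(train_loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        # the summed-projector eigenvalues lie in [0, J], so 0 <= loss <= J*k
        assert -1e-6 <= train_loss <= upper + 1e-6

        grads: list[np.ndarray] = []
        for net, O in zip(nets, outputs):
            d_out = -loss_gradient(O, G, config.ridge)  # minimize J*k - L
            dW, db = net.backward(d_out)
            grads.extend([*dW, *db])
        opt.step(grads)

        val_outputs = [net.forward(X, train_mode=False) for net, X in zip(nets, val_views)]
        L_val, _ = dgcca_loss(val_outputs, config.k, config.ridge)
        val_loss = upper - L_val
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        history.append(
            {"epoch": epoch, "train_loss": float(train_loss), "val_loss": float(val_loss)}
        )
        epochs_ran = epoch
        if config.restore_best and val_loss < best_val:
            best_val = float(val_loss)
            best_params = [p.copy() for net in nets for p in net.params]
        if stopper.update(float(val_loss)):
            break

    if config.restore_best and best_params is not None:
        flat = [p for net in nets for p in net.params]
        for dst, src in zip(flat, best_params):
            dst[...] = src

    final_outputs = [net.forward(X, train_mode=False) for net, X in zip(nets, train_views)]
    fit = fit_gcca(final_outputs, config.k, ridge=config.ridge)

    return DgccaModel(
        specs=list(specs),
        networks=nets,
        U=fit.U,
        G_train=fit.G,
        history=history,
        epochs_ran=epochs_ran,
        config=config,
        train_indices=train_idx,
        val_indices=val_idx,
        view_means=means,
        view_stds=stds,
    )


def embed(
    model: DgccaModel, views: list[np.ndarray]
) -> tuple[list[np.ndarray], np.ndarray]:
    """Eval-mode projections ``O_j U_j`` and a recomputed shared ``G``.

    ``G`` comes from a fresh GCCA fit on the eval-mode outputs of the
    supplied samples with the model's stored embedding dimension; applied to
    the training split this reproduces ``G_train`` exactly (the fit is
    deterministic).
    """
    if not model.trained:
        raise ValueError("model has no projections; train it first")
    std_views, _, _ = standardize_views(
        [np.asarray(X, dtype=float) for X in views], model.view_means, model.view_stds
    )
    outputs = [net.forward(X, train_mode=False) for net, X in zip(model.networks, std_views)]
    projections = [project_view(O, Uj) for O, Uj in zip(outputs, model.U)]
    fit = fit_gcca(outputs, model.config.k, ridge=model.config.ridge)
    return projections, fit.G
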