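"""The adjacency-parameterized variational autoencoder for GRN inference.

The model rests on a linear structural equation view of gene regulation:
for log-scale expression X (cells x genes) and a weighted gene-gene
adjacency matrix A (regulator rows, target columns, zero diagonal),

    X = X A + Z          ⇔          Z = X (I - A),   X = Z (I - A)^{-1}.

The residual Z plays the role of a per-cell, per-gene latent variable, so
the two rearrangements form a natural encoder/decoder pair: the encoder
maps (augmented) expression X' to an approximate posterior over Z', and the
decoder reconstructs X' from a latent sample by solving against (I - A).
Small per-gene neural nets — shared across genes — wrap both sides so the
model is not strictly linear; configured as identities they vanish and the
encoder mean is exactly X'(I - A).

A third head, a 3-layer tanh MLP ending in a sigmoid, predicts from the
latent state which entries were zeroed by dropout augmentation; its binary
cross entropy enters the training objective so the latent space learns to
segregate likely-dropout values.

The composite objective is

    L = recon + α Σ|A| + β KL(q(Z'|X') || N(0, I)) + γ BCE(M, M̂),

with the L1 term held at zero for the first ``sparse_delay`` training
iterations (introducing sparsity only once the adjacency gradients have
stabilized). The reconstruction term is a Gaussian likelihood with unit
variance: squared error summed over genes and averaged over cells, matching
the KL scaling. All diagonal entries of A are hard-masked to zero — a
self-loop would reconstruct each gene from itself and trivialize the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor, gene_mix, gene_unmix
from .data_io import ExpressionMatrix
from .augmentation import DropoutMask

__all__ = [
    "AdjacencyMatrix",
    "LatentState",
    "ModelConfig",
    "ModelParams",
    "LossComponents",
    "ModelError",
    "encode",
    "decode",
    "classify_dropout",
    "bce_loss",
    "kl_divergence",
    "reconstruction_loss",
    "compose_loss",
    "extract_edges",
]

_BCE_EPS = 1e-8


class ModelError(RuntimeError):
    """Numerical failure inside the model (NaN, singular system)."""


@dataclass
class AdjacencyMatrix:
    """Weighted gene-gene adjacency: entry (i, j) is regulator i -> target j.

    The diagonal is zeroed on construction; entries must be finite.
    """

    weights: np.ndarray
    gene_names: list[str]

    def __post_init__(self) -> None:
        w = np.array(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if len(self.gene_names) != w.shape[0]:
            raise ValueError("gene_names length must match adjacency size")
        if not np.isfinite(w).all():
            raise ModelError("adjacency contains non-finite entries")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]


@dataclass
class LatentState:
    """Per-cell, per-gene latent posterior (mean, log-variance) and a sample."""

    mean: np.ndarray        # (n, m, d)
    log_var: np.ndarray     # (n, m, d)
    sample: np.ndarray      # (n, m, d)
    epsilon: np.ndarray | None = None  # recorded noise when stochastic


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``latent_dim`` is the number of latent channels per gene; ``hidden_dim``
    sizes the shared per-gene MLPs; ``identity_nets`` replaces every
    nonlinear net with the identity (requires ``latent_dim == 1``), leaving
    the pure linear structural equation model.
    """

    n_genes: int
    latent_dim: int = 1
    hidden_dim: int = 64
    clf_hidden: int = 16
    clf_base_rate: float | None = None
    identity_nets: bool = False

    def __post_init__(self) -> None:
        if self.clf_base_rate is not None and not 0.0 < self.clf_base_rate < 1.0:
            raise ValueError("clf_base_rate must be in (0, 1) or None")
        if self.identity_nets and self.latent_dim != 1:
            raise ValueError("identity nets require latent_dim == 1")


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


class ModelParams:
    """All trainable tensors: adjacency, per-gene nets, classifier.

    Per-gene nets share weights across genes (they act on each gene's
    channel vector independently); the adjacency matrix is the only
    parameter that scales quadratically with gene count.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        m, d, h = cfg.n_genes, cfg.latent_dim, cfg.hidden_dim
        # adjacency starts near zero: (I - A) ~ I is well conditioned and the
        # L1 subgradient is silent until data pulls entries away from zero
        self.adj = Tensor(rng.normal(0.0, 1e-4, size=(m, m)), requires_grad=True)
        np.fill_diagonal(self.adj.data, 0.0)
        self._offdiag = Tensor(1.0 - np.eye(m))
        self._eye = Tensor(np.eye(m))
        if cfg.identity_nets:
            # single trainable log-variance scalar; everything else is exact
            self.enc_logvar0 = Tensor(np.zeros((1, 1, 1)), requires_grad=True)
            self._nn: list[Tensor] = [self.enc_logvar0]
        else:
            self.W_lift = Tensor(np.ones((1, d)), requires_grad=True)
            self.b_lift = Tensor(np.zeros(d), requires_grad=True)
            self.W_f1 = Tensor(_xavier(rng, 1, h), requires_grad=True)
            self.b_f1 = Tensor(np.zeros(h), requires_grad=True)
            self.W_f2 = Tensor(np.zeros((h, d)), requires_grad=True)  # zero: init = linear path
            self.b_f2 = Tensor(np.zeros(d), requires_grad=True)
            self.W_mu = Tensor(np.eye(d), requires_grad=True)
            self.b_mu = Tensor(np.zeros(d), requires_grad=True)
            # posterior log-variance starts small (std ~0.14) so early
            # adjacency gradients are signal- rather than noise-dominated
            self.W_lv = Tensor(np.zeros((d, d)), requires_grad=True)
            self.b_lv = Tensor(np.full(d, -4.0), requires_grad=True)
            self.W_out = Tensor(np.ones((d, 1)), requires_grad=True)
            self.b_out = Tensor(np.zeros(1), requires_grad=True)
            self.W_d1 = Tensor(_xavier(rng, d, h), requires_grad=True)
            self.b_d1 = Tensor(np.zeros(h), requires_grad=True)
            self.W_d2 = Tensor(np.zeros((h, 1)), requires_grad=True)
            self.b_d2 = Tensor(np.zeros(1), requires_grad=True)
            self._nn = [self.W_lift, self.b_lift, self.W_f1, self.b_f1,
                        self.W_f2, self.b_f2, self.W_mu, self.b_mu,
                        self.W_lv, self.b_lv, self.W_out, self.b_out,
                        self.W_d1, self.b_d1, self.W_d2, self.b_d2]
        # dropout classifier: narrow 3-layer tanh MLP (its input is d channels,
        # so a small width suffices); zero-initialized final layer so every
        # initial probability is sigmoid(0) = 0.5
        hc = cfg.clf_hidden
        # random hidden biases break the odd symmetry of a bias-free tanh
        # net: detecting a masked entry is an even (magnitude) feature
        self.W_c1 = Tensor(_xavier(rng, d, hc), requires_grad=True)
        self.b_c1 = Tensor(rng.normal(0.0, 0.5, hc), requires_grad=True)
        self.W_c2 = Tensor(_xavier(rng, hc, hc), requires_grad=True)
        self.b_c2 = Tensor(rng.normal(0.0, 0.5, hc), requires_grad=True)
        self.W_c3 = Tensor(np.zeros((hc, 1)), requires_grad=True)
        # starting the output bias at the known augmentation base rate skips
        # the calibration transient, so the head fits the class contrast
        # from the first step (standard imbalanced-classifier init)
        p0 = cfg.clf_base_rate
        bias0 = 0.0 if p0 is None else float(np.log(p0 / (1.0 - p0)))
        self.b_c3 = Tensor(np.full(1, bias0), requires_grad=True)
        self._clf = [self.W_c1, self.b_c1, self.W_c2, self.b_c2, self.W_c3, self.b_c3]

    # -- parameter access -----------------------------------------------------
    def nn_parameters(self) -> list[Tensor]:
        return self._nn + self._clf

    def all_parameters(self) -> list[Tensor]:
        return [self.adj] + self.nn_parameters()

    def adjacency_effective(self) -> Tensor:
        """A with the diagonal hard-masked to zero (used in every forward)."""
        return self.adj * self._offdiag

    def adjacency(self, gene_names: list[str] | None = None) -> AdjacencyMatrix:
        m = self.cfg.n_genes
        names = gene_names if gene_names is not None else [f"g{i}" for i in range(m)]
        return AdjacencyMatrix(self.adj.data * (1.0 - np.eye(m)), names)

    def zero_adj_diagonal(self) -> None:
        np.fill_diagonal(self.adj.data, 0.0)

    def i_minus_a(self) -> Tensor:
        return self._eye - self.adjacency_effective()

    # -- forward pieces (tensor graph) ---------------------------------------
    def encode_t(self, x: Tensor, stochastic: bool,
                 rng: np.random.Generator | None = None,
                 ) -> tuple[Tensor, Tensor, Tensor, np.ndarray | None]:
        """Tensor-graph encoder: returns (mean, log_var, sample, eps)."""
        n, m = x.shape
        d = self.cfg.latent_dim
        x3 = x.reshape(n, m, 1)
        if self.cfg.identity_nets:
            h = x3
        else:
            hid = (x3 @ self.W_f1 + self.b_f1).tanh()
            h = x3 @ self.W_lift + self.b_lift + (hid @ self.W_f2 + self.b_f2)
        zb = gene_mix(h, self.i_minus_a())
        if self.cfg.identity_nets:
            mean = zb
            log_var = self.enc_logvar0 * Tensor(np.ones((n, m, d)))
        else:
            mean = zb @ self.W_mu + self.b_mu
            log_var = zb @ self.W_lv + self.b_lv
        eps = None
        if stochastic:
            if rng is None:
                raise ValueError("stochastic encoding requires an rng")
            eps = rng.standard_normal((n, m, d))
            sample = mean + (log_var * 0.5).exp() * Tensor(eps)
        else:
            sample = mean
        return mean, log_var, sample, eps

    def decode_t(self, sample: Tensor) -> Tensor:
        """Tensor-graph decoder: latent sample -> reconstructed expression."""
        n, m, d = sample.shape
        try:
            xb = gene_unmix(sample, self.i_minus_a())
        except np.linalg.LinAlgError as exc:
            raise ModelError(
                "(I - A) is singular; consider stronger sparsity (alpha) or a "
                "smaller adjacency learning rate") from exc
        if self.cfg.identity_nets:
            return xb.reshape(n, m)
        hid = (xb @ self.W_d1 + self.b_d1).tanh()
        out = xb @ self.W_out + self.b_out + (hid @ self.W_d2 + self.b_d2)
        return out.reshape(n, m)

    def classify_t(self, sample: Tensor) -> Tensor:
        """Tensor-graph dropout classifier: latent sample -> P(masked)."""
        n, m, _ = sample.shape
        h1 = (sample @ self.W_c1 + self.b_c1).tanh()
        h2 = (h1 @ self.W_c2 + self.b_c2).tanh()
        logits = (h2 @ self.W_c3 + self.b_c3).reshape(n, m)
        return logits.sigmoid()

    # -- (de)serialization ----------------------------------------------------
    def save(self, path) -> None:
        """Write a single-archive checkpoint (parameters + architecture)."""
        meta = {"n_genes": self.cfg.n_genes, "latent_dim": self.cfg.latent_dim,
                "hidden_dim": self.cfg.hidden_dim, "clf_hidden": self.cfg.clf_hidden,
                "clf_base_rate": (np.nan if self.cfg.clf_base_rate is None
                                  else self.cfg.clf_base_rate),
                "identity_nets": float(self.cfg.identity_nets)}
        arrays = {f"param_{k}": v for k, v in self.state_dict().items()}
        if hasattr(self, "input_mean"):
            arrays["stat_input_mean"] = self.input_mean
            arrays["stat_input_std"] = self.input_std
        np.savez(path, _meta=np.array(list(meta.items()), dtype=object), **arrays)

    @classmethod
    def load(cls, path) -> "ModelParams":
        with np.load(path, allow_pickle=True) as archive:
            meta = dict(archive["_meta"].tolist())
            base_rate = float(meta["clf_base_rate"])
            cfg = ModelConfig(
                n_genes=int(meta["n_genes"]), latent_dim=int(meta["latent_dim"]),
                hidden_dim=int(meta["hidden_dim"]), clf_hidden=int(meta["clf_hidden"]),
                clf_base_rate=None if np.isnan(base_rate) else base_rate,
                identity_nets=bool(float(meta["identity_nets"])))
            params = cls(cfg, np.random.default_rng(0))
            params.load_state_dict({k[len("param_"):]: archive[k]
                                    for k in archive.files if k.startswith("param_")})
            if "stat_input_mean" in archive.files:
                params.input_mean = archive["stat_input_mean"]
                params.input_std = archive["stat_input_std"]
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        skip = {"cfg", "_nn", "_clf", "_offdiag", "_eye"}
        out = {}
        for name, val in self.__dict__.items():
            if name in skip:
                continue
            if isinstance(val, Tensor):
                out[name] = val.data.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, arr in state.items():
            getattr(self, name).data[...] = arr


# ---------------------------------------------------------------------------
# public functional operations (numpy in / numpy out)
# ---------------------------------------------------------------------------

def _as_values(x) -> np.ndarray:
    return x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=np.float64)


def encode(x_aug, params: ModelParams, stochastic: bool = False,
           rng: np.random.Generator | None = None) -> LatentState:
    """Encode (augmented) expression into the latent posterior.

    With identity nets and one latent channel the posterior mean is exactly
    ``X'(I - A)``.
    """
    x = Tensor(_as_values(x_aug))
    mean, log_var, sample, eps = params.encode_t(x, stochastic, rng)
    for name, t in (("mean", mean), ("log_var", log_var), ("sample", sample)):
        if not np.isfinite(t.data).all():
            raise ModelError(f"encoder produced non-finite {name}")
    lv = np.broadcast_to(log_var.data, mean.data.shape).copy()
    return LatentState(mean=mean.data, log_var=lv, sample=sample.data, epsilon=eps)


def decode(z: LatentState, params: ModelParams) -> np.ndarray:
    """Reconstruct expression from a latent sample via the (I - A) solve."""
    out = params.decode_t(Tensor(z.sample))
    if not np.isfinite(out.data).all():
        raise ModelError("decoder produced non-finite output")
    return out.data


def classify_dropout(z: LatentState, params: ModelParams,
                     use_mean: bool = False) -> np.ndarray:
    """Per-entry probability that the entry was an augmented dropout.

    Training consumes the latent sample; at evaluation time pass
    ``use_mean=True`` to score the posterior mean instead.
    """
    src = z.mean if use_mean else z.sample
    return params.classify_t(Tensor(src)).data


def bce_loss(mask: DropoutMask | np.ndarray, mask_prob: np.ndarray) -> float:
    """Mean binary cross entropy between the true mask and predicted probs."""
    m = mask.mask if isinstance(mask, DropoutMask) else np.asarray(mask)
    p = np.clip(np.asarray(mask_prob, dtype=np.float64), _BCE_EPS, 1.0 - _BCE_EPS)
    if m.shape != p.shape:
        raise ValueError(f"mask shape {m.shape} != probability shape {p.shape}")
    mf = m.astype(np.float64)
    return float(-(mf * np.log(p) + (1.0 - mf) * np.log(1.0 - p)).mean())


def kl_divergence(z: LatentState) -> float:
    """KL from the posterior to the standard-normal prior.

    Mean over cells of the sum over gene-channels of
    ``(exp(log_var) + mean^2 - 1 - log_var) / 2``.
    """
    per_entry = 0.5 * (np.exp(z.log_var) + z.mean ** 2 - 1.0 - z.log_var)
    return float(per_entry.sum() / z.mean.shape[0])


def reconstruction_loss(x_aug, x_hat: np.ndarray) -> float:
    """Gaussian (unit variance) reconstruction error.

    Squared error summed over genes, averaged over cells — the per-cell
    scaling that matches the KL term.
    """
    x = _as_values(x_aug)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return float(((x - x_hat) ** 2).sum() / x.shape[0])


@dataclass
class LossComponents:
    """The four loss terms, their coefficients, and the exact total."""

    reconstruction: float
    kl: float
    l1_sparse: float
    bce: float
    alpha: float   # effective coefficient (0 during the sparse delay)
    beta: float
    gamma: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = (self.reconstruction + self.alpha * self.l1_sparse
                      + self.beta * self.kl + self.gamma * self.bce)


def effective_alpha(alpha: float, epoch: int, sparse_delay: int) -> float:
    """The delayed-sparsity schedule: zero before ``sparse_delay``, alpha after."""
    return 0.0 if epoch < sparse_delay else alpha


def compose_loss(reconstruction: float, kl: float, bce: float,
                 adjacency: AdjacencyMatrix | np.ndarray,
                 alpha: float, beta: float, gamma: float,
                 epoch: int, sparse_delay: int = 5) -> LossComponents:
    """Assemble the composite objective with the delayed L1 schedule.

    ``l1_sparse`` is the sum of |A| over off-diagonal entries; the alpha
    actually applied is zero while ``epoch < sparse_delay``.
    """
    if alpha < 0 or beta < 0 or gamma < 0:
        raise ValueError("loss coefficients must be nonnegative")
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    w = adjacency.weights if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency)
    offdiag = w * (1.0 - np.eye(w.shape[0]))
    l1 = float(np.abs(offdiag).sum())
    return LossComponents(reconstruction=reconstruction, kl=kl, l1_sparse=l1,
                          bce=bce, alpha=effective_alpha(alpha, epoch, sparse_delay),
                          beta=beta, gamma=gamma)


def extract_edges(adj: AdjacencyMatrix, threshold: float = 0.001) -> pd.DataFrame:
    """Edges with |weight| strictly above the threshold, strongest first.

    Ties in |weight| break lexicographically by (regulator, target).
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    i_idx, j_idx = np.nonzero(np.abs(adj.weights) > threshold)
    rows = [(adj.gene_names[i], adj.gene_names[j],
             float(adj.weights[i, j]), float(abs(adj.weights[i, j])))
            for i, j in zip(i_idx, j_idx)]
    rows.sort(key=lambda r: (-r[3], r[0], r[1]))
    return pd.DataFrame(rows, columns=["regulator", "target", "weight", "abs_weight"])
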