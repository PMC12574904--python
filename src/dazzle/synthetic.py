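"""Synthetic worlds: sparse networks and expression with the model's own structure.

The generator realizes exactly the statistical assumptions the inference
model makes — a linear structural equation model X = Z (I - A)^{-1} with
i.i.d. Gaussian noise Z, a sparse weighted adjacency A with spectral radius
bounded below one, and i.i.d. Bernoulli dropout applied to the observed
matrix. Parameter-recovery and robustness experiments therefore need no
external data: the ground truth is the sampled A itself.

Expression is generated directly on the log scale (the scale the model
consumes); values are shifted up by the global minimum and floored at zero
so that dropout zeros sit at the matrix minimum, as in real data. Networks
may contain cycles — only the spectral-radius bound is enforced, since the
inference model imposes no acyclicity constraint either.

Deliberately not emulated: count-level noise (negative binomial),
library-size variation, pseudotime or branching structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .augmentation import DropoutMask, apply_mask, sample_mask
from .data_io import ExpressionMatrix
from .model import AdjacencyMatrix

__all__ = ["SyntheticConfig", "SyntheticWorld", "sample_grn",
           "simulate_expression", "make_world", "write_world"]

_SPECTRAL_CAP = 0.8


@dataclass
class SyntheticConfig:
    """Generator settings.

    Defaults define the reference study condition used throughout the test
    and acceptance experiments: 50 genes, 500 cells, 5% edge density,
    unit-scale weights and noise, and 20% observed dropout.
    """

    n_genes: int = 50
    n_cells: int = 500
    density: float = 0.05
    weight_scale: float = 1.0
    noise_scale: float = 1.0
    dropout_rate: float = 0.2
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must be in (0, 1)")
        if self.weight_scale <= 0 or self.noise_scale <= 0:
            raise ValueError("scales must be positive")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")


@dataclass
class SyntheticWorld:
    """A generated ground-truth network plus clean and observed expression."""

    true_adjacency: AdjacencyMatrix
    tf_names: set[str]
    expression_clean: ExpressionMatrix
    expression_observed: ExpressionMatrix
    dropout_mask: DropoutMask
    config: SyntheticConfig


def _gene_names(m: int) -> list[str]:
    width = len(str(m))
    return [f"g{i:0{width}d}" for i in range(1, m + 1)]


def sample_grn(m: int, density: float, weight_scale: float,
               rng: np.random.Generator) -> tuple[AdjacencyMatrix, set[str]]:
    """Sample a sparse signed network with spectral radius at most 0.8.

    Off-diagonal entries are present independently with probability
    ``density``; weights are uniform in ±[0.5, 1] times ``weight_scale``,
    then globally rescaled if the spectral radius exceeds the cap. TFs are
    the genes with at least one outgoing edge.
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must be in (0, 1)")
    names = _gene_names(m)
    for attempt in range(2):
        present = rng.random((m, m)) < density
        np.fill_diagonal(present, False)
        if present.any():
            break
    else:
        raise ValueError(f"no edges drawn at density {density} (m={m}); "
                         "increase density or gene count")
    magnitude = rng.uniform(0.5, 1.0, size=(m, m)) * weight_scale
    sign = np.where(rng.random((m, m)) < 0.5, -1.0, 1.0)
    weights = present * magnitude * sign
    radius = float(np.abs(np.linalg.eigvals(weights)).max())
    if radius > _SPECTRAL_CAP:
        weights *= _SPECTRAL_CAP / radius
    adj = AdjacencyMatrix(weights, names)
    tf_names = {names[i] for i in np.where(present.any(axis=1))[0]}
    return adj, tf_names


def simulate_expression(adj: AdjacencyMatrix, n: int, noise_scale: float,
                        rng: np.random.Generator) -> ExpressionMatrix:
    """Draw X = Z (I - A)^{-1}, Z ~ N(0, noise_scale^2), shifted nonnegative.

    The raw SEM draw is shifted up by |min| and floored at zero, and the
    result is marked log-space (the generator works directly on the scale
    the model consumes).
    """
    m = adj.n_genes
    names = list(adj.gene_names)
    if n == 0:
        return ExpressionMatrix(np.zeros((0, m)), names, [],
                                is_log_transformed=True)
    radius = float(np.abs(np.linalg.eigvals(adj.weights)).max())
    if radius >= 1.0:
        raise ValueError(f"spectral radius {radius:.3f} >= 1; (I - A) may be singular")
    z = rng.normal(0.0, noise_scale, size=(n, m))
    ia = np.eye(m) - adj.weights
    x = np.linalg.solve(ia.T, z.T).T
    lo = x.min()
    if lo < 0:
        x = x - lo
    x = np.maximum(x, 0.0)
    cells = [f"cell_{i}" for i in range(n)]
    return ExpressionMatrix(x, names, cells, is_log_transformed=True)


def make_world(cfg: SyntheticConfig | None = None, **overrides) -> SyntheticWorld:
    """Generate a full synthetic world, deterministic from ``cfg.seed``."""
    if cfg is None:
        cfg = SyntheticConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    ss = np.random.SeedSequence(cfg.seed)
    grn_rng, expr_rng, drop_rng = map(np.random.default_rng, ss.spawn(3))
    adj, tf_names = sample_grn(cfg.n_genes, cfg.density, cfg.weight_scale, grn_rng)
    clean = simulate_expression(adj, cfg.n_cells, cfg.noise_scale, expr_rng)
    mask = sample_mask(cfg.n_cells, cfg.n_genes, cfg.dropout_rate, drop_rng)
    observed, _ = apply_mask(clean, mask)
    return SyntheticWorld(true_adjacency=adj, tf_names=tf_names,
                          expression_clean=clean, expression_observed=observed,
                          dropout_mask=mask, config=cfg)


def write_world(world: SyntheticWorld, outdir: str | Path) -> dict[str, Path]:
    """Write the world in the formats the readers consume.

    Emits the observed expression (delimited, header of gene names), the
    clean expression, the true edge list (two-column TSV) and the TF list
    (one name per line). Returns the paths.
    """
    from .data_io import write_expression
    from .model import extract_edges

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.csv",
        "expression_clean": outdir / "expression_clean.csv",
        "edges": outdir / "true_edges.tsv",
        "tfs": outdir / "tfs.txt",
    }
    write_expression(world.expression_observed, paths["expression"])
    write_expression(world.expression_clean, paths["expression_clean"])
    edges = extract_edges(world.true_adjacency, threshold=0.0)
    edges[["regulator", "target"]].to_csv(paths["edges"], sep="\t",
                                          header=False, index=False)
    paths["tfs"].write_text("\n".join(sorted(world.tf_names)) + "\n")
    return paths
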