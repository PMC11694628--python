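"""Naive, grid, and combined fusion classifiers with their training loop.

Three architectures:

* **Naive stream** — an MLP over the per-segment tabular feature vector
  (distance, speed, SOG, direction on the unit circle). Hidden widths
  128/64/32 with ReLU, dropout 0.5 after the first two hidden layers,
  2-class softmax head.
* **Grid stream** — a small CNN over the G x G x 1 binary occupancy grid:
  one 3x3 valid convolution with 32 filters, 2x2 max pooling (identity when
  the post-conv map is 1x1, as with G = 3), flatten, then FC 256/64/32 with
  dropout 0.5 after the first FC. Its 32-dim final layer is the stream's
  embedding.
* **Combined** — both streams in fusion mode; their 32-dim embeddings are
  concatenated into a 64-dim vector and passed through FC 256/64/32 and a
  2-class softmax head.

Training follows the reference configuration: Adam at learning rate 0.001
with cross-entropy loss. All randomness (init, dropout, batch order) is
driven by seeds, so identical seeds give bitwise-identical runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = [
    "NaiveStreamSpec",
    "GridStreamSpec",
    "CombinedSpec",
    "TrainingConfig",
    "SpecError",
    "DegenerateTrainingError",
    "NotFittedError",
    "NaiveModel",
    "GridModel",
    "CombinedModel",
    "build_naive_stream",
    "build_grid_stream",
    "build_combined",
    "build_model",
    "specs_for_experiment",
    "train_model",
    "predict_proba",
    "parameter_count",
]


class SpecError(ValueError):
    """Inconsistent architecture specification."""


class DegenerateTrainingError(ValueError):
    """Training data contains fewer than two classes."""


class NotFittedError(RuntimeError):
    """Prediction requested from a model that has not been trained."""


@dataclass(frozen=True)
class NaiveStreamSpec:
    """Tabular-stream MLP. Default 5 inputs: distance, speed, SOG, azimuth_x/y.

    ``input_dim=4`` is the strict variant where direction is a single scaled
    azimuth value instead of the two unit-circle components.
    """

    input_dim: int = 5
    hidden_dims: tuple[int, ...] = (128, 64, 32)
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if len(self.hidden_dims) < 1:
            raise SpecError("need at least one hidden layer")
        if not 0.0 <= self.dropout < 1.0:
            raise SpecError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.input_dim < 1:
            raise SpecError(f"input_dim must be >= 1, got {self.input_dim}")


@dataclass(frozen=True)
class GridStreamSpec:
    """Occupancy-grid CNN stream; the final FC width is the embedding dim."""

    extent_g: int = 3
    conv_filters: int = 32
    kernel: int = 3
    fc_dims: tuple[int, ...] = (256, 64, 32)
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.extent_g < self.kernel:
            raise SpecError(
                f"grid extent {self.extent_g} smaller than conv kernel {self.kernel}"
            )
        if len(self.fc_dims) < 1:
            raise SpecError("need at least one FC layer")

    @property
    def embedding_dim(self) -> int:
        return self.fc_dims[-1]


@dataclass(frozen=True)
class CombinedSpec:
    """Fusion head over the concatenated stream embeddings."""

    fusion_dim: int = 64
    fc_dims: tuple[int, ...] = (256, 64, 32)
    dropout: float = 0.5


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise SpecError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.epochs < 1 or self.batch_size < 1:
            raise SpecError("epochs and batch_size must be >= 1")


def _mlp_body(
    in_dim: int, hidden: tuple[int, ...], dropout: float, rng: np.random.Generator
) -> nn.Sequential:
    """ReLU MLP with dropout after the first two hidden layers."""
    layers: list[nn.Layer] = []
    d = in_dim
    for i, h in enumerate(hidden):
        layers += [nn.Dense(d, h, rng), nn.ReLU()]
        if i < 2 and dropout > 0:
            layers.append(nn.Dropout(dropout, rng))
        d = h
    return nn.Sequential(layers)


class NaiveModel:
    """Tabular stream; standalone (softmax head) or fusion (embedding) mode."""

    kind = "naive"

    def __init__(
        self, spec: NaiveStreamSpec, rng: np.random.Generator, fusion: bool = False
    ) -> None:
        self.spec = spec
        self.body = _mlp_body(spec.input_dim, spec.hidden_dims, spec.dropout, rng)
        self.embedding_dim = spec.hidden_dims[-1]
        self.head = None if fusion else nn.Dense(self.embedding_dim, 2, rng)
        self.fitted = False
        assert self.body.out_shape((spec.input_dim,)) == (self.embedding_dim,)

    def forward(self, x_naive, x_grid, train: bool) -> np.ndarray:
        h = self.body.forward(x_naive, train)
        return self.head.forward(h, train) if self.head is not None else h

    def backward(self, grad) -> None:
        if self.head is not None:
            grad = self.head.backward(grad)
        self.body.backward(grad)

    def embed(self, x_naive, train: bool = False) -> np.ndarray:
        return self.body.forward(x_naive, train)

    def parameters(self):
        ps = self.body.parameters()
        if self.head is not None:
            ps += list(zip(self.head.params, self.head.grads))
        return ps


class GridModel:
    """Occupancy-grid CNN stream; input (N, G, G, 1) channels-last."""

    kind = "grid"

    def __init__(
        self, spec: GridStreamSpec, rng: np.random.Generator, fusion: bool = False
    ) -> None:
        self.spec = spec
        g = spec.extent_g
        layers: list[nn.Layer] = [
            nn.Conv2D(1, spec.conv_filters, spec.kernel, rng),
            nn.ReLU(),
            nn.MaxPool2x2(),
            nn.Flatten(),
        ]
        stem = nn.Sequential(layers)
        flat = stem.out_shape((g, g, 1))[0]
        d = flat
        for i, h in enumerate(spec.fc_dims):
            layers += [nn.Dense(d, h, rng), nn.ReLU()]
            if i == 0 and spec.dropout > 0:
                layers.append(nn.Dropout(spec.dropout, rng))
            d = h
        self.body = nn.Sequential(layers)
        self.embedding_dim = spec.embedding_dim
        self.head = None if fusion else nn.Dense(self.embedding_dim, 2, rng)
        self.fitted = False
        assert self.body.out_shape((g, g, 1)) == (self.embedding_dim,)
        # with G = 3 the valid 3x3 conv yields a 1x1x32 map and pooling is identity
        if g == spec.kernel:
            conv_out = layers[0].out_shape((g, g, 1))
            assert conv_out == (1, 1, spec.conv_filters)

    def forward(self, x_naive, x_grid, train: bool) -> np.ndarray:
        h = self.body.forward(x_grid, train)
        return self.head.forward(h, train) if self.head is not None else h

    def backward(self, grad) -> None:
        if self.head is not None:
            grad = self.head.backward(grad)
        self.body.backward(grad)

    def embed(self, x_grid, train: bool = False) -> np.ndarray:
        return self.body.forward(x_grid, train)

    def parameters(self):
        ps = self.body.parameters()
        if self.head is not None:
            ps += list(zip(self.head.params, self.head.grads))
        return ps


class CombinedModel:
    """Two fusion-mode streams concatenated, refined by an FC stack + softmax."""

    kind = "combined"

    def __init__(
        self,
        naive: NaiveModel,
        grid: GridModel,
        spec: CombinedSpec,
        rng: np.random.Generator,
    ) -> None:
        if naive.head is not None or grid.head is not None:
            raise SpecError("streams must be built in fusion mode (no softmax heads)")
        fusion_in = naive.embedding_dim + grid.embedding_dim
        if fusion_in != spec.fusion_dim:
            raise SpecError(
                f"fusion_dim {spec.fusion_dim} != sum of stream embeddings {fusion_in}"
            )
        self.naive, self.grid, self.spec = naive, grid, spec
        layers: list[nn.Layer] = []
        d = fusion_in
        for i, h in enumerate(spec.fc_dims):
            layers += [nn.Dense(d, h, rng), nn.ReLU()]
            if i == 0 and spec.dropout > 0:
                layers.append(nn.Dropout(spec.dropout, rng))
            d = h
        layers.append(nn.Dense(d, 2, rng))
        self.fusion = nn.Sequential(layers)
        self.fitted = False

    def forward(self, x_naive, x_grid, train: bool) -> np.ndarray:
        en = self.naive.body.forward(x_naive, train)
        eg = self.grid.body.forward(x_grid, train)
        self._split = en.shape[1]
        return self.fusion.forward(np.concatenate([en, eg], axis=1), train)

    def backward(self, grad) -> None:
        dz = self.fusion.backward(grad)
        self.naive.body.backward(dz[:, : self._split])
        self.grid.body.backward(dz[:, self._split :])

    def parameters(self):
        return (
            self.naive.parameters() + self.grid.parameters() + self.fusion.parameters()
        )


Model = NaiveModel | GridModel | CombinedModel


def build_naive_stream(
    spec: NaiveStreamSpec = NaiveStreamSpec(),
    seed: int | np.random.Generator = 0,
    fusion: bool = False,
) -> NaiveModel:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return NaiveModel(spec, rng, fusion=fusion)


def build_grid_stream(
    spec: GridStreamSpec = GridStreamSpec(),
    seed: int | np.random.Generator = 0,
    fusion: bool = False,
) -> GridModel:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return GridModel(spec, rng, fusion=fusion)


def build_combined(
    naive: NaiveModel,
    grid: GridModel,
    spec: CombinedSpec = CombinedSpec(),
    seed: int | np.random.Generator = 0,
) -> CombinedModel:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return CombinedModel(naive, grid, spec, rng)


def build_model(
    kind: str,
    seed: int = 0,
    naive_spec: NaiveStreamSpec = NaiveStreamSpec(),
    grid_spec: GridStreamSpec = GridStreamSpec(),
    combined_spec: CombinedSpec | None = None,
) -> Model:
    """Build a classifier of the given kind from one seed."""
    rng = np.random.default_rng(seed)
    if kind == "naive":
        return NaiveModel(naive_spec, rng)
    if kind == "grid":
        return GridModel(grid_spec, rng)
    if kind == "combined":
        naive = NaiveModel(naive_spec, rng, fusion=True)
        grid = GridModel(grid_spec, rng, fusion=True)
        spec = combined_spec or CombinedSpec(
            fusion_dim=naive.embedding_dim + grid.embedding_dim
        )
        return CombinedModel(naive, grid, spec, rng)
    raise SpecError(f"unknown model kind {kind!r}")


def specs_for_experiment(
    node_config: tuple[int, ...],
    hidden_layers: int,
    input_dim: int = 5,
    extent_g: int = 3,
) -> tuple[NaiveStreamSpec, GridStreamSpec, CombinedSpec]:
    """Map a (width triple, depth) experiment row onto concrete stream specs.

    The first ``hidden_layers`` entries of the node configuration become the
    hidden widths of the naive MLP and the FC widths of both the grid stream
    and the fusion stack, so one row reconfigures all three approaches
    consistently.
    """
    if not 1 <= hidden_layers <= len(node_config):
        raise SpecError(
            f"hidden_layers {hidden_layers} incompatible with node config {node_config}"
        )
    dims = tuple(node_config[:hidden_layers])
    naive = NaiveStreamSpec(input_dim=input_dim, hidden_dims=dims)
    grid = GridStreamSpec(extent_g=extent_g, fc_dims=dims)
    combined = CombinedSpec(fusion_dim=2 * dims[-1], fc_dims=dims)
    return naive, grid, combined


def parameter_count(model: Model) -> int:
    return int(sum(p.size for p, _ in model.parameters()))


def _inputs_for(model: Model, x_naive, x_grid):
    if model.kind == "naive" and x_naive is None:
        raise SpecError("naive model needs tabular inputs")
    if model.kind == "grid" and x_grid is None:
        raise SpecError("grid model needs occupancy-grid inputs")
    if model.kind == "combined" and (x_naive is None or x_grid is None):
        raise SpecError("combined model needs both input streams")
    return x_naive, x_grid


def train_model(
    model: Model,
    x_naive: np.ndarray | None,
    x_grid: np.ndarray | None,
    y: np.ndarray,
    cfg: TrainingConfig = TrainingConfig(),
) -> list[float]:
    """Minibatch Adam / cross-entropy training; returns per-epoch mean loss.

    Deterministic given the config seed (batch order) and the model's
    construction seed (init and dropout masks).
    """
    x_naive, x_grid = _inputs_for(model, x_naive, x_grid)
    y = np.asarray(y, dtype=np.int64)
    if np.unique(y).size < 2:
        raise DegenerateTrainingError("training data must contain both classes")
    if x_naive is not None:
        # standardize tabular features on the training set; the fitted scale
        # travels with the model and is re-applied at prediction time
        mu = x_naive.mean(axis=0)
        sd = x_naive.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        model.naive_scaler = (mu, sd)
        x_naive = (x_naive - mu) / sd
    n = y.shape[0]
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history: list[float] = []
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            b = perm[s : s + cfg.batch_size]
            bn = x_naive[b] if x_naive is not None else None
            bg = x_grid[b] if x_grid is not None else None
            logits = model.forward(bn, bg, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[b])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    model.fitted = True
    model.training_config = asdict(cfg)
    return history


def predict_proba(
    model: Model,
    x_naive: np.ndarray | None = None,
    x_grid: np.ndarray | None = None,
    batch_size: int = 4096,
) -> np.ndarray:
    """Class probabilities (N, 2), rows summing to 1. Requires a fitted model."""
    if not getattr(model, "fitted", False):
        raise NotFittedError("model must be trained before predicting")
    x_naive, x_grid = _inputs_for(model, x_naive, x_grid)
    scaler = getattr(model, "naive_scaler", None)
    if x_naive is not None and scaler is not None:
        x_naive = (x_naive - scaler[0]) / scaler[1]
    n = (x_naive if x_naive is not None else x_grid).shape[0]
    out = []
    for s in range(0, n, batch_size):
        bn = x_naive[s : s + batch_size] if x_naive is not None else None
        bg = x_grid[s : s + batch_size] if x_grid is not None else None
        out.append(nn.softmax(model.forward(bn, bg, train=False)))
    return np.concatenate(out, axis=0)
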