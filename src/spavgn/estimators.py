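"""scikit-learn-style estimator wrappers.

`SpaVGNImputer` packages the self-supervised training loop behind the usual
``fit`` / ``predict`` surface: ``fit(grid)`` builds the down-sample training
pair for the grid's lattice dialect and trains the network; ``predict(grid)``
(alias ``transform``) returns the 2x super-resolved grid.  Fitted state
lives in trailing-underscore attributes, and ``get_params``/``set_params``
work through ``BaseEstimator``, so the classes compose with sklearn's
model-selection utilities.  The underlying functional API is in
:mod:`spavgn.training` and :mod:`spavgn.baselines`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .baselines import BaselineSpec, interpolate
from .grid_io import ExpressionGrid
from .model import ModelConfig
from .protocol import make_training_pair
from .training import TrainConfig, enhance, train

__all__ = ["SpaVGNImputer", "BaselineInterpolator"]


class SpaVGNImputer(BaseEstimator):
    """2x spatial-transcriptomics super-resolution estimator.

    Parameters mirror :class:`spavgn.model.ModelConfig` and
    :class:`spavgn.training.TrainConfig`; see those classes for semantics.

    Attributes (after ``fit``)
    --------------------------
    state_ : NetworkState
        Trained parameters.
    loss_trace_ : list of float
        Per-epoch masked-MSE values.
    config_ : ModelConfig
    train_config_ : TrainConfig
    """

    def __init__(self, cnn_channels=(32, 32), cnn_kernel=3, patch_size=2,
                 embed_dim=128, n_heads=4, n_blocks=4, mlp_ratio=2,
                 gnn_sigma=1.0, gnn_k=4, gnn_epsilon=1e-8,
                 use_pe=True, use_gnn=True,
                 epochs=500, learning_rate=1e-3, weight_decay=0.0,
                 loss_norm="4n", seed=0):
        self.cnn_channels = cnn_channels
        self.cnn_kernel = cnn_kernel
        self.patch_size = patch_size
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.n_blocks = n_blocks
        self.mlp_ratio = mlp_ratio
        self.gnn_sigma = gnn_sigma
        self.gnn_k = gnn_k
        self.gnn_epsilon = gnn_epsilon
        self.use_pe = use_pe
        self.use_gnn = use_gnn
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.loss_norm = loss_norm
        self.seed = seed

    def _configs(self) -> tuple[ModelConfig, TrainConfig]:
        mc = ModelConfig(
            cnn_channels=tuple(self.cnn_channels), cnn_kernel=self.cnn_kernel,
            patch_size=self.patch_size, embed_dim=self.embed_dim,
            n_heads=self.n_heads, n_blocks=self.n_blocks,
            mlp_ratio=self.mlp_ratio, gnn_sigma=self.gnn_sigma,
            gnn_k=self.gnn_k, gnn_epsilon=self.gnn_epsilon,
            use_pe=self.use_pe, use_gnn=self.use_gnn, seed=self.seed)
        tc = TrainConfig(epochs=self.epochs, learning_rate=self.learning_rate,
                         weight_decay=self.weight_decay,
                         loss_norm=self.loss_norm, seed=self.seed)
        return mc, tc

    def fit(self, X: ExpressionGrid, y=None) -> "SpaVGNImputer":
        mc, tc = self._configs()
        pair = make_training_pair(X)
        self.state_, self.loss_trace_ = train(pair, mc, tc)
        self.config_, self.train_config_ = mc, tc
        return self

    def predict(self, X: ExpressionGrid) -> ExpressionGrid:
        if not hasattr(self, "state_"):
            raise RuntimeError("SpaVGNImputer is not fitted")
        return enhance(X, self.state_, self.config_)

    transform = predict

    def fit_transform(self, X: ExpressionGrid, y=None) -> ExpressionGrid:
        return self.fit(X).predict(X)


class BaselineInterpolator(BaseEstimator):
    """Classical interpolation of masked lattice positions.

    ``fit`` stores the low-resolution grid; ``predict(targets)`` returns a
    (genes, targets) matrix of interpolated expression at original-grid
    coordinates.  ``method`` is one of nearest / linear / cubic / nedi.
    """

    def __init__(self, method: str = "linear"):
        self.method = method

    def fit(self, X: ExpressionGrid, y=None) -> "BaselineInterpolator":
        BaselineSpec(self.method)        # validate early
        self.low_ = X
        return self

    def predict(self, targets) -> np.ndarray:
        if not hasattr(self, "low_"):
            raise RuntimeError("BaselineInterpolator is not fitted")
        res = interpolate(self.low_, list(targets), BaselineSpec(self.method))
        self.outside_hull_ = res.outside_hull
        return res.predictions
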