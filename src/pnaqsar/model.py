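"""The multitask regressor: PNA graph branch + fingerprint deep branch.

`PNAMultitaskRegressor` is a scikit-learn-style estimator.  ``fit`` takes a
list of SMILES and an ``(n, T)`` label matrix with NaN marking missing task
labels; ``predict`` returns an ``(n, T)`` matrix of predicted pIC50 for every
task regardless of which labels were observed.  All layers are shared across
tasks except the final linear heads (hard parameter sharing); the training
loss is the sum over tasks of the per-task mean squared error over observed
labels in the batch, minimized with Adam + L2 and early stopping on a
validation set.
"""

from __future__ import annotations

import logging
import pickle
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import __version__ as _pkg_version
from ._autograd import Parameter, Tensor, concat, gather_rows, segment_mean, segment_sum
from .chem import (
    DEFAULT_FAMILIES,
    EDGE_DIM,
    NODE_DIM,
    CanonicalMolecule,
    FeatureReducer,
    MolGraph,
    canonicalize_desalt,
    fingerprint_block,
    smiles_to_graph,
)
from .nn import (
    MLP,
    Adam,
    EarlyStopping,
    Linear,
    ScalerParams,
    compute_delta,
    masked_loss_tensor,
    masked_multitask_loss,
    pna_aggregate_batch,
    scaler_columns,
)

logger = logging.getLogger(__name__)

RTK_TARGETS = ("ALK", "EGFR", "ERBB2", "ERBB4", "MET", "RET", "ROS1")

__all__ = ["PNAMultitaskRegressor", "RTK_TARGETS", "masked_multitask_loss"]


# ---------------------------------------------------------------------------
# featurized data and batching
# ---------------------------------------------------------------------------

@dataclass
class _Featurized:
    graphs: list[MolGraph]
    reduced: np.ndarray            # (n, d) PCA-reduced fingerprint block
    ok: np.ndarray                 # (n,) parse success per input row
    smiles: list[str]


def _collate(graphs: Sequence[MolGraph], scaler: ScalerParams):
    """Stack molecule graphs into one disjoint-union graph."""
    node_x, edge_src, edge_dst, edge_x, graph_id = [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        node_x.append(g.node_features)
        if g.n_edges:
            edge_src.append(g.edges[:, 0] + offset)
            edge_dst.append(g.edges[:, 1] + offset)
            edge_x.append(g.edge_features)
        graph_id.append(np.full(g.n_nodes, gi, dtype=np.int64))
        offset += g.n_nodes
    node_x = np.concatenate(node_x)
    graph_id = np.concatenate(graph_id)
    if edge_src:
        edge_src = np.concatenate(edge_src)
        edge_dst = np.concatenate(edge_dst)
        edge_x = np.concatenate(edge_x)
    else:  # batch of single atoms
        edge_src = np.zeros(0, dtype=np.int64)
        edge_dst = np.zeros(0, dtype=np.int64)
        edge_x = np.zeros((0, EDGE_DIM))
    degrees = np.concatenate([g.degrees for g in graphs])
    return {
        "node_x": node_x,
        "edge_src": edge_src,
        "edge_dst": edge_dst,
        "edge_x": edge_x,
        "graph_id": graph_id,
        "n_graphs": len(graphs),
        "scaler_cols": scaler_columns(degrees, scaler),
    }


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class _PNANetwork:
    """Forward graph of the fused model; pure NumPy + autodiff tape."""

    def __init__(self, *, n_tasks: int, dnn_in: int, hidden_dim: int,
                 n_pna_layers: int, mlp_hidden: int, fc_widths: Sequence[int],
                 dnn_widths: Sequence[int], dropout: float, pooling: str,
                 std_eps: float, rng: np.random.Generator):
        self.dropout = dropout
        self.pooling = pooling
        self.std_eps = std_eps
        self.msg_mlps: list[MLP] = []
        self.upd_mlps: list[MLP] = []
        h = NODE_DIM
        for _ in range(n_pna_layers):
            self.msg_mlps.append(MLP((h + EDGE_DIM + h, mlp_hidden), rng))
            self.upd_mlps.append(MLP((h + 12 * mlp_hidden, hidden_dim), rng))
            h = hidden_dim
        self.post_pool = MLP((h, hidden_dim), rng)
        self.dnn = MLP((dnn_in, *dnn_widths), rng)
        fc_in = hidden_dim + dnn_widths[-1]
        self.fc = MLP((fc_in, *fc_widths), rng)
        self.heads = Linear(fc_widths[-1], n_tasks, rng)  # per-task final layers

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for m in (*self.msg_mlps, *self.upd_mlps, self.post_pool, self.dnn, self.fc):
            params.extend(m.parameters())
        params.extend(self.heads.parameters())
        return params

    def _maybe_dropout(self, x: Tensor, training: bool,
                       rng: np.random.Generator | None) -> Tensor:
        if not training or self.dropout <= 0:
            return x
        keep = 1.0 - self.dropout
        mask = (rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)

    def forward(self, batch: dict, reduced: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        x = Tensor(batch["node_x"])
        edge_x = Tensor(batch["edge_x"])
        n_nodes = batch["node_x"].shape[0]
        for msg_mlp, upd_mlp in zip(self.msg_mlps, self.upd_mlps):
            if batch["edge_src"].size:
                x_dst = gather_rows(x, batch["edge_dst"])
                x_src = gather_rows(x, batch["edge_src"])
                msg = msg_mlp(concat([x_dst, edge_x, x_src]))
                agg = pna_aggregate_batch(
                    msg, batch["edge_dst"], n_nodes, batch["scaler_cols"], self.std_eps
                )
            else:
                width = 12 * self.msg_mlps[0].layers[-1].b.data.shape[0]
                agg = Tensor(np.zeros((n_nodes, width)))
            x = upd_mlp(concat([x, agg]))
            x = self._maybe_dropout(x, training, rng)
        pool = segment_sum if self.pooling == "sum" else segment_mean
        g = pool(x, batch["graph_id"], batch["n_graphs"])
        g = self.post_pool(g)
        d = self.dnn(Tensor(reduced))
        d = self._maybe_dropout(d, training, rng)
        fused = self.fc(concat([g, d]))
        fused = self._maybe_dropout(fused, training, rng)
        return self.heads(fused)

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p.data = w.copy()


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class PNAMultitaskRegressor(BaseEstimator, RegressorMixin):
    """Multitask pIC50 regressor fusing a PNA graph branch with a fingerprint DNN.

    Parameters
    ----------
    targets : tuple of str
        Ordered task names; default the seven receptor tyrosine kinases.
    hidden_dim, n_pna_layers, mlp_hidden, fc_widths, dnn_widths, dropout
        Architecture of the shared trunk.  The final linear layer holds one
        head per task (hard parameter sharing).
    learning_rate, weight_decay, batch_size, max_epochs
        Adam + L2 training schedule.
    patience, window
        Early stopping: halt after `patience` epochs without improvement of
        the validation loss or of its `window`-epoch moving average; the
        weights of the best-validation epoch are restored.
    variance_target : float
        Fraction of fingerprint variance the PCA reducer must retain.
    fingerprint_families : tuple of str
        Fingerprint roster; recorded in the checkpoint for reproducibility.
    validation_fraction : float
        Fraction of the training data held out for early stopping when no
        explicit validation set is passed to ``fit``.
    """

    def __init__(
        self,
        targets: Sequence[str] = RTK_TARGETS,
        hidden_dim: int = 48,
        n_pna_layers: int = 1,
        mlp_hidden: int = 16,
        fc_widths: Sequence[int] = (64,),
        dnn_widths: Sequence[int] = (96,),
        dropout: float = 0.0,
        learning_rate: float = 5e-3,
        weight_decay: float = 1e-5,
        batch_size: int = 32,
        max_epochs: int = 100,
        patience: int = 10,
        window: int = 10,
        variance_target: float = 0.95,
        fingerprint_families: Sequence[str] = DEFAULT_FAMILIES,
        pooling: str = "sum",
        std_eps: float = 1e-8,
        validation_fraction: float = 0.1,
        seed: int = 0,
        verbose: int = 0,
    ):
        self.targets = targets
        self.hidden_dim = hidden_dim
        self.n_pna_layers = n_pna_layers
        self.mlp_hidden = mlp_hidden
        self.fc_widths = fc_widths
        self.dnn_widths = dnn_widths
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.window = window
        self.variance_target = variance_target
        self.fingerprint_families = fingerprint_families
        self.pooling = pooling
        self.std_eps = std_eps
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.verbose = verbose

    # -- featurization ------------------------------------------------------

    def _featurize(self, smiles: Sequence[str], reducer: FeatureReducer | None,
                   strict: bool) -> tuple[_Featurized, list]:
        mols = [canonicalize_desalt(s) for s in smiles]
        ok = np.array([m.parse_ok for m in mols])
        if strict and not ok.all():
            bad = [s for s, o in zip(smiles, ok) if not o]
            raise ValueError(f"unparsable SMILES in training input: {bad[:5]}")
        graphs, blocks = [], []
        for m in mols:
            if m.parse_ok:
                graphs.append(smiles_to_graph(m))
                blocks.append(fingerprint_block(m, self.fingerprint_families))
            else:
                graphs.append(None)
                blocks.append(None)
        good_blocks = [b for b in blocks if b is not None]
        if reducer is None:
            reducer = FeatureReducer(self.variance_target).fit(good_blocks)
        if good_blocks:
            Z_good = reducer.transform(good_blocks)
            reduced = np.zeros((len(smiles), Z_good.shape[1]))
            reduced[ok] = Z_good
        else:
            reduced = np.zeros((len(smiles), reducer.n_components_))
        feats = _Featurized(graphs=graphs, reduced=reduced, ok=ok,
                            smiles=[m.smiles for m in mols])
        return feats, reducer

    # -- fitting ------------------------------------------------------------

    def fit(self, X: Sequence[str], y, X_val: Sequence[str] | None = None,
            y_val=None):
        """Fit on SMILES ``X`` and label matrix ``y`` (NaN = missing task label)."""
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 1:
            y = y[:, None]
        targets = tuple(self.targets)
        if y.shape[1] != len(targets):
            raise ValueError(
                f"y has {y.shape[1]} columns but {len(targets)} targets configured"
            )
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.seed)

        if X_val is None:
            idx = rng.permutation(len(X))
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            X_tr = [X[i] for i in tr_idx]
            y_tr = y[tr_idx]
            X_val = [X[i] for i in val_idx]
            y_val = y[val_idx]
        else:
            X_tr, y_tr = list(X), y
            y_val = np.asarray(y_val, dtype=np.float64)
            if y_val.ndim == 1:
                y_val = y_val[:, None]

        train_feats, reducer = self._featurize(X_tr, None, strict=True)
        val_feats, _ = self._featurize(X_val, reducer, strict=True)
        scaler = compute_delta(train_feats.graphs)

        # standardize the reduced fingerprint components (train statistics)
        mu = train_feats.reduced.mean(axis=0)
        sd = train_feats.reduced.std(axis=0)
        sd[sd == 0] = 1.0
        self._feat_mu_, self._feat_sd_ = mu, sd
        train_feats.reduced = (train_feats.reduced - mu) / sd
        val_feats.reduced = (val_feats.reduced - mu) / sd

        net = _PNANetwork(
            n_tasks=len(targets), dnn_in=train_feats.reduced.shape[1],
            hidden_dim=self.hidden_dim, n_pna_layers=self.n_pna_layers,
            mlp_hidden=self.mlp_hidden, fc_widths=tuple(self.fc_widths),
            dnn_widths=tuple(self.dnn_widths), dropout=self.dropout,
            pooling=self.pooling, std_eps=self.std_eps, rng=rng,
        )
        opt = Adam(net.parameters(), lr=self.learning_rate,
                   weight_decay=self.weight_decay)

        mask_tr = ~np.isnan(y_tr)
        if not mask_tr.any():
            raise ValueError("no observed labels in the training set")
        mask_val = ~np.isnan(y_val)
        val_batch = _collate(val_feats.graphs, scaler)

        n = len(X_tr)
        best_weights = net.get_weights()
        monitor = EarlyStopping(patience=self.patience, window=self.window)
        train_losses: list[float] = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)  # mixed batches of random task order
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, self.batch_size):
                sel = order[start:start + self.batch_size]
                if not mask_tr[sel].any():
                    continue
                batch = _collate([train_feats.graphs[i] for i in sel], scaler)
                pred = net.forward(batch, train_feats.reduced[sel],
                                   training=True, rng=rng)
                loss = masked_loss_tensor(pred, y_tr[sel], mask_tr[sel])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            val_pred = net.forward(val_batch, val_feats.reduced).data
            val_loss = masked_multitask_loss(val_pred, np.where(mask_val, y_val, 0.0),
                                             mask_val)
            train_losses.append(epoch_loss / max(n_batches, 1))
            if self.verbose:
                logger.info("epoch %d train %.4f val %.4f", epoch,
                            train_losses[-1], val_loss)
            should_stop = monitor.update(val_loss)
            if monitor.best_index == epoch:
                best_weights = net.get_weights()
            if should_stop:
                break
        net.set_weights(best_weights)

        self.network_ = net
        self.reducer_ = reducer
        self.scaler_ = scaler
        self.targets_ = targets
        self.roster_ = tuple(self.fingerprint_families)
        self.training_log_ = {
            "train_loss": train_losses,
            "val_loss": monitor.losses,
            "best_epoch": int(monitor.best_index),
            "n_epochs_run": len(monitor.losses),
        }
        self.n_features_reduced_ = train_feats.reduced.shape[1]
        return self

    # -- prediction ---------------------------------------------------------

    def predict(self, X: Sequence[str]) -> np.ndarray:
        """Predict (n, T) pIC50; rows for unparsable SMILES are NaN."""
        check_is_fitted(self, "network_")
        if len(X) == 0:
            return np.zeros((0, len(self.targets_)))
        feats, _ = self._featurize(X, self.reducer_, strict=False)
        feats.reduced = (feats.reduced - self._feat_mu_) / self._feat_sd_
        out = np.full((len(X), len(self.targets_)), np.nan)
        good = np.flatnonzero(feats.ok)
        if good.size:
            batch = _collate([feats.graphs[i] for i in good], self.scaler_)
            pred = self.network_.forward(batch, feats.reduced[good]).data
            out[good] = pred
        return out

    def predict_frame(self, X: Sequence[str]):
        """DataFrame of predictions with a per-row parse status column."""
        import pandas as pd

        pred = self.predict(X)
        df = pd.DataFrame(pred, columns=[f"pIC50_{t}" for t in self.targets_])
        df.insert(0, "smiles", list(X))
        df["status"] = np.where(np.isnan(pred).all(axis=1), "parse_error", "ok")
        return df

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Write a single checkpoint archive (weights + reducer + roster + config)."""
        check_is_fitted(self, "network_")
        payload = {
            "format": "pnaqsar-checkpoint-v1",
            "package_version": _pkg_version,
            "params": self.get_params(),
            "weights": self.network_.get_weights(),
            "delta": self.scaler_.delta,
            "reducer": self.reducer_,
            "roster": self.roster_,
            "targets": self.targets_,
            "training_log": self.training_log_,
            "n_features_reduced": self.n_features_reduced_,
            "feature_scale": (self._feat_mu_, self._feat_sd_),
            "ad_params": getattr(self, "ad_params_", None),
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path, expected_targets: Sequence[str] | None = None,
             expected_roster: Sequence[str] | None = None) -> "PNAMultitaskRegressor":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format") != "pnaqsar-checkpoint-v1":
            raise ValueError("not a pnaqsar checkpoint")
        if expected_targets is not None and tuple(expected_targets) != tuple(payload["targets"]):
            raise ValueError(
                f"checkpoint target order {payload['targets']} does not match "
                f"expected {tuple(expected_targets)}"
            )
        if expected_roster is not None and tuple(expected_roster) != tuple(payload["roster"]):
            raise ValueError("checkpoint fingerprint roster mismatch")
        est = cls(**payload["params"])
        est.targets_ = tuple(payload["targets"])
        est.roster_ = tuple(payload["roster"])
        if tuple(est.fingerprint_families) != est.roster_:
            raise ValueError("checkpoint roster inconsistent with stored config")
        est.reducer_ = payload["reducer"]
        est.scaler_ = ScalerParams(delta=payload["delta"])
        est.training_log_ = payload["training_log"]
        est.n_features_reduced_ = payload["n_features_reduced"]
        est._feat_mu_, est._feat_sd_ = payload["feature_scale"]
        rng = np.random.default_rng(0)
        net = _PNANetwork(
            n_tasks=len(est.targets_), dnn_in=est.n_features_reduced_,
            hidden_dim=est.hidden_dim, n_pna_layers=est.n_pna_layers,
            mlp_hidden=est.mlp_hidden, fc_widths=tuple(est.fc_widths),
            dnn_widths=tuple(est.dnn_widths), dropout=est.dropout,
            pooling=est.pooling, std_eps=est.std_eps, rng=rng,
        )
        net.set_weights(payload["weights"])
        est.network_ = net
        if payload.get("ad_params") is not None:
            est.ad_params_ = payload["ad_params"]
        return est
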