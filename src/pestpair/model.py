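"""Model/Results interface for fitting the predator-pest recognizer.

:class:`InsectPairModel` binds data (in-memory arrays or a generated
manifest) to a network specification; :meth:`InsectPairModel.fit` runs the
training loop (AdamW, cosine-annealed learning rate, early stopping on
validation loss) and returns an :class:`InsectPairResults` carrying the
fitted parameters, per-epoch history, evaluation helpers and a ``summary()``
table.

Default training hyperparameters: initial
learning rate 1e-4 with cosine annealing, batch size 32, early stopping
after 10 epochs without a validation-loss improvement of at least 1e-4, and
the composite objective ``L_bce + 0.4 * L_pair``. Both loss terms use the
sum-over-terms reduction that their printed forms prescribe (the pair
weight 0.4 is calibrated to that scale); a mean reduction is available via
``reduction="mean"``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import BackboneConfig
from .coattention import CoAttentionNet, cooccurrence_diagnostic
from .losses import (
    DEFAULT_LAMBDA,
    bce_loss,
    make_pair_set,
    pair_indicators,
    pairwise_matching_loss,
    total_loss,
)
from .metrics import DecisionRule, MetricsBundle, classification_metrics, pair_metrics
from .nn import AdamW, Tensor, cosine_lr
from .synthetic import manifest_arrays

__all__ = ["TrainConfig", "InsectPairModel", "InsectPairResults"]


@dataclass
class TrainConfig:
    """Optimisation settings.

    ``mixed_precision`` is accepted for config compatibility but inert: the
    numpy core computes uniformly in float32. ``repeats`` is the number of
    seed replicates an experiment driver should average over; a single
    ``fit()`` always performs one run at ``seed``.
    """

    lr_init: float = 1e-4
    weight_decay: float = 0.01
    epochs: int = 30
    batch_size: int = 32
    grad_accum_steps: int = 1
    lambda_pair: float = DEFAULT_LAMBDA
    pair_mode: str = "all"
    reduction: str = "sum"
    early_stop_patience: int = 10
    early_stop_min_delta: float = 1e-4
    mixed_precision: bool = False
    repeats: int = 5
    seed: int = 0
    verbose: bool = False

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.grad_accum_steps < 1:
            raise ValueError("counts must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.lambda_pair < 0:
            raise ValueError("lambda must be >= 0")

    def replicate_seeds(self) -> list[int]:
        """The seed list a repeated experiment runs over."""
        return [self.seed + 2 * k for k in range(self.repeats)]


def _normalize(images: np.ndarray) -> np.ndarray:
    x = images.astype(np.float32) / 255.0
    return (x - 0.5) / 0.5


def _to_nchw(images: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(_normalize(images), (0, 3, 1, 2)))


class InsectPairModel:
    """Multi-label recognizer bound to training (and optional validation) data.

    Parameters
    ----------
    train_images, train_labels
        uint8 scenes [n, S, S, 3] and multi-hot labels [n, C].
    val_images, val_labels
        Optional held-out data monitored for early stopping.
    config
        Backbone configuration; defaults to the desk profile.
    attention_mode
        "co" (full model), "self" (spatial attention only) or "none".
    schema
        Optional category schema (enables predator-pest pair mode and
        named reports).
    """

    def __init__(
        self,
        train_images: np.ndarray,
        train_labels: np.ndarray,
        val_images: np.ndarray | None = None,
        val_labels: np.ndarray | None = None,
        config: BackboneConfig | None = None,
        attention_mode: str = "co",
        schema=None,
    ):
        if len(train_images) == 0:
            raise ValueError("empty training set")
        self.train_images = np.asarray(train_images)
        self.train_labels = np.asarray(train_labels)
        self.val_images = None if val_images is None else np.asarray(val_images)
        self.val_labels = None if val_labels is None else np.asarray(val_labels)
        self.config = config or BackboneConfig.desk()
        self.attention_mode = attention_mode
        self.schema = schema
        self.n_labels = self.train_labels.shape[1]

    @classmethod
    def from_manifest(
        cls,
        train_manifest: str | Path,
        val_manifest: str | Path | None = None,
        **kwargs,
    ) -> "InsectPairModel":
        xtr, ytr = manifest_arrays(train_manifest)
        xva, yva = (None, None)
        if val_manifest is not None:
            xva, yva = manifest_arrays(val_manifest)
        return cls(xtr, ytr, xva, yva, **kwargs)

    # ------------------------------------------------------------------ fit
    def fit(self, train_config: TrainConfig | None = None) -> "InsectPairResults":
        cfg = train_config or TrainConfig()
        rng = np.random.default_rng(cfg.seed)
        net = CoAttentionNet(
            self.config, self.n_labels, attention_mode=self.attention_mode, rng=rng
        )
        pair_set = make_pair_set(self.n_labels, cfg.pair_mode, self.schema)
        opt = AdamW(net.parameters(), lr=cfg.lr_init, weight_decay=cfg.weight_decay)

        x_all = _to_nchw(self.train_images)
        y_all = self.train_labels.astype(np.float32)
        y_pair_all = pair_indicators(self.train_labels, pair_set)
        n = len(x_all)
        steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
        total_steps = steps_per_epoch * cfg.epochs

        history = []
        best_val = np.inf
        best_state = None
        best_epoch = -1
        since_improve = 0
        step = 0
        for epoch in range(cfg.epochs):
            net.train()
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                opt.lr = cosine_lr(cfg.lr_init, step, total_steps)
                logits = net(Tensor(x_all[idx]))
                p_hat = logits.sigmoid()
                l_bce = bce_loss(p_hat, y_all[idx], reduction=cfg.reduction)
                l_pair = pairwise_matching_loss(
                    p_hat, y_pair_all[idx], pair_set, reduction=cfg.reduction
                )
                total, breakdown = total_loss(l_bce, l_pair, cfg.lambda_pair)
                if not np.isfinite(total.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} step {step}: "
                        f"bce={breakdown.l_bce}, pair={breakdown.l_pair}"
                    )
                scaled = total * (1.0 / cfg.grad_accum_steps)
                scaled.backward()
                if (step + 1) % cfg.grad_accum_steps == 0:
                    opt.step()
                    opt.zero_grad()
                epoch_losses.append(breakdown.l_total)
                step += 1

            record = {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "lr": opt.lr,
            }
            if self.val_images is not None:
                val_loss = self._eval_loss(net, pair_set, cfg)
                record["val_loss"] = val_loss
                if val_loss < best_val - cfg.early_stop_min_delta:
                    best_val = val_loss
                    best_state = net.state_dict()
                    best_epoch = epoch
                    since_improve = 0
                else:
                    since_improve += 1
            history.append(record)
            if cfg.verbose:
                print(f"epoch {epoch}: " + ", ".join(f"{k}={v:.5f}" for k, v in record.items() if k != "epoch"))
            if self.val_images is not None and since_improve >= cfg.early_stop_patience:
                break

        if best_state is not None:
            net.load_state_dict(best_state)
        else:
            best_epoch = len(history) - 1
        net.eval()
        return InsectPairResults(
            model=self,
            net=net,
            train_config=cfg,
            history=pd.DataFrame(history),
            best_epoch=best_epoch,
            pair_set=pair_set,
        )

    def _eval_loss(self, net: CoAttentionNet, pair_set, cfg: TrainConfig) -> float:
        net.eval()
        x = _to_nchw(self.val_images)
        y = self.val_labels.astype(np.float32)
        y_pair = pair_indicators(self.val_labels, pair_set)
        losses = []
        weights = []
        for start in range(0, len(x), cfg.batch_size):
            sl = slice(start, start + cfg.batch_size)
            p = net.predict_proba(x[sl], batch_size=cfg.batch_size)
            l_bce = bce_loss(p, y[sl], reduction=cfg.reduction)
            l_pair = pairwise_matching_loss(p, y_pair[sl], pair_set, reduction=cfg.reduction)
            losses.append(l_bce + cfg.lambda_pair * l_pair)
            weights.append(len(y[sl]))
        return float(np.average(losses, weights=weights))


@dataclass
class InsectPairResults:
    """Fitted recognizer: parameters, history and evaluation utilities."""

    model: InsectPairModel
    net: CoAttentionNet
    train_config: TrainConfig
    history: pd.DataFrame
    best_epoch: int
    pair_set: object
    rule: DecisionRule = field(default_factory=DecisionRule)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(_to_nchw(np.asarray(images)))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.rule.decide(self.predict_proba(images))

    def evaluate(
        self, images: np.ndarray | None = None, labels: np.ndarray | None = None
    ) -> MetricsBundle:
        if images is None:
            images, labels = self.model.val_images, self.model.val_labels
        if images is None:
            raise ValueError("no evaluation data available")
        return classification_metrics(self.predict_proba(images), labels, self.rule)

    def evaluate_pairs(
        self,
        images: np.ndarray | None = None,
        labels: np.ndarray | None = None,
        pairs=None,
        pair_names=None,
    ) -> pd.DataFrame:
        if images is None:
            images, labels = self.model.val_images, self.model.val_labels
        if images is None:
            raise ValueError("no evaluation data available")
        pairs = pairs if pairs is not None else self.pair_set
        return pair_metrics(self.predict_proba(images), labels, pairs, self.rule, pair_names)

    def attention_maps(self, images: np.ndarray) -> np.ndarray:
        return self.net.attention_maps(_to_nchw(np.asarray(images)))

    def label_cooccurrence(self, images: np.ndarray) -> np.ndarray:
        """Diagnostic CL x CL cosine-similarity matrix of fused label vectors."""
        self.predict_proba(images)
        if getattr(self.net.head, "last_fused", None) is None:
            raise ValueError("co-occurrence diagnostic requires the co-attention head")
        return cooccurrence_diagnostic(self.net.head.last_fused)

    # -------------------------------------------------------------- summary
    def summary(self) -> str:
        buf = io.StringIO()
        cfg, tc = self.model.config, self.train_config
        n_params = sum(p.data.size for p in self.net.parameters())
        buf.write("InsectPairModel Results\n")
        buf.write("=" * 56 + "\n")
        rows = [
            ("profile", cfg.profile),
            ("attention mode", self.net.attention_mode),
            ("labels", self.model.n_labels),
            ("parameters", n_params),
            ("train images", len(self.model.train_images)),
            ("val images", 0 if self.model.val_images is None else len(self.model.val_images)),
            ("epochs run", len(self.history)),
            ("best epoch", self.best_epoch),
            ("lambda (pair loss)", tc.lambda_pair),
            ("lr init / schedule", f"{tc.lr_init:g} / cosine"),
            ("batch size", tc.batch_size),
        ]
        for k, v in rows:
            buf.write(f"{k:<24}{v}\n")
        if "val_loss" in self.history.columns and len(self.history):
            buf.write(f"{'final val loss':<24}{self.history['val_loss'].iloc[-1]:.5f}\n")
        if self.model.val_images is not None:
            m = self.evaluate()
            buf.write("-" * 56 + "\n")
            buf.write("validation metrics (%, macro)\n")
            for k, v in m.as_series().items():
                buf.write(f"{k:<24}{v:.2f}\n")
        buf.write("=" * 56 + "\n")
        return buf.getvalue()

    # ----------------------------------------------------------- checkpoint
    def save(self, path: str | Path) -> Path:
        """Single-file .npz archive with parameters and embedded config."""
        path = Path(path)
        state = self.net.state_dict()
        meta = {
            "backbone": vars(self.model.config) | {"stage_channels": list(self.model.config.stage_channels)},
            "attention_mode": self.net.attention_mode,
            "n_labels": self.model.n_labels,
            "train_config": vars(self.train_config),
            "best_epoch": int(self.best_epoch),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)
        return path

    @staticmethod
    def load_net(path: str | Path) -> CoAttentionNet:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        bk = dict(meta["backbone"])
        bk["stage_channels"] = tuple(bk["stage_channels"])
        config = BackboneConfig(**bk)
        net = CoAttentionNet(
            config,
            meta["n_labels"],
            attention_mode=meta["attention_mode"],
            rng=np.random.default_rng(0),
        )
        net.load_state_dict(state)
        net.eval()
        return net
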