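"""Model classes and the training protocol.

The public surface follows the statsmodels convention: a model object is
constructed from data (a tagged :class:`~laidrivers.preprocess.SampleSet`),
``fit()`` runs the optimization and returns a results object carrying the
selected parameters, the loss curves and prediction/attention methods, and
``summary()`` renders a small text table.

Training protocol: Adam (learning rate 0.001), mini-batches of 256 shuffled
each epoch with the run seed, mean-squared error on normalized LAI, a fixed
number of epochs with no explicit regularization; after every epoch the
validation loss is computed full-batch and the parameters at the minimum
validation loss are the ones retained (early stopping by model selection).
A global model can be pre-trained on the pooled grids and used to initialize
an independent fine-tuning run per grid, yielding one parameter set per grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Dict, Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .networks import ANNNet, IMVNet, LSTMNet, Network
from .preprocess import SampleSet, pool_samples

MODEL_FAMILIES = ("ann", "lstm", "imv")


class TrainingFailure(RuntimeError):
    """Loss became non-finite during optimization."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainConfig:
    """Optimization hyperparameters (reference values as defaults)."""

    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 300
    seed: int = 0
    hidden: int = 256
    ann_hidden: tuple = (32, 256, 256, 32)
    finetune_epochs: Optional[int] = None
    #: "mse" (squared error on the mixture mean) or "gaussian_mixture"
    #: (negative log-likelihood of a per-variable Gaussian mixture; IMV only)
    loss: str = "mse"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.loss not in ("mse", "gaussian_mixture"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @classmethod
    def test_profile(cls, seed: int = 0, epochs: int = 100) -> "TrainConfig":
        """Small configuration for minutes-scale CPU runs.

        Only the recurrent hidden size shrinks (256 -> 16); the ANN keeps its
        fixed four-hidden-layer architecture.
        """
        return cls(epochs=epochs, seed=seed, hidden=16, batch_size=256)


class Adam:
    """Adam optimizer over a parameter dict (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: Dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k in sorted(self.params):
            p = self.params[k]
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _mse_loss(net: Network, X: np.ndarray, y: np.ndarray) -> Tensor:
    pred = net.forward(X)
    if isinstance(pred, tuple):
        pred = pred[0]
    err = pred - Tensor(y[:, None])
    return ad.mean(err * err)


_LOG_2PI = float(np.log(2.0 * np.pi))


def _gaussian_mixture_nll(net, X: np.ndarray, y: np.ndarray) -> Tensor:
    """Negative log-likelihood of the per-variable Gaussian mixture:
    p(y) = sum_n Pr(z=n) N(y; mu_n, sigma_n^2)."""
    _, mus, logits, _, _ = net.forward_parts(X)
    N = net.n_vars
    logpr = logits - ad.logsumexp(logits, axis=1)                   # (B, N)
    mu_cat = ad.concat([ad.select(mus, n) for n in range(N)], axis=1)
    logsig = ad.concat([ad.select(net.params["logsig"], n) for n in range(N)],
                       axis=1)                                      # (1, N)
    z = (Tensor(y[:, None]) - mu_cat) * ad.exp(logsig * (-1.0))
    comp = logpr + ad.square(z) * (-0.5) + logsig * (-1.0) - 0.5 * _LOG_2PI
    return ad.mean(ad.logsumexp(comp, axis=1)) * (-1.0)


def _make_loss(net: Network, kind: str):
    if kind == "mse":
        return _mse_loss
    if not hasattr(net, "forward_parts"):
        raise ValueError("gaussian_mixture loss requires the IMV-LSTM family")
    return _gaussian_mixture_nll


@dataclass
class FitResult:
    """Outcome of one training run.

    ``params`` are the weights at the epoch with minimum validation loss.
    """

    params: Dict[str, np.ndarray]
    train_losses: np.ndarray
    val_losses: np.ndarray
    best_epoch: int

    @property
    def best_val_loss(self) -> float:
        return float(self.val_losses[self.best_epoch])


class LAIResults:
    """Results wrapper: selected parameters bound to a live network."""

    def __init__(self, model: "BaseLAIModel", fit_result: FitResult, config: TrainConfig):
        self.model = model
        self.fit_result = fit_result
        self.config = config
        model.net.set_state(fit_result.params)

    @property
    def best_epoch(self) -> int:
        return self.fit_result.best_epoch

    def predict(self, samples: SampleSet | np.ndarray) -> np.ndarray:
        """Normalized LAI predictions, shape (n,)."""
        X = samples.inputs if isinstance(samples, SampleSet) else np.asarray(samples)
        out = self.model.net.forward(X)
        if isinstance(out, tuple):
            out = out[0]
        return out.data[:, 0]

    def summary(self) -> str:
        fr = self.fit_result
        n_par = sum(v.size for v in fr.params.values())
        lines = [
            f"{type(self.model).__name__} fit results",
            "=" * 40,
            f"parameters            {n_par}",
            f"epochs                {len(fr.train_losses)}",
            f"best epoch (val)      {fr.best_epoch}",
            f"train loss @ best     {fr.train_losses[fr.best_epoch]:.6f}",
            f"val loss @ best       {fr.best_val_loss:.6f}",
            f"final train loss      {fr.train_losses[-1]:.6f}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize parameters with the architecture/config needed to reload."""
        meta = dict(family=self.model.family, config=asdict(self.config))
        meta["config"]["ann_hidden"] = list(self.config.ann_hidden)
        np.savez(path, __meta__=json.dumps(meta),
                 best_epoch=self.fit_result.best_epoch,
                 train_losses=self.fit_result.train_losses,
                 val_losses=self.fit_result.val_losses,
                 **{f"param/{k}": v for k, v in self.fit_result.params.items()})


class IMVResults(LAIResults):
    """IMV-LSTM results additionally expose attention records."""

    def attention(self, samples: SampleSet | np.ndarray):
        X = samples.inputs if isinstance(samples, SampleSet) else np.asarray(samples)
        _, record = self.model.net.forward(X, return_attention=True)
        return record


class BaseLAIModel:
    """Common fit machinery; subclasses choose the network family."""

    family: str = ""
    results_class = LAIResults

    def __init__(self, samples: SampleSet):
        if samples.splits is None:
            raise ValueError("samples must carry train/val/test split tags")
        self.samples = samples
        self.train_set = samples.subset("train")
        self.val_set = samples.subset("val")
        if len(self.train_set) == 0 or len(self.val_set) == 0:
            raise ValueError("train and validation sets must be non-empty")
        self.net: Network | None = None

    def _build_net(self, config: TrainConfig, rng: np.random.Generator) -> Network:
        raise NotImplementedError

    def fit(self, config: TrainConfig | None = None,
            init_state: Dict[str, np.ndarray] | None = None,
            epochs: int | None = None) -> LAIResults:
        config = config or TrainConfig()
        rng = np.random.default_rng(config.seed)
        self.net = self._build_net(config, rng)
        if init_state is not None:
            self.net.set_state(init_state)
        fr = _fit_network(self.net, self.train_set, self.val_set, config,
                          rng, epochs=epochs)
        return self.results_class(self, fr, config)


def _fit_network(net: Network, train: SampleSet, val: SampleSet,
                 config: TrainConfig, rng: np.random.Generator,
                 epochs: int | None = None) -> FitResult:
    n_epochs = epochs if epochs is not None else config.epochs
    opt = Adam(net.params, config.learning_rate)
    loss_fn = _make_loss(net, config.loss)
    Xtr, ytr = train.inputs, train.targets
    Xva, yva = val.inputs, val.targets
    n = len(ytr)
    train_losses, val_losses = [], []
    best_val, best_state, best_epoch = np.inf, net.get_state(), -1
    for epoch in range(n_epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss = loss_fn(net, Xtr[idx], ytr[idx])
            if not np.isfinite(loss.data):
                raise TrainingFailure(epoch)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_loss = float(loss_fn(net, Xva, yva).data)
        if not np.isfinite(val_loss):
            raise TrainingFailure(epoch)
        train_losses.append(epoch_loss / n_batches)
        val_losses.append(val_loss)
        if val_loss < best_val:
            best_val, best_state, best_epoch = val_loss, net.get_state(), epoch
    return FitResult(best_state, np.asarray(train_losses), np.asarray(val_losses), best_epoch)


class ANNModel(BaseLAIModel):
    """Feed-forward baseline on the flattened window."""

    family = "ann"

    def _build_net(self, config, rng):
        n_steps, n_vars = self.train_set.inputs.shape[1:]
        return ANNNet(n_steps, n_vars, hidden=config.ann_hidden, rng=rng)


class LSTMModel(BaseLAIModel):
    """Single-layer LSTM reading the window step by step."""

    family = "lstm"

    def _build_net(self, config, rng):
        return LSTMNet(self.train_set.inputs.shape[2], hidden=config.hidden, rng=rng)


class IMVLSTMModel(BaseLAIModel):
    """Interpretable multivariable LSTM with hybrid attention."""

    family = "imv"
    results_class = IMVResults

    def _build_net(self, config, rng):
        return IMVNet(self.train_set.inputs.shape[2], hidden=config.hidden, rng=rng)


MODEL_CLASSES = {"ann": ANNModel, "lstm": LSTMModel, "imv": IMVLSTMModel}


def load_results(path) -> LAIResults:
    """Reload a serialized results object; predictions are reproducible."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        params = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        fr = FitResult(params, z["train_losses"], z["val_losses"], int(z["best_epoch"]))
    cfg_d = meta["config"]
    cfg_d["ann_hidden"] = tuple(cfg_d["ann_hidden"])
    config = TrainConfig(**cfg_d)
    family = meta["family"]
    # rebuild a bare network of the right shape; bypass data-bound constructor
    model = object.__new__(MODEL_CLASSES[family])
    model.samples = model.train_set = model.val_set = None
    if family == "ann":
        w0 = params["W0"]
        n_in = w0.shape[0]
        hidden = tuple(params[f"W{l}"].shape[1]
                       for l in range(len([k for k in params if k.startswith('W')]) - 1))
        model.net = ANNNet(n_steps=n_in // 2, n_vars=2, hidden=hidden)
    elif family == "lstm":
        model.net = LSTMNet(n_vars=params["Wi"].shape[0] - params["Wi"].shape[1],
                            hidden=params["Wi"].shape[1])
    else:
        model.net = IMVNet(n_vars=params["Wj"].shape[0], hidden=params["Wj"].shape[1])
    results_class = IMVResults if family == "imv" else LAIResults
    res = object.__new__(results_class)
    res.model, res.fit_result, res.config = model, fr, config
    model.net.set_state(params)
    return res


def pretrain_finetune(family: str, per_grid: Dict[object, SampleSet],
                      config: TrainConfig, pretrain: bool = True
                      ) -> Dict[object, LAIResults]:
    """Pooled pre-training followed by independent per-grid fine-tuning.

    Pre-training fits one model on all grids' training/validation samples;
    its selected parameters initialize a fresh optimization per grid (the
    optimizer state is not carried over).  With ``pretrain=False`` each grid
    trains from random initialization under the same interface.
    """
    if family not in MODEL_CLASSES:
        raise ValueError(f"unknown model family {family!r}")
    if not per_grid:
        raise ValueError("no grids supplied")
    init_state = None
    if pretrain:
        pooled = pool_samples(per_grid.values())
        pooled_model = MODEL_CLASSES[family](pooled)
        init_state = pooled_model.fit(config).fit_result.params
    out: Dict[object, LAIResults] = {}
    ft_epochs = config.finetune_epochs
    for grid_id, samples in per_grid.items():
        model = MODEL_CLASSES[family](samples)
        out[grid_id] = model.fit(config, init_state=init_state, epochs=ft_epochs)
    return out
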