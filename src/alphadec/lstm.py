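"""LSTM decoder over 1-s epochs of SSD components.

A small recurrent classifier: one or two LSTM layers slide over the 250
samples of an epoch; the final hidden state feeds one or two fully
connected layers (ReLU/ELU) and a scalar tanh output matched to the -1/+1
arousal labels with a mean-squared-error loss, optimized with Adam in
random mini-batches of 9 for 20 passes over the training data.  L1 or L2
weight regularization with strength Lambda is part of the hyperparameter
space, as is the number of SSD component slots fed to the network.

The network, backpropagation through time, and Adam are implemented
directly on numpy arrays; gradients are validated against central finite
differences in the test suite.  The hyperparameter search is the two-step
random search of the study design: a broad random draw evaluated on a
subject subset, then the per-subject best configurations re-applied to all
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

from .preprocess import EpochedData, LabelSet

__all__ = [
    "LAYER_SIZES",
    "REG_STRENGTHS",
    "LEARNING_RATES",
    "HPConfig",
    "HPSpace",
    "LSTMDataset",
    "LSTMNet",
    "build_dataset",
    "train",
    "predict",
    "evaluate_cv",
    "random_search",
    "sample_hp",
]

LAYER_SIZES = (10, 15, 20, 25, 30, 40, 50, 65, 80, 100)
REG_STRENGTHS = (0.00, 0.18, 0.36, 0.72, 1.44)
LEARNING_RATES = (1e-2, 1e-3, 5e-4)
N_COMPONENT_SLOTS = 10


@dataclass(frozen=True)
class HPConfig:
    """One point of the hyperparameter space (validated against the grids).

    Layer sizes must be non-increasing across successive layers
    (bottleneck architecture), LSTM layers first, then fully connected.
    """

    lstm_sizes: tuple[int, ...] = (25,)
    fc_sizes: tuple[int, ...] = (10,)
    activation: str = "relu"            # relu | elu
    regularizer: str = "l2"             # l1 | l2
    reg_strength: float = 0.0
    learning_rate: float = 1e-3
    n_components: int = 10
    batch_size: int = 9
    n_epochs_train: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.lstm_sizes) <= 2 or not 1 <= len(self.fc_sizes) <= 2:
            raise ValueError("one or two LSTM layers and one or two FC layers")
        sizes = self.lstm_sizes + self.fc_sizes
        if any(s not in LAYER_SIZES for s in sizes):
            raise ValueError(f"layer sizes must come from {LAYER_SIZES}")
        if any(b > a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("bottleneck violation: successive layer larger than its input")
        if self.activation not in ("relu", "elu"):
            raise ValueError("activation must be relu or elu")
        if self.regularizer not in ("l1", "l2"):
            raise ValueError("regularizer must be l1 or l2")
        if self.reg_strength not in REG_STRENGTHS:
            raise ValueError(f"reg_strength must come from {REG_STRENGTHS}")
        if self.learning_rate not in LEARNING_RATES:
            raise ValueError(f"learning_rate must come from {LEARNING_RATES}")
        if not 1 <= self.n_components <= N_COMPONENT_SLOTS:
            raise ValueError("n_components must lie in [1, 10]")


@dataclass(frozen=True)
class HPSpace:
    """Grids the random search draws from (defaults = the study's grids)."""

    layer_sizes: tuple[int, ...] = LAYER_SIZES
    reg_strengths: tuple[float, ...] = REG_STRENGTHS
    learning_rates: tuple[float, ...] = LEARNING_RATES
    max_components: int = N_COMPONENT_SLOTS


@dataclass
class LSTMDataset:
    """Epochs x 250 samples x 10 component slots, labels in {-1, +1}."""

    tensor: NDArray[np.float64]
    labels: NDArray[np.int_]

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.tensor.ndim != 3 or self.tensor.shape[0] != self.labels.size:
            raise ValueError("tensor must be epochs x samples x slots, one label per epoch")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be -1 or +1")

    @property
    def n_epochs(self) -> int:
        return self.tensor.shape[0]


def build_dataset(
    epochs: EpochedData,
    labels: LabelSet,
    n_components: int = N_COMPONENT_SLOTS,
    standardize: bool = True,
) -> LSTMDataset:
    """Assemble the network input from SSD-space epochs and tertile labels.

    The full epochs x samples x 10 tensor is built first (slots beyond the
    available or requested components are exactly zero), then the
    mid-tertile rows are dropped and the remaining epochs labelled -1
    (low) / +1 (high).  Each component slot is scaled to unit overall
    standard deviation by default: µV-scale inputs saturate the gate
    nonlinearities and stall learning.
    """
    if n_components > N_COMPONENT_SLOTS:
        raise ValueError("at most 10 component slots")
    tensor = epochs.tensor
    n_ep, n_samp, n_avail = tensor.shape
    n_used = min(n_components, n_avail)
    full = np.zeros((n_ep, n_samp, N_COMPONENT_SLOTS))
    used = tensor[:, :, :n_used]
    if standardize:
        sd = used.std(axis=(0, 1), keepdims=True)
        sd[sd == 0] = 1.0
        used = used / sd
    full[:, :, :n_used] = used
    mask = labels.binary_mask
    return LSTMDataset(tensor=full[mask], labels=labels.binary_labels)


def _sigmoid(x: NDArray) -> NDArray:
    return 1.0 / (1.0 + np.exp(-x))


class LSTMNet:
    """Stacked LSTM + FC network with manual backpropagation through time."""

    def __init__(self, hp: HPConfig, input_dim: int = N_COMPONENT_SLOTS,
                 rng: np.random.Generator | None = None) -> None:
        self.hp = hp
        rng = rng or np.random.default_rng(hp.seed)
        self.params: dict[str, NDArray[np.float64]] = {}
        d = input_dim
        for l, h in enumerate(hp.lstm_sizes):
            s = 1.0 / np.sqrt(d + h)
            self.params[f"lstm{l}_W"] = rng.uniform(-s, s, (d + h, 4 * h))
            b = np.zeros(4 * h)
            b[h : 2 * h] = 1.0  # forget-gate bias
            self.params[f"lstm{l}_b"] = b
            d = h
        dims = [hp.lstm_sizes[-1], *hp.fc_sizes, 1]
        for l, (din, dout) in enumerate(zip(dims, dims[1:])):
            s = 1.0 / np.sqrt(din)
            self.params[f"fc{l}_W"] = rng.uniform(-s, s, (din, dout))
            self.params[f"fc{l}_b"] = np.zeros(dout)
        self.n_fc = len(dims) - 1

    # -- forward ----------------------------------------------------------

    def _act(self, x: NDArray) -> NDArray:
        if self.hp.activation == "relu":
            return np.maximum(0.0, x)
        return np.where(x > 0, x, np.expm1(x))

    def _act_grad(self, x: NDArray) -> NDArray:
        if self.hp.activation == "relu":
            return (x > 0).astype(float)
        return np.where(x > 0, 1.0, np.exp(x))

    def forward(self, X: NDArray[np.float64], want_cache: bool = False):
        """X: batch x T x input_dim -> output in (-1, 1), shape (batch,)."""
        B, T, _ = X.shape
        cache: dict = {"X": X, "lstm": []}
        seq = X
        for l, H in enumerate(self.hp.lstm_sizes):
            W = self.params[f"lstm{l}_W"]
            b = self.params[f"lstm{l}_b"]
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            gates = np.empty((T, B, 4 * H))
            cs = np.empty((T, B, H))
            hs = np.empty((T, B, H))
            c_prevs = np.empty((T, B, H))
            for t in range(T):
                z = np.concatenate([seq[:, t, :], h], axis=1) @ W + b
                H1 = H
                i = _sigmoid(z[:, :H1])
                f = _sigmoid(z[:, H1 : 2 * H1])
                g = np.tanh(z[:, 2 * H1 : 3 * H1])
                o = _sigmoid(z[:, 3 * H1 :])
                c_prevs[t] = c
                c = f * c + i * g
                h = o * np.tanh(c)
                gates[t] = np.concatenate([i, f, g, o], axis=1)
                cs[t] = c
                hs[t] = h
            if want_cache:
                cache["lstm"].append(
                    {"in": seq, "gates": gates, "cs": cs, "hs": hs, "c_prevs": c_prevs}
                )
            seq = hs.transpose(1, 0, 2)
        a = seq[:, -1, :]  # final hidden state h_T
        cache["fc"] = []
        for l in range(self.n_fc):
            z = a @ self.params[f"fc{l}_W"] + self.params[f"fc{l}_b"]
            if want_cache:
                cache["fc"].append({"in": a, "z": z})
            a = self._act(z) if l < self.n_fc - 1 else z
        y = np.tanh(a[:, 0])
        cache["y"] = y
        return (y, cache) if want_cache else y

    # -- backward ---------------------------------------------------------

    def backward(self, cache: dict, dy: NDArray[np.float64]) -> dict[str, NDArray]:
        """Gradients of the data loss; dy = dL/dy, shape (batch,)."""
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        y = cache["y"]
        da = (dy * (1.0 - y**2))[:, None]
        for l in range(self.n_fc - 1, -1, -1):
            fc = cache["fc"][l]
            if l < self.n_fc - 1:
                da = da * self._act_grad(fc["z"])
            grads[f"fc{l}_W"] += fc["in"].T @ da
            grads[f"fc{l}_b"] += da.sum(axis=0)
            da = da @ self.params[f"fc{l}_W"].T
        # da now w.r.t. final hidden state of the top LSTM layer
        B, T, _ = cache["X"].shape
        top = len(self.hp.lstm_sizes) - 1
        dh_seq = np.zeros((T, B, self.hp.lstm_sizes[top]))
        dh_seq[-1] = da
        for l in range(top, -1, -1):
            lc = cache["lstm"][l]
            H = self.hp.lstm_sizes[l]
            W = self.params[f"lstm{l}_W"]
            din = W.shape[0] - H
            dW = grads[f"lstm{l}_W"]
            db = grads[f"lstm{l}_b"]
            dx_seq = np.zeros((T, B, din))
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                dh = dh_seq[t] + dh_next
                i = lc["gates"][t][:, :H]
                f = lc["gates"][t][:, H : 2 * H]
                g = lc["gates"][t][:, 2 * H : 3 * H]
                o = lc["gates"][t][:, 3 * H :]
                c = lc["cs"][t]
                c_prev = lc["c_prevs"][t]
                tc = np.tanh(c)
                do = dh * tc
                dc = dc_next + dh * o * (1.0 - tc**2)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                da_t = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                    axis=1,
                )
                h_prev = lc["hs"][t - 1] if t > 0 else np.zeros((B, H))
                inp = np.concatenate([lc["in"][:, t, :], h_prev], axis=1)
                dW += inp.T @ da_t
                db += da_t.sum(axis=0)
                dfull = da_t @ W.T
                dx_seq[t] = dfull[:, :din]
                dh_next = dfull[:, din:]
                dc_next = dc * f
            dh_seq = dx_seq
        return grads

    # -- regularization ---------------------------------------------------

    def reg_loss(self) -> float:
        lam = self.hp.reg_strength
        if lam == 0:
            return 0.0
        total = 0.0
        for k, v in self.params.items():
            if k.endswith("_W"):
                total += np.sum(v**2) if self.hp.regularizer == "l2" else np.sum(np.abs(v))
        return lam * total

    def add_reg_grads(self, grads: dict[str, NDArray]) -> None:
        lam = self.hp.reg_strength
        if lam == 0:
            return
        for k, v in self.params.items():
            if k.endswith("_W"):
                grads[k] += 2 * lam * v if self.hp.regularizer == "l2" else lam * np.sign(v)

    def weight_norm(self) -> float:
        return float(
            np.sqrt(sum(np.sum(v**2) for k, v in self.params.items() if k.endswith("_W")))
        )


class _Adam:
    def __init__(self, params: dict[str, NDArray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, NDArray], grads: dict[str, NDArray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    dataset: LSTMDataset,
    hp: HPConfig,
    train_idx: NDArray[np.int_] | None = None,
) -> tuple[LSTMNet, NDArray[np.float64]]:
    """Train on (a subset of) the dataset; returns (model, learning curve).

    The learning curve holds the regularized training loss per pass over
    the data.  Reproducible from ``hp.seed``.
    """
    if dataset.n_epochs == 0:
        raise ValueError("empty dataset")
    idx = np.arange(dataset.n_epochs) if train_idx is None else np.asarray(train_idx)
    rng = np.random.default_rng(hp.seed)
    net = LSTMNet(hp, input_dim=dataset.tensor.shape[2], rng=rng)
    opt = _Adam(net.params, hp.learning_rate)
    X = dataset.tensor[idx]
    y = dataset.labels[idx].astype(float)
    curve = np.empty(hp.n_epochs_train)
    for it in range(hp.n_epochs_train):
        order = rng.permutation(idx.size)
        losses = []
        for start in range(0, idx.size, hp.batch_size):
            sel = order[start : start + hp.batch_size]
            out, cache = net.forward(X[sel], want_cache=True)
            err = out - y[sel]
            loss = float(np.mean(err**2)) + net.reg_loss()
            dy = 2.0 * err / sel.size
            grads = net.backward(cache, dy)
            net.add_reg_grads(grads)
            opt.step(net.params, grads)
            losses.append(loss)
        curve[it] = np.mean(losses)
    return net, curve


def predict(
    model: LSTMNet, X: NDArray[np.float64]
) -> tuple[NDArray[np.int_], NDArray[np.float64]]:
    """Class labels via the sign of the tanh output (0 maps to +1, the
    deterministic tie-break) and the raw scores in (-1, 1)."""
    scores = model.forward(np.asarray(X, dtype=float))
    labels = np.where(scores >= 0, 1, -1)
    return labels, scores


def evaluate_cv(
    dataset: LSTMDataset,
    hp: HPConfig,
    folds: list[NDArray[np.int_]] | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, NDArray[np.int_]]:
    """Cross-validated accuracy with pooled per-epoch predictions.

    ``folds`` may be the split object shared with the CSP randomized CV;
    otherwise stratified folds are drawn from ``seed``.
    """
    from .csp import _stratified_folds

    if folds is None:
        folds = _stratified_folds(dataset.labels, k, np.random.default_rng(seed))
    predictions = np.zeros(dataset.n_epochs, dtype=int)
    accs = []
    for f, test in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(dataset.n_epochs), test)
        model, _ = train(dataset, replace(hp, seed=hp.seed + 1000 * f), train_idx)
        pred, _ = predict(model, dataset.tensor[test])
        predictions[test] = pred
        accs.append(np.mean(pred == dataset.labels[test]))
    return float(np.mean(accs)), predictions


def sample_hp(space: HPSpace, rng: np.random.Generator) -> HPConfig:
    """Draw one configuration, respecting the bottleneck constraint."""
    sizes: list[int] = []
    n_lstm = int(rng.integers(1, 3))
    n_fc = int(rng.integers(1, 3))
    for _ in range(n_lstm + n_fc):
        allowed = [s for s in space.layer_sizes if not sizes or s <= sizes[-1]]
        sizes.append(int(rng.choice(allowed)))
    return HPConfig(
        lstm_sizes=tuple(sizes[:n_lstm]),
        fc_sizes=tuple(sizes[n_lstm:]),
        activation=str(rng.choice(["relu", "elu"])),
        regularizer=str(rng.choice(["l1", "l2"])),
        reg_strength=float(rng.choice(space.reg_strengths)),
        learning_rate=float(rng.choice(space.learning_rates)),
        n_components=int(rng.integers(1, space.max_components + 1)),
        seed=int(rng.integers(2**31)),
    )


def random_search(
    subjects: dict[int, LSTMDataset],
    space: HPSpace | None = None,
    n_draws: int = 20,
    seed: int = 0,
    n_broad_subjects: int = 10,
    eval_fn=None,
) -> dict[int, HPConfig]:
    """Two-step random hyperparameter search.

    Step 1: ``n_draws`` random configurations are evaluated (mean CV
    accuracy) on a random subset of up to ``n_broad_subjects`` subjects.
    Step 2: the two best configurations of each subset subject are pooled
    and re-evaluated on every subject; each subject keeps the winner.
    Ties break deterministically by draw order.  ``eval_fn(dataset, hp)``
    may replace the default CV evaluation (used by fast tests).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    if not subjects:
        raise ValueError("no subjects given")
    space = space or HPSpace()
    rng = np.random.default_rng(seed)
    if eval_fn is None:
        eval_fn = lambda ds, hp: evaluate_cv(ds, hp, seed=hp.seed)[0]  # noqa: E731

    configs = [sample_hp(space, rng) for _ in range(n_draws)]
    ids = sorted(subjects)
    subset = list(rng.choice(ids, size=min(n_broad_subjects, len(ids)), replace=False))

    candidate_idx: list[int] = []
    for sid in subset:
        scores = [eval_fn(subjects[sid], hp) for hp in configs]
        best_two = np.argsort(-np.asarray(scores), kind="stable")[:2]
        candidate_idx.extend(int(i) for i in best_two)
    # preserve draw order, drop duplicates
    candidates = [configs[i] for i in sorted(set(candidate_idx))]

    best: dict[int, HPConfig] = {}
    for sid in ids:
        scores = [eval_fn(subjects[sid], hp) for hp in candidates]
        best[sid] = candidates[int(np.argmax(scores))]
    return best
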