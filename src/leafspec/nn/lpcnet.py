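"""LPCNet: a 1-D CNN + BiLSTM + multi-head self-attention spectral regressor.

The model reads one reflectance spectrum as a band sequence:

1. three convolution blocks (conv -> ReLU -> max-pool) extract local
   band-neighborhood features and shorten the sequence;
2. a bidirectional LSTM reads the reduced band sequence forward and
   backward, capturing long-range dependencies between distant wavelengths;
3. a six-head self-attention block re-weights the sequence — per head,
   queries/keys/values are linear projections of the hidden vectors, scores
   are query-key dot products, softmax-normalized rows weight the values,
   and the concatenated heads pass through an output projection W_O;
4. mean pooling over the sequence and a small dense head emit one scalar
   (one model per pigment).

Ablation variants drop the BiLSTM and/or attention blocks with everything
else held fixed, so module contributions can be compared under identical
seeds and hyperparameters.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ..chemomodels import FitReport, metrics
from .autodiff import Adam, Tensor, concat, conv1d, max_pool1d, no_grad, softmax

__all__ = ["LPCNetConfig", "LPCNet", "mhsa", "build_lpcnet", "train", "ablate"]


@dataclass
class LPCNetConfig:
    """Architecture and training hyperparameters.

    ``conv_blocks`` is a tuple of (kernel, channels) per block, each
    followed by ReLU and max-pool of ``pool``.  ``heads`` self-attention
    units of dimension ``width // heads`` run in parallel.  ``scale_scores``
    divides attention scores by sqrt(head_dim) (standard practice; switch
    off for a literal unscaled dot-product).
    """

    n_bands: int = 256
    conv_blocks: tuple = ((7, 16), (5, 32), (3, 64))
    pool: int = 2
    lstm_hidden: int = 64
    heads: int = 6
    epochs: int = 200
    lr: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    scale_scores: bool = True
    use_bilstm: bool = True
    use_mhsa: bool = True
    head_units: int = 32
    select_best_epoch: bool = True


def mhsa(
    h: np.ndarray | Tensor,
    params: dict,
    heads: int,
    scale: bool = True,
) -> tuple[Tensor, np.ndarray]:
    """Multi-head self-attention over a batch of sequences.

    ``h``: (N, T, D).  ``params`` holds ``Wq, Wk, Wv`` of shape
    (D, heads*dh) and ``Wo`` of shape (heads*dh, D_out).  Per head the
    score matrix is q @ k^T (optionally / sqrt(dh)), softmax-normalized per
    row; outputs are the attention-weighted values, concatenated over heads
    and projected by ``Wo``.

    Returns (output sequence, attention weights (N, heads, T, T)).  Every
    attention row sums to 1; asserted here on every forward pass.
    """
    if not isinstance(h, Tensor):
        h = Tensor(h)
    N, T, D = h.shape
    dh = params["Wq"].shape[1] // heads

    def split_heads(x):  # (N,T,heads*dh) -> (N,heads,T,dh)
        return x.reshape(N, T, heads, dh).transpose(0, 2, 1, 3)

    q = split_heads(h @ params["Wq"])
    k = split_heads(h @ params["Wk"])
    v = split_heads(h @ params["Wv"])
    scores = q @ k.transpose(0, 1, 3, 2)
    if scale:
        scores = scores * (1.0 / np.sqrt(dh))
    w = softmax(scores, axis=-1)  # (N, heads, T, T)
    rows = w.data.sum(axis=-1)
    assert np.allclose(rows, 1.0, atol=1e-6), "attention rows must sum to 1"
    out = w @ v  # (N, heads, T, dh)
    out = out.transpose(0, 2, 1, 3).reshape(N, T, heads * dh)
    return out @ params["Wo"], w.data


class LPCNet:
    """The assembled regressor; one scalar output per spectrum."""

    def __init__(self, config: LPCNetConfig):
        config = copy.deepcopy(config)
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, Tensor] = {}

        def param(name, shape, fan_in):
            t = Tensor(rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape))
            t.requires_grad = True
            self.params[name] = t
            return t

        # conv stack
        c_in, L = 1, config.n_bands
        for i, (ksize, c_out) in enumerate(config.conv_blocks):
            if L < ksize:
                raise ValueError("band count too small for the conv stack")
            param(f"conv{i}_w", (c_out, c_in, ksize), c_in * ksize)
            zb = Tensor(np.zeros(c_out))
            zb.requires_grad = True
            self.params[f"conv{i}_b"] = zb
            L = (L - ksize + 1) // config.pool
            c_in = c_out
        if L < 1:
            raise ValueError("band count too small for the conv stack")
        self.seq_len = L
        feat = c_in

        # BiLSTM
        if config.use_bilstm:
            H = config.lstm_hidden
            for d in ("fwd", "bwd"):
                param(f"lstm_{d}_wih", (feat, 4 * H), feat)
                param(f"lstm_{d}_whh", (H, 4 * H), H)
                bias = np.zeros(4 * H)
                bias[H:2 * H] = 1.0  # forget gate open at init (standard)
                zb = Tensor(bias)
                zb.requires_grad = True
                self.params[f"lstm_{d}_b"] = zb
            feat = 2 * H

        # MHSA
        if config.use_mhsa:
            dh = max(1, feat // config.heads)
            inner = dh * config.heads
            for name in ("Wq", "Wk", "Wv"):
                param(f"attn_{name}", (feat, inner), feat)
            # residual-branch output projection starts at zero so the
            # network begins as the conv/recurrent stack and the attention
            # contribution grows in as it becomes useful (standard
            # residual-init practice; stabilizes early training)
            zo = Tensor(np.zeros((inner, feat)))
            zo.requires_grad = True
            self.params["attn_Wo"] = zo

        # head: the full sequence is flattened (not pooled) so the dense
        # layer stays wavelength-position aware — pigment absorption lives
        # at specific bands, which global pooling would average away
        head_in = feat * self.seq_len
        param("head_w1", (head_in, config.head_units), head_in)
        zb = Tensor(np.zeros(config.head_units))
        zb.requires_grad = True
        self.params["head_b1"] = zb
        param("head_w2", (config.head_units, 1), config.head_units)
        zb2 = Tensor(np.zeros(1))
        zb2.requires_grad = True
        self.params["head_b2"] = zb2

        self.last_attention: np.ndarray | None = None

    # ------------------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        """Total trainable scalar parameters (closed-form checkable)."""
        return sum(p.data.size for p in self.params.values())

    def parameters(self) -> list:
        return list(self.params.values())

    def _lstm_pass(self, seq: Tensor, direction: str) -> list:
        """One LSTM direction over a (N, T, feat) sequence tensor.

        Input projections for every timestep are batched into one matmul;
        only the hidden-state recurrence stays sequential.
        """
        P = self.params
        H = self.config.lstm_hidden
        N, T, _ = seq.shape
        wih, whh, b = (
            P[f"lstm_{direction}_wih"],
            P[f"lstm_{direction}_whh"],
            P[f"lstm_{direction}_b"],
        )
        xproj = seq @ wih + b  # (N, T, 4H)
        h = Tensor(np.zeros((N, H)))
        c = Tensor(np.zeros((N, H)))
        steps = range(T) if direction == "fwd" else range(T - 1, -1, -1)
        outs = []
        for t in steps:
            z = xproj[:, t, :] + h @ whh
            i = z[:, 0 * H:1 * H].sigmoid()
            f = z[:, 1 * H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return outs if direction == "fwd" else outs[::-1]

    def forward(self, X: np.ndarray) -> Tensor:
        """Score a batch of spectra; returns a (N, 1) tensor."""
        cfg = self.config
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        N = X.shape[0]
        x = Tensor(X[:, None, :])  # (N, 1, B)
        for i in range(len(cfg.conv_blocks)):
            x = conv1d(x, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"]).relu()
            x = max_pool1d(x, cfg.pool)
        # (N, C, T) -> sequence of T timesteps, each (N, C)
        T = x.shape[2]
        h = x.transpose(0, 2, 1)  # (N, T, C)

        if cfg.use_bilstm:
            fwd = self._lstm_pass(h, "fwd")
            bwd = self._lstm_pass(h, "bwd")
            both = [
                concat([f.reshape(N, 1, -1), b.reshape(N, 1, -1)], axis=2)
                for f, b in zip(fwd, bwd)
            ]
            h = concat(both, axis=1)  # (N, T, 2H)

        if cfg.use_mhsa:
            attn_params = {
                "Wq": self.params["attn_Wq"],
                "Wk": self.params["attn_Wk"],
                "Wv": self.params["attn_Wv"],
                "Wo": self.params["attn_Wo"],
            }
            attended, weights = mhsa(h, attn_params, cfg.heads, cfg.scale_scores)
            # residual around the attention block: attention contributes
            # context without erasing band-position information
            h = h + attended
            self.last_attention = weights

        flat = h.reshape(N, -1)  # (N, T * feat), band-position preserved
        z = (flat @ self.params["head_w1"] + self.params["head_b1"]).relu()
        return z @ self.params["head_w2"] + self.params["head_b2"]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Numpy prediction on the original target scale.

        Applies the input/target standardization learned during training
        (identity if the model is untrained).
        """
        X = np.asarray(X, dtype=float)
        if hasattr(self, "_x_mu"):
            X = (X - self._x_mu) / self._x_sd
        with no_grad():
            out = self.forward(X).data.ravel()
        return out * self._y_sd + self._y_mu if hasattr(self, "_y_mu") else out

    def state(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()


def build_lpcnet(config: LPCNetConfig) -> LPCNet:
    """Construct an LPCNet (or ablated variant) from a config."""
    return LPCNet(config)


@dataclass
class TrainResult:
    report: FitReport
    loss_curve: np.ndarray
    r2_curve: np.ndarray
    best_epoch: int
    model: LPCNet = field(repr=False, default=None)


def train(model: LPCNet, X: np.ndarray, y: np.ndarray, split, config=None) -> TrainResult:
    """Train on the calibration rows of ``split``; track prediction R^2.

    Minimizes mean-squared error with Adam for ``config.epochs`` epochs and
    returns the epoch with the best prediction-set R^2 (the final epoch if
    ``select_best_epoch`` is off).  Inputs are standardized per band and the
    target z-scored using calibration statistics only; predictions are
    returned on the original scale.  Fully seeded: identical seeds give
    identical loss curves.
    """
    cfg = config or model.config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    ci, pi = np.asarray(split.calib_idx), np.asarray(split.pred_idx)
    if np.intersect1d(ci, pi).size:
        raise ValueError("calibration and prediction indices overlap")

    mu, sd = X[ci].mean(axis=0), X[ci].std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    y_mu, y_sd = y[ci].mean(), y[ci].std()
    y_sd = y_sd if y_sd > 0 else 1.0
    ys = (y - y_mu) / y_sd
    model._y_mu, model._y_sd = y_mu, y_sd
    model._x_mu, model._x_sd = mu, sd

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), lr=cfg.lr)
    losses, r2s = [], []
    best_state, best_r2, best_epoch = model.state(), -np.inf, -1

    def eval_pred_r2():
        with no_grad():
            pred = model.forward(Xs[pi]).data.ravel()
        try:
            _, r2, _ = metrics(ys[pi], pred)
        except ValueError:
            r2 = np.nan
        return r2

    # The tape graph is acyclic (children reference parents only), so
    # refcounting reclaims it; cyclic GC would rescan every live node each
    # few hundred allocations, dominating the run time.  Pause it.
    import gc

    gc_was_enabled = gc.isenabled()
    gc.disable()
    try:
        for epoch in range(cfg.epochs):
            order = rng.permutation(ci.size)
            ep_loss, n_batches = 0.0, 0
            for start in range(0, ci.size, cfg.batch_size):
                rows = ci[order[start:start + cfg.batch_size]]
                out = model.forward(Xs[rows])
                resid = out.reshape(-1) - Tensor(ys[rows])
                loss = (resid * resid).mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {loss.data}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_loss += float(loss.data)
                n_batches += 1
            losses.append(ep_loss / max(n_batches, 1))
            r2 = eval_pred_r2()
            r2s.append(r2)
            if cfg.select_best_epoch and np.isfinite(r2) and r2 > best_r2:
                best_r2, best_epoch = r2, epoch
                best_state = model.state()
    finally:
        if gc_was_enabled:
            gc.enable()

    if cfg.select_best_epoch and best_epoch >= 0:
        model.load_state(best_state)
    else:
        best_epoch = cfg.epochs - 1

    def rescale(pred):
        return pred * y_sd + y_mu

    with no_grad():
        p_cal = rescale(model.forward(Xs[ci]).data.ravel())
        p_val = rescale(model.forward(Xs[pi]).data.ravel())
    report = FitReport.from_predictions(
        y[ci], p_cal, y[pi], p_val, model=_variant_name(cfg), combo="lpcnet"
    )
    return TrainResult(
        report=report,
        loss_curve=np.array(losses),
        r2_curve=np.array(r2s),
        best_epoch=best_epoch,
        model=model,
    )


def _variant_name(cfg: LPCNetConfig) -> str:
    if cfg.use_bilstm and cfg.use_mhsa:
        return "lpcnet"
    if cfg.use_bilstm:
        return "cnn_bilstm"
    if cfg.use_mhsa:
        return "cnn_mhsa"
    return "cnn"


#: Fixed ablation order: backbone alone, + recurrence, + attention, full.
ABLATION_VARIANTS = ("cnn", "cnn_bilstm", "cnn_mhsa", "lpcnet")


def ablate(
    X: np.ndarray,
    y: np.ndarray,
    split,
    config: LPCNetConfig,
    variants: tuple = ABLATION_VARIANTS,
) -> dict:
    """Train the module-ablation variants under identical settings.

    Returns an ordered dict variant -> TrainResult; all variants share the
    same split, seed, and hyperparameters, differing only in the presence
    of the BiLSTM and attention blocks.  ``variants`` defaults to all four
    (CNN, CNN-BiLSTM, CNN-MHSA, LPCNet) and may be restricted for quicker
    pairwise comparisons.
    """
    flags = {
        "cnn": (False, False),
        "cnn_bilstm": (True, False),
        "cnn_mhsa": (False, True),
        "lpcnet": (True, True),
    }
    results = {}
    for name in variants:
        use_bilstm, use_mhsa = flags[name]
        cfg = copy.deepcopy(config)
        cfg.use_bilstm, cfg.use_mhsa = use_bilstm, use_mhsa
        model = build_lpcnet(cfg)
        results[name] = train(model, X, y, split, cfg)
    return results
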