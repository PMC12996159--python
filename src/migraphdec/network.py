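"""The dual-branch motor-imagery decoder.

The model classifies one EEG trial from two complementary spatial views:

* a *temporal-spectral-spatial* branch — m spatial filters with a (C, 1)
  receptive field over all filter-bank views, batch-norm, ELU, then a
  temporal log-variance layer over non-overlapping windows of w samples
  (a band-power surrogate), giving an (m, t) feature map;
* a *spatial guidance* branch — a (1, 1) pointwise convolution fuses the
  spectral views into per-electrode node features, a two-argument graph
  attention layer (GATv2) aggregates them over the trial's PLV graph, and a
  global sum readout produces a t-vector that is broadcast-added to the
  convolutional features.

The fused (m, t) map is recalibrated spectro-wise by a cross-correlation
attention gate (ACSIM) and pooled over windows by per-row softmax attention
(ASDTA) before a linear classifier.  With the canonical 4-class
configuration (C=22, T=1000, 9 bands, m=64, w=250, 3 heads, l=7) the model
has exactly 13,458 trainable parameters.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import (
    Tensor,
    batch_norm_train,
    elu,
    leaky_relu,
    log_window_variance,
    pad1d,
    sigmoid,
    softmax,
)
from .connectivity import Adjacency

__all__ = [
    "ModelConfig",
    "ForwardTrace",
    "MIGraphNet",
    "log_variance",
    "readout_sum",
    "fuse_add",
]


@dataclass
class ModelConfig:
    """Architectural hyperparameters.

    ``m`` spatial filters must exceed the number of bands so the latent
    space gains spectral resolution; ``l`` is the (odd) cross-correlation
    window of the spectral attention gate; ``t = T // w`` windows.
    """

    C: int = 22
    T: int = 1000
    n_bands: int = 9
    m: int = 64
    w: int = 250
    n_classes: int = 4
    n_heads: int = 3
    l: int = 7
    dropout: float = 0.1
    max_norm: float = 2.0
    var_eps: float = 1e-6
    edge_budget: int = 100

    def __post_init__(self):
        if self.m <= self.n_bands:
            raise ValueError("m must exceed the number of bands")
        if self.l % 2 == 0:
            raise ValueError("cross-correlation window l must be odd")
        if self.T < self.w:
            raise ValueError("window w longer than the trial")
        if self.t < 1:
            raise ValueError("need at least one full window")

    @property
    def t(self) -> int:
        return self.T // self.w

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class ForwardTrace:
    """Every named intermediate of a single-trial forward pass."""

    x_ssf: np.ndarray    # (m, T)  spatially filtered views
    x_tssf: np.ndarray   # (m, t)  windowed log-variance features
    x_sf: np.ndarray     # (C, t)  node features of the graph branch
    x_sgf: np.ndarray    # (t,)    graph readout
    x_estf: np.ndarray   # (m, t)  fused branch output
    u: np.ndarray        # (m,)    spectral attention gate
    x_acsif: np.ndarray  # (m, t)  gated features
    asdta_alpha: np.ndarray  # (m, t) temporal attention weights
    x_asdtf: np.ndarray  # (m,)    attention-pooled features
    logits: np.ndarray   # (n_classes,)


# ---------------------------------------------------------------------------
# stateless building blocks (Tensor in, Tensor out)

def _log_variance_t(x: Tensor, w: int, eps: float) -> Tensor:
    """log(max(population variance, eps)) over half-open windows of w samples."""
    T = x.shape[-1]
    if w > T:
        raise ValueError(f"window w={w} exceeds T={T}")
    return log_window_variance(x, w, eps)


def log_variance(x: np.ndarray, w: int, eps: float = 1e-6) -> np.ndarray:
    """Temporal log-variance features of an (..., T) array -> (..., t)."""
    return _log_variance_t(Tensor(np.asarray(x, dtype=np.float64)), w, eps).data


def readout_sum(node_features: np.ndarray) -> np.ndarray:
    """Global sum pooling over nodes: (C, t) -> (t,)."""
    return np.asarray(node_features).sum(axis=-2)


def fuse_add(x_tssf: np.ndarray, x_sgf: np.ndarray) -> np.ndarray:
    """Broadcast-add the graph readout onto every spatial-filter row."""
    x_tssf = np.asarray(x_tssf)
    x_sgf = np.asarray(x_sgf)
    if x_tssf.shape[-1] != x_sgf.shape[-1]:
        raise ValueError("window counts of the two branches differ")
    return x_tssf + x_sgf[..., None, :]


class _BatchNorm:
    """Batch normalisation over the given axes with running statistics."""

    def __init__(self, param_shape, axes, dtype, eps=1e-5, momentum=0.1):
        self.gamma = Tensor(np.ones(param_shape, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(param_shape, dtype=dtype), requires_grad=True)
        self.axes = axes
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(param_shape, dtype=dtype)
        self.running_var = np.ones(param_shape, dtype=dtype)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            out, mu, var = batch_norm_train(x, self.gamma, self.beta,
                                            self.axes, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.reshape(
                self.running_mean.shape)
            self.running_var = (1 - m) * self.running_var + m * var.reshape(
                self.running_var.shape)
            return out
        scale = self.gamma * (Tensor(self.running_var) + self.eps) ** -0.5
        shift = self.beta - Tensor(self.running_mean) * scale
        return x * scale + shift


def _glorot(rng: np.random.Generator, shape, dtype) -> np.ndarray:
    fan_in, fan_out = (shape[-1], shape[-2]) if len(shape) >= 2 else (shape[0], 1)
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class MIGraphNet:
    """The full decoder; all parameters live in named autodiff tensors."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 dtype=np.float32):
        self.config = cfg = config or ModelConfig()
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        m, t, l = cfg.m, cfg.t, cfg.l
        K = cfg.n_bands * cfg.C

        self.spatial_w = Tensor(_glorot(rng, (m, K), dtype), requires_grad=True)
        self.bn_spatial = _BatchNorm((1, m, 1), axes=(0, 2), dtype=dtype)
        self.point_w = Tensor(_glorot(rng, (1, cfg.n_bands), dtype)[0],
                              requires_grad=True)
        self.point_b = Tensor(np.zeros(1, dtype=dtype), requires_grad=True)
        self.bn_point = _BatchNorm((1, 1, 1), axes=(0, 1, 2), dtype=dtype)
        self.gat_wl = Tensor(_glorot(rng, (cfg.n_heads, t, t), dtype),
                             requires_grad=True)
        self.gat_wr = Tensor(_glorot(rng, (cfg.n_heads, t, t), dtype),
                             requires_grad=True)
        self.gat_a = Tensor(_glorot(rng, (cfg.n_heads, 1, t), dtype)[:, 0, :],
                            requires_grad=True)
        self.bn_gat = _BatchNorm((1, 1, t), axes=(0, 1), dtype=dtype)
        # attention modules start neutral: gate 0.5, uniform window weights
        self.acsim_w_max = Tensor(np.zeros(l, dtype=dtype), requires_grad=True)
        self.acsim_w_avg = Tensor(np.zeros(l, dtype=dtype), requires_grad=True)
        self.asdta_w = Tensor(np.zeros((m, t), dtype=dtype), requires_grad=True)
        self.fc_w = Tensor(_glorot(rng, (cfg.n_classes, m), dtype),
                           requires_grad=True)
        self.fc_b = Tensor(np.zeros(cfg.n_classes, dtype=dtype), requires_grad=True)
        self._dropout_rng = np.random.default_rng(seed + 1)

    # -- parameter bookkeeping -------------------------------------------
    def named_parameters(self) -> dict[str, Tensor]:
        return {
            "spatial_w": self.spatial_w,
            "bn_spatial.gamma": self.bn_spatial.gamma,
            "bn_spatial.beta": self.bn_spatial.beta,
            "point_w": self.point_w,
            "point_b": self.point_b,
            "bn_point.gamma": self.bn_point.gamma,
            "bn_point.beta": self.bn_point.beta,
            "gat_wl": self.gat_wl,
            "gat_wr": self.gat_wr,
            "gat_a": self.gat_a,
            "bn_gat.gamma": self.bn_gat.gamma,
            "bn_gat.beta": self.bn_gat.beta,
            "acsim_w_max": self.acsim_w_max,
            "acsim_w_avg": self.acsim_w_avg,
            "asdta_w": self.asdta_w,
            "fc_w": self.fc_w,
            "fc_b": self.fc_b,
        }

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def parameter_breakdown(self) -> dict[str, int]:
        cfg = self.config
        t = cfg.t
        return {
            "spatial_conv": cfg.m * cfg.n_bands * cfg.C,
            "bn_spatial": 2 * cfg.m,
            "pointwise_conv": cfg.n_bands + 1,
            "bn_pointwise": 2,
            "gatv2": cfg.n_heads * (2 * t * t + t),
            "bn_gat": 2 * t,
            "acsim": 2 * cfg.l,
            "asdta": cfg.m * t,
            "classifier": cfg.m * cfg.n_classes + cfg.n_classes,
        }

    def count_parameters(self) -> int:
        total = sum(p.size for p in self.parameters() if p.requires_grad)
        assert total == sum(self.parameter_breakdown().values())
        return total

    # -- forward stages (Tensor level, batched) ---------------------------
    def _spatial(self, x_fb: Tensor, training: bool) -> Tensor:
        B, Nb, C, T = x_fb.shape
        flat = x_fb.reshape(B, Nb * C, T)
        out = self.spatial_w @ flat  # (B, m, T)
        return elu(self.bn_spatial(out, training))

    def _spectral_fuse(self, x_fb: Tensor, training: bool) -> Tensor:
        B, Nb, C, T = x_fb.shape
        w = self.point_w.reshape(1, Nb, 1, 1)
        fused = (x_fb * w).sum(axis=1) + self.point_b.reshape(1, 1, 1)
        fused = elu(self.bn_point(fused, training))  # (B, C, T)
        return _log_variance_t(fused, self.config.w, self.config.var_eps)

    def _gat(self, H: Tensor, mask: np.ndarray, training: bool) -> Tensor:
        """GATv2 over (B, C, t) node features with a (B, C, C) neighbour mask
        (self-loops included), then BN over the feature axis and ELU."""
        cfg = self.config
        B, C, t = H.shape
        neg = np.where(mask > 0, 0.0, -1e30).astype(H.data.dtype)
        agg = None
        for k in range(cfg.n_heads):
            Hl = H @ self.gat_wl[k]
            Hr = H @ self.gat_wr[k]
            pair = leaky_relu(Hl.reshape(B, C, 1, t) + Hr.reshape(B, 1, C, t))
            e = (pair * self.gat_a[k].reshape(1, 1, 1, t)).sum(axis=-1)
            alpha = softmax(e + Tensor(neg), axis=-1)  # (B, C, C)
            head_out = alpha @ Hr
            agg = head_out if agg is None else agg + head_out
        agg = agg * (1.0 / cfg.n_heads)
        return elu(self.bn_gat(agg, training))

    def _acsim(self, x: Tensor) -> tuple[Tensor, Tensor]:
        B, m, t = x.shape
        z_max = x.max(axis=-1)   # (B, m)
        z_avg = x.mean(axis=-1)
        u = sigmoid(self._xcorr(z_max, self.acsim_w_max)
                    + self._xcorr(z_avg, self.acsim_w_avg))
        return x * u.reshape(B, m, 1), u

    def _xcorr(self, z: Tensor, w: Tensor) -> Tensor:
        """1-D cross-correlation of (B, m) along the spectral axis with a
        length-l kernel, centred window, zero padding at the boundaries."""
        l = self.config.l
        m = z.shape[-1]
        zp = pad1d(z, l // 2, l // 2, axis=-1)
        acc = None
        for k in range(l):
            term = w[k] * zp[:, k : k + m]
            acc = term if acc is None else acc + term
        return acc

    def _asdta(self, x: Tensor) -> tuple[Tensor, Tensor]:
        B, m, t = x.shape
        alpha = softmax(self.asdta_w, axis=-1)  # (m, t)
        pooled = (x * alpha.reshape(1, m, t)).sum(axis=-1)
        return pooled, alpha

    def _forward(self, x_fb: np.ndarray, mask: np.ndarray,
                 training: bool = False) -> dict[str, Tensor]:
        """Batched forward pass; returns every intermediate as a Tensor.

        ``x_fb``: (B, N_b, C, T) filter-bank views; ``mask``: (B, C, C)
        adjacency with self-loops.
        """
        cfg = self.config
        x_fb = Tensor(np.asarray(x_fb, dtype=self.dtype))
        if x_fb.shape[1:] != (cfg.n_bands, cfg.C, cfg.T):
            raise ValueError(
                f"expected (B, {cfg.n_bands}, {cfg.C}, {cfg.T}) input, "
                f"got {x_fb.shape}"
            )
        B = x_fb.shape[0]
        if mask.shape != (B, cfg.C, cfg.C):
            raise ValueError("adjacency mask shape mismatch")

        x_ssf = self._spatial(x_fb, training)
        x_tssf = _log_variance_t(x_ssf, cfg.w, cfg.var_eps)
        x_sf = self._spectral_fuse(x_fb, training)
        g = self._gat(x_sf, mask, training)
        x_sgf = g.sum(axis=1)  # (B, t) global sum pooling readout
        x_estf = x_tssf + x_sgf.reshape(B, 1, cfg.t)
        if training and cfg.dropout > 0:
            keep = (self._dropout_rng.random(x_estf.shape) >= cfg.dropout)
            x_estf = x_estf * Tensor(
                keep.astype(self.dtype) / (1.0 - cfg.dropout)
            )
        x_acsif, u = self._acsim(x_estf)
        x_asdtf, alpha = self._asdta(x_acsif)
        logits = x_asdtf @ self.fc_w.transpose(1, 0) + self.fc_b
        return {
            "x_ssf": x_ssf, "x_tssf": x_tssf, "x_sf": x_sf, "x_sgf": x_sgf,
            "x_estf": x_estf, "u": u, "x_acsif": x_acsif,
            "asdta_alpha": alpha, "x_asdtf": x_asdtf, "logits": logits,
        }

    # -- public per-trial / numpy API -------------------------------------
    @staticmethod
    def _mask_from_adjacency(adj, C: int) -> np.ndarray:
        a = adj.matrix if isinstance(adj, Adjacency) else np.asarray(adj)
        if a.shape != (C, C):
            raise ValueError(f"adjacency must be ({C}, {C}), got {a.shape}")
        return a + np.eye(C)  # self-loops so every neighbourhood is non-empty

    def forward(self, trial_views: np.ndarray, adjacency) -> ForwardTrace:
        """Eval-mode forward of one (N_b, C, T) trial; records all stages."""
        cfg = self.config
        mask = self._mask_from_adjacency(adjacency, cfg.C)[None]
        trace = self._forward(np.asarray(trial_views)[None], mask,
                              training=False)
        npy = {k: v.data[0] if v.data.shape[0] == 1 and k != "asdta_alpha"
               else v.data for k, v in trace.items()}
        npy["asdta_alpha"] = trace["asdta_alpha"].data  # shared across trials
        return ForwardTrace(**npy)

    def predict_logits(self, x_fb: np.ndarray, masks: np.ndarray) -> np.ndarray:
        return self._forward(x_fb, masks, training=False)["logits"].data

    def spatial_conv_forward(self, trial_views: np.ndarray) -> np.ndarray:
        """(N_b, C, T) -> (m, T): spatial conv + BN (eval) + ELU."""
        out = self._spatial(Tensor(np.asarray(trial_views, dtype=self.dtype)[None]),
                            training=False)
        return out.data[0]

    def spectral_fuse(self, trial_views: np.ndarray) -> np.ndarray:
        """(N_b, C, T) -> (C, t) node features."""
        out = self._spectral_fuse(
            Tensor(np.asarray(trial_views, dtype=self.dtype)[None]), training=False
        )
        return out.data[0]

    def gatv2_forward(self, H: np.ndarray, adjacency) -> np.ndarray:
        """(C, t) node features + adjacency -> (C, t) attended features."""
        mask = self._mask_from_adjacency(adjacency, self.config.C)[None]
        out = self._gat(Tensor(np.asarray(H, dtype=self.dtype)[None]), mask,
                        training=False)
        return out.data[0]

    def acsim_forward(self, x_estf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        out, u = self._acsim(Tensor(np.asarray(x_estf, dtype=self.dtype)[None]))
        return out.data[0], u.data[0]

    def asdta_forward(self, x_acsif: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        out, alpha = self._asdta(Tensor(np.asarray(x_acsif, dtype=self.dtype)[None]))
        return out.data[0], alpha.data

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        """Single-file archive: parameter tensors, BN stats, embedded config."""
        with zipfile.ZipFile(path, "w") as z:
            meta = {**self.config.to_dict(), "dtype": np.dtype(self.dtype).name}
            z.writestr("config.json", json.dumps(meta, indent=1))
            for name, p in self.named_parameters().items():
                z.writestr(f"param/{name}.npy", _np_bytes(p.data))
            for bn_name, bn in self._bn_layers().items():
                z.writestr(f"stat/{bn_name}.mean.npy", _np_bytes(bn.running_mean))
                z.writestr(f"stat/{bn_name}.var.npy", _np_bytes(bn.running_var))

    def _bn_layers(self) -> dict[str, _BatchNorm]:
        return {"bn_spatial": self.bn_spatial, "bn_point": self.bn_point,
                "bn_gat": self.bn_gat}

    @classmethod
    def load(cls, path) -> "MIGraphNet":
        with zipfile.ZipFile(path) as z:
            meta = json.loads(z.read("config.json"))
            cfg = ModelConfig.from_dict(meta)
            model = cls(cfg, dtype=np.dtype(meta.get("dtype", "float32")))
            for name, p in model.named_parameters().items():
                p.data = _np_load(z.read(f"param/{name}.npy")).astype(model.dtype)
            for bn_name, bn in model._bn_layers().items():
                bn.running_mean = _np_load(z.read(f"stat/{bn_name}.mean.npy"))
                bn.running_var = _np_load(z.read(f"stat/{bn_name}.var.npy"))
        return model

    def band_energy(self) -> np.ndarray:
        """Squared-weight energy of the spatial filters per filter-bank band."""
        cfg = self.config
        w = self.spatial_w.data.reshape(cfg.m, cfg.n_bands, cfg.C)
        return (w ** 2).sum(axis=(0, 2))


def _np_bytes(arr: np.ndarray) -> bytes:
    buf = io.BytesIO()
    np.save(buf, arr)
    return buf.getvalue()


def _np_load(raw: bytes) -> np.ndarray:
    return np.load(io.BytesIO(raw))
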