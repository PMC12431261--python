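"""Conditional adversarial model for temporal measurement series.

The generator maps a latent noise vector concatenated with a condition vector
(a statistical summary of the constrained static event data: binned/one-hot
demographics, multi-hot outcome labels, event-count features) to a fixed
grid of measurements; learned positional encodings are added before a
self-attention block, and a sigmoid head keeps outputs inside the per-variable
min-max range observed in training.  The discriminator mirrors the generator
and pools over time to a scalar real/fake probability.  Training follows the
minimax objective

    min_G max_D  E_t[log D(t | c)] + E_z[log(1 - D(G(z, c)))]

with alternating Adam updates; the standard non-saturating generator loss is
available behind a config flag (off by default).  The generator loss also
carries a conditional moment-matching auxiliary (first and second group
moments plus within-series temporal variance; ``moment_weight`` disables it
at 0) that pins per-condition statistics the adversarial signal alone leaves
loose.

Irregular input series are regularized to the model grid by
last-observation-carried-forward with per-variable observed masks; the
adversarial game runs over the value channels on fixed-shape tensors, and
generated missingness is replicated from the empirical per-cell observation
rates rather than learned adversarially.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._autodiff import Adam, Tensor
from .data_model import StaticEventData, TemporalPoint, TemporalSeries, QA_CONSTRAINED, QA_RAW


# ---------------------------------------------------------------------------
# condition encoding

@dataclass
class ConditionSchema:
    """Declared encoding of constrained static event data into a fixed vector.

    Blocks, in order: one-hot per categorical demographic field, binned age,
    multi-hot outcome labels, scaled event count.
    """

    categorical_fields: dict[str, list[str]] = field(default_factory=dict)
    age_bins: list[float] = field(default_factory=lambda: [18, 40, 65, 80])
    labels: list[str] = field(default_factory=list)
    event_count_scale: float = 10.0

    @property
    def width(self) -> int:
        w = sum(len(v) for v in self.categorical_fields.values())
        w += len(self.age_bins) + 1
        w += len(self.labels)
        w += 1  # event count
        return w

    def encode(self, m: StaticEventData) -> np.ndarray:
        blocks: list[np.ndarray] = []
        for fname in sorted(self.categorical_fields):
            cats = self.categorical_fields[fname]
            v = np.zeros(len(cats))
            val = str(m.covariates.get(fname, ""))
            if val in cats:
                v[cats.index(val)] = 1.0
            blocks.append(v)
        age_vec = np.zeros(len(self.age_bins) + 1)
        try:
            age = float(m.covariates.get("age", "nan"))
            age_vec[int(np.searchsorted(self.age_bins, age))] = 1.0
        except (TypeError, ValueError):
            pass
        blocks.append(age_vec)
        lab = np.array([1.0 if l in m.outcomes else 0.0 for l in self.labels])
        blocks.append(lab)
        blocks.append(np.array([len(m.events) / self.event_count_scale]))
        return np.concatenate(blocks) if blocks else np.zeros(0)


def summarize_condition(m: StaticEventData, schema: ConditionSchema) -> np.ndarray:
    """Deterministic condition vector; only constrained records may condition
    the model."""
    if m.qa_status != QA_CONSTRAINED:
        raise ValueError("summarize_condition requires qa_status=constrained")
    return schema.encode(m)


# ---------------------------------------------------------------------------
# configuration and model state

@dataclass
class GANConfig:
    n_variables: int
    latent_dim: int = 8
    sequence_length: int = 8
    grid_hours: int = 6
    hidden: int = 32
    attention_heads: int = 1
    epochs: int = 200
    batch_size: int = 64
    lr_generator: float = 1e-3
    lr_discriminator: float = 1e-3
    non_saturating: bool = False
    lr_decay: bool = True  # linear decay of both learning rates to 10%
    ema_decay: float = 0.999  # exponential moving average of generator weights
    instance_noise: float = 0.1  # initial std of decaying noise fed to D inputs
    d_steps: int = 1  # discriminator updates per generator update
    moment_weight: float = 100.0  # conditional moment-matching auxiliary (0 disables)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden % self.attention_heads != 0:
            raise ValueError("hidden must be divisible by attention_heads")


def _init_params(cfg: GANConfig, cond_dim: int, rng: np.random.Generator) -> dict[str, Tensor]:
    """Glorot-scaled parameters for generator (g_*) and discriminator (d_*)."""
    L, H, V = cfg.sequence_length, cfg.hidden, cfg.n_variables
    C = V  # adversarial game runs over the value channels
    nh, Hh = cfg.attention_heads, cfg.hidden // cfg.attention_heads

    def glorot(*shape):
        fan = sum(shape)
        return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan), size=shape))

    p: dict[str, Tensor] = {
        "g_in_w": glorot(cfg.latent_dim + cond_dim, H), "g_in_b": Tensor(np.zeros(H)),
        "g_pos": Tensor(rng.normal(0, 0.1, size=(L, H))),
        "g_head_w": glorot(H, C), "g_head_b": Tensor(np.zeros(C)),
        "g_skip_w": glorot(cond_dim, C),  # direct condition -> output path
        "d_in_w": glorot(C + cond_dim, H), "d_in_b": Tensor(np.zeros(H)),
        "d_pos": Tensor(rng.normal(0, 0.1, size=(L, H))),
        # mix layer sees attention features, raw per-variable time-means and
        # the condition, so conditional mean mismatches are linearly visible
        "d_mix_w": glorot(H + C + cond_dim, H), "d_mix_b": Tensor(np.zeros(H)),
        "d_out_w": glorot(H, 1), "d_out_b": Tensor(np.zeros(1)),
    }
    for side in ("g", "d"):
        for h in range(nh):
            p[f"{side}_wq{h}"] = glorot(H, Hh)
            p[f"{side}_wk{h}"] = glorot(H, Hh)
            p[f"{side}_wv{h}"] = glorot(H, Hh)
            p[f"{side}_wo{h}"] = glorot(Hh, H)
    return p


def _attention(x: Tensor, params: dict[str, Tensor], side: str, cfg: GANConfig) -> Tensor:
    """Residual multi-head self-attention block with tanh output."""
    nh = cfg.attention_heads
    Hh = cfg.hidden // nh
    scale = 1.0 / np.sqrt(Hh)
    y: Optional[Tensor] = None
    for h in range(nh):
        q = x @ params[f"{side}_wq{h}"]
        k = x @ params[f"{side}_wk{h}"]
        v = x @ params[f"{side}_wv{h}"]
        att = (q @ _swap(k)) * scale
        a = att.softmax(axis=-1)
        head = (a @ v) @ params[f"{side}_wo{h}"]
        y = head if y is None else y + head
    return (x + y).tanh()


def _swap(t: Tensor) -> Tensor:
    """Transpose the last two axes (manual op: reshape-free swapaxes)."""
    out = Tensor(np.swapaxes(t.data, -1, -2), (t,))

    def _backward():
        t.grad += np.swapaxes(out.grad, -1, -2)
    out._backward = _backward
    return out


def _generator_forward(z: np.ndarray, cond: np.ndarray, params: dict[str, Tensor],
                       cfg: GANConfig) -> Tensor:
    """z carries ``latent_dim`` fresh noise coordinates per time step, so the
    generator can span the full per-step measurement noise, not just a
    low-dimensional series manifold."""
    B = z.shape[0]
    L, H = cfg.sequence_length, cfg.hidden
    cond_rep = np.repeat(cond[:, None, :], L, axis=1)             # (B, L, Cd)
    inp = Tensor(np.concatenate([z, cond_rep], axis=2))           # (B, L, Z+Cd)
    h0 = (inp @ params["g_in_w"] + params["g_in_b"]).tanh()       # (B, L, H)
    x = h0 + params["g_pos"]                                      # (B, L, H)
    x = _attention(x, params, "g", cfg)
    skip = (Tensor(cond) @ params["g_skip_w"]).reshape(B, 1, -1)
    out = (x @ params["g_head_w"] + params["g_head_b"] + skip).sigmoid()  # (B, L, V)
    return out


def _discriminator_forward(x: Tensor, cond: np.ndarray, params: dict[str, Tensor],
                           cfg: GANConfig) -> Tensor:
    B, L = x.shape[0], cfg.sequence_length
    cond_t = Tensor(np.repeat(cond[:, None, :], L, axis=1))       # (B, L, C)
    # concatenate along channels without a dedicated op: project separately
    inp = _concat_channels(x, cond_t)
    h = (inp @ params["d_in_w"] + params["d_in_b"]).tanh() + params["d_pos"]
    h = _attention(h, params, "d", cfg)
    pooled = h.mean(axis=1)                                       # (B, H)
    value_means = x.mean(axis=1)                                  # (B, C)
    mixed = (_concat_channels(_concat_channels(pooled, value_means), Tensor(cond))
             @ params["d_mix_w"] + params["d_mix_b"]).tanh()
    return (mixed @ params["d_out_w"] + params["d_out_b"]).sigmoid()


def _concat_channels(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(np.concatenate([a.data, b.data], axis=-1), (a, b))
    na = a.data.shape[-1]

    def _backward():
        a.grad += out.grad[..., :na]
        b.grad += out.grad[..., na:]
    out._backward = _backward
    return out


@dataclass
class GANModel:
    """Trained parameter state plus the config and scaling that produced it.

    ``mask_rates`` holds the empirical per-(grid step, variable) observation
    probability of the training data; generated series replicate missingness
    by seeded Bernoulli draws from these rates rather than learning them
    adversarially (a constant observed channel would otherwise hand the
    discriminator a degenerate separating direction)."""

    cfg: GANConfig
    cond_dim: int
    variables: list[str]
    params: dict[str, Tensor]
    var_min: np.ndarray
    var_max: np.ndarray
    mask_rates: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    history: list[dict] = field(default_factory=list)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"param__{k}": v.data for k, v in self.params.items()}
        meta = json.dumps({
            "cfg": asdict(self.cfg), "cond_dim": self.cond_dim,
            "variables": self.variables, "history": self.history,
            "format_version": "1.0",
        })
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 var_min=self.var_min, var_max=self.var_max,
                 mask_rates=self.mask_rates, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GANModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            params = {k[len("param__"):]: Tensor(data[k])
                      for k in data.files if k.startswith("param__")}
            return cls(cfg=GANConfig(**meta["cfg"]), cond_dim=meta["cond_dim"],
                       variables=meta["variables"], params=params,
                       var_min=data["var_min"], var_max=data["var_max"],
                       mask_rates=data["mask_rates"], history=meta["history"])


# ---------------------------------------------------------------------------
# grid regularization and scaling

def series_to_grid(series: TemporalSeries, variables: Sequence[str],
                   cfg: GANConfig) -> tuple[np.ndarray, np.ndarray]:
    """(values, mask) on the model grid via last-observation-carried-forward."""
    L, V = cfg.sequence_length, len(variables)
    idx = {v: i for i, v in enumerate(variables)}
    values = np.zeros((L, V))
    mask = np.zeros((L, V))
    last = np.full(V, np.nan)
    pt_iter = iter(series.points)
    current = next(pt_iter, None)
    for step in range(L):
        t_hi = (step + 1) * cfg.grid_hours
        observed_here = np.zeros(V, dtype=bool)
        while current is not None and current.time < t_hi:
            for name, value in current.measurements:
                if name in idx:
                    last[idx[name]] = value
                    observed_here[idx[name]] = True
            current = next(pt_iter, None)
        carried = ~np.isnan(last)
        values[step, carried] = last[carried]
        mask[step] = observed_here.astype(float)
    return values, mask


def _fit_scaler(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variable observed min/max over the training tensor (N, L, V)."""
    V = values.shape[-1]
    vmin, vmax = np.zeros(V), np.ones(V)
    for j in range(V):
        obs = values[..., j][mask[..., j] > 0]
        if obs.size:
            vmin[j], vmax[j] = obs.min(), obs.max()
            if vmax[j] <= vmin[j]:
                vmax[j] = vmin[j] + 1.0
    return vmin, vmax


def _scale(values: np.ndarray, vmin: np.ndarray, vmax: np.ndarray) -> np.ndarray:
    return (values - vmin) / (vmax - vmin)


def _unscale(scaled: np.ndarray, vmin: np.ndarray, vmax: np.ndarray) -> np.ndarray:
    return scaled * (vmax - vmin) + vmin


# ---------------------------------------------------------------------------
# training and generation

def train_gan(real: Sequence[tuple[TemporalSeries, np.ndarray]], cfg: GANConfig,
              variables: Optional[Sequence[str]] = None) -> GANModel:
    """Train on (series, condition) pairs; fully seeded, loss trace recorded.

    With ``cfg.epochs == 0`` the returned model is its seeded initialization.
    """
    if len(real) < 2:
        raise ValueError("train_gan needs at least 2 training pairs")
    if variables is None:
        seen: dict[str, None] = {}
        for series, _ in real:
            for name in series.variables():
                seen.setdefault(name)
        variables = sorted(seen)
    cond_dim = len(real[0][1])
    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, cond_dim, rng)

    grids = [series_to_grid(s, variables, cfg) for s, _ in real]
    values = np.stack([g[0] for g in grids])
    masks = np.stack([g[1] for g in grids])
    conds = np.stack([c for _, c in real]).astype(float)
    vmin, vmax = _fit_scaler(values, masks)
    x_real = _scale(values, vmin, vmax)

    model = GANModel(cfg=cfg, cond_dim=cond_dim, variables=list(variables),
                     params=params, var_min=vmin, var_max=vmax,
                     mask_rates=masks.mean(axis=0))
    if cfg.epochs == 0:
        return model

    g_params = {k: v for k, v in params.items() if k.startswith("g_")}
    d_params = {k: v for k, v in params.items() if k.startswith("d_")}
    opt_g = Adam(g_params, lr=cfg.lr_generator)
    opt_d = Adam(d_params, lr=cfg.lr_discriminator)
    ema = {k: v.data.copy() for k, v in g_params.items()}
    n = len(real)
    for epoch in range(cfg.epochs):
        if cfg.lr_decay:
            frac = 1.0 - 0.9 * epoch / max(cfg.epochs - 1, 1)
            opt_g.lr = cfg.lr_generator * frac
            opt_d.lr = cfg.lr_discriminator * frac
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        # decaying instance noise fed to the discriminator smooths the game
        noise_std = cfg.instance_noise * (1.0 - epoch / max(cfg.epochs - 1, 1))
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb, cb = x_real[sel], conds[sel]
            B = len(sel)
            # --- discriminator ascent on log D(real) + log(1 - D(fake))
            for _ in range(cfg.d_steps):
                z = rng.standard_normal((B, cfg.sequence_length, cfg.latent_dim))
                fake = _generator_forward(z, cb, params, cfg).data  # detached
                opt_d.zero_grad()
                xb_noisy = xb + noise_std * rng.standard_normal(xb.shape)
                fake_noisy = fake + noise_std * rng.standard_normal(fake.shape)
                d_real = _discriminator_forward(Tensor(xb_noisy), cb, params, cfg)
                d_fake = _discriminator_forward(Tensor(fake_noisy), cb, params, cfg)
                d_obj = d_real.log().mean() + (1.0 - d_fake).log().mean()
                d_loss = -d_obj
                if not np.all(np.isfinite(d_loss.data)):
                    raise FloatingPointError(f"non-finite discriminator loss at epoch {epoch}")
                d_loss.backward()
                opt_d.step()
            # --- generator step
            z = rng.standard_normal((B, cfg.sequence_length, cfg.latent_dim))
            opt_g.zero_grad()
            fake_t = _generator_forward(z, cb, params, cfg)
            fake_adv = fake_t
            if noise_std > 0:
                fake_adv = fake_t + Tensor(noise_std * rng.standard_normal(fake_t.shape))
            d_on_fake = _discriminator_forward(fake_adv, cb, params, cfg)
            if cfg.non_saturating:
                g_loss = -(d_on_fake.log().mean())
            else:
                g_loss = (1.0 - d_on_fake).log().mean()
            if cfg.moment_weight > 0:
                # conditional first moments: for every distinct condition
                # vector in the batch, match the fake group mean to the real
                # group mean (direct empirical estimate of E[x | c])
                lv = cfg.sequence_length * cfg.n_variables
                f_flat = fake_t.reshape(B, lv)
                r_flat = xb.reshape(B, lv)
                _, inverse = np.unique(cb, axis=0, return_inverse=True)
                n_groups = int(inverse.max()) + 1
                w = np.zeros((n_groups, B))
                w[inverse, np.arange(B)] = 1.0
                w /= w.sum(axis=1, keepdims=True)
                wt = Tensor(w)
                diff = wt @ f_flat - Tensor(w @ r_flat)
                diff2 = wt @ (f_flat * f_flat) - Tensor(w @ (r_flat * r_flat))
                # within-series temporal variance per variable: the embedding
                # features (std, min, max) collapse without it
                f_center = fake_t - fake_t.mean(axis=1, keepdims=True)
                f_tvar = (f_center * f_center).mean(axis=1)          # (B, V)
                xb3 = xb.reshape(B, cfg.sequence_length, cfg.n_variables)
                r_tvar = ((xb3 - xb3.mean(axis=1, keepdims=True)) ** 2).mean(axis=1)
                r_group_tvar = w @ r_tvar
                diff_tv = (wt @ f_tvar - Tensor(r_group_tvar)) \
                    * Tensor(1.0 / (r_group_tvar + 1e-3))  # relative error
                mm = (diff * diff).mean() + (diff2 * diff2).mean() \
                    + 0.2 * (diff_tv * diff_tv).mean()
                g_loss = g_loss + cfg.moment_weight * mm
            if not np.all(np.isfinite(g_loss.data)):
                raise FloatingPointError(f"non-finite generator loss at epoch {epoch}")
            g_loss.backward()
            opt_g.step()
            for k in ema:
                ema[k] = cfg.ema_decay * ema[k] + (1 - cfg.ema_decay) * g_params[k].data
            d_losses.append(float(d_loss.data))
            g_losses.append(float(g_loss.data))
        model.history.append({"epoch": epoch,
                              "d_loss": float(np.mean(d_losses)),
                              "g_loss": float(np.mean(g_losses))})
    # generation uses the averaged generator (smooths adversarial oscillation)
    for k, avg in ema.items():
        params[k].data = avg
    return model


def discriminator_accuracy(model: GANModel, real: Sequence[tuple[TemporalSeries, np.ndarray]],
                           seed: int = 0) -> float:
    """Held-out real-vs-generated accuracy of the trained discriminator."""
    cfg = model.cfg
    grids = [series_to_grid(s, model.variables, cfg) for s, _ in real]
    values = np.stack([g[0] for g in grids])
    conds = np.stack([c for _, c in real]).astype(float)
    x_real = _scale(values, model.var_min, model.var_max)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(real), cfg.sequence_length, cfg.latent_dim))
    fake = _generator_forward(z, conds, model.params, cfg).data
    p_real = _discriminator_forward(Tensor(x_real), conds, model.params, cfg).data.ravel()
    p_fake = _discriminator_forward(Tensor(fake), conds, model.params, cfg).data.ravel()
    correct = (p_real > 0.5).sum() + (p_fake <= 0.5).sum()
    return float(correct) / (2 * len(real))


def generate_temporal(model: GANModel, condition: np.ndarray, n_samples: int,
                      seed: int = 0) -> list[TemporalSeries]:
    """Sample series on the model grid for one condition vector; qa_status=raw."""
    if len(condition) != model.cond_dim:
        raise ValueError(
            f"condition dimension {len(condition)} != model cond_dim {model.cond_dim}")
    if n_samples == 0:
        return []
    cfg = model.cfg
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, cfg.sequence_length, cfg.latent_dim))
    cond = np.repeat(condition[None, :].astype(float), n_samples, axis=0)
    scaled = _generator_forward(z, cond, model.params, cfg).data
    V = cfg.n_variables
    values = _unscale(scaled, model.var_min, model.var_max)
    rates = model.mask_rates if model.mask_rates.size else np.ones(
        (cfg.sequence_length, V))
    mask = rng.random((n_samples, cfg.sequence_length, V)) < rates
    series_list = []
    for i in range(n_samples):
        points = []
        for step in range(cfg.sequence_length):
            meas = [(model.variables[j], float(values[i, step, j]))
                    for j in range(V) if mask[i, step, j]]
            if not meas:  # degenerate draw: keep the grid point fully observed
                meas = [(model.variables[j], float(values[i, step, j])) for j in range(V)]
            points.append(TemporalPoint(step * cfg.grid_hours, meas))
        series_list.append(TemporalSeries(points=points, qa_status=QA_RAW))
    return series_list
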