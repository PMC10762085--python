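"""Adversarial training loops.

Two modes share one loop skeleton:

* ``cgan`` — conditional Wasserstein GAN.  The critic is trained to maximize
  the empirical Wasserstein loss E[D(x, y) - D(G(z, y), y)] minus a
  two-sided gradient penalty lambda_gp * (||grad_xhat D(xhat, y)|| - 1)^2 on
  random interpolates xhat between real and generated sequences; the
  generator minimizes -E[D(G(z, y), y)].  In this mode the generator update
  never touches a real sequence x except through the critic's score.
* ``pix2pix`` — deterministic baseline.  The generator takes only y (no
  latent), batch normalization replaces CIN, and the generator objective
  adds an L1 reconstruction term lambda_l1 * E||G(y) - x||_1.

Training is seeded and exactly resumable: a :class:`TrainState` carries the
network parameters, both optimizer states, the loss curves and the RNG
state, so 10 + 10 epochs from a checkpoint reproduce 20 straight epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, grad
from .networks import Critic, CriticSpec, Generator, GeneratorSpec, sample_latent
from .nn import Adam
from .phantom import PairedDataset

__all__ = [
    "TrainConfig",
    "TrainState",
    "wgan_loss",
    "gradient_penalty",
    "train_cgan",
    "train_pix2pix",
    "dataset_arrays",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    mode: str = "cgan"  # "cgan" | "pix2pix"
    epochs: int = 10
    batch_size: int = 8
    n_critic: int = 5
    lambda_gp: float = 10.0
    # Lazy regularization: apply the gradient penalty on every k-th critic
    # step with its weight scaled by k (same average penalty, less compute).
    gp_every: int = 1
    lambda_l1: float = 100.0  # pix2pix only
    lr: float = 1e-4
    lr_critic: float | None = None  # defaults to lr; a higher critic rate
    # (two-time-scale training) sharpens the Wasserstein estimate
    betas: tuple[float, float] = (0.5, 0.9)
    seed: int = 0
    log_every: int = 10
    divergence_threshold: float = 1e6
    # Linearly decay both learning rates to zero over `total_epochs` (default:
    # the configured epoch count); stabilizes the late-training equilibrium.
    lr_decay: bool = True
    # Exponential moving average of generator weights used at evaluation
    # time; damps the step-to-step wobble of the adversarial equilibrium.
    ema_decay: float = 0.999

    def validate(self) -> None:
        if self.mode not in ("cgan", "pix2pix"):
            raise ValueError("mode must be 'cgan' or 'pix2pix'")
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        if min(self.lambda_gp, self.lambda_l1, self.lr) < 0:
            raise ValueError("weights and learning rate must be non-negative")


@dataclass
class TrainState:
    """Everything needed to continue (or reproduce) a training run."""

    config: TrainConfig
    generator: Generator
    critic: Critic
    epoch: int = 0
    step: int = 0
    critic_steps: int = 0
    history: dict[str, list[float]] = field(
        default_factory=lambda: {"critic_loss": [], "gen_loss": [], "penalty": []}
    )
    rng: np.random.Generator | None = None
    opt_g: Adam | None = None
    opt_d: Adam | None = None
    ema_params: list[np.ndarray] | None = None

    def eval_generator(self) -> Generator:
        """Generator to evaluate/sample with: EMA weights when enabled."""
        if self.ema_params is None:
            return self.generator
        import copy

        g = copy.deepcopy(self.generator)
        g.load_state_dict(self.ema_params)
        return g


def wgan_loss(d_real: Tensor, d_fake: Tensor) -> Tensor:
    """Empirical Wasserstein critic objective: mean(D_real) - mean(D_fake)."""
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("empty critic batch")
    if d_real.size != d_fake.size:
        raise ValueError("real and fake batches must have equal size")
    return d_real.mean() - d_fake.mean()


def gradient_penalty(
    critic: Critic,
    x_real: np.ndarray,
    x_fake: np.ndarray,
    y: np.ndarray,
    lambda_gp: float,
    rng: np.random.Generator,
) -> Tensor:
    """Two-sided penalty on the critic's input-gradient norm.

    Interpolates xhat = eps * x_real + (1 - eps) * x_fake with eps ~ U(0, 1)
    per sample, and returns lambda_gp * mean((||grad_xhat D(xhat, y)||_2 - 1)^2).
    The result carries the double-backward graph needed to differentiate it
    with respect to the critic parameters.
    """
    if lambda_gp < 0:
        raise ValueError("lambda_gp must be non-negative")
    b = x_real.shape[0]
    dtype = critic.dtype
    eps = rng.uniform(size=(b, 1, 1, 1))
    xhat = Tensor(
        (eps * x_real + (1.0 - eps) * x_fake).astype(dtype), requires_grad=True
    )
    d_sum = critic(xhat, np.asarray(y)).sum()
    g = grad(d_sum, [xhat], create_graph=True)[0]
    gnorm = ((g**2.0).sum(axis=(1, 2, 3)) + 1e-12) ** 0.5
    return lambda_gp * ((gnorm - 1.0) ** 2.0).mean()


def dataset_arrays(dataset: PairedDataset) -> tuple[np.ndarray, np.ndarray]:
    """Stack a filled dataset into (X, Y) arrays of shape [M, 4, H, W]."""
    if not dataset.pairs:
        raise ValueError("training dataset is empty")
    xs, ys = [], []
    for pair in dataset.pairs:
        if pair.filled is None:
            raise ValueError(
                "pairs must be filled with the linear reconstructor first "
                "(see linear_recon.fill_dataset)"
            )
        xs.append(pair.x.phases)
        ys.append(pair.filled.phases)
    return np.stack(xs), np.stack(ys)


def _check_finite(value: float, cfg: TrainConfig, what: str) -> None:
    if not np.isfinite(value) or abs(value) > cfg.divergence_threshold:
        raise RuntimeError(f"training diverged: {what} = {value}")


def _critic_step(state: TrainState, x, y, cfg) -> tuple[float, float]:
    G, D, rng = state.generator, state.critic, state.rng
    b = x.shape[0]
    if cfg.mode == "cgan":
        z = sample_latent(rng, b, G.spec.latent_dim)
        x_fake = G(y, z).detach().data
    else:
        x_fake = G(y).detach().data
    d_real = D(x, y)
    d_fake = D(x_fake, y)
    # ascend the Wasserstein objective = descend its negation (plus penalty)
    loss = -wgan_loss(d_real, d_fake)
    pen_value = 0.0
    if state.critic_steps % cfg.gp_every == 0:
        pen = gradient_penalty(
            D, x, x_fake, y, cfg.lambda_gp * cfg.gp_every, rng
        )
        loss = loss + pen
        pen_value = float(pen.item())
    state.critic_steps += 1
    grads = grad(loss, D.parameters())
    state.opt_d.step(grads)
    return float(loss.item()), pen_value


def _generator_step_cgan(state: TrainState, y, cfg) -> float:
    """cGAN generator update: sees only y and the critic's score (never x)."""
    G, D, rng = state.generator, state.critic, state.rng
    z = sample_latent(rng, y.shape[0], G.spec.latent_dim)
    x_fake = G(y, z)
    loss = -(D(x_fake, np.asarray(y)).mean())
    grads = grad(loss, G.parameters())
    state.opt_g.step(grads)
    return float(loss.item())


def _generator_step_pix2pix(state: TrainState, x, y, cfg) -> float:
    G, D = state.generator, state.critic
    x_fake = G(y)
    l1 = (x_fake - Tensor(np.asarray(x, dtype=G.dtype))).abs().mean()
    loss = -(D(x_fake, np.asarray(y)).mean()) + cfg.lambda_l1 * l1
    grads = grad(loss, G.parameters())
    state.opt_g.step(grads)
    return float(loss.item())


def _init_state(
    dataset: PairedDataset,
    gen_spec: GeneratorSpec,
    critic_spec: CriticSpec,
    cfg: TrainConfig,
) -> TrainState:
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    s_init, s_loop = ss.spawn(2)
    init_rng = np.random.default_rng(s_init)
    G = Generator(gen_spec, init_rng)
    D = Critic(critic_spec, init_rng)
    state = TrainState(config=cfg, generator=G, critic=D)
    state.rng = np.random.default_rng(s_loop)
    state.opt_g = Adam(G.parameters(), lr=cfg.lr, betas=cfg.betas)
    state.opt_d = Adam(D.parameters(), lr=cfg.lr_critic or cfg.lr, betas=cfg.betas)
    if cfg.ema_decay:
        state.ema_params = [p.data.copy() for p in G.parameters()]
    return state


def _train(
    dataset: PairedDataset,
    gen_spec: GeneratorSpec,
    critic_spec: CriticSpec,
    cfg: TrainConfig,
    state: TrainState | None,
    epochs: int | None,
    checkpoint_dir: str | Path | None,
) -> TrainState:
    if state is None:
        state = _init_state(dataset, gen_spec, critic_spec, cfg)
    cfg = state.config
    X, Y = dataset_arrays(dataset)
    m = X.shape[0]
    b = min(cfg.batch_size, m)
    target_epoch = state.epoch + (epochs if epochs is not None else cfg.epochs)

    while state.epoch < target_epoch:
        if cfg.lr_decay:
            # decay against the configured total epoch budget so a resumed
            # run follows the same schedule as an uninterrupted one
            frac = max(0.0, 1.0 - state.epoch / max(1, cfg.epochs))
            state.opt_g.lr = cfg.lr * frac
            state.opt_d.lr = (cfg.lr_critic or cfg.lr) * frac
        rng = state.rng
        order = rng.permutation(m)
        n_batches = m // b
        groups = max(1, n_batches)
        for g_i in range(0, groups, cfg.n_critic):
            chunk = range(g_i, min(g_i + cfg.n_critic, groups))
            for c_i in chunk:
                idx = order[c_i * b : (c_i + 1) * b]
                c_loss, pen = _critic_step(state, X[idx], Y[idx], cfg)
                state.history["critic_loss"].append(c_loss)
                state.history["penalty"].append(pen)
                _check_finite(c_loss, cfg, "critic loss")
            idx = rng.choice(m, size=b, replace=False)
            if cfg.mode == "cgan":
                g_loss = _generator_step_cgan(state, Y[idx], cfg)
            else:
                g_loss = _generator_step_pix2pix(state, X[idx], Y[idx], cfg)
            state.history["gen_loss"].append(g_loss)
            _check_finite(g_loss, cfg, "generator loss")
            if state.ema_params is not None:
                d = cfg.ema_decay
                for e, p in zip(state.ema_params, state.generator.parameters()):
                    e *= d
                    e += (1.0 - d) * p.data
            state.step += 1
        state.epoch += 1
        if checkpoint_dir is not None:
            save_checkpoint(state, Path(checkpoint_dir) / "checkpoint.npz")
    return state


def train_cgan(
    dataset: PairedDataset,
    gen_spec: GeneratorSpec,
    critic_spec: CriticSpec,
    cfg: TrainConfig,
    state: TrainState | None = None,
    epochs: int | None = None,
    checkpoint_dir: str | Path | None = None,
) -> TrainState:
    """Train the conditional Wasserstein GAN (n_critic ascents per descent)."""
    if state is None and cfg.mode != "cgan":
        raise ValueError("train_cgan requires mode='cgan'")
    return _train(dataset, gen_spec, critic_spec, cfg, state, epochs, checkpoint_dir)


def train_pix2pix(
    dataset: PairedDataset,
    gen_spec: GeneratorSpec,
    critic_spec: CriticSpec,
    cfg: TrainConfig,
    state: TrainState | None = None,
    epochs: int | None = None,
    checkpoint_dir: str | Path | None = None,
) -> TrainState:
    """Train the deterministic pix2pix-style baseline (adversarial + L1)."""
    if state is None:
        if cfg.mode != "pix2pix":
            raise ValueError("train_pix2pix requires mode='pix2pix'")
        if gen_spec.norm != "batch":
            raise ValueError("pix2pix generator must use batch normalization")
    return _train(dataset, gen_spec, critic_spec, cfg, state, epochs, checkpoint_dir)


# -- checkpointing -------------------------------------------------------------


def save_checkpoint(state: TrainState, path: str | Path) -> None:
    """Serialize parameters, optimizer state, RNG state and loss curves."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(state.generator.state_dict()):
        arrays[f"g_{i}"] = p
    for i, p in enumerate(state.critic.state_dict()):
        arrays[f"d_{i}"] = p
    for name, opt in (("og", state.opt_g), ("od", state.opt_d)):
        s = opt.state()
        for i, (m, v) in enumerate(zip(s["m"], s["v"])):
            arrays[f"{name}_m_{i}"] = m
            arrays[f"{name}_v_{i}"] = v
    bn_means, bn_vars = _batchnorm_buffers(state.generator)
    for i, (m, v) in enumerate(zip(bn_means, bn_vars)):
        arrays[f"bn_mean_{i}"] = m
        arrays[f"bn_var_{i}"] = v
    if state.ema_params is not None:
        for i, e in enumerate(state.ema_params):
            arrays[f"ema_{i}"] = e
    meta = {
        "config": asdict(state.config),
        "gen_spec": asdict(state.generator.spec),
        "critic_spec": asdict(state.critic.spec),
        "epoch": state.epoch,
        "step": state.step,
        "critic_steps": state.critic_steps,
        "opt_t": {"og": state.opt_g.t, "od": state.opt_d.t},
        "history": state.history,
        "rng_state": _encode_rng(state.rng),
    }
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> TrainState:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg_d = meta["config"]
        cfg_d["betas"] = tuple(cfg_d["betas"])
        cfg = TrainConfig(**cfg_d)
        gs_d = meta["gen_spec"]
        cs_d = meta["critic_spec"]
        cs_d["fc_widths"] = tuple(cs_d["fc_widths"])
        gen_spec = GeneratorSpec(**gs_d)
        critic_spec = CriticSpec(**cs_d)
        init_rng = np.random.default_rng(0)  # overwritten by loaded weights
        G = Generator(gen_spec, init_rng)
        D = Critic(critic_spec, init_rng)
        G.load_state_dict(
            [data[f"g_{i}"] for i in range(len(G.parameters()))]
        )
        D.load_state_dict(
            [data[f"d_{i}"] for i in range(len(D.parameters()))]
        )
        state = TrainState(config=cfg, generator=G, critic=D)
        state.epoch = int(meta["epoch"])
        state.step = int(meta["step"])
        state.critic_steps = int(meta.get("critic_steps", 0))
        state.history = {k: list(v) for k, v in meta["history"].items()}
        state.rng = _decode_rng(meta["rng_state"])
        state.opt_g = Adam(G.parameters(), lr=cfg.lr, betas=cfg.betas)
        state.opt_d = Adam(D.parameters(), lr=cfg.lr, betas=cfg.betas)
        for name, opt in (("og", state.opt_g), ("od", state.opt_d)):
            n = len(opt.params)
            opt.load_state(
                {
                    "t": meta["opt_t"][name],
                    "m": [data[f"{name}_m_{i}"] for i in range(n)],
                    "v": [data[f"{name}_v_{i}"] for i in range(n)],
                }
            )
        means = [data[k] for k in sorted_keys(data, "bn_mean_")]
        variances = [data[k] for k in sorted_keys(data, "bn_var_")]
        _restore_batchnorm_buffers(G, means, variances)
        ema_keys = sorted_keys(data, "ema_")
        if ema_keys:
            state.ema_params = [data[k].copy() for k in ema_keys]
    return state


def sorted_keys(data, prefix: str) -> list[str]:
    keys = [k for k in data.files if k.startswith(prefix)]
    return sorted(keys, key=lambda k: int(k[len(prefix):]))


def _batchnorm_buffers(module) -> tuple[list[np.ndarray], list[np.ndarray]]:
    from .nn import BatchNorm2d

    means, variances = [], []
    for m in module.modules():
        if isinstance(m, BatchNorm2d):
            means.append(m.running_mean.copy())
            variances.append(m.running_var.copy())
    return means, variances


def _restore_batchnorm_buffers(module, means, variances) -> None:
    from .nn import BatchNorm2d

    i = 0
    for m in module.modules():
        if isinstance(m, BatchNorm2d):
            m.running_mean = means[i].copy()
            m.running_var = variances[i].copy()
            i += 1


def _encode_rng(rng: np.random.Generator) -> dict:
    st = rng.bit_generator.state
    return json.loads(json.dumps(st, default=int))


def _decode_rng(state: dict) -> np.random.Generator:
    rng = np.random.default_rng(0)
    st = rng.bit_generator.state
    st["state"]["state"] = int(state["state"]["state"])
    st["state"]["inc"] = int(state["state"]["inc"])
    if "has_uint32" in state:
        st["has_uint32"] = int(state["has_uint32"])
        st["uinteger"] = int(state["uinteger"])
    rng.bit_generator.state = st
    return rng
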