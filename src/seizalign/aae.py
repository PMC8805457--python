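"""Adversarial autoencoder with cross-domain latent alignment.

The model is a deterministic dense autoencoder G = (encoder, decoder), a
discriminator D on the latent space, and a linear max-margin classifier
head C, trained jointly:

    min_{G,C} max_D   Lcla + lambda0 * Lrec + lambda1 * Jadv + lambda2 * Rdis

* ``Lrec`` — squared reconstruction error of the spectrogram maps;
* ``Jadv`` — GAN cross-entropy pushing the aggregated latent posterior
  toward a Laplace(eta) prior (non-saturating generator form);
* ``Rdis`` — the kernel-MMD alignment penalty over patient domains;
* ``Lcla`` — hinge loss of the classifier head.

Batches are domain-stratified (equal windows per patient per step) so the
alignment term is estimable at every step.  Training is fully reproducible
from the seed: all randomness flows through one numpy generator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, as_tensor, concat
from .mmd import KernelConfig, domain_regularizer

__all__ = [
    "AaeParams", "TrainedModel", "TrainingDivergence",
    "reconstruction_loss", "sample_prior", "adversarial_step",
    "total_objective", "train", "save_model", "load_model",
]

_CLAMP = 1e-7   # discriminator output clamp before log


@dataclass(frozen=True)
class AaeParams:
    """Architecture, prior and optimization settings.

    Trade-off weights ``lambdas = (lambda0, lambda1, lambda2)`` weight the
    reconstruction, adversarial and alignment terms against the hinge loss.
    In the joint objective the reconstruction term is normalized per input
    dimension (lambda0 * Lrec / d), so lambda0 is on the scale of a
    per-pixel squared error and the default 1.05 matches the intracranial
    tuning; lambda1 multiplies a unit-scale GAN cross-entropy (log 2 at an
    undecided discriminator), default 1.0; lambda2 weights the kernel
    alignment penalty (default 2.5: strong enough to align at desk-scale
    batch sizes, ramped in over ``align_warmup_epochs``).  ``eta`` is the Laplace prior scale (variance
    2 eta^2).  The default kernel rescales its bandwidth mixture by the
    batch median distance so the alignment penalty is insensitive to the
    overall latent scale.
    """

    latent_dim: int = 16
    encoder_widths: tuple[int, ...] = (512, 256)
    disc_widths: tuple[int, ...] = (64,)
    eta: float = 1.0
    lambdas: tuple[float, float, float] = (1.05, 1.0, 2.5)
    lr_g: float = 1e-3
    lr_d: float = 1e-3
    epochs: int = 30
    batch_per_domain: int = 16
    margin: float = 1.0
    c_reg: float = 1e-3
    kernel: KernelConfig = field(default_factory=lambda: KernelConfig(
        bandwidths=(0.5, 1.0, 2.0), bandwidth_mode="median"))
    align_metric: str = "mmd"
    #: linear ramp (epochs) on the adversarial and alignment weights: the
    #: embedding forms under reconstruction + hinge first, then gets pulled
    #: together — guards against the collapse optimum of the alignment term
    align_warmup_epochs: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1 or self.eta <= 0:
            raise ValueError("latent_dim >= 1 and eta > 0 required")
        if any(l < 0 for l in self.lambdas):
            raise ValueError("trade-off weights must be non-negative")


class TrainingDivergence(RuntimeError):
    """Raised when a loss component becomes non-finite; carries the partial
    history for diagnosis."""

    def __init__(self, message: str, history: dict):
        super().__init__(message)
        self.history = history


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _init_mlp(rng: np.random.Generator, dims: list[int]) -> list[tuple[Tensor, Tensor]]:
    layers = []
    for d_in, d_out in zip(dims, dims[1:]):
        w = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        layers.append((Tensor(w), Tensor(np.zeros(d_out))))
    return layers


def _forward(layers, x: Tensor) -> Tensor:
    h = x
    for i, (w, b) in enumerate(layers):
        h = h @ w + b
        if i < len(layers) - 1:
            h = h.relu()
    return h


def _forward_np(layers, x: np.ndarray) -> np.ndarray:
    h = np.asarray(x, dtype=float)
    for i, (w, b) in enumerate(layers):
        h = h @ w.value + b.value
        if i < len(layers) - 1:
            h = np.maximum(h, 0.0)
    return h


def _mlp_params(layers):
    return [t for pair in layers for t in pair]


@dataclass
class TrainedModel:
    """Weights plus per-epoch loss history of a joint training run."""

    params: AaeParams
    input_dim: int
    encoder: list
    decoder: list
    discriminator: list
    classifier: list
    history: dict[str, list[float]] = field(default_factory=dict)

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Latent codes of a batch (rows are flattened spectrograms)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} features, got {X.shape[1]}")
        return _forward_np(self.encoder, X)

    def decode(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.params.latent_dim:
            raise ValueError("latent width mismatch")
        return _forward_np(self.decoder, Z)

    def discriminate(self, Z: np.ndarray) -> np.ndarray:
        logits = _forward_np(self.discriminator, np.atleast_2d(Z))
        return 1.0 / (1.0 + np.exp(-logits))

    def classifier_scores(self, X: np.ndarray) -> np.ndarray:
        return _forward_np(self.classifier, self.encode(X)).ravel()


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

_PARTS = ("encoder", "decoder", "discriminator", "classifier")


def save_model(model: TrainedModel, path) -> None:
    """Write a single-archive checkpoint (weights + config + history)."""
    arrays = {}
    for part in _PARTS:
        for i, (w, b) in enumerate(getattr(model, part)):
            arrays[f"{part}_{i}_w"] = w.value
            arrays[f"{part}_{i}_b"] = b.value
    meta = {"params": asdict(model.params), "history": model.history,
            "input_dim": model.input_dim}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8).copy()
    np.savez(path, **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode("utf-8"))
        p = meta["params"]
        p["kernel"] = KernelConfig(**{**p["kernel"],
                                      "bandwidths": tuple(p["kernel"]["bandwidths"])})
        for key in ("encoder_widths", "disc_widths", "lambdas"):
            p[key] = tuple(p[key])
        params = AaeParams(**p)
        parts = {}
        for part in _PARTS:
            layers = []
            i = 0
            while f"{part}_{i}_w" in npz:
                layers.append((Tensor(npz[f"{part}_{i}_w"]),
                               Tensor(npz[f"{part}_{i}_b"])))
                i += 1
            parts[part] = layers
    return TrainedModel(params=params, input_dim=int(meta["input_dim"]),
                        encoder=parts["encoder"], decoder=parts["decoder"],
                        discriminator=parts["discriminator"],
                        classifier=parts["classifier"],
                        history=meta["history"])


# ---------------------------------------------------------------------------
# loss components
# ---------------------------------------------------------------------------

def reconstruction_loss(x, x_tilde):
    """Squared Euclidean reconstruction error, averaged over the batch."""
    xt, xr = as_tensor(x_tilde), as_tensor(x)
    if xt.value.shape != xr.value.shape:
        raise ValueError("shape mismatch between input and reconstruction")
    n = xt.value.shape[0] if xt.value.ndim > 1 else 1
    d = xt - xr
    loss = (d * d).sum() * (1.0 / n)
    if isinstance(x, Tensor) or isinstance(x_tilde, Tensor):
        return loss
    return float(loss.value)


def sample_prior(n: int, l: int, eta: float, rng) -> np.ndarray:
    """i.i.d. Laplace(0, eta) latent prior samples, n x l."""
    if n < 1:
        raise ValueError("n >= 1")
    if eta <= 0:
        raise ValueError("eta must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.laplace(loc=0.0, scale=eta, size=(n, l))


def _disc_prob(disc, z: Tensor) -> Tensor:
    return _forward(disc, z).sigmoid().clip(_CLAMP, 1.0 - _CLAMP)


def adversarial_step(z_f, z_r, disc) -> tuple[Tensor, Tensor]:
    """Discriminator and (non-saturating) generator losses.

    d_loss = -[mean log D(z_r) + mean log(1 - D(z_f))]
    g_loss = -mean log D(z_f)
    """
    d_real = _disc_prob(disc, as_tensor(z_r))
    d_fake = _disc_prob(disc, as_tensor(z_f))
    d_loss = -(d_real.log().mean() + (1.0 - d_fake).log().mean())
    g_loss = -d_fake.log().mean()
    return d_loss, g_loss


def total_objective(lrec, jadv, rdis, lcla, lambdas):
    """Joint generator/classifier objective
    Lcla + lambda0*Lrec + lambda1*Jadv + lambda2*Rdis."""
    l0, l1, l2 = lambdas
    return lcla + l0 * lrec + l1 * jadv + l2 * rdis


def _hinge(scores: Tensor, y_pm: np.ndarray, margin: float) -> Tensor:
    return (margin - scores * y_pm).relu().mean()


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(data: dict[str, tuple[np.ndarray, np.ndarray]],
          params: AaeParams,
          val_data: tuple[np.ndarray, np.ndarray] | None = None,
          early_stop_patience: int | None = None) -> TrainedModel:
    """Jointly train encoder, decoder, discriminator and classifier head.

    ``data`` maps patient_id -> (X, y) with X an n_i x d matrix of flattened
    spectrograms and y in {0, 1}.  Every training domain must supply both
    classes.  Each step takes an equal-size batch from every domain,
    performs one discriminator update on prior-vs-encoded latents (skipped
    when lambda1 = 0), then one generator/classifier update on the joint
    objective.  All four components are recorded per epoch whether or not
    their weight is zero.
    """
    if not data:
        raise ValueError("no training domains")
    doms = sorted(data)
    X = {d: np.asarray(data[d][0], dtype=float) for d in doms}
    y_pm = {d: np.asarray(data[d][1], dtype=float) * 2.0 - 1.0 for d in doms}
    for d in doms:
        if len(np.unique(y_pm[d])) < 2:
            raise ValueError(f"domain {d} lacks one of the two classes")
    dim = X[doms[0]].shape[1]
    l0, l1, l2 = params.lambdas
    l = params.latent_dim

    rng = np.random.default_rng(params.seed)
    enc = _init_mlp(rng, [dim, *params.encoder_widths, l])
    dec = _init_mlp(rng, [l, *reversed(params.encoder_widths), dim])
    disc = _init_mlp(rng, [l, *params.disc_widths, 1])
    cls = _init_mlp(rng, [l, 1])
    opt_g = Adam(_mlp_params(enc) + _mlp_params(dec) + _mlp_params(cls),
                 lr=params.lr_g)
    opt_d = Adam(_mlp_params(disc), lr=params.lr_d)

    bpd = params.batch_per_domain
    steps = max(1, min(X[d].shape[0] for d in doms) // bpd)
    history: dict[str, list[float]] = {k: [] for k in
                                       ("Lrec", "Jadv", "Rdis", "Lcla",
                                        "d_loss", "total")}
    if val_data is not None:
        history["val_loss"] = []
    best_val, best_state, patience_left = np.inf, None, early_stop_patience

    for epoch in range(params.epochs):
        warm = params.align_warmup_epochs
        ramp = min(1.0, (epoch + 1) / warm) if warm > 0 else 1.0
        perms = {d: rng.permutation(X[d].shape[0]) for d in doms}
        acc = {k: 0.0 for k in history if k != "val_loss"}
        for step in range(steps):
            xb = {d: X[d][perms[d][step * bpd:(step + 1) * bpd]] for d in doms}
            yb = np.concatenate([y_pm[d][perms[d][step * bpd:(step + 1) * bpd]]
                                 for d in doms])
            n_tot = sum(b.shape[0] for b in xb.values())

            # discriminator step on detached latents
            z_detached = np.vstack([_forward_np(enc, xb[d]) for d in doms])
            z_r = sample_prior(n_tot, l, params.eta, rng)
            d_loss_t, _ = adversarial_step(Tensor(z_detached), Tensor(z_r), disc)
            if l1 > 0:
                opt_d.zero_grad()
                d_loss_t.backward()
                opt_d.step()

            # generator/classifier step
            z_doms = [_forward(enc, Tensor(xb[d])) for d in doms]
            z_all = concat(z_doms)
            x_all = Tensor(np.vstack([xb[d] for d in doms]))
            lrec = reconstruction_loss(x_all, _forward(dec, z_all))
            _, jadv = adversarial_step(z_all, z_r, disc)
            rdis = domain_regularizer(z_doms, params.kernel,
                                      metric=params.align_metric)
            scores = _forward(cls, z_all).reshape(-1)
            w = cls[0][0]
            lcla = (_hinge(scores, yb, params.margin)
                    + params.c_reg * (w * w).sum())
            total = lcla
            if l0 > 0:
                total = total + (l0 / dim) * lrec   # per-pixel scale
            if l1 > 0:
                total = total + (ramp * l1) * jadv
            if l2 > 0:
                total = total + (ramp * l2) * rdis
            opt_g.zero_grad()
            for p in opt_d.params:
                p.grad = None
            total.backward()
            opt_g.step()

            vals = {"Lrec": lrec.value, "Jadv": jadv.value, "Rdis": rdis.value,
                    "Lcla": lcla.value, "d_loss": d_loss_t.value,
                    "total": total.value}
            for k, v in vals.items():
                v = float(v)
                if not np.isfinite(v):
                    raise TrainingDivergence(
                        f"non-finite {k} at epoch {epoch}, step {step}",
                        history)
                acc[k] += v
        for k in acc:
            history[k].append(acc[k] / steps)

        if val_data is not None:
            s = _forward_np(cls, _forward_np(enc, val_data[0])).ravel()
            yv = np.asarray(val_data[1], dtype=float) * 2.0 - 1.0
            vloss = float(np.maximum(0.0, params.margin - s * yv).mean())
            history["val_loss"].append(vloss)
            if early_stop_patience is not None:
                if vloss < best_val - 1e-6:
                    best_val, patience_left = vloss, early_stop_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break

    return TrainedModel(params=params, input_dim=dim, encoder=enc,
                        decoder=dec, discriminator=disc, classifier=cls,
                        history=history)
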