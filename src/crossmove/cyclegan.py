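"""Class-conditioned cycle-consistent adversarial translation.

Two conditional generators G: (X, Z) -> Y and F: (Y, Z) -> X are trained
jointly against two patch discriminators D_X, D_Y.  The objective is

    L = L_GAN(G, D_Y) + L_GAN(F, D_X)
        + lambda_cyc * [ |F(G(x,z),z) - x|_1 + |G(F(y,z),z) - y|_1 ]
        + lambda_id  * [ |G(y,z) - y|_1 + |F(x,z) - x|_1 ]

with lambda_cyc = 10 and lambda_id = 5.  The adversarial term is the
log-loss (patchwise binary cross-entropy); generators minimize the
non-saturating variant (-log D(fake)) for trainability.  Discriminators
use Adam at a constant learning rate of 2e-4; generators follow a
pair-dependent schedule (see :func:`generator_lr`).  After training, the
generator pair from the epoch with the lowest epoch-mean generator
objective is selected.

Subject identity enters as a one-hot class embedding concatenated to the
input channels of every network, so the translation can preserve who is
moving, not just how.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .networks import (Discriminator, DiscriminatorSpec, Generator,
                       GeneratorSpec, build_discriminator, build_generator)
from .preprocess import MovementVector

__all__ = [
    "ClassEmbedding",
    "TrainingPlan",
    "TrainedPair",
    "adversarial_loss",
    "cycle_loss",
    "identity_loss",
    "total_objective",
    "generator_lr",
    "schedule_kind_for",
    "train_pair",
    "translate_dataset",
    "save_pair",
    "load_pair",
]


@dataclass(frozen=True)
class ClassEmbedding:
    """One-hot subject condition vector z."""

    vector: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=np.float64)
        object.__setattr__(self, "vector", v)
        if v.ndim != 1 or not np.all((v == 0) | (v == 1)) or v.sum() != 1:
            raise ValueError("class embedding must be one-hot")

    @classmethod
    def from_index(cls, index: int, n_classes: int) -> "ClassEmbedding":
        v = np.zeros(n_classes)
        v[index] = 1.0
        return cls(v)

    @property
    def index(self) -> int:
        return int(np.argmax(self.vector))


@dataclass(frozen=True)
class TrainingPlan:
    """Optimization hyperparameters of one translation pair."""

    epochs: int = 200
    batch_size: int = 64
    lambda_cyc: float = 10.0
    lambda_id: float = 5.0
    d_lr: float = 2e-4
    schedule_kind: str = "locomotion_pair"
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    seed: int = 0
    g_lr_override: float | None = None  # constant lr overriding the schedule
    #: adversarial loss form: "log" (patchwise binary cross-entropy, the
    #: printed objective; generators minimize the non-saturating variant)
    #: or "least_squares" (scores regressed to 1/0 without a sigmoid).
    gan_loss: str = "log"
    #: which epoch's generators to return: "best" selects the lowest
    #: epoch-mean generator objective; "last" keeps the final epoch.
    checkpoint: str = "best"
    #: discriminator updates per generator update.  The boosted
    #: writing-pair generator schedule multiplies the generator rate by
    #: the batch size while the discriminator rate stays fixed; extra
    #: discriminator steps keep the adversarial game balanced there.
    d_steps: int = 1
    #: matching-aware discriminator negatives: real signals paired with a
    #: *wrong* subject class are scored as fake.  Off by default — at the
    #: training scales this package targets it slows realism learning
    #: more than it sharpens subject consistency.
    class_mismatch_negatives: bool = False

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.lambda_cyc < 0 or self.lambda_id < 0 or self.d_lr < 0:
            raise ValueError("loss weights and learning rates must be >= 0")
        if self.schedule_kind not in ("locomotion_pair", "writing_pair"):
            raise ValueError(f"unknown schedule kind {self.schedule_kind!r}")
        if self.gan_loss not in ("log", "least_squares"):
            raise ValueError(f"unknown gan loss {self.gan_loss!r}")
        if self.checkpoint not in ("best", "last"):
            raise ValueError(f"unknown checkpoint policy {self.checkpoint!r}")
        if self.d_steps < 1:
            raise ValueError("d_steps must be >= 1")


def schedule_kind_for(domain_a: str, domain_b: str) -> str:
    """Writing-involving pairs use the boosted three-phase schedule."""
    return "writing_pair" if "writing" in (domain_a, domain_b) else "locomotion_pair"


def generator_lr(epoch: int, kind: str, total_epochs: int = 200,
                 batch_size: int = 64, base_lr: float = 2e-4) -> float:
    """Generator learning rate at a (0-based) epoch.

    ``locomotion_pair``: constant ``base_lr`` for the first half of
    training, then linear decay to 0.

    ``writing_pair``: ``base_lr * batch_size`` for the first quarter
    (0.0128 at the default batch of 64), ``base_lr * sqrt(batch_size)``
    for the second quarter (0.0016), then linear decay of that value to
    0 over the second half.
    """
    if not 0 <= epoch < total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs})")
    half = total_epochs / 2.0
    decay = max(1.0 - (epoch - half) / (total_epochs - half), 0.0)
    if kind == "locomotion_pair":
        return base_lr if epoch < half else base_lr * decay
    if kind == "writing_pair":
        if epoch < total_epochs / 4.0:
            return base_lr * batch_size
        mid = base_lr * math.sqrt(batch_size)
        return mid if epoch < half else mid * decay
    raise ValueError(f"unknown schedule kind {kind!r}")


# ---------------------------------------------------------------------------
# Loss values (evaluation form, on plain arrays)

def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("discriminator outputs must be probabilities in [0, 1]")
    return p


def adversarial_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """GAN log-loss: E[log D(real)] + E[log(1 - D(fake))].

    The discriminator maximizes this; the generator minimizes it.  Its
    supremum 0 is reached at D(real) = 1, D(fake) = 0.
    """
    d_real, d_fake = _check_probs(d_real), _check_probs(d_fake)
    with np.errstate(divide="ignore"):
        return float(np.mean(np.log(d_real)) + np.mean(np.log1p(-d_fake)))


def _pairwise_l1(u, v) -> float:
    u, v = np.asarray(u, dtype=np.float64), np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError("length mismatch in L1 term")
    return float(np.mean(np.abs(u - v)))


def cycle_loss(x, x_reconstructed, y, y_reconstructed) -> float:
    """Forward plus backward cycle reconstruction error (mean L1)."""
    return _pairwise_l1(x_reconstructed, x) + _pairwise_l1(y_reconstructed, y)


def identity_loss(y, g_of_y, x, f_of_x) -> float:
    """Penalty for altering inputs already in the target domain (mean L1)."""
    return _pairwise_l1(g_of_y, y) + _pairwise_l1(f_of_x, x)


def total_objective(l_gan_g: float, l_gan_f: float, l_cyc: float,
                    l_id: float, plan: TrainingPlan) -> float:
    """Weighted full objective."""
    for value in (l_gan_g, l_gan_f, l_cyc, l_id):
        if not np.isfinite(value):
            raise ValueError("loss components must be finite")
    return (l_gan_g + l_gan_f + plan.lambda_cyc * l_cyc
            + plan.lambda_id * l_id)


# ---------------------------------------------------------------------------
# Training

@dataclass
class TrainedPair:
    """Result of training one translation pair.

    ``G`` maps domain A to domain B, ``F`` the reverse; both are at the
    selected (lowest epoch-mean generator objective) checkpoint.
    """

    G: Generator
    F: Generator
    loss_log: pd.DataFrame
    selected_epoch: int
    classes: tuple
    domain_a: str
    domain_b: str
    plan: TrainingPlan


def _dataset_arrays(trials: list[MovementVector], classes: tuple):
    idx = {c: i for i, c in enumerate(classes)}
    x = np.stack([t.values for t in trials])
    z = np.array([idx[t.subject_id] for t in trials])
    return x[:, None, :], z


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def train_pair(data_a: list[MovementVector], data_b: list[MovementVector],
               plan: TrainingPlan,
               gen_spec: GeneratorSpec = GeneratorSpec(),
               disc_spec: DiscriminatorSpec = DiscriminatorSpec(),
               progress: bool = False) -> TrainedPair:
    """Train a conditional translation pair between two trial sets.

    Per batch, both discriminators take one Adam step on real/fake
    log-loss, then both generators take one joint step on the full
    objective (both mapping directions share G, F, D_X, D_Y).  The
    smaller domain is resampled with replacement so every epoch covers
    the larger domain once.  Fully reproducible given ``plan.seed``.
    """
    if not data_a or not data_b:
        raise ValueError("both datasets must be non-empty")
    subjects_a = {t.subject_id for t in data_a}
    subjects_b = {t.subject_id for t in data_b}
    if subjects_a != subjects_b:
        raise ValueError("domains must share the same subject classes")
    classes = tuple(sorted(subjects_a))
    k = len(classes)
    domain_a, domain_b = data_a[0].domain, data_b[0].domain

    seeds = np.random.SeedSequence([plan.seed, 17]).generate_state(5)
    G = build_generator(gen_spec, k, seed=int(seeds[0]) % (2**31))
    F = build_generator(gen_spec, k, seed=int(seeds[1]) % (2**31))
    DX = build_discriminator(disc_spec, k, seed=int(seeds[2]) % (2**31))
    DY = build_discriminator(disc_spec, k, seed=int(seeds[3]) % (2**31))
    rng = np.random.default_rng(int(seeds[4]) % (2**31))

    xa, za = _dataset_arrays(data_a, classes)
    xb, zb = _dataset_arrays(data_b, classes)
    eye = np.eye(k)
    na, nb = len(xa), len(xb)
    n_batches = -(-max(na, nb) // plan.batch_size)

    opt_d = Adam(DX.params + DY.params, plan.d_lr, plan.beta1, plan.beta2,
                 plan.eps)
    opt_g = Adam(G.params + F.params, 0.0, plan.beta1, plan.beta2, plan.eps)

    def batches_for(n: int) -> np.ndarray:
        """Epoch-covering index plan: permutation padded by resampling."""
        need = n_batches * plan.batch_size
        perm = rng.permutation(n)
        if need > n:
            extra = rng.integers(0, n, size=need - n)
            perm = np.concatenate([perm, extra])
        return perm[:need].reshape(n_batches, plan.batch_size)

    adv_term = (ad.bce_with_logits if plan.gan_loss == "log"
                else ad.mse_to_constant)
    log_rows = []
    best = (np.inf, None, None, -1)
    for epoch in range(plan.epochs):
        lr_g = (plan.g_lr_override if plan.g_lr_override is not None else
                generator_lr(epoch, plan.schedule_kind, plan.epochs,
                             plan.batch_size))
        opt_g.lr = lr_g
        plan_a, plan_b = batches_for(na), batches_for(nb)
        epoch_log = np.zeros(5)
        for ia, ib in zip(plan_a, plan_b):
            a, oa = Tensor(xa[ia]), eye[za[ia]]
            b, ob = Tensor(xb[ib]), eye[zb[ib]]

            # --- discriminator step(s) (generators frozen)
            with ad.no_grad():
                fake_b = G.forward(a, oa).data
                fake_a = F.forward(b, ob).data
            for _ in range(plan.d_steps):
                opt_d.zero_grad()
                d_loss = (adv_term(DY.forward(b, ob), 1.0)
                          + adv_term(DY.forward(Tensor(fake_b), oa), 0.0)
                          + adv_term(DX.forward(a, oa), 1.0)
                          + adv_term(DX.forward(Tensor(fake_a), ob), 0.0))
                if plan.class_mismatch_negatives and k > 1:
                    # real signal + wrong class scored as fake
                    wrong_a = eye[(za[ia]
                                   + rng.integers(1, k, size=len(ia))) % k]
                    wrong_b = eye[(zb[ib]
                                   + rng.integers(1, k, size=len(ib))) % k]
                    d_loss = d_loss + (
                        adv_term(DY.forward(b, wrong_b), 0.0)
                        + adv_term(DX.forward(a, wrong_a), 0.0))
                d_loss.backward()
                opt_d.step()

            # --- generator step (discriminators frozen)
            opt_g.zero_grad()
            fb = G.forward(a, oa)
            fa = F.forward(b, ob)
            adv_g = adv_term(DY.forward(fb, oa), 1.0)
            adv_f = adv_term(DX.forward(fa, ob), 1.0)
            cyc = ad.l1_mean(F.forward(fb, oa), a) + ad.l1_mean(
                G.forward(fa, ob), b)
            idt = ad.l1_mean(G.forward(b, ob), b) + ad.l1_mean(
                F.forward(a, oa), a)
            g_total = (adv_g + adv_f + plan.lambda_cyc * cyc
                       + plan.lambda_id * idt)
            opt_d.zero_grad()  # discard gradients that flowed into D
            g_total.backward()
            opt_g.step()

            # --- log the evaluation-form components (Eq.-style values)
            with ad.no_grad():
                pr_b = _sigmoid(DY.forward(b, ob).data)
                pf_b = _sigmoid(DY.forward(Tensor(fb.data), oa).data)
                pr_a = _sigmoid(DX.forward(a, oa).data)
                pf_a = _sigmoid(DX.forward(Tensor(fa.data), ob).data)
            l_gan_g = adversarial_loss(pr_b, pf_b)
            l_gan_f = adversarial_loss(pr_a, pf_a)
            epoch_log += [l_gan_g, l_gan_f, cyc.item(), idt.item(),
                          total_objective(l_gan_g, l_gan_f, cyc.item(),
                                          idt.item(), plan)]
        epoch_log /= n_batches
        log_rows.append({"epoch": epoch, "lr_g": lr_g,
                         "l_gan_G": epoch_log[0], "l_gan_F": epoch_log[1],
                         "l_cyc": epoch_log[2], "l_id": epoch_log[3],
                         "total": epoch_log[4]})
        if epoch_log[4] < best[0]:
            best = (epoch_log[4], G.get_state(), F.get_state(), epoch)
        if progress:
            print(f"epoch {epoch + 1}/{plan.epochs}  total={epoch_log[4]:.4f}"
                  f"  cyc={epoch_log[2]:.4f}  id={epoch_log[3]:.4f}")

    if plan.checkpoint == "best":
        G.set_state(best[1])
        F.set_state(best[2])
        selected = best[3]
    else:
        selected = plan.epochs - 1
    G.classes, G.target_domain = classes, domain_b
    F.classes, F.target_domain = classes, domain_a
    return TrainedPair(G=G, F=F, loss_log=pd.DataFrame(log_rows),
                       selected_epoch=selected, classes=classes,
                       domain_a=domain_a, domain_b=domain_b, plan=plan)


def translate_dataset(gen: Generator,
                      trials: list[MovementVector],
                      chunk: int = 64) -> list[MovementVector]:
    """Translate trials into the generator's target domain.

    Each trial is conditioned on its own subject class; subject and
    condition labels pass through unchanged and the output is marked as
    generated from the source domain.
    """
    classes = getattr(gen, "classes", None)
    target = getattr(gen, "target_domain", None)
    if classes is None or target is None:
        raise ValueError("generator has not been trained on labelled data")
    idx = {c: i for i, c in enumerate(classes)}
    for t in trials:
        if t.subject_id not in idx:
            raise ValueError(f"unknown subject class {t.subject_id!r}")
    eye = np.eye(len(classes))
    out = []
    for lo in range(0, len(trials), chunk):
        part = trials[lo:lo + chunk]
        x = np.stack([t.values for t in part])
        onehot = eye[[idx[t.subject_id] for t in part]]
        y = gen(x, onehot)
        for t, values in zip(part, y):
            out.append(MovementVector(
                values=values, domain=target, subject_id=t.subject_id,
                condition=t.condition, source_trial_id=t.source_trial_id,
                origin="generated", source_domain=t.domain))
    return out


# ---------------------------------------------------------------------------
# Checkpoint persistence: binary parameter store + plain-text manifest

def save_pair(pair: TrainedPair, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "params_G.npz",
             *[p.data for p in pair.G.params])
    np.savez(directory / "params_F.npz",
             *[p.data for p in pair.F.params])
    pair.loss_log.to_csv(directory / "loss_log.csv", index=False)
    manifest = {
        "domain_a": pair.domain_a, "domain_b": pair.domain_b,
        "classes": list(pair.classes),
        "selected_epoch": pair.selected_epoch,
        "plan": asdict(pair.plan),
        "generator_spec": asdict(pair.G.spec),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_pair(directory) -> TrainedPair:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec = GeneratorSpec(**manifest["generator_spec"])
    classes = tuple(manifest["classes"])
    k = len(classes)
    pair_gens = []
    for name, target in (("G", manifest["domain_b"]),
                         ("F", manifest["domain_a"])):
        gen = build_generator(spec, k)
        with np.load(directory / f"params_{name}.npz") as store:
            gen.set_state([store[key] for key in store.files])
        gen.classes, gen.target_domain = classes, target
        pair_gens.append(gen)
    return TrainedPair(
        G=pair_gens[0], F=pair_gens[1],
        loss_log=pd.read_csv(directory / "loss_log.csv"),
        selected_epoch=manifest["selected_epoch"], classes=classes,
        domain_a=manifest["domain_a"], domain_b=manifest["domain_b"],
        plan=TrainingPlan(**manifest["plan"]))
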