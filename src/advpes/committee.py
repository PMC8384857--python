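"""Committee (deep-ensemble) energy models: training, statistics, calibration.

The modelling surface follows the fitted-model idiom: :class:`CommitteeModel`
is built from a :class:`~advpes.data.Dataset` plus a :class:`TrainConfig`, and
``fit()`` returns a :class:`CommitteeResults` object carrying the trained
members, their training histories, prediction methods and a ``summary()``
table.  Committee statistics use the unbiased 1/(M-1) variance; the force
variance is a single scalar per configuration, the member variance of the
per-component mean squared force deviation.

Epistemic uncertainty is thresholded by :class:`InDomainClassifier`: a
configuration is in-domain when its committee variance lies strictly below a
threshold calibrated as a percentile of the variance over a reference set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .data import Configuration, Dataset
from .nn import MLP, Adam

__all__ = [
    "TrainConfig",
    "CommitteePrediction",
    "CommitteeModel",
    "CommitteeResults",
    "InDomainClassifier",
    "ensemble_statistics",
    "matching_loss",
]

DIVERSITY_MODES = ("shared-splits-different-inits", "different-splits")
VARIANCE_STATISTICS = ("force_variance", "energy_variance")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for committee training.

    Defaults follow the double-well preset at desk scale: five members, four
    softplus hidden layers of 64 units (1024 at full scale), energy-only
    supervision, Adam, batch size 35, 60:20:20 splits, shared splits with
    different initial weights.  Narrow members need a stronger optimization
    schedule than wide ones to reach the same converged fit, so the default
    is up to 3000 Adam steps at learning rate 1e-2 decaying to 1e-3; the
    full-scale protocol (``hidden=(1024,)*4``, 600 epochs, lr 1e-3) is a
    config away.  Remainder
    minibatches smaller than half the batch size are dropped: with
    adaptive-moment updates a 2-3 point leftover batch carries the same
    weight as a full one and visibly destabilizes convergence.
    """

    n_members: int = 5
    hidden: Tuple[int, ...] = (64, 64, 64, 64)
    alpha_E: float = 1.0
    alpha_F: float = 0.0
    epochs: int = 3000
    max_steps: Optional[int] = 3000  # cap on optimizer steps; None = epochs only
    batch_size: int = 35
    lr: float = 1e-2
    lr_decay: float = 0.1  # final lr = lr * lr_decay, exponential over epochs
    split: Tuple[float, float, float] = (0.6, 0.2, 0.2)
    diversity: str = "shared-splits-different-inits"
    seed: int = 0

    def __post_init__(self):
        if self.n_members < 2:
            raise ValueError("a committee needs at least two members")
        if self.alpha_E < 0 or self.alpha_F < 0 or self.alpha_E + self.alpha_F == 0:
            raise ValueError("alpha_E, alpha_F must be nonnegative and not both zero")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.diversity not in DIVERSITY_MODES:
            raise ValueError(f"diversity must be one of {DIVERSITY_MODES}")


@dataclass(frozen=True)
class CommitteePrediction:
    """Committee mean and variance of energy and forces for one configuration."""

    mean_energy: float
    var_energy: float
    mean_forces: np.ndarray
    var_forces: float


def ensemble_statistics(energies: np.ndarray, forces: np.ndarray) -> CommitteePrediction:
    """Committee statistics from per-member predictions.

    Parameters
    ----------
    energies : (M,) array of member energies.
    forces : (M, ...) array of member forces (any coordinate shape).

    The energy variance is the unbiased member variance.  The force variance
    averages squared deviations over all coordinate components (3n for a
    molecule, d for a bare vector) before the 1/(M-1) member sum, so it is a
    single scalar per configuration.
    """
    energies = np.asarray(energies, float)
    forces = np.asarray(forces, float)
    M = energies.shape[0]
    if M < 2:
        raise ValueError("committee variance needs at least two members")
    mean_E = energies.mean()
    var_E = float(np.sum((energies - mean_E) ** 2) / (M - 1))
    mean_F = forces.mean(axis=0)
    dev = (forces - mean_F).reshape(M, -1)
    var_F = float(np.sum(np.mean(dev**2, axis=1)) / (M - 1))
    return CommitteePrediction(float(mean_E), var_E, mean_F, var_F)


def matching_loss(E, E_hat, F=None, F_hat=None, alpha_E: float = 1.0, alpha_F: float = 0.0) -> float:
    """Batch-averaged energy/force-matching loss
    (1/N) sum_i [alpha_E ||E_i - Ehat_i||^2 + alpha_F ||F_i - Fhat_i||^2].
    """
    E = np.asarray(E, float).ravel()
    E_hat = np.asarray(E_hat, float).ravel()
    if E.size == 0:
        raise ValueError("empty batch")
    loss = alpha_E * np.sum((E - E_hat) ** 2)
    if alpha_F > 0:
        if F is None or F_hat is None:
            raise ValueError("force-matching requires forces")
        F = np.asarray(F, float).reshape(E.size, -1)
        F_hat = np.asarray(F_hat, float).reshape(E.size, -1)
        loss += alpha_F * np.sum((F - F_hat) ** 2)
    return float(loss / E.size)


def model_forces(model: MLP, config: Configuration) -> np.ndarray:
    """Predicted forces: negative input gradient of the model energy."""
    g = model.input_grad(config.flat[None, :])[0]
    return (-g).reshape(config.coords.shape)


@dataclass(frozen=True)
class InDomainClassifier:
    """Variance-threshold rule: in-domain iff the statistic is strictly below t."""

    threshold: float
    statistic: str = "force_variance"
    percentile: float = 80.0

    def __post_init__(self):
        if self.statistic not in VARIANCE_STATISTICS:
            raise ValueError(f"statistic must be one of {VARIANCE_STATISTICS}")
        if self.threshold < 0:
            raise ValueError("threshold must be nonnegative")

    def classify_value(self, variance: float) -> int:
        return 1 if variance < self.threshold else 0

    def __call__(self, results: "CommitteeResults", config: Configuration) -> int:
        pred = results.predict(config)
        value = pred.var_forces if self.statistic == "force_variance" else pred.var_energy
        return self.classify_value(value)


class CommitteeModel:
    """Committee of feedforward energy regressors, built from a dataset."""

    def __init__(self, dataset: Dataset, config: TrainConfig = TrainConfig()):
        if len(dataset) == 0:
            raise ValueError("cannot train on an empty dataset")
        self.dataset = dataset
        self.config = config

    @classmethod
    def from_dataframe(cls, frame, coord_columns: Sequence[str], energy_column: str = "energy", config: TrainConfig = TrainConfig()):
        """Build a vector-kind committee model from a pandas DataFrame."""
        from .data import LabeledSample

        samples = []
        for _, row in frame.iterrows():
            coords = np.array([row[c] for c in coord_columns], float)
            samples.append(LabeledSample(Configuration(coords), float(row[energy_column]), np.zeros_like(coords)))
        return cls(Dataset(samples, ["other"] * len(samples)), config)

    # --------------------------------------------------------------- fitting

    def _make_splits(self, rng: np.random.Generator, n: int):
        perm = rng.permutation(n)
        n_train = max(1, int(round(self.config.split[0] * n)))
        n_val = int(round(self.config.split[1] * n))
        return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]

    def fit(self) -> "CommitteeResults":
        cfg = self.config
        X = self.dataset.coords_matrix()
        E = self.dataset.energies()
        F = np.array([np.asarray(s.forces).ravel() for s in self.dataset])
        n = len(self.dataset)

        ss = np.random.SeedSequence(cfg.seed)
        split_ss, *member_ss = ss.spawn(1 + cfg.n_members)

        batch_size = cfg.batch_size
        shared_splits = self._make_splits(np.random.default_rng(split_ss), n)
        if cfg.split[0] * n < cfg.batch_size:
            batch_size = max(1, int(cfg.split[0] * n))
            warnings.warn(
                f"training split smaller than batch size; using batch size {batch_size}"
            )

        members: List[MLP] = []
        histories: List[np.ndarray] = []
        splits = []
        member_children = [member_ss[m].spawn(3) for m in range(cfg.n_members)]
        for m in range(cfg.n_members):
            child = member_children[m]
            if cfg.diversity == "different-splits":
                splits.append(self._make_splits(np.random.default_rng(child[0]), n))
            else:
                splits.append(shared_splits)

        joint = cfg.diversity == "shared-splits-different-inits" and cfg.alpha_F == 0
        if joint:
            # shared splits + shared batch order: train all members in one
            # stacked pass (member diversity comes from the initial weights)
            seed_table = [
                np.random.default_rng(child[1]).integers(2**31 - 1, size=3)
                for child in member_children
            ]
            init_seeds = [int(s[0]) for s in seed_table]
            batch_rng = np.random.default_rng(member_children[0][2])
            members, histories = _train_members_jointly(
                X, E, shared_splits[0], init_seeds, batch_rng, cfg, batch_size
            )
            # a member stuck far above the committee's typical train error is
            # an optimization failure, not an epistemic signal: retrain it
            # from a fresh deterministic init (at most two retries)
            idx_train = shared_splits[0]
            for attempt in (1, 2):
                rmse = np.array(
                    [
                        float(np.sqrt(np.mean((net.energy(X[idx_train]) - E[idx_train]) ** 2)))
                        for net in members
                    ]
                )
                bad = np.flatnonzero(rmse > 3.0 * np.median(rmse) + 1e-12)
                if bad.size == 0 or bad.size == len(members):
                    break
                retry_seeds = [int(seed_table[m][attempt]) for m in bad]
                retry_rng = np.random.default_rng(member_children[0][2])
                new_members, new_hist = _train_members_jointly(
                    X, E, idx_train, retry_seeds, retry_rng, cfg, batch_size
                )
                for k, m in enumerate(bad):
                    members[m] = new_members[k]
                    histories[m] = new_hist[k]
            return CommitteeResults(self, members, histories, splits)

        for m in range(cfg.n_members):
            child = member_children[m]
            idx_train = splits[m][0]
            init_seed = int(np.random.default_rng(child[1]).integers(2**31 - 1))
            net = MLP(X.shape[1], cfg.hidden, seed=init_seed)
            batch_rng = np.random.default_rng(child[2])
            opt = Adam([p.shape for p in net.get_params()], lr=cfg.lr)
            history = []
            Xt, Et, Ft = X[idx_train], E[idx_train], F[idx_train]
            use_forces = cfg.alpha_F > 0
            steps_done = 0
            for epoch in range(cfg.epochs):
                if cfg.max_steps is not None and steps_done >= cfg.max_steps:
                    break
                if cfg.epochs > 1:
                    opt.lr = cfg.lr * cfg.lr_decay ** (epoch / (cfg.epochs - 1))
                order = batch_rng.permutation(len(idx_train))
                losses = []
                for start in range(0, len(order), batch_size):
                    sel = order[start : start + batch_size]
                    if start > 0 and len(sel) < batch_size // 2:
                        continue
                    if cfg.max_steps is not None and steps_done >= cfg.max_steps:
                        break
                    steps_done += 1
                    loss, gW, gb = net.param_grads(
                        Xt[sel],
                        Et[sel],
                        Ft[sel] if use_forces else None,
                        alpha_E=cfg.alpha_E,
                        alpha_F=cfg.alpha_F if use_forces else 0.0,
                    )
                    opt.step(net.W + net.b, gW + gb, sign=-1.0)
                    losses.append(loss)
                if losses:
                    history.append(float(np.mean(losses)))
            members.append(net)
            histories.append(np.array(history))
        return CommitteeResults(self, members, histories, splits)


def _train_members_jointly(X, E, idx_train, init_seeds, batch_rng, cfg: TrainConfig, batch_size: int):
    """Energy-only training of all members at once via stacked tensors.

    Equivalent to per-member loops with shared batch order; one set of numpy
    calls per step instead of one per member, which dominates runtime for
    narrow members.  All parameters live in one flat buffer so the
    adaptive-moment update is a handful of vector operations.  The stacked
    pass runs in single precision (standardized targets keep the dynamic
    range of order one); final parameters are promoted to float64.
    """
    M = len(init_seeds)
    nets = [MLP(X.shape[1], cfg.hidden, seed=s) for s in init_seeds]
    L = len(nets[0].W)
    # standardize targets for conditioning; undone exactly on the linear
    # output layer after training, so predictions stay in raw energy units
    mu = float(E[idx_train].mean())
    sd = float(E[idx_train].std())
    if sd < 1e-12:
        sd = 1.0
    E = (E - mu) / sd

    shapes = [(M,) + nets[0].W[l].shape for l in range(L)] + [
        (M,) + nets[0].b[l].shape for l in range(L)
    ]
    sizes = [int(np.prod(s)) for s in shapes]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    theta = np.empty(offs[-1], dtype=np.float32)
    grad = np.zeros(offs[-1], dtype=np.float32)
    views = [theta[offs[i] : offs[i + 1]].reshape(shapes[i]) for i in range(2 * L)]
    gviews = [grad[offs[i] : offs[i + 1]].reshape(shapes[i]) for i in range(2 * L)]
    Ws, bs = views[:L], views[L:]
    gW, gb = gviews[:L], gviews[L:]
    for l in range(L):
        Ws[l][:] = np.stack([net.W[l] for net in nets])
        bs[l][:] = np.stack([net.b[l] for net in nets])

    Xt = X[idx_train].astype(np.float32)
    Et = E[idx_train].astype(np.float32)
    n_train = len(idx_train)
    starts = [s for s in range(0, n_train, batch_size) if s == 0 or n_train - s >= batch_size // 2]
    total_steps = cfg.epochs * len(starts)
    if cfg.max_steps is not None:
        total_steps = min(total_steps, cfg.max_steps)
    n_epochs = (total_steps + len(starts) - 1) // len(starts)

    opt = Adam([theta.shape], lr=cfg.lr, dtype=np.float32)
    from .nn import softplus_and_sigmoid

    histories = np.empty((M, n_epochs))
    step = 0
    for epoch in range(n_epochs):
        order = batch_rng.permutation(n_train)
        epoch_losses = []
        for start in starts:
            if step >= total_steps:
                break
            if total_steps > 1:
                opt.lr = cfg.lr * cfg.lr_decay ** (step / (total_steps - 1))
            sel = order[start : start + batch_size]
            Xb, Eb = Xt[sel], Et[sel]
            B = len(sel)
            acts = []
            sigs = []
            z = Xb @ Ws[0] + bs[0][:, None, :]  # (M, B, h) via broadcasting
            a, s = softplus_and_sigmoid(z)
            acts.append(a)
            sigs.append(s)
            for l in range(1, L - 1):
                z = a @ Ws[l] + bs[l][:, None, :]
                a, s = softplus_and_sigmoid(z)
                acts.append(a)
                sigs.append(s)
            Ehat = (a @ Ws[-1] + bs[-1][:, None, :])[:, :, 0]
            res = Ehat - Eb[None, :]
            epoch_losses.append(cfg.alpha_E * np.mean(res**2, axis=1))
            bar_z = (2.0 * cfg.alpha_E / B) * res[:, :, None]  # (M, B, 1)
            np.matmul(acts[-1].transpose(0, 2, 1), bar_z, out=gW[-1])
            np.sum(bar_z, axis=1, out=gb[-1])
            bar_a = bar_z @ Ws[-1].transpose(0, 2, 1)
            for l in range(L - 2, -1, -1):
                bar_z = bar_a * sigs[l]
                if l > 0:
                    np.matmul(acts[l - 1].transpose(0, 2, 1), bar_z, out=gW[l])
                else:
                    np.matmul(Xb.T, bar_z, out=gW[l])
                np.sum(bar_z, axis=1, out=gb[l])
                if l > 0:
                    bar_a = bar_z @ Ws[l].transpose(0, 2, 1)
            opt.step([theta], [grad], sign=-1.0)
            step += 1
        histories[:, epoch] = (
            np.mean(epoch_losses, axis=0) if epoch_losses else histories[:, epoch - 1]
        )
    for m, net in enumerate(nets):
        params = [Ws[l][m].copy() for l in range(L)] + [bs[l][m].copy() for l in range(L)]
        params[L - 1] = params[L - 1] * sd  # undo target standardization
        params[2 * L - 1] = params[2 * L - 1] * sd + mu
        net.set_params(params)
    return nets, [histories[m] for m in range(M)]


class CommitteeResults:
    """Fitted committee: members, training history, prediction and diagnostics."""

    def __init__(self, model: CommitteeModel, members: List[MLP], histories, splits):
        self.model = model
        self.members = members
        self.histories = histories
        self.splits = splits

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def dataset(self) -> Dataset:
        return self.model.dataset

    # ------------------------------------------------------------ prediction

    def member_energies(self, X: np.ndarray) -> np.ndarray:
        """(M, N) member energies over an (N, d) coordinate matrix."""
        X = np.atleast_2d(np.asarray(X, float))
        return np.stack([m.energy(X) for m in self.members])

    def member_grads(self, X: np.ndarray) -> np.ndarray:
        """(M, N, d) member energy gradients (negative forces)."""
        X = np.atleast_2d(np.asarray(X, float))
        return np.stack([m.input_grad(X) for m in self.members])

    def predict_batch(self, X: np.ndarray) -> dict:
        """Vectorized committee statistics over an (N, d) coordinate matrix."""
        X = np.atleast_2d(np.asarray(X, float))
        M = self.n_members
        E = self.member_energies(X)
        G = self.member_grads(X)
        mean_E = E.mean(axis=0)
        var_E = np.sum((E - mean_E) ** 2, axis=0) / (M - 1)
        mean_G = G.mean(axis=0)
        var_F = np.sum(np.mean((G - mean_G) ** 2, axis=2), axis=0) / (M - 1)
        return {
            "mean_energy": mean_E,
            "var_energy": var_E,
            "mean_forces": -mean_G,
            "var_forces": var_F,
        }

    def predict(self, config: Configuration) -> CommitteePrediction:
        x = config.flat[None, :]
        E = self.member_energies(x)[:, 0]
        F = -self.member_grads(x)[:, 0, :]
        pred = ensemble_statistics(E, F)
        return CommitteePrediction(
            pred.mean_energy,
            pred.var_energy,
            pred.mean_forces.reshape(config.coords.shape),
            pred.var_forces,
        )

    def variance_statistic(self, X: np.ndarray, statistic: str = "force_variance") -> np.ndarray:
        stats = self.predict_batch(X)
        key = "var_forces" if statistic == "force_variance" else "var_energy"
        return stats[key]

    # ----------------------------------------------------------- calibration

    def calibrate_threshold(
        self,
        calibration: Optional[Dataset] = None,
        percentile: float = 80.0,
        statistic: str = "force_variance",
    ) -> InDomainClassifier:
        """Threshold = ``percentile`` of the variance statistic over the
        calibration set (the committee's own training data by default)."""
        if not 0 < percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        data = calibration if calibration is not None else self.dataset
        if len(data) == 0:
            raise ValueError("empty calibration set")
        values = self.variance_statistic(data.coords_matrix(), statistic)
        if np.allclose(values, values[0]):
            warnings.warn("degenerate calibration: all variances equal")
        t = float(np.percentile(values, percentile))
        return InDomainClassifier(t, statistic, percentile)

    # ----------------------------------------------------------- diagnostics

    def rmse(self, which: str = "train") -> np.ndarray:
        """Per-member energy RMSE on the train/val/test split."""
        idx_of = {"train": 0, "val": 1, "test": 2}[which]
        X = self.dataset.coords_matrix()
        E = self.dataset.energies()
        out = []
        for net, split in zip(self.members, self.splits):
            idx = split[idx_of]
            if len(idx) == 0:
                out.append(np.nan)
                continue
            r = net.energy(X[idx]) - E[idx]
            out.append(float(np.sqrt(np.mean(r**2))))
        return np.array(out)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Committee fit summary",
            "=====================",
            f"members: {self.n_members}   hidden: {cfg.hidden}   diversity: {cfg.diversity}",
            f"dataset: {len(self.dataset)} samples ({self.dataset.counts_by_provenance()})",
            f"loss weights: alpha_E={cfg.alpha_E} alpha_F={cfg.alpha_F}   "
            f"epochs={cfg.epochs} batch={cfg.batch_size} lr={cfg.lr}",
            "",
            "member  first-epoch loss  last-epoch loss  train RMSE  val RMSE",
        ]
        tr = self.rmse("train")
        va = self.rmse("val")
        for m in range(self.n_members):
            h = self.histories[m]
            lines.append(
                f"{m:6d}  {h[0]:16.6f}  {h[-1]:15.6f}  {tr[m]:10.4f}  {va[m]:8.4f}"
            )
        return "\n".join(lines)

    # --------------------------------------------------------- serialization

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = self.model.config
        meta = {
            "config": {
                "n_members": cfg.n_members,
                "hidden": list(cfg.hidden),
                "alpha_E": cfg.alpha_E,
                "alpha_F": cfg.alpha_F,
                "epochs": cfg.epochs,
                "batch_size": cfg.batch_size,
                "lr": cfg.lr,
                "split": list(cfg.split),
                "diversity": cfg.diversity,
                "seed": cfg.seed,
            },
            "splits": [[list(map(int, s)) for s in split] for split in self.splits],
        }
        with open(directory / "meta.json", "w") as fh:
            json.dump(meta, fh)
        for m, net in enumerate(self.members):
            with open(directory / f"member_{m:02d}.json", "w") as fh:
                json.dump(net.to_dict(), fh)
            np.savetxt(directory / f"history_{m:02d}.txt", self.histories[m])

    @classmethod
    def load(cls, directory, dataset: Dataset) -> "CommitteeResults":
        directory = Path(directory)
        with open(directory / "meta.json") as fh:
            meta = json.load(fh)
        c = meta["config"]
        cfg = TrainConfig(
            n_members=c["n_members"],
            hidden=tuple(c["hidden"]),
            alpha_E=c["alpha_E"],
            alpha_F=c["alpha_F"],
            epochs=c["epochs"],
            batch_size=c["batch_size"],
            lr=c["lr"],
            split=tuple(c["split"]),
            diversity=c["diversity"],
            seed=c["seed"],
        )
        members = []
        histories = []
        for m in range(cfg.n_members):
            with open(directory / f"member_{m:02d}.json") as fh:
                members.append(MLP.from_dict(json.load(fh)))
            histories.append(np.loadtxt(directory / f"history_{m:02d}.txt"))
        splits = [tuple(np.array(s, int) for s in split) for split in meta["splits"]]
        return cls(CommitteeModel(dataset, cfg), members, histories, splits)
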