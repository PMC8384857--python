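"""The attack engine: likelihood-weighted uncertainty loss and gradient ascent.

Candidate configurations are proposed by maximizing

    L_adv(X_delta) = p(X_delta) * sigma_F^2(X_delta),

the product of a Boltzmann likelihood p = exp(-Ebar/kT)/Q (committee mean
energy, dataset-derived normalizer Q) and the committee force variance.  The
gradient with respect to the perturbation delta flows through both factors;
the force-variance part needs second derivatives of each member energy, which
the committee members expose as Hessian-vector products.  Perturbations act
either directly on Cartesian coordinates or on torsional collective
variables through the differentiable backmap.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .committee import CommitteePrediction, CommitteeResults, ensemble_statistics
from .cv import DihedralCV, backmap_with_jacobian
from .data import Configuration, Dataset
from .nn import Adam

__all__ = [
    "Normalizer",
    "AttackConfig",
    "AttackResult",
    "AttackDivergedError",
    "partition_normalizer",
    "boltzmann_likelihood",
    "adversarial_loss",
    "adversarial_loss_terms",
    "adversarial_loss_and_grad",
    "init_delta",
    "run_attack",
    "batch_attacks",
]


@dataclass(frozen=True)
class Normalizer:
    """Dataset Boltzmann normalizer Q = sum exp(-E/kT), stored in log space.

    ``log_q`` is computed with a max-energy shift (logsumexp), so downstream
    likelihoods equal the unshifted textbook definition in exact arithmetic
    while staying finite for large |E|/kT.
    """

    log_q: float
    kT: float

    @property
    def q(self) -> float:
        return float(np.exp(self.log_q))


def partition_normalizer(dataset: Dataset, kT: float) -> Normalizer:
    if len(dataset) == 0:
        raise ValueError("normalizer needs a nonempty dataset")
    if kT <= 0:
        raise ValueError("kT must be positive")
    E = dataset.energies()
    return Normalizer(float(logsumexp(-E / kT)), float(kT))


def boltzmann_likelihood(mean_energy, normalizer: Normalizer, kT: float):
    """Sampling likelihood p = exp(-Ebar/kT) / Q (vectorized over Ebar)."""
    if abs(kT - normalizer.kT) > 1e-12:
        raise ValueError("kT does not match the normalizer's temperature")
    mean_energy = np.asarray(mean_energy, float)
    p = np.exp(-mean_energy / kT - normalizer.log_q)
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class AttackConfig:
    """Gradient-ascent attack settings.

    ``sigma_delta`` is the standard deviation of the normal initialization of
    delta (0 gives the deterministic attack); ``kT`` the sampling temperature
    in the dataset's energy units; ``lr`` the ascent learning rate; ``space``
    selects Cartesian or collective-variable perturbations; ``optimizer`` is
    adaptive-moment by default with plain gradient ascent available.
    """

    sigma_delta: float = 0.01
    kT: float = 5.0
    lr: float = 3e-3
    n_steps: int = 600
    space: str = "cartesian"
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.sigma_delta < 0 or self.kT <= 0 or self.lr <= 0 or self.n_steps < 1:
            raise ValueError("invalid attack configuration")
        if self.space not in ("cartesian", "cv"):
            raise ValueError("space must be 'cartesian' or 'cv'")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass
class AttackResult:
    """Trajectory and outcome of one attack."""

    seed_config: Configuration
    delta_history: np.ndarray  # (n_steps + 1, delta_dim)
    loss_history: np.ndarray  # (n_steps + 1,)
    final_config: Configuration
    final_prediction: CommitteePrediction
    failed: bool = False
    likelihood_history: Optional[np.ndarray] = None  # p per iteration
    force_variance_history: Optional[np.ndarray] = None  # sigma_F^2 per iteration

    @property
    def final_delta(self) -> np.ndarray:
        return self.delta_history[-1]


class AttackDivergedError(RuntimeError):
    """Raised when the attack loss or gradient becomes non-finite."""

    def __init__(self, message, last_delta, last_loss, step):
        super().__init__(message)
        self.last_delta = last_delta
        self.last_loss = last_loss
        self.step = step


def init_delta(shape, sigma_delta: float, seed) -> np.ndarray:
    """Initial perturbation ~ N(0, sigma_delta^2 I); exact zeros when sigma=0."""
    if sigma_delta == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed)
    return sigma_delta * rng.standard_normal(shape)


def _config_entropy(config: Configuration) -> int:
    """Stable per-seed entropy derived from the configuration content."""
    digest = hashlib.sha256(np.ascontiguousarray(config.flat).tobytes()).digest()
    return int.from_bytes(digest[:8], "little") >> 4


def adversarial_loss_terms(results: CommitteeResults, X: np.ndarray, normalizer: Normalizer):
    """Vectorized (p, sigma_F^2) over an (N, d) coordinate matrix."""
    stats = results.predict_batch(X)
    p = np.exp(-stats["mean_energy"] / normalizer.kT - normalizer.log_q)
    return p, stats["var_forces"]


def adversarial_loss(
    results: CommitteeResults,
    config: Configuration,
    normalizer: Normalizer,
    kT: Optional[float] = None,
) -> float:
    """L_adv = p(X) * sigma_F^2(X) for a single configuration."""
    if kT is not None and abs(kT - normalizer.kT) > 1e-12:
        raise ValueError("kT does not match the normalizer's temperature")
    p, var_f = adversarial_loss_terms(results, config.flat[None, :], normalizer)
    return float(p[0] * var_f[0])


def adversarial_loss_and_grad(
    results: CommitteeResults, X: np.ndarray, normalizer: Normalizer, return_terms: bool = False
):
    """Loss and its coordinate gradient for a batch of configurations.

    Returns ``(loss (N,), grad (N, d))``, plus ``(p, sigma_F^2)`` when
    ``return_terms`` is set.  Writing g_m for the member energy
    gradients and gbar for their mean::

        grad sigma_F^2 = 2 / ((M-1) d) * sum_m H_m (g_m - gbar)
        grad p         = -p / kT * gbar
        grad L         = sigma_F^2 * grad p + p * grad sigma_F^2

    with H_m the member Hessians applied through Hessian-vector products, so
    the whole expression is exact (no finite differencing).
    """
    X = np.atleast_2d(np.asarray(X, float))
    M = results.n_members
    d = X.shape[1]
    E = results.member_energies(X)  # (M, N)
    G = results.member_grads(X)  # (M, N, d)
    mean_E = E.mean(axis=0)
    mean_G = G.mean(axis=0)
    var_f = np.sum(np.mean((G - mean_G) ** 2, axis=2), axis=0) / (M - 1)
    p = np.exp(-mean_E / normalizer.kT - normalizer.log_q)
    loss = p * var_f

    grad_var = np.zeros_like(mean_G)
    for m, net in enumerate(results.members):
        hvp, _, _ = net.dgrad(X, G[m] - mean_G)
        grad_var += hvp
    grad_var *= 2.0 / ((M - 1) * d)
    grad = (-(p * var_f) / normalizer.kT)[:, None] * mean_G + p[:, None] * grad_var
    if return_terms:
        return loss, grad, p, var_f
    return loss, grad


def _predict_single(results: CommitteeResults, config: Configuration) -> CommitteePrediction:
    return results.predict(config)


def batch_attacks(
    results: CommitteeResults,
    seeds: Sequence[Configuration],
    attack_cfg: AttackConfig,
    normalizer: Normalizer,
    cvs: Optional[Sequence[DihedralCV]] = None,
) -> List[AttackResult]:
    """Run one attack per seed configuration.

    Per-seed randomness is derived from ``attack_cfg.seed`` and the seed
    configuration's content, so results are independent of batch partitioning
    and permuting the seeds permutes the results.  Cartesian attacks on a
    shared composition are vectorized across seeds; per-seed non-finite
    losses are flagged on the result instead of aborting the batch.
    """
    if len(seeds) == 0:
        raise ValueError("batch_attacks needs at least one seed configuration")
    if attack_cfg.space == "cv":
        out = []
        for seed_config in seeds:
            try:
                out.append(run_attack(results, seed_config, attack_cfg, normalizer, cvs=cvs))
            except AttackDivergedError as err:
                warnings.warn(f"attack diverged at step {err.step}; flagged")
                delta = np.atleast_2d(err.last_delta)
                final = _cv_candidate(seed_config, cvs, err.last_delta)
                out.append(
                    AttackResult(
                        seed_config,
                        delta,
                        np.atleast_1d(err.last_loss),
                        final,
                        _predict_single(results, final),
                        failed=True,
                    )
                )
        return out
    return _cartesian_batch(results, list(seeds), attack_cfg, normalizer)


def run_attack(
    results: CommitteeResults,
    seed_config: Configuration,
    attack_cfg: AttackConfig,
    normalizer: Normalizer,
    cvs: Optional[Sequence[DihedralCV]] = None,
) -> AttackResult:
    """Maximize L_adv from one seed by iterative ascent.

    delta lives in Cartesian coordinates (candidate = seed + delta) or in CV
    space (candidate = backmap(seed, cvs, delta)).  The composition Z is
    never modified.  Raises :class:`AttackDivergedError` on non-finite loss
    or gradient, carrying the last valid iterate.
    """
    if attack_cfg.space == "cartesian":
        return _cartesian_batch(results, [seed_config], attack_cfg, normalizer, strict=True)[0]
    if cvs is None or len(cvs) == 0:
        raise ValueError("cv-space attacks require a list of DihedralCVs")
    return _cv_attack(results, seed_config, attack_cfg, normalizer, cvs)


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------


def _cartesian_batch(results, seeds, cfg: AttackConfig, normalizer, strict: bool = False):
    dofs = {s.dof for s in seeds}
    if len(dofs) != 1:
        raise ValueError("cartesian batch requires a shared composition")
    d = dofs.pop()
    S = len(seeds)
    X0 = np.stack([s.flat for s in seeds])
    delta = np.stack(
        [
            init_delta(d, cfg.sigma_delta, np.random.SeedSequence([cfg.seed, _config_entropy(s)]))
            for s in seeds
        ]
    )
    opt = Adam([delta.shape], lr=cfg.lr) if cfg.optimizer == "adam" else None
    delta_hist = np.empty((cfg.n_steps + 1, S, d))
    loss_hist = np.empty((cfg.n_steps + 1, S))
    p_hist = np.empty((cfg.n_steps + 1, S))
    v_hist = np.empty((cfg.n_steps + 1, S))
    alive = np.ones(S, dtype=bool)
    loss, grad, p, var_f = adversarial_loss_and_grad(results, X0 + delta, normalizer, return_terms=True)
    delta_hist[0] = delta
    loss_hist[0] = loss
    p_hist[0] = p
    v_hist[0] = var_f
    for step in range(cfg.n_steps):
        bad = ~np.isfinite(loss) | ~np.isfinite(grad).any(axis=1)
        if bad.any():
            if strict:
                k = int(np.flatnonzero(bad)[0])
                raise AttackDivergedError(
                    f"non-finite adversarial loss/gradient at step {step}",
                    delta_hist[step, k],
                    loss_hist[step, k],
                    step,
                )
            alive &= ~bad
            grad[bad] = 0.0
        if opt is not None:
            opt.step([delta], [np.where(alive[:, None], grad, 0.0)], sign=+1.0)
        else:
            delta += cfg.lr * np.where(alive[:, None], grad, 0.0)
        loss, grad, p, var_f = adversarial_loss_and_grad(results, X0 + delta, normalizer, return_terms=True)
        # frozen seeds keep their last valid loss
        loss = np.where(alive, loss, loss_hist[step])
        delta_hist[step + 1] = np.where(alive[:, None], delta, delta_hist[step])
        loss_hist[step + 1] = loss
        p_hist[step + 1] = np.where(alive, p, p_hist[step])
        v_hist[step + 1] = np.where(alive, var_f, v_hist[step])
    out = []
    for k, seed_config in enumerate(seeds):
        final = seed_config.displaced(delta_hist[-1, k])
        out.append(
            AttackResult(
                seed_config,
                delta_hist[:, k].copy(),
                loss_hist[:, k].copy(),
                final,
                _predict_single(results, final),
                failed=not bool(alive[k]),
                likelihood_history=p_hist[:, k].copy(),
                force_variance_history=v_hist[:, k].copy(),
            )
        )
    return out


def _cv_candidate(seed_config: Configuration, cvs, delta) -> Configuration:
    from .cv import backmap

    return seed_config.with_coords(backmap(seed_config.coords, cvs, delta))


def _cv_attack(results, seed_config, cfg: AttackConfig, normalizer, cvs):
    K = len(cvs)
    delta = init_delta(
        K, cfg.sigma_delta, np.random.SeedSequence([cfg.seed, _config_entropy(seed_config)])
    )
    opt = Adam([delta.shape], lr=cfg.lr) if cfg.optimizer == "adam" else None
    delta_hist = np.empty((cfg.n_steps + 1, K))
    loss_hist = np.empty(cfg.n_steps + 1)
    p_hist = np.empty(cfg.n_steps + 1)
    v_hist = np.empty(cfg.n_steps + 1)

    def loss_and_grad(dlt):
        coords, T = backmap_with_jacobian(seed_config.coords, cvs, dlt)
        loss, grad_x, p, var_f = adversarial_loss_and_grad(
            results, coords.ravel()[None, :], normalizer, return_terms=True
        )
        grad_delta = T.reshape(K, -1) @ grad_x[0]
        return float(loss[0]), grad_delta, float(p[0]), float(var_f[0])

    loss, grad, p, var_f = loss_and_grad(delta)
    delta_hist[0] = delta
    loss_hist[0] = loss
    p_hist[0] = p
    v_hist[0] = var_f
    for step in range(cfg.n_steps):
        if not (np.isfinite(loss) and np.all(np.isfinite(grad))):
            raise AttackDivergedError(
                f"non-finite adversarial loss/gradient at step {step}",
                delta_hist[step],
                loss_hist[step],
                step,
            )
        if opt is not None:
            opt.step([delta], [grad], sign=+1.0)
        else:
            delta += cfg.lr * grad
        loss, grad, p, var_f = loss_and_grad(delta)
        delta_hist[step + 1] = delta
        loss_hist[step + 1] = loss
        p_hist[step + 1] = p
        v_hist[step + 1] = var_f
    final = _cv_candidate(seed_config, cvs, delta_hist[-1])
    return AttackResult(
        seed_config,
        delta_hist,
        loss_hist,
        final,
        _predict_single(results, final),
        likelihood_history=p_hist,
        force_variance_history=v_hist,
    )
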