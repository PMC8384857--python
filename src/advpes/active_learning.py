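"""Active-learning orchestration: train, attack, select, label, augment, repeat.

One *generation* takes the current dataset and fitted committee, proposes
candidates (adversarial attacks from dataset seeds, or the random-distortion
baseline), pushes them through the selection pipeline
(deduplicate -> uncertainty filter -> oracle evaluation -> energy discard),
appends the survivors with provenance tags, and retrains the committee from
scratch.  :func:`replicate_experiment` runs paired adversarial/random loops
over many seeds and tabulates per-generation medians and interquartile
ranges of the benchmark metrics (grid RMSE, training-set size, energy of
newly added points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .adversarial import AttackConfig, batch_attacks, partition_normalizer
from .committee import CommitteeModel, CommitteeResults, TrainConfig
from .data import Configuration, Dataset
from .potentials import GroundTruthPotential, evaluate_oracle, sample_initial_dataset
from .selection import SelectionConfig, deduplicate, energy_discard, uncertainty_accept

__all__ = [
    "ALConfig",
    "GenerationRecord",
    "ALState",
    "run_generation",
    "run_random_generation",
    "run_loop",
    "grid_rmse",
    "replicate_experiment",
    "summarize_replicates",
]


@dataclass(frozen=True)
class ALConfig:
    """Settings of the full loop; sub-configs own their stages.

    The double-well defaults mirror the toy benchmark protocol: up to 800
    uniform points filtered at E < -2 as initial data, 20 attack seeds per
    generation, dedup threshold 0.02, 80th-percentile uncertainty filter,
    random baseline delta ~ U(-1, 1) with up to 20 picks, 8 generations.
    """

    n_generations: int = 8
    seeds_per_generation: int = 20
    train: TrainConfig = TrainConfig()
    attack: AttackConfig = AttackConfig()
    # extremely-high-energy candidates interfere with retraining without
    # informing the benchmark region; they are discarded after labeling
    selection: SelectionConfig = SelectionConfig(max_energy_discard=200.0)
    init_n_max: int = 800
    init_filter_max_energy: float = -2.0
    region: tuple = ((-1.5, 1.5), (-1.5, 1.5))
    random_sigma: float = 1.0
    random_max_picks: int = 20

    def __post_init__(self):
        if self.n_generations < 1 or self.seeds_per_generation < 1:
            raise ValueError("n_generations and seeds_per_generation must be >= 1")


@dataclass
class GenerationRecord:
    """Per-generation benchmark metrics and selection accounting."""

    generation: int
    rmse: float
    n_dataset: int
    n_candidates: int
    n_after_dedup: int
    n_after_uncertainty: int
    n_added: int
    median_new_energy: float  # NaN when nothing was added


@dataclass
class ALState:
    """Loop state: generation index, dataset, fitted committee, metric history."""

    generation: int
    dataset: Dataset
    results: CommitteeResults
    metrics: List[GenerationRecord] = field(default_factory=list)


def grid_rmse(
    results: CommitteeResults,
    potential: GroundTruthPotential,
    region=((-1.5, 1.5), (-1.5, 1.5)),
    resolution: int = 100,
) -> float:
    """RMSE between committee mean energy and ground truth on a regular grid."""
    axes = [np.linspace(lo, hi, resolution) for lo, hi in region]
    mesh = np.meshgrid(*axes, indexing="ij")
    X = np.stack([m.ravel() for m in mesh], axis=1)
    pred = results.predict_batch(X)["mean_energy"]
    truth = potential.energy_batch(X)
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def _retrain(dataset: Dataset, train_cfg: TrainConfig, seed: int) -> CommitteeResults:
    """Fresh parameters each generation: the committee is a pure function of
    (dataset, seed)."""
    return CommitteeModel(dataset, replace(train_cfg, seed=seed)).fit()


def _pick_seed_configs(dataset: Dataset, k: int, rng: np.random.Generator) -> List[Configuration]:
    idx = rng.choice(len(dataset), size=min(k, len(dataset)), replace=False)
    return [dataset[i].config for i in idx]


def _select_and_augment(
    state: ALState,
    candidates: Sequence[Configuration],
    potential: GroundTruthPotential,
    cfg: ALConfig,
    provenance: str,
    retrain_seed: int,
    rng: np.random.Generator,
) -> ALState:
    """Common tail of a generation: selection pipeline, oracle, retrain, metrics."""
    n_candidates = len(candidates)
    deduped = deduplicate(list(candidates), state.results, cfg.selection) if candidates else []
    # also reject candidates that duplicate existing training points: the
    # whole point of deduplication is never to evaluate the same geometry twice
    if deduped:
        Xd = state.dataset.coords_matrix()
        scale = np.sqrt(Xd.shape[1])
        deduped = [
            c
            for c in deduped
            if np.linalg.norm(Xd - c.flat, axis=1).min() / scale
            > cfg.selection.rmsd_threshold
        ]
    classifier = state.results.calibrate_threshold(
        percentile=cfg.selection.uncertainty_percentile
    )
    accepted = uncertainty_accept(deduped, state.results, classifier)
    n_after_uncertainty = len(accepted)
    if provenance == "random" and len(accepted) > cfg.random_max_picks:
        idx = rng.choice(len(accepted), size=cfg.random_max_picks, replace=False)
        accepted = [accepted[i] for i in sorted(idx)]
    labeled = evaluate_oracle(potential, accepted)
    labeled = energy_discard(labeled, cfg.selection.max_energy_discard)
    if labeled:
        dataset = state.dataset.extended(labeled, provenance)
    else:
        warnings.warn(f"generation {state.generation + 1}: no candidates survived selection")
        dataset = state.dataset
    results = _retrain(dataset, cfg.train, retrain_seed)
    new_energies = np.array([s.energy for s in labeled])
    record = GenerationRecord(
        generation=state.generation + 1,
        rmse=grid_rmse(results, potential, cfg.region),
        n_dataset=len(dataset),
        n_candidates=n_candidates,
        n_after_dedup=len(deduped),
        n_after_uncertainty=n_after_uncertainty,
        n_added=len(labeled),
        median_new_energy=float(np.median(new_energies)) if labeled else float("nan"),
    )
    return ALState(state.generation + 1, dataset, results, state.metrics + [record])


def run_generation(
    state: ALState,
    potential: GroundTruthPotential,
    cfg: ALConfig,
    seed: int,
) -> ALState:
    """One adversarial generation: attack 20 dataset seeds, select, label, retrain."""
    ss = np.random.SeedSequence([seed, state.generation])
    pick_ss, attack_ss, retrain_ss = ss.spawn(3)
    rng = np.random.default_rng(pick_ss)
    seeds = _pick_seed_configs(state.dataset, cfg.seeds_per_generation, rng)
    attack_cfg = replace(
        cfg.attack, seed=int(np.random.default_rng(attack_ss).integers(2**31 - 1))
    )
    normalizer = partition_normalizer(state.dataset, attack_cfg.kT)
    attacks = batch_attacks(state.results, seeds, attack_cfg, normalizer)
    candidates = [a.final_config for a in attacks if not a.failed]
    retrain_seed = int(np.random.default_rng(retrain_ss).integers(2**31 - 1))
    return _select_and_augment(
        state, candidates, potential, cfg, "adversarial", retrain_seed, rng
    )


def run_random_generation(
    state: ALState,
    potential: GroundTruthPotential,
    cfg: ALConfig,
    seed: int,
) -> ALState:
    """Baseline generation: uniform distortions delta ~ U(-sigma, sigma) of
    training points, then the identical selection pipeline."""
    ss = np.random.SeedSequence([seed, state.generation])
    pick_ss, distort_ss, retrain_ss = ss.spawn(3)
    rng = np.random.default_rng(pick_ss)
    seeds = _pick_seed_configs(state.dataset, cfg.seeds_per_generation, rng)
    drng = np.random.default_rng(distort_ss)
    candidates = [
        s.displaced(drng.uniform(-cfg.random_sigma, cfg.random_sigma, size=s.dof))
        for s in seeds
    ]
    retrain_seed = int(np.random.default_rng(retrain_ss).integers(2**31 - 1))
    return _select_and_augment(state, candidates, potential, cfg, "random", retrain_seed, rng)


def run_loop(
    potential: GroundTruthPotential,
    cfg: ALConfig,
    seed: int,
    mode: str = "adversarial",
    initial: Optional[Dataset] = None,
) -> ALState:
    """Full loop from initial sampling through ``n_generations`` generations.

    A single master seed derives every stage seed, so two runs with the same
    seed produce bit-identical trajectories.
    """
    if mode not in ("adversarial", "random"):
        raise ValueError("mode must be 'adversarial' or 'random'")
    ss = np.random.SeedSequence(seed)
    init_ss, train_ss, loop_ss = ss.spawn(3)
    if initial is None:
        initial = sample_initial_dataset(
            potential,
            n_max=cfg.init_n_max,
            filter_max_energy=cfg.init_filter_max_energy,
            region=cfg.region,
            seed=init_ss,
        )
    results = _retrain(initial, cfg.train, int(np.random.default_rng(train_ss).integers(2**31 - 1)))
    record = GenerationRecord(
        generation=0,
        rmse=grid_rmse(results, potential, cfg.region),
        n_dataset=len(initial),
        n_candidates=0,
        n_after_dedup=0,
        n_after_uncertainty=0,
        n_added=0,
        median_new_energy=float("nan"),
    )
    state = ALState(0, initial, results, [record])
    loop_seed = int(np.random.default_rng(loop_ss).integers(2**31 - 1))
    step = run_generation if mode == "adversarial" else run_random_generation
    for _ in range(cfg.n_generations):
        state = step(state, potential, cfg, loop_seed)
    return state


def replicate_experiment(
    potential: GroundTruthPotential,
    cfg: ALConfig,
    n_replicates: int,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Paired adversarial vs random loops over ``n_replicates`` seeds.

    Returns a long-format table with one row per (replicate, strategy,
    generation).  Individual replicate failures are recorded as missing rows
    rather than aborting the experiment.
    """
    if n_replicates < 2:
        raise ValueError("need at least two replicates")
    rows = []
    child_seeds = np.random.SeedSequence(base_seed).generate_state(n_replicates) >> 1
    for r, seed in enumerate(child_seeds):
        for mode in ("adversarial", "random"):
            try:
                state = run_loop(potential, cfg, int(seed), mode=mode)
            except Exception as err:  # pragma: no cover - defensive
                warnings.warn(f"replicate {r} ({mode}) failed: {err}")
                continue
            for rec in state.metrics:
                rows.append(
                    {
                        "replicate": r,
                        "strategy": mode,
                        "generation": rec.generation,
                        "rmse": rec.rmse,
                        "n_train": rec.n_dataset,
                        "n_added": rec.n_added,
                        "median_new_energy": rec.median_new_energy,
                    }
                )
    return pd.DataFrame(rows)


def summarize_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range per generation and strategy."""

    def q25(x):
        return x.quantile(0.25)

    def q75(x):
        return x.quantile(0.75)

    out = (
        table.groupby(["strategy", "generation"])
        .agg(
            rmse_median=("rmse", "median"),
            rmse_q25=("rmse", q25),
            rmse_q75=("rmse", q75),
            n_train_median=("n_train", "median"),
            new_energy_median=("median_new_energy", "median"),
        )
        .reset_index()
    )
    return out
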