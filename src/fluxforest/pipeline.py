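"""End-to-end surrogate-modeling workflow.

Chains the five stages — flux sampling, label simulation, measurement
modeling, training-set extraction, forest training — into convenience
functions used by the command line, the examples, and the acceptance
script.  EMU decompositions are cached per (network, fragment set) so a
cohort of tens of thousands of flux maps costs one decomposition and a
handful of vectorized linear solves per sample batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emu import EMUSystem
from .forest import RatioPredictor, SimulatedDataset, evaluate_mae, make_training_set, train
from .labels import SubstrateLabelMixture
from .measurements import MeasurementSpec, add_noise, extract_features
from .network import MetabolicNetwork
from .ratios import RatioDefinition
from .sampling import FluxCohort, ratio_values, stratified_cohort

__all__ = [
    "get_emu_system",
    "simulate_measurements",
    "build_dataset",
    "train_ratio_predictor",
    "PipelineResult",
]

_EMU_CACHE: dict[tuple[int, tuple], EMUSystem] = {}


def get_emu_system(network: MetabolicNetwork, spec: MeasurementSpec) -> EMUSystem:
    """EMU decomposition for a measurement spec, cached per network object."""
    key = (id(network), tuple(sorted(spec.targets)))
    if key not in _EMU_CACHE:
        _EMU_CACHE[key] = EMUSystem(network, spec.targets)
    return _EMU_CACHE[key]


def simulate_measurements(
    network: MetabolicNetwork,
    cohort: FluxCohort,
    tracer: SubstrateLabelMixture,
    spec: MeasurementSpec,
    noise_level: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Feature matrix of measurable MDV entries for every cohort sample."""
    spec.validate(network)
    emu = get_emu_system(network, spec)
    mdvs = emu.simulate(cohort.fwd, cohort.bwd, tracer)
    X = extract_features(mdvs, spec)
    if noise_level > 0:
        X = add_noise(X, noise_level, seed, spec)
    return X


@dataclass
class PipelineResult:
    """Everything produced by one train/evaluate run."""

    predictor: RatioPredictor
    dataset: SimulatedDataset
    test_mae: float
    cohort: FluxCohort | None = None
    extras: dict = field(default_factory=dict)


def build_dataset(
    network: MetabolicNetwork,
    ratio_def: RatioDefinition,
    tracer: SubstrateLabelMixture,
    spec: MeasurementSpec,
    *,
    n_bins: int = 10,
    cohort_per_bin: int = 300,
    train_per_bin: int | None = None,
    exch_bound: float = 1.0,
    noise_level: float = 0.01,
    seed: int = 0,
    cohort: FluxCohort | None = None,
) -> tuple[SimulatedDataset, FluxCohort]:
    """Stratified cohort -> simulated features -> noised, balanced, split set.

    When ``cohort`` is given it is reused (its ratio labels are recomputed
    for ``ratio_def`` if absent) so that several designs can share one set
    of flux maps.
    """
    rng = np.random.SeedSequence(seed)
    s_cohort, s_noise, s_split = (int(s.generate_state(1)[0] % 2**31)
                                  for s in rng.spawn(3))
    if cohort is None:
        cohort = stratified_cohort(
            network, ratio_def, n_bins, cohort_per_bin, exch_bound, s_cohort
        )
    y = cohort.ratios.get(ratio_def.name)
    if y is None:
        y = ratio_values(ratio_def, network, cohort.net)
        cohort.ratios[ratio_def.name] = y
    X = simulate_measurements(
        network, cohort, tracer, spec, noise_level=noise_level, seed=s_noise
    )
    from .sampling import infeasible_bin_indices

    exclude = infeasible_bin_indices(cohort, ratio_def.name, n_bins)
    dataset = make_training_set(
        X, y, n_bins=n_bins, n_per_bin=train_per_bin, seed=s_split,
        manifest=spec.manifest, ratio_name=ratio_def.name, exclude_bins=exclude,
    )
    dataset.metadata.update(
        {
            "noise_level": noise_level,
            "exch_bound": cohort.metadata.get("exch_bound", exch_bound),
            "tracer": tracer.name,
            "platform": spec.platform,
            "seed": seed,
        }
    )
    return dataset, cohort


def train_ratio_predictor(
    network: MetabolicNetwork,
    ratio_def: RatioDefinition,
    tracer: SubstrateLabelMixture,
    spec: MeasurementSpec,
    *,
    ntree: int = 100,
    mtry: int = 20,
    feature_selection: bool = False,
    seed: int = 0,
    **dataset_kwargs,
) -> PipelineResult:
    """Full workflow for one ratio: returns predictor + held-out test MAE."""
    from .forest import select_features

    dataset, cohort = build_dataset(
        network, ratio_def, tracer, spec, seed=seed, **dataset_kwargs
    )
    subset = None
    extras = {}
    if feature_selection:
        subset, table = select_features(
            dataset, seed=seed, ntree=ntree, mtry=mtry
        )
        extras["feature_selection"] = table
    predictor = train(
        dataset, ntree=ntree, mtry=mtry, seed=seed, feature_subset=subset
    )
    predictor.metadata.update(dataset.metadata)
    mae = evaluate_mae(predictor, dataset)
    return PipelineResult(predictor, dataset, mae, cohort, extras)
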