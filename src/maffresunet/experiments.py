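"""Reproducible desk-scale experiments on phantom data.

The configuration here is the package's CPU-scale study regime: a
reduced-width network (base_filters = fusion_channels = 8) trained on 8
phantom slices at 64×64 crop for 200 Adam steps with lr 5e-3 under the poly
schedule. This is an overfitting smoke experiment — it demonstrates that
the full pipeline (phantom generation → preprocessing → model → composite
loss → optimizer → metrics) learns the segmentation, not that the model
generalizes; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import SlicePair, preprocess_case, slice_and_filter
from .metrics import MetricsReport
from .model import MAFFResUNet, ModelConfig
from .phantom import PhantomSpec, generate_case
from .train_eval import TrainConfig, TrainState, evaluate, train

SMOKE_CROP_SIZE = 64
SMOKE_N_SLICES = 8


def smoke_model_config(seed: int = 0) -> ModelConfig:
    return ModelConfig(base_filters=8, fusion_channels=8, seed=seed)


def smoke_train_config(seed: int = 0, max_iter: int = 200) -> TrainConfig:
    return TrainConfig(lr_init=5e-3, batch_size=4, max_iter=max_iter,
                       seed=seed, checkpoint_every=10_000)


def phantom_slices(seed: int, n_slices: int = SMOKE_N_SLICES,
                   crop_size: int = SMOKE_CROP_SIZE,
                   n_cases: int = 2) -> list[SlicePair]:
    """Preprocessed tumor-containing slices from deterministic phantoms.

    Slices are taken evenly across the pooled axial extent so the set spans
    small and large tumor cross-sections.
    """
    spec = PhantomSpec(seed=seed)
    pairs: list[SlicePair] = []
    for index in range(n_cases):
        case = preprocess_case(generate_case(spec, index))
        pairs.extend(slice_and_filter(case, crop_size=crop_size))
    if len(pairs) < n_slices:
        raise ValueError(f"only {len(pairs)} tumor slices available, "
                         f"need {n_slices}")
    chosen = np.linspace(0, len(pairs) - 1, n_slices).astype(int)
    return [pairs[i] for i in chosen]


@dataclass
class SmokeResult:
    state: TrainState
    report: MetricsReport
    model: MAFFResUNet
    slices: list[SlicePair] = field(repr=False, default_factory=list)

    @property
    def initial_loss(self) -> float:
        return self.state.history[0]["train_loss"]

    @property
    def final_loss(self) -> float:
        return self.state.history[-1]["train_loss"]

    @property
    def loss_ratio(self) -> float:
        return self.final_loss / self.initial_loss


def overfit_phantom_experiment(seed: int = 0, max_iter: int = 200
                               ) -> SmokeResult:
    """Train the reduced-width network on 8 phantom slices and evaluate on
    those same slices."""
    slices = phantom_slices(seed=seed + 1)
    model = MAFFResUNet(smoke_model_config(seed=seed))
    cfg = smoke_train_config(seed=seed, max_iter=max_iter)
    state = train(model, slices, None, cfg)
    report = evaluate(model, slices, cfg)
    return SmokeResult(state=state, report=report, model=model,
                       slices=slices)
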