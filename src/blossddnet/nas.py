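"""Decoder architecture search: enumerate, train, select by validation Dice.

The search space is a clean Cartesian grid over the decoder sub-block
template ``dilated conv -> depthwise-separable conv -> tail``:

    (dilated kernel in {3,5}) x (dilation in {1,2,3})
    x (depthwise kernel in {3,5}) x (tail in {SE-attention, maxpool 3x3 s1})

i.e. 24 candidates, each used as the shared spec of all stages of the
searched branch while the partner branch is frozen to its default spec.
Selection is train-and-compare: every candidate is trained with the
branch-appropriate loss and the one with the maximum validation Dice wins;
ties break toward fewer parameters, then enumeration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .losses import LossWeights
from .metrics import dice_coefficient
from .model import BlockSpec, DualTaskNet, ModelConfig
from .train import TrainConfig, train_model

__all__ = [
    "SearchSpace",
    "CandidateResult",
    "enumerate_candidates",
    "evaluate_candidate",
    "select_best",
    "run_search",
]


@dataclass
class SearchSpace:
    """Enumerable grids of the decoder search."""

    dilated_kernels: tuple = (3, 5)
    dilations: tuple = (1, 2, 3)
    dws_kernels: tuple = (3, 5)
    tails: tuple = ("se_attention", "maxpool3_s1")

    def __post_init__(self):
        for name in ("dilated_kernels", "dilations", "dws_kernels", "tails"):
            if not getattr(self, name):
                raise ValueError(f"empty grid: {name}")


@dataclass
class CandidateResult:
    """Outcome of training one candidate decoder spec."""

    spec: list
    val_dice: float
    parameter_count: int
    seed: int
    index: int = 0  # enumeration order, the final tie-break
    failed: bool = False
    extras: dict = field(default_factory=dict)


def enumerate_candidates(space: SearchSpace | None = None):
    """All decoder specs of the grid, in stable enumeration order."""
    space = space or SearchSpace()
    candidates = []
    for dk, d, wk, tail in product(
        space.dilated_kernels, space.dilations, space.dws_kernels, space.tails
    ):
        candidates.append(
            [
                BlockSpec("dilated", kernel=dk, dilation=d, stride=1),
                BlockSpec("depthwise_separable", kernel=wk, stride=1, tail=tail),
            ]
        )
    return candidates


def evaluate_candidate(
    spec,
    train_scenes,
    val_scenes,
    budget: int = 2,
    seed: int = 0,
    role: str = "mask",
    base_channels: int = 8,
    index: int = 0,
) -> CandidateResult:
    """Train a model whose ``role`` branch uses ``spec`` and score it by the
    mean validation Dice of that branch's thresholded output.

    The partner branch keeps its default (reported-final) spec so results
    are comparable.  A run that diverges (non-finite loss) is marked failed
    with ``val_dice = -1``.
    """
    if budget < 1:
        raise ValueError(f"budget must be >= 1 epoch, got {budget}")
    if not train_scenes or not val_scenes:
        raise ValueError("train and validation scene lists must be nonempty")
    if role not in ("mask", "boundary"):
        raise ValueError(f"role must be 'mask' or 'boundary', got {role!r}")
    kwargs = {"base_channels": base_channels, "se_reduction": 4}
    if role == "mask":
        kwargs["mask_decoder_spec"] = spec
        # NAS-phase mask objective 0.3*BCE + 0.7*Dice on the mask branch
        weights = LossWeights(alpha=0.3, beta=0.7, gamma=0.0)
    else:
        kwargs["boundary_decoder_spec"] = spec
        weights = LossWeights()
    model_cfg = ModelConfig(**kwargs)
    cfg = TrainConfig(epochs=budget, seed=seed, weights=weights)
    model, history = train_model(train_scenes, config=cfg, model_config=model_cfg)
    if history.attrs.get("diverged"):
        return CandidateResult(
            spec=spec, val_dice=-1.0, parameter_count=model.parameter_count(),
            seed=seed, index=index, failed=True,
        )
    model.eval()
    dices = []
    for scene in val_scenes:
        out = model.forward(scene.image)
        if role == "mask":
            dices.append(dice_coefficient(scene.mask, out.mask_prob >= 0.5))
        else:
            dices.append(dice_coefficient(scene.boundary, out.boundary_prob >= 0.5))
    val_dice = float(sum(dices) / len(dices))
    return CandidateResult(
        spec=spec, val_dice=val_dice, parameter_count=model.parameter_count(),
        seed=seed, index=index,
    )


def select_best(results):
    """Argmax validation Dice; ties break toward fewer parameters, then
    enumeration order.  Raises if every candidate failed."""
    viable = [r for r in results if not r.failed and r.val_dice >= 0]
    if not viable:
        raise RuntimeError("no viable candidate: every search run failed")
    best = min(viable, key=lambda r: (-r.val_dice, r.parameter_count, r.index))
    return best.spec


def run_search(
    train_scenes,
    val_scenes,
    space: SearchSpace | None = None,
    budget: int = 2,
    seed: int = 0,
    role: str = "mask",
    base_channels: int = 8,
):
    """Full grid search; returns (winning spec, results, ranked DataFrame)."""
    results = []
    for i, spec in enumerate(enumerate_candidates(space)):
        results.append(
            evaluate_candidate(
                spec, train_scenes, val_scenes, budget=budget, seed=seed,
                role=role, base_channels=base_channels, index=i,
            )
        )
    rows = []
    for r in results:
        dilated, dws = r.spec[0], r.spec[1]
        rows.append(
            {
                "index": r.index,
                "dilated_kernel": dilated.kernel,
                "dilation": dilated.dilation,
                "dws_kernel": dws.kernel,
                "tail": dws.tail,
                "val_dice": r.val_dice,
                "parameters": r.parameter_count,
                "failed": r.failed,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["val_dice", "parameters", "index"], ascending=[False, True, True]
    )
    return select_best(results), results, table
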