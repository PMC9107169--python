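"""Seeded end-to-end validation experiment on synthetic phantoms.

Trains the two-module system on a freshly generated phantom training set and
measures label-recovery accuracy on a disjoint held-out phantom set. Because
the phantom classes are separable by construction (see
:func:`ctqc.phantom.classify_phantom_rule_based`), a correctly wired
pipeline is expected to recover 100% of body-part and contrast labels; any
shortfall points at a defect in preprocessing, training or voting rather
than at task difficulty.
"""

from __future__ import annotations

from dataclasses import dataclass

from .phantom import DEFAULT_GRID, DEFAULT_NOISE_SIGMA, generate_labeled_volumes
from .pipeline import classify_volumes, contrast_label, train_two_module_system
from .training import TrainConfig

__all__ = ["HeldOutResult", "held_out_phantom_validation"]

# offset separating held-out generator seeds from training seeds
_HELDOUT_SEED_OFFSET = 500_009


@dataclass(frozen=True)
class HeldOutResult:
    """Accuracies (percent) of the two modules on the held-out set."""

    body_part_accuracy: float
    contrast_accuracy: float
    overall_accuracy: float  # both labels correct
    n_train: int
    n_test: int


def held_out_phantom_validation(
    seed: int,
    n_train_per_cell: int = 10,
    n_test_per_cell: int = 5,
    grid: tuple[int, int, int] = DEFAULT_GRID,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    config: TrainConfig | None = None,
    log=None,
) -> HeldOutResult:
    """Train on ``10·n_train_per_cell`` phantoms, score ``10·n_test_per_cell`` held out.

    The held-out set uses generator seeds offset from the training seeds, so
    no phantom (geometry + noise draw) is shared between the two sets.
    """
    train = generate_labeled_volumes(n_train_per_cell, grid, noise_sigma, seed=seed)
    test = generate_labeled_volumes(
        n_test_per_cell, grid, noise_sigma, seed=seed + _HELDOUT_SEED_OFFSET
    )
    volumes = [v for v, _, _ in train]
    body_labels = [b for _, b, _ in train]
    contrast_flags = [c for _, _, c in train]
    config = config or TrainConfig(seed=seed)

    body_module, contrast_modules = train_two_module_system(
        volumes, body_labels, contrast_flags, config, log=log
    )
    results = classify_volumes([v for v, _, _ in test], body_module, contrast_modules)

    body_ok = sum(r.body_part == b for r, (_, b, _) in zip(results, test))
    con_ok = sum(r.contrast == contrast_label(c) for r, (_, _, c) in zip(results, test))
    both_ok = sum(
        r.body_part == b and r.contrast == contrast_label(c)
        for r, (_, b, c) in zip(results, test)
    )
    n = len(test)
    return HeldOutResult(
        body_part_accuracy=100.0 * body_ok / n,
        contrast_accuracy=100.0 * con_ok / n,
        overall_accuracy=100.0 * both_ok / n,
        n_train=len(train),
        n_test=n,
    )
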