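"""End-to-end orchestration: cohort -> arrays -> trained models.

Glue used by the command-line interface and by scripted experiments:
building the per-model network factories, running the block schedule
for each of the three models on one prepared cohort, and saving /
loading checkpoints (NumPy archive + JSON sidecar recording the specs
and seeds).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import RunConfig
from .lossfn import LossParams
from .models import AnnSpec, CnnSpec, ConcatSpec, build_concat_model
from .nn import FusionNetwork
from .phantom import generate_cohort
from .training import (
    Schedule,
    SplitSpec,
    prepare_cohort_arrays,
    train_and_evaluate,
)

MODEL_MODES = ("cnn", "ann", "concat")


def model_factory(
    mode: str,
    n_kernels: int = 32,
    ann: AnnSpec = AnnSpec(),
    head: ConcatSpec = ConcatSpec(),
):
    """A seed -> network callable for one of the three model modes."""
    if mode not in MODEL_MODES:
        raise ValueError(f"mode must be one of {MODEL_MODES}, got {mode!r}")
    cnn_spec = CnnSpec(n_kernels=n_kernels) if mode in ("cnn", "concat") else None
    ann_spec = ann if mode in ("ann", "concat") else None

    def factory(seed: int) -> FusionNetwork:
        return build_concat_model(cnn_spec, ann_spec, head, rng=seed)

    return factory


def run_training(config: RunConfig, mode: str = "concat", seed: int | None = None) -> dict:
    """Generate the phantom cohort and train one model end to end.

    Returns the ``train_and_evaluate`` result dict plus the prepared
    arrays under ``"data"``.
    """
    seed = config.seed if seed is None else seed
    records = generate_cohort(config.phantom)
    data = prepare_cohort_arrays(
        records,
        config.phantom,
        split_spec=SplitSpec(fractions=config.split.fractions, seed=seed),
        seed=seed,
    )
    factory = model_factory(mode, config.n_kernels, config.ann, config.head)
    result = train_and_evaluate(
        factory,
        data["train"],
        data["val"],
        data["test"],
        schedule=config.schedule,
        loss_params=config.loss,
        seed=seed,
    )
    result["data"] = data
    result["mode"] = mode
    return result


def compare_models(
    phantom_spec,
    schedule: Schedule,
    split_spec: SplitSpec = SplitSpec(),
    loss_params: LossParams = LossParams(),
    ann: AnnSpec = AnnSpec(),
    head: ConcatSpec = ConcatSpec(),
    n_kernels: int = 32,
    seed: int = 0,
    data: dict | None = None,
) -> dict:
    """Train all three models on one prepared cohort.

    Returns {"cnn": ..., "ann": ..., "concat": ...} of
    ``train_and_evaluate`` results, plus the shared arrays under
    ``"data"``.  Pass ``data`` to reuse already-prepared arrays (the
    expensive preprocessing is shared across training seeds).
    """
    if data is None:
        records = generate_cohort(phantom_spec)
        data = prepare_cohort_arrays(records, phantom_spec, split_spec=split_spec, seed=seed)
    out: dict = {"data": data}
    for mode in MODEL_MODES:
        factory = model_factory(mode, n_kernels, ann, head)
        out[mode] = train_and_evaluate(
            factory,
            data["train"],
            data["val"],
            data["test"],
            schedule=schedule,
            loss_params=loss_params,
            seed=seed,
        )
    return out


def save_checkpoint(
    network: FusionNetwork, path: str | Path, meta: dict | None = None
) -> Path:
    """Save network state as an .npz plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = network.get_state()
    flat = {}
    for i, entry in enumerate(state):
        for key, arr in entry.items():
            flat[f"layer{i:03d}/{key}"] = arr
    np.savez(path, **flat)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta or {}, indent=2, default=str))
    return path


def load_checkpoint(network: FusionNetwork, path: str | Path) -> FusionNetwork:
    """Restore a saved state into a freshly built network of the same spec."""
    archive = np.load(Path(path))
    state: list[dict] = []
    for name in archive.files:
        layer_tag, key = name.split("/", 1)
        idx = int(layer_tag.removeprefix("layer"))
        while len(state) <= idx:
            state.append({})
        state[idx][key] = archive[name]
    network.set_state(state)
    return network
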