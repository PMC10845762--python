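"""From simulated datasets to network training pairs.

The sinogram network learns ``linear-interpolation-initialized sinogram ->
metal-free dense ground-truth sinogram``; the image network learns ``FBP of
the synthesized sinogram -> FBP of the ground-truth sinogram`` (so its input
carries exactly the residual artifacts the first stage leaves behind, and its
target carries the reconstruction-filter characteristics a real reference
image would have).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .completion import (
    guarded_synthesize,
    linear_interpolate,
    sinogram_network_input,
    unet_synthesize,
    upsample_view_grid,
)
from .geometry import ImageSlice, ScanGeometry, Sinogram
from .metal import MetalMask, MetalTrace, remove_metal
from .nn import NetConfig, PatchSet, TrainConfig, TrainState, extract_patches, train_model
from .nn.models import _Model, build_modified_resunet, build_modified_unet
from .recon import FBPConfig, fbp_reconstruct

__all__ = [
    "DatasetCase",
    "load_dataset",
    "completion_input",
    "build_training_pairs",
    "train_stage",
    "simulate_and_train",
]


@dataclass
class DatasetCase:
    index: int
    group: str
    ground_truth: ImageSlice
    dense_sinogram: Sinogram
    sparse_sinogram: Sinogram
    metal_mask: MetalMask
    metal_trace: MetalTrace
    artifact_image: ImageSlice


def load_dataset(path) -> tuple[ScanGeometry, int, list[DatasetCase]]:
    """Read a dataset written by :func:`sinomar.simulate.generate_dataset`."""
    import json

    with h5py.File(path, "r") as f:
        geometry = ScanGeometry(
            n_views=int(f.attrs["n_views"]),
            angle_step_deg=float(f.attrs["angle_step_deg"]),
            n_bins=int(f.attrs["n_bins"]),
            bin_spacing=float(f.attrs["bin_spacing"]),
            image_size=int(f.attrs["image_size"]),
            pixel_size=float(f.attrs["pixel_size"]),
        )
        factor = int(json.loads(f.attrs["manifest"])["decimation_factor"])
        sparse_geom = geometry.with_views(geometry.n_views // factor)
        cases = []
        for name in sorted(k for k in f.keys() if k.startswith("case_")):
            grp = f[name]
            support = grp["metal_mask"][()].astype(bool)
            cases.append(
                DatasetCase(
                    index=int(name.split("_")[1]),
                    group=str(grp.attrs["group"]),
                    ground_truth=ImageSlice(grp["ground_truth"][()], geometry),
                    dense_sinogram=Sinogram(grp["dense_sinogram"][()], geometry),
                    sparse_sinogram=Sinogram(grp["sparse_sinogram"][()], sparse_geom),
                    metal_mask=MetalMask(support, grp["metal_values"][()]),
                    metal_trace=MetalTrace(grp["metal_trace"][()].astype(bool)),
                    artifact_image=ImageSlice(grp["artifact_image"][()], geometry),
                )
            )
    return geometry, factor, cases


def completion_input(case: DatasetCase, factor: int) -> tuple[Sinogram, np.ndarray]:
    """Up-sample the sparse sinogram, remove the metal trace, fill by linear
    interpolation.  Returns the initialized sinogram and the mask of entries
    that were originally missing."""
    up = upsample_view_grid(case.sparse_sinogram, factor)
    if not case.metal_trace.is_empty:
        up = remove_metal(up, case.metal_trace)
    invalid = ~up.valid_mask
    return linear_interpolate(up), invalid


def build_training_pairs(
    cases: list[DatasetCase],
    stage: str,
    factor: int,
    sino_model: _Model | None = None,
    fbp_config: FBPConfig | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(input, target) 2-D arrays for one training stage, one pair per case."""
    if stage not in ("sino", "image"):
        raise ValueError("stage must be 'sino' or 'image'")
    fbp_config = fbp_config or FBPConfig()
    pairs = []
    for case in cases:
        lin, invalid = completion_input(case, factor)
        if stage == "sino":
            net_input = sinogram_network_input(lin, invalid, case.metal_trace.support)
            pairs.append((net_input, case.dense_sinogram.values))
        else:
            if sino_model is None:
                raise ValueError("image-stage training needs the trained sinogram model")
            syn, _ = guarded_synthesize(
                lin, sino_model, invalid_mask=invalid, trace_mask=case.metal_trace.support
            )
            recon = fbp_reconstruct(syn, fbp_config)
            target = fbp_reconstruct(case.dense_sinogram, fbp_config)
            pairs.append((recon.values, target.values))
    return pairs


def train_stage(
    cases: list[DatasetCase],
    stage: str,
    factor: int,
    net_config: NetConfig,
    train_config: TrainConfig,
    sino_model: _Model | None = None,
    sampling_weights: str = "artifact",
    val_cases: list[DatasetCase] | None = None,
) -> tuple[_Model, TrainState, PatchSet]:
    """Build pairs, extract patches and train one network stage.

    Validation patches are drawn from *held-out phantoms* so early stopping
    measures generalization to new objects: ``val_cases`` if given, otherwise
    the last quarter (at least one) of ``cases`` is held out automatically.
    """
    if val_cases is None and len(cases) >= 2:
        n_val = max(1, len(cases) // 4)
        cases, val_cases = cases[:-n_val], cases[-n_val:]
    fit_pairs = build_training_pairs(cases, stage, factor, sino_model=sino_model)
    n_fit = train_config.n_train_patches
    if not val_cases:  # single-phantom fallback: patch-level validation split
        n_fit += train_config.n_val_patches
    patchset = extract_patches(
        fit_pairs,
        net_config.patch_size,
        n_fit,
        sampling_weights=sampling_weights,
        seed=train_config.seed,
    )
    val_patchset = None
    if val_cases:
        val_pairs = build_training_pairs(val_cases, stage, factor, sino_model=sino_model)
        val_patchset = extract_patches(
            val_pairs,
            net_config.patch_size,
            train_config.n_val_patches,
            sampling_weights=sampling_weights,
            seed=train_config.seed + 1,
        )
    in_channels = 6 if stage == "sino" else 1
    if net_config.kind == "modified_unet":
        model = build_modified_unet(net_config, seed=train_config.seed, in_channels=in_channels)
    else:
        model = build_modified_resunet(
            net_config, seed=train_config.seed, in_channels=in_channels
        )
    val_fn = None
    val_every = 1
    if stage == "sino":
        model.value_channels = 2  # primary and angular fills share the scaling
        if val_cases:
            # early-stop on the actual task error — full-sinogram completion
            # RMSE on the held-out phantoms — rather than on patch loss, whose
            # region weighting differs from the task's
            from .metrics import rmse as _rmse

            val_inputs = [completion_input(c, factor) for c in val_cases]

            def val_fn():
                errs = []
                for (lin, invalid), case in zip(val_inputs, val_cases):
                    syn = unet_synthesize(
                        lin,
                        model,
                        invalid_mask=invalid,
                        trace_mask=case.metal_trace.support,
                        stride=net_config.patch_size // 2,
                    )
                    errs.append(_rmse(syn.values, case.dense_sinogram.values))
                return float(np.mean(errs))

            val_every = 3
    state = train_model(
        model, patchset, train_config, val_patchset=val_patchset,
        val_fn=val_fn, val_every=val_every,
    )
    return model, state, patchset


def simulate_and_train(
    geometry: ScanGeometry,
    path,
    seed: int,
    n_train_phantoms: int = 32,
    n_test_phantoms: int = 2,
    sino_epochs: int = 24,
    image_epochs: int = 12,
) -> dict:
    """The canonical desk-scale experiment: simulate a paired dataset and
    train both network stages on it.

    Training wires are stratified over the (radius, eccentricity) grid for
    coverage; the held-out test phantoms use the random wire sampler (the
    deployment distribution).  A quarter of the training phantoms (spread
    across the strata) are held out for validation-based early stopping.
    Runs in roughly a quarter of an hour on one CPU.  Returns the trained
    models, the dataset cases and the training states.
    """
    from .simulate import (
        generate_dataset,
        random_phantom_spec,
        random_wire_spec,
        stratified_wire_sampler,
    )

    n_cases = n_train_phantoms + n_test_phantoms
    strat = stratified_wire_sampler(n_train_phantoms, geometry)
    counter = {"i": 0}

    def wire_sampler(rng, geom):
        i = counter["i"]
        counter["i"] += 1
        if i < n_train_phantoms:
            return strat(rng, geom)
        return random_wire_spec(rng, geom)

    generate_dataset(
        n_cases,
        random_phantom_spec,
        geometry,
        path,
        seed=seed,
        wire_sampler=wire_sampler,
        decimation_factor=4,
        n_train=n_train_phantoms,
    )
    _, factor, cases = load_dataset(path)
    pool = [c for c in cases if c.group == "train"]
    test_cases = [c for c in cases if c.group == "test"]
    val_idx = set(range(3, n_train_phantoms, max(4, n_train_phantoms // 4)))
    if not val_idx:
        val_idx = {len(pool) - 1}
    fit_cases = [c for i, c in enumerate(pool) if i not in val_idx]
    val_cases = [c for i, c in enumerate(pool) if i in val_idx]

    sino_config = NetConfig(kind="modified_unet", depth=2, base_channels=8, patch_size=24)
    sino_train = TrainConfig(
        n_train_patches=2400, n_val_patches=300, epochs=sino_epochs,
        learning_rate=1e-3, batch_size=32, seed=seed % 2**31,
    )
    sino_model, sino_state, _ = train_stage(
        fit_cases, "sino", factor, sino_config, sino_train,
        sampling_weights="mixed", val_cases=val_cases,
    )
    image_config = NetConfig(kind="modified_resunet", depth=2, base_channels=8, patch_size=24)
    image_train = TrainConfig(
        n_train_patches=1200, n_val_patches=200, epochs=image_epochs,
        learning_rate=1e-3, batch_size=32, seed=(seed + 1) % 2**31,
    )
    image_model, image_state, _ = train_stage(
        fit_cases[:12], "image", factor, image_config, image_train,
        sino_model=sino_model, val_cases=val_cases[:2],
    )
    return {
        "geometry": geometry,
        "factor": factor,
        "fit_cases": fit_cases,
        "val_cases": val_cases,
        "test_cases": test_cases,
        "sino_model": sino_model,
        "sino_state": sino_state,
        "image_model": image_model,
        "image_state": image_state,
    }
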