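"""End-to-end orchestration: simulate → train → segment → split → mechanics.

Each stage writes its artifacts to disk (TIFF/CSV/JSON) so stages are
independently inspectable and resumable; :func:`run_pipeline` chains them
and writes a summary JSON with the Dice statistics, the per-chamber
mechanics, and an echo of the configuration. All randomness is seeded from
the config, so two runs with the same config produce identical summaries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import chamber_split, mechanics, phantom, stacks_io, unet
from .containers import CineSequence, Mask3D

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "keep_largest_component", "segment_cine"]


@dataclass
class RunConfig:
    """Structured configuration for one full pipeline run."""

    out_dir: str = "cardiomorph_run"
    dpf: int = 4
    pitch: float = 4.0  # μm; 4 μm is the fast profile, 2 μm the full one
    frames: int = 20
    sim_seed: int = 0
    # training corpus (randomized 2D slices from the phantom)
    n_slices: int = 200
    slice_size: int = 128
    slice_seed: int = 0
    # reduced architecture by default; set depth=4, base_features=64,
    # input_size=512 for the full-scale network
    input_size: int = 128
    depth: int = 3
    base_features: int = 8
    epochs: int = 40
    batch_size: int = 8
    learning_rate: float = 1e-3
    train_fraction: float = 0.8
    train_seed: int = 0
    # chamber split
    se_radius: int = 1
    max_iterations: int = 50
    identity_rule: str = "larger-is-ventricle"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def keep_largest_component(mask: Mask3D) -> Mask3D:
    """Drop all but the largest 26-connected component (noise specks)."""
    labeled, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return Mask3D(labeled == keep, mask.spacing)


def segment_cine(
    model: unet.UNet, images: CineSequence, tau: float = 0.5, clean: bool = True
) -> CineSequence:
    """Apply the U-net slice-by-slice to every frame of a cine."""
    masks = []
    for vol in images:
        prob = unet.predict_padded(model, vol.data)
        m = Mask3D(unet.threshold(prob, tau), vol.spacing)
        if clean:
            m = keep_largest_component(m)
        masks.append(m)
    return CineSequence(masks, images.frame_interval, images.period)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage %-9s %.1f s", name, time.time() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate → train → segment → split → mechanics → evaluate.

    Writes all intermediate artifacts under ``config.out_dir`` and returns
    the summary dict (also saved as summary.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    @_stage("simulate")
    def simulate():
        params = phantom.preset(config.dpf, pitch=config.pitch, frames=config.frames)
        images, truths = phantom.make_cine(params, seed=config.sim_seed)
        stacks_io.write_cine(
            images, truths, out / "sim", extra_meta={"seed": config.sim_seed, "params": params.to_dict()}
        )
        return images, truths

    @_stage("train")
    def train_stage():
        seeds = np.random.SeedSequence(config.slice_seed).generate_state(config.n_slices)
        imgs, msks = phantom.training_slices(
            [int(s % 2**31) for s in seeds],
            size=config.slice_size,
            pitch=config.pitch,
            dpf=config.dpf,
        )
        idx_train, _ = unet.split_train_val(
            list(range(config.n_slices)), config.train_fraction, seed=config.train_seed
        )
        spec = unet.UNetSpec(
            input_size=config.input_size,
            depth=config.depth,
            base_features=config.base_features,
        )
        model = unet.build_unet(spec, seed=config.train_seed)
        tspec = unet.TrainSpec(
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            train_fraction=config.train_fraction,
            seed=config.train_seed,
        )
        model, history = unet.train(model, imgs[idx_train], msks[idx_train], tspec)
        unet.save_model(model, out / "model")
        (out / "model" / "train_spec.json").write_text(json.dumps(asdict(tspec)))
        return model, history

    @_stage("segment")
    def segment(model, images):
        pred = segment_cine(model, images)
        pred_dir = out / "pred"
        pred_dir.mkdir(exist_ok=True)
        stacks_io.write_meta(
            stacks_io.StackMeta(
                voxel_spacing=pred.spacing,
                frame_interval=pred.frame_interval,
                period=pred.period,
            ),
            pred_dir / "meta.json",
        )
        for k, m in enumerate(pred):
            stacks_io.write_mask(m, pred_dir / f"mask_{k:03d}.tif")
        return pred

    @_stage("split")
    def split(pred):
        cfg = chamber_split.SplitConfig(config.se_radius, config.max_iterations)
        chambers, iters = chamber_split.split_cine(pred, cfg, rule=config.identity_rule)
        ch_dir = out / "chambers"
        ch_dir.mkdir(exist_ok=True)
        stacks_io.write_meta(
            stacks_io.StackMeta(
                voxel_spacing=chambers.spacing,
                frame_interval=chambers.frame_interval,
                period=chambers.period,
            ),
            ch_dir / "meta.json",
        )
        for k, m in enumerate(chambers):
            stacks_io.write_mask(m, ch_dir / f"chambers_{k:03d}.tif")
        return chambers, iters

    @_stage("mechanics")
    def mech(chambers):
        reports = [
            mechanics.chamber_mechanics(chambers, label, dpf=config.dpf)
            for label in (1, 2)
        ]
        stacks_io.write_report(reports, out / "report.csv")
        return reports

    @_stage("evaluate")
    def evaluate(pred, truths):
        table = mechanics.dice_table(pred, truths)
        table.to_csv(out / "dice.csv", index=False, float_format="%.6g")
        frame_dice = table[table.scope == "frame"].dice
        return {"mean": float(frame_dice.mean()), "sd": float(frame_dice.std(ddof=0))}

    images, truths = simulate()
    model, history = train_stage()
    pred = segment(model, images)
    chambers, iters = split(pred)
    reports = mech(chambers)
    dice_stats = evaluate(pred, truths)

    summary = {
        "dice": dice_stats,
        "mechanics": [asdict(r) for r in reports],
        "split_iterations": iters,
        "final_train_loss": history[-1] if history else None,
        "config": asdict(config),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
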