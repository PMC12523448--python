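"""End-to-end orchestration: phantom -> train -> predict -> evaluate ->
mesh -> measure -> slice, with seeded reproducibility and a hashed
artifact manifest.

Every stage derives its seed deterministically from the global seed, so
two runs of the same configuration produce byte-identical artifacts and
manifest hashes.  A stage failure aborts downstream stages and the
partial manifest is still written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .anatomy import SUBSTRUCTURES
from .phantom import PhantomSpec, generate_phantom, save_nifti, split_cases
from .segmentation import (CascadeModel, TrainConfig, predict_cascade,
                           save_checkpoint, train_cascade)

log = logging.getLogger("cardiofab.pipeline")

ALL_STAGES = ("phantom", "split", "train", "predict", "evaluate",
              "mesh", "measure", "slice")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-loadable).

    ``stages`` selects which steps run, in dependency order; parameter
    blocks mirror the per-module dataclasses.  ``seed`` feeds every
    stage-local seed.
    """

    output_dir: str = "cardiofab_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    log_level: str = "INFO"
    # phantom block
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    n_cases: int = 12
    split_ratios: tuple[float, float, float] = (6, 2, 2)
    phantom: dict = field(default_factory=dict)
    # train block (TrainConfig fields)
    train: dict = field(default_factory=dict)
    # mesh/measure block
    smoothing_iters: int = 10
    measure_repeats: int = 5
    measure_jitter_sd: float = 0.1
    print_noise_sd: float = 0.2
    # slice block (SliceParams fields)
    slice: dict = field(default_factory=dict)
    slice_structures: tuple[str, ...] = ("LV",)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for tup in ("stages", "grid_shape", "split_ratios", "slice_structures"):
            setattr(cfg, tup, tuple(getattr(cfg, tup)))
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the artifact manifest.

    The manifest maps each produced file (relative to the output
    directory) to its SHA-256 content hash and records per-stage status.
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("cardiofab")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {"config": dataclasses.asdict(config), "stages": {},
                      "artifacts": {}}

    def record(path):
        rel = os.path.relpath(path, out)
        manifest["artifacts"][rel] = _sha256(path)

    state: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            log.info("stage %s: start", stage)
            try:
                _STAGES[stage](config, state, out, record)
            except Exception as exc:  # abort downstream, keep partial manifest
                log.error("stage %s failed: %s", stage, exc)
                manifest["stages"][stage] = f"failed: {exc}"
                break
            manifest["stages"][stage] = "ok"
            log.info("stage %s: done", stage)
    finally:
        mpath = os.path.join(out, "manifest.json")
        with open(mpath, "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True)
        root.removeHandler(handler)
        handler.close()
    return manifest


def _stage_phantom(cfg, state, out, record):
    pdir = os.path.join(out, "phantom")
    os.makedirs(pdir, exist_ok=True)
    spec = PhantomSpec.desk(tuple(cfg.grid_shape), **cfg.phantom)
    cases = []
    for i in range(cfg.n_cases):
        vol = generate_phantom(spec.with_seed(cfg.seed * 1000 + i))
        vol.case_id = f"case_{i:03d}"
        for p in save_nifti(vol, pdir, vol.case_id):
            record(p)
        cases.append(vol)
    state["cases"] = cases


def _stage_split(cfg, state, out, record):
    cases = state["cases"]
    ids = [c.case_id for c in cases]
    tr, va, te = split_cases(ids, cfg.split_ratios, seed=cfg.seed)
    path = os.path.join(out, "split.json")
    with open(path, "w") as f:
        json.dump({"train": tr, "val": va, "test": te}, f, indent=2)
    record(path)
    by_id = {c.case_id: c for c in cases}
    state["train"] = [by_id[i] for i in tr]
    state["val"] = [by_id[i] for i in va]
    state["test"] = [by_id[i] for i in te]


def _stage_train(cfg, state, out, record):
    tc = TrainConfig(seed=cfg.seed, **cfg.train)
    model = CascadeModel.create(seed=cfg.seed)
    history = train_cascade(model, state["train"], tc)
    ckpt = os.path.join(out, "cascade.npz")
    save_checkpoint(model, ckpt)
    record(ckpt)
    hpath = os.path.join(out, "loss_history.json")
    with open(hpath, "w") as f:
        json.dump(history, f, indent=2)
    record(hpath)
    state["model"] = model


def _stage_predict(cfg, state, out, record):
    pdir = os.path.join(out, "predictions")
    os.makedirs(pdir, exist_ok=True)
    from .phantom import LabeledVolume, save_nifti as _save

    preds = []
    for c in state["test"]:
        pr = predict_cascade(state["model"], c.intensity)
        vol = LabeledVolume(intensity=c.intensity, labels=pr.labels,
                            spacing=c.spacing, case_id=c.case_id + "_pred")
        _, lab = _save(vol, pdir, vol.case_id)
        record(lab)
        preds.append(pr)
    state["predictions"] = preds


def _stage_evaluate(cfg, state, out, record):
    from .evaluation import evaluate_cases

    rep = evaluate_cases(state["predictions"], state["test"],
                         [c.case_id for c in state["test"]])
    path = os.path.join(out, "dice.csv")
    rep.to_frame().to_csv(path, index=False)
    record(path)
    state["dice_report"] = rep


def _stage_mesh(cfg, state, out, record):
    from .meshing import extract_mesh, write_stl

    mdir = os.path.join(out, "meshes")
    os.makedirs(mdir, exist_ok=True)
    case = state["test"][0] if state.get("test") else state["cases"][0]
    meshes = {}
    for s in SUBSTRUCTURES:
        mesh = extract_mesh(case, s.abbrev, smoothing_iters=cfg.smoothing_iters)
        path = os.path.join(mdir, f"{s.abbrev}.stl")
        write_stl(mesh, path, "binary")
        record(path)
        meshes[s.abbrev] = mesh
    state["meshes"] = meshes


def _stage_measure(cfg, state, out, record):
    from .measurement import fidelity_report, simulate_print, tabulate

    pre = state["meshes"]
    post = {k: simulate_print(m, cfg.print_noise_sd, seed=cfg.seed + i)
            for i, (k, m) in enumerate(sorted(pre.items()))}
    rep = fidelity_report(pre, post, repeats=cfg.measure_repeats,
                          jitter_sd=cfg.measure_jitter_sd, seed=cfg.seed)
    df, text = tabulate(rep)
    path = os.path.join(out, "fidelity.csv")
    df.to_csv(path, index=False)
    record(path)
    log.info("fidelity table:\n%s", text)
    state["fidelity"] = rep


def _stage_slice(cfg, state, out, record):
    from .slicer import SliceParams, concentric_infill, emit_gcode, slice_mesh

    gdir = os.path.join(out, "gcode")
    os.makedirs(gdir, exist_ok=True)
    params = SliceParams(**cfg.slice)
    for abbr in cfg.slice_structures:
        mesh = state["meshes"][abbr]
        layers = slice_mesh(mesh, params)
        for ly in layers:
            concentric_infill(ly, params)
        prog = emit_gcode(layers, params, name=abbr)
        gpath = os.path.join(gdir, f"{abbr}.gcode")
        with open(gpath, "w") as f:
            f.write(prog.text)
        record(gpath)
        tpath = os.path.join(gdir, f"{abbr}_totals.json")
        with open(tpath, "w") as f:
            json.dump({"path_length_mm": prog.path_length_mm,
                       "track_volume_mm3": prog.track_volume_mm3,
                       "ink_volume_mm3": prog.ink_volume_mm3,
                       "construct_ink_ratio": prog.construct_ink_ratio,
                       "n_layers": prog.n_layers}, f, indent=2)
        record(tpath)


_STAGES = {
    "phantom": _stage_phantom,
    "split": _stage_split,
    "train": _stage_train,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
    "mesh": _stage_mesh,
    "measure": _stage_measure,
    "slice": _stage_slice,
}


def import_dicom(directory) -> "LabeledVolume":
    """Read one DICOM series into a LabeledVolume (intensity only).

    Slices are sorted by their position along the slice normal
    (falling back to InstanceNumber), intensities are rescaled by the
    stored slope/intercept, and the voxel spacing is taken from the
    PixelSpacing tag plus the inter-slice distance.
    """
    import pydicom

    from .phantom import LabeledVolume

    files = sorted(os.path.join(directory, f) for f in os.listdir(directory)
                   if not f.startswith("."))
    if not files:
        raise ValueError(f"no files in {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    uids = {getattr(s, "SeriesInstanceUID", None) for s in slices}
    if len(uids) != 1:
        raise ValueError(f"directory mixes {len(uids)} DICOM series")
    for s in slices:
        if not getattr(s, "PixelSpacing", None):
            raise ValueError("missing PixelSpacing tag")

    def zpos(s):
        ipp = getattr(s, "ImagePositionPatient", None)
        return float(ipp[2]) if ipp else float(getattr(s, "InstanceNumber", 0))

    slices.sort(key=zpos)
    arrs = []
    for s in slices:
        a = s.pixel_array.astype(np.float32)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        inter = float(getattr(s, "RescaleIntercept", 0.0))
        arrs.append(a * slope + inter)
    vol = np.stack(arrs)
    py, px = (float(v) for v in slices[0].PixelSpacing)
    if len(slices) > 1:
        dz = abs(zpos(slices[1]) - zpos(slices[0]))
        if dz == 0:
            dz = float(getattr(slices[0], "SliceThickness", 1.0))
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    return LabeledVolume(intensity=vol,
                         labels=np.zeros(vol.shape, dtype=np.uint8),
                         spacing=(dz, py, px),
                         case_id=os.path.basename(str(directory)))
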