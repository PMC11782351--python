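"""End-to-end pipeline experiments: the figure-analog studies on synthetic data.

Each experiment reproduces, at desk scale, one of the validation analyses of
the virtual-staining workflow:

* ``table1_analog`` — structure specificity of virtual staining, as a TOS
  cross-matrix between predicted and true channels on held-out scenes;
* ``fig34_analog`` — morphometric agreement (area, circularity, solidity R^2)
  between ground-truth masks and the virtual-stain -> watershed route;
* ``fig6_analog`` — chloroplast speed recovery from tracked centroids vs the
  generator's ground-truth speeds;
* ``fig7_analog`` — living/dead classification accuracy from bright-field vs
  virtually stained crops, over several random-forest seeds.

``run_experiment`` writes a deterministic directory with the resolved config,
package version, and a JSON summary; the pipeline functions are importable on
their own for tests and scripting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import mannwhitneyu

from . import __version__
from .coloc import TOSConfig, tos_batch
from .imgen import SceneSpec, SpeedModel, generate_scene, generate_timelapse, \
    generate_viability_set
from .io import RunConfig
from .morph import WatershedConfig, agreement, marker_watershed, measure_cells
from .motion import LinkConfig, extract_centroids, link_tracks, speed_agreement
from .staining import ModelConfig, build_model, predict, train
from .viability import GLCMConfig, evaluate, texture_features

logger = logging.getLogger("vstain")

EXPERIMENTS = ("table1_analog", "fig34_analog", "fig6_analog", "fig7_analog")

# study conditions for the desk-scale analogs
MEMBRANE_MODEL_CONFIG = ModelConfig(depth=2, base_channels=8, attention_reduction_r=4,
                                    patch_size_px=64, epochs=10, batch_size=8,
                                    learning_rate=2e-3, seed=7)
VIABILITY_MODEL_CONFIG = dataclasses.replace(MEMBRANE_MODEL_CONFIG, epochs=16, seed=11)


def membrane_training_scene(seed: int) -> "ScenePair":
    """64x64 pavement scene used as one membrane training pair."""
    return generate_scene(SceneSpec(width_px=64, height_px=64, n_cells=4,
                                    shape_model="pavement", seed=seed))


def nucleus_training_scene(seed: int) -> "ScenePair":
    """64x64 BY-2-style scene with nucleus / vacuole / membrane channels."""
    return generate_scene(SceneSpec(width_px=64, height_px=64, n_cells=2,
                                    shape_model="by2_file", seed=seed))


def train_channel_model(channel: str, n_train: int, seed: int,
                        config: ModelConfig = None, scene_fn=None):
    """Train a single-channel staining model on generated scenes."""
    cfg = config or dataclasses.replace(MEMBRANE_MODEL_CONFIG, seed=seed)
    if scene_fn is None:
        scene_fn = membrane_training_scene if channel == "membrane" else nucleus_training_scene
    pairs = []
    for i in range(n_train):
        sc = scene_fn(seed * 100_000 + i)
        pairs.append((sc.brightfield, sc.channels[channel]))
    model, history = train(build_model(cfg, channel), pairs)
    return model, history


def tos_cross_matrix(models: dict, test_scenes, percentile_t: float = 1.0) -> dict:
    """TOS of each model's prediction against each true channel (Table 1 analog)."""
    cfg = TOSConfig(percentile_t)
    out = {}
    for model_name, model in models.items():
        preds = [predict(model, sc.brightfield) for sc in test_scenes]
        for channel in models:
            pairs = [(p, sc.channels[channel]) for p, sc in zip(preds, test_scenes)]
            s = tos_batch(pairs, cfg)
            out[f"{model_name}_vs_{channel}"] = {"mean": s.mean, "sd": s.sd, "n": s.n}
    return out


def segment_virtual_stain(stain: np.ndarray, tolerance: float = 0.4,
                          presmooth_sigma: float = 1.0, zoom: int = 2) -> np.ndarray:
    """Watershed segmentation of a membrane stain at ``zoom``-fold resolution.

    Segmenting the upsampled image places watershed lines with sub-pixel
    precision; the returned label image is at the zoomed resolution (measure
    it with ``pixel_size / zoom``).
    """
    img = np.asarray(stain, dtype=float)
    if zoom > 1:
        img = ndi.zoom(img, zoom, order=1)
    cfg = WatershedConfig(tolerance=tolerance, presmooth_sigma=presmooth_sigma)
    return marker_watershed(img, cfg)


def match_cells(truth_labels: np.ndarray, seg_labels: np.ndarray, zoom: int = 1,
                min_iou: float = 0.5):
    """One-to-one (truth cell, segmented region) id pairs by maximum overlap.

    Border-touching truth cells are excluded; matches below ``min_iou`` are
    dropped; each segmented region is used at most once.
    """
    lab_up = np.repeat(np.repeat(truth_labels, zoom, 0), zoom, 1) if zoom > 1 else truth_labels
    border = set(np.unique(np.concatenate([
        truth_labels[0], truth_labels[-1], truth_labels[:, 0], truth_labels[:, -1]])))
    matches, used = [], set()
    for tid in np.unique(truth_labels[truth_labels > 0]):
        if tid in border:
            continue
        mask = lab_up == tid
        ids, counts = np.unique(seg_labels[mask], return_counts=True)
        sid = int(ids[np.argmax(counts)])
        if sid == 0 or sid in used:
            continue
        inter = int(counts.max())
        union = int(mask.sum() + (seg_labels == sid).sum() - inter)
        if inter / union < min_iou:
            continue
        used.add(sid)
        matches.append((int(tid), sid))
    return lab_up, matches


def morphometry_agreement(model, n_scenes: int = 20, seed: int = 30_000,
                          scene_px: int = 224, n_cells: int = 12,
                          max_lobe_amplitude: float = 8.0,
                          tolerance: float = 0.4, zoom: int = 2) -> dict:
    """Fig 3/4 analog: R^2 of watershed-route metrics against truth-mask metrics.

    Scenes sweep lobe amplitude from 0 to ``max_lobe_amplitude`` so the cell
    population spans convex to strongly lobed shapes, as in wild-type-vs-mutant
    comparisons.
    """
    pairs = []
    for i in range(n_scenes):
        amp = max_lobe_amplitude * i / max(n_scenes - 1, 1)
        sc = generate_scene(SceneSpec(width_px=scene_px, height_px=scene_px,
                                      n_cells=n_cells, shape_model="pavement",
                                      lobe_amplitude=amp, seed=seed + i))
        stain = predict(model, sc.brightfield)
        seg = segment_virtual_stain(stain, tolerance=tolerance, zoom=zoom)
        lab_up, matches = match_cells(sc.labels, seg, zoom=zoom)
        px = sc.spec.pixel_size_um
        truth_recs = {r.id: r for r in measure_cells(lab_up, px / zoom)}
        seg_recs = {r.id: r for r in measure_cells(seg, px / zoom)}
        pairs += [(truth_recs[t], seg_recs[s]) for t, s in matches
                  if t in truth_recs and s in seg_recs]
    out = {"n_cells_matched": len(pairs)}
    for metric in ("area_um2", "circularity", "solidity"):
        rep = agreement([p[0] for p in pairs], [p[1] for p in pairs], metric)
        out[f"r2_{metric}"] = rep.r2
    return out


def speed_recovery(n_objects: int = 30, n_frames: int = 10, seed: int = 40_000,
                   mean_um_s: float = 1.5, sd: float = 0.5,
                   scene_px: int = 384, stain_model=None) -> dict:
    """Fig 6 analog: track centroids and compare speeds with ground truth.

    Centroids come from the chloroplast stain channel (or from ``stain_model``
    predictions of the bright-field frames when a model is supplied), using the
    recording calibration of 0.28 um/px and 0.5 s between frames.
    """
    spec = SceneSpec(width_px=scene_px, height_px=scene_px, n_cells=n_objects,
                     shape_model="chloroplast_field", pixel_size_um=0.28, seed=seed)
    tl = generate_timelapse(spec, n_frames, SpeedModel(mean_um_s, sd, 0.8), dt_s=0.5)
    frames = []
    for f in tl.frames:
        if stain_model is not None:
            frames.append(np.clip(predict(stain_model, f.brightfield), 0, 1))
        else:
            frames.append(f.channels["chloroplast"])
    dets = [extract_centroids(fr) for fr in frames]
    cfg = LinkConfig(max_disp_px=15.0, dt_s=0.5, pixel_size_um=0.28)
    tracks = link_tracks(dets, cfg)
    rep = speed_agreement(tl, tracks)
    return {"r2_speed": rep.r2, "n_speed_pairs": rep.n, "n_tracks": len(tracks),
            "tracks": tracks, "truth": tl}


def viability_comparison(n_train_per_class: int = 900, n_test_per_class: int = 300,
                         seeds=range(10), seed: int = 50_000,
                         stain_config: ModelConfig = None,
                         n_stain_pairs: int = 300, n_trees: int = 500) -> dict:
    """Fig 7 analog: random-forest accuracy from bright-field vs virtual stain.

    A staining model is trained on its own crops, then both channels of a
    disjoint train/test split are featurized (13 Haralick statistics, 1-99
    percentile quantization) and classified; the comparison is over the given
    random-forest seeds on the fixed split.
    """
    cfg = stain_config or VIABILITY_MODEL_CONFIG
    stain_crops = generate_viability_set(n_stain_pairs // 2, seed=seed + 1)
    stain_pairs = [(sc.brightfield, sc.channels["membrane"]) for sc, _ in stain_crops]
    model, _ = train(build_model(cfg, "membrane"), stain_pairs)

    train_crops = generate_viability_set(n_train_per_class, seed=seed + 2)
    test_crops = generate_viability_set(n_test_per_class, seed=seed + 3)
    gcfg = GLCMConfig(robust_quantize=True)

    def featurize(crops, virtual):
        feats, labels = [], []
        for sc, lab in crops:
            img = np.clip(predict(model, sc.brightfield), 0, 1) if virtual \
                else sc.brightfield
            feats.append(texture_features(img, gcfg))
            labels.append(lab)
        return np.array(feats), np.array(labels)

    out = {"model": model, "features": {}}
    for channel, virtual in (("brightfield", False), ("virtual", True)):
        Xtr, ytr = featurize(train_crops, virtual)
        Xte, yte = featurize(test_crops, virtual)
        out["features"][channel] = (Xtr, ytr, Xte, yte)
        rep = evaluate(Xtr, ytr, Xte, yte, seeds=seeds, n_trees=n_trees)
        out[channel] = rep
    u = mannwhitneyu(out["virtual"].accuracies, out["brightfield"].accuracies,
                     alternative="greater")
    out["p_value"] = float(u.pvalue)
    return out


# ---------------------------------------------------------------------------

def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


def run_experiment(config: RunConfig) -> Path:
    """Run one figure-analog experiment; returns the artifact directory."""
    if config.experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {config.experiment!r}; "
                         f"choose from {EXPERIMENTS}")
    opts = dict(config.options)
    out_dir = Path(config.out_dir) / f"{config.experiment}_seed{config.seed}"
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {"experiment": config.experiment, "seed": config.seed,
               "version": __version__}

    if config.experiment == "table1_analog":
        n_train = opts.get("n_train", 150)
        n_test = opts.get("n_test", 10)
        epochs = opts.get("epochs", 10)
        models = {}
        for channel, scene_fn in (("membrane", membrane_training_scene),
                                  ("nucleus", nucleus_training_scene)):
            mcfg = dataclasses.replace(MEMBRANE_MODEL_CONFIG, epochs=epochs,
                                       seed=config.child_seed(channel))
            logger.info("training %s model (%d pairs, %d epochs)", channel, n_train, epochs)
            models[channel], _ = train_channel_model(
                channel, n_train, seed=config.child_seed(channel),
                config=mcfg, scene_fn=scene_fn)
        test_scenes = [nucleus_training_scene(config.child_seed("test") + i)
                       for i in range(n_test)]
        summary["tos_matrix"] = tos_cross_matrix(models, test_scenes)

    elif config.experiment == "fig34_analog":
        n_train = opts.get("n_train", 200)
        model, _ = train_channel_model("membrane", n_train,
                                       seed=config.child_seed("membrane"))
        res = morphometry_agreement(model, n_scenes=opts.get("n_scenes", 20),
                                    seed=config.child_seed("scenes"))
        summary.update(res)
        summary["pass_r2_ge_0.95"] = all(
            res[f"r2_{m}"] >= 0.95 for m in ("area_um2", "circularity", "solidity"))

    elif config.experiment == "fig6_analog":
        res = speed_recovery(n_objects=opts.get("n_objects", 30),
                             n_frames=opts.get("n_frames", 10),
                             seed=config.child_seed("timelapse"))
        tracks, truth = res.pop("tracks"), res.pop("truth")
        rows = ["track_id,frame,x_px,y_px,speed_um_s"]
        for t in tracks:
            for k, (fi, x, y) in enumerate(t.points):
                sp = t.speeds_um_s[k - 1] if k > 0 else ""
                rows.append(f"{t.id},{fi},{x:.3f},{y:.3f},{sp}")
        (out_dir / "tracks.csv").write_text("\n".join(rows) + "\n")
        summary.update(res)
        summary["pass_r2_ge_0.95"] = res["r2_speed"] >= 0.95

    elif config.experiment == "fig7_analog":
        res = viability_comparison(
            n_train_per_class=opts.get("n_train_per_class", 900),
            n_test_per_class=opts.get("n_test_per_class", 300),
            seeds=range(opts.get("n_seeds", 10)),
            seed=config.child_seed("viability"),
            n_stain_pairs=opts.get("n_stain_pairs", 300),
            n_trees=opts.get("n_trees", 500))
        res.pop("model")
        res.pop("features")
        for channel in ("brightfield", "virtual"):
            rep = res[channel]
            summary[channel] = {
                "accuracies": list(rep.accuracies),
                "mean": rep.mean_accuracy, "sd": rep.sd_accuracy,
                "confusion_first_seed": rep.confusion.tolist(),
                "class_order": list(rep.class_order)}
        summary["p_value_virtual_gt_brightfield"] = res["p_value"]

    config.save(out_dir / "config.json")
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default))
    return out_dir
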