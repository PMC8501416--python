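"""End-to-end workflow: simulate, restore, aggregate, classify, report.

The functions here chain the stage modules into the full analysis: raw
mosaic+comb frames are restored into 9-band cubes, masked, white-referenced,
binned into classification cubes, summarized into image and patient spectra
with variance tables, then split at the cube level and pushed through the
seven-classifier comparison with all four accuracy surfaces.  Each function
exists both as an in-memory operation and (via cli.py) as a disk-based
command.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as msio
from .classify import METHODS, SplitSpec, split_dataset, train_classifier
from .evaluate import (
    confusion_and_metrics,
    false_rgb,
    majority_accuracy,
    map_from_predictions,
    mode_noise_filter,
    per_image_accuracy,
    per_pixel_accuracy,
)
from .raw import MASK_VALID, MosaicLayout, RawFrame, detect_fiber_cores, restore_frame
from .spectral import (
    Spectrum,
    bin_spatial,
    compute_white_reference,
    mask_low_signal,
    apply_white_reference,
    max_normalize_cube,
    mean_image_spectrum,
    patient_spectrum,
)
from .synthetic import (
    CLASS_NAMES,
    SimulatedDataset,
    generate_class_spectra,
    make_chart_model,
    simulate_color_chart_dataset,
    simulate_procedure_dataset,
)
from .variance import group_sigma, within_patient_sigma


def default_config() -> dict:
    """Resolved default run configuration (thresholds, binning, splits)."""
    return {
        "mode": "tissue",
        "seed": 0,
        "frame_shape": [1024, 1280],
        "n_cores": 10000,
        "n_white_frames": 10,
        "dark_level": 8.0,
        "white_level": 220.0,
        "illumination_falloff": 0.35,
        "separation": 0.25,
        "sigma_patient": 0.04,
        "sigma_image": 0.03,
        "sigma_pixel": 0.10,
        "n_patients": 15,
        "regions_per_patient": 2,
        "cubes_per_region": 24,
        "frames_per_patch": 24,
        "saturation_threshold": 250,
        "low_signal_threshold": 50,
        "block": 32,
        "roi_radius_frac": 0.5,
        "k": 3,
        "pca_var_target": 0.99,
        "train_fraction": 0.8,
        "methods": list(METHODS),
    }


def build_dataset(config: dict) -> SimulatedDataset:
    """Simulate a dataset (tissue or color-chart mode) from a config."""
    cfg = {**default_config(), **config}
    shape = tuple(cfg["frame_shape"])
    common = dict(
        frame_shape=shape,
        n_cores=cfg["n_cores"],
        n_white_frames=cfg["n_white_frames"],
        dark_level=cfg["dark_level"],
        white_level=cfg["white_level"],
        illumination_falloff=cfg["illumination_falloff"],
    )
    if cfg["mode"] == "chart":
        chart = make_chart_model(seed=cfg["seed"], frames_per_patch=cfg["frames_per_patch"])
        return simulate_color_chart_dataset(chart, **common)
    model = generate_class_spectra(
        cfg["seed"],
        cfg["separation"],
        sigma_patient=cfg["sigma_patient"],
        sigma_image=cfg["sigma_image"],
        sigma_pixel=cfg["sigma_pixel"],
        n_patients=cfg["n_patients"],
        regions_per_patient=cfg["regions_per_patient"],
        cubes_per_region=cfg["cubes_per_region"],
    )
    return simulate_procedure_dataset(model, **common)


@dataclass
class ProcessedDataset:
    """Binned, masked, max-normalized cubes plus aggregated spectra."""

    cubes: list  # binned normalized ImageCubes, labels carry class_index
    image_spectra: list  # one Spectrum (level=image) per cube
    patient_spectra: list  # Spectrum (level=patient) per (patient, class)
    class_names: tuple
    log: dict = field(default_factory=dict)


def process_dataset(
    dataset: SimulatedDataset,
    block: int = 32,
    roi_radius_frac: float = 0.5,
    low_signal_threshold: float = 50.0,
    class_names: tuple | None = None,
) -> ProcessedDataset:
    """Restore and aggregate every sample frame of a simulated dataset.

    Fiber cores are detected per patient from the mean dark-subtracted
    white frame; the white reference spectrum is the ROI average of the
    restored white cubes.  Sample frames then pass through the audited
    chain (saturation, dark, demosaic, decomb, low-signal, white reference,
    binning, max-normalization).
    """
    if class_names is None:
        labels = {t.label for t in dataset.truths}
        class_names = (
            CLASS_NAMES
            if labels <= set(CLASS_NAMES)
            else tuple(sorted(labels))
        )
    name_to_idx = {name: i for i, name in enumerate(class_names)}

    cubes = []
    image_spectra = []
    mask_log = {"saturated": 0, "low_signal": 0, "out_of_bundle": 0}
    by_patient: dict[int, list] = {}
    for frame, truth in zip(dataset.frames, dataset.truths):
        by_patient.setdefault(truth.patient, []).append((frame, truth))

    for patient, items in sorted(by_patient.items()):
        refs = dataset.references[patient]
        dark: RawFrame = refs["dark"]
        whites: list[RawFrame] = refs["white"]
        mean_white = np.mean(
            [w.pixels.astype(float) - dark.pixels.astype(float) for w in whites], axis=0
        )
        fibers = detect_fiber_cores(np.maximum(mean_white, 0.0))
        white_cubes = [
            restore_frame(w, dark, dataset.mosaic, fibers) for w in whites
        ]
        white_ref = compute_white_reference(white_cubes, roi_radius_frac)

        scale = float(block)
        center = (fibers.bundle_center[0] / scale, fibers.bundle_center[1] / scale)
        radius = fibers.bundle_radius / scale
        for frame, truth in items:
            labels = {
                "patient": truth.patient,
                "region": truth.region,
                "cube_id": truth.cube_id,
                "class": truth.label,
                "class_index": name_to_idx[truth.label],
            }
            cube = restore_frame(frame, dark, dataset.mosaic, fibers, labels=labels)
            cube = mask_low_signal(cube, threshold=low_signal_threshold)
            cube = apply_white_reference(cube, white_ref)
            binned = bin_spatial(cube, block=block)
            spec = mean_image_spectrum(
                binned,
                roi_radius_frac=roi_radius_frac,
                center=center,
                bundle_radius=radius,
            )
            spec.labels = dict(labels)
            norm = max_normalize_cube(binned)
            cubes.append(norm)
            image_spectra.append(spec)
            mask_log["saturated"] += int(np.sum(cube.mask == 1))
            mask_log["low_signal"] += int(np.sum(cube.mask == 2))
            mask_log["out_of_bundle"] += int(np.sum(cube.mask == 3))

    patient_specs = []
    groups: dict[tuple, list] = {}
    for s in image_spectra:
        groups.setdefault((s.labels["patient"], s.labels["class"]), []).append(s)
    for (_p, _c), specs in sorted(groups.items()):
        patient_specs.append(patient_spectrum(specs))
    return ProcessedDataset(
        cubes=cubes,
        image_spectra=image_spectra,
        patient_spectra=patient_specs,
        class_names=tuple(class_names),
        log=mask_log,
    )


def pixel_spectra_arrays(cubes: list, cube_ids=None):
    """Flatten the valid per-pixel spectra of selected cubes.

    Returns (X, y, cube_id) arrays; ``y`` is the cube's class index.
    """
    keep = None if cube_ids is None else set(int(i) for i in cube_ids)
    Xs, ys, cs = [], [], []
    for cube in cubes:
        cid = int(cube.labels["cube_id"])
        if keep is not None and cid not in keep:
            continue
        valid = cube.mask == MASK_VALID
        if not valid.any():
            continue
        Xs.append(cube.values[valid])
        n = int(valid.sum())
        ys.append(np.full(n, int(cube.labels["class_index"])))
        cs.append(np.full(n, cid))
    if not Xs:
        raise ValueError("no valid spectra in selection")
    return np.concatenate(Xs), np.concatenate(ys), np.concatenate(cs)


def variance_tables(proc: ProcessedDataset) -> list[dict]:
    """Per-class variance summary at the three aggregation levels, with the
    within-patient variant for image spectra."""
    rows = []
    for ci, cname in enumerate(proc.class_names):
        class_cubes = [c for c in proc.cubes if c.labels["class_index"] == ci]
        if class_cubes:
            X, _, _ = pixel_spectra_arrays(class_cubes)
            r = group_sigma(X, group=cname, level="pixel")
            rows.append({"group": cname, "level": "pixel", "n": r.n, "sigma": r.sigma})
        img = [s for s in proc.image_spectra if s.labels["class"] == cname]
        if img:
            r = group_sigma(np.stack([s.y for s in img]), group=cname, level="image")
            rows.append({"group": cname, "level": "image", "n": r.n, "sigma": r.sigma})
            per_patient = {}
            for s in img:
                per_patient.setdefault(s.labels["patient"], []).append(s.y)
            sigmas = [
                group_sigma(np.stack(v), level="image")
                for v in per_patient.values()
                if len(v) >= 1
            ]
            w = within_patient_sigma(sigmas)
            rows.append(
                {
                    "group": cname,
                    "level": "image_within_patient",
                    "n": w.n_patients,
                    "sigma": w.sigma_within,
                }
            )
        pat = [s for s in proc.patient_spectra if s.labels["class"] == cname]
        if len(pat) >= 1:
            r = group_sigma(np.stack([s.y for s in pat]), group=cname, level="patient")
            rows.append({"group": cname, "level": "patient", "n": r.n, "sigma": r.sigma})
    return rows


# ---------------------------------------------------------------------------
# evaluation


def evaluate_processed(
    proc: ProcessedDataset,
    methods: list | None = None,
    k: int = 3,
    pca_var_target: float = 0.99,
    seed: int = 0,
    two_way: bool = False,
    positive_class: str = "neoplasia",
) -> dict:
    """Train the requested methods on the 80% cube split and evaluate the
    four accuracy surfaces on the held-out cubes.

    In two-way mode the squamous cubes are dropped and every model is
    retrained from scratch on NDBE + neoplasia cubes only; the binary
    confusion metrics take neoplasia as the positive class.
    """
    methods = list(methods or METHODS)
    cubes = proc.cubes
    image_spectra = proc.image_spectra
    class_names = list(proc.class_names)
    if two_way:
        keep = [n for n in class_names if n != "squamous"]
        cubes = [c for c in cubes if c.labels["class"] in keep]
        image_spectra = [s for s in image_spectra if s.labels["class"] in keep]
    present = sorted({int(c.labels["class_index"]) for c in cubes})
    if len(present) < 2:
        raise ValueError("evaluation requires at least two classes")

    cube_ids = np.array([int(c.labels["cube_id"]) for c in cubes])
    split = split_dataset(cube_ids, SplitSpec(seed=seed))
    X_tr, y_tr, _ = pixel_spectra_arrays(cubes, split.train)
    X_te, y_te, c_te = pixel_spectra_arrays(cubes, split.test)
    X_val, y_val, _ = pixel_spectra_arrays(cubes, split.nn_val)
    X_nnte, y_nnte, c_nnte = pixel_spectra_arrays(cubes, split.nn_test)

    spec_by_cube = {int(s.labels["cube_id"]): s for s in image_spectra}

    def image_arrays(ids):
        X = np.stack([spec_by_cube[int(i)].y for i in ids if int(i) in spec_by_cube])
        y = np.array(
            [
                int(spec_by_cube[int(i)].labels["class_index"])
                for i in ids
                if int(i) in spec_by_cube
            ]
        )
        return X, y

    Xi_tr, yi_tr = image_arrays(split.train)
    Xi_te, yi_te = image_arrays(split.test)
    Xi_val, yi_val = image_arrays(split.nn_val)
    Xi_nnte, yi_nnte = image_arrays(split.nn_test)

    cube_class = {int(c.labels["cube_id"]): int(c.labels["class_index"]) for c in cubes}

    report = {
        "seed": seed,
        "two_way": two_way,
        "classes": [class_names[i] for i in present],
        "n_train_cubes": len(split.train),
        "n_test_cubes": len(split.test),
        "n_train_spectra": len(X_tr),
        "n_test_spectra": len(X_te),
        "methods": {},
    }
    pos_idx = class_names.index(positive_class) if positive_class in class_names else None

    for method in methods:
        kw = dict(k=k, pca_var_target=pca_var_target, seed=seed)
        if method == "nn":
            clf = train_classifier(method, X_tr, y_tr, X_val=X_val, y_val=y_val, **kw)
            Xe, ye, ce = X_nnte, y_nnte, c_nnte
            clf_img = train_classifier(
                method, Xi_tr, yi_tr, X_val=Xi_val, y_val=yi_val, **kw
            )
            Xie, yie = Xi_nnte, yi_nnte
        else:
            clf = train_classifier(method, X_tr, y_tr, **kw)
            Xe, ye, ce = X_te, y_te, c_te
            clf_img = train_classifier(method, Xi_tr, yi_tr, **kw)
            Xie, yie = Xi_te, yi_te

        pred = clf.predict(Xe)
        per_image_preds = []
        per_image_truths = []
        for cid in np.unique(ce):
            sel = ce == cid
            per_image_preds.append(pred[sel])
            per_image_truths.append(cube_class[int(cid)])
        acc_px = per_pixel_accuracy(pred, ye)
        acc_img_mean, acc_img_sd, excluded = per_image_accuracy(
            per_image_preds, per_image_truths
        )
        acc_maj, ties, _ = majority_accuracy(per_image_preds, per_image_truths)
        cm_px, bin_px = confusion_and_metrics(
            pred, ye, classes=present, positive_class=pos_idx
        )

        pred_img = clf_img.predict(Xie)
        acc_spec = per_pixel_accuracy(pred_img, yie)
        cm_img, bin_img = confusion_and_metrics(
            pred_img, yie, classes=present, positive_class=pos_idx
        )

        entry = {
            "per_pixel_acc": acc_px,
            "per_image_acc_mean": acc_img_mean,
            "per_image_acc_sd": acc_img_sd,
            "majority_per_image_acc": acc_maj,
            "majority_ties": ties,
            "images_excluded": excluded,
            "per_image_spectrum_acc": acc_spec,
            "confusion_pixel": cm_px.tolist(),
            "confusion_image_spectrum": cm_img.tolist(),
        }
        if method == "pca-knn":
            entry["n_components"] = clf.n_components
        if two_way and bin_px is not None:
            entry["binary_pixel"] = _binary_dict(bin_px)
            entry["binary_image_spectrum"] = _binary_dict(bin_img)
        # per-class majority accuracy
        per_class = {}
        for ci in present:
            sel = [i for i, t in enumerate(per_image_truths) if t == ci]
            if sel:
                acc_c, _, _ = majority_accuracy(
                    [per_image_preds[i] for i in sel], [ci] * len(sel)
                )
                per_class[class_names[ci]] = acc_c
        entry["majority_acc_per_class"] = per_class
        report["methods"][method] = entry
    return report


def _binary_dict(m):
    return {
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "ppv": m.ppv,
        "npv": m.npv,
        "tp": m.tp,
        "fp": m.fp,
        "tn": m.tn,
        "fn": m.fn,
    }


def render_maps(
    proc: ProcessedDataset,
    clf,
    cube_ids: list,
    outdir: Path | None = None,
    noise_filter: bool = True,
):
    """Classification maps (optionally mode-filtered) and false-RGB
    companions for the selected cubes; written as PNGs when ``outdir`` is
    given."""
    results = []
    by_id = {int(c.labels["cube_id"]): c for c in proc.cubes}
    for cid in cube_ids:
        cube = by_id[int(cid)]
        valid = cube.mask == MASK_VALID
        preds = clf.predict(cube.values[valid])
        cmap = map_from_predictions(cube, preds, provenance={"cube_id": cid})
        if noise_filter:
            cmap = mode_noise_filter(cmap)
        rgb = false_rgb(cube)
        results.append((cmap, rgb))
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            msio.write_rgb_png(
                outdir / f"map_{int(cid):04d}.png",
                msio.map_to_rgb(cmap.labels, n_classes=len(proc.class_names)),
            )
            msio.write_rgb_png(outdir / f"rgb_{int(cid):04d}.png", rgb)
    return results


# ---------------------------------------------------------------------------
# disk-based entry points


def run_simulate(config: dict, outdir) -> dict:
    """Simulate a dataset and write frames, references, truths, manifest."""
    cfg = {**default_config(), **config}
    outdir = Path(outdir)
    (outdir / "frames").mkdir(parents=True, exist_ok=True)
    dataset = build_dataset(cfg)
    rows = []
    for frame, truth in zip(dataset.frames, dataset.truths):
        name = f"sample_{truth.cube_id:05d}.png"
        msio.write_frame(outdir / "frames" / name, frame)
        rows.append(
            {
                "file": f"frames/{name}",
                "role": "sample",
                "patient": truth.patient,
                "region": truth.region,
                "cube_id": truth.cube_id,
                "class": truth.label,
            }
        )
    for patient, refs in dataset.references.items():
        name = f"dark_p{patient:03d}.png"
        msio.write_frame(outdir / "frames" / name, refs["dark"])
        rows.append(
            {
                "file": f"frames/{name}",
                "role": "dark",
                "patient": patient,
                "region": -1,
                "cube_id": -1,
                "class": "",
            }
        )
        for wi, wf in enumerate(refs["white"]):
            name = f"white_p{patient:03d}_{wi:02d}.png"
            msio.write_frame(outdir / "frames" / name, wf)
            rows.append(
                {
                    "file": f"frames/{name}",
                    "role": "white",
                    "patient": patient,
                    "region": -1,
                    "cube_id": wi,
                    "class": "",
                }
            )
    msio.write_manifest(outdir / "manifest.csv", rows)
    msio.save_config(outdir / "config.yaml", cfg)
    return {"n_frames": len(rows), "outdir": str(outdir)}


def load_dataset(indir) -> SimulatedDataset:
    """Re-read a simulated dataset written by run_simulate."""
    from .synthetic import SceneGroundTruth

    indir = Path(indir)
    df = msio.read_manifest(indir / "manifest.csv")
    cfg = msio.load_config(indir / "config.yaml")
    shape = tuple(cfg.get("frame_shape", [1024, 1280]))
    class_names = list(CLASS_NAMES) if cfg.get("mode", "tissue") == "tissue" else [
        f"patch_{i + 1:02d}" for i in range(24)
    ]
    frames, truths = [], []
    references: dict[int, dict] = {}
    for _, row in df.iterrows():
        meta = {"patient": int(row["patient"])}
        if row["role"] == "sample":
            cls = str(row["class"])
            frame = msio.read_frame(indir / row["file"], role="sample", meta=meta)
            frames.append(frame)
            truths.append(
                SceneGroundTruth(
                    class_grid=np.full(shape, class_names.index(cls), dtype=np.int8),
                    patient=int(row["patient"]),
                    region=int(row["region"]),
                    cube_id=int(row["cube_id"]),
                    label=cls,
                )
            )
        elif row["role"] == "dark":
            references.setdefault(int(row["patient"]), {"white": []})["dark"] = (
                msio.read_frame(indir / row["file"], role="dark", meta=meta)
            )
        else:
            references.setdefault(int(row["patient"]), {"white": []})["white"].append(
                msio.read_frame(indir / row["file"], role="white", meta=meta)
            )
    fibers = None  # re-detected from white frames during processing
    return SimulatedDataset(frames, truths, references, fibers, MosaicLayout())


def run_pipeline(config: dict, indir, outdir) -> ProcessedDataset:
    """Process a simulated dataset from disk: cubes, spectra and variance
    tables are written under ``outdir``."""
    cfg = {**default_config(), **config}
    indir, outdir = Path(indir), Path(outdir)
    if not (indir / "manifest.csv").exists():
        raise FileNotFoundError("manifest.csv not found; run simulate first")
    dataset = load_dataset(indir)
    for refs in dataset.references.values():
        if "dark" not in refs or not refs["white"]:
            raise ValueError("missing dark/white reference frames")
    proc = process_dataset(
        dataset,
        block=cfg["block"],
        roi_radius_frac=cfg["roi_radius_frac"],
        low_signal_threshold=cfg["low_signal_threshold"],
    )
    (outdir / "cubes").mkdir(parents=True, exist_ok=True)
    for cube in proc.cubes:
        msio.write_cube(outdir / "cubes" / f"cube_{cube.labels['cube_id']:05d}.tif", cube)
    msio.spectra_to_frame(proc.image_spectra + proc.patient_spectra).to_csv(
        outdir / "spectra.csv", index=False
    )
    import pandas as pd

    pd.DataFrame(variance_tables(proc)).to_csv(outdir / "variance.csv", index=False)
    msio.save_config(outdir / "config.yaml", cfg)
    return proc


def load_processed(indir) -> ProcessedDataset:
    """Re-read a processed dataset (cubes + spectra tables) from disk."""
    import pandas as pd

    indir = Path(indir)
    cubes = [msio.read_cube(p) for p in sorted((indir / "cubes").glob("*.tif"))]
    if not cubes:
        raise FileNotFoundError(f"no cubes found under {indir / 'cubes'}")
    df = pd.read_csv(indir / "spectra.csv")
    class_index = {
        c.labels["class"]: int(c.labels["class_index"]) for c in cubes
    }
    image_spectra = msio.frame_to_spectra(df[df["level"] == "image"])
    for s in image_spectra:
        s.labels["class_index"] = class_index[s.labels["class"]]
    patient_spectra = msio.frame_to_spectra(df[df["level"] == "patient"])
    names = sorted(class_index, key=class_index.get)
    return ProcessedDataset(
        cubes=cubes,
        image_spectra=image_spectra,
        patient_spectra=patient_spectra,
        class_names=tuple(names),
    )


def run_evaluate(config: dict, proc: ProcessedDataset, outdir) -> dict:
    """Evaluate the classifier comparison on a processed dataset and write
    the report (JSON + CSV summary) and example maps."""
    cfg = {**default_config(), **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = evaluate_processed(
        proc,
        methods=cfg["methods"],
        k=cfg["k"],
        pca_var_target=cfg["pca_var_target"],
        seed=cfg["seed"],
    )
    if cfg.get("two_way", False) and "neoplasia" in proc.class_names:
        report["two_way_report"] = evaluate_processed(
            proc,
            methods=cfg["methods"],
            k=cfg["k"],
            pca_var_target=cfg["pca_var_target"],
            seed=cfg["seed"],
            two_way=True,
        )
    msio.write_report(outdir / "report.json", report)
    import pandas as pd

    rows = []
    for method, entry in report["methods"].items():
        rows.append(
            {
                "method": method,
                "per_pixel_acc": entry["per_pixel_acc"],
                "per_image_acc_mean": entry["per_image_acc_mean"],
                "per_image_acc_sd": entry["per_image_acc_sd"],
                "majority_per_image_acc": entry["majority_per_image_acc"],
                "per_image_spectrum_acc": entry["per_image_spectrum_acc"],
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "report_summary.csv", index=False)

    # maps for a few held-out cubes with the best method
    cube_ids = np.array([int(c.labels["cube_id"]) for c in proc.cubes])
    split = split_dataset(cube_ids, SplitSpec(seed=cfg["seed"]))
    X_tr, y_tr, _ = pixel_spectra_arrays(proc.cubes, split.train)
    clf = train_classifier(
        "pca-knn", X_tr, y_tr, k=cfg["k"], pca_var_target=cfg["pca_var_target"]
    )
    render_maps(proc, clf, list(split.test[:3]), outdir=outdir / "maps")
    return report
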