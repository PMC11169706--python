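"""End-to-end orchestration: phantom-or-load → features → segmentation →
ROIs → ROC filter → PLS-DA MCCV → fold changes → annotation → report.

The pipeline is linear and fully seeded; a run writes its tables plus a
manifest of every parameter and seed, so a second run from the same
configuration reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discriminant as disc
from . import preprocess as pre
from . import segmentation as seg
from .io import MSImageDataset, read_dataset, read_samples_file
from .masses import annotation_report, load_lipid_table
from .phantom import default_config, generate_cohort
from .segmentation import ROIMask

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_ion_image"]

DEFAULT_ROC_MODE = {"GM": "strict", "WM": "strict", "CC": "strict", "HC": "loose", "OC": "loose"}


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    # input: either imzML files + samples file, or a phantom spec
    imzml_paths: list[str] = field(default_factory=list)
    samples_file: str | None = None
    phantom: dict | None = None  # kwargs: n_sham, n_injured, master_seed, n_decoys, ...

    # feature list
    mean_bin_ppm: float = 1.0
    initial_half_width_ppm: float = 5.0
    refined_half_width_ppm: float = 3.0
    min_intensity: float | None = None
    background_mz: list[float] = field(default_factory=list)
    background_tol_ppm: float = 5.0
    deisotope: bool = True

    # segmentation
    n_segments: int = 9
    denoise: str = "strong"
    seg_seed: int = 0

    # ROI rules: name -> {"type": "marker"|"labels"|"polygon"|"outer_cortex", ...}
    roi_rules: dict = field(default_factory=dict)
    roc_mode: dict = field(default_factory=lambda: dict(DEFAULT_ROC_MODE))

    # modeling
    k_grid: list[int] = field(default_factory=lambda: [2, 4, 8])
    latent_grid: list[int] = field(default_factory=lambda: [1, 2, 3])
    repeats: int = 100
    model_seed: int = 0

    # annotation
    lipid_table: str | None = None
    tolerance_da: float = 0.005

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    features: pre.FeatureList
    roi_masks: dict  # section_id -> {roi: ROIMask}
    tables: dict  # roi -> disc.SampleTable
    models: dict  # roi -> (k, L, disc.MCCVResult)
    fold_changes: dict  # roi -> pd.DataFrame
    report: pd.DataFrame
    annotations: pd.DataFrame
    manifest: dict


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


def _load_inputs(config: PipelineConfig) -> list[MSImageDataset]:
    if config.phantom is not None:
        kw = dict(config.phantom)
        cohort_kw = {
            k: kw.pop(k)
            for k in ("n_sham", "n_injured", "master_seed", "sections_per_animal")
            if k in kw
        }
        phantom_cfg = default_config(**kw)
        datasets, _ = generate_cohort(phantom_cfg, **cohort_kw)
        return datasets
    if not config.imzml_paths or not config.samples_file:
        raise PipelineError("input", "provide either a phantom spec or imzML paths + samples file")
    metas = {m.section_id: m for m in read_samples_file(config.samples_file)}
    datasets = []
    for p in config.imzml_paths:
        sid = Path(p).stem
        if sid not in metas:
            raise PipelineError("input", f"section {sid} missing from samples file")
        datasets.append(read_dataset(p, metadata=metas[sid]))
    return datasets


def _marker_index(features: pre.FeatureList, mz: float, stage: str) -> int:
    idx = int(np.argmin(np.abs(features.mz - mz)))
    if abs(features.mz[idx] - mz) > features.mz[idx] * features.ppm[idx] * 1e-6:
        raise PipelineError(stage, f"no feature within window of marker m/z {mz}")
    return idx


def _build_rois(
    config: PipelineConfig,
    dataset: MSImageDataset,
    seg_result: seg.SegmentationResult,
    pixel_table: np.ndarray,
    features: pre.FeatureList,
    tissue_mask: np.ndarray,
) -> dict:
    if not config.roi_rules:
        raise PipelineError("roi", "no ROI rules configured")
    gi = dataset.pixel_grid_index()
    border = seg.border_labels(seg_result, gi, dataset.shape)
    rois: dict[str, ROIMask] = {}
    for name, rule in config.roi_rules.items():
        if not rule:
            raise PipelineError("roi", f"empty rule for ROI {name!r}")
        kind = rule.get("type")
        try:
            if kind == "marker":
                j = _marker_index(features, float(rule["mz"]), "roi")
                rois[name] = seg.segments_to_roi(
                    seg_result, gi, dataset.shape, name,
                    marker_values=pixel_table[:, j],
                    threshold_frac=float(rule.get("threshold_frac", 0.5)),
                    top_n=rule.get("top_n"),
                    exclude=border,
                )
            elif kind == "labels":
                rois[name] = seg.segments_to_roi(
                    seg_result, gi, dataset.shape, name, labels=rule["labels"]
                )
            elif kind == "polygon":
                rois[name] = seg.manual_polygon_roi(
                    [tuple(v) for v in rule["vertices"]], dataset.shape, name
                )
            elif kind == "outer_cortex":
                rois[name] = seg.outer_cortex_selection(
                    seg_result, gi, dataset.shape, tissue_mask,
                    target_range=tuple(rule.get("target_range", (2500, 3500))),
                    name=name, exclude=border,
                )
            else:
                raise PipelineError("roi", f"ROI {name!r}: unknown rule type {kind!r}")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("roi", f"ROI {name!r}: {exc}") from exc
    return rois


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    fit_models: bool = True,
) -> PipelineResult:
    """Execute all stages; optionally write the report bundle to ``outdir``.

    ``fit_models=False`` stops after ROC filtering and fold changes (no
    MCCV model optimization), which is enough for recovery diagnostics.
    """
    datasets = _load_inputs(config)
    if not datasets:
        raise PipelineError("input", "no datasets")

    # --- normalize + cohort feature list
    norm = [pre.normalize_dataset(d) for d in datasets]
    mean = pre.mean_spectrum(norm, bin_ppm=config.mean_bin_ppm)
    features = pre.sliding_window_peaks(
        mean, config.initial_half_width_ppm, config.min_intensity
    )
    features = pre.refine_feature_list(features, mean, config.refined_half_width_ppm)
    if config.background_mz:
        features = pre.remove_background_features(
            features, config.background_mz, config.background_tol_ppm
        )
    if config.deisotope:
        totals = pre.extract_feature_table(
            MSImageDataset([mean], shape=(1, 1)), features
        )[0]
        features = pre.deisotope(features, totals)
    if len(features) == 0:
        raise PipelineError("features", "feature list is empty")

    # --- per-section pixel tables, segmentation, ROIs, ROI means
    roi_masks: dict[str, dict[str, ROIMask]] = {}
    roi_means: dict[str, dict[str, np.ndarray]] = {}
    groups, section_ids = [], []
    for d in norm:
        sid = d.metadata.section_id if d.metadata else f"section_{len(section_ids)}"
        section_ids.append(sid)
        groups.append(d.metadata.group if d.metadata else "sham")
        ptab = pre.extract_feature_table(d, features)
        # spatially denoised copy for segmentation only ("none" segments on
        # the raw per-pixel abundances)
        gi = d.pixel_grid_index()
        if config.denoise in (None, "none"):
            seg_tab = ptab
        else:
            seg_tab = np.empty_like(ptab)
            for j in range(ptab.shape[1]):
                img = np.full(d.shape, np.nan)
                img[gi[:, 0], gi[:, 1]] = ptab[:, j]
                img = pre.median_denoise(img, config.denoise)
                seg_tab[:, j] = img[gi[:, 0], gi[:, 1]]
        seg_result = seg.bisecting_kmeans(
            seg_tab, config.n_segments, seed=config.seg_seed
        )
        border = seg.border_labels(seg_result, gi, d.shape)
        tissue = np.zeros(d.shape, dtype=bool)
        inner = ~np.isin(seg_result.labels, sorted(border))
        tissue[gi[inner, 0], gi[inner, 1]] = True
        rois = _build_rois(config, d, seg_result, ptab, features, tissue)
        roi_masks[sid] = rois
        roi_means[sid] = {
            name: seg.roi_mean_abundance(ptab, mask, gi) for name, mask in rois.items()
        }

    # --- per-ROI section tables, ROC filter, model, fold changes
    groups = pd.Series(groups, index=section_ids)
    tables, models, fcs, report_rows = {}, {}, {}, []
    for roi in config.roi_rules:
        X = pd.DataFrame(
            {sid: roi_means[sid][roi] for sid in section_ids}, index=features.labels
        ).T
        table = disc.SampleTable(X, groups)
        tables[roi] = table
        aucs = [disc.feature_auc(X[c], groups) for c in X.columns]
        mode = config.roc_mode.get(roi, "loose")
        kept = disc.roc_filter(aucs, mode)
        if not kept:
            kept = disc.roc_filter(aucs, "loose")
        if not kept:  # nothing discriminant at all: rank by |AUC - 0.5|
            ranked = sorted(aucs, key=lambda a: -abs(a.auc - 0.5))
            kept = [a.feature for a in ranked[: max(config.k_grid)]]
        sub = table.subset_features(kept)
        if fit_models:
            k_grid = [k for k in config.k_grid if k <= len(kept)] or [len(kept)]
            n_latent_max = min(len(kept), len(section_ids) - 1)
            latent_grid = [L for L in config.latent_grid if L <= n_latent_max] or [1]
            k, L, res = disc.model_optimize(
                sub, k_grid, latent_grid, repeats=config.repeats, seed=config.model_seed
            )
            models[roi] = (k, L, res)
        auc_of = {a.feature: a.auc for a in aucs}
        fc = pd.DataFrame(
            {
                "feature": kept,
                "fold_change": [disc.fold_change(sub, f) for f in kept],
                "auc": [auc_of[f] for f in kept],
            }
        )
        fcs[roi] = fc
        row = {"roi": roi, "roc_mode": mode, "n_features_kept": len(kept)}
        if fit_models:
            row.update(
                k=k, n_latent=L, pooled_auc=res.pooled_auc,
                ci_low=res.ci_low, ci_high=res.ci_high,
            )
        report_rows.append(row)
    report = pd.DataFrame(report_rows)

    # --- annotation of every feature apex
    lipids = load_lipid_table(config.lipid_table)
    annotations = annotation_report(
        list(features.mz), lipids, tolerance_da=config.tolerance_da
    )
    annotations.insert(0, "label", features.labels)

    manifest = {
        "config": config.to_dict(),
        "sections": section_ids,
        "n_features": len(features),
        "seeds": {"segmentation": config.seg_seed, "model": config.model_seed,
                  "phantom_master": (config.phantom or {}).get("master_seed")},
    }
    result = PipelineResult(
        features=features, roi_masks=roi_masks, tables=tables, models=models,
        fold_changes=fcs, report=report, annotations=annotations, manifest=manifest,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.features.write(outdir / "features.tsv")
    result.report.to_csv(outdir / "model_report.tsv", sep="\t", index=False)
    result.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    for roi, (k, L, res) in result.models.items():
        res.importance.to_csv(outdir / f"importance_{roi}.tsv", sep="\t", index=False)
        result.fold_changes[roi].to_csv(outdir / f"fold_changes_{roi}.tsv", sep="\t", index=False)
        np.savetxt(outdir / f"repeat_aucs_{roi}.tsv", res.repeat_aucs, fmt="%.6f")
    for sid, rois in result.roi_masks.items():
        for name, mask in rois.items():
            mask.write_png(outdir / f"mask_{sid}_{name}.png")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


def render_ion_image(
    dataset: MSImageDataset,
    features: pre.FeatureList,
    mz: float,
    hotspot_quantile: float | None = 0.99,
    denoise: str | None = "weak",
    path: str | Path | None = None,
):
    """Normalized, clipped, denoised ion image for one feature.

    Returns the image array; with ``path`` set, also saves a figure with a
    colorbar and a ±ppm window caption.
    """
    j = _marker_index(features, mz, "render")
    norm = pre.normalize_dataset(dataset) if not dataset.normalized else dataset
    img = pre.feature_image(norm, features, j)
    if hotspot_quantile is not None:
        img = pre.hotspot_clip(img, hotspot_quantile)
    if denoise is not None:
        img = pre.median_denoise(img, denoise)
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(img, cmap="inferno", origin="upper")
        ax.set_title(
            f"m/z {features.mz[j]:.4f} ± {features.ppm[j]:.0f} ppm ({features.labels[j]})"
        )
        ax.axis("off")
        fig.colorbar(im, ax=ax, label="RMS-normalized abundance")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return img
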