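"""End-to-end orchestration of the two section pipelines and the ablation harness.

Transverse chain:  detect ROI -> paint/recover the blue box -> five-stage
enhancement -> snake from the box-initialized contour -> lumen mask.

Longitudinal chain:  detect ROI -> paint/recover the blue box -> automated
scanning-window mask generation -> Chan-Vese level-set evolution -> lumen
mask.

Ablation flags reproduce the study configurations: ``no_preprocess`` skips
enhancement (transverse), ``no_roi`` replaces the ROI with the whole image,
and ``no_padded_mask`` initializes Chan-Vese directly from the raw detection
box instead of the generated mask.  Chan-Vese divergence is surfaced as a
structured ``"failed"`` result rather than an exception - non-convergence is
an outcome the harness must be able to tabulate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chanvese as cv
from . import enhance as enh
from . import localization as loc
from . import longmask as lm
from . import metrics as met
from . import snake as snk
from .annotations import PixelBox
from .errors import CarotidSegError, NumericalInstabilityError

__all__ = ["PipelineConfig", "PipelineResult", "run_transverse",
           "run_longitudinal", "run_batch", "BatchReport"]


@dataclass(frozen=True)
class PipelineConfig:
    section: str = "transverse"  # "transverse" | "longitudinal"
    enhance: enh.EnhanceConfig = field(default_factory=enh.EnhanceConfig)
    snake: snk.SnakeParams = field(default_factory=snk.SnakeParams)
    maskgen: lm.MaskGenConfig = field(default_factory=lm.MaskGenConfig)
    chanvese: cv.ChanVeseParams = field(default_factory=cv.ChanVeseParams)
    pad_frac: float = 0.1
    box_thickness: int = 3
    no_preprocess: bool = False
    no_roi: bool = False
    no_padded_mask: bool = False

    def __post_init__(self):
        if self.section not in ("transverse", "longitudinal"):
            raise ValueError(f"unknown section {self.section!r}")


@dataclass
class PipelineResult:
    mask: np.ndarray
    status: str  # "ok" | "failed"
    scores: met.SegScores | None = None
    box: PixelBox | None = None
    diagnostics: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)


def _detect_box(img, truth_mask, detector, cfg) -> PixelBox:
    """Run the detector and round-trip its output through the blue overlay."""
    gray = enh.to_gray(img)
    if detector is None:
        if truth_mask is None:
            raise CarotidSegError("need a detector or a truth mask (oracle)")
        detector = loc.OracleDetector(truth_mask, pad_frac=cfg.pad_frac)
    box = detector(gray)
    overlay = loc.paint_box(gray, box, thickness=cfg.box_thickness)
    return loc.recover_blue_box(overlay)


def _full_image_box(shape, margin: int = 2) -> PixelBox:
    h, w = shape
    return PixelBox(margin, margin, w - 2 * margin, h - 2 * margin)


def run_transverse(
    img: np.ndarray,
    truth_mask: np.ndarray | None = None,
    cfg: PipelineConfig | None = None,
    detector: loc.Detector | None = None,
    keep_artifacts: bool = False,
) -> PipelineResult:
    """Transverse pipeline; scores against ``truth_mask`` when given."""
    if cfg is None:
        cfg = PipelineConfig(section="transverse")
    gray = enh.to_gray(img)
    diagnostics: dict = {}
    artifacts: dict = {}

    if cfg.no_roi:
        box = _full_image_box(gray.shape)
    else:
        box = _detect_box(img, truth_mask, detector, cfg)
    diagnostics["box"] = [box.left, box.top, box.width, box.height]

    if cfg.no_preprocess:
        work = gray
        diagnostics["enhanced"] = False
    else:
        work, report = enh.enhance_pipeline(gray, cfg.enhance)
        diagnostics["enhanced"] = True
        diagnostics["quality"] = report
        if keep_artifacts:
            artifacts["enhanced"] = work

    contour0 = snk.box_to_initial_contour(box, cfg.snake.n_points)
    h, w = gray.shape
    contour0[:, 0] = np.clip(contour0[:, 0], 0, w - 1)
    contour0[:, 1] = np.clip(contour0[:, 1], 0, h - 1)
    result = snk.evolve_snake(work, contour0, cfg.snake)
    mask = snk.contour_to_mask(result.contour, gray.shape)
    diagnostics["snake_iters"] = result.n_iters
    diagnostics["snake_converged"] = result.converged
    diagnostics["snake_energy"] = result.energies[-1]
    if keep_artifacts:
        artifacts["contour"] = result.contour
        artifacts["energies"] = result.energies

    scores = met.score_masks(mask, truth_mask) if truth_mask is not None else None
    return PipelineResult(mask=mask, status="ok", scores=scores, box=box,
                          diagnostics=diagnostics, artifacts=artifacts)


def run_longitudinal(
    img: np.ndarray,
    truth_mask: np.ndarray | None = None,
    cfg: PipelineConfig | None = None,
    detector: loc.Detector | None = None,
    keep_artifacts: bool = False,
) -> PipelineResult:
    """Longitudinal pipeline; Chan-Vese divergence yields status "failed"."""
    if cfg is None:
        cfg = PipelineConfig(section="longitudinal")
    gray = enh.to_gray(img)
    h, w = gray.shape
    diagnostics: dict = {}
    artifacts: dict = {}

    if cfg.no_roi:
        box = _full_image_box(gray.shape)
        init_mask = np.ones(gray.shape, dtype=bool)
        diagnostics["init"] = "whole-image"
    else:
        box = _detect_box(img, truth_mask, detector, cfg)
        if cfg.no_padded_mask:
            init_mask = box.to_mask(gray.shape)
            diagnostics["init"] = "roi-box"
        else:
            gen = lm.generate_longitudinal_mask(gray, box, cfg.maskgen)
            init_mask = gen.mask
            diagnostics["init"] = "generated-mask"
            diagnostics["maskgen"] = gen.diagnostics()
    diagnostics["box"] = [box.left, box.top, box.width, box.height]
    if keep_artifacts:
        artifacts["init_mask"] = init_mask

    try:
        result = cv.segment(gray, init_mask, cfg.chanvese)
    except NumericalInstabilityError as exc:
        diagnostics["error"] = str(exc)
        empty = np.zeros(gray.shape, dtype=bool)
        scores = met.score_masks(empty, truth_mask) if truth_mask is not None else None
        return PipelineResult(mask=empty, status="failed", scores=scores,
                              box=box, diagnostics=diagnostics, artifacts=artifacts)

    mask = result.mask
    diagnostics["cv_iters"] = result.n_iters
    diagnostics["cv_converged"] = result.converged
    diagnostics["cv_energy"] = result.energies[-1]
    diagnostics["c1"] = result.c1
    diagnostics["c2"] = result.c2
    if keep_artifacts:
        artifacts["levelset"] = result.levelset
        artifacts["energies"] = result.energies

    scores = met.score_masks(mask, truth_mask) if truth_mask is not None else None
    return PipelineResult(mask=mask, status="ok", scores=scores, box=box,
                          diagnostics=diagnostics, artifacts=artifacts)


def run_one(img, truth_mask=None, cfg: PipelineConfig | None = None,
            detector=None, **kw) -> PipelineResult:
    if cfg is None:
        cfg = PipelineConfig()
    if cfg.section == "transverse":
        return run_transverse(img, truth_mask, cfg, detector, **kw)
    return run_longitudinal(img, truth_mask, cfg, detector, **kw)


@dataclass
class BatchReport:
    per_image: pd.DataFrame
    summary: pd.DataFrame
    ttests: dict[str, met.PairedTestResult]


def run_batch(
    items,
    configs: dict[str, PipelineConfig] | PipelineConfig,
    detectors: dict | None = None,
) -> BatchReport:
    """Run one or more configurations over a batch of (image, mask) items.

    ``items`` is an iterable of dicts with keys ``id``, plus either in-memory
    ``image``/``mask`` arrays or ``image_path``/``mask_path``.  When several
    configurations are given, the first is the reference and a paired t test
    on the Dice scores is reported for every other configuration against it.
    Items that fail to load are reported in their row and skipped.
    """
    from . import io as _io

    if isinstance(configs, PipelineConfig):
        configs = {"default": configs}
    rows = []
    dice_by_cfg: dict[str, dict] = {name: {} for name in configs}
    for item in items:
        item_id = item.get("id", "?")
        try:
            img = item["image"] if "image" in item else _io.read_image(item["image_path"])
            mask = item.get("mask")
            if mask is None and "mask_path" in item:
                mask = _io.read_mask(item["mask_path"])
        except Exception as exc:  # missing file etc.: report and continue
            for name in configs:
                rows.append({"id": item_id, "config": name, "status": "error",
                             "error": str(exc)})
            continue
        detector = (detectors or {}).get(item_id)
        for name, cfg in configs.items():
            res = run_one(img, mask, cfg, detector)
            row = {"id": item_id, "config": name, "status": res.status}
            if res.scores is not None:
                row.update(res.scores.as_dict())
                dice_by_cfg[name][item_id] = res.scores.dice
            rows.append(row)
    per_image = pd.DataFrame(rows)

    score_cols = [c for c in ("dice", "sensitivity", "specificity", "accuracy")
                  if c in per_image.columns]
    if score_cols:
        summary = per_image.groupby("config")[score_cols].agg(["mean", "std"])
    else:
        summary = pd.DataFrame()

    ttests: dict[str, met.PairedTestResult] = {}
    names = list(configs)
    if len(names) > 1:
        ref = names[0]
        for other in names[1:]:
            shared = sorted(set(dice_by_cfg[ref]) & set(dice_by_cfg[other]))
            if len(shared) >= 2:
                a = [dice_by_cfg[ref][i] for i in shared]
                b = [dice_by_cfg[other][i] for i in shared]
                ttests[f"{ref}_vs_{other}"] = met.paired_t_test(a, b)
    return BatchReport(per_image=per_image, summary=summary, ttests=ttests)
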