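"""Batch workflow: paired left/right flash images -> measurement CSV.

Image pairs follow the ``<id>_L.png`` / ``<id>_R.png`` naming convention
(TIFF also accepted).  Each pair runs through preprocess (illumination
correction, minimum-tonal fusion, red-channel extraction), segmentation,
mask cleaning and skeleton measurement; the result is one CSV row per
image plus a 1-bit mask image.  A lone ``<id>.png`` without a partner is
an error unless single-image mode is enabled (fusion is then skipped).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, measure, segment
from .errors import PairingError, ParameterError

log = logging.getLogger("rootmetrics")

_EXTS = (".png", ".tif", ".tiff")


@dataclass
class RunConfig:
    """Configuration of one batch run; every CLI flag maps onto a field."""

    input_dir: str
    output_dir: str
    channel: str = "red"
    method: str = "adaptive"  # global | auto | adaptive | double
    polarity: str = "root_bright"
    global_t: float | None = None
    block_size: int = 64
    proportion: float = 0.1
    neighborhood_sizes: tuple[int, ...] = (5, 15, 31)
    min_change: float = 0.1
    mm_per_px: float = 0.13
    class_edges: tuple[float, ...] = (0.5,)
    prune_px: int = 5
    min_object_px: int = 20
    fill_holes: bool = False  # crossing roots enclose real background; do not fill
    allow_single: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    report: pd.DataFrame
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def exit_code(self) -> int:
        return 1 if self.errors else 0


def find_pairs(input_dir: str | Path, allow_single: bool = False):
    """Collect (id, left, right) triples; right is None in single mode."""
    input_dir = Path(input_dir)
    files = [p for p in sorted(input_dir.iterdir()) if p.suffix.lower() in _EXTS]
    lefts, rights, singles = {}, {}, {}
    for p in files:
        stem = p.stem
        if stem.endswith("_L"):
            lefts[stem[:-2]] = p
        elif stem.endswith("_R"):
            rights[stem[:-2]] = p
        else:
            singles[stem] = p
    pairs = []
    orphans = []
    for key in sorted(set(lefts) | set(rights)):
        if key in lefts and key in rights:
            pairs.append((key, lefts[key], rights[key]))
        else:
            orphans.append(str(lefts.get(key, rights.get(key))))
    if orphans:
        raise PairingError(f"unpaired left/right files: {', '.join(orphans)}")
    if singles:
        if not allow_single:
            raise PairingError(
                "files without _L/_R suffix (use allow_single for single-image mode): "
                + ", ".join(str(p) for p in singles.values())
            )
        pairs.extend((key, path, None) for key, path in sorted(singles.items()))
    return pairs


def _segment(gray, config: RunConfig) -> segment.BinaryMask:
    if config.method == "global":
        t = config.global_t
        if t is None:
            raise ParameterError("method 'global' needs global_t")
        return segment.global_threshold(gray, t, config.polarity)
    if config.method == "auto":
        return segment.global_threshold(gray, segment.auto_threshold(gray), config.polarity)
    if config.method == "adaptive":
        return segment.adaptive_threshold(
            gray, config.block_size, config.proportion, config.polarity
        )
    if config.method == "double":
        return segment.double_adaptive_threshold(
            gray, config.neighborhood_sizes, config.min_change, config.polarity
        )
    raise ParameterError(f"unknown segmentation method {config.method!r}")


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full measurement workflow over every pair in ``input_dir``.

    Per-file failures are logged and collected; the batch continues and the
    result carries a nonzero exit code.  Deterministic for a fixed config.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = find_pairs(config.input_dir, allow_single=config.allow_single)
    if not pairs:
        log.warning("no input image pairs found in %s", config.input_dir)

    rows = []
    errors: dict[str, str] = {}
    for key, left_path, right_path in pairs:
        try:
            left = imaging.imread(left_path, mm_per_px=config.mm_per_px)
            if right_path is None:
                gray = (
                    imaging.to_gray(left, config.channel) if left.is_color else left
                )
            else:
                right = imaging.imread(right_path, mm_per_px=config.mm_per_px)
                gray = imaging.preprocess(left, right, channel=config.channel)
            mask = _segment(gray, config)
            mask = segment.clean_mask(
                mask, min_object_px=config.min_object_px, fill_holes=config.fill_holes
            )
            imaging.imwrite(
                out_dir / f"{key}_mask.png",
                imaging.RasterImage(
                    mask.mask.astype(float) * 255, mm_per_px=config.mm_per_px
                ),
            )
            report = measure.measure_mask(
                mask, prune_px=config.prune_px, class_edges=config.class_edges
            )
            rows.append({"image": key, **report.as_row()})
            log.info("%s: total length %.1f mm", key, report.smoothed_length)
        except Exception as exc:  # per-file failure must not kill the batch
            errors[key] = str(exc)
            log.error("%s: %s", key, exc)

    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "measurements.csv", index=False)
    (out_dir / "run_config.json").write_text(
        json.dumps({"config": asdict(config), "hash": config.config_hash()}, indent=2, default=str)
        + "\n"
    )
    return RunResult(report=df, errors=errors)
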