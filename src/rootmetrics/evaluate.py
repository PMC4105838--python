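"""Accuracy scoring against ground truth and the artificial-root benchmark.

The benchmark mirrors the validation experiment for root-measurement
software: render a batch of artificial root images whose true centerline
length is known analytically, run the full measurement pipeline (segment ->
thin -> prune -> measure) and score per-image relative deviations, plus the
agreement (squared Pearson correlation) between two independent backends -
the raster skeleton measurement and a vector "replay" that integrates the
generating centerlines directly.

``repeatability`` implements the variance-component statistic used for
operator studies: R^2 = var_image / (var_image + var_error), where
var_image is the between-image variance component and var_error the
image-by-user interaction (plus residual) component, estimated by
method-of-moments ANOVA on a complete image x user table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import measure, rootgen, segment
from .errors import DegenerateInputError, MissingCellError, ParameterError


def relative_deviation(measured: float, truth: float, signed: bool = False) -> float:
    """Relative deviation in percent, |measured - truth| / truth * 100
    (or signed when requested)."""
    if truth <= 0:
        raise ParameterError("truth must be positive")
    dev = 100.0 * (measured - truth) / truth
    return float(dev if signed else abs(dev))


@dataclass
class DeviationReport:
    """Per-image relative deviations (%) of a backend against ground truth."""

    deviations: np.ndarray  # absolute, %
    signed: np.ndarray  # signed, %
    n: int = 0

    def __post_init__(self) -> None:
        self.deviations = np.asarray(self.deviations, dtype=float)
        self.signed = np.asarray(self.signed, dtype=float)
        self.n = len(self.deviations)

    @property
    def max(self) -> float:
        return float(self.deviations.max())

    @property
    def mean(self) -> float:
        return float(self.deviations.mean())


@dataclass
class RepeatabilityResult:
    var_image: float
    var_error: float
    r2: float


def repeatability(table: pd.DataFrame) -> RepeatabilityResult:
    """Variance-component repeatability from a complete image x user table.

    ``table`` has one row per image and one column per user (one measurement
    per cell).  Components come from balanced two-way ANOVA expected mean
    squares: var_error is the interaction/residual mean square, var_image =
    (MS_image - var_error) / n_users, negatives truncated at zero, and
    R^2 = var_image / (var_image + var_error).
    """
    values = table.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ParameterError("need a table with >= 2 images and >= 2 users")
    if np.isnan(values).any():
        rows, cols = np.nonzero(np.isnan(values))
        raise MissingCellError(
            f"table has {rows.size} missing cell(s), first at row {rows[0]}, col {cols[0]}"
        )
    a, b = values.shape  # images, users
    grand = values.mean()
    img_means = values.mean(axis=1)
    user_means = values.mean(axis=0)
    ms_image = b * np.sum((img_means - grand) ** 2) / (a - 1)
    ss_err = np.sum((values - img_means[:, None] - user_means[None, :] + grand) ** 2)
    ms_err = ss_err / ((a - 1) * (b - 1))
    var_error = max(float(ms_err), 0.0)
    var_image = max(float((ms_image - ms_err) / b), 0.0)
    denom = var_image + var_error
    r2 = var_image / denom if denom > 0 else 0.0
    return RepeatabilityResult(var_image=var_image, var_error=var_error, r2=float(r2))


def pairwise_r2(lengths: pd.DataFrame | dict) -> pd.DataFrame:
    """Squared Pearson correlation between measurement backends.

    ``lengths`` holds one column per backend and one row per image; the
    result is a symmetric backend x backend matrix with unit diagonal.
    """
    df = pd.DataFrame(lengths)
    if len(df) < 3:
        raise ParameterError("need >= 3 images for a correlation")
    stds = df.std(ddof=0)
    zero = stds[stds == 0]
    if len(zero):
        raise DegenerateInputError(
            f"backend(s) with zero variance: {', '.join(map(str, zero.index))}"
        )
    return df.corr() ** 2


@dataclass
class BenchmarkConfig:
    """Study conditions of the artificial-root benchmark.

    Defaults render noiseless, high-contrast images at the working
    resolution of 0.13 mm/px and segment with the default adaptive
    threshold; each generated system cycles through 1-3 axile roots with a
    modest lateral density, giving a spread of total lengths.
    """

    extent: tuple[float, float] = (60.0, 80.0)
    mm_per_px: float = 0.13
    foreground_amplitude: float = 200.0
    background_level: float = 40.0
    noise_sd: float = 0.0
    ragged_edges: bool = False
    block_size: int = 64
    proportion: float = 0.1
    min_object_px: int = 20
    fill_holes: bool = False  # crossing roots legitimately enclose background
    prune_px: int = 5
    replay_step_mm: float = 0.13


@dataclass
class BenchmarkResult:
    lengths: pd.DataFrame  # columns: truth_mm, skeleton_mm, replay_mm
    skeleton: DeviationReport
    replay: DeviationReport
    r2: pd.DataFrame  # backends x backends

    @property
    def r2_skeleton_replay(self) -> float:
        return float(self.r2.loc["skeleton_mm", "replay_mm"])


def run_benchmark(
    n_systems: int = 10, seed: int = 42, config: BenchmarkConfig | None = None
) -> BenchmarkResult:
    """Generate, render, segment and measure ``n_systems`` artificial root
    images; score both backends against the analytic ground truth."""
    if n_systems < 2:
        raise ParameterError("n_systems must be >= 2")
    config = config or BenchmarkConfig()
    rng = np.random.default_rng(seed)
    render_cfg = rootgen.RenderConfig(
        mm_per_px=config.mm_per_px,
        foreground_amplitude=config.foreground_amplitude,
        background_level=config.background_level,
        noise_sd=config.noise_sd,
        ragged_edges=config.ragged_edges,
    )

    rows = []
    for i in range(n_systems):
        sys_seed = int(rng.integers(0, 2**31 - 1))
        system = rootgen.generate_root_system(
            n_axile=1 + i % 3,
            laterals_per_cm=(0.5, 1.0, 2.0)[i % 3],
            extent=config.extent,
            seed=sys_seed,
        )
        image, gt = rootgen.render(system, render_cfg)
        mask = segment.adaptive_threshold(
            image,
            block_size=config.block_size,
            proportion=config.proportion,
            polarity="root_bright",
        )
        mask = segment.clean_mask(
            mask, min_object_px=config.min_object_px, fill_holes=config.fill_holes
        )
        report = measure.measure_mask(mask, prune_px=config.prune_px)
        _, replay_mm = rootgen.true_length(system, step=config.replay_step_mm)
        rows.append(
            {
                "truth_mm": gt.total_length_mm,
                "skeleton_mm": report.smoothed_length,
                "replay_mm": replay_mm,
            }
        )

    lengths = pd.DataFrame(rows)
    truth = lengths["truth_mm"].to_numpy()
    reports = {}
    for col in ("skeleton_mm", "replay_mm"):
        vals = lengths[col].to_numpy()
        signed = 100.0 * (vals - truth) / truth
        reports[col] = DeviationReport(deviations=np.abs(signed), signed=signed)
    r2 = pairwise_r2(lengths[["skeleton_mm", "replay_mm"]])
    return BenchmarkResult(
        lengths=lengths, skeleton=reports["skeleton_mm"], replay=reports["replay_mm"], r2=r2
    )
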