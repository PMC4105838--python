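"""Reflectance spectroscopy support for choosing the segmentation channel.

Hyperspectral point spectra of roots and candidate germination papers
(400-1000 nm) are exposure-corrected, normalized against a white diffuse
reference (spectralon), and compared band by band.  The camera channel with
the strongest worst-case root/background contrast is recommended for
grayscale conversion.  Qualitative findings this module reproduces on its
built-in fixtures: strongly blue/grey papers reflect about half as much as
the root between 560 and 720 nm (so the red channel separates best), while
white paper reflects about twice the root everywhere (no channel is good).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import DimensionError, ParameterError

#: band edges in nm; visible edges follow the usual shaded figure ranges,
#: the near-infrared interval is 790-1000 nm.
DEFAULT_BANDS = {
    "blue": (450.0, 490.0),
    "green": (520.0, 560.0),
    "red": (620.0, 720.0),
    "nir": (790.0, 1000.0),
}

#: wavelength interval over which blue/grey papers reflect ~half the root
CONTRAST_BAND = (560.0, 720.0)


@dataclass
class SpectralCurve:
    """Wavelength-indexed intensities with the exposure time they were
    recorded at (sensor counts scale linearly with exposure)."""

    wavelengths: np.ndarray  # nm, strictly increasing
    intensities: np.ndarray
    exposure_time: float  # seconds

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.intensities.shape:
            raise DimensionError("wavelengths and intensities must be matching 1-D arrays")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if self.exposure_time <= 0:
            raise ParameterError("exposure_time must be positive")
        if np.any(self.intensities < 0):
            raise ParameterError("intensities must be >= 0")

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# exposure_s={self.exposure_time}\n")
            pd.DataFrame(
                {"wavelength_nm": self.wavelengths, "intensity": self.intensities}
            ).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralCurve":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline().strip()
            if not header.startswith("# exposure_s="):
                raise ParameterError(f"{path}: missing '# exposure_s=' header line")
            exposure = float(header.split("=", 1)[1])
            df = pd.read_csv(fh)
        return cls(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(), exposure)


@dataclass(frozen=True)
class BandSet:
    """Named wavelength intervals used for channel comparison."""

    blue: tuple[float, float] = DEFAULT_BANDS["blue"]
    green: tuple[float, float] = DEFAULT_BANDS["green"]
    red: tuple[float, float] = DEFAULT_BANDS["red"]
    nir: tuple[float, float] = DEFAULT_BANDS["nir"]

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {"blue": self.blue, "green": self.green, "red": self.red, "nir": self.nir}


def correct_exposure(sample: SpectralCurve, reference_exposure: float) -> SpectralCurve:
    """Rescale intensities to a common exposure time:
    corrected = intensity * t_reference / t_sample."""
    if reference_exposure <= 0:
        raise ParameterError("reference_exposure must be positive")
    factor = reference_exposure / sample.exposure_time
    return SpectralCurve(
        sample.wavelengths.copy(), sample.intensities * factor, reference_exposure
    )


def normalize_to_reference(sample: SpectralCurve, reference: SpectralCurve) -> SpectralCurve:
    """Relative reflectance: exposure-correct both curves, then divide the
    sample pointwise by the white reference."""
    if sample.wavelengths.shape != reference.wavelengths.shape or np.any(
        sample.wavelengths != reference.wavelengths
    ):
        raise DimensionError("sample and reference wavelength grids differ")
    ref = reference.intensities
    if np.any(ref <= 0):
        wl = reference.wavelengths[np.argmax(ref <= 0)]
        raise ParameterError(f"reference intensity is zero at {wl:g} nm; cannot normalize")
    sample_c = correct_exposure(sample, reference.exposure_time)
    return SpectralCurve(
        sample.wavelengths.copy(), sample_c.intensities / ref, reference.exposure_time
    )


def band_contrast(
    root: SpectralCurve, paper: SpectralCurve, band: tuple[float, float]
) -> float:
    """Root/background contrast in a band: ratio of band-mean reflectances."""
    if root.wavelengths.shape != paper.wavelengths.shape or np.any(
        root.wavelengths != paper.wavelengths
    ):
        raise DimensionError("curves must share a wavelength grid")
    lo, hi = band
    sel = (root.wavelengths >= lo) & (root.wavelengths <= hi)
    if not sel.any():
        raise ParameterError(f"band {band} does not intersect the measured grid")
    return float(root.intensities[sel].mean() / paper.intensities[sel].mean())


@dataclass
class ChannelRecommendation:
    """Chosen channel plus the full paper x band contrast table."""

    channel: str
    contrasts: pd.DataFrame  # index: paper name, columns: band names


def recommend_channel(
    root: SpectralCurve,
    papers: dict[str, SpectralCurve] | list[SpectralCurve],
    bands: BandSet | None = None,
    candidates: tuple[str, ...] = ("blue", "green", "red"),
) -> ChannelRecommendation:
    """Pick the camera channel with the best worst-case contrast.

    For every candidate band the score is the minimum over papers of
    |log contrast| (a channel must separate root from *every* paper in a
    batch; |log| treats root-bright and root-dark contrast symmetrically).
    Ties break toward the longer wavelength.
    """
    if not papers:
        raise ParameterError("need at least one paper curve")
    bands = bands or BandSet()
    band_map = bands.as_dict()
    if isinstance(papers, list):
        papers = {f"paper_{i + 1}": p for i, p in enumerate(papers)}

    table = pd.DataFrame(
        {
            band: {
                name: band_contrast(root, paper, band_map[band])
                for name, paper in papers.items()
            }
            for band in band_map
        }
    )
    scores = {
        band: float(np.min(np.abs(np.log(table[band].to_numpy())))) for band in candidates
    }
    # argmax score; ties toward longer wavelength (larger band upper edge)
    best = max(candidates, key=lambda b: (scores[b], band_map[b][1]))
    return ChannelRecommendation(channel=best, contrasts=table)


# ---------------------------------------------------------------------------
# fixture spectra
# ---------------------------------------------------------------------------

#: recorded exposure times (s) for the reference and the tested papers
FIXTURE_EXPOSURES = {
    "spectralon": 0.21,
    "root": 0.35,
    "steel_blue": 0.4,
    "whatman_blue": 0.4,
    "sebio_grey": 0.4,
    "light_blue": 0.3,
    "white": 0.25,
}

# paper/root reflectance-ratio control points (nm, ratio); PCHIP-interpolated
_RATIO_SHAPES = {
    # strongly blue/grey papers: blue peak, exactly half the root between
    # 560 and 720 nm, rising again in the NIR
    "steel_blue": [(400, 1.20), (460, 1.35), (520, 0.85), (560, 0.5), (640, 0.5),
                   (720, 0.5), (790, 0.85), (900, 1.25), (1000, 1.40)],
    "whatman_blue": [(400, 0.85), (460, 0.92), (520, 0.75), (560, 0.5), (640, 0.5),
                     (720, 0.5), (790, 0.80), (900, 1.15), (1000, 1.30)],
    "sebio_grey": [(400, 0.80), (460, 0.88), (520, 0.70), (560, 0.5), (640, 0.5),
                   (720, 0.5), (790, 0.75), (900, 1.10), (1000, 1.25)],
    # light blue: brighter than the root, maxima in blue and NIR
    "light_blue": [(400, 1.30), (460, 1.50), (520, 1.20), (560, 1.12), (640, 1.10),
                   (720, 1.10), (790, 1.20), (900, 1.40), (1000, 1.50)],
    # white: about twice the root across the whole range
    "white": [(400, 2.0), (700, 2.0), (1000, 2.0)],
}


@dataclass
class FixtureSpectra:
    """Synthetic raw-sensor spectra shaped like a real root/paper batch."""

    root: SpectralCurve
    spectralon: SpectralCurve
    papers: dict[str, SpectralCurve]


def make_fixture_spectra(seed: int = 0) -> FixtureSpectra:
    """Deterministic raw spectra on a 2-nm grid, 400-1000 nm.

    The curves are synthetic but encode the measured ratio structure: the
    three strongly blue/grey papers reflect half the root's intensity
    between 560 and 720 nm, the white paper twice the root everywhere, and
    the light blue paper is brighter than the root with blue/NIR maxima.
    Raw counts include the lamp/sensor response and per-sample exposure
    times, so exposure correction and spectralon normalization are
    exercised for real.
    """
    rng = np.random.default_rng(seed)
    wl = np.arange(400.0, 1000.0 + 1e-9, 2.0)

    # lamp * sensor response of the (synthetic) instrument, in counts/s
    response = 9000.0 * np.exp(-(((wl - 640.0) / 420.0) ** 2)) + 2500.0

    def raw(reflectance: np.ndarray, name: str) -> SpectralCurve:
        t = FIXTURE_EXPOSURES[name]
        counts = reflectance * response * (t / FIXTURE_EXPOSURES["spectralon"])
        counts = counts * (1.0 + rng.normal(0.0, 0.002, size=wl.shape))
        return SpectralCurve(wl.copy(), np.maximum(counts, 0.0), t)

    root_refl = 0.30 + 0.03 * (wl - 400.0) / 600.0  # flat-ish, slight rise
    curves: dict[str, SpectralCurve] = {}
    for name, ctrl in _RATIO_SHAPES.items():
        xs, ys = zip(*ctrl)
        ratio = PchipInterpolator(np.asarray(xs, float), np.asarray(ys, float))(wl)
        curves[name] = raw(root_refl * ratio, name)

    return FixtureSpectra(
        root=raw(root_refl, "root"),
        spectralon=raw(np.ones_like(wl), "spectralon"),
        papers=curves,
    )
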