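"""Synthetic phantoms and cohorts with known ground truth.

No patient radiographs ship with this package; every pipeline stage is
instead exercised on generated inputs whose correct answer is known:

* binary textures with closed-form box-counting dimension (the depth-d
  Sierpinski carpet has dimension log 8 / log 3 ~ 1.8928 at every
  depth), plus line, point, lattice and spectral-noise patterns;
* radiograph-like grey patches: a texture mapped to two grey levels
  with a low-order polynomial illumination surface and pixel noise
  superimposed, so the background-removal step has real work to do;
* landmark fixtures constructed from chosen cortical-width / height
  values, so morphometry can be checked against construction values;
* three-group patient cohorts (cholesterol strata normal / borderline /
  high, split at 5.2 and 6.2 mmol/L total cholesterol) with
  configurable location shifts in anterior fractal dimension, for
  calibrating the nonparametric test chain.

All generators are deterministic: identical parameters (including the
seed) produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidParameterError
from .morphometry import LandmarkSet
from .preprocess import BinaryPatch, GreyPatch, Stage

__all__ = [
    "TEXTURE_MODELS",
    "GROUP_LABELS",
    "CHOLESTEROL_BANDS",
    "SynthParams",
    "CohortParams",
    "SyntheticGreyPatch",
    "make_ifs_fractal",
    "make_binary_texture",
    "make_grey_patch",
    "make_cohort",
    "make_landmark_fixture",
    "shift_for_cohens_f",
    "save_patch",
    "write_cohort_csv",
]

TEXTURE_MODELS = (
    "ifs_fractal",
    "spectral_surface",
    "strut_lattice",
    "uniform",
    "single_line",
    "single_point",
)

GROUP_LABELS = ("normal", "borderline", "high")
#: total-cholesterol sampling bands per group (mmol/L); the study's
#: thresholds are < 5.2 (normal), 5.2-6.2 (borderline), > 6.2 (high)
CHOLESTEROL_BANDS = {
    "normal": (3.6, 5.19),
    "borderline": (5.2, 6.2),
    "high": (6.21, 9.5),
}

CARPET_DIMENSION = float(np.log(8) / np.log(3))  # ~1.8928

# group medians of the study cohort, per metric; one value per group
# (normal, borderline, high) -- the generator's default locations
STUDY_FD_MEDIANS = {
    "anterior": (1.4192, 1.4273, 1.4771),
    "premolar": (1.5100, 1.5060, 1.5045),
    "molar": (1.5180, 1.5062, 1.5305),
}
STUDY_LACUNARITY_MEDIANS = {
    "anterior": (0.2036, 0.1906, 0.1866),
    "premolar": (0.1805, 0.1630, 0.1702),
    "molar": (0.1774, 0.1815, 0.1650),
}
STUDY_MCW_MEDIANS = {
    "right": (47.50, 47.70, 45.25),
    "left": (49.00, 46.70, 43.65),
}
STUDY_PMI_MEDIANS = {
    "right": (0.3670, 0.3609, 0.3687),
    "left": (0.3585, 0.3597, 0.3568),
}
STUDY_AGE = ((60.4, 19.0), (62.7, 14.4), (68.88, 8.2))  # mean, sd per group
STUDY_FEMALE_FRACTION = (19 / 35, 18 / 33, 21 / 24)
STUDY_N_PER_GROUP = (35, 33, 24)


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic patch."""

    seed: int = 0
    texture_model: str = "ifs_fractal"
    size: int = 64
    illumination_amplitude: float = 0.0  # grey levels, peak-to-peak
    noise_sd: float = 0.0  # grey levels
    model_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.texture_model not in TEXTURE_MODELS:
            raise InvalidParameterError(
                f"unknown texture model {self.texture_model!r}; "
                f"expected one of {TEXTURE_MODELS}"
            )
        if self.size < 8:
            raise InvalidParameterError(f"size must be >= 8, got {self.size}")
        if not 0.0 <= self.illumination_amplitude <= 127.0:
            raise InvalidParameterError(
                "illumination_amplitude must be in [0, 127] grey levels"
            )
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass
class SyntheticGreyPatch(GreyPatch):
    """Grey patch that remembers its clean binary texture for oracles."""

    clean_pattern: np.ndarray | None = None


def _carpet(depth: int) -> np.ndarray:
    """Depth-d Sierpinski carpet on a 3^d grid; 8^d foreground pixels."""
    pattern = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        k = pattern.shape[0]
        nxt = np.zeros((3 * k, 3 * k), dtype=bool)
        for i in range(3):
            for j in range(3):
                if (i, j) != (1, 1):
                    nxt[i * k : (i + 1) * k, j * k : (j + 1) * k] = pattern
        pattern = nxt
    return pattern


def _nearest_resample(pattern: np.ndarray, size: int) -> np.ndarray:
    n = pattern.shape[0]
    idx = (np.arange(size) * n / size).astype(int)
    return pattern[np.ix_(idx, idx)]


def _thicken(pattern: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return pattern
    from scipy.ndimage import binary_dilation

    return binary_dilation(pattern, structure=np.ones((width, width), bool))


def make_binary_texture(params: SynthParams) -> np.ndarray:
    """Dispatch to the requested texture model; returns a boolean grid."""
    rng = np.random.default_rng(params.seed)
    size = params.size
    mp = params.model_params
    model = params.texture_model
    if model == "uniform":
        return np.ones((size, size), dtype=bool)
    if model == "single_line":
        out = np.zeros((size, size), dtype=bool)
        out[mp.get("row", size // 2), :] = True
        return out
    if model == "single_point":
        out = np.zeros((size, size), dtype=bool)
        out[mp.get("row", size // 2), mp.get("col", size // 2)] = True
        return out
    if model == "ifs_fractal":
        depth = int(mp.get("depth", 4))
        if depth < 1:
            raise InvalidParameterError("IFS depth must be >= 1")
        carpet = _carpet(depth)
        if size != carpet.shape[0]:
            carpet = _nearest_resample(carpet, size)
        return _thicken(carpet, int(mp.get("strut_width", 1)))
    if model == "strut_lattice":
        spacing = int(mp.get("spacing", 8))
        width = int(mp.get("width", 3))
        if spacing < 2 or width < 1 or width >= spacing:
            raise InvalidParameterError(
                f"lattice needs 1 <= width < spacing, got {width}/{spacing}"
            )
        out = np.zeros((size, size), dtype=bool)
        for s in range(0, size, spacing):
            out[s : s + width, :] = True
            out[:, s : s + width] = True
        return out
    if model == "spectral_surface":
        beta = float(mp.get("beta", 3.0))
        freq_r = np.fft.fftfreq(size)[:, None]
        freq_c = np.fft.fftfreq(size)[None, :]
        radius = np.sqrt(freq_r**2 + freq_c**2)
        radius[0, 0] = 1.0
        amp = radius ** (-beta / 2.0)
        amp[0, 0] = 0.0
        phase = rng.uniform(0, 2 * np.pi, (size, size))
        surface = np.real(np.fft.ifft2(amp * np.exp(1j * phase)))
        return surface >= np.median(surface)
    raise InvalidParameterError(f"unhandled texture model {model!r}")


def make_ifs_fractal(params: SynthParams) -> BinaryPatch:
    """Iterated-function-system fractal with closed-form dimension.

    The depth-d Sierpinski carpet on a 3^d grid has exactly 8^d
    foreground pixels and box-counting dimension log 8 / log 3 on
    grid-aligned box sizes {3, 9, ..., 3^d}. When ``size`` differs from
    3^d the carpet is rasterized by nearest-neighbour scaling.
    """
    if params.texture_model not in ("ifs_fractal", "uniform"):
        params = replace(params, texture_model="ifs_fractal")
    return BinaryPatch(make_binary_texture(params), stage=Stage.SYNTHETIC)


def make_grey_patch(params: SynthParams) -> SyntheticGreyPatch:
    """Radiograph-like grey patch: texture + illumination surface + noise.

    The texture foreground is mapped to the dark grey level (default
    90 on a 160 background) because the preprocessing chain ends by
    inverting the thresholded image: the originally dark phase is the
    one that is skeletonized and analysed. For the carpet texture the
    struts default to 3 px wide (``strut_width=3``) -- like trabeculae
    on real radiographs they must be thicker than the 3x3 noise-removal
    opening, or the cleaning step would erase the structure it is meant
    to preserve.

    The illumination surface is a linear ramp of the stated peak-to-peak
    amplitude (``model_params['illumination_axis']`` in {'col', 'row',
    'diag'}), standing in for the smooth brightness bias that soft
    tissue and bone thickness add to a radiograph. The returned patch
    records the clean binary texture in ``clean_pattern`` for oracle
    comparisons.
    """
    if params.texture_model == "ifs_fractal":
        mp = dict(params.model_params)
        mp.setdefault("strut_width", 3)
        params = replace(params, model_params=mp)
    pattern = make_binary_texture(params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    dark, bright = params.model_params.get("grey_levels", (90, 160))
    grey = np.where(pattern, float(dark), float(bright))
    size = params.size
    axis = params.model_params.get("illumination_axis", "col")
    coords = np.arange(size, dtype=float) / (size - 1)
    if axis == "col":
        ramp = np.broadcast_to(coords[None, :], (size, size))
    elif axis == "row":
        ramp = np.broadcast_to(coords[:, None], (size, size))
    elif axis == "diag":
        ramp = (coords[:, None] + coords[None, :]) / 2.0
    else:
        raise InvalidParameterError(
            f"illumination_axis must be col/row/diag, got {axis!r}"
        )
    grey = grey + params.illumination_amplitude * ramp
    if params.noise_sd > 0:
        grey = grey + rng.normal(0.0, params.noise_sd, (size, size))
    rounded = np.trunc(grey + np.copysign(0.5, grey))
    pixels = np.clip(rounded, 0, 255).astype(np.uint8)
    return SyntheticGreyPatch(
        pixels,
        provenance=f"synthetic:{params.texture_model}:seed={params.seed}",
        clean_pattern=pattern,
    )


@dataclass(frozen=True)
class CohortParams:
    """Parameters of a synthetic three-group patient cohort.

    Defaults reproduce the structure of the study cohort: group sizes
    35/33/24, the published group medians for every metric, ages and
    sex ratios per group. ``fd_medians`` etc. map region (or side) to
    the three group locations; within-group variation is Gaussian with
    the metric's ``spread``.
    """

    n_per_group: tuple[int, int, int] = STUDY_N_PER_GROUP
    fd_medians: dict = field(default_factory=lambda: dict(STUDY_FD_MEDIANS))
    lacunarity_medians: dict = field(
        default_factory=lambda: dict(STUDY_LACUNARITY_MEDIANS)
    )
    mcw_medians: dict = field(default_factory=lambda: dict(STUDY_MCW_MEDIANS))
    pmi_medians: dict = field(default_factory=lambda: dict(STUDY_PMI_MEDIANS))
    fd_sd: float = 0.12
    lacunarity_sd: float = 0.05
    mcw_sd: float = 9.0
    pmi_sd: float = 0.10
    age_mean_sd: tuple = STUDY_AGE
    female_fraction: tuple = STUDY_FEMALE_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3 or any(n < 2 for n in self.n_per_group):
            raise InvalidParameterError(
                "n_per_group must be three integers >= 2"
            )

    def with_null_shift(self) -> "CohortParams":
        """All three groups share each metric's normal-group location."""
        flat = lambda d: {k: (v[0],) * 3 for k, v in d.items()}
        return replace(
            self,
            fd_medians=flat(self.fd_medians),
            lacunarity_medians=flat(self.lacunarity_medians),
            mcw_medians=flat(self.mcw_medians),
            pmi_medians=flat(self.pmi_medians),
        )

    def with_anterior_effect(self, f: float) -> "CohortParams":
        """Null everywhere except an anterior-FD shift of population
        Cohen's f equal to ``f`` (monotone normal < borderline < high)."""
        base = self.with_null_shift()
        means = shift_for_cohens_f(
            f,
            self.n_per_group,
            self.fd_sd,
            center=self.fd_medians["anterior"][0],
        )
        fd = dict(base.fd_medians)
        fd["anterior"] = means
        return replace(base, fd_medians=fd)


def shift_for_cohens_f(
    f: float,
    n_per_group: tuple[int, int, int],
    sd: float,
    center: float = 1.42,
    pattern: tuple[float, float, float] = (-1.0, 0.0, 1.0),
) -> tuple[float, float, float]:
    """Group means with population Cohen's f for given sizes and SD.

    Cohen's f for k groups is sigma_means / sigma, where sigma_means is
    the size-weighted SD of the group means. The ``pattern`` of offsets
    is scaled so the weighted dispersion of the returned means around
    their weighted average hits the requested f exactly.
    """
    if f < 0:
        raise InvalidParameterError("f must be >= 0")
    n = np.asarray(n_per_group, dtype=float)
    w = n / n.sum()
    p = np.asarray(pattern, dtype=float)
    pbar = float((w * p).sum())
    disp = float(np.sqrt((w * (p - pbar) ** 2).sum()))
    if disp == 0 and f > 0:
        raise InvalidParameterError("pattern has no dispersion")
    scale = 0.0 if f == 0 else f * sd / disp
    return tuple(center + scale * (pi - pbar) for pi in p)


def make_cohort(params: CohortParams) -> pd.DataFrame:
    """Long-format cohort table, one row per patient and region/side.

    Columns: ``patient_id, group, age, sex, cholesterol, region, fd,
    lacunarity, mcw, pmi``. The three mandibular regions carry fd and
    lacunarity; the two sides carry mcw and pmi (other cells are NaN).
    Group membership is consistent with the drawn total-cholesterol
    value under the 5.2 / 6.2 mmol/L thresholds. Deterministic under
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    pid = 0
    for g, (label, n) in enumerate(zip(GROUP_LABELS, params.n_per_group)):
        mean_age, sd_age = params.age_mean_sd[g]
        lo, hi = CHOLESTEROL_BANDS[label]
        for _ in range(n):
            pid += 1
            age = float(np.clip(rng.normal(mean_age, sd_age), 18, 95))
            sex = "female" if rng.random() < params.female_fraction[g] else "male"
            chol = float(rng.uniform(lo, hi))
            base = {
                "patient_id": f"P{pid:03d}",
                "group": label,
                "age": round(age, 1),
                "sex": sex,
                "cholesterol": round(chol, 2),
            }
            for region in ("anterior", "premolar", "molar"):
                rows.append(
                    base
                    | {
                        "region": region,
                        "fd": float(
                            rng.normal(params.fd_medians[region][g], params.fd_sd)
                        ),
                        "lacunarity": float(
                            abs(
                                rng.normal(
                                    params.lacunarity_medians[region][g],
                                    params.lacunarity_sd,
                                )
                            )
                        ),
                        "mcw": np.nan,
                        "pmi": np.nan,
                    }
                )
            for side in ("right", "left"):
                rows.append(
                    base
                    | {
                        "region": side,
                        "fd": np.nan,
                        "lacunarity": np.nan,
                        "mcw": float(
                            abs(rng.normal(params.mcw_medians[side][g], params.mcw_sd))
                        ),
                        "pmi": float(
                            abs(rng.normal(params.pmi_medians[side][g], params.pmi_sd))
                        ),
                    }
                )
    return pd.DataFrame(rows)


def make_landmark_fixture(
    seed: int,
    mcw: float = 12.0,
    foramen_height: float = 40.0,
    angle_deg: float | None = None,
    side: str = "right",
) -> tuple[LandmarkSet, float, float]:
    """Landmarks constructed from a chosen cortical width and height.

    Builds a straight inferior border, an endosteal (inner cortical)
    margin parallel to it at distance ``mcw``, and a mental-foramen
    lower edge at distance ``foramen_height``, then applies a rigid
    rotation (random unless ``angle_deg`` is given) and translation.
    Returns the landmark set together with the construction values, so
    morphometry can be checked against ground truth: recovered MCW must
    equal ``mcw`` and PMI must equal ``mcw / foramen_height``.
    """
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(
        rng.uniform(-60, 60) if angle_deg is None else angle_deg
    )
    xs = np.linspace(-60.0, 60.0, 25)
    jitter = rng.normal(0.0, 0.0, xs.size)  # border is exactly straight
    border = np.column_stack([np.full_like(xs, 100.0) + jitter, xs])
    margin = np.column_stack([np.full_like(xs, 100.0 - mcw), xs])
    foramen = np.array([100.0 - foramen_height, float(rng.uniform(-20, 20))])
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    shift = rng.uniform(-30, 30, size=2)

    def xf(pts: np.ndarray) -> np.ndarray:
        return (pts - [100.0, 0.0]) @ rot.T + [100.0, 0.0] + shift

    landmarks = LandmarkSet(
        inferior_border=xf(border),
        foramen_lower_edge=xf(foramen[None, :])[0],
        cortical_inner_margin=xf(margin),
        side=side,
    )
    return landmarks, float(mcw), float(foramen_height)


def save_patch(path: str | Path, patch: GreyPatch | BinaryPatch) -> None:
    """Write a patch as 8-bit greyscale TIFF or PNG (by extension)."""
    path = Path(path)
    if isinstance(patch, BinaryPatch):
        arr = patch.pixels.astype(np.uint8) * 255
    else:
        arr = patch.pixels
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_cohort_csv(path: str | Path, cohort: pd.DataFrame) -> None:
    cols = [
        "patient_id",
        "group",
        "age",
        "sex",
        "cholesterol",
        "region",
        "fd",
        "lacunarity",
        "mcw",
        "pmi",
    ]
    cohort.loc[:, [c for c in cols if c in cohort.columns]].to_csv(
        path, index=False
    )
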