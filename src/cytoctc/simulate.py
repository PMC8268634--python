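"""Synthetic cytospin images and patient cohorts with ground truth.

After size-based enrichment of a blood sample, the captured cells are
cytocentrifuged onto a slide and imaged in five fluorescence channels:
DAPI (nuclei), a tumor lineage marker on AF488 (pan-keratin for carcinomas,
PMEL17/Melan-A for melanoma), the leukocyte exclusion marker CD45 on AF647,
and the two receptors of interest CD74 and CD44.  This module emulates such
slides: it plants leukocytes and tumor cells of known morphotype (classical
8-20 um, large >25 um, multinucleated, 2-6-cell clusters) with known
per-channel mean grey values, paints them onto a multi-page raster and
returns the full ground truth so that downstream detection, gating and
classification can be validated cell by cell.

A second generator produces whole patient cohorts (CTC counts per patient,
metastasis-site flags, receptor status, survival) plus per-CTC CD74/CD44
expression with a configurable Pearson correlation, emulating the cohort
structure the statistics operate on.

Intensities live on an 8-bit-like [0, 255] mean-grey-value scale so that the
expression category thresholds (negative <= 10, weak < 21, strong >= 21) are
directly meaningful.  Noise is additive Gaussian (default sd 2 grey values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "CellSpec",
    "ImageParams",
    "ImageGroundTruth",
    "PlacementError",
    "generate_cytospin",
    "CohortParams",
    "generate_cohort",
    "draw_marker_expression",
    "normal_scale_rho",
]

CHANNELS = ("DAPI", "AF488_tumor", "AF647_CD45", "CD74", "CD44")

CLASS_LABELS = (
    "leukocyte",
    "classical_ctc",
    "large_cell",
    "multinucleated_cell",
    "cluster_member",
)
_TUMOR_CLASSES = set(CLASS_LABELS[1:])

# gating anchors on the mean-grey-value scale (shared with cytoctc.classify)
_TUMOR_POSITIVE_MIN = 21.0
_CD45_POSITIVE_MAX = 10.0

# nucleus geometry relative to the cell body radius; multinucleated nuclei
# sit well inside the body so their spacing (< 0.9 R) stays clearly below
# the centre distance of touching cluster members (~ sum of the radii)
_NUCLEUS_FRAC_MONO = 0.55
_NUCLEUS_FRAC_MULTI = 0.32
_NUCLEUS_OFFSET_MULTI = 0.42
# fraction of the sum of radii at which touching cluster members are placed
_CLUSTER_CONTACT = 0.98


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed at the requested density."""


# ---------------------------------------------------------------------------
# cell specification
# ---------------------------------------------------------------------------

@dataclass
class CellSpec:
    """One planted cell: identity, geometry and planted channel means."""

    cell_id: str
    class_label: str
    centroid: tuple[float, float]  # (x, y) in pixels, origin top-left
    diameter_um: float
    n_nuclei: int
    cluster_id: Optional[str]
    channel_means: dict[str, float]

    def validate(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if set(self.channel_means) != set(CHANNELS):
            raise ValueError("channel_means must cover exactly the 5 channels")
        if any(v < 0 for v in self.channel_means.values()):
            raise ValueError("channel means must be non-negative")
        af488 = self.channel_means["AF488_tumor"]
        af647 = self.channel_means["AF647_CD45"]
        if self.class_label == "leukocyte":
            if not (af647 > _CD45_POSITIVE_MAX and af488 < _TUMOR_POSITIVE_MIN):
                raise ValueError("leukocyte must be CD45-bright and tumor-marker-dim")
        else:
            if not (af488 >= _TUMOR_POSITIVE_MIN and af647 <= _CD45_POSITIVE_MAX):
                raise ValueError("tumor cell must be tumor-marker-bright and CD45-dim")
        if self.class_label == "classical_ctc":
            if not (8.0 <= self.diameter_um <= 20.0) or self.n_nuclei != 1:
                raise ValueError("classical CTC must be 8-20 um with one nucleus")
        if self.class_label == "large_cell" and not self.diameter_um > 25.0:
            raise ValueError("large cell must exceed 25 um")
        if self.class_label == "multinucleated_cell" and self.n_nuclei < 2:
            raise ValueError("multinucleated cell needs >= 2 nuclei")
        if (self.cluster_id is not None) != (self.class_label == "cluster_member"):
            raise ValueError("cluster_id is set iff the cell is a cluster member")


# ---------------------------------------------------------------------------
# image parameters
# ---------------------------------------------------------------------------

@dataclass
class ImageParams:
    """Settings for one synthetic cytospin slide.

    The default leukocyte carryover per slide (1,000) reflects a typical
    post-enrichment background; it is a free parameter of the emulation.
    Per-class diameters are drawn from clipped normals (um); tumor-marker,
    CD45 and DAPI intensities from clipped lognormals; CD74/CD44 on tumor
    cells from a correlated bivariate lognormal (see ``cd74_cd44_rho``).
    """

    shape: tuple[int, int] = (3000, 3000)  # (rows, cols) pixels
    pixel_size_um: float = 0.5
    background_level: float = 5.0
    noise_sd: float = 2.0
    n_leukocytes: int = 1000
    n_classical: int = 5
    n_large: int = 0
    n_multinucleated: int = 0
    cluster_sizes: tuple[int, ...] = ()
    cd74_cd44_rho: float = 0.9686
    # (mean, sd, lo, hi) of clipped-normal diameter draws, um
    diameter_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "leukocyte": (10.0, 1.0, 7.5, 13.5),
            "classical_ctc": (13.0, 2.5, 8.5, 19.5),
            "large_cell": (30.0, 3.0, 25.5, 40.0),
            "multinucleated_cell": (24.0, 4.0, 16.0, 34.0),
            "cluster_member": (13.0, 2.5, 8.5, 19.5),
        }
    )
    # (median, sigma_log, lo, hi) of clipped-lognormal intensity draws
    leukocyte_intensities: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "DAPI": (150.0, 0.15, 100.0, 255.0),
            "AF488_tumor": (2.0, 0.4, 0.2, 8.0),
            "AF647_CD45": (160.0, 0.25, 30.0, 255.0),
            "CD74": (30.0, 0.4, 1.0, 150.0),
            "CD44": (35.0, 0.4, 1.0, 150.0),
        }
    )
    tumor_intensities: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "DAPI": (150.0, 0.15, 100.0, 255.0),
            "AF488_tumor": (120.0, 0.25, 30.0, 255.0),
            "AF647_CD45": (2.0, 0.4, 0.2, 8.0),
            # CD74/CD44 medians and log-sd feed the correlated bivariate draw
            "CD74": (45.0, 0.5, 0.5, 255.0),
            "CD44": (40.0, 0.5, 0.5, 255.0),
        }
    )
    max_placement_retries: int = 500

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name in ("n_leukocytes", "n_classical", "n_large", "n_multinucleated"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for s in self.cluster_sizes:
            if s < 2:
                raise ValueError("cluster sizes must be >= 2")
        if abs(self.cd74_cd44_rho) > 1:
            raise ValueError("|cd74_cd44_rho| must be <= 1")


@dataclass
class ImageGroundTruth:
    """A simulated slide paired with its complete ground truth.

    ``truth_labels`` assigns each painted pixel the 1-based index of its cell
    in ``cells`` (painting order resolves the thin overlap between touching
    cluster members); ``nucleus_labels`` does the same for nucleus pixels.
    """

    image: np.ndarray  # (5, H, W) float32
    pixel_size_um: float
    cells: list[CellSpec]
    seed: int
    background_level: float
    noise_sd: float
    truth_labels: np.ndarray  # (H, W) int32
    nucleus_labels: np.ndarray  # (H, W) int32
    params: ImageParams

    def cell_mask(self, index: int) -> tuple[np.ndarray, np.ndarray]:
        """Pixel coordinates (rows, cols) painted for cell ``index`` (0-based)."""
        return np.nonzero(self.truth_labels == index + 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for spec in self.cells:
            row = {
                "cell_id": spec.cell_id,
                "class_label": spec.class_label,
                "x": spec.centroid[0],
                "y": spec.centroid[1],
                "diameter_um": spec.diameter_um,
                "n_nuclei": spec.n_nuclei,
                "cluster_id": spec.cluster_id if spec.cluster_id is not None else "",
            }
            for ch in CHANNELS:
                row[f"mean_{ch}"] = spec.channel_means[ch]
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlated lognormal marker draws
# ---------------------------------------------------------------------------

def normal_scale_rho(target_rho: float, sigma1: float, sigma2: float) -> float:
    """Normal-scale correlation that yields ``target_rho`` after exponentiation.

    For (X, Y) bivariate normal with log-sds sigma1, sigma2 and correlation
    rho*, the Pearson correlation of (e^X, e^Y) is
    (e^{rho* s1 s2} - 1) / sqrt((e^{s1^2} - 1)(e^{s2^2} - 1)); this inverts
    that relation so the generated mean-grey values carry the requested
    correlation on the observed scale.
    """
    if abs(target_rho) > 1:
        raise ValueError("|rho| must be <= 1")
    denom = math.sqrt(math.expm1(sigma1**2) * math.expm1(sigma2**2))
    arg = 1.0 + target_rho * denom
    if arg <= 0:
        raise ValueError(
            f"target correlation {target_rho} is unattainable for lognormals "
            f"with sigmas ({sigma1}, {sigma2})"
        )
    rho_star = math.log(arg) / (sigma1 * sigma2)
    if abs(rho_star) > 1:
        raise ValueError(
            f"target correlation {target_rho} requires normal-scale correlation "
            f"{rho_star:.4f} outside [-1, 1]"
        )
    return rho_star


def _correlated_lognormal(
    rng: np.random.Generator,
    n: int,
    median1: float,
    sigma1: float,
    median2: float,
    sigma2: float,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    """n pairs from a bivariate lognormal with observed-scale Pearson rho."""
    rho_star = normal_scale_rho(rho, sigma1, sigma2)
    cov = np.array([[sigma1**2, rho_star * sigma1 * sigma2],
                    [rho_star * sigma1 * sigma2, sigma2**2]])
    z = rng.multivariate_normal(
        [math.log(median1), math.log(median2)], cov, size=n, method="cholesky"
    )
    return np.exp(z[:, 0]), np.exp(z[:, 1])


# ---------------------------------------------------------------------------
# slide generation
# ---------------------------------------------------------------------------

def _clipped_normal(rng, mean, sd, lo, hi, size=None):
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def _clipped_lognormal(rng, median, sigma, lo, hi, size=None):
    return np.clip(rng.lognormal(math.log(median), sigma, size=size), lo, hi)


def _draw_channel_means(
    rng: np.random.Generator, params: ImageParams, class_label: str
) -> dict[str, float]:
    table = (
        params.leukocyte_intensities
        if class_label == "leukocyte"
        else params.tumor_intensities
    )
    means = {}
    for ch in ("DAPI", "AF488_tumor", "AF647_CD45"):
        med, sig, lo, hi = table[ch]
        means[ch] = float(_clipped_lognormal(rng, med, sig, lo, hi))
    if class_label == "leukocyte":
        for ch in ("CD74", "CD44"):
            med, sig, lo, hi = table[ch]
            means[ch] = float(_clipped_lognormal(rng, med, sig, lo, hi))
    else:
        m74, s74, lo74, hi74 = table["CD74"]
        m44, s44, lo44, hi44 = table["CD44"]
        cd74, cd44 = _correlated_lognormal(
            rng, 1, m74, s74, m44, s44, params.cd74_cd44_rho
        )
        means["CD74"] = float(np.clip(cd74[0], lo74, hi74))
        means["CD44"] = float(np.clip(cd44[0], lo44, hi44))
    return means


class _Placer:
    """Rejection-sampling placement with a clear-separation rule.

    Non-cluster entities are kept apart by at least one cell diameter of the
    larger partner (centre distance >= r_i + r_j + 2 max(r_i, r_j)).
    """

    def __init__(self, shape: tuple[int, int], max_retries: int):
        self.h, self.w = shape
        self.max_retries = max_retries
        self.xs: list[float] = []
        self.ys: list[float] = []
        self.rs: list[float] = []

    def place(self, rng: np.random.Generator, radius_px: float) -> tuple[float, float]:
        margin = radius_px + 2.0
        if 2 * margin >= min(self.h, self.w):
            raise PlacementError(
                f"cell of radius {radius_px:.1f} px does not fit the "
                f"{self.h}x{self.w} image"
            )
        xs = np.asarray(self.xs)
        ys = np.asarray(self.ys)
        rs = np.asarray(self.rs)
        for _ in range(self.max_retries):
            x = rng.uniform(margin, self.w - 1 - margin)
            y = rng.uniform(margin, self.h - 1 - margin)
            if len(xs):
                d2 = (xs - x) ** 2 + (ys - y) ** 2
                need = rs + radius_px + 2.0 * np.maximum(rs, radius_px)
                if np.any(d2 < need**2):
                    continue
            self.xs.append(x)
            self.ys.append(y)
            self.rs.append(radius_px)
            return x, y
        raise PlacementError(
            f"could not place a cell of radius {radius_px:.1f} px after "
            f"{self.max_retries} attempts; the requested density is infeasible "
            f"for a {self.h}x{self.w} image"
        )


def _disk_coords(cx: float, cy: float, r: float, shape: tuple[int, int]):
    """Pixel coordinates of the disk of radius r (px) centred at (cx, cy)."""
    h, w = shape
    r0 = max(int(math.floor(cy - r)) - 1, 0)
    r1 = min(int(math.ceil(cy + r)) + 2, h)
    c0 = max(int(math.floor(cx - r)) - 1, 0)
    c1 = min(int(math.ceil(cx + r)) + 2, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return yy[inside], xx[inside]


def _nucleus_centres(
    spec: CellSpec, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """(x, y, radius_px-free) nucleus geometry in um offsets from the centre."""
    r_um = spec.diameter_um / 2.0
    if spec.n_nuclei == 1:
        return [(0.0, 0.0, r_um * _NUCLEUS_FRAC_MONO)]
    phase = rng.uniform(0, 2 * math.pi)
    out = []
    for i in range(spec.n_nuclei):
        ang = phase + 2 * math.pi * i / spec.n_nuclei
        off = r_um * _NUCLEUS_OFFSET_MULTI
        out.append((off * math.cos(ang), off * math.sin(ang), r_um * _NUCLEUS_FRAC_MULTI))
    return out


def generate_cytospin(params: ImageParams | None = None, seed: int = 0) -> ImageGroundTruth:
    """Simulate one multi-channel cytospin slide with ground truth.

    Cells are placed largest-first by rejection sampling with a clear
    separation between non-cluster entities; cluster members are laid out as
    touching chains.  Each cell's body is painted with its planted channel
    means into the four cytoplasmic channels and its nuclei into DAPI, then
    i.i.d. Gaussian noise is added to every pixel.  Identical parameters and
    seed give bit-identical output.
    """
    params = params or ImageParams()
    params.validate()
    rng = np.random.default_rng(seed)
    h, w = params.shape

    # --- draw cell specs -------------------------------------------------
    singles: list[CellSpec] = []

    def draw_spec(label: str, idx: int, cluster_id: Optional[str] = None) -> CellSpec:
        mean, sd, lo, hi = params.diameter_params[label]
        diameter = float(_clipped_normal(rng, mean, sd, lo, hi))
        n_nuclei = 1
        if label == "multinucleated_cell":
            n_nuclei = int(rng.integers(2, 5))
        spec = CellSpec(
            cell_id=f"c{idx:04d}",
            class_label=label,
            centroid=(0.0, 0.0),
            diameter_um=diameter,
            n_nuclei=n_nuclei,
            cluster_id=cluster_id,
            channel_means=_draw_channel_means(rng, params, label),
        )
        return spec

    idx = 0
    for label, count in (
        ("large_cell", params.n_large),
        ("multinucleated_cell", params.n_multinucleated),
        ("classical_ctc", params.n_classical),
        ("leukocyte", params.n_leukocytes),
    ):
        for _ in range(count):
            singles.append(draw_spec(label, idx))
            idx += 1

    clusters: list[list[CellSpec]] = []
    for ci, size in enumerate(params.cluster_sizes):
        members = []
        for _ in range(size):
            members.append(draw_spec("cluster_member", idx, cluster_id=f"cl{ci:02d}"))
            idx += 1
        clusters.append(members)

    # --- placement -------------------------------------------------------
    px = params.pixel_size_um
    placer = _Placer((h, w), params.max_placement_retries)

    placed: list[CellSpec] = []
    # singles, largest first so big cells find room
    for spec in sorted(singles, key=lambda s: -s.diameter_um):
        r_px = spec.diameter_um / 2.0 / px
        x, y = placer.place(rng, r_px)
        placed.append(replace(spec, centroid=(x, y)))

    for members in clusters:
        # chain layout in local um coordinates, then place the chain as one blob
        local: list[tuple[float, float]] = [(0.0, 0.0)]
        heading = rng.uniform(0, 2 * math.pi)
        for prev, cur in zip(members, members[1:]):
            heading += rng.uniform(-math.pi / 3, math.pi / 3)
            step = _CLUSTER_CONTACT * (prev.diameter_um + cur.diameter_um) / 2.0
            lx, ly = local[-1]
            local.append((lx + step * math.cos(heading), ly + step * math.sin(heading)))
        radii = [m.diameter_um / 2.0 for m in members]
        cx = float(np.mean([p[0] for p in local]))
        cy = float(np.mean([p[1] for p in local]))
        blob_r_um = max(
            math.hypot(p[0] - cx, p[1] - cy) + r for p, r in zip(local, radii)
        )
        bx, by = placer.place(rng, blob_r_um / px)
        for m, (lx, ly) in zip(members, local):
            placed.append(
                replace(m, centroid=(bx + (lx - cx) / px, by + (ly - cy) / px))
            )

    for spec in placed:
        spec.validate()

    # --- painting --------------------------------------------------------
    image = np.full((len(CHANNELS), h, w), params.background_level, dtype=np.float32)
    truth = np.zeros((h, w), dtype=np.int32)
    nuc_labels = np.zeros((h, w), dtype=np.int32)
    dapi_idx = CHANNELS.index("DAPI")
    cyto_idx = [i for i in range(len(CHANNELS)) if i != dapi_idx]

    for i, spec in enumerate(placed):
        x, y = spec.centroid
        r_px = spec.diameter_um / 2.0 / px
        rows, cols = _disk_coords(x, y, r_px, (h, w))
        free = truth[rows, cols] == 0
        rows, cols = rows[free], cols[free]
        truth[rows, cols] = i + 1
        for c in cyto_idx:
            image[c, rows, cols] = spec.channel_means[CHANNELS[c]]
        for ox, oy, nr_um in _nucleus_centres(spec, rng):
            nrows, ncols = _disk_coords(x + ox / px, y + oy / px, nr_um / px, (h, w))
            own = truth[nrows, ncols] == i + 1
            nrows, ncols = nrows[own], ncols[own]
            image[dapi_idx, nrows, ncols] = spec.channel_means["DAPI"]
            nuc_labels[nrows, ncols] = i + 1

    # noise is left unclipped (like background-subtracted measurements) so
    # that planted-mask means stay unbiased even for near-zero channels
    if params.noise_sd > 0:
        noise = rng.standard_normal(image.shape, dtype=np.float32)
        image += params.noise_sd * noise

    return ImageGroundTruth(
        image=image,
        pixel_size_um=px,
        cells=placed,
        seed=seed,
        background_level=params.background_level,
        noise_sd=params.noise_sd,
        truth_labels=truth,
        nucleus_labels=nuc_labels,
        params=params,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Statistical structure of a synthetic patient cohort.

    Per-entity defaults mirror the cohort sizes, CTC positivity rates and
    count medians/ranges typical of brain-metastatic liquid-biopsy series:
    breast n=14 (median count 5, range 3-16), NSCLC n=18 (median 3, range
    1-19), melanoma n=11 (median 6.5, range 1-12).  Counts for positive
    patients are zero-truncated negative binomial; CD74/CD44 per-cell mean
    grey values are bivariate lognormal with the configured observed-scale
    Pearson correlation; survival times are exponential per CTC stratum with
    uniform censoring over the follow-up window.
    """

    entity: str = "breast"
    n_patients: int = 14
    ctc_prevalence: float = 0.5
    nb_mean: float = 6.0
    nb_size: float = 4.0
    cd74_cd44_rho: float = 0.9686
    # marker -> (median mgv, sigma on the log scale)
    expression_means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CD74": (45.0, 0.5), "CD44": (40.0, 0.5)}
    )
    metastasis_site_probs: dict[str, float] = field(
        default_factory=lambda: {
            "bone": 0.50,
            "liver": 0.22,
            "lung": 0.50,
            "lymph_node": 0.36,
            "other": 0.44,
            "oligo_brain": 0.22,
        }
    )
    receptor_probs: dict[str, float] = field(
        default_factory=lambda: {"ER": 8 / 14, "PR": 6 / 14, "HER2": 10 / 14}
    )
    # median overall survival (months) per CTC stratum, and follow-up window
    survival_median_neg: float = 24.0
    survival_median_pos: float = 14.0
    followup_months: float = 60.0
    seed: int = 0

    @classmethod
    def for_entity(cls, entity: str, **overrides) -> "CohortParams":
        presets = {
            "breast": {},
            "nsclc": dict(
                n_patients=18,
                ctc_prevalence=0.5,
                nb_mean=4.5,
                nb_size=1.2,
                receptor_probs={"EGFR": 1 / 18},
                metastasis_site_probs={
                    "bone": 1 / 18,
                    "liver": 1 / 18,
                    "lung": 1 / 18,
                    "lymph_node": 8 / 18,
                    "other": 3 / 18,
                    "oligo_brain": 15 / 18,
                },
                survival_median_neg=13.0,
                survival_median_pos=11.0,
            ),
            "melanoma": dict(
                n_patients=11,
                ctc_prevalence=4 / 11,
                nb_mean=7.0,
                nb_size=2.5,
                receptor_probs={"BRAF": 8 / 11},
                metastasis_site_probs={
                    "bone": 0.55,
                    "liver": 0.60,
                    "lung": 0.90,
                    "lymph_node": 0.90,
                    "other": 0.85,
                    "oligo_brain": 0.09,
                },
                survival_median_neg=30.0,
                survival_median_pos=9.0,
            ),
        }
        if entity not in presets:
            raise ValueError(f"unknown entity {entity!r}; expected one of {sorted(presets)}")
        kwargs = dict(presets[entity])
        kwargs.update(overrides)
        return cls(entity=entity, **kwargs)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.ctc_prevalence <= 1:
            raise ValueError("ctc_prevalence must be in [0, 1]")
        if abs(self.cd74_cd44_rho) > 1:
            raise ValueError("|cd74_cd44_rho| must be <= 1")
        if self.nb_mean <= 0 or self.nb_size <= 0:
            raise ValueError("negative-binomial parameters must be positive")
        for site, p in self.metastasis_site_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"site probability for {site} outside [0, 1]")
        for mk, (med, sig) in self.expression_means_sds.items():
            if med <= 0 or sig <= 0:
                raise ValueError(f"lognormal parameters for {mk} must be positive")
        if self.survival_median_neg <= 0 or self.survival_median_pos <= 0:
            raise ValueError("survival medians must be positive")


def _zero_truncated_nb(rng: np.random.Generator, mean: float, size: float) -> int:
    """One draw from a zero-truncated negative binomial (mean/size form)."""
    p = size / (size + mean)
    for _ in range(10_000):
        k = int(rng.negative_binomial(size, p))
        if k > 0:
            return k
    raise RuntimeError("zero-truncated draw failed; parameters degenerate")


def draw_marker_expression(
    params: CohortParams, n_cells: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-cell CD74/CD44 mean grey values with the configured correlation."""
    m74, s74 = params.expression_means_sds["CD74"]
    m44, s44 = params.expression_means_sds["CD44"]
    cd74, cd44 = _correlated_lognormal(
        rng, n_cells, m74, s74, m44, s44, params.cd74_cd44_rho
    )
    return pd.DataFrame({"mean_CD74": cd74, "mean_CD44": cd44})


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a patient cohort: patient table plus per-CTC marker table.

    Returns
    -------
    (patients, cells)
        ``patients`` has one row per patient: entity, CTC count, morphotype
        counts, positivity flags at both cut-offs, metastasis-site flags,
        receptor status, survival time and vital status.  ``cells`` has one
        row per CTC with correlated CD74/CD44 mean grey values.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ln2 = math.log(2.0)

    patients = []
    cell_rows = []
    for i in range(params.n_patients):
        pid = f"{params.entity[:2].upper()}{i + 1:03d}"
        positive = rng.random() < params.ctc_prevalence
        count = _zero_truncated_nb(rng, params.nb_mean, params.nb_size) if positive else 0

        # morphotype composition: classical-dominated, occasional large /
        # multinucleated cells and rare small clusters, never without a
        # classical CTC (large-only patients are not observed in practice)
        n_classical, n_large, n_multi, n_cluster = count, 0, 0, 0
        if count >= 2 and rng.random() < 0.10:
            n_large += 1
            n_classical -= 1
        if n_classical >= 2 and rng.random() < 0.10:
            n_multi += 1
            n_classical -= 1
        if n_classical >= 3 and rng.random() < 0.08:
            n_cluster += 2
            n_classical -= 2

        stratum_median = (
            params.survival_median_pos if positive else params.survival_median_neg
        )
        t_event = rng.exponential(stratum_median / ln2)
        t_cens = rng.uniform(0.5, params.followup_months)
        time = max(min(t_event, t_cens), 0.1)
        event = bool(t_event <= t_cens)

        row = {
            "patient_id": pid,
            "entity": params.entity,
            "ctc_count": count,
            "n_classical": n_classical,
            "n_large": n_large,
            "n_multinucleated": n_multi,
            "n_cluster_members": n_cluster,
            "ctc_positive_ge1": count >= 1,
            "ctc_positive_ge2": count >= 2,
            "survival_months": float(time),
            "event": event,
            "vital_status": "dead" if event else "alive",
        }
        for site, p in params.metastasis_site_probs.items():
            row[site] = bool(rng.random() < p)
        for receptor, p in params.receptor_probs.items():
            row[receptor] = bool(rng.random() < p)
        patients.append(row)

        if count > 0:
            markers = draw_marker_expression(params, count, rng)
            for j, mrow in markers.iterrows():
                cell_rows.append(
                    {
                        "patient_id": pid,
                        "cell_id": f"{pid}_ctc{j:03d}",
                        "mean_CD74": float(mrow["mean_CD74"]),
                        "mean_CD44": float(mrow["mean_CD44"]),
                    }
                )

    patients_df = pd.DataFrame(patients)
    cells_df = pd.DataFrame(
        cell_rows, columns=["patient_id", "cell_id", "mean_CD74", "mean_CD44"]
    )
    return patients_df, cells_df
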