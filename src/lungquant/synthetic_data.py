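"""Synthetic study-data generator with known ground truth.

Emulates the inputs of a 2x2 factorial mouse emphysema study (diet: CD vs
VDD, exposure: NS vs CSE; default 11 mice/group, 10 histology images per
mouse):

* H&E-like parenchyma images built from a Poisson-Voronoi septum phantom:
  cell nuclei points are sampled with an intensity matched to a target
  mean cell diameter, tissue is the band within half a septal thickness of
  a Voronoi edge, airspace is everything else.  Optional dark intra-
  airspace macrophage blobs (which two-class segmentation assigns to
  tissue, reproducing the macrophage confound on L_M) and sub-500-px white
  speckles on tissue (exercising the small-component filter).
* quasi-static PV loops from the Salazar-Knowles relation plus a closing
  hysteresis offset; complex impedance spectra from the constant-phase
  model; both with additive Gaussian noise.
* qPCR Ct tables with programmed per-group log2 fold-changes against the
  RPL13a housekeeping gene, and ordinal pathology scores drawn from
  per-group prevalences.

Every generator is deterministic for a fixed seed; cohort generation
derives one independent RNG stream per animal (and per image) from the
master seed by a counter scheme, so an animal can be regenerated without
replaying the whole cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy import ndimage
from scipy.spatial import cKDTree

from .mechanics import (
    ImpedanceSpectrum,
    PVLoop,
    constant_phase_impedance,
    salazar_knowles_volume,
)
from .morphometry import CalibratedImage, DEFAULT_PX_PER_MICRON

logger = logging.getLogger(__name__)

GROUPS = ("CD-NS", "CD-CSE", "VDD-NS", "VDD-CSE")
HOUSEKEEPING_GENE = "RPL13a"
GENES = ("MMP9", "TIMP1", "A1AT", HOUSEKEEPING_GENE)

# H&E-like palette (config defaults, not science).
AIRSPACE_RGB = np.array([247, 247, 247], dtype=np.uint8)
TISSUE_RGB = np.array([214, 143, 168], dtype=np.uint8)
# Dusty brown, darker than tissue but close enough in RGB that two-class
# clustering groups macrophages with tissue rather than pulling tissue into
# the airspace cluster.
MACROPHAGE_RGB = np.array([150, 105, 95], dtype=np.uint8)

PATHOLOGY_FEATURES = (
    "airway_inflammation",
    "parenchymal_inflammation",
    "pigmented_macrophages",
    "pneumocyte_hyperplasia",
)

#: Per-group presence probability of each pathology feature (defaults follow
#: the prevalences such a study reports: pigmented macrophages essentially
#: absent without smoke and frequent with it).
DEFAULT_PATHOLOGY_PREVALENCE: dict[str, dict[str, float]] = {
    "airway_inflammation": {"CD-NS": 0.44, "VDD-NS": 0.55, "CD-CSE": 0.0, "VDD-CSE": 0.36},
    "parenchymal_inflammation": {"CD-NS": 0.78, "VDD-NS": 0.73, "CD-CSE": 0.67, "VDD-CSE": 0.55},
    "pigmented_macrophages": {"CD-NS": 0.0, "VDD-NS": 0.18, "CD-CSE": 0.75, "VDD-CSE": 0.91},
    "pneumocyte_hyperplasia": {"CD-NS": 0.22, "VDD-NS": 0.45, "CD-CSE": 0.0, "VDD-CSE": 0.18},
}


class NoAirspaceError(Exception):
    """Raised when a mask contains no airspace chords at all."""


# ---------------------------------------------------------------------------
# Parenchyma phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParenchymaParams:
    """Geometry and rendering controls for one parenchyma image.

    Lengths are in micron; the raster is ``image_width`` x ``image_height``
    pixels at ``px_per_micron``.  ``target_cell_diameter`` sets the Voronoi
    point-process intensity (equivalent-circle diameter of the mean cell).
    """

    image_width: int = 1600
    image_height: int = 1200
    px_per_micron: float = DEFAULT_PX_PER_MICRON
    target_cell_diameter: float = 33.0  # micron
    septal_thickness: float = 3.5  # micron
    macrophage_count: int = 0
    macrophage_diameter: float = 12.0  # micron
    speckle_count: int = 0
    noise_sd: float = 6.0  # 8-bit intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.px_per_micron <= 0:
            raise ValueError("px_per_micron must be positive")
        for name in ("target_cell_diameter", "septal_thickness", "macrophage_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.macrophage_count < 0 or self.speckle_count < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.target_cell_diameter <= self.septal_thickness:
            raise ValueError("target_cell_diameter must exceed septal_thickness")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew, before confounders."""

    airspace_mask: np.ndarray  # bool, True = airspace, pre-macrophage/speckle
    true_mean_airspace_chord: float | None  # micron; None if no airspace
    true_airspace_fraction: float
    seed: int


@dataclass(frozen=True)
class ChordSummary:
    mean_um: float
    count: int


def measure_true_chords(mask: np.ndarray, px_per_micron: float) -> ChordSummary:
    """Exhaustive horizontal chord scan of a binary airspace mask.

    Every maximal horizontal run of airspace pixels in every pixel row is
    one chord; border-touching chords are included.  Returns the mean
    chord length in micron and the chord count.  An all-tissue mask has no
    chords and raises :class:`NoAirspaceError` rather than returning 0.
    """
    if px_per_micron <= 0:
        raise ValueError("px_per_micron must be positive")
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    padded = np.zeros((m.shape[0], m.shape[1] + 2), dtype=np.int8)
    padded[:, 1:-1] = m
    d = np.diff(padded, axis=1)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    if len(starts) == 0:
        raise NoAirspaceError("mask contains no airspace: chord mean undefined")
    lengths_px = ends - starts
    return ChordSummary(mean_um=float(lengths_px.mean() / px_per_micron),
                        count=int(len(lengths_px)))


def _disk_offsets(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = yy**2 + xx**2 <= radius_px**2
    return yy[inside], xx[inside]


def generate_parenchyma_image(
    params: ParenchymaParams,
) -> tuple[CalibratedImage, GroundTruth]:
    """Render one H&E-like parenchyma field with known airspace mask.

    Construction: cell centres are a Poisson point process whose intensity
    makes the mean Voronoi cell's equivalent-circle diameter equal the
    target; a pixel is tissue when its perpendicular distance to the
    bisector of its two nearest centres is at most half the septal
    thickness, airspace otherwise.  Macrophage blobs (dark, entirely
    inside airspaces) and white speckles (< 500 px, on tissue) are drawn
    into the rendered image only -- the ground-truth mask precedes them.
    Additive Gaussian pixel noise is clipped to [0, 255].
    """
    p = params
    if p.macrophage_diameter > p.target_cell_diameter:
        raise ValueError("macrophage_diameter exceeds target_cell_diameter: "
                         "blob cannot fit inside an airspace")
    rng = np.random.default_rng(p.seed)
    W, H = p.image_width, p.image_height
    ppm = p.px_per_micron

    # Poisson intensity: mean cell area 1/lambda = pi*(d/2)^2.
    area_um2 = (W * H) / ppm**2
    lam = 4.0 / (np.pi * p.target_cell_diameter**2)
    n_sites = max(int(rng.poisson(lam * area_um2)), 2)
    sites = rng.uniform([0.0, 0.0], [W, H], size=(n_sites, 2))

    xs = np.arange(W) + 0.5
    ys = np.arange(H) + 0.5
    px = np.column_stack(
        [np.tile(xs, H), np.repeat(ys, W)]
    )
    tree = cKDTree(sites)
    dist, idx = tree.query(px, k=2)
    s1 = sites[idx[:, 0]]
    s2 = sites[idx[:, 1]]
    pair = np.linalg.norm(s2 - s1, axis=1)
    # Exact perpendicular distance from the pixel to the bisector of its
    # two nearest sites: (d2^2 - d1^2) / (2*|s2 - s1|).
    edge_dist = (dist[:, 1] ** 2 - dist[:, 0] ** 2) / (2.0 * np.maximum(pair, 1e-12))
    septal_px = p.septal_thickness * ppm
    tissue = edge_dist <= septal_px / 2.0
    mask = ~tissue.reshape(H, W)  # True = airspace

    try:
        chords = measure_true_chords(mask, ppm)
        mean_chord: float | None = chords.mean_um
    except NoAirspaceError:
        mean_chord = None
    truth = GroundTruth(
        airspace_mask=mask,
        true_mean_airspace_chord=mean_chord,
        true_airspace_fraction=float(mask.mean()),
        seed=p.seed,
    )

    img = np.empty((H, W, 3), dtype=np.uint8)
    img[:] = TISSUE_RGB
    img[mask] = AIRSPACE_RGB

    # Macrophage blobs: centred at Voronoi sites (cell interiors), kept only
    # when the whole disk lies in airspace and inside the frame.
    if p.macrophage_count > 0:
        r_px = p.macrophage_diameter * ppm / 2.0
        dy, dx = _disk_offsets(r_px)
        placed = 0
        for j in rng.permutation(n_sites):
            if placed >= p.macrophage_count:
                break
            cx, cy = sites[j]
            cyi, cxi = int(round(cy)), int(round(cx))
            yy, xx = cyi + dy, cxi + dx
            if (yy.min() < 0 or xx.min() < 0 or yy.max() >= H or xx.max() >= W):
                continue
            if not mask[yy, xx].all():
                continue
            img[yy, xx] = MACROPHAGE_RGB
            placed += 1
        if placed < p.macrophage_count:
            logger.warning("placed only %d of %d macrophages", placed, p.macrophage_count)

    # White speckles: small disks fully inside tissue (area < 500 px by
    # construction; radius capped at 12 px).
    if p.speckle_count > 0:
        depth = ndimage.distance_transform_edt(~mask)  # distance to airspace
        placed = 0
        for _ in range(p.speckle_count * 50):
            if placed >= p.speckle_count:
                break
            cyi = int(rng.integers(0, H))
            cxi = int(rng.integers(0, W))
            fit = depth[cyi, cxi] - 1.0
            if fit < 1.0:
                continue
            r = float(min(fit, 12.0))
            if r > 1.0:
                r = float(rng.uniform(1.0, r))
            dy, dx = _disk_offsets(r)
            yy, xx = cyi + dy, cxi + dx
            keep = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
            img[yy[keep], xx[keep]] = AIRSPACE_RGB
            placed += 1
        if placed < p.speckle_count:
            logger.warning("placed only %d of %d speckles", placed, p.speckle_count)

    if p.noise_sd > 0:
        noisy = img.astype(np.float64) + rng.normal(0.0, p.noise_sd, size=img.shape)
        img = np.clip(noisy, 0, 255).round().astype(np.uint8)

    return CalibratedImage(pixels=img, px_per_micron=ppm), truth


# ---------------------------------------------------------------------------
# Mechanics generators
# ---------------------------------------------------------------------------

def generate_pv_loop(
    A: float,
    B: float,
    K: float,
    pressures: np.ndarray,
    hysteresis_offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PVLoop:
    """Salazar-Knowles PV loop with a closing hysteresis lobe.

    Deflation limb V(P) = A - B*exp(-K*P); the inflation limb sits below
    it by ``hysteresis_offset`` times a half-sine shape that vanishes at
    both pressure endpoints, so the loop closes.  Gaussian volume noise
    (sd in mL) is added to both limbs.
    """
    if not (A > B > 0):
        raise ValueError("require A > B > 0")
    if K <= 0:
        raise ValueError("require K > 0")
    P = np.asarray(pressures, dtype=float)
    if P.ndim != 1 or len(P) < 2 or np.any(np.diff(P) <= 0):
        raise ValueError("pressures must be a strictly ascending grid")
    rng = np.random.default_rng(seed)
    v_def = salazar_knowles_volume(P, A, B, K)
    span = P[-1] - P[0]
    shape = np.sin(np.pi * (P - P[0]) / span)
    v_inf = v_def - hysteresis_offset * shape
    if noise_sd > 0:
        v_def = v_def + rng.normal(0.0, noise_sd, size=len(P))
        v_inf = v_inf + rng.normal(0.0, noise_sd, size=len(P))
    return PVLoop(pressure=P, volume_inflation=v_inf, volume_deflation=v_def)


def generate_impedance(
    Rn: float,
    Iaw: float,
    G: float,
    H: float,
    freqs: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ImpedanceSpectrum:
    """Constant-phase impedance spectrum with complex Gaussian noise."""
    if G <= 0 or H <= 0:
        raise ValueError("G and H must be positive")
    f = np.asarray(freqs, dtype=float)
    Z = constant_phase_impedance(f, Rn, Iaw, G, H)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        Z = Z + rng.normal(0.0, noise_sd, len(f)) + 1j * rng.normal(0.0, noise_sd, len(f))
    return ImpedanceSpectrum(freqs=f, Z=Z)


def generate_single_compartment_record(
    R: float,
    C: float,
    P0: float,
    duration: float = 1.2,
    freq_hz: float = 2.5,
    tidal_volume: float = 0.2,
    n_samples: int = 300,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> "PerturbationRecord":
    """Sinusoidal volume drive through the single-compartment model.

    V(t) = (Vt/2)*(1 - cos(2*pi*f*t)), flow its derivative, pressure from
    P = R*flow + V/C + P0 plus Gaussian noise.
    """
    from .mechanics import PerturbationRecord

    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_samples)
    w = 2 * np.pi * freq_hz
    vol = 0.5 * tidal_volume * (1 - np.cos(w * t))
    flow = 0.5 * tidal_volume * w * np.sin(w * t)
    pressure = R * flow + vol / C + P0
    if noise_sd > 0:
        pressure = pressure + rng.normal(0.0, noise_sd, n_samples)
    return PerturbationRecord(time=t, pressure=pressure, flow=flow, volume=vol)


# ---------------------------------------------------------------------------
# Expression and pathology generators
# ---------------------------------------------------------------------------

DEFAULT_BASELINE_CT: dict[str, float] = {
    "MMP9": 26.0, "TIMP1": 24.0, "A1AT": 21.0, HOUSEKEEPING_GENE: 18.0,
}

#: Programmed per-group log2 fold-changes (vs the CD-NS baseline): the
#: combined-insult group shifts toward proteolysis (MMP9 up, TIMP1 and
#: A1AT down); smoke alone nudges MMP9.
DEFAULT_LOG2FC: dict[str, dict[str, float]] = {
    "MMP9": {"CD-NS": 0.0, "VDD-NS": 0.0, "CD-CSE": 0.5, "VDD-CSE": 0.8},
    "TIMP1": {"CD-NS": 0.0, "VDD-NS": 0.0, "CD-CSE": 0.0, "VDD-CSE": -1.0},
    "A1AT": {"CD-NS": 0.0, "VDD-NS": 0.0, "CD-CSE": 0.0, "VDD-CSE": -1.2},
}


def generate_ct_table(
    animals: pd.DataFrame,
    baseline_ct: Mapping[str, float] | None = None,
    log2fc: Mapping[str, Mapping[str, float]] | None = None,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table: Ct(gene, animal) = baseline - log2fc(gene, group) + noise.

    ``animals`` needs columns ``animal_id`` and ``group``.  The
    housekeeping gene's fold-change is fixed at 0 in every group.  Raises
    if the housekeeping gene is missing from the baseline table.
    """
    baseline = dict(baseline_ct) if baseline_ct is not None else dict(DEFAULT_BASELINE_CT)
    if HOUSEKEEPING_GENE not in baseline:
        raise ValueError(f"baseline Ct table must include {HOUSEKEEPING_GENE}")
    fc = {g: dict(v) for g, v in (log2fc or DEFAULT_LOG2FC).items()}
    fc[HOUSEKEEPING_GENE] = {}  # housekeeping never shifts
    rng = np.random.default_rng(seed)
    rows = []
    for _, animal in animals.iterrows():
        for gene, base in baseline.items():
            shift = fc.get(gene, {}).get(animal["group"], 0.0)
            ct = base - shift
            if ct_noise_sd > 0:
                ct += rng.normal(0.0, ct_noise_sd)
            rows.append({"animal_id": animal["animal_id"], "group": animal["group"],
                         "gene": gene, "ct": ct})
    return pd.DataFrame(rows)


def generate_pathology_scores(
    animals: pd.DataFrame,
    prevalence: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Ordinal pathology scores on the four-tier 0/1/2/3 scale.

    Presence is Bernoulli per animal per feature at the group's configured
    prevalence; present findings are mostly focal (score 1), sometimes 2,
    rarely 3, mirroring how such blinded reads skew low.
    """
    prev = prevalence or DEFAULT_PATHOLOGY_PREVALENCE
    rng = np.random.default_rng(seed)
    rows = []
    for _, animal in animals.iterrows():
        for feature, by_group in prev.items():
            p = by_group.get(animal["group"], 0.0)
            if rng.random() < p:
                score = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
            else:
                score = 0
            rows.append({"animal_id": animal["animal_id"], "group": animal["group"],
                         "feature": feature, "score": score,
                         "presence": int(score > 0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort design and full-bundle generation
# ---------------------------------------------------------------------------

#: Per-group morphometry targets (micron): the combined-insult group has
#: visibly larger airspaces; smoke alone adds intra-airspace macrophages,
#: which depress the measured (not the true) L_M.
DEFAULT_GROUP_PARENCHYMA: dict[str, dict[str, float | int]] = {
    "CD-NS": {"target_cell_diameter": 33.0, "macrophage_count": 0},
    "VDD-NS": {"target_cell_diameter": 33.5, "macrophage_count": 1},
    "CD-CSE": {"target_cell_diameter": 33.0, "macrophage_count": 8},
    "VDD-CSE": {"target_cell_diameter": 36.5, "macrophage_count": 5},
}

#: Per-group mechanics truth: smoke-exposed lungs are more compliant
#: (higher A hence TLC and Cst, lower tissue elastance H).
DEFAULT_GROUP_MECHANICS: dict[str, dict[str, float]] = {
    "CD-NS": {"A": 1.00, "B": 0.90, "K": 0.12, "Rn": 0.30, "Iaw": 0.005,
              "G": 4.5, "H": 24.0, "R": 0.55, "C": 0.045, "P0": 3.0},
    "VDD-NS": {"A": 1.02, "B": 0.92, "K": 0.12, "Rn": 0.30, "Iaw": 0.005,
               "G": 4.5, "H": 23.5, "R": 0.55, "C": 0.046, "P0": 3.0},
    "CD-CSE": {"A": 1.15, "B": 1.03, "K": 0.13, "Rn": 0.28, "Iaw": 0.005,
               "G": 4.0, "H": 20.0, "R": 0.50, "C": 0.055, "P0": 3.0},
    "VDD-CSE": {"A": 1.18, "B": 1.06, "K": 0.13, "Rn": 0.28, "Iaw": 0.005,
                "G": 3.9, "H": 19.0, "R": 0.50, "C": 0.057, "P0": 3.0},
}

DEFAULT_PV_PRESSURES = np.linspace(0.0, 30.0, 16)
DEFAULT_IMPEDANCE_FREQS = np.array(
    [1.0, 1.5, 2.5, 3.5, 5.5, 7.5, 9.5, 11.5, 13.5, 15.5, 17.5, 19.5, 20.5]
)


@dataclass(frozen=True)
class CohortDesign:
    """Study layout: 2x2 factorial groups, mice per group, images per mouse."""

    groups: tuple[str, ...] = GROUPS
    mice_per_group: int = 11
    images_per_mouse: int = 10
    parenchyma: ParenchymaParams = field(default_factory=ParenchymaParams)
    group_parenchyma: Mapping[str, Mapping[str, float | int]] = field(
        default_factory=lambda: DEFAULT_GROUP_PARENCHYMA
    )
    group_mechanics: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_GROUP_MECHANICS
    )
    pv_noise_sd: float = 0.004  # mL
    impedance_noise_sd: float = 0.01  # cmH2O.s/mL
    snapshot_noise_sd: float = 0.05  # cmH2O
    ct_noise_sd: float = 0.4  # cycles
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.mice_per_group < 1 or self.images_per_mouse < 1:
            raise ValueError("mice_per_group and images_per_mouse must be >= 1")
        for g in self.groups:
            diet, smoke = split_group_label(g)

    def animal_table(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            diet, smoke = split_group_label(g)
            for m in range(self.mice_per_group):
                rows.append({"animal_id": f"{g}-m{m+1:02d}", "group": g,
                             "diet": diet, "smoke": smoke})
        return pd.DataFrame(rows)

    def parenchyma_for(self, group: str, seed: int) -> ParenchymaParams:
        overrides = dict(self.group_parenchyma.get(group, {}))
        return replace(self.parenchyma, seed=seed, **overrides)


def split_group_label(group: str) -> tuple[str, str]:
    """'VDD-CSE' -> ('VDD', 'CSE'); validates both factor levels."""
    try:
        diet, smoke = group.split("-")
    except ValueError as exc:
        raise ValueError(f"group label {group!r} is not DIET-SMOKE") from exc
    if diet not in ("CD", "VDD") or smoke not in ("NS", "CSE"):
        raise ValueError(f"group label {group!r} has unknown factor levels")
    return diet, smoke


def derive_seed(master_seed: int, *counters: int) -> int:
    """Counter-scheme child seed, stable and independent of cohort order."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(counters))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def iter_cohort_images(
    design: CohortDesign,
) -> Iterator[tuple[str, str, int, CalibratedImage, GroundTruth]]:
    """Yield (animal_id, group, image_index, image, truth) for the cohort.

    Image seeds derive from (master_seed, group_index, mouse_index,
    image_index), so any single image is reproducible in isolation.
    """
    for gi, g in enumerate(design.groups):
        for m in range(design.mice_per_group):
            animal_id = f"{g}-m{m+1:02d}"
            for k in range(design.images_per_mouse):
                seed = derive_seed(design.master_seed, gi, m, k)
                params = design.parenchyma_for(g, seed)
                image, truth = generate_parenchyma_image(params)
                yield animal_id, g, k, image, truth


def generate_cohort(design: CohortDesign, out_dir: str | Path) -> Path:
    """Write a full on-disk study bundle and return its directory.

    Layout: ``design.csv``, ``images/<animal>_img<k>.png``,
    ``mechanics/<animal>_{pv,impedance,timeseries}.csv``,
    ``expression.csv``, ``pathology.csv`` and a ``manifest.yaml`` holding
    the calibration, every derived seed and the per-group truth.  Two runs
    with the same design are byte-identical.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "mechanics").mkdir(parents=True, exist_ok=True)

    animals = design.animal_table()
    if animals["animal_id"].duplicated().any():
        raise ValueError("duplicate animal identifiers in design")
    animals.to_csv(out / "design.csv", index=False)

    manifest: dict = {
        "master_seed": design.master_seed,
        "px_per_micron": design.parenchyma.px_per_micron,
        "groups": list(design.groups),
        "mice_per_group": design.mice_per_group,
        "images_per_mouse": design.images_per_mouse,
        "truth": {
            "parenchyma": {g: dict(design.group_parenchyma.get(g, {}))
                           for g in design.groups},
            "mechanics": {g: dict(design.group_mechanics.get(g, {}))
                          for g in design.groups},
        },
        "image_seeds": {},
        "animal_seeds": {},
    }

    n_images = 0
    for animal_id, g, k, image, truth in iter_cohort_images(design):
        fname = f"{animal_id}_img{k:02d}.png"
        Image.fromarray(image.pixels).save(out / "images" / fname)
        manifest["image_seeds"][fname] = int(truth.seed)
        n_images += 1

    for gi, g in enumerate(design.groups):
        mech = design.group_mechanics.get(g, DEFAULT_GROUP_MECHANICS["CD-NS"])
        for m in range(design.mice_per_group):
            animal_id = f"{g}-m{m+1:02d}"
            seed = derive_seed(design.master_seed, 1000 + gi, m)
            manifest["animal_seeds"][animal_id] = seed

            loop = generate_pv_loop(
                mech["A"], mech["B"], mech["K"], DEFAULT_PV_PRESSURES,
                hysteresis_offset=0.06, noise_sd=design.pv_noise_sd, seed=seed,
            )
            pd.DataFrame({
                "pressure": np.concatenate([loop.pressure, loop.pressure[::-1]]),
                "volume": np.concatenate([loop.volume_inflation,
                                          loop.volume_deflation[::-1]]),
                "limb": ["inflation"] * len(loop.pressure)
                        + ["deflation"] * len(loop.pressure),
            }).to_csv(out / "mechanics" / f"{animal_id}_pv.csv", index=False)

            spec = generate_impedance(
                mech["Rn"], mech["Iaw"], mech["G"], mech["H"],
                DEFAULT_IMPEDANCE_FREQS,
                noise_sd=design.impedance_noise_sd, seed=seed + 1,
            )
            pd.DataFrame({
                "freq": spec.freqs, "z_real": spec.Z.real, "z_imag": spec.Z.imag,
            }).to_csv(out / "mechanics" / f"{animal_id}_impedance.csv", index=False)

            rec = generate_single_compartment_record(
                mech["R"], mech["C"], mech["P0"],
                noise_sd=design.snapshot_noise_sd, seed=seed + 2,
            )
            pd.DataFrame({
                "time": rec.time, "pressure": rec.pressure,
                "flow": rec.flow, "volume": rec.volume,
            }).to_csv(out / "mechanics" / f"{animal_id}_timeseries.csv", index=False)

    ct = generate_ct_table(animals, ct_noise_sd=design.ct_noise_sd,
                           seed=derive_seed(design.master_seed, 2000))
    ct.to_csv(out / "expression.csv", index=False)

    scores = generate_pathology_scores(animals,
                                       seed=derive_seed(design.master_seed, 3000))
    scores.to_csv(out / "pathology.csv", index=False)

    manifest["n_images"] = n_images
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out
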