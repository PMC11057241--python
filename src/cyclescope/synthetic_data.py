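"""Synthetic multi-channel plate simulator with per-nucleus ground truth.

Real acquisitions of this assay (DNA stain + two Fucci reporter channels
on a high-content imager) are rarely shareable, so the simulator
generates fields that embody the statistical structure the downstream
analysis assumes:

* DNA-channel integrated intensity proportional to DNA content (2N-4N)
  and projected nuclear area proportional to content^(2/3), so intensity
  and size carry cell-cycle signal;
* Fucci channel means placed on the correct side of the gating
  thresholds for the nucleus's true phase, with a safety margin of at
  least 20% of the threshold before multiplicative reporter noise;
* apoptotic nuclei rendered as bright chromatin fragments inside one
  footprint, giving DNA-channel coefficients of variation above the 70%
  exclusion cutoff;
* per-condition cell-cycle distributions that shift with drug exposure
  (e.g. S/G2/M accumulation under an antimetabolite, G1 arrest under a
  PI3K inhibitor);
* Poisson shot noise, Gaussian read noise and a smooth parabolic
  illumination background per channel.

Every stochastic choice flows from one ``numpy.random.default_rng`` seed,
so outputs are byte-identical across runs for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .gating import FucciGatingConfig, gate

__all__ = [
    "CellState",
    "ConditionPreset",
    "FieldGeometry",
    "NoiseParams",
    "TruthNucleus",
    "ImageField",
    "PlacementError",
    "sample_population",
    "render_field",
    "simulate_plate",
    "default_presets",
    "CHANNEL_ROLES",
]

CHANNEL_ROLES = ("dna", "red", "green")

#: cycle phases the simulator can assign (apoptotic is not a cycle class)
SIM_PHASES = ("G1", "earlyS", "SG2M", "DN", "apoptotic")

#: DNA content interval (N-genome equivalents) per phase
_CONTENT_RANGE = {
    "G1": (2.0, 2.0),
    "earlyS": (2.0, 2.5),
    "SG2M": (2.5, 4.0),
    "DN": (2.0, 4.0),  # double-negative nuclei span the full range
    "apoptotic": (2.0, 4.0),
}


class PlacementError(RuntimeError):
    """Raised when a field cannot accommodate the requested nucleus count."""


class ConfigurationError(ValueError):
    """Raised for invalid simulator configuration."""


@dataclass(frozen=True)
class CellState:
    """True state of one simulated cell: phase plus DNA content (2N-4N)."""

    phase: str
    dna_content: float

    def __post_init__(self) -> None:
        if self.phase not in SIM_PHASES:
            raise ConfigurationError(f"unknown phase: {self.phase!r}")
        lo, hi = _CONTENT_RANGE[self.phase]
        if not (lo - 1e-9 <= self.dna_content <= hi + 1e-9):
            raise ConfigurationError(
                f"dna_content {self.dna_content} outside [{lo}, {hi}] "
                f"for phase {self.phase}")

    @property
    def apoptotic(self) -> bool:
        return self.phase == "apoptotic"


@dataclass(frozen=True)
class ConditionPreset:
    """One experimental condition: cell line, drug, dose and cycle mix.

    ``phase_probs`` is the (G1, earlyS, SG2M, DN) distribution among
    viable nuclei; ``apoptotic_frac`` is the probability that a cell is
    apoptotic instead of belonging to any cycle class.
    """

    cell_line: str
    drug: str
    concentration_m: float
    phase_probs: tuple[float, float, float, float]
    apoptotic_frac: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.phase_probs, dtype=float)
        if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "phase_probs must be 4 non-negative values summing to 1")
        if not 0.0 <= self.apoptotic_frac <= 1.0:
            raise ConfigurationError("apoptotic_frac must be in [0, 1]")
        if self.concentration_m != 0.0 and not (
                1e-10 - 1e-16 <= self.concentration_m <= 1e-4 + 1e-10):
            raise ConfigurationError(
                "concentration must be 0 (control) or within [1e-10, 1e-4] M")

    @property
    def label(self) -> str:
        return self.name or f"{self.cell_line}_{self.drug}"


@dataclass(frozen=True)
class FieldGeometry:
    """Field raster size and nucleus size/placement parameters.

    Defaults emulate a 10x high-content acquisition downsampled to a
    512 x 512 16-bit raster: nucleus equivalent diameters fall in the
    15-25 px range and about a hundred nuclei fit per field without
    overlap.
    """

    width: int = 512
    height: int = 512
    pixel_size_um: float = 0.66
    base_area_px: float = 230.0     # truth-mask area at dna_content = 2
    dna_counts_2n: float = 340_000.0  # integrated DNA counts of a 2N nucleus
    axis_ratio_max: float = 1.35
    placement_margin_px: float = 3.0
    border_margin_px: float = 4.0
    max_placement_tries: int = 500


@dataclass(frozen=True)
class NoiseParams:
    """All stochastic nuisance parameters of the renderer.

    ``area_sigma`` / ``stain_sigma`` are log-normal sigmas of the
    per-nucleus area and staining factors; ``fucci_sigma`` is the
    log-normal sigma of reporter brightness around its gate-consistent
    target (the default gives roughly 2% of nuclei crossing a gating
    threshold); ``texture_amp`` scales band-passed chromatin texture.
    Backgrounds are (base, amplitude) of a smooth parabolic profile in
    camera counts.
    """

    area_sigma: float = 0.08
    stain_sigma: float = 0.10
    fucci_sigma: float = 0.15
    texture_amp: float = 0.35
    shot_noise: bool = True
    read_noise_sd: float = 3.0
    dna_background: tuple[float, float] = (40.0, 80.0)
    fucci_background: tuple[float, float] = (4.0, 8.0)

    @classmethod
    def none(cls) -> "NoiseParams":
        """Fully deterministic rendering: no noise of any kind."""
        return cls(area_sigma=0.0, stain_sigma=0.0, fucci_sigma=0.0,
                   texture_amp=0.0, shot_noise=False, read_noise_sd=0.0,
                   dna_background=(0.0, 0.0), fucci_background=(0.0, 0.0))


@dataclass
class TruthNucleus:
    """Ground truth for one rendered nucleus."""

    nucleus_id: int
    state: CellState
    bbox: tuple[int, int, int, int]          # (row0, col0, row1, col1)
    mask: np.ndarray                          # bool, bbox-local
    centroid: tuple[float, float]             # (row, col)
    red_mean: float                           # rendered Fucci target means
    green_mean: float


@dataclass
class ImageField:
    """One simulated multi-channel field plus its ground truth."""

    pixels: np.ndarray            # (3, H, W) uint16; order: dna, red, green
    pixel_size_um: float
    well_id: str
    truth: list[TruthNucleus] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def channel(self, role: str) -> np.ndarray:
        return self.pixels[CHANNEL_ROLES.index(role)]


def sample_population(preset: ConditionPreset, n_cells: int,
                      seed: int | np.random.Generator = 0) -> list[CellState]:
    """Draw ``n_cells`` i.i.d. cell states for one condition.

    A cell is apoptotic with probability ``preset.apoptotic_frac``;
    otherwise its phase is drawn from ``preset.phase_probs`` and its DNA
    content uniformly within the phase's content interval.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    phases = np.array(["G1", "earlyS", "SG2M", "DN"])
    states: list[CellState] = []
    for _ in range(n_cells):
        if rng.random() < preset.apoptotic_frac:
            phase = "apoptotic"
        else:
            phase = str(rng.choice(phases, p=np.asarray(preset.phase_probs)))
        lo, hi = _CONTENT_RANGE[phase]
        content = lo if lo == hi else float(rng.uniform(lo, hi))
        states.append(CellState(phase=phase, dna_content=content))
    return states


# ---------------------------------------------------------------------------
# rendering


def _ellipse_params(state: CellState, geom: FieldGeometry,
                    noise: NoiseParams, rng: np.random.Generator):
    """Semi-axes (a >= b) and orientation for one nucleus footprint."""
    area = geom.base_area_px * (state.dna_content / 2.0) ** (2.0 / 3.0)
    if noise.area_sigma > 0:
        area *= float(np.exp(rng.normal(0.0, noise.area_sigma)))
    q = float(rng.uniform(1.0, geom.axis_ratio_max))
    a = np.sqrt(area * q / np.pi)
    b = np.sqrt(area / (np.pi * q))
    phi = float(rng.uniform(0.0, np.pi))
    return a, b, phi


def _place_centers(radii: Sequence[float], geom: FieldGeometry,
                   rng: np.random.Generator) -> list[tuple[float, float]]:
    """Dart-throwing placement of non-overlapping circumscribed circles."""
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii:
        lo_r = r + geom.border_margin_px
        hi_row = geom.height - lo_r
        hi_col = geom.width - lo_r
        if hi_row <= lo_r or hi_col <= lo_r:
            raise PlacementError("field smaller than a single nucleus")
        for _ in range(geom.max_placement_tries):
            row = rng.uniform(lo_r, hi_row)
            col = rng.uniform(lo_r, hi_col)
            ok = True
            for (rr, cc), rj in zip(centers, placed_r):
                if (row - rr) ** 2 + (col - cc) ** 2 < (
                        r + rj + geom.placement_margin_px) ** 2:
                    ok = False
                    break
            if ok:
                centers.append((row, col))
                placed_r.append(r)
                break
        else:
            raise PlacementError(
                f"could not place nucleus {len(centers)} of {len(radii)}; "
                "field too crowded")
    return centers


def _fucci_targets(phase: str, ref: FucciGatingConfig, noise: NoiseParams,
                   rng: np.random.Generator) -> tuple[float, float]:
    """Gate-consistent (red, green) mean targets with >= 20% threshold margin.

    The deterministic target sits in a log-uniform band at least 30%
    away from the threshold; multiplicative log-normal reporter noise
    (``fucci_sigma``) then produces a small, controllable rate of
    boundary crossing.  Apoptotic nuclei lose both reporters.
    """
    def above(thr: float) -> float:
        return thr * float(np.exp(rng.uniform(np.log(1.3), np.log(2.4))))

    def below(thr: float) -> float:
        return thr * float(np.exp(rng.uniform(np.log(0.15), np.log(0.72))))

    red_thr, green_thr = ref.red_threshold, ref.green_threshold
    if phase == "G1":
        red, green = above(red_thr), below(green_thr)
    elif phase == "earlyS":
        red, green = above(red_thr), above(green_thr)
    elif phase == "SG2M":
        red, green = below(red_thr), above(green_thr)
    else:  # DN and apoptotic
        red, green = below(red_thr), below(green_thr)
    if noise.fucci_sigma > 0:
        red *= float(np.exp(rng.normal(0.0, noise.fucci_sigma)))
        green *= float(np.exp(rng.normal(0.0, noise.fucci_sigma)))
    return red, green


def _texture(shape: tuple[int, int], sigma: float,
             rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-passed Gaussian noise (chromatin texture)."""
    white = rng.normal(size=shape)
    band = ndi.gaussian_filter(white, sigma) - ndi.gaussian_filter(
        white, 2.0 * sigma)
    sd = band.std()
    return band / sd if sd > 0 else band


def _render_viable(state, a, b, phi, total_counts, texture_amp, rng):
    """DNA footprint of one viable nucleus on a local bbox grid.

    Returns (profile image, truth mask).  The radial profile is flat in
    the interior with a soft rim; chromatin texture is band-passed noise
    whose grain coarsens with DNA content (chromatin condenses as the
    cell progresses toward division), so texture features carry cycle
    signal through the same latent variable as intensity and area.
    """
    half = int(np.ceil(a)) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    c, s = np.cos(phi), np.sin(phi)
    u = (c * xx + s * yy) / a
    v = (-s * xx + c * yy) / b
    rho2 = u * u + v * v
    rho = np.sqrt(rho2)
    profile = np.clip((1.05 - rho) / 0.15, 0.0, 1.0)  # flat core, soft rim
    mask = rho <= 0.95
    if texture_amp > 0:
        sigma_tex = 0.5 * state.dna_content  # 1 px at 2N -> 2 px at 4N
        tex = _texture(profile.shape, sigma_tex, rng)
        profile = profile * np.clip(1.0 + texture_amp * tex, 0.05, None)
    ssum = profile.sum()
    if ssum > 0:
        profile *= total_counts / ssum
    return profile, mask


def _render_apoptotic(a, total_counts, rng):
    """Fragmented apoptotic nucleus: 3-6 bright blobs in one footprint.

    Concentrating the chromatin into fragments leaves most footprint
    pixels dark, so the DNA-channel CV over the footprint exceeds the
    70% apoptotic-exclusion cutoff.
    """
    half = int(np.ceil(a)) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    rho = np.sqrt(xx * xx + yy * yy) / a
    mask = rho <= 0.95
    n_frag = int(rng.integers(3, 7))
    frag_r = a / 3.4
    profile = np.zeros_like(rho)
    for _ in range(n_frag):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.0, 0.62) * a
        fy, fx = rad * np.sin(ang), rad * np.cos(ang)
        d2 = (yy - fy) ** 2 + (xx - fx) ** 2
        blob = np.exp(-d2 / (2 * (frag_r / 1.6) ** 2))
        profile += blob * float(rng.uniform(0.7, 1.3))
    profile[~mask] = 0.0
    profile[profile < 0.05 * profile.max()] = 0.0  # hard dark gaps
    ssum = profile.sum()
    if ssum > 0:
        profile *= total_counts / ssum
    return profile, mask


def _parabolic_background(shape: tuple[int, int], base: float, amp: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Smooth parabolic illumination profile with a jittered apex."""
    if base == 0.0 and amp == 0.0:
        return np.zeros(shape)
    h, w = shape
    cy = rng.uniform(0.3, 0.7) * h
    cx = rng.uniform(0.3, 0.7) * w
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    r2 = ((yy - cy) / h) ** 2 + ((xx - cx) / w) ** 2
    return base + amp * np.clip(1.0 - r2, 0.0, None)


def render_field(states: Sequence[CellState],
                 geometry: FieldGeometry | None = None,
                 noise: NoiseParams | None = None,
                 gating_ref: FucciGatingConfig | None = None,
                 seed: int | np.random.Generator = 0,
                 well_id: str = "A01") -> ImageField:
    """Render one 3-channel field (DNA, red Fucci, green Fucci).

    Nuclei are placed without overlap; each viable nucleus is a textured
    ellipse whose integrated DNA intensity is proportional to its DNA
    content (times a log-normal staining factor) and whose area scales
    as content^(2/3).  Fucci channels are filled with gate-consistent
    means so that thresholding recovers the true phase.  Apoptotic
    nuclei are rendered as chromatin fragments.  Shot noise, read noise
    and a parabolic background are then added per channel.
    """
    geom = geometry or FieldGeometry()
    noise = noise or NoiseParams()
    ref = gating_ref or FucciGatingConfig.for_cell_line("HeLa")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    shape = (geom.height, geom.width)
    signal = np.zeros((3,) + shape, dtype=float)

    params = [_ellipse_params(st, geom, noise, rng) for st in states]
    centers = _place_centers([p[0] for p in params], geom, rng)

    truth: list[TruthNucleus] = []
    for nid, (st, (a, b, phi), (crow, ccol)) in enumerate(
            zip(states, params, centers), start=1):
        total = geom.dna_counts_2n * st.dna_content / 2.0
        if noise.stain_sigma > 0:
            total *= float(np.exp(rng.normal(0.0, noise.stain_sigma)))
        if st.apoptotic:
            profile, mask = _render_apoptotic(a, total, rng)
        else:
            profile, mask = _render_viable(
                st, a, b, phi, total, noise.texture_amp, rng)
        red, green = _fucci_targets(st.phase, ref, noise, rng)

        half = profile.shape[0] // 2
        r0 = int(round(crow)) - half
        c0 = int(round(ccol)) - half
        r1, c1 = r0 + profile.shape[0], c0 + profile.shape[1]
        sr0, sc0 = max(r0, 0), max(c0, 0)
        sr1, sc1 = min(r1, geom.height), min(c1, geom.width)
        lr0, lc0 = sr0 - r0, sc0 - c0
        lr1, lc1 = lr0 + (sr1 - sr0), lc0 + (sc1 - sc0)
        sub = np.s_[sr0:sr1, sc0:sc1]
        loc = np.s_[lr0:lr1, lc0:lc1]

        signal[0][sub] += profile[loc]
        # Fucci fill: flat over the footprint with the same soft rim, so
        # the mean over the truth mask equals the drawn target exactly
        hh = profile.shape[0]
        yy, xx = np.mgrid[0:hh, 0:hh].astype(float) - half
        if st.apoptotic:
            rho = np.sqrt(yy * yy + xx * xx) / a
        else:
            c_, s_ = np.cos(phi), np.sin(phi)
            u = (c_ * xx + s_ * yy) / a
            v = (-s_ * xx + c_ * yy) / b
            rho = np.sqrt(u * u + v * v)
        fucci_support = np.where(rho <= 0.95, 1.0,
                                 np.clip((1.05 - rho) / 0.10, 0.0, 1.0))
        signal[1][sub] += red * fucci_support[loc]
        signal[2][sub] += green * fucci_support[loc]

        mloc = mask[loc]
        rows, cols = np.nonzero(mloc)
        if rows.size == 0:
            continue
        br0, bc0 = sr0 + rows.min(), sc0 + cols.min()
        br1, bc1 = sr0 + rows.max() + 1, sc0 + cols.max() + 1
        truth.append(TruthNucleus(
            nucleus_id=nid, state=st,
            bbox=(br0, bc0, br1, bc1),
            mask=mloc[rows.min():rows.max() + 1, cols.min():cols.max() + 1],
            centroid=(sr0 + rows.mean(), sc0 + cols.mean()),
            red_mean=red, green_mean=green))

    bgs = [noise.dna_background, noise.fucci_background,
           noise.fucci_background]
    out = np.empty_like(signal)
    for ch, (base, amp) in enumerate(bgs):
        img = signal[ch] + _parabolic_background(shape, base, amp, rng)
        if noise.shot_noise:
            img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0.0, noise.read_noise_sd, size=shape)
        out[ch] = img
    pixels = np.clip(np.rint(out), 0, 65535).astype(np.uint16)

    return ImageField(pixels=pixels, pixel_size_um=geom.pixel_size_um,
                      well_id=well_id, truth=truth)


# ---------------------------------------------------------------------------
# condition presets and plate simulation

# (G1, earlyS, SG2M, DN) mixes and apoptotic fractions per condition.
# Control mixes follow typical asynchronous cultures; high-dose mixes are
# qualitative translations of the expected pharmacology: S/G2/M
# accumulation under 5-FU and SN-38 in HeLa, G1 arrest under ZSTK474 in
# MCF7, heavy apoptosis under staurosporine.
_PRESET_TABLE: dict[str, list[tuple[str, float, tuple, float]]] = {
    "HeLa": [
        ("control", 0.0, (0.50, 0.08, 0.36, 0.06), 0.02),
        ("5-FU", 1e-5, (0.18, 0.10, 0.66, 0.06), 0.06),
        ("SN-38", 1e-6, (0.15, 0.08, 0.71, 0.06), 0.08),
        ("selumetinib", 1e-5, (0.58, 0.06, 0.30, 0.06), 0.03),
        ("staurosporine", 1e-6, (0.40, 0.06, 0.40, 0.14), 0.30),
        ("ZSTK474", 1e-5, (0.54, 0.07, 0.33, 0.06), 0.04),
    ],
    "MCF7": [
        ("control", 0.0, (0.55, 0.07, 0.31, 0.07), 0.06),
        ("5-FU", 1e-5, (0.50, 0.09, 0.34, 0.07), 0.10),
        ("SN-38", 1e-6, (0.48, 0.08, 0.37, 0.07), 0.12),
        ("selumetinib", 1e-5, (0.62, 0.05, 0.26, 0.07), 0.06),
        ("staurosporine", 1e-6, (0.50, 0.05, 0.31, 0.14), 0.32),
        ("ZSTK474", 1e-5, (0.78, 0.04, 0.11, 0.07), 0.06),
    ],
}


def default_presets(cell_line: str = "HeLa") -> list[ConditionPreset]:
    """Built-in condition presets: control plus one high dose per drug."""
    if cell_line not in _PRESET_TABLE:
        raise ConfigurationError(f"unknown cell line: {cell_line!r}")
    presets = []
    for drug, conc, probs, apop in _PRESET_TABLE[cell_line]:
        presets.append(ConditionPreset(
            cell_line=cell_line, drug=drug, concentration_m=conc,
            phase_probs=probs, apoptotic_frac=apop,
            name=f"{cell_line}_{drug}" + ("" if conc == 0.0 else "_high")))
    return presets


def get_preset(cell_line: str, drug: str) -> ConditionPreset:
    """Look up a built-in preset by cell line and drug name."""
    for p in default_presets(cell_line):
        if p.drug == drug:
            return p
    raise KeyError(f"no preset for {cell_line}/{drug}")


def simulate_plate(presets: Sequence[ConditionPreset],
                   fields_per_condition: int,
                   out_dir: str | Path,
                   seed: int = 0,
                   nuclei_per_field: int = 100,
                   geometry: FieldGeometry | None = None,
                   noise: NoiseParams | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and write a plate experiment to ``out_dir``.

    Writes one multi-page TIFF per field (page order: DNA, red, green)
    with a sidecar JSON of channel roles and pixel size, plus
    ``metadata.csv`` (field_id, well, cell_line, drug, concentration_M)
    and ``truth.csv`` (field_id, nucleus_id, phase, dna_content,
    centroid_x, centroid_y; 0-based, x = column).  Returns the two
    tables.  Reproducible for a fixed seed.
    """
    if not presets:
        raise ConfigurationError("presets must be non-empty")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    geom = geometry or FieldGeometry()
    noise = noise or NoiseParams()

    meta_rows, truth_rows = [], []
    for ci, preset in enumerate(presets):
        ref = FucciGatingConfig.for_cell_line(preset.cell_line)
        well = f"{chr(ord('A') + ci % 16)}{ci // 16 + 1:02d}"
        for fi in range(fields_per_condition):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, ci, fi]))
            states = sample_population(preset, nuclei_per_field, rng)
            fld = render_field(states, geom, noise, ref, rng, well_id=well)
            field_id = f"{preset.label}_f{fi:03d}"
            tif_path = out / f"{field_id}.tiff"
            tifffile.imwrite(tif_path, fld.pixels,
                             photometric="minisblack",
                             metadata={"axes": "CYX"})
            sidecar = {"channel_roles": list(CHANNEL_ROLES),
                       "pixel_size_um": geom.pixel_size_um,
                       "well_id": well, "field_id": field_id}
            (out / f"{field_id}.json").write_text(
                json.dumps(sidecar, indent=1))
            meta_rows.append({
                "field_id": field_id, "well": well,
                "cell_line": preset.cell_line, "drug": preset.drug,
                "concentration_M": preset.concentration_m})
            for t in fld.truth:
                truth_rows.append({
                    "field_id": field_id, "nucleus_id": t.nucleus_id,
                    "phase": t.state.phase,
                    "dna_content": t.state.dna_content,
                    "centroid_x": t.centroid[1], "centroid_y": t.centroid[0]})
    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    metadata.to_csv(out / "metadata.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    return metadata, truth


def load_field(tiff_path: str | Path) -> ImageField:
    """Read a simulated field (TIFF + sidecar JSON) back from disk."""
    tiff_path = Path(tiff_path)
    pixels = tifffile.imread(tiff_path)
    sidecar = json.loads(tiff_path.with_suffix(".json").read_text())
    return ImageField(pixels=pixels,
                      pixel_size_um=float(sidecar["pixel_size_um"]),
                      well_id=sidecar.get("well_id", ""),
                      metadata=sidecar)


def gate_truth(fld: ImageField, ref: FucciGatingConfig) -> list[str]:
    """Gate each truth nucleus by its rendered Fucci target means."""
    return [gate(t.red_mean, t.green_mean, ref) for t in fld.truth]
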