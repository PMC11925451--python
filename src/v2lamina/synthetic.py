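"""Synthetic cortical patches, stripe maps, block designs and BOLD data.

The generator plants, on an abstract 2D cortical sheet x depth grid, every
structure the downstream analyses assume:

* four retinotopic areas (V1, V2, V3ab, V4), each a rectangular grid of
  cortical columns with three depth samples per column placed at
  equal-volume fractions (so the equi-volume depth formula is exercised
  whenever the sheet is "curved", i.e. inner and outer surface-area
  elements differ);
* interdigitated thin/pale/thick/pale stripe compartments in V2, constant
  along v (perpendicular to the V1-V2 border at v = 0) and periodic along u;
* condition-pair block designs (24 s blocks, lead/trail fixation);
* depth-dependent gain with a pial (vein) bias, plus a small set of
  high-gain "vein" columns;
* laminar and eccentricity modulations of condition preferences (e.g.
  superficial color selectivity, deep texture selectivity, texture
  selectivity growing with eccentricity);
* block-level response-amplitude variability, optionally shared between
  chosen (area, depth-bin) pairs -- the ground truth for informational
  connectivity;
* spatially autocorrelated Gaussian noise (white noise smoothed on the
  sheet with a fixed FWHM), independent across areas and timepoints.

Everything is reproducible from a seed: one master seed per dataset, with
sub-streams derived by fixed integer offsets per run/area/purpose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from . import glm as _glm
from . import laminar as _laminar
from .exceptions import ConfigurationError, InputError

AREAS = ("V1", "V2", "V3ab", "V4")
COMPARTMENTS = ("thin", "thick", "pale", "none")
#: condition pair (preferred first) per stimulus contrast
CONTRAST_CONDITIONS = {
    "color": ("chr", "ach"),
    "disparity": ("3d", "2d"),
    "texture": ("tex", "noi"),
}
CONTRASTS = tuple(CONTRAST_CONDITIONS)

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))

# fixed sub-stream tags (master seed + tag [+ indices] feed the RNG)
_TAG_VEINS = 11
_TAG_LATENT = 21
_TAG_JITTER = 22
_TAG_NOISE = 31
_TAG_ORDER = 41


# ---------------------------------------------------------------------------
# cortical patch


@dataclass
class GridSpec:
    """Geometry of one area's column grid."""

    nu: int
    nv: int
    n_depth: int
    spacing_mm: float
    v0_mm: float  # sheet v coordinate of the first row
    column_offset: int  # first global column id of this area
    voxel_offset: int  # first global voxel id of this area


@dataclass
class PatchConfig:
    """Geometry specification for :func:`make_cortical_patch`.

    ``curvature_amplitude`` modulates the outer surface-area element as
    ``A_outer = 1 + amplitude * sin(2 pi u / curvature_period_mm)`` (set to 0
    for flat cortex, where depth equals the volume fraction).
    """

    area_grids: dict = field(
        default_factory=lambda: {a: (60, 50) for a in AREAS}
    )  # area -> (nu, nv) columns
    spacing_mm: float = 1.0
    n_depth: int = 3
    ecc_range: tuple = (0.0, 18.0)
    curvature_amplitude: float = 0.3
    curvature_period_mm: float = 30.0


@dataclass
class CorticalPatch:
    """Synthetic cortical sheet.

    ``voxels`` has one row per voxel: voxel_id, column_id, area, iu, iv, u, v,
    depth_index, alpha (volume fraction), depth, eccentricity, A_inner,
    A_outer.  ``grids`` maps each area to its :class:`GridSpec`.  Within an
    area, voxels are ordered depth-major then row-major:
    index = (depth_index * nv + iv) * nu + iu.
    """

    voxels: pd.DataFrame
    grids: dict
    config: PatchConfig

    @property
    def n_voxels(self):
        return len(self.voxels)

    def area_voxels(self, area) -> pd.DataFrame:
        return self.voxels[self.voxels["area"] == area]

    def columns(self, area=None) -> pd.DataFrame:
        vox = self.voxels if area is None else self.area_voxels(area)
        return vox.drop_duplicates("column_id")[
            ["column_id", "area", "iu", "iv", "u", "v", "eccentricity"]
        ].reset_index(drop=True)

    def column_grid(self, area, values: pd.Series) -> np.ndarray:
        """Arrange per-column values of one area on its (nv, nu) grid (NaN where absent)."""
        g = self.grids[area]
        out = np.full((g.nv, g.nu), np.nan)
        cols = self.columns(area)
        idx = cols["column_id"].to_numpy()
        present = np.isin(idx, values.index.to_numpy())
        sub = cols[present]
        out[sub["iv"].to_numpy(), sub["iu"].to_numpy()] = values.loc[
            sub["column_id"].to_numpy()
        ].to_numpy()
        return out

    def column_means(self, area, voxel_values: pd.Series) -> pd.Series:
        """Average per-voxel values across depths within each column of ``area``."""
        vox = self.area_voxels(area)
        sub = voxel_values.loc[vox["voxel_id"].to_numpy()]
        return sub.groupby(vox["column_id"].to_numpy()).mean()


def make_cortical_patch(config: PatchConfig | None = None) -> CorticalPatch:
    """Build a deterministic cortical patch from a geometry config.

    V1 sits at v < 0, V2 at v >= 0 (the V1-V2 border is v = 0); V3ab and V4
    occupy disjoint sheets further along v.  Eccentricity increases linearly
    with distance from the area's border row over ``ecc_range``.  Depth
    samples sit at equal-volume fractions (k + 1/2)/n_depth and are converted
    to geometric depth with the equi-volume formula.
    """
    cfg = config or PatchConfig()
    for area, (nu, nv) in cfg.area_grids.items():
        if nu <= 0 or nv <= 0:
            raise ConfigurationError(f"non-positive grid dimension for {area}: {(nu, nv)}")
    if cfg.n_depth <= 0:
        raise ConfigurationError("n_depth must be positive")
    if cfg.spacing_mm <= 0:
        raise ConfigurationError("spacing_mm must be positive")

    frames = []
    grids = {}
    col_off = 0
    vox_off = 0
    v_cursor = 0.0
    gap = 5.0 * cfg.spacing_mm
    lo, hi = cfg.ecc_range
    for area in [a for a in AREAS if a in cfg.area_grids]:
        nu, nv = cfg.area_grids[area]
        if area == "V1":
            v0 = -nv * cfg.spacing_mm
        elif area == "V2":
            v0 = 0.0
            v_cursor = nv * cfg.spacing_mm + gap
        else:
            v0 = v_cursor
            v_cursor += nv * cfg.spacing_mm + gap
        grids[area] = GridSpec(nu, nv, cfg.n_depth, cfg.spacing_mm, v0, col_off, vox_off)

        iu, iv = np.meshgrid(np.arange(nu), np.arange(nv))
        iu, iv = iu.ravel(), iv.ravel()
        u = iu * cfg.spacing_mm
        v = v0 + iv * cfg.spacing_mm
        # eccentricity grows away from the V1-V2 border row
        border_dist = (nv - 1 - iv) if area == "V1" else iv
        ecc = lo + (hi - lo) * border_dist / max(nv - 1, 1)
        a_inner = np.ones(nu * nv)
        a_outer = 1.0 + cfg.curvature_amplitude * np.sin(
            2.0 * np.pi * u / cfg.curvature_period_mm
        )
        if np.any(a_outer <= 0):
            raise ConfigurationError("curvature_amplitude yields non-positive A_outer")
        col_ids = col_off + iv * nu + iu

        for k in range(cfg.n_depth):
            alpha = (k + 0.5) / cfg.n_depth
            depth = _laminar.equivolume_depth(np.full(nu * nv, alpha), a_inner, a_outer)
            frames.append(
                pd.DataFrame(
                    {
                        "voxel_id": vox_off + k * nu * nv + iv * nu + iu,
                        "column_id": col_ids,
                        "area": area,
                        "iu": iu,
                        "iv": iv,
                        "u": u,
                        "v": v,
                        "depth_index": k,
                        "alpha": alpha,
                        "depth": depth,
                        "eccentricity": ecc,
                        "A_inner": a_inner,
                        "A_outer": a_outer,
                    }
                )
            )
        col_off += nu * nv
        vox_off += cfg.n_depth * nu * nv

    voxels = pd.concat(frames, ignore_index=True).sort_values("voxel_id").reset_index(drop=True)
    patch = CorticalPatch(voxels, grids, cfg)
    bins = _laminar.depth_bin(voxels["depth"].to_numpy())
    for area in grids:
        present = set(bins[voxels["area"].to_numpy() == area])
        if present != set(_laminar.DEPTH_BINS):
            raise ConfigurationError(
                f"area {area} lacks voxels in depth bins {set(_laminar.DEPTH_BINS) - present}"
            )
    return patch


# ---------------------------------------------------------------------------
# stripe map


@dataclass
class StripeMap:
    """Per-voxel stripe compartment labels (ground truth or estimate)."""

    compartment: pd.Series  # index: voxel_id; values in COMPARTMENTS
    cycle_mm: float | None = None

    def of_voxels(self, voxel_ids):
        return self.compartment.loc[np.asarray(voxel_ids)].to_numpy()


def make_stripe_map(patch, cycle_mm=8.0, duty=(0.25, 0.25, 0.25, 0.25), phase_mm=0.0) -> StripeMap:
    """Periodic thin/pale/thick/pale stripe labels for V2 columns.

    ``duty`` gives the (thin, pale, thick, pale) fractions of one cycle and
    must sum to 1.  Bands are constant along v (perpendicular to the V1-V2
    border); voxels outside V2 are labelled ``none``.
    """
    if cycle_mm <= 0:
        raise ConfigurationError("cycle_mm must be positive")
    duty = np.asarray(duty, dtype=float)
    if duty.size != 4 or abs(duty.sum() - 1.0) > 1e-9:
        raise ConfigurationError("duty fractions (thin, pale, thick, pale) must sum to 1")
    edges = np.concatenate([[0.0], np.cumsum(duty)]) * cycle_mm
    order = ("thin", "pale", "thick", "pale")

    vox = patch.voxels
    labels = np.full(len(vox), "none", dtype=object)
    in_v2 = (vox["area"] == "V2").to_numpy()
    x = np.mod(vox["u"].to_numpy()[in_v2] + phase_mm, cycle_mm)
    lab_v2 = np.full(x.size, "pale", dtype=object)
    for name, left, right in zip(order, edges[:-1], edges[1:]):
        lab_v2[(x >= left) & (x < right)] = name
    labels[in_v2] = lab_v2
    return StripeMap(
        pd.Series(labels, index=vox["voxel_id"].to_numpy()), cycle_mm=cycle_mm
    )


# ---------------------------------------------------------------------------
# block design


@dataclass
class BlockDesign:
    """A block design: condition labels, timing, and per-run block onsets."""

    conditions: tuple
    n_runs: int
    blocks_per_condition: int = 5
    block_duration_s: float = 24.0
    fixation_s: float = 16.8
    tr_s: float = 2.4
    block_onsets: list = field(default_factory=list)  # per run: [(onset_s, condition)]

    @property
    def n_blocks(self):
        return len(self.conditions) * self.blocks_per_condition

    @property
    def run_length_s(self):
        return 2.0 * self.fixation_s + self.n_blocks * self.block_duration_s

    @property
    def n_timepoints(self):
        return int(round(self.run_length_s / self.tr_s))

    def to_dict(self):
        return {
            "conditions": list(self.conditions),
            "n_runs": self.n_runs,
            "blocks_per_condition": self.blocks_per_condition,
            "block_duration_s": self.block_duration_s,
            "fixation_s": self.fixation_s,
            "tr_s": self.tr_s,
            "block_onsets": [[[t, c] for t, c in run] for run in self.block_onsets],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            conditions=tuple(d["conditions"]),
            n_runs=d["n_runs"],
            blocks_per_condition=d["blocks_per_condition"],
            block_duration_s=d["block_duration_s"],
            fixation_s=d["fixation_s"],
            tr_s=d["tr_s"],
            block_onsets=[[(t, c) for t, c in run] for run in d["block_onsets"]],
        )


#: maximum tolerated mismatch between run length and a whole number of TRs
TR_ALIGNMENT_TOL = 0.01  # in TR units


def make_block_design(
    conditions,
    n_runs,
    blocks_per_condition=5,
    block_duration_s=24.0,
    fixation_s=16.8,
    tr_s=2.4,
    seed=0,
) -> BlockDesign:
    """Counterbalanced block design.

    With two conditions the blocks alternate, with the leading condition
    alternating across runs; with more conditions each sweep is a seeded
    random permutation.  The run length must be a whole number of TRs within
    a small tolerance (e.g. 16.8 s fixation with TR 2.4 s gives 114 TRs for
    ten 24 s blocks; 16.0 s does not divide and is rejected).
    """
    conditions = tuple(conditions)
    if blocks_per_condition < 1:
        raise ConfigurationError("blocks_per_condition must be >= 1")
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    design = BlockDesign(
        conditions, n_runs, blocks_per_condition, block_duration_s, fixation_s, tr_s
    )
    ratio = design.run_length_s / tr_s
    if abs(ratio - round(ratio)) > TR_ALIGNMENT_TOL:
        raise ConfigurationError(
            f"run length {design.run_length_s} s is not a whole number of TRs "
            f"(TR {tr_s} s): {ratio:.3f}"
        )
    rng = np.random.default_rng([int(seed) % (2**31), _TAG_ORDER])
    for r in range(n_runs):
        if len(conditions) == 2:
            a, b = conditions if r % 2 == 0 else conditions[::-1]
            order = [a, b] * blocks_per_condition
        else:
            order = []
            for _ in range(blocks_per_condition):
                order.extend(rng.permutation(conditions))
        onsets = [
            (fixation_s + i * block_duration_s, c) for i, c in enumerate(order)
        ]
        design.block_onsets.append(onsets)
    return design


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class Coupling:
    """Block-level shared response variability between two (area, depth-bin) nodes."""

    area_a: str
    bin_a: str
    area_b: str
    bin_b: str
    contrast: str
    weight: float

    def nodes(self):
        return (self.area_a, self.bin_a), (self.area_b, self.bin_b)


@dataclass
class GroundTruth:
    """Planted effects the analyses are meant to recover.

    Amplitudes are percent signal change at the block plateau.  The response
    of voxel i to block b of condition c is

        amp(i, c) * laminar_gain(bin) * vein_gain(depth) * m(node(i), b)

    with m = 1 + w * s_b + jitter, where s_b is a standard-normal block
    latent shared across each coupled node pair and jitter is independent
    N(0, amplitude_jitter_sd^2).  ``laminar_boost`` multiplies the preferred
    (first) condition's amplitude in chosen bins/areas and is what creates
    depth-dependent selectivity; ``ecc_boost`` scales the preferred
    condition by (1 + slope * ecc / ecc_max).
    """

    stripe_amplitudes: dict = field(default_factory=dict)  # compartment -> cond -> amp
    area_amplitudes: dict = field(default_factory=dict)  # area -> cond -> amp
    laminar_gain: dict = field(
        default_factory=lambda: {"deep": 0.8, "middle": 1.0, "superficial": 1.2}
    )
    vein_bias_amplitude: float = 0.8  # gain = 1 + a * depth^2
    vein_column_fraction: float = 0.05
    vein_column_gain: float = 2.5
    laminar_boost: dict = field(default_factory=dict)  # contrast -> {areas, bins{bin: x}}
    ecc_boost: dict = field(default_factory=dict)  # contrast -> slope
    shared_variability: list = field(default_factory=list)  # list[Coupling]
    amplitude_jitter_sd: float = 0.15
    noise_sd: float = 4.0
    noise_fwhm_mm: float = 2.0
    seed: int = 0

    def validate(self):
        problems = []
        for c in self.shared_variability:
            if not 0.0 <= c.weight <= 1.0:
                problems.append(f"coupling weight {c.weight} outside [0, 1]")
            if c.contrast not in CONTRAST_CONDITIONS:
                problems.append(f"unknown contrast {c.contrast!r} in coupling")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if self.noise_fwhm_mm < 0:
            problems.append("noise_fwhm_mm must be >= 0")
        for d in (self.stripe_amplitudes, self.area_amplitudes):
            for sub in d.values():
                for v in sub.values():
                    if not np.isfinite(v):
                        problems.append("amplitudes must be finite")
        return problems

    def to_dict(self):
        d = asdict(self)
        d["shared_variability"] = [asdict(c) for c in self.shared_variability]
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["shared_variability"] = [Coupling(**c) for c in d.get("shared_variability", [])]
        return cls(**d)


def default_truth(seed=0) -> GroundTruth:
    """Default planted effects.

    The defaults encode the qualitative findings the pipeline is built to
    recover: color-preferring thin and disparity-preferring thick stripes
    with pale stripes in between (and no texture preference across
    compartments); superficial color selectivity and deep texture
    selectivity in V1/V2 with a flat disparity profile; texture selectivity
    growing with eccentricity; and one planted block-level coupling between
    the deep bins of V4 and V2 for the texture contrast (the feedback
    pathway the connectivity analysis should flag).
    """
    return GroundTruth(
        stripe_amplitudes={
            "thin": {"chr": 2.6, "ach": 1.4, "3d": 1.6, "2d": 2.0},
            "thick": {"chr": 1.6, "ach": 2.0, "3d": 2.6, "2d": 1.4},
            "pale": {"chr": 2.0, "ach": 2.0, "3d": 2.0, "2d": 2.0},
        },
        area_amplitudes={
            "V1": {"chr": 2.3, "ach": 1.7, "3d": 2.2, "2d": 1.8, "tex": 1.9, "noi": 2.1},
            "V2": {"tex": 2.2, "noi": 1.8},
            "V3ab": {"chr": 2.0, "ach": 2.0, "3d": 2.5, "2d": 1.5, "tex": 2.2, "noi": 1.8},
            "V4": {"chr": 2.5, "ach": 1.5, "3d": 2.0, "2d": 2.0, "tex": 2.6, "noi": 1.4},
        },
        laminar_boost={
            "color": {"areas": ["V1", "V2"], "bins": {"superficial": 1.6}},
            "texture": {"areas": ["V1", "V2"], "bins": {"deep": 1.6}},
        },
        ecc_boost={"texture": 1.0},
        shared_variability=[Coupling("V2", "deep", "V4", "deep", "texture", 0.8)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# BOLD simulation


@dataclass
class BOLDDataset:
    """One simulated (or loaded) experiment: runs, design, patch, truth."""

    runs: list  # list of voxel x timepoint arrays (percent signal change)
    design: BlockDesign
    patch: CorticalPatch
    contrast: str | None = None
    truth: GroundTruth | None = None
    stripe_map: StripeMap | None = None

    @property
    def n_runs(self):
        return len(self.runs)


def _smooth_unit_noise(rng, shape_tvnu, sigma_vox):
    """White noise smoothed over the trailing (nv, nu) axes, unit variance."""
    noise = rng.standard_normal(shape_tvnu)
    if sigma_vox > 0:
        ndimage.gaussian_filter(noise, sigma=sigma_vox, axes=(-2, -1), output=noise, mode="wrap")
        # analytic variance correction: squared-sum of the separable kernel
        impulse = np.zeros(shape_tvnu[-2:])
        impulse[shape_tvnu[-2] // 2, shape_tvnu[-1] // 2] = 1.0
        k = ndimage.gaussian_filter(impulse, sigma=sigma_vox, mode="wrap")
        noise /= np.sqrt((k**2).sum())
    return noise


def condition_amplitudes(patch, stripe_map, truth, contrast) -> np.ndarray:
    """Noise-free response amplitude of every voxel to each condition.

    Returns an (n_voxels, 2) array ordered as ``CONTRAST_CONDITIONS[contrast]``.
    V2 voxels take compartment amplitudes from the stripe map for the color
    and disparity contrasts; everything else uses area amplitudes.
    """
    conds = CONTRAST_CONDITIONS[contrast]
    vox = patch.voxels
    n = len(vox)
    amp = np.zeros((n, 2))
    area = vox["area"].to_numpy()
    bins = _laminar.depth_bin(vox["depth"].to_numpy())
    for j, cond in enumerate(conds):
        base = np.empty(n)
        for a in patch.grids:
            mask = area == a
            if a == "V2" and contrast in ("color", "disparity"):
                if stripe_map is None:
                    raise InputError(f"stripe map required for the {contrast} contrast in V2")
                comp = stripe_map.of_voxels(vox["voxel_id"].to_numpy()[mask])
                vals = np.array(
                    [truth.stripe_amplitudes[c][cond] for c in comp], dtype=float
                )
                base[mask] = vals
            else:
                base[mask] = truth.area_amplitudes[a][cond]
        amp[:, j] = base
    # laminar boost on the preferred condition
    boost = truth.laminar_boost.get(contrast)
    if boost:
        sel = np.isin(area, boost.get("areas", list(patch.grids)))
        for b, mult in boost.get("bins", {}).items():
            amp[sel & (bins == b), 0] *= mult
    slope = truth.ecc_boost.get(contrast, 0.0)
    if slope:
        ecc = vox["eccentricity"].to_numpy()
        emax = max(patch.config.ecc_range[1], 1e-9)
        amp[:, 0] *= 1.0 + slope * ecc / emax
    return amp


def _voxel_gain(patch, truth, seed):
    """Static multiplicative gain per voxel: laminar x pial vein x vein columns."""
    vox = patch.voxels
    depth = vox["depth"].to_numpy()
    bins = _laminar.depth_bin(depth)
    gain = np.array([truth.laminar_gain[b] for b in bins])
    gain = gain * (1.0 + truth.vein_bias_amplitude * depth**2)
    if truth.vein_column_fraction > 0 and truth.vein_column_gain != 1.0:
        rng = np.random.default_rng([seed, _TAG_VEINS])
        cols = vox.drop_duplicates("column_id")
        vein_cols = []
        for a in patch.grids:
            ids = cols.loc[cols["area"] == a, "column_id"].to_numpy()
            k = int(round(truth.vein_column_fraction * ids.size))
            if k:
                vein_cols.append(rng.choice(ids, size=k, replace=False))
        if vein_cols:
            vein_cols = np.concatenate(vein_cols)
            gain = np.where(
                vox["column_id"].isin(vein_cols).to_numpy(),
                gain * truth.vein_column_gain,
                gain,
            )
    return gain


def _node_index(patch):
    """(area, depth-bin) node key per voxel, and the ordered node list."""
    vox = patch.voxels
    bins = _laminar.depth_bin(vox["depth"].to_numpy())
    keys = list(zip(vox["area"].to_numpy(), bins))
    nodes = sorted(set(keys))
    lookup = {k: i for i, k in enumerate(nodes)}
    return np.array([lookup[k] for k in keys]), nodes


def simulate_bold(
    patch,
    stripe_map,
    design,
    truth,
    contrast,
    seed=None,
    session=0,
) -> BOLDDataset:
    """Simulate one experiment (all runs) for one subject.

    ``seed`` defaults to ``truth.seed``; ``session`` shifts the noise and
    block-variability streams while keeping the planted spatial structure,
    which is how repeat scan sessions are emulated.
    """
    if contrast not in CONTRAST_CONDITIONS:
        raise InputError(f"unknown contrast {contrast!r}")
    if stripe_map is not None and not stripe_map.compartment.index.equals(
        pd.Index(patch.voxels["voxel_id"].to_numpy())
    ):
        raise InputError("stripe map voxels do not match the patch")
    seed = int(truth.seed if seed is None else seed) % (2**31)
    conds = CONTRAST_CONDITIONS[contrast]
    amp = condition_amplitudes(patch, stripe_map, truth, contrast)
    amp = amp * _voxel_gain(patch, truth, seed)[:, None]
    node_of_voxel, nodes = _node_index(patch)
    couplings = [c for c in truth.shared_variability if c.contrast == contrast]
    node_lookup = {k: i for i, k in enumerate(nodes)}
    cidx = int(CONTRASTS.index(contrast))

    tgrid, curve = _glm._block_curve(design.block_duration_s)
    n_tr = design.n_timepoints
    times = np.arange(n_tr) * design.tr_s
    sigma_vox = truth.noise_fwhm_mm * FWHM_TO_SIGMA / patch.config.spacing_mm

    runs = []
    for r in range(design.n_runs):
        onsets = design.block_onsets[r]
        n_blocks = len(onsets)
        # block-level amplitude modulation per node
        rng_lat = np.random.default_rng([seed, _TAG_LATENT, cidx, session, r])
        rng_jit = np.random.default_rng([seed, _TAG_JITTER, cidx, session, r])
        m = 1.0 + truth.amplitude_jitter_sd * rng_jit.standard_normal(
            (len(nodes), n_blocks)
        )
        for c in couplings:
            s_b = rng_lat.standard_normal(n_blocks)
            for node in c.nodes():
                if node in node_lookup:
                    m[node_lookup[node]] += c.weight * s_b
        # voxel x block amplitude, then convolve through the block regressors
        cond_idx = np.array([conds.index(c) for _, c in onsets])
        A = amp[:, cond_idx] * m[node_of_voxel][:, np.arange(n_blocks)]
        R = np.stack(
            [np.interp(times - t0, tgrid, curve, left=0.0, right=0.0) for t0, _ in onsets]
        )
        data = A @ R
        if truth.noise_sd > 0:
            for a, g in patch.grids.items():
                rng_noise = np.random.default_rng(
                    [seed, _TAG_NOISE, cidx, session, r, list(patch.grids).index(a)]
                )
                noise = _smooth_unit_noise(
                    rng_noise, (n_tr, g.n_depth, g.nv, g.nu), sigma_vox
                )
                # (t, k, iv, iu) -> voxel order (k*nv+iv)*nu+iu within the area
                block = noise.transpose(1, 2, 3, 0).reshape(g.n_depth * g.nv * g.nu, n_tr)
                data[g.voxel_offset : g.voxel_offset + block.shape[0]] += (
                    truth.noise_sd * block
                )
        runs.append(data)
    return BOLDDataset(runs, design, patch, contrast, truth, stripe_map)


def simulate_subject(patch, stripe_map, designs, truth, seed=None, session=0):
    """Simulate all three experiments for one subject.

    ``designs`` maps contrast -> BlockDesign.  Returns contrast -> BOLDDataset.
    """
    return {
        k: simulate_bold(patch, stripe_map, designs[k], truth, k, seed=seed, session=session)
        for k in designs
    }


# ---------------------------------------------------------------------------
# disk round trip (NIfTI volumes + metadata CSV + design/truth JSON)


def write_dataset(dataset: BOLDDataset, outdir):
    """Write a dataset as NIfTI runs + voxel-metadata CSV + design/truth JSON.

    Voxels are unfolded onto a (u, v, depth) voxel grid; areas are stacked
    along the v axis in patch order.  The metadata CSV records the grid
    indices so the trio can be read back losslessly.
    """
    import pathlib

    import nibabel as nib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patch = dataset.patch
    areas = list(patch.grids)
    nu_max = max(g.nu for g in patch.grids.values())
    nv_total = sum(g.nv for g in patch.grids.values())
    n_depth = max(g.n_depth for g in patch.grids.values())
    v_off = dict(zip(areas, np.cumsum([0] + [patch.grids[a].nv for a in areas[:-1]])))

    vox = patch.voxels
    gi = vox["iu"].to_numpy()
    gj = vox["iv"].to_numpy() + np.array([v_off[a] for a in vox["area"]])
    gk = vox["depth_index"].to_numpy()
    for r, data in enumerate(dataset.runs):
        vol = np.zeros((nu_max, nv_total, n_depth, data.shape[1]), dtype=np.float32)
        vol[gi, gj, gk] = data
        img = nib.Nifti1Image(vol, affine=np.diag([patch.config.spacing_mm] * 3 + [1.0]))
        img.header.set_zooms(
            (patch.config.spacing_mm,) * 3 + (dataset.design.tr_s,)
        )
        nib.save(img, outdir / f"run{r:02d}.nii")

    meta = vox.copy()
    meta["grid_i"], meta["grid_j"], meta["grid_k"] = gi, gj, gk
    if dataset.stripe_map is not None:
        meta["compartment"] = dataset.stripe_map.of_voxels(vox["voxel_id"].to_numpy())
    meta.to_csv(outdir / "voxels.csv", index=False)
    (outdir / "design.json").write_text(json.dumps(dataset.design.to_dict(), indent=1))
    payload = {"contrast": dataset.contrast}
    if dataset.truth is not None:
        payload["truth"] = dataset.truth.to_dict()
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1))


def read_dataset(indir, patch: CorticalPatch) -> BOLDDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    import pathlib

    import nibabel as nib

    indir = pathlib.Path(indir)
    meta = pd.read_csv(indir / "voxels.csv")
    design = BlockDesign.from_dict(json.loads((indir / "design.json").read_text()))
    payload = json.loads((indir / "truth.json").read_text())
    truth = GroundTruth.from_dict(payload["truth"]) if "truth" in payload else None
    gi = meta["grid_i"].to_numpy()
    gj = meta["grid_j"].to_numpy()
    gk = meta["grid_k"].to_numpy()
    runs = []
    for f in sorted(indir.glob("run*.nii")):
        vol = np.asanyarray(nib.load(f).dataobj)
        runs.append(vol[gi, gj, gk].astype(float))
    stripe = None
    if "compartment" in meta.columns:
        stripe = StripeMap(pd.Series(meta["compartment"].to_numpy(), index=meta["voxel_id"].to_numpy()))
    return BOLDDataset(runs, design, patch, payload.get("contrast"), truth, stripe)


def percent_signal_change(raw_runs):
    """Scale raw intensity runs to percent signal change per voxel: 100*(y/mean - 1)."""
    out = []
    for run in raw_runs:
        mean = run.mean(axis=1, keepdims=True)
        if np.any(mean == 0):
            raise InputError("zero-mean voxel timecourse cannot be scaled")
        out.append(100.0 * (run / mean - 1.0))
    return out
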