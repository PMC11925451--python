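"""Selectivity indices, laminar/eccentricity profiles, stripe segmentation.

The selectivity index of a condition pair is SI = (bA - bB) / (bA + bB) on
ROI-averaged betas (average first, then take the index).  Stripe
compartments are estimated from the color-minus-disparity differential map
by thresholding its z-scored values and labelling the inter-band gaps that
are flanked by one thin and one thick band as pale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import laminar as _laminar
from .exceptions import InputError
from .synthetic import CONTRAST_CONDITIONS

#: half-open eccentricity bin edges (deg); the last bin is closed
ECC_BIN_EDGES = (0.0, 3.0, 6.0, 18.0)
ECC_BIN_NAMES = ("central", "parafoveal", "peripheral")


def selectivity_index(beta_a, beta_b):
    """(bA - bB) / (bA + bB); NaN (with a warning) where the denominator is 0.

    Antisymmetric in its arguments and bounded in [-1, 1] for positive betas.
    """
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    denom = a + b
    bad = np.isclose(denom, 0.0)
    if np.any(bad):
        warnings.warn("zero denominator in selectivity index; value undefined (NaN)")
    with np.errstate(divide="ignore", invalid="ignore"):
        si = np.where(bad, np.nan, (a - b) / np.where(bad, np.nan, denom))
    return float(si) if si.ndim == 0 else si


def _roi_si(betas, mask, label):
    """SI of ROI-mean betas; ``betas`` is (V, 2) preferred-first."""
    if mask.sum() == 0:
        raise InputError(f"empty ROI: {label}")
    mean = betas[mask].mean(axis=0)
    return selectivity_index(mean[0], mean[1])


def laminar_profile(betas, patch, area, contrast, vein_excluded=None) -> pd.DataFrame:
    """SI per depth bin over all retained voxels of ``area``.

    ``betas`` is an (n_voxels, 2) array over the whole patch, ordered as the
    contrast's (preferred, non-preferred) conditions.  ``vein_excluded`` is
    an optional boolean per voxel (True = drop).
    """
    vox = patch.voxels
    bins = _laminar.depth_bin(vox["depth"].to_numpy())
    keep = (vox["area"] == area).to_numpy()
    if vein_excluded is not None:
        keep &= ~np.asarray(vein_excluded, dtype=bool)
    rows = []
    for b in _laminar.DEPTH_BINS:
        rows.append(
            {
                "area": area,
                "contrast": contrast,
                "bin": b,
                "si": _roi_si(betas, keep & (bins == b), f"{area}/{b}"),
            }
        )
    return pd.DataFrame(rows)


def eccentricity_profile(
    betas, patch, area, contrast, bin_edges=ECC_BIN_EDGES, vein_excluded=None
) -> pd.DataFrame:
    """SI per eccentricity bin (half-open bins; the last closed at the top edge)."""
    vox = patch.voxels
    ecc = vox["eccentricity"].to_numpy()
    keep = (vox["area"] == area).to_numpy()
    if vein_excluded is not None:
        keep &= ~np.asarray(vein_excluded, dtype=bool)
    rows = []
    for i, (lo, hi) in enumerate(zip(bin_edges[:-1], bin_edges[1:])):
        mask = keep & (ecc >= lo) & ((ecc < hi) | ((i == len(bin_edges) - 2) & (ecc <= hi)))
        name = ECC_BIN_NAMES[i] if len(bin_edges) == 4 else f"{lo}-{hi}"
        rows.append(
            {
                "area": area,
                "contrast": contrast,
                "bin": name,
                "ecc_lo": lo,
                "ecc_hi": hi,
                "si": _roi_si(betas, mask, f"{area}/ecc {lo}-{hi}"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StripeEstimate:
    """Estimated stripe compartments.

    ``compartment`` maps voxel_id -> {thin, thick, pale, none}; ``status`` is
    "ok" or "empty" (no suprathreshold voxels).
    """

    compartment: pd.Series
    threshold: float
    status: str = "ok"

    def of_voxels(self, voxel_ids):
        return self.compartment.loc[np.asarray(voxel_ids)].to_numpy()


def _label_grid(zmap, z):
    """Label a standardized differential column grid.

    Returns an object array over the grid: thin where z > +z, thick where
    z < -z (each as connected components so bands are contiguous objects),
    pale where an unlabelled cell's nearest labelled cells along u on both
    sides are one thin and one thick band.
    """
    lab = np.full(zmap.shape, "none", dtype=object)
    finite = np.isfinite(zmap)
    thin_mask = finite & (zmap > z)
    thick_mask = finite & (zmap < -z)
    # connected components (4-connectivity) keep bands as discrete objects;
    # single suprathreshold voxels still count
    for mask, name in ((thin_mask, "thin"), (thick_mask, "thick")):
        comp, _ = ndimage.label(mask)
        lab[comp > 0] = name
    for iv in range(zmap.shape[0]):
        row = lab[iv]
        labelled = np.where((row == "thin") | (row == "thick"))[0]
        if labelled.size == 0:
            continue
        for iu in np.where((row == "none") & finite[iv])[0]:
            left = labelled[labelled < iu]
            right = labelled[labelled > iu]
            if left.size and right.size and {row[left[-1]], row[right[0]]} == {"thin", "thick"}:
                row[iu] = "pale"
    return lab


def segment_stripes(differential, patch, z=1.0, include=None) -> StripeEstimate:
    """Estimate thin/thick/pale stripes from a columnar differential map.

    Parameters
    ----------
    differential : pd.Series
        Color-minus-disparity differential response indexed by V2
        ``column_id`` (one value per cortical column).
    patch : CorticalPatch
    z : float
        Threshold on the z-scored differential map.
    include : pd.Series or array, optional
        Boolean per column (aligned with ``differential``); columns with
        False (e.g. mean activation <= 0) are never labelled.

    Notes
    -----
    The map is z-scored across included V2 columns, so the estimate is
    invariant to adding a constant to the differential map.  Labels
    propagate to every depth of a column; non-V2 voxels are ``none``.
    """
    if include is not None:
        inc = pd.Series(np.asarray(include, dtype=bool), index=differential.index)
        differential = differential.where(inc)
    grid = patch.column_grid("V2", differential.astype(float))
    finite = np.isfinite(grid)
    if finite.sum() < 2:
        raise InputError("differential map has fewer than 2 usable columns")
    mu, sd = grid[finite].mean(), grid[finite].std()
    if sd == 0:
        raise InputError("differential map has zero variance")
    zmap = (grid - mu) / sd
    status = "ok"
    if not np.any(np.abs(zmap[finite]) > z):
        warnings.warn("no suprathreshold columns; stripe estimate is empty")
        status = "empty"
    lab = _label_grid(zmap, z)

    vox = patch.voxels
    labels = np.full(len(vox), "none", dtype=object)
    in_v2 = (vox["area"] == "V2").to_numpy()
    labels[in_v2] = lab[vox["iv"].to_numpy()[in_v2], vox["iu"].to_numpy()[in_v2]]
    return StripeEstimate(
        pd.Series(labels, index=vox["voxel_id"].to_numpy()), threshold=z, status=status
    )


def compartment_profile(betas, stripes, contrast, voxel_ids=None, vein_excluded=None) -> pd.DataFrame:
    """SI of compartment-averaged betas for thin, thick and pale stripes."""
    comp = stripes.compartment
    ids = comp.index.to_numpy() if voxel_ids is None else np.asarray(voxel_ids)
    labels = comp.loc[ids].to_numpy()
    rows = []
    keep = np.ones(ids.size, dtype=bool)
    if vein_excluded is not None:
        keep = ~np.asarray(vein_excluded, dtype=bool)
    for c in ("thin", "thick", "pale"):
        mask = keep & (labels == c)
        rows.append(
            {
                "compartment": c,
                "contrast": contrast,
                "si": _roi_si(betas, mask, f"compartment {c}"),
            }
        )
    return pd.DataFrame(rows)


def dice_coefficient(est_labels, true_labels, compartment):
    """Dice overlap of one compartment between estimated and true labels."""
    a = np.asarray(est_labels) == compartment
    b = np.asarray(true_labels) == compartment
    denom = a.sum() + b.sum()
    if denom == 0:
        return np.nan
    return 2.0 * (a & b).sum() / denom


def contrast_betas(glm_results, design, contrast):
    """Average (preferred, non-preferred) betas across per-run GLM results.

    ``glm_results`` is a list of per-run GLMResult from per-condition fits of
    one experiment.  Returns (n_voxels, 2).
    """
    conds = CONTRAST_CONDITIONS[contrast]
    stacks = [np.column_stack([res.beta(c) for c in conds]) for res in glm_results]
    return np.mean(stacks, axis=0)
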