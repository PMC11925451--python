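"""Cortical depth handling: equi-volume depth, three-bin assignment, vein removal.

Depth runs from 0 at the white-matter surface to 1 at the pial surface.
Voxels are grouped into three bins -- deep [0, 0.33), middle [0.33, 0.67)
and superficial [0.67, 1] -- the standard partition for depth-dependent
BOLD analyses.  Gradient-echo BOLD is inflated near the pial surface by
draining veins; :func:`remove_pial_veins` excludes the most responsive
cortical columns (all depths of a column) to mitigate that bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError

DEPTH_BINS = ("deep", "middle", "superficial")
#: half-open bin edges on the depth fraction; the last bin is closed at 1.0
DEPTH_BIN_EDGES = (0.0, 0.33, 0.67, 1.0)


def equivolume_depth(alpha, a_inner, a_outer):
    """Equi-volume depth of a point at cumulative volume fraction ``alpha``.

    Under cortical folding, layers keep their volume fraction rather than
    their Euclidean thickness.  Modelling a cortical column as a wedge whose
    cross-sectional area interpolates linearly from ``a_inner`` (white-matter
    surface) to ``a_outer`` (pial surface), the depth ``rho`` enclosing volume
    fraction ``alpha`` solves

        alpha * (a_inner + a_outer) / 2 = a_inner * rho + (a_outer - a_inner) * rho**2 / 2

    whose positive root is

        rho = (-a_inner + sqrt(alpha * a_outer**2 + (1 - alpha) * a_inner**2))
              / (a_outer - a_inner)

    reducing to ``rho = alpha`` for flat cortex (equal areas).

    Parameters
    ----------
    alpha : float or array
        Cumulative volume fraction from the white-matter surface, in [0, 1].
    a_inner, a_outer : float or array
        Local surface-area elements (mm^2) of the inner and outer surfaces;
        must be positive.

    Returns
    -------
    float or ndarray
        Depth fraction in [0, 1], strictly increasing in ``alpha``.
    """
    alpha = np.asarray(alpha, dtype=float)
    a_in = np.asarray(a_inner, dtype=float)
    a_out = np.asarray(a_outer, dtype=float)
    if np.any((alpha < 0) | (alpha > 1)):
        raise InputError("alpha must lie in [0, 1]")
    if np.any(a_in <= 0) or np.any(a_out <= 0):
        raise InputError("surface areas must be positive")
    delta = a_out - a_in
    # guard the flat limit: the closed form is 0/0 there but -> alpha
    flat = np.abs(delta) <= 1e-12 * (a_in + a_out)
    delta_safe = np.where(flat, 1.0, delta)
    disc = alpha * a_out**2 + (1.0 - alpha) * a_in**2
    rho = (-a_in + np.sqrt(disc)) / delta_safe
    rho = np.where(flat, alpha, rho)
    rho = np.clip(rho, 0.0, 1.0)
    return float(rho) if rho.ndim == 0 else rho


def depth_bin(depth):
    """Map depth fractions to bin labels using the half-open convention."""
    depth = np.asarray(depth, dtype=float)
    if np.any((depth < 0) | (depth > 1)):
        raise InputError("depth must lie in [0, 1]")
    out = np.where(
        depth < DEPTH_BIN_EDGES[1],
        "deep",
        np.where(depth < DEPTH_BIN_EDGES[2], "middle", "superficial"),
    )
    return str(out) if out.ndim == 0 else out.astype(object)


def assign_depth_bins(patch) -> pd.DataFrame:
    """Per-voxel depth-bin assignment for a cortical patch.

    Returns a DataFrame with columns ``voxel_id``, ``depth``, ``bin``.
    """
    vox = patch.voxels
    return pd.DataFrame(
        {
            "voxel_id": vox["voxel_id"].to_numpy(),
            "depth": vox["depth"].to_numpy(),
            "bin": depth_bin(vox["depth"].to_numpy()),
        }
    )


@dataclass
class VeinMask:
    """Columns excluded as putative pial veins.

    ``excluded_columns`` are column ids; ``voxel_excluded`` maps every voxel
    id to a boolean (True for all depths of an excluded column).
    """

    excluded_columns: np.ndarray
    voxel_excluded: pd.Series  # index: voxel_id
    fraction: float

    def retained_voxels(self) -> np.ndarray:
        return self.voxel_excluded.index.to_numpy()[~self.voxel_excluded.to_numpy()]


def remove_pial_veins(values, column_ids=None, fraction=0.05):
    """Flag the top ``fraction`` of cortical columns by mean signal change.

    Exactly ``ceil(fraction * N)`` columns -- those with the largest values --
    are excluded.  Ties at the cutoff are broken deterministically: the
    smaller column id is excluded first.

    Parameters
    ----------
    values : array
        One mean-signal-change value per cortical column (vertex).
    column_ids : array, optional
        Column identifiers; defaults to 0..N-1.
    fraction : float
        Fraction of columns to exclude, in (0, 1).

    Returns
    -------
    ndarray of bool
        True where the column is excluded.
    """
    values = np.asarray(values, dtype=float)
    if not 0.0 < fraction < 1.0:
        raise InputError("fraction must lie in (0, 1)")
    n = values.size
    if n == 0:
        raise InputError("no columns supplied")
    ids = np.arange(n) if column_ids is None else np.asarray(column_ids)
    n_excl = math.ceil(fraction * n)
    # sort by value descending, id ascending (deterministic tie-break)
    order = np.lexsort((ids, -values))
    excluded = np.zeros(n, dtype=bool)
    excluded[order[:n_excl]] = True
    return excluded


def vein_mask(patch, column_signal: pd.Series, fraction=0.05, per_area=True) -> VeinMask:
    """Build a voxel-level vein mask from per-column mean signal change.

    The exclusion is applied separately within each cortical area (each area
    loses its own top ``fraction``), and propagates to every depth of an
    excluded column.

    Parameters
    ----------
    patch : CorticalPatch
    column_signal : pd.Series
        Mean signal change indexed by ``column_id`` (one value per column).
    fraction : float
    per_area : bool
        If False, rank all columns jointly instead of per area.
    """
    vox = patch.voxels
    col_area = vox.drop_duplicates("column_id").set_index("column_id")["area"]
    missing = col_area.index.difference(column_signal.index)
    if len(missing):
        raise InputError(f"column_signal missing {len(missing)} columns")
    excluded_cols = []
    if per_area:
        groups = [ids.to_numpy() for _, ids in col_area.groupby(col_area).groups.items()]
    else:
        groups = [col_area.index.to_numpy()]
    for ids in groups:
        ids = np.sort(ids)
        mask = remove_pial_veins(column_signal.loc[ids].to_numpy(), ids, fraction)
        excluded_cols.append(ids[mask])
    excluded_cols = np.sort(np.concatenate(excluded_cols))
    vox_excl = vox["column_id"].isin(excluded_cols).to_numpy()
    return VeinMask(
        excluded_columns=excluded_cols,
        voxel_excluded=pd.Series(vox_excl, index=vox["voxel_id"].to_numpy()),
        fraction=fraction,
    )
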