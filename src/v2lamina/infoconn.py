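"""Layer-specific informational connectivity.

For each (area, depth-bin) node and stimulus contrast, block-wise t-score
patterns are decoded with a linear max-margin classifier under
leave-one-run-out cross-validation: per fold, features are selected from
the training runs only (top 20% by visual responsiveness, then the most
positive and most negative 200 voxels of the differential-t distribution),
patterns are L2-normalised, and the signed geometric distance of each
held-out block to the decision boundary is recorded.  Informational
connectivity between two nodes is the fold-averaged Pearson correlation of
their held-out distance series, computed on within-condition fluctuations
(each condition's mean distance is removed per fold, so the stimulus
sequence itself does not drive the correlation).

Pathway conventions follow the canonical cortical microcircuit:
feedforward = superficial (lower area) paired with middle (higher area);
feedback = deep paired with deep.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import stats as _stats
from .exceptions import InputError
from .synthetic import CONTRAST_CONDITIONS

FEEDFORWARD = "feedforward"
FEEDBACK = "feedback"
#: (lower-area bin, higher-area bin) per pathway direction
PATHWAY_BINS = {FEEDFORWARD: ("superficial", "middle"), FEEDBACK: ("deep", "deep")}
#: adjacent area pairs in the visual hierarchy (lower, higher)
DEFAULT_PAIRS = (("V1", "V2"), ("V2", "V3ab"), ("V2", "V4"))


@dataclass
class FeatureSet:
    """Voxels selected for one cross-validation fold (training data only)."""

    voxel_index: np.ndarray  # indices into the node's voxel axis
    fold: int
    n_pool: int
    n_tail: int


def select_features(visual_t, differential_t, top_frac=0.2, n_tail=200, fold=-1) -> FeatureSet:
    """Two-stage feature selection.

    Stage 1 keeps the ``ceil(top_frac * N)`` most visually responsive voxels
    (largest ``visual_t``); stage 2 takes the ``n_tail`` largest and
    ``n_tail`` smallest ``differential_t`` among them (so with an all-positive
    differential distribution the "low" tail is still the least-positive
    voxels).  Ties are broken by the smaller index.  Both statistics must be
    computed from training folds only; the caller is responsible for that.
    """
    vt = np.asarray(visual_t, dtype=float)
    dt = np.asarray(differential_t, dtype=float)
    if vt.shape != dt.shape or vt.ndim != 1:
        raise InputError("visual_t and differential_t must be matching 1D arrays")
    n = vt.size
    idx = np.arange(n)
    n_pool = math.ceil(top_frac * n)
    if n_pool < 2 * n_tail:
        raise InputError(
            f"feature pool too small: need {2 * n_tail} voxels, "
            f"top {top_frac:.0%} of {n} gives {n_pool}"
        )
    pool = idx[np.lexsort((idx, -vt))][:n_pool]
    high = pool[np.lexsort((pool, -dt[pool]))][:n_tail]
    rest = pool[~np.isin(pool, high)]
    low = rest[np.lexsort((rest, dt[rest]))][:n_tail]
    chosen = np.sort(np.concatenate([high, low]))
    return FeatureSet(chosen, fold=fold, n_pool=n_pool, n_tail=n_tail)


def l2_normalize(pattern):
    """Scale a pattern vector to unit Euclidean norm."""
    x = np.asarray(pattern, dtype=float)
    norm = np.linalg.norm(x, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise InputError("cannot L2-normalize a zero vector")
    return x / norm


@dataclass
class DistanceSeries:
    """Signed decision-boundary distances of held-out blocks.

    One distance per held-out block; positive = classified as the preferred
    (first) condition.  ``blocks`` carries (run, block, condition) rows in
    the same order as ``distances``; ``fold`` marks the held-out run.
    """

    distances: np.ndarray
    blocks: pd.DataFrame  # columns: run, block, condition, fold
    area: str | None = None
    depth_bin: str | None = None
    contrast: str | None = None

    def fold_ids(self):
        return sorted(self.blocks["fold"].unique())


def decode_distances(
    patterns,
    blocks,
    run_stats,
    conditions,
    top_frac=0.2,
    n_tail=200,
    C=1.0,
    area=None,
    depth_bin=None,
    contrast=None,
) -> DistanceSeries:
    """Leave-one-run-out decoding distances for one node.

    Parameters
    ----------
    patterns : ndarray (n_blocks_total, n_voxels)
        Block-wise t-score patterns, all runs concatenated in block order.
    blocks : DataFrame with columns (run, block, condition)
        Metadata aligned with ``patterns`` rows.
    run_stats : dict run -> (visual_t, differential_t)
        Per-run selection statistics; each fold averages them over its
        training runs only (the held-out run never contributes).
    conditions : (str, str)
        Preferred and non-preferred condition labels (+1 / -1 classes).
    C : float
        Soft-margin regularisation of the linear max-margin classifier.
    """
    patterns = np.asarray(patterns, dtype=float)
    blocks = blocks.reset_index(drop=True)
    if len(blocks) != patterns.shape[0]:
        raise InputError("blocks metadata does not match pattern rows")
    runs = sorted(blocks["run"].unique())
    if len(runs) < 2:
        raise InputError("leave-one-run-out needs >= 2 runs")
    cond_a, cond_b = conditions
    y_all = np.where(blocks["condition"] == cond_a, 1, -1)

    dist_parts, meta_parts = [], []
    for fold, held in enumerate(runs):
        train_runs = [r for r in runs if r != held]
        train_mask = blocks["run"].isin(train_runs).to_numpy()
        if len(set(y_all[train_mask])) < 2:
            raise InputError(f"single class in training data for fold {fold}")
        vt = np.mean([run_stats[r][0] for r in train_runs], axis=0)
        dt = np.mean([run_stats[r][1] for r in train_runs], axis=0)
        feats = select_features(vt, dt, top_frac=top_frac, n_tail=n_tail, fold=fold)
        Xtr = l2_normalize(patterns[train_mask][:, feats.voxel_index])
        clf = SVC(kernel="linear", C=C, tol=1e-6)
        clf.fit(Xtr, y_all[train_mask])
        test_mask = (blocks["run"] == held).to_numpy()
        Xte = l2_normalize(patterns[test_mask][:, feats.voxel_index])
        d = clf.decision_function(Xte) / np.linalg.norm(clf.coef_)
        dist_parts.append(d)
        meta = blocks.loc[test_mask, ["run", "block", "condition"]].copy()
        meta["fold"] = fold
        meta_parts.append(meta)
    return DistanceSeries(
        np.concatenate(dist_parts),
        pd.concat(meta_parts, ignore_index=True),
        area=area,
        depth_bin=depth_bin,
        contrast=contrast,
    )


def _remove_design_profile(distances, blocks):
    """Subtract per-(block position, condition) mean distances across folds.

    The decoding distance of a block carries a deterministic component set
    by the design alone (edge blocks and drift collinearity modulate the
    per-block estimation variance identically in every region), which would
    masquerade as connectivity.  Because that component is identical across
    folds, removing each (within-run block index, condition) cell mean
    cancels it exactly while leaving block-level response fluctuations
    intact.  Requires every cell to contain >= 2 folds; otherwise the
    series is returned unchanged (the per-fold condition centring still
    applies).
    """
    d = distances.astype(float).copy()
    keys = list(zip(blocks["block"], blocks["condition"]))
    cells = {}
    for i, k in enumerate(keys):
        cells.setdefault(k, []).append(i)
    if min(len(ix) for ix in cells.values()) < 2:
        return d
    for ix in cells.values():
        d[ix] -= d[ix].mean()
    return d


def informational_connectivity(series_a: DistanceSeries, series_b: DistanceSeries, min_blocks=3):
    """Fold-averaged Pearson correlation of two distance series.

    The design-driven distance profile (identical across folds) is removed
    per node first; then, per fold, each node's distances are centred
    within condition (removing the stimulus-driven component) and
    correlated over that fold's held-out blocks.  The plain mean of the
    fold correlations is returned.  Folds with fewer than ``min_blocks``
    blocks, mismatched block order, or zero variance are skipped with a
    warning; if every fold is skipped an error is raised.
    """
    folds = series_a.fold_ids()
    if folds != series_b.fold_ids():
        raise InputError("distance series have mismatched folds")
    dist_a = _remove_design_profile(series_a.distances, series_a.blocks)
    dist_b = _remove_design_profile(series_b.distances, series_b.blocks)
    rs = []
    for f in folds:
        ma = (series_a.blocks["fold"] == f).to_numpy()
        mb = (series_b.blocks["fold"] == f).to_numpy()
        ba = series_a.blocks.loc[ma, ["run", "block", "condition"]].reset_index(drop=True)
        bb = series_b.blocks.loc[mb, ["run", "block", "condition"]].reset_index(drop=True)
        if not ba.equals(bb):
            raise InputError(f"block order differs between series in fold {f}")
        if len(ba) < min_blocks:
            warnings.warn(f"fold {f} has fewer than {min_blocks} blocks; skipped")
            continue
        da = dist_a[ma].copy()
        db = dist_b[mb].copy()
        for cond in ba["condition"].unique():
            cm = (ba["condition"] == cond).to_numpy()
            da[cm] -= da[cm].mean()
            db[cm] -= db[cm].mean()
        if da.std() == 0 or db.std() == 0:
            warnings.warn(f"zero variance in fold {f}; skipped")
            continue
        rs.append(np.corrcoef(da, db)[0, 1])
    if not rs:
        raise InputError("no usable folds for informational connectivity")
    return float(np.mean(rs))


def pathway_matrix(distances, pairs=DEFAULT_PAIRS, contrasts=None) -> pd.DataFrame:
    """Feedforward and feedback connectivity for every pathway and contrast.

    Parameters
    ----------
    distances : dict (contrast, area, depth_bin) -> DistanceSeries
    pairs : sequence of (lower, higher) area pairs
    contrasts : optional subset of contrasts

    Returns a tidy DataFrame (contrast, lower, higher, direction, r, z).
    """
    if contrasts is None:
        contrasts = sorted({k[0] for k in distances})
    rows = []
    for contrast in contrasts:
        for lower, higher in pairs:
            for direction, (bin_lo, bin_hi) in PATHWAY_BINS.items():
                ka = (contrast, lower, bin_lo)
                kb = (contrast, higher, bin_hi)
                if ka not in distances or kb not in distances:
                    raise InputError(f"missing distance series for pathway {ka} - {kb}")
                r = informational_connectivity(distances[ka], distances[kb])
                rows.append(
                    {
                        "contrast": contrast,
                        "lower": lower,
                        "higher": higher,
                        "direction": direction,
                        "r": r,
                        "z": _stats.fisher_z(min(max(r, -0.999999), 0.999999)),
                    }
                )
    return pd.DataFrame(rows)


def group_inference(subject_table: pd.DataFrame) -> pd.DataFrame:
    """Group-level inference on Fisher-z connectivity values.

    ``subject_table`` is tidy with columns (subject, contrast, lower,
    higher, direction, z).  A two-sided one-sample t against 0 is run per
    pathway cell and Benjamini-Hochberg FDR is applied across the whole
    family of tested cells.
    """
    cells = subject_table.groupby(["contrast", "lower", "higher", "direction"])
    rows = []
    for key, g in cells:
        z = g["z"].to_numpy()
        if z.size < 3:
            raise InputError(f"need >= 3 subjects per cell; {key} has {z.size}")
        res = _stats.one_sample_t(z)
        rows.append(
            dict(
                zip(["contrast", "lower", "higher", "direction"], key),
                n=z.size,
                mean_r=_stats.fisher_z_inverse(z.mean()),
                t=res.t,
                df=res.df,
                p=res.p,
            )
        )
    out = pd.DataFrame(rows)
    out["q"] = _stats.fdr_bh(out["p"].to_numpy())
    return out
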