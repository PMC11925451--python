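"""End-to-end orchestration: simulate cohorts, analyse subjects, group stats.

``analyze_subject`` consumes the three simulated experiments of one subject
and produces everything the figures of a columnar/laminar study need:
compartment selectivity profiles with a stripe-segmentation estimate,
depth-bin selectivity profiles after pial-vein removal, an eccentricity
profile for texture, and layer-specific informational-connectivity
distances.  ``run_cohort`` repeats that over simulated subjects and adds the
group statistics (paired t, repeated-measures ANOVA, bootstrap compartment
null, FDR-corrected connectivity inference).  ``reliability_analysis``
emulates the two-session test-retest protocol with its Monte-Carlo FWE
null.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import glm as _glm
from . import infoconn as _ic
from . import laminar as _laminar
from . import reliability as _rel
from . import selectivity as _sel
from . import stats as _stats
from . import synthetic as _syn
from .exceptions import InputError
from .synthetic import CONTRAST_CONDITIONS, CONTRASTS


@dataclass
class AnalysisConfig:
    """Analysis knobs (defaults follow the standard protocol)."""

    stripe_z: float = 1.0
    vein_fraction: float = 0.05
    drift_order: int = 2
    top_frac: float = 0.2
    n_tail: int = 200
    svm_C: float = 1.0
    concatenate_folds: bool = False  # alternative correlation mode (off by default)


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults emulate the reference protocol: ten subjects, six scanned with
    ten runs per experiment and four with four runs, 24 s blocks with five
    blocks per condition, TR 2.4 s, and stripe cycles of 8 mm.
    """

    n_subjects: int = 10
    runs_per_subject: tuple = (10, 10, 10, 10, 10, 10, 4, 4, 4, 4)
    patch: _syn.PatchConfig = field(default_factory=_syn.PatchConfig)
    truth: _syn.GroundTruth = field(default_factory=_syn.default_truth)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    stripe_cycle_mm: float = 8.0
    stripe_duty: tuple = (0.25, 0.25, 0.25, 0.25)
    blocks_per_condition: int = 5
    block_duration_s: float = 24.0
    fixation_s: float = 16.8
    tr_s: float = 2.4
    seed: int = 0

    def __post_init__(self):
        if len(self.runs_per_subject) != self.n_subjects:
            object.__setattr__(
                self,
                "runs_per_subject",
                tuple(self.runs_per_subject)[: self.n_subjects]
                + (self.runs_per_subject[-1],)
                * max(0, self.n_subjects - len(self.runs_per_subject)),
            )


def subject_seed(master_seed, subject):
    """Derived per-subject seed (stable, below 2**31)."""
    return int((int(master_seed) * 10007 + 97 * subject + 13) % (2**31))


def make_designs(cfg: CohortConfig, n_runs):
    return {
        contrast: _syn.make_block_design(
            CONTRAST_CONDITIONS[contrast],
            n_runs=n_runs,
            blocks_per_condition=cfg.blocks_per_condition,
            block_duration_s=cfg.block_duration_s,
            fixation_s=cfg.fixation_s,
            tr_s=cfg.tr_s,
            seed=cfg.seed,
        )
        for contrast in CONTRASTS
    }


def simulate_cohort_subject(cfg: CohortConfig, patch, subject, session=0):
    """Simulate all three experiments for one cohort subject."""
    seed = subject_seed(cfg.seed, subject)
    phase = float(
        np.random.default_rng([seed, 5]).uniform(0.0, cfg.stripe_cycle_mm)
    )
    stripes = _syn.make_stripe_map(
        patch, cycle_mm=cfg.stripe_cycle_mm, duty=cfg.stripe_duty, phase_mm=phase
    )
    truth = replace(cfg.truth, seed=seed)
    designs = make_designs(cfg, cfg.runs_per_subject[subject])
    data = _syn.simulate_subject(patch, stripes, designs, truth, session=session)
    return data, stripes


# ---------------------------------------------------------------------------
# subject-level analysis


@dataclass
class SubjectAnalysis:
    subject: int
    compartment_si: pd.DataFrame
    laminar_si: pd.DataFrame
    ecc_si: pd.DataFrame
    dice: pd.DataFrame
    connectivity: pd.DataFrame
    stripe_estimate: _sel.StripeEstimate
    vein: _laminar.VeinMask


def _fit_runs(dataset, drift_order):
    """Per-run per-condition and per-block GLM fits for one experiment."""
    cond_fits, block_fits = [], []
    for r in range(dataset.n_runs):
        Xc = _glm.build_design_matrix(dataset.design, r, "per_condition", drift_order)
        Xb = _glm.build_design_matrix(dataset.design, r, "per_block", drift_order)
        cond_fits.append(_glm.fit_glm(dataset.runs[r], Xc))
        block_fits.append(_glm.fit_glm(dataset.runs[r], Xb))
    return cond_fits, block_fits


def analyze_subject(datasets, cfg: AnalysisConfig, subject=0, planted_stripes=None) -> SubjectAnalysis:
    """Full single-subject analysis of the three experiments.

    ``datasets`` maps contrast -> BOLDDataset (sharing one patch).
    """
    patch = next(iter(datasets.values())).patch
    vox = patch.voxels
    cond_fits, block_fits, betas = {}, {}, {}
    for contrast, ds in datasets.items():
        cf, bf = _fit_runs(ds, cfg.drift_order)
        cond_fits[contrast], block_fits[contrast] = cf, bf
        betas[contrast] = _sel.contrast_betas(cf, ds.design, contrast)

    # vein removal: mean response to all stimulus conditions vs baseline,
    # averaged over experiments, then over depths within each column
    overall = np.mean([b.mean(axis=1) for b in betas.values()], axis=0)
    overall = pd.Series(overall, index=vox["voxel_id"].to_numpy())
    col_signal = pd.concat(
        [patch.column_means(a, overall) for a in patch.grids]
    )
    vein = _laminar.vein_mask(patch, col_signal, fraction=cfg.vein_fraction)
    excluded = vein.voxel_excluded.loc[vox["voxel_id"].to_numpy()].to_numpy()

    # stripe segmentation from the color-minus-disparity differential map
    diff_vox = (betas["color"][:, 0] - betas["color"][:, 1]) - (
        betas["disparity"][:, 0] - betas["disparity"][:, 1]
    )
    diff_cols = patch.column_means("V2", pd.Series(diff_vox, index=vox["voxel_id"].to_numpy()))
    act_cols = patch.column_means("V2", overall)
    stripes = _sel.segment_stripes(
        diff_cols, patch, z=cfg.stripe_z, include=act_cols > 0
    )

    in_v2 = (vox["area"] == "V2").to_numpy()
    comp_rows, dice_rows = [], []
    for contrast in datasets:
        prof = _sel.compartment_profile(
            betas[contrast][in_v2],
            stripes,
            contrast,
            voxel_ids=vox["voxel_id"].to_numpy()[in_v2],
        )
        comp_rows.append(prof)
    if planted_stripes is not None:
        est = stripes.of_voxels(vox["voxel_id"].to_numpy()[in_v2])
        true = planted_stripes.of_voxels(vox["voxel_id"].to_numpy()[in_v2])
        for c in ("thin", "thick", "pale"):
            dice_rows.append(
                {"compartment": c, "dice": _sel.dice_coefficient(est, true, c)}
            )

    lam_rows = [
        _sel.laminar_profile(betas[contrast], patch, area, contrast, vein_excluded=excluded)
        for contrast in datasets
        for area in patch.grids
    ]
    ecc_rows = [
        _sel.eccentricity_profile(
            betas[contrast], patch, "V2", contrast, vein_excluded=excluded
        )
        for contrast in datasets
    ]

    connectivity = _subject_connectivity(datasets, cond_fits, block_fits, excluded, cfg)

    def _tag(df):
        df = pd.concat(df, ignore_index=True) if isinstance(df, list) else df
        df.insert(0, "subject", subject)
        return df

    return SubjectAnalysis(
        subject=subject,
        compartment_si=_tag(comp_rows),
        laminar_si=_tag(lam_rows),
        ecc_si=_tag(ecc_rows),
        dice=_tag([pd.DataFrame(dice_rows)]) if dice_rows else pd.DataFrame(),
        connectivity=_tag([connectivity]),
        stripe_estimate=stripes,
        vein=vein,
    )


def _subject_connectivity(datasets, cond_fits, block_fits, excluded, cfg: AnalysisConfig):
    """Distance series per (contrast, area, bin) node and the pathway table."""
    patch = next(iter(datasets.values())).patch
    vox = patch.voxels
    bins = _laminar.depth_bin(vox["depth"].to_numpy())
    distances = {}
    for contrast, ds in datasets.items():
        conds = CONTRAST_CONDITIONS[contrast]
        # concatenated block metadata and t patterns across runs
        metas, tmats = [], []
        for r, bres in enumerate(block_fits[contrast]):
            onsets = ds.design.block_onsets[r]
            metas.append(
                pd.DataFrame(
                    {
                        "run": r,
                        "block": np.arange(len(onsets)),
                        "condition": [c for _, c in onsets],
                    }
                )
            )
            tmats.append(bres.block_t)
        blocks = pd.concat(metas, ignore_index=True)
        tall = np.concatenate(tmats, axis=1)  # voxel x total blocks
        vis = {
            r: cres.contrast_t({conds[0]: 1.0, conds[1]: 1.0})
            for r, cres in enumerate(cond_fits[contrast])
        }
        dif = {
            r: cres.contrast_t({conds[0]: 1.0, conds[1]: -1.0})
            for r, cres in enumerate(cond_fits[contrast])
        }
        for area in patch.grids:
            for b in _laminar.DEPTH_BINS:
                node = ((vox["area"] == area).to_numpy()) & (bins == b) & (~excluded)
                distances[(contrast, area, b)] = _ic.decode_distances(
                    tall[node].T,
                    blocks,
                    {r: (vis[r][node], dif[r][node]) for r in vis},
                    conds,
                    top_frac=cfg.top_frac,
                    n_tail=cfg.n_tail,
                    C=cfg.svm_C,
                    area=area,
                    depth_bin=b,
                    contrast=contrast,
                )
    return _ic.pathway_matrix(distances, contrasts=list(datasets))


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortResult:
    config: CohortConfig
    compartment_si: pd.DataFrame
    laminar_si: pd.DataFrame
    ecc_si: pd.DataFrame
    dice: pd.DataFrame
    connectivity: pd.DataFrame
    group_connectivity: pd.DataFrame

    def compartment_table(self, contrast):
        """subject x compartment SI matrix (thin, thick, pale order)."""
        sub = self.compartment_si[self.compartment_si["contrast"] == contrast]
        return sub.pivot(index="subject", columns="compartment", values="si")[
            ["thin", "thick", "pale"]
        ]

    def laminar_table(self, area, contrast):
        sub = self.laminar_si[
            (self.laminar_si["area"] == area) & (self.laminar_si["contrast"] == contrast)
        ]
        return sub.pivot(index="subject", columns="bin", values="si")[
            list(_laminar.DEPTH_BINS)
        ]

    def ecc_table(self, contrast):
        sub = self.ecc_si[self.ecc_si["contrast"] == contrast]
        return sub.pivot(index="subject", columns="bin", values="si")[
            list(_sel.ECC_BIN_NAMES)
        ]


def run_cohort(cfg: CohortConfig, progress=False) -> CohortResult:
    """Simulate and analyse a whole cohort; returns tidy result tables."""
    if cfg.n_subjects < 3:
        raise InputError("group statistics need at least 3 subjects")
    patch = _syn.make_cortical_patch(cfg.patch)
    parts = {k: [] for k in ("compartment_si", "laminar_si", "ecc_si", "dice", "connectivity")}
    for s in range(cfg.n_subjects):
        data, planted = simulate_cohort_subject(cfg, patch, s)
        sa = analyze_subject(data, cfg.analysis, subject=s, planted_stripes=planted)
        for k in parts:
            parts[k].append(getattr(sa, k))
        del data, sa
        if progress:
            print(f"subject {s + 1}/{cfg.n_subjects} done", flush=True)
    tables = {k: pd.concat(v, ignore_index=True) for k, v in parts.items()}
    group = _ic.group_inference(
        tables["connectivity"][["subject", "contrast", "lower", "higher", "direction", "z"]]
    )
    return CohortResult(cfg, group_connectivity=group, **tables)


# ---------------------------------------------------------------------------
# test-retest reliability


@dataclass
class ReliabilityResult:
    contrast: str
    observed_r: float
    p_fwe: float
    critical_r: float
    n_iter: int
    acf: _rel.ACFModel


def session_column_maps(cfg: CohortConfig, patch, subject, contrast, sessions=(0, 1)):
    """Columnar differential maps (and session-1 residual maps) for two sessions."""
    seed = subject_seed(cfg.seed, subject)
    phase = float(np.random.default_rng([seed, 5]).uniform(0.0, cfg.stripe_cycle_mm))
    stripes = _syn.make_stripe_map(
        patch, cycle_mm=cfg.stripe_cycle_mm, duty=cfg.stripe_duty, phase_mm=phase
    )
    truth = replace(cfg.truth, seed=seed)
    design = make_designs(cfg, cfg.runs_per_subject[subject])[contrast]
    maps, resid_maps = [], None
    vox = patch.voxels
    for si, session in enumerate(sessions):
        ds = _syn.simulate_bold(patch, stripes, design, truth, contrast, session=session)
        cf = [
            _glm.fit_glm(
                ds.runs[r],
                _glm.build_design_matrix(
                    design, r, "per_condition", AnalysisConfig().drift_order
                ),
            )
            for r in range(ds.n_runs)
        ]
        betas = _sel.contrast_betas(cf, design, contrast)
        diff = pd.Series(
            betas[:, 0] - betas[:, 1], index=vox["voxel_id"].to_numpy()
        )
        maps.append(patch.column_grid("V2", patch.column_means("V2", diff)))
        if si == 0:
            # session-1 residuals, column-averaged, as (T, nv, nu) maps
            res = cf[0].residuals
            g = patch.grids["V2"]
            v2 = vox["area"].to_numpy() == "V2"
            rm = np.zeros((res.shape[1], g.nv, g.nu))
            counts = np.zeros((g.nv, g.nu))
            np.add.at(counts, (vox["iv"].to_numpy()[v2], vox["iu"].to_numpy()[v2]), 1)
            for t in range(res.shape[1]):
                acc = np.zeros((g.nv, g.nu))
                np.add.at(
                    acc, (vox["iv"].to_numpy()[v2], vox["iu"].to_numpy()[v2]), res[v2, t]
                )
                rm[t] = acc / counts
            resid_maps = rm
        del ds
    return maps, resid_maps


def reliability_analysis(
    cfg: CohortConfig, subject=0, contrast="color", n_iter=10000, seed=0
) -> ReliabilityResult:
    """Two-session pattern correlation with the Monte-Carlo FWE null."""
    patch = _syn.make_cortical_patch(cfg.patch)
    (map1, map2), resid_maps = session_column_maps(cfg, patch, subject, contrast)
    acf = _rel.estimate_acf(resid_maps, spacing_mm=cfg.patch.spacing_mm)
    observed = _rel.pattern_correlation(map1, map2)
    null = _rel.simulate_null_correlations(acf, map1, n_iter=n_iter, seed=seed)
    return ReliabilityResult(
        contrast=contrast,
        observed_r=observed,
        p_fwe=_rel.fwe_corrected_p(observed, null),
        critical_r=null.critical_value(0.05),
        n_iter=n_iter,
        acf=acf,
    )


def reliability_type1_rate(acf, shape, n_repeats=1000, n_iter=1000, seed=0, alpha=0.05):
    """Empirical false-positive rate of the FWE test under independent sessions.

    Both "session" maps and the null maps are drawn from the same fitted
    ACF, so the p-value should be uniform and p < alpha should occur at
    rate alpha.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 73])
    hits = 0
    for rep in range(n_repeats):
        pair = _rel.simulate_smooth_maps(acf, shape, 2, rng)
        obs = _rel.pattern_correlation(pair[0], pair[1])
        null = _rel.simulate_null_correlations(
            acf, pair[0], n_iter=n_iter, seed=int(rng.integers(2**31))
        )
        if _rel.fwe_corrected_p(obs, null) < alpha:
            hits += 1
    return hits / n_repeats


# ---------------------------------------------------------------------------
# group summaries used by reports


def laminar_group_tests(result: CohortResult, area="V2"):
    """RM-ANOVA across depth bins plus post hoc paired t-tests, per contrast."""
    rows = []
    for contrast in CONTRASTS:
        tab = result.laminar_table(area, contrast)
        an = _stats.rm_anova_oneway(tab.to_numpy())
        row = {
            "area": area,
            "contrast": contrast,
            "F": an.f,
            "df1": an.df_effect,
            "df2": an.df_error,
            "p_anova": an.p,
        }
        for a, b in (("superficial", "middle"), ("superficial", "deep"), ("deep", "middle")):
            t, df, p = _stats.paired_t(tab[a], tab[b])
            row[f"t_{a[0]}_vs_{b[0]}"] = t
            row[f"p_{a[0]}_vs_{b[0]}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def compartment_group_tests(result: CohortResult, n_boot=10000, seed=0):
    """Compartment-level tests: paired t for the planted preferences,
    RM-ANOVA and bootstrap null for texture."""
    color = result.compartment_table("color")
    disp = result.compartment_table("disparity")
    tex = result.compartment_table("texture")
    t_thin, _, p_thin = _stats.paired_t(color["thin"], color["thick"])
    t_thick, _, p_thick = _stats.paired_t(disp["thick"], disp["thin"])
    an = _stats.rm_anova_oneway(tex.to_numpy())
    boot = _stats.bootstrap_compartment_null(
        tex.to_numpy(), labels=list(tex.columns), n_iter=n_boot, seed=seed
    )
    return {
        "color_thin_vs_thick": {"t": t_thin, "p": p_thin},
        "disparity_thick_vs_thin": {"t": t_thick, "p": p_thick},
        "texture_anova": {"F": an.f, "p": an.p},
        "texture_bootstrap_p": dict(
            (f"{a}_vs_{b}", p) for (a, b), p in boot.p.items()
        ),
    }


def config_to_dict(cfg: CohortConfig):
    d = dataclasses.asdict(cfg)
    d["truth"] = cfg.truth.to_dict()
    return d
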