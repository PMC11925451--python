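"""YAML-serialisable run configuration and static validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from . import pipeline as _pipe
from . import synthetic as _syn
from .exceptions import ConfigurationError


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    ``cohort`` carries the generator and analysis settings; ``reliability``
    the Monte-Carlo settings of the test-retest stage.
    """

    cohort: _pipe.CohortConfig = field(default_factory=_pipe.CohortConfig)
    reliability_n_iter: int = 10000
    reliability_subject: int = 0
    bootstrap_n_iter: int = 10000
    seed: int = 0

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["cohort"] = _pipe.config_to_dict(self.cohort)
        return d

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        coh = dict(d.pop("cohort", {}))
        if "patch" in coh:
            p = dict(coh["patch"])
            if "area_grids" in p:
                p["area_grids"] = {k: tuple(v) for k, v in p["area_grids"].items()}
            if "ecc_range" in p:
                p["ecc_range"] = tuple(p["ecc_range"])
            coh["patch"] = _syn.PatchConfig(**p)
        if "truth" in coh:
            coh["truth"] = _syn.GroundTruth.from_dict(coh["truth"])
        if "analysis" in coh:
            coh["analysis"] = _pipe.AnalysisConfig(**coh["analysis"])
        for key in ("runs_per_subject", "stripe_duty"):
            if key in coh:
                coh[key] = tuple(coh[key])
        return cls(cohort=_pipe.CohortConfig(**coh), **d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self):
        """Stable hash of the full configuration (for provenance logs)."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(config: RunConfig):
    """Statically check every documented invariant; returns a list of violations."""
    v = []
    coh = config.cohort
    for area, dims in coh.patch.area_grids.items():
        if min(dims) <= 0:
            v.append(f"make_cortical_patch: non-positive grid dimension for {area}")
    if coh.patch.n_depth <= 0:
        v.append("make_cortical_patch: n_depth must be positive")
    duty = coh.stripe_duty
    if len(duty) != 4 or abs(sum(duty) - 1.0) > 1e-9:
        v.append("make_stripe_map: duty fractions must sum to 1")
    if coh.stripe_cycle_mm <= 0:
        v.append("make_stripe_map: cycle_mm must be positive")
    ratio = (
        2 * coh.fixation_s
        + 2 * coh.blocks_per_condition * coh.block_duration_s
    ) / coh.tr_s
    if abs(ratio - round(ratio)) > _syn.TR_ALIGNMENT_TOL:
        v.append("make_block_design: run length is not a whole number of TRs")
    v.extend(f"ground truth: {msg}" for msg in coh.truth.validate())
    if coh.n_subjects < 3:
        v.append("group statistics require n_subjects >= 3")
    ana = coh.analysis
    if not 0 < ana.top_frac <= 1:
        v.append("analysis: top_frac must lie in (0, 1]")
    if ana.n_tail < 1:
        v.append("analysis: n_tail must be >= 1")
    n_cols = min(dims[0] * dims[1] for dims in coh.patch.area_grids.values())
    import math

    if math.ceil(ana.top_frac * n_cols) < 2 * ana.n_tail:
        v.append(
            "analysis: feature pool (top_frac of smallest area's columns) "
            "smaller than 2 * n_tail"
        )
    if ana.svm_C <= 0:
        v.append("analysis: svm_C must be positive")
    if config.reliability_n_iter < 100:
        v.append("reliability: n_iter must be >= 100")
    return v


def check_config(config: RunConfig):
    violations = validate_config(config)
    if violations:
        raise ConfigurationError("; ".join(violations))
    return config
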