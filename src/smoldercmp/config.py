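"""Simulation and pipeline configuration objects.

Defaults encode the cohort the generator emulates: two confounded treatment
groups (teriflunomide vs ocrelizumab) of relapsing-remitting MS patients with
annual clinical visits, sparse MRI, low relapse rates on therapy, slow
confirmed-worsening accrual, and group-specific brain-atrophy rates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Optional

GROUPS = ("ocrelizumab", "teriflunomide")

#: Volumetric outcomes (ml columns in mri.csv) modelled with exponential decay.
VOLUMETRIC_OUTCOMES = ("brain_ml", "cortex_ml", "thalamus_ml", "gm_ml")

DTI_METRICS = ("fa", "md", "rd", "ad")
DTI_REGIONS = ("wml", "nawm", "cortex")
DTI_OUTCOMES = tuple(f"{m}_{r}" for m in DTI_METRICS for r in DTI_REGIONS)


def _default_true_apc() -> dict:
    # %/year; negative = loss. Group-specific atrophy rates.
    return {
        "brain_ml": {"ocrelizumab": -1.06, "teriflunomide": -0.80},
        "cortex_ml": {"ocrelizumab": -1.24, "teriflunomide": -0.97},
        "thalamus_ml": {"ocrelizumab": -0.97, "teriflunomide": -1.04},
        "gm_ml": {"ocrelizumab": -1.20, "teriflunomide": -0.92},
    }


def _default_dti_drift() -> dict:
    # %/year drift per DTI outcome; null by default (no group difference).
    return {k: {"ocrelizumab": 0.0, "teriflunomide": 0.0} for k in DTI_OUTCOMES}


def _default_measurement_sd() -> dict:
    # multiplicative noise SD on the log scale (volumes ~0.4% scan-rescan),
    # relative noise for DTI region means, additive for EDSS (0 keeps the
    # trajectory on-scale; worsening enters through explicit steps).
    return {"volume": 0.004, "dti": 0.01, "edss": 0.0}


@dataclass
class SimulationConfig:
    """Free parameters of the synthetic cohort generator.

    Rates are per person-year; days are integers from treatment start
    (day 0); ``followup_median_years`` is per-group to mirror the
    asymmetric observation periods of the two treatment arms.
    """

    n_per_group: int = 128
    seed: int = 0
    confounding_strength: float = 0.5  # log-odds scale on the covariate score
    true_pira_hazard_ratio: float = 0.80  # teriflunomide vs ocrelizumab
    baseline_pira_rate: float = 0.10  # true onset rate / person-year (ocrelizumab
    # arm); annual visit grids confirm roughly half of onsets, so the detected
    # incidence lands near the ~0.05/person-year seen in comparable cohorts
    relapse_rate: float = 0.15  # events / person-year
    true_apc: dict = field(default_factory=_default_true_apc)
    dti_drift: dict = field(default_factory=_default_dti_drift)
    prl_new_prob: float = 0.025  # new-PRL probability / person-year
    visit_interval_days: float = 365.0
    visit_jitter_days: float = 60.0
    mri_interval_days: float = 365.0
    mri_jitter_days: float = 90.0
    dropout_rate: float = 0.05  # / person-year
    measurement_sd: dict = field(default_factory=_default_measurement_sd)
    followup_median_years: dict = field(
        default_factory=lambda: {"ocrelizumab": 3.1, "teriflunomide": 1.9}
    )
    followup_max_years: float = 6.0
    # residual step probability + transient bump of a relapse
    relapse_residual_prob: float = 0.3
    relapse_bump_decay_days: float = 90.0
    # new/enlarged-T2 flag probabilities per MRI interval
    new_t2_base_prob: float = 0.05
    new_t2_relapse_prob: float = 0.60
    # sub-cohort sizes per group with MRI data (None -> all patients)
    n_atrophy_per_group: Optional[int] = 72
    n_dti_per_group: Optional[int] = 33
    n_prl_per_group: Optional[int] = 31

    def validate(self) -> "SimulationConfig":
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in (
            "baseline_pira_rate",
            "relapse_rate",
            "dropout_rate",
            "visit_interval_days",
            "mri_interval_days",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("prl_new_prob", "new_t2_base_prob", "new_t2_relapse_prob",
                     "relapse_residual_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.true_pira_hazard_ratio <= 0:
            raise ValueError("true_pira_hazard_ratio must be > 0")
        for g in GROUPS:
            if g not in self.followup_median_years:
                raise ValueError(f"followup_median_years missing group {g}")
        for out in VOLUMETRIC_OUTCOMES:
            if out not in self.true_apc:
                raise ValueError(f"true_apc missing outcome {out}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimulationConfig keys: {sorted(unknown)}")
        merged = cls(**d)
        # nested maps: overlay user-provided entries on the defaults
        for attr, default in (
            ("true_apc", _default_true_apc()),
            ("dti_drift", _default_dti_drift()),
            ("measurement_sd", _default_measurement_sd()),
        ):
            if attr in d:
                merged_map = default
                merged_map.update(d[attr])
                setattr(merged, attr, merged_map)
        return merged.validate()


def config_hash(payload: Any) -> str:
    """Stable SHA-256 hash of a JSON-serializable config payload."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
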