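"""Synthetic cohorts with planted subgroup structure.

The generator emulates the statistical shape of a very-preterm follow-up
cohort integrated from three data types:

- ``neonatal`` (mixed): two numeric variables — neighborhood deprivation
  (IMD) and gestational age (GA) — plus three zero-inflated counts (days on
  ventilation, parenteral nutrition and CPAP) that preprocessing recodes to
  3-level ordinals;
- ``socioemotional`` (numeric): four questionnaire subscales;
- ``executive_function`` (numeric): five rating subscales;

together with held-out numeric outcomes (psychopathology, temperament, IQ,
home stimulation) and covariates (age at assessment, sex).

Planted structure: each subject belongs to one of C clusters; numeric
variables are cluster-specific Gaussians whose adjacent-cluster centroids are
``effect_size`` standard deviations apart (sign alternating across variables
so no single direction dominates); zero-inflated counts are a cluster-specific
point mass at zero plus a shifted Poisson whose rate follows the cluster's
ordinal profile; out-of-model outcomes get their own standardized separation.
Labels are emitted separately and are never visible to the clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import FeatureBlock, write_blocks

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "default_ordinal_profiles"]

BLOCK1_NUMERIC = ("imd", "ga")
BLOCK1_COUNTS = ("ventilation_days", "tpn_days", "cpap_days")
BLOCK2_VARS = ("emotion_contagion", "attention_to_emotions", "prosocial_behaviors", "srs_total")
BLOCK3_VARS = ("inhibit", "shift", "emotional_control", "working_memory", "plan_organize")
OUT_OF_MODEL_VARS = (
    "sdq_internalizing", "sdq_externalizing", "sdq_total",
    "cbq_negative_affectivity", "cbq_surgency", "cbq_effortful_control",
    "wppsi_fsiq", "csps",
)

# nominal offsets/scales so raw tables look like plausible instrument scores;
# separations are defined on the standardized scale, so these do not affect
# any downstream statistic
_BASE = {
    "imd": (20.0, 8.0), "ga": (30.0, 2.0),
    "emotion_contagion": (8.0, 2.0), "attention_to_emotions": (10.0, 2.5),
    "prosocial_behaviors": (12.0, 3.0), "srs_total": (40.0, 10.0),
    "inhibit": (25.0, 5.0), "shift": (15.0, 4.0), "emotional_control": (14.0, 4.0),
    "working_memory": (26.0, 6.0), "plan_organize": (17.0, 4.0),
    "sdq_internalizing": (5.0, 2.0), "sdq_externalizing": (6.0, 2.5),
    "sdq_total": (11.0, 4.0), "cbq_negative_affectivity": (4.0, 0.8),
    "cbq_surgency": (4.5, 0.8), "cbq_effortful_control": (5.0, 0.7),
    "wppsi_fsiq": (100.0, 15.0), "csps": (25.0, 5.0),
}


def default_ordinal_profiles(n_clusters: int, effect_size: float) -> dict:
    """Cluster-graded 3-level profiles for the zero-inflated count variables.

    At ``effect_size=0`` every cluster shares one profile (no signal); as the
    effect grows (capped at 2) profiles spread so higher-index clusters carry
    more mass at higher levels, mimicking sicker neonates accruing more days
    of support.
    """
    w = min(effect_size, 2.0) / 2.0
    base = np.array([0.5, 0.35, 0.15])
    profiles = {}
    for var in BLOCK1_COUNTS:
        rows = []
        for c in range(n_clusters):
            t = c / (n_clusters - 1) if n_clusters > 1 else 0.5
            target = np.array([0.7 - 0.5 * t, 0.3 + 0.1 * t, 0.4 * t])
            target /= target.sum()
            rows.append((1 - w) * base + w * target)
        profiles[var] = np.asarray(rows)
    return profiles


@dataclass
class CohortSpec:
    """Parameters of a planted-cluster synthetic cohort.

    effect_size : standardized adjacent-cluster centroid separation on every
        in-model numeric variable (units of that variable's SD).
    out_of_model_effect : same, for held-out outcomes.
    noise_sd : within-cluster SD on the standardized scale.
    outlier_rate : per-entry probability of replacing an in-model numeric
        value with an extreme one (~12 SD out), to exercise the exclusion rule.
    ordinal_profiles : per-variable (n_clusters x 3) probability arrays for
        the zero-inflated counts; defaults to effect-graded profiles.
    equicorrelation : within-block correlation of the numeric noise.
    covariate_confounding : shift of mean age per cluster index (years), to
        induce confounding for covariate-adjusted tests.
    """

    n_subjects: int = 198
    cluster_proportions: tuple = (0.5, 0.5)
    effect_size: float = 1.0
    ordinal_profiles: dict | None = None
    noise_sd: float = 1.0
    outlier_rate: float = 0.0
    out_of_model_effect: float = 1.0
    equicorrelation: float = 0.0
    covariate_confounding: float = 0.0
    age_range: tuple = (4.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.cluster_proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-12 or (p < 0).any():
            raise ValueError("cluster_proportions must be nonnegative and sum to 1 (tol 1e-12)")
        if self.n_subjects < 3 * len(p):
            raise ValueError("n_subjects must be >= 3 x number of clusters")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.outlier_rate <= 1):
            raise ValueError("outlier_rate must lie in [0, 1]")
        if self.effect_size < 0 or self.out_of_model_effect < 0:
            raise ValueError("effect sizes must be nonnegative")
        if not (0 <= self.equicorrelation < 1):
            raise ValueError("equicorrelation must lie in [0, 1)")
        if self.ordinal_profiles is None:
            self.ordinal_profiles = default_ordinal_profiles(len(p), self.effect_size)
        for var, prof in self.ordinal_profiles.items():
            prof = np.asarray(prof, dtype=float)
            if prof.shape != (len(p), 3):
                raise ValueError(
                    f"ordinal profile for {var!r} must have shape ({len(p)}, 3)"
                )
            if (prof < 0).any() or not np.allclose(prof.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"ordinal profile rows for {var!r} must sum to 1")
            self.ordinal_profiles[var] = prof

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_proportions)

    def cluster_counts(self) -> np.ndarray:
        """Deterministic largest-remainder allocation of subjects to clusters."""
        p = np.asarray(self.cluster_proportions, dtype=float)
        raw = self.n_subjects * p
        counts = np.floor(raw).astype(int)
        rem = self.n_subjects - counts.sum()
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:rem]] += 1
        return counts

    def _offset(self, var_index: int, cluster: int, effect: float) -> float:
        sign = 1.0 if var_index % 2 == 0 else -1.0
        return effect * sign * (cluster - (self.n_clusters - 1) / 2.0)

    def cluster_mean(self, var: str, cluster: int) -> float:
        """Planted mean of a numeric variable within a cluster (raw scale)."""
        base, scale = _BASE[var]
        if var in OUT_OF_MODEL_VARS:
            eff, vars_list = self.out_of_model_effect, list(OUT_OF_MODEL_VARS)
        else:
            eff = self.effect_size
            vars_list = [*BLOCK1_NUMERIC, *BLOCK2_VARS, *BLOCK3_VARS]
        j = vars_list.index(var)
        return base + scale * self.noise_sd * self._offset(j, cluster, eff)

    def cluster_sd(self, var: str) -> float:
        return _BASE[var][1] * self.noise_sd


@dataclass
class SyntheticCohort:
    """Generated cohort: blocks, held-out outcomes, covariates, true labels."""

    blocks: list[FeatureBlock]
    out_of_model: pd.DataFrame
    covariates: pd.DataFrame
    true_labels: pd.Series
    spec: CohortSpec = field(repr=False, default=None)

    def write(self, directory) -> None:
        """Write block CSVs + manifest, outcomes, covariates and labels.

        True labels go to their own file so the clustering inputs never
        contain them.
        """
        directory = Path(directory)
        write_blocks(self.blocks, directory)
        self.out_of_model.to_csv(directory / "out_of_model.csv")
        self.covariates.to_csv(directory / "covariates.csv")
        self.true_labels.rename("cluster").to_csv(directory / "true_labels.csv")


def _numeric_matrix(rng, spec, labels, var_names, effect, rho):
    n = len(labels)
    k = len(var_names)
    z = rng.standard_normal((n, k))
    if rho > 0:
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * z
    cols = {}
    for j, var in enumerate(var_names):
        base, scale = _BASE[var]
        offsets = np.array(
            [spec._offset(j, c, effect) for c in range(spec.n_clusters)]
        )[labels]
        cols[var] = base + scale * spec.noise_sd * (offsets + z[:, j])
    return cols


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort from the spec; bit-identical given the same seed."""
    rng = np.random.default_rng(spec.seed)
    counts = spec.cluster_counts()
    labels0 = np.repeat(np.arange(spec.n_clusters), counts)  # 0-based
    ids = [f"S{i + 1:04d}" for i in range(spec.n_subjects)]

    b1 = _numeric_matrix(rng, spec, labels0, BLOCK1_NUMERIC, spec.effect_size,
                         spec.equicorrelation)
    for var in BLOCK1_COUNTS:
        prof = spec.ordinal_profiles[var]
        pi_zero = prof[labels0, 0]
        lvl12 = prof[:, 1] + prof[:, 2]
        share2 = np.where(lvl12 > 0, prof[:, 2] / np.where(lvl12 > 0, lvl12, 1.0), 0.0)
        rate = 1.0 + 6.0 * share2
        zero = rng.random(spec.n_subjects) < pi_zero
        counts_draw = 1 + rng.poisson(rate[labels0])
        b1[var] = np.where(zero, 0, counts_draw).astype(float)

    b2 = _numeric_matrix(rng, spec, labels0, BLOCK2_VARS, spec.effect_size,
                         spec.equicorrelation)
    b3 = _numeric_matrix(rng, spec, labels0, BLOCK3_VARS, spec.effect_size,
                         spec.equicorrelation)
    oom = _numeric_matrix(rng, spec, labels0, OUT_OF_MODEL_VARS,
                          spec.out_of_model_effect, 0.0)

    # inject outliers on in-model numerics (far outside any 3xIQR fence)
    if spec.outlier_rate > 0:
        for cols, var_names in ((b1, BLOCK1_NUMERIC), (b2, BLOCK2_VARS), (b3, BLOCK3_VARS)):
            for var in var_names:
                hit = rng.random(spec.n_subjects) < spec.outlier_rate
                sign = np.where(rng.random(spec.n_subjects) < 0.5, -1.0, 1.0)
                base, scale = _BASE[var]
                cols[var] = np.where(
                    hit, base + sign * 12.0 * scale * spec.noise_sd, cols[var]
                )

    age = rng.uniform(*spec.age_range, size=spec.n_subjects)
    age = age + spec.covariate_confounding * labels0
    sex = rng.integers(0, 2, size=spec.n_subjects)

    blocks = [
        FeatureBlock(
            "block1",
            pd.DataFrame(b1, index=ids),
            {**{v: "numeric" for v in BLOCK1_NUMERIC},
             **{v: "zero_inflated_count" for v in BLOCK1_COUNTS}},
            "mixed",
        ),
        FeatureBlock("block2", pd.DataFrame(b2, index=ids),
                     {v: "numeric" for v in BLOCK2_VARS}, "numeric_only"),
        FeatureBlock("block3", pd.DataFrame(b3, index=ids),
                     {v: "numeric" for v in BLOCK3_VARS}, "numeric_only"),
    ]
    return SyntheticCohort(
        blocks=blocks,
        out_of_model=pd.DataFrame(oom, index=ids),
        covariates=pd.DataFrame({"age": age, "sex": sex}, index=ids),
        true_labels=pd.Series(labels0 + 1, index=ids, name="cluster"),
        spec=spec,
    )
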