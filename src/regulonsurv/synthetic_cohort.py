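"""Synthetic expression + survival cohorts with planted regulon structure.

The generator emulates the statistical setting the pipeline assumes: each
transcription regulator has a latent per-sample activity that drives a
correlated block of target genes, survival follows a proportional-hazards
model on those latent activities, and validation cohorts can be distorted by
per-sample monotone "platform" transforms that leave within-sample expression
ranks intact.

Generative model, per sample ``s`` and regulator ``r``:

* latent activity ``a[r, s] ~ N(0, 1)`` (independent across regulators by
  default; an equicorrelation parameter is exposed);
* the regulator's own expression is ``a[r, s] + N(0, noise_sd)``;
* each of its ``regulon_size`` planted targets is
  ``target_effect * a[r, s] + N(0, noise_sd)``;
* background genes are pure ``N(0, noise_sd)`` noise;
* death time is exponential with rate
  ``baseline_hazard * exp(sum_r coef[r] * a[r, s])``, censoring time is
  exponential with rate ``censor_rate``; observed time is the minimum and the
  event flag marks death before censoring.

The returned candidate target map contains, per regulator, the planted
targets plus an equal number of decoy background genes, so the co-expression
refinement step has a non-trivial intersection to perform.  Optionally an
ordinal stage label correlated with the latent log-hazard is attached to the
clinical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import ExpressionMatrix, RegulatorTargetMap, SurvivalTable

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "apply_platform_transform",
]

_STAGE_LABELS = ("I", "II", "III", "IV")


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``prognostic_regulators`` lists ``(regulator_index, log_hazard_per_sd)``
    pairs; all other regulators carry a zero coefficient.  Rates are per day:
    the defaults give a median survival of roughly six years and ~50%
    censoring, in the range of breast-cancer overall-survival cohorts.
    """

    n_samples: int = 300
    n_genes: int = 600
    n_regulators: int = 10
    regulon_size: int = 20
    target_effect: float = 1.0
    noise_sd: float = 1.0
    prognostic_regulators: Sequence[tuple[int, float]] = ((0, 0.5), (1, -0.5))
    baseline_hazard: float = 3e-4
    censor_rate: float = 3e-4
    activity_correlation: float = 0.0
    n_stages: int = 0
    stage_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        # normalize (e.g. YAML lists) so configs compare equal after round-trips
        self.prognostic_regulators = tuple(
            (int(idx), float(coef)) for idx, coef in self.prognostic_regulators
        )

    def validate(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_regulators, self.regulon_size) <= 0:
            raise ValueError("n_samples, n_genes, n_regulators, regulon_size must be positive")
        if self.n_regulators * self.regulon_size > self.n_genes - self.n_regulators:
            raise ValueError(
                "planted targets do not fit: need n_regulators * regulon_size "
                "<= n_genes - n_regulators"
            )
        if self.target_effect < 0:
            raise ValueError("target_effect must be non-negative")
        if self.noise_sd <= 0 or self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValueError("noise_sd, baseline_hazard and censor_rate must be positive")
        if not 0.0 <= self.activity_correlation < 1.0:
            raise ValueError("activity_correlation must be in [0, 1)")
        for idx, _coef in self.prognostic_regulators:
            if not 0 <= idx < self.n_regulators:
                raise ValueError(f"prognostic regulator index {idx} out of range")
        if self.n_stages and not 2 <= self.n_stages <= len(_STAGE_LABELS):
            raise ValueError(f"n_stages must be 0 or in [2, {len(_STAGE_LABELS)}]")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort."""

    true_targets: dict[str, set[str]]
    true_activities: np.ndarray  # regulators x samples
    true_coefficients: dict[str, float]
    regulators: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def activity_of(self, regulator: str) -> np.ndarray:
        return self.true_activities[self.regulators.index(regulator)]


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, SurvivalTable, RegulatorTargetMap, SyntheticTruth]:
    """Draw one cohort; bitwise reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    R, n, G = config.n_regulators, config.n_samples, config.n_genes
    k = config.regulon_size

    regulators = [f"TF{i + 1:03d}" for i in range(R)]
    n_targets = R * k
    target_genes = [f"G{i + 1:05d}" for i in range(n_targets)]
    n_background = G - R - n_targets
    background_genes = [f"BG{i + 1:05d}" for i in range(n_background)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # latent activities, optionally equicorrelated through a shared factor
    activities = rng.standard_normal((R, n))
    if config.activity_correlation > 0:
        rho = config.activity_correlation
        shared = rng.standard_normal(n)
        activities = math.sqrt(rho) * shared + math.sqrt(1 - rho) * activities

    values = np.empty((G, n))
    values[:R] = activities + rng.normal(0.0, config.noise_sd, size=(R, n))
    true_targets: dict[str, set[str]] = {}
    for r in range(R):
        block = slice(R + r * k, R + (r + 1) * k)
        values[block] = config.target_effect * activities[r] + rng.normal(
            0.0, config.noise_sd, size=(k, n)
        )
        true_targets[regulators[r]] = set(target_genes[r * k : (r + 1) * k])
    values[R + n_targets :] = rng.normal(0.0, config.noise_sd, size=(n_background, n))

    expr = ExpressionMatrix(regulators + target_genes + background_genes, sample_ids, values)

    # decoy candidate targets: background genes with no co-expression signal
    if n_background >= R * k:
        pool = rng.permutation(n_background)
        decoys = [pool[r * k : (r + 1) * k] for r in range(R)]
    elif n_background >= k:
        decoys = [rng.choice(n_background, size=k, replace=False) for r in range(R)]
    else:
        raise ValueError(
            f"need at least regulon_size={k} background genes for decoy targets, "
            f"have {n_background}"
        )
    entries = {
        regulators[r]: true_targets[regulators[r]] | {background_genes[i] for i in decoys[r]}
        for r in range(R)
    }
    target_map = RegulatorTargetMap(entries)

    # proportional-hazards survival with exponential baseline and censoring
    coefs = np.zeros(R)
    for idx, coef in config.prognostic_regulators:
        coefs[idx] = coef
    log_hazard = coefs @ activities
    death = rng.exponential(1.0 / (config.baseline_hazard * np.exp(log_hazard)))
    censor = rng.exponential(1.0 / config.censor_rate, size=n)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)

    stage = None
    if config.n_stages:
        # ordinal stage from equal-probability cuts of a noisy risk score
        noisy = log_hazard + rng.normal(0.0, config.stage_noise_sd, size=n)
        scale = math.sqrt(float(coefs @ coefs) + config.stage_noise_sd**2)
        if scale == 0:
            scale = 1.0
        from scipy.stats import norm

        cuts = norm.ppf(np.linspace(0, 1, config.n_stages + 1)[1:-1]) * scale
        stage = np.array([_STAGE_LABELS[int(np.searchsorted(cuts, x))] for x in noisy], dtype=object)

    survival = SurvivalTable(sample_ids, time, event, stage=stage)
    truth = SyntheticTruth(
        true_targets=true_targets,
        true_activities=activities,
        true_coefficients={regulators[r]: float(coefs[r]) for r in range(R)},
        regulators=regulators,
        sample_ids=sample_ids,
    )
    return expr, survival, target_map, truth


# ---------------------------------------------------------------------------
# platform transforms
# ---------------------------------------------------------------------------


def apply_platform_transform(
    expr: ExpressionMatrix,
    kind: str,
    params: dict | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Distort a matrix the way a different expression platform would.

    ``affine`` and ``monotone_spline`` apply per-sample strictly increasing
    maps and therefore preserve within-sample expression ranks exactly;
    ``gene_dropout`` removes a fraction of genes at random.  Parameters not
    supplied are drawn per sample from ``seed``.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    values = expr.values.copy()
    n = expr.n_samples

    if kind == "affine":
        slope = params.get("slope")
        intercept = params.get("intercept")
        slopes = np.full(n, float(slope)) if slope is not None else rng.uniform(0.5, 2.0, n)
        intercepts = (
            np.full(n, float(intercept)) if intercept is not None else rng.uniform(-2.0, 2.0, n)
        )
        if np.any(slopes <= 0):
            raise ValueError("affine slope must be positive (a non-positive slope reverses ranks)")
        values = values * slopes + intercepts
        return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), values)

    if kind == "monotone_spline":
        # smooth strictly increasing map f(x) = a*x + b*tanh(c*x), f' = a + b*c*sech^2 > 0
        a = rng.uniform(0.5, 2.0, n)
        b = rng.uniform(0.0, 1.0, n)
        c = rng.uniform(0.2, 1.0, n)
        values = a * values + b * np.tanh(c * values)
        return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), values)

    if kind == "gene_dropout":
        fraction = float(params.get("fraction", 0.0))
        if not 0.0 <= fraction < 1.0:
            raise ValueError("dropout fraction must be in [0, 1)")
        n_drop = int(fraction * expr.n_genes)
        if n_drop == 0:
            return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), values)
        drop = set(rng.choice(expr.n_genes, size=n_drop, replace=False).tolist())
        keep = [i for i in range(expr.n_genes) if i not in drop]
        return ExpressionMatrix(
            [expr.gene_ids[i] for i in keep], list(expr.sample_ids), values[keep]
        )

    raise ValueError(f"unknown platform transform {kind!r}")
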