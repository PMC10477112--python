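"""Standard validation experiments for the quantification stack.

These functions define the package's documented evaluation conditions —
ground-truth recovery of the two image pipelines, the detection power of the
full pipeline-plus-statistics stack, and the null calibration of the ROUT
outlier gate — at a desk-scale problem size (160-pixel frames for recovery,
96-pixel frames for the power sweep). Both the test suite and
``scripts/acceptance.py`` run them, so the numbers they print are always
recomputed from scratch.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .organelle import OrganelleParams, quantify_organelle_image
from .pla import PlaParams, quantify_pla_image
from .stats import rout_outliers, t_test_two_tailed
from .synthetic import SceneSpec, derive_seed, generate_scene

#: Recovery evaluation scene: one full-stack nucleus plus 150 dots per field.
PLA_EVAL_SPEC = SceneSpec(
    shape=(21, 160, 160), n_nuclei=1, nucleus_radii=(14.0, 45.0, 45.0),
    n_pla_dots=150, n_organelles=0,
)

#: Organelle evaluation scene: 40 vesicles, 30 % of dots placed inside them.
ORGANELLE_EVAL_SPEC = SceneSpec(
    shape=(21, 160, 160), n_nuclei=0, n_pla_dots=150, n_organelles=40,
    organelle_radius=6.0, primary="organelle", fraction_dots_in_organelle=0.3,
)

#: Power-sweep scenes: small fields differing only in dot count (4x).
POWER_SPEC_LOW = SceneSpec(
    shape=(12, 96, 96), n_nuclei=1, nucleus_radii=(8.0, 30.0, 30.0),
    n_pla_dots=25, n_organelles=0,
)
POWER_SPEC_HIGH = dataclasses.replace(POWER_SPEC_LOW, n_pla_dots=100)


def _noise_free(spec: SceneSpec) -> SceneSpec:
    return dataclasses.replace(spec, poisson_gain=0.0, gaussian_noise_sigma=0.0)


def pla_recovery_errors(n_seeds: int = 20, noise: bool = True,
                        base_seed: int = 0) -> np.ndarray:
    """Relative errors of the recovered PLA/nucleus ratio vs ground truth.

    Returns one signed relative error per seed (0.05 means 5 % above truth).
    """
    spec0 = PLA_EVAL_SPEC if noise else _noise_free(PLA_EVAL_SPEC)
    errors = []
    for i in range(n_seeds):
        spec = dataclasses.replace(spec0, seed=derive_seed(base_seed, i))
        pair, truth = generate_scene(spec)
        result = quantify_pla_image(pair, PlaParams())
        true_ratio = truth.true_pla_area / truth.true_nucleus_area
        errors.append(result.ratio / true_ratio - 1.0)
    return np.asarray(errors)


def organelle_recovery_errors(n_seeds: int = 20, noise: bool = True,
                              base_seed: int = 0) -> np.ndarray:
    """Signed errors, in percentage points, of recovered percent-occupied."""
    spec0 = ORGANELLE_EVAL_SPEC if noise else _noise_free(ORGANELLE_EVAL_SPEC)
    errors = []
    for i in range(n_seeds):
        spec = dataclasses.replace(spec0, seed=derive_seed(base_seed, 1000 + i))
        pair, truth = generate_scene(spec)
        result = quantify_organelle_image(pair, OrganelleParams())
        true_pct = 100.0 * truth.true_overlap_area / truth.true_organelle_area
        errors.append(result.percent_occupied - true_pct)
    return np.asarray(errors)


def pipeline_power_fraction(n_repetitions: int = 50, n_images_per_group: int = 15,
                            base_seed: int = 0, rout_q: float = 0.001) -> float:
    """Fraction of repetitions where a 4x dot-density difference gives p < 0.05.

    Each repetition simulates two groups of images, quantifies every image
    with the macro-1 pipeline, applies ROUT per group and runs the pooled
    two-tailed t test — the full stack, end to end.
    """
    hits = 0
    for rep in range(n_repetitions):
        ratios = {}
        for g, spec0 in enumerate((POWER_SPEC_LOW, POWER_SPEC_HIGH)):
            vals = []
            for i in range(n_images_per_group):
                seed = derive_seed(base_seed, 10_000 + 100 * rep + 2 * i + g)
                pair, _ = generate_scene(dataclasses.replace(spec0, seed=seed))
                vals.append(quantify_pla_image(pair, PlaParams()).ratio)
            ratios[g] = rout_outliers(np.asarray(vals), q=rout_q).kept
        p = t_test_two_tailed(ratios[0], ratios[1]).p_value
        hits += p < 0.05
    return hits / n_repetitions


def rout_null_false_flag_rate(n_datasets: int = 10_000, n: int = 50,
                              q: float = 0.001, base_seed: int = 0) -> float:
    """Fraction of clean standard-normal datasets with any point flagged."""
    rng = np.random.default_rng(derive_seed(base_seed, 77))
    flagged = 0
    for _ in range(n_datasets):
        flagged += rout_outliers(rng.standard_normal(n), q=q).n_outliers > 0
    return flagged / n_datasets


def rout_contaminant_detection_rate(n_datasets: int = 5_000, n: int = 50,
                                    shift: float = 10.0, q: float = 0.001,
                                    base_seed: int = 0) -> float:
    """Fraction of datasets where a single ``shift``-sigma contaminant is caught."""
    rng = np.random.default_rng(derive_seed(base_seed, 78))
    hits = 0
    for _ in range(n_datasets):
        x = rng.standard_normal(n)
        x[0] += shift
        hits += 0 in rout_outliers(x, q=q).outlier_indices
    return hits / n_datasets
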