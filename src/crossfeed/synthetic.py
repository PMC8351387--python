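"""Seeded generators for every input the analysis stages consume.

Each generator is a pure function of its parameters and seed and returns
its ground truth alongside the data, so downstream tests are closed-loop
parameter-recovery tests. Randomness uses numpy's Philox counter-based
bit generator, which produces identical streams across platforms for a
given key.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .marge import (
    ConditionSpec,
    ExpressionInput,
    MetabolicModel,
    estimate_specific_rate,
    toy_riboflavin_model,
)
from .phenomics import GrowthCurve, PlateAssay

__all__ = [
    "rng_for",
    "gen_growth_curve",
    "gen_fluorescence_plate",
    "gen_toy_model_case",
    "DEFAULT_INTENSITY_SIGMA",
]

#: lognormal sigma for plate intensities; matches a ~39% CV, the level of
#: replicate scatter seen in parental secretion measurements (16.4/42).
DEFAULT_INTENSITY_SIGMA = 0.39


def rng_for(seed: int) -> np.random.Generator:
    """The package's canonical counter-based generator for a seed."""
    return np.random.Generator(np.random.Philox(key=seed))


def gen_growth_curve(
    seed: int,
    rate: float = 0.5,
    capacity: float = 2.0,
    od0: float = 0.01,
    t_max: float = 48.0,
    dt: float = 1.0,
    sigma_log2: float = 0.02,
) -> tuple[GrowthCurve, dict]:
    """A logistic OD600 curve with multiplicative noise.

    OD(t) = K / (1 + (K/OD0 - 1) * 2**(-r t)) sampled on an hourly grid;
    noise is Gaussian on log2(OD) with standard deviation ``sigma_log2``.
    ``rate`` is the low-density growth rate in doublings per hour. Returns
    the curve and a ground-truth dict.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if capacity <= od0 or od0 <= 0:
        raise ValueError("need capacity > od0 > 0")
    if sigma_log2 < 0:
        raise ValueError("sigma_log2 must be >= 0")
    rng = rng_for(seed)
    t = np.arange(0.0, t_max + 0.5 * dt, dt)
    od = capacity / (1.0 + (capacity / od0 - 1.0) * 2.0 ** (-rate * t))
    noisy = od * 2.0 ** (sigma_log2 * rng.standard_normal(t.size))
    truth = {"rate": rate, "capacity": capacity, "od0": od0,
             "sigma_log2": sigma_log2}
    return GrowthCurve(times=t, ods=noisy), truth


def gen_fluorescence_plate(
    seed: int,
    parental_mean: float = 1000.0,
    true_folds: dict[str, float] | None = None,
    n_replicates: int = 5,
    sigma: float = DEFAULT_INTENSITY_SIGMA,
) -> tuple[PlateAssay, dict]:
    """A screening-plate fluorescence table with known fold-changes.

    Isolate wells are named letter+community the way evolved isolates are
    labelled (B4 = isolate B from community 4). Intensities are the true
    strain mean times lognormal noise (median-parameterized: the noise
    factor is exp(sigma * z)).
    """
    if parental_mean <= 0:
        raise ValueError("parental_mean must be > 0")
    if true_folds is None:
        true_folds = {"B4": 3.2, "E6": 10.0, "D5": 1.0}
    rng = rng_for(seed)

    def draw(mean, n):
        return mean * np.exp(sigma * rng.standard_normal(n))

    assay = PlateAssay(
        parental_values=draw(parental_mean, n_replicates),
        isolate_values={
            iso: draw(parental_mean * f, n_replicates)
            for iso, f in sorted(true_folds.items())
        },
    )
    truth = {"parental_mean": parental_mean, "true_folds": dict(true_folds),
             "sigma": sigma}
    return assay, truth


def gen_toy_model_case(
    pathway_log2fc: float = 1.0,
    mu_ref: float = 0.3,
    mu_evo: float = 0.3,
    titer_ng_per_ml: float = 42.0,
) -> tuple[MetabolicModel, ExpressionInput, ConditionSpec, ConditionSpec]:
    """The bundled riboflavin toy network plus a matched expression table.

    Applies ``pathway_log2fc`` to the first riboflavin-pathway enzyme
    (GTP cyclohydrolase II, the step where biosynthesis is controlled) and
    near-zero changes to two housekeeping enzymes, which the 0.5 filter
    removes. The reference condition anchors riboflavin production to the
    specific rate estimated from the given titer; the evolved condition
    leaves it free, to be predicted from the expression input.
    """
    model = toy_riboflavin_model()
    expression = ExpressionInput({
        "ribA": pathway_log2fc,
        "pgi": 0.1,
        "aaP": -0.2,
    })
    product_lb = estimate_specific_rate(titer_ng_per_ml, 72.0, 2.0)
    reference = ConditionSpec(growth_lower_bound=mu_ref,
                              product_lower_bound=product_lb)
    evolved = ConditionSpec(growth_lower_bound=mu_evo)
    return model, expression, reference, evolved
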