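"""Synthetic DHS-like survey generator with known ground truth.

Records are drawn from the same generative model the package fits:
categorical covariates sampled independently from configurable marginals
(defaults mirror the published survey margins), age uniform on the
reproductive range, region uniform over a division graph, and the
trichotomous nutrition outcome drawn from the multinomial logit with
user-specified linear, smooth-nonlinear and spatial effects.  Every
simulated dataset carries its ground truth, so parameter-recovery and
model-selection behaviour can be tested without access to the gated
microdata.

A BMI value consistent with the drawn category is attached to each record
so that the BMI-classification stage can be exercised on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import surveys
from .graphs import RegionGraph, make_region_graph
from .model import multinomial_probs
from .spatial import sample_icar


def sinusoid(amplitude: float = 0.6, phase: float = 0.0, age_range=(15.0, 49.0)):
    """A documented smooth-truth shape: one full sine period over the range.

    f(z) = A * sin(2*pi*(z - z_min)/(z_max - z_min) + phase); with phase 0
    or -pi/2 it integrates to ~0 over a uniform age distribution, so it
    leaves the category prevalences set by the intercepts untouched.
    """
    lo, hi = age_range

    def f(z):
        z = np.asarray(z, dtype=float)
        return amplitude * np.sin(2.0 * np.pi * (z - lo) / (hi - lo) + phase)

    return f


def default_true_linear_effects() -> dict:
    """Per-category linear ground truth with published-table magnitudes.

    Dummy coefficients echo the fitted linear effects reported for the
    2014 round; intercepts are calibrated so the implied prevalences are
    roughly (18%, 41%, 41%) for (underweight, normal, overweight/obese)
    under the 2014 covariate marginals.
    """
    return {
        "underweight": {
            "intercept": -0.57,
            "residence:City Corporation": 0.106,
            "residence:Other Urban": -0.075,
            "wealth:Poorer": 0.221,
            "wealth:Middle": 0.003,
            "wealth:Richer": -0.193,
            "wealth:Richest": -0.389,
            "education:Primary": -0.269,
            "education:Secondary": -0.303,
            "education:Higher": 0.713,
            "working:Yes": -0.027,
            "water:Protected": -0.026,
            "toilet:Improved": -0.049,
            "electricity:Yes": -0.027,
            "newspaper:Yes": -0.172,
            "radio:Yes": -0.037,
            "television:Yes": -0.054,
        },
        "overweight_obese": {
            "intercept": -0.49,
            "residence:City Corporation": 0.15,
            "residence:Other Urban": 0.033,
            "wealth:Poorer": -0.246,
            "wealth:Middle": -0.106,
            "wealth:Richer": 0.177,
            "wealth:Richest": 0.64,
            "education:Primary": 0.464,
            "education:Secondary": 0.63,
            "education:Higher": -1.339,
            "working:Yes": -0.027,
            "water:Protected": 0.042,
            "toilet:Improved": 0.016,
            "electricity:Yes": 0.023,
            "newspaper:Yes": 0.181,
            "radio:Yes": -0.11,
            "television:Yes": 0.137,
        },
    }


def default_true_smooth_functions() -> dict:
    """Sinusoidal age-effect truths (amplitude 0.6, quarter-period apart)."""
    return {
        "underweight": sinusoid(0.6, 0.0),
        "overweight_obese": sinusoid(0.6, -np.pi / 2),
    }


@dataclass
class GeneratorConfig:
    """Study conditions of one synthetic survey draw."""

    n_records: int = 4000
    seed: int = 0
    year: int = 2018
    graph: RegionGraph | str = "bdhs2018"
    age_range: tuple = (15.0, 49.0)
    category_marginals: dict | None = None  # default: published margins of `year`
    true_linear_effects: dict = field(default_factory=dict)
    true_smooth_functions: dict | None = None
    true_structured_effects: dict | None = None  # per-category region vectors
    true_unstructured_effects: dict | None = None
    structured_truth_delta: float | None = None  # draw g once from ICAR(delta)
    unstructured_truth_tau2: float | None = None  # draw h once from N(0, tau2)
    region_marginals: dict | None = None  # default: uniform over regions

    def resolved_graph(self) -> RegionGraph:
        g = self.graph
        return make_region_graph(g) if isinstance(g, str) else g

    def resolved_marginals(self) -> dict:
        m = self.category_marginals
        if m is None:
            m = surveys.default_table1_marginals(self.year)
        return m

    def validate(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        lo, hi = self.age_range
        if not (15.0 <= lo < hi <= 49.0):
            raise ValueError("age_range must be within [15, 49]")
        for var, probs in self.resolved_marginals().items():
            vec = np.array(list(probs.values()), dtype=float)
            if abs(vec.sum() - 1.0) > 1e-12 or np.any(vec < 0):
                raise ValueError(f"marginal for {var!r} is not a probability vector")
        graph = self.resolved_graph()
        for name, eff in (
            ("structured", self.true_structured_effects),
            ("unstructured", self.true_unstructured_effects),
        ):
            if eff is not None:
                for cat, vec in eff.items():
                    if len(np.asarray(vec)) != graph.n_regions:
                        raise ValueError(
                            f"{name} truth for {cat!r} needs one entry per region"
                        )


@dataclass
class SyntheticSurvey:
    """A simulated dataset plus the ground truth that produced it."""

    data: pd.DataFrame
    graph: RegionGraph
    config: GeneratorConfig
    truth: dict

    def truth_sidecar(self) -> pd.DataFrame:
        """Per-region truth table (structured and unstructured effects)."""
        rows = {"region": list(self.graph.region_ids)}
        for kind in ("structured", "unstructured"):
            eff = self.truth.get(kind)
            if eff:
                for cat, vec in eff.items():
                    rows[f"{kind[0]}_{cat}"] = np.asarray(vec)
        return pd.DataFrame(rows)


# BMI is drawn uniformly inside the interval matching the drawn category,
# purely so the classification stage round-trips on synthetic data.
_BMI_RANGES = {
    "underweight": (15.0, 18.5),
    "normal": (18.5, 23.0),
    "overweight_obese": (23.0, 33.0),
}


def simulate_dataset(config: GeneratorConfig, debug_probs: bool = False) -> SyntheticSurvey:
    """Draw one synthetic survey under ``config``.

    Reproducible: the same config and seed give an identical dataset.
    With ``debug_probs=True`` the realized latent category probabilities
    are attached as extra columns (test oracle use).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    graph = config.resolved_graph()
    marginals = config.resolved_marginals()
    n = config.n_records

    df = pd.DataFrame({"id": [f"w{i:06d}" for i in range(n)]})
    for var in surveys.COVARIATES:
        if var not in marginals:
            continue
        levels = list(marginals[var].keys())
        probs = np.array(list(marginals[var].values()), dtype=float)
        df[var] = rng.choice(levels, size=n, p=probs / probs.sum())
    df["age"] = rng.uniform(config.age_range[0], config.age_range[1], size=n)

    regions = list(graph.region_ids)
    if config.region_marginals is not None:
        rp = np.array([config.region_marginals[r] for r in regions], dtype=float)
        rp = rp / rp.sum()
    else:
        rp = np.full(len(regions), 1.0 / len(regions))
    df["region"] = rng.choice(regions, size=n, p=rp)

    # resolve ground truth (drawing spatial truths once if so configured)
    truth: dict = {"linear": {}, "smooth": {}, "structured": {}, "unstructured": {}}
    categories = [l for l in surveys.OUTCOME_LEVELS if l != surveys.OUTCOME_REFERENCE]
    for cat in categories:
        truth["linear"][cat] = dict(config.true_linear_effects.get(cat, {}))
    smooth = config.true_smooth_functions or {}
    truth["smooth"] = {c: smooth.get(c) for c in categories}
    for kind, explicit, scale in (
        ("structured", config.true_structured_effects, config.structured_truth_delta),
        ("unstructured", config.true_unstructured_effects, config.unstructured_truth_tau2),
    ):
        if explicit is not None:
            truth[kind] = {c: np.asarray(explicit.get(c, np.zeros(graph.n_regions)), float)
                           for c in categories}
        elif scale is not None:
            for cat in categories:
                if kind == "structured":
                    vec = sample_icar(graph, scale, rng)
                else:
                    vec = rng.normal(0.0, np.sqrt(scale), size=graph.n_regions)
                    vec = vec - vec.mean()
                truth[kind][cat] = vec
        else:
            truth[kind] = {}

    eta = np.zeros((n, len(categories)))
    region_idx = df["region"].map({r: i for i, r in enumerate(regions)}).to_numpy()
    for j, cat in enumerate(categories):
        lin = truth["linear"][cat]
        eta[:, j] += lin.get("intercept", 0.0)
        for key, value in lin.items():
            if key == "intercept":
                continue
            cov, level = key.split(":", 1)
            eta[:, j] += value * (df[cov].astype(str) == level).to_numpy(float)
        f = truth["smooth"].get(cat)
        if f is not None:
            eta[:, j] += f(df["age"].to_numpy())
        for kind in ("structured", "unstructured"):
            if truth[kind]:
                eta[:, j] += np.asarray(truth[kind][cat])[region_idx]

    probs = multinomial_probs(eta)  # columns: categories..., reference last
    u = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    choice = (u[:, None] > cum).sum(axis=1)
    labels = categories + [surveys.OUTCOME_REFERENCE]
    df["nutrition_category"] = np.asarray(labels, dtype=object)[choice]

    lo_hi = np.array([_BMI_RANGES[c] for c in df["nutrition_category"]])
    df["bmi"] = rng.uniform(lo_hi[:, 0], lo_hi[:, 1])

    if debug_probs:
        for j, lab in enumerate(labels):
            df[f"prob_{lab}"] = probs[:, j]

    return SyntheticSurvey(data=df, graph=graph, config=config, truth=truth)
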