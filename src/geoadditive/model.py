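"""Model specifications, design construction, predictor and likelihood.

Six nested predictors for the trichotomous outcome (reference category
"normal"), each defined per non-reference category r:

====  =========================================================
M1    eta = u'beta
M2    eta = u'beta + f(z)
M3    eta = u'beta + g(S) + h(S)
M4    eta = u'beta + f(z) + g(S)
M5    eta = u'beta + f(z) + h(S)
M6    eta = u'beta + f(z) + g(S) + h(S)
====  =========================================================

with u the dummy-coded categorical covariates (plus intercept), f a
penalized spline in age z, g the structured (ICAR) and h the unstructured
(iid) spatial effect of the region S.  Category probabilities follow the
multinomial logit P[y = r] = exp(eta_r) / (1 + sum_s exp(eta_s)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import SplineBasis
from .graphs import RegionGraph
from . import surveys

MODEL_VARIANTS = ("M1", "M2", "M3", "M4", "M5", "M6")

_SWITCHES = {
    # variant: (spline, structured, unstructured)
    "M1": (False, False, False),
    "M2": (True, False, False),
    "M3": (False, True, True),
    "M4": (True, True, False),
    "M5": (True, False, True),
    "M6": (True, True, True),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which predictor variant is fitted, and its fixed structure."""

    variant: str = "M6"
    outcome_levels: tuple = surveys.OUTCOME_LEVELS
    reference: str = surveys.OUTCOME_REFERENCE
    # inverse-gamma hyperparameters (shape, rate) for each variance
    spline_prior: tuple = (0.001, 0.001)
    structured_prior: tuple = (0.001, 0.001)
    unstructured_prior: tuple = (0.001, 0.001)

    def __post_init__(self):
        if self.variant not in _SWITCHES:
            raise ValueError(f"unknown model variant {self.variant!r}")
        if self.reference not in self.outcome_levels:
            raise ValueError("reference category must be an outcome level")

    @property
    def has_spline(self) -> bool:
        return _SWITCHES[self.variant][0]

    @property
    def has_structured(self) -> bool:
        return _SWITCHES[self.variant][1]

    @property
    def has_unstructured(self) -> bool:
        return _SWITCHES[self.variant][2]

    @property
    def has_spatial(self) -> bool:
        return self.has_structured or self.has_unstructured

    @property
    def nonreference(self) -> tuple:
        return tuple(l for l in self.outcome_levels if l != self.reference)

    @property
    def n_categories(self) -> int:
        return len(self.outcome_levels)


class ModelData:
    """Design pieces shared by all six variants on one dataset.

    Holds the dummy-coded linear design (intercept first), the spline
    basis evaluated at each record's age, the region index of each record,
    and the outcome coded against the non-reference categories.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        graph: RegionGraph | None = None,
        covariates=surveys.COVARIATES,
        levels=None,
        age_col: str = "age",
        region_col: str = "region",
        outcome_col: str = "nutrition_category",
        n_knots: int = 20,
        degree: int = 3,
        outcome_levels=surveys.OUTCOME_LEVELS,
        reference: str = surveys.OUTCOME_REFERENCE,
    ):
        self.covariates = tuple(c for c in covariates if c in df.columns)
        missing = [c for c in covariates if c not in df.columns]
        if missing and covariates is not surveys.COVARIATES:
            raise ValueError(f"covariates absent from data: {missing}")
        levels = levels or surveys.COVARIATE_LEVELS
        self.graph = graph

        cols = [np.ones(len(df))]
        labels = ["intercept"]
        for cov in self.covariates:
            lv = levels.get(cov)
            if lv is None:
                lv = tuple(sorted(df[cov].astype(str).unique()))
            observed = set(df[cov].astype(str))
            unknown = observed - set(lv)
            if unknown:
                raise ValueError(f"unknown level(s) {sorted(unknown)} for {cov!r}")
            for level in lv[1:]:  # first level is the reference
                cols.append((df[cov].astype(str) == level).to_numpy(float))
                labels.append(f"{cov}:{level}")
        self.x_linear = np.column_stack(cols)
        self.linear_labels = tuple(labels)
        rank = np.linalg.matrix_rank(self.x_linear)
        if rank < self.x_linear.shape[1]:
            raise ValueError(
                "dummy-coded design is rank deficient "
                f"(rank {rank} < {self.x_linear.shape[1]} columns); "
                "a covariate level may be empty or aliased"
            )

        self.age = df[age_col].to_numpy(float)
        self.basis = SplineBasis(
            float(self.age.min()), float(self.age.max()), n_knots=n_knots, degree=degree
        )
        self.b_spline = self.basis.design_matrix(self.age)

        if graph is not None:
            region_index = {r: i for i, r in enumerate(graph.region_ids)}
            regions = df[region_col].astype(str)
            bad = set(regions) - set(region_index)
            if bad:
                raise ValueError(f"regions not in graph: {sorted(bad)}")
            self.region_idx = regions.map(region_index).to_numpy(np.int64)
        else:
            self.region_idx = None

        self.outcome_levels = tuple(outcome_levels)
        self.reference = reference
        self.nonreference = tuple(l for l in outcome_levels if l != reference)
        y = df[outcome_col].astype(str)
        bad = set(y) - set(outcome_levels)
        if bad:
            raise ValueError(f"unknown outcome level(s): {sorted(bad)}")
        # y_code: index into nonreference, -1 for the reference category
        code = {l: i for i, l in enumerate(self.nonreference)}
        code[reference] = -1
        self.y_code = y.map(code).to_numpy(np.int64)
        self.n = len(df)

    @property
    def n_linear(self) -> int:
        return self.x_linear.shape[1]

    @property
    def n_regions(self) -> int:
        return self.graph.n_regions if self.graph is not None else 0

    def validate_for(self, spec: ModelSpec) -> None:
        if spec.has_spatial:
            if self.graph is None:
                raise ValueError(f"{spec.variant} needs a region graph")
            if self.graph.n_regions < 2:
                raise ValueError(
                    f"{spec.variant} needs at least two regions; "
                    f"got {self.graph.n_regions}"
                )


def empty_params(spec: ModelSpec, data: ModelData) -> dict:
    """Zero-initialized parameter blocks for the blocks the spec enables."""
    ncat = len(spec.nonreference)
    params = {"beta": np.zeros((ncat, data.n_linear))}
    if spec.has_spline:
        params["theta"] = np.zeros((ncat, data.basis.n_basis))
    if spec.has_structured:
        params["g"] = np.zeros((ncat, data.n_regions))
    if spec.has_unstructured:
        params["h"] = np.zeros((ncat, data.n_regions))
    return params


def assemble_predictor(data: ModelData, spec: ModelSpec, params: dict) -> np.ndarray:
    """Predictor matrix eta (n x K-1), summing the blocks the spec enables."""
    expected = set(empty_params(spec, data))
    got = set(params)
    if got != expected:
        raise ValueError(f"expected parameter blocks {sorted(expected)}, got {sorted(got)}")
    eta = data.x_linear @ np.asarray(params["beta"]).T
    if spec.has_spline:
        eta = eta + data.b_spline @ np.asarray(params["theta"]).T
    if spec.has_spatial and data.region_idx is None:
        raise ValueError("spatial terms require region data")
    if spec.has_structured:
        eta = eta + np.asarray(params["g"]).T[data.region_idx]
    if spec.has_unstructured:
        eta = eta + np.asarray(params["h"]).T[data.region_idx]
    return eta


def multinomial_probs(eta) -> np.ndarray:
    """Category probabilities from the (K-1) non-reference predictors.

    Accepts a length-(K-1) vector or an (n, K-1) matrix; returns the
    corresponding K-vector / (n, K) matrix ordered as (non-reference...,
    reference last).  Numerically stabilized by shifting by the row max.
    """
    eta = np.asarray(eta, dtype=float)
    if np.any(np.isnan(eta)):
        raise ValueError("NaN predictor")
    single = eta.ndim == 1
    eta2 = np.atleast_2d(eta)
    full = np.concatenate([eta2, np.zeros((eta2.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    ex = np.exp(full)
    probs = ex / ex.sum(axis=1, keepdims=True)
    return probs[0] if single else probs


def loglik(data: ModelData, eta: np.ndarray) -> float:
    """Multinomial log-likelihood of the observed outcomes under eta."""
    probs = multinomial_probs(eta)
    idx = np.where(data.y_code >= 0, data.y_code, probs.shape[1] - 1)
    p_obs = probs[np.arange(data.n), idx]
    if np.any(p_obs <= 0):
        return -np.inf
    return float(np.log(p_obs).sum())


def deviance(data: ModelData, spec: ModelSpec, params: dict) -> float:
    """Deviance -2 log L; +inf if any observed outcome has probability 0."""
    ll = loglik(data, assemble_predictor(data, spec, params))
    return float(-2.0 * ll)
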