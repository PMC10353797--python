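"""DIC model comparison and posterior effect summaries.

DIC = Dbar + pD with Dbar the posterior mean deviance and pD (the
effective number of parameters, Spiegelhalter's form) the gap between Dbar
and the deviance at the posterior-mean parameters.  Models within 5 DIC of
the best are flagged as fitting the data about equally well.

Significance convention throughout: an effect is "significant" when zero
lies outside its central 95% credible interval (empirical 2.5%/97.5%
quantiles of the retained draws).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorFit
from .model import assemble_predictor, loglik

#: DIC gap under which two models are treated as fitting equally well.
DIC_SIMILARITY_THRESHOLD = 5.0


@dataclass(frozen=True)
class DicResult:
    spec_id: str
    mean_deviance: float
    effective_parameters: float

    @property
    def dic(self) -> float:
        return self.mean_deviance + self.effective_parameters


def dic_from_components(spec_id: str, mean_deviance: float, effective_parameters: float) -> DicResult:
    """Assemble a DicResult from already-computed (Dbar, pD)."""
    if not np.isfinite(effective_parameters):
        raise ValueError("pD must be finite")
    return DicResult(spec_id, float(mean_deviance), float(effective_parameters))


def compute_dic(fit: PosteriorFit) -> DicResult:
    """DIC of a fitted model: Dbar from the deviance trace, pD = Dbar - D(mean)."""
    if fit.n_retained < 2:
        raise ValueError("need at least 2 retained draws for DIC")
    dbar = fit.mean_deviance()
    eta_at_mean = assemble_predictor(fit.data, fit.spec, fit.posterior_mean_params())
    d_at_mean = -2.0 * loglik(fit.data, eta_at_mean)
    return dic_from_components(fit.spec.variant, dbar, dbar - d_at_mean)


def compare_models(dic_results, reference: str | None = None) -> pd.DataFrame:
    """Comparison table with DIC differences against a reference model.

    Rows are sorted by spec id; ``dic_difference`` is dic(model) -
    dic(reference) (default reference: the last spec id in sort order,
    i.e. the richest of M1..M6 fitted); ``similar_to_best`` flags models
    within 5 DIC of the minimum.
    """
    results = sorted(dic_results, key=lambda r: r.spec_id)
    if len({r.spec_id for r in results}) != len(results):
        raise ValueError("duplicate spec ids in DIC comparison")
    if reference is None:
        reference = results[-1].spec_id
    by_id = {r.spec_id: r for r in results}
    if reference not in by_id:
        raise ValueError(f"reference {reference!r} not among results")
    ref_dic = by_id[reference].dic
    best = min(r.dic for r in results)
    return pd.DataFrame(
        {
            "model": [r.spec_id for r in results],
            "mean_deviance": [r.mean_deviance for r in results],
            "pd": [r.effective_parameters for r in results],
            "dic": [r.dic for r in results],
            "dic_difference": [r.dic - ref_dic for r in results],
            "similar_to_best": [
                r.dic - best <= DIC_SIMILARITY_THRESHOLD for r in results
            ],
        }
    )


def _interval(draws_1d, level=0.95):
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(draws_1d, lo)),
        float(np.quantile(draws_1d, 1.0 - lo)),
    )


def summarize_effects(fit: PosteriorFit, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean, credible interval and significance per scalar parameter.

    Covers the linear coefficients and every variance parameter, per
    non-reference outcome category, in the published-table layout.
    """
    import warnings

    if fit.n_retained < 100:
        warnings.warn(
            f"only {fit.n_retained} retained draws; summaries will be noisy",
            stacklevel=2,
        )
    rows = []
    labels = fit.data.linear_labels
    for ci, cat in enumerate(fit.categories):
        for pi, label in enumerate(labels):
            d = fit.draws["beta"][:, ci, pi]
            lo, hi = _interval(d, level)
            rows.append(
                {
                    "block": "linear",
                    "category": cat,
                    "parameter": label,
                    "mean": float(d.mean()),
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "significant": not lo <= 0.0 <= hi,
                }
            )
        for vname in ("sigma2_spline", "delta", "tau2"):
            if vname in fit.draws:
                d = fit.draws[vname][:, ci]
                lo, hi = _interval(d, level)
                rows.append(
                    {
                        "block": "variance",
                        "category": cat,
                        "parameter": vname,
                        "mean": float(d.mean()),
                        "ci_lower": lo,
                        "ci_upper": hi,
                        "significant": not lo <= 0.0 <= hi,
                    }
                )
    return pd.DataFrame(rows)


def export_spatial_effects(fit: PosteriorFit, level: float = 0.95) -> pd.DataFrame:
    """Per-region posterior summaries of the spatial effects.

    One row per region x category x spatial block, with a three-class
    significance code mirroring the map-colouring convention:
    ``+`` (interval above zero), ``0`` (interval covers zero), ``-``
    (interval below zero).
    """
    if not fit.spec.has_spatial:
        raise ValueError(f"{fit.spec.variant} has no spatial block")
    rows = []
    regions = fit.data.graph.region_ids
    for name, block in (("structured", "g"), ("unstructured", "h")):
        if block not in fit.draws:
            continue
        for ci, cat in enumerate(fit.categories):
            for ri, region in enumerate(regions):
                d = fit.draws[block][:, ci, ri]
                lo, hi = _interval(d, level)
                code = "+" if lo > 0 else ("-" if hi < 0 else "0")
                rows.append(
                    {
                        "block": name,
                        "category": cat,
                        "region": region,
                        "mean": float(d.mean()),
                        "ci_lower": lo,
                        "ci_upper": hi,
                        "significance": code,
                    }
                )
    return pd.DataFrame(rows)


def export_nonlinear_effect(fit: PosteriorFit, grid=None, level: float = 0.95) -> pd.DataFrame:
    """Pointwise posterior mean and band of the smooth age effect.

    Evaluates f(z) from every retained spline-coefficient draw on ``grid``
    (default: 101 points over the fitted age range); grid points outside
    the knot range are refused.
    """
    if "theta" not in fit.draws:
        raise ValueError(f"{fit.spec.variant} has no smooth age effect")
    basis = fit.data.basis
    if grid is None:
        grid = np.linspace(basis.z_min, basis.z_max, 101)
    grid = np.asarray(grid, dtype=float)
    bmat = basis.design_matrix(grid, on_outside="raise")
    rows = []
    lo_q = (1.0 - level) / 2.0
    for ci, cat in enumerate(fit.categories):
        curves = fit.draws["theta"][:, ci, :] @ bmat.T  # (S, len(grid))
        rows.append(
            pd.DataFrame(
                {
                    "category": cat,
                    "age": grid,
                    "mean": curves.mean(axis=0),
                    "ci_lower": np.quantile(curves, lo_q, axis=0),
                    "ci_upper": np.quantile(curves, 1.0 - lo_q, axis=0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
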