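"""CSV ingestion, report writing and synthetic test fixtures.

Input data are plain CSV panels: one row per observational unit with m
response columns (shock component first), m paired exposure columns, and p
predictor columns, mapped by an explicit :class:`PanelSchema` rather than by
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gig import GIGParams
from .regression import CoefficientSet, CountPanel, FitResult
from .inference import TestReport, aicc


@dataclass
class PanelSchema:
    """Column mapping for a CSV count panel.

    ``responses[0]`` is the common-shock component; exposures pair with
    responses index by index.
    """

    responses: Sequence[str]
    exposures: Sequence[str]
    predictors: Sequence[str]
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.responses) != len(self.exposures):
            raise ValueError("responses and exposures must pair up (equal length)")
        if len(self.responses) < 2:
            raise ValueError("need at least two response columns")
        all_cols = list(self.responses) + list(self.exposures) + list(self.predictors)
        if self.unit:
            all_cols.append(self.unit)
        if len(set(all_cols)) != len(all_cols):
            raise ValueError("schema lists a column twice")


def read_panel(path, schema: PanelSchema, on_support_violation: str = "error") -> CountPanel:
    """Load and validate a CSV count panel.

    ``on_support_violation`` is ``"error"`` (default) or ``"drop"`` — rows with
    y_ij < y_i1 are either reported as an error or warned about and removed.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [
        c
        for c in list(schema.responses) + list(schema.exposures) + list(schema.predictors)
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")

    resp = df[list(schema.responses)].to_numpy()
    if np.any(resp != np.floor(resp)):
        r, c = np.argwhere(resp != np.floor(resp))[0]
        raise ValueError(
            f"fractional count at row {r}, column {schema.responses[c]!r}"
        )
    resp = resp.astype(np.int64)
    if np.any(resp < 0):
        r, c = np.argwhere(resp < 0)[0]
        raise ValueError(f"negative count at row {r}, column {schema.responses[c]!r}")
    expo = df[list(schema.exposures)].to_numpy(dtype=float)
    if np.any(expo <= 0):
        r, c = np.argwhere(expo <= 0)[0]
        raise ValueError(
            f"non-positive exposure at row {r}, column {schema.exposures[c]!r}"
        )
    pred = df[list(schema.predictors)].to_numpy(dtype=float)
    labels = df[schema.unit].astype(str).tolist() if schema.unit else None

    bad = np.flatnonzero(np.any(resp[:, 1:] < resp[:, [0]], axis=1))
    if bad.size:
        if on_support_violation == "drop":
            import warnings

            warnings.warn(
                f"dropping {bad.size} rows violating y_ij >= y_i1: "
                f"{bad[:10].tolist()}",
                RuntimeWarning,
            )
            keep = np.setdiff1d(np.arange(len(resp)), bad)
            resp, expo, pred = resp[keep], expo[keep], pred[keep]
            if labels:
                labels = [labels[i] for i in keep]
        else:
            raise ValueError(
                f"rows violate the support law y_ij >= y_i1: {bad[:10].tolist()} "
                "(pass on_support_violation='drop' to remove them)"
            )
    return CountPanel(responses=resp, exposures=expo, predictors=pred, labels=labels)


def write_panel(panel: CountPanel, path, schema: Optional[PanelSchema] = None) -> PanelSchema:
    """Write a panel to CSV; returns the schema describing the layout."""
    m, p = panel.m, panel.p
    if schema is None:
        schema = PanelSchema(
            responses=[f"y{j + 1}" for j in range(m)],
            exposures=[f"q{j + 1}" for j in range(m)],
            predictors=[f"x{k + 1}" for k in range(p)],
            unit="unit",
        )
    data = {}
    if schema.unit:
        data[schema.unit] = (
            list(panel.labels) if panel.labels is not None else list(range(panel.n))
        )
    for j, col in enumerate(schema.responses):
        data[col] = panel.responses[:, j]
    for j, col in enumerate(schema.exposures):
        data[col] = panel.exposures[:, j]
    for k, col in enumerate(schema.predictors):
        data[col] = panel.predictors[:, k]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    return schema


def write_report(fit: FitResult, tests: Optional[TestReport], path, seed=None) -> None:
    """Coefficient table CSV plus a run-metadata sidecar (JSON).

    The coefficient table has one row per estimated beta (estimate, SE, Z, p)
    in the shape of a standard regression output; metadata records the model
    settings, log-likelihood, AICc, iteration count and seed.
    """
    import json

    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    if tests is not None and tests.wald:
        for rec in tests.wald:
            rows.append(rec)
    else:
        for name, est, se in zip(fit.param_names, _flat(fit), fit.se):
            if name.startswith("beta_"):
                rows.append({"name": name, "estimate": est, "se": se})
    pd.DataFrame(rows).to_csv(path, index=False)

    meta = {
        "model": fit.model,
        "n": fit.n_obs,
        "n_params": fit.n_params,
        "loglik": fit.loglik,
        "aicc": aicc(fit),
        "iterations": fit.iterations,
        "converged": fit.converged,
        "seed": seed,
        "tool_version": __version__,
    }
    if fit.estimates.gig is not None:
        g = fit.estimates.gig
        meta.update(
            {"gamma": g.gamma_shape, "tau": g.tau, "xi": g.xi, "omega": g.omega}
        )
    if tests is not None:
        meta.update(
            {
                "mlrt_g2": tests.g2, "mlrt_df": tests.df,
                "mlrt_p_value": tests.p_value,
                "mlrt_critical_value": tests.critical_value,
                "alpha": tests.alpha, "reject_null": tests.reject,
            }
        )
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def _flat(fit: FitResult) -> list:
    est = fit.estimates
    vals = list(est.betas[fit.slope_mask])
    if est.gig is not None:
        vals += [est.gig.tau, est.gig.xi]
    return vals


def make_fixture(kind: str = "small-panel", seed: int = 0):
    """Deterministic small synthetic panels with their generating truth.

    kinds: ``small-panel`` (n=10), ``null-panel`` (n=50, slopes all 0),
    ``overdispersed-panel`` (n=50, heavy GIG mixing).
    Returns ``(panel, truth)``.
    """
    from .simulate import default_truth, generate_design, simulate_dataset

    kind_tag = {"small-panel": 1, "null-panel": 2, "overdispersed-panel": 3}.get(kind, 0)
    rng = np.random.default_rng(np.random.SeedSequence([kind_tag, seed]))
    if kind == "small-panel":
        truth = default_truth(-0.5)
        design = generate_design(10, seed=rng)
        panel = simulate_dataset(design, truth, family="MCPGIG", seed=rng)
    elif kind == "null-panel":
        betas = np.zeros((2, 3))
        betas[:, 0] = (-2.0, 1.0)
        truth = CoefficientSet(betas=betas, gig=GIGParams(0.5, 1.0, -0.5))
        design = generate_design(50, seed=rng)
        panel = simulate_dataset(design, truth, family="MCPGIG", seed=rng)
    elif kind == "overdispersed-panel":
        betas = np.array([[-1.5, 0.05, 0.02], [1.5, 0.07, 0.05]])
        truth = CoefficientSet(betas=betas, gig=GIGParams(0.3, 1.0, -0.5))
        design = generate_design(50, seed=rng)
        panel = simulate_dataset(design, truth, family="MCPGIG", seed=rng)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return panel, truth
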