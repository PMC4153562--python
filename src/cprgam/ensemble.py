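"""The ten-member model ensemble and its comparison table.

Members 1-6 form the original single-component ensemble (additive to
fully interacting space/day-of-year structures, with and without a year
smooth); members 7-10 extend it with component-conditional day-of-year
and/or year smooths (two spawning components split at a fixed latitude).
All members carry the day/night factor.

The comparison table reports, per member: structure description,
component count, deviance explained, in-sample AUC (ties counted 1/2),
AIC, delta-AIC against the best of the first ensemble and against the
best overall, the day/night coefficient, and a no-empirical-support flag
(delta-AIC > 20, reported, not acted on).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bernoulli_gam import FitSettings, FittedModel, ModelSpec, fit_model

__all__ = ["build_ensemble", "auc", "compare", "EnsembleResult", "NO_SUPPORT_DAIC"]

NO_SUPPORT_DAIC = 20.0

_TABLE_ROWS = [
    # (model_id, space_time, doy_by_comp, year_term)
    (1, "e+n+doy", False, "none"),
    (2, "e+n+doy", False, "smooth"),
    (3, "e*n+doy", False, "none"),
    (4, "e*n+doy", False, "smooth"),
    (5, "e*n*doy", False, "none"),
    (6, "e*n*doy", False, "smooth"),
    (7, "e*n+doy", False, "smooth_by_comp"),
    (8, "e*n+doy", True, "smooth"),
    (9, "e*n+doy", True, "smooth_by_comp"),
    (10, "e*n*doy", False, "smooth_by_comp"),
]


def build_ensemble(split_latitude: float = 53.0) -> list[ModelSpec]:
    """The ten candidate structures, in fixed table order."""
    return [
        ModelSpec(
            space_time=st,
            doy_by_comp=byc,
            year_term=yt,
            split_latitude=split_latitude,
            model_id=mid,
        )
        for mid, st, byc, yt in _TABLE_ROWS
    ]


def auc(y, p) -> float:
    """Area under the ROC curve; ties count one half.

    Equals the probability that a random presence outscores a random
    absence (Mann-Whitney statistic / trapezoidal ROC integration).
    """
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must align")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    r = rankdata(p)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class EnsembleResult:
    """Per-model comparison rows plus the fitted models themselves."""

    table: pd.DataFrame
    models: dict[int, FittedModel] = field(default_factory=dict)
    errors: dict[int, str] = field(default_factory=dict)


def compare(
    data: pd.DataFrame,
    specs: Optional[Sequence[ModelSpec]] = None,
    settings: Optional[FitSettings] = None,
) -> EnsembleResult:
    """Fit every spec and produce the comparison table in input order.

    Individual fit failures are recorded per row and excluded from the
    delta-AIC reference computations; the comparison proceeds.
    """
    specs = list(specs) if specs is not None else build_ensemble()
    if len(specs) < 2:
        raise ValueError("compare requires at least two specs")
    settings = settings or FitSettings()
    ycol = "y" if "y" in data.columns else "present"
    y = data[ycol].to_numpy(dtype=float)

    rows = []
    models: dict[int, FittedModel] = {}
    errors: dict[int, str] = {}
    for i, spec in enumerate(specs):
        mid = spec.model_id if spec.model_id is not None else i + 1
        row = {
            "model": mid,
            "f_function": spec.description,
            "components": spec.components,
            "dev_expl": np.nan,
            "auc": np.nan,
            "aic": np.nan,
            "dn_coef": np.nan,
            "error": "",
        }
        try:
            fit = fit_model(data, spec, settings)
            phat = fit.predict_prob(data)
            row.update(
                dev_expl=fit.deviance_explained(),
                auc=auc(y, phat),
                aic=fit.aic(),
                dn_coef=fit.dn_coefficient,
            )
            models[mid] = fit
        except Exception as exc:
            errors[mid] = str(exc)
            row["error"] = str(exc)
        rows.append(row)

    table = pd.DataFrame(rows)
    ens1 = table[(table["components"] == 1) & table["aic"].notna()]
    ref1 = ens1["aic"].min() if len(ens1) else np.nan
    ref_all = table["aic"].min() if table["aic"].notna().any() else np.nan
    table["delta_aic_ens1"] = np.where(
        table["components"] == 1, table["aic"] - ref1, np.nan
    )
    table["delta_aic_all"] = table["aic"] - ref_all
    table["no_empirical_support"] = table["delta_aic_all"] > NO_SUPPORT_DAIC
    return EnsembleResult(table=table, models=models, errors=errors)
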