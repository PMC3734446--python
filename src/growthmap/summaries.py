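"""Post-fit effect summaries: interquartile odds ratios, variance partition,
exceedance probabilities and between-period stability.

The interquartile odds ratio (IQOR) expresses the between-suburb spread of a
log-odds effect as the odds ratio between the 75th and 25th centile suburb:
``exp(q75 - q25)`` of the per-suburb posterior-mean effects, with
linear-interpolation quantiles.  It is >= 1 by construction and translation
invariant, so it can compare random-effect and fixed-effect components on
one scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .bym import PosteriorDraws
from .spatial import pearson_r

__all__ = [
    "iqor",
    "component_effects",
    "variance_partition",
    "exceedance",
    "period_stability",
]


def iqor(effects) -> float:
    """exp(q75 - q25) of per-suburb effects on the log-odds scale.

    Quantiles use linear interpolation between order statistics (numpy's
    default); with a couple of hundred suburbs the convention matters, so it
    is fixed here.
    """
    x = np.asarray(effects, float)
    if x.size < 4:
        raise ValueError("need at least four suburbs for an IQOR")
    q25, q75 = np.quantile(x, [0.25, 0.75], method="linear")
    return float(np.exp(q75 - q25))


def component_effects(draws: PosteriorDraws, table: pd.DataFrame) -> dict:
    """Per-suburb posterior-mean effects per model component.

    Returns a dict with the available keys among ``"u"``, ``"v"``,
    ``"u_plus_v"`` and ``"ses"`` (the fixed-effect contribution
    ``mean(b1) * X_i``), each a Series indexed by suburb id.
    """
    idx = pd.Index(draws.ids, name="suburb_id")
    out: dict[str, pd.Series] = {}
    if draws.u is not None:
        out["u"] = pd.Series(draws.u.mean(axis=0), index=idx)
    if draws.v is not None:
        out["v"] = pd.Series(draws.v.mean(axis=0), index=idx)
    if draws.u is not None and draws.v is not None:
        out["u_plus_v"] = pd.Series((draws.u + draws.v).mean(axis=0), index=idx)
    if draws.beta1 is not None:
        x = table.set_index("suburb_id").loc[list(idx), "ses_std"]
        out["ses"] = float(draws.beta1.mean()) * x
    return out


def variance_partition(draws: PosteriorDraws,
                       use_hyperparameters: bool = False) -> float:
    """Share of random-effect variance carried by the spatial component.

    Default: per retained sample the empirical across-suburb variances of
    the sampled ``u`` and ``v`` vectors; returns the mean over samples of
    ``var(u) / (var(u) + var(v))``.  The hyperparameter reading
    ``sigma_u^2 / (sigma_u^2 + sigma_v^2)`` is available behind a flag but
    note the ICAR sigma_u is a conditional, not marginal, scale.
    """
    if draws.u is None or draws.v is None:
        raise ValueError("variance partition needs both u and v in the model")
    if use_hyperparameters:
        su2 = draws.sigma_u ** 2
        sv2 = draws.sigma_v ** 2
        return float((su2 / (su2 + sv2)).mean())
    vu = draws.u.var(axis=1)
    vv = draws.v.var(axis=1)
    tot = vu + vv
    if np.all(tot == 0):
        warnings.warn("both components identically zero; returning 0")
        return 0.0
    return float((vu / tot).mean())


def exceedance(draws: PosteriorDraws, threshold: float = 0.90) -> pd.DataFrame:
    """Per-suburb posterior probability that the combined random effect
    ``u_i + v_i`` is positive, i.e. that the suburb's odds ratio exceeds 1
    relative to the (SES-adjusted, for the full model) mean incidence.

    Returns a DataFrame with ``probability`` and a boolean ``flagged``
    column (probability strictly above ``threshold``).
    """
    comp = 0.0
    if draws.u is not None:
        comp = comp + draws.u
    if draws.v is not None:
        comp = comp + draws.v
    if np.isscalar(comp):
        raise ValueError("model has no random effects to summarise")
    prob = (comp > 0).mean(axis=0)
    return pd.DataFrame({"suburb_id": draws.ids, "probability": prob,
                         "flagged": prob > threshold})


def period_stability(effects_a: dict, effects_b: dict) -> dict:
    """Pearson correlations of per-suburb quantities between two periods.

    ``effects_a`` / ``effects_b`` map component name -> Series indexed by
    suburb id (as from :func:`component_effects`, possibly augmented with a
    raw-SES entry).  Components present in both periods are correlated after
    index alignment; mismatched suburb sets raise.
    """
    out = {}
    for key in effects_a:
        if key not in effects_b:
            continue
        a, b = effects_a[key], effects_b[key]
        if set(a.index) != set(b.index):
            raise ValueError(f"suburb sets differ for component {key!r}")
        b = b.reindex(a.index)
        out[key] = pearson_r(a.to_numpy(), b.to_numpy())
    return out
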