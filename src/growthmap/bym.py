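"""Bayesian binomial-logit disease-mapping models with BYM random effects.

Four nested models of suburb-level counts ``R_i ~ Binomial(N_i, p_i)``:

* null:           logit(p_i) = b0
* random effects: logit(p_i) = b0 + u_i + v_i
* fixed effect:   logit(p_i) = b0 + b1 * X_i
* full:           logit(p_i) = b0 + b1 * X_i + u_i + v_i

where ``X_i`` is the standardised socioeconomic index, ``u`` follows an
intrinsic CAR (pairwise-difference) prior over the suburb adjacency graph
with scale ``sigma_u`` and a sum-to-zero constraint per connected component,
and ``v`` is exchangeable Normal(0, sigma_v^2).  Priors: Normal(0, 100^2)
on b0 and b1; half-Normal(scale 100) on sigma_u and sigma_v.

Fitting is Metropolis-within-Gibbs: random-walk updates for b0/b1, chromatic
(graph-coloured, vectorised) single-site random walks for u, joint
elementwise random walks for v, and log-scale random walks for the two
scale parameters.  Proposal scales adapt during burn-in only.  Model
comparison uses DIC with pD = mean deviance minus the deviance at the
posterior-mean linear predictors; the deviance omits the binomial
coefficient constant throughout, which cancels in all comparisons.

The public surface follows the Model/Results idiom: build a
:class:`BYMModel` from a suburb table and adjacency, call :meth:`fit`, and
read estimates, DIC and diagnostics off the returned :class:`BYMResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .geography import Adjacency

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "PosteriorDraws",
    "BYMModel",
    "BYMResults",
    "log_likelihood",
    "car_log_prior",
    "dic",
    "geweke",
    "ConvergenceWarning",
]

MODEL_NAMES = {"null": (False, False, False),
               "random": (False, True, True),
               "fixed": (True, False, False),
               "full": (True, True, True)}


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the linear predictor, plus prior scales."""

    include_fixed_ses: bool
    include_car: bool
    include_iid: bool
    beta_prior_sd: float = 100.0
    sigma_prior_sd: float = 100.0

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        try:
            return cls(*MODEL_NAMES[name])
        except KeyError:
            raise ValueError(f"unknown model {name!r}; "
                             f"choose from {sorted(MODEL_NAMES)}")

    @property
    def name(self) -> str:
        key = (self.include_fixed_ses, self.include_car, self.include_iid)
        for n, flags in MODEL_NAMES.items():
            if flags == key:
                return n
        return "custom"


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.  Desk-scale defaults keep a fit to seconds; the
    original six-figure run lengths remain available by configuration."""

    iterations: int = 60_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    adapt_interval: int = 100

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must be < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC samples; vectors are ordered as ``ids``."""

    ids: list
    beta0: np.ndarray
    deviance: np.ndarray
    beta1: Optional[np.ndarray] = None
    u: Optional[np.ndarray] = None          # (S, n)
    v: Optional[np.ndarray] = None          # (S, n)
    sigma_u: Optional[np.ndarray] = None
    sigma_v: Optional[np.ndarray] = None

    @property
    def n_samples(self) -> int:
        return len(self.beta0)

    def to_frame(self) -> pd.DataFrame:
        cols = {"beta0": self.beta0, "deviance": self.deviance}
        if self.beta1 is not None:
            cols["beta1"] = self.beta1
        if self.sigma_u is not None:
            cols["sigma_u"] = self.sigma_u
        if self.sigma_v is not None:
            cols["sigma_v"] = self.sigma_v
        df = pd.DataFrame(cols)
        if self.u is not None:
            for k, sid in enumerate(self.ids):
                df[f"u_{sid}"] = self.u[:, k]
        if self.v is not None:
            for k, sid in enumerate(self.ids):
                df[f"v_{sid}"] = self.v[:, k]
        return df


# ---------------------------------------------------------------------------
# Likelihood and priors
# ---------------------------------------------------------------------------

def _binom_ll_terms(eta, R, N):
    # log Bin(R | N, inv_logit(eta)) without the binomial coefficient
    return R * eta - N * np.logaddexp(0.0, eta)


def log_likelihood(table: pd.DataFrame, eta) -> float:
    """Binomial log-likelihood at linear predictor ``eta`` (aligned with the
    table's rows); the binomial-coefficient constant is omitted."""
    R = table["cases"].to_numpy(float)
    N = table["births"].to_numpy(float)
    eta = np.asarray(eta, float)
    if eta.shape != R.shape:
        raise ValueError("linear predictor not aligned with table")
    return float(_binom_ll_terms(eta, R, N).sum())


def car_log_prior(u, adjacency: Adjacency, sigma_u: float) -> float:
    """Intrinsic CAR log-density (up to a constant):
    ``-(1/(2 sigma_u^2)) * sum over edges (u_i - u_j)^2``.

    Implies the full conditional u_i | u_-i ~ Normal(mean of neighbours,
    sigma_u^2 / n_i).  Island units (no neighbours) contribute nothing and
    are pinned at 0 by the sampler.
    """
    u = np.asarray(u, float)
    w = adjacency.to_sparse()
    deg = np.asarray(w.sum(axis=1)).ravel()
    quad = float(u @ (deg * u) - u @ (w @ u))  # = sum_edges (u_i - u_j)^2
    return -quad / (2.0 * sigma_u ** 2)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _color_classes(adjacency: Adjacency):
    g = adjacency.to_graph()
    coloring = nx.greedy_color(g, strategy="DSATUR")
    index = {uid: k for k, uid in enumerate(adjacency.ids)}
    classes: dict[int, list[int]] = {}
    for uid, col in coloring.items():
        classes.setdefault(col, []).append(index[uid])
    return [np.array(sorted(c)) for c in classes.values()]


def _run_mcmc(spec: ModelSpec, R, N, X, adjacency: Adjacency,
              config: McmcConfig):
    rng = np.random.default_rng(config.seed)
    n = len(R)
    ids = list(adjacency.ids)
    w = adjacency.to_sparse()
    deg = np.asarray(w.sum(axis=1)).ravel()
    coo = sp.triu(w).tocoo()
    edge_i, edge_j = coo.row, coo.col

    def lap_quad(u):  # sum over undirected edges of (u_i - u_j)^2
        d = u[edge_i] - u[edge_j]
        return float(d @ d)

    comps = adjacency.connected_components()
    index = {uid: k for k, uid in enumerate(ids)}
    comp_idx = [np.array([index[i] for i in c]) for c in comps if len(c) > 1]
    island = deg == 0
    n_car = int((~island).sum())
    n_comp = len(comp_idx)
    single_full_component = n_comp == 1 and n_car == n
    classes = [c[~island[c]] for c in _color_classes(adjacency)]
    classes = [c for c in classes if len(c)]
    # pre-sliced per-class quantities; sparse ops inside the loop are slow,
    # so neighbour sums use fancy indexing + add.reduceat over CSR arrays
    w_csr = w.tocsr()
    class_data = []
    for cls in classes:
        sub = w_csr[cls]
        class_data.append((cls, sub.indices, sub.indptr[:-1],
                           R[cls], N[cls], deg[cls]))

    # state
    p0 = np.clip(R.sum() / N.sum(), 1e-4, 1 - 1e-4)
    beta0 = float(np.log(p0 / (1 - p0)))
    beta1 = 0.0
    u = np.zeros(n)
    v = np.zeros(n)
    sig_u = 0.1
    sig_v = 0.1

    # adaptive proposal scales
    s_b0, s_b1 = 0.05, 0.05
    s_u = np.full(n, 0.2)
    s_v = np.full(n, 0.2)
    s_su, s_sv = 0.3, 0.3
    acc = {"b0": 0, "b1": 0, "su": 0, "sv": 0}
    acc_u = np.zeros(n)
    acc_v = np.zeros(n)
    target, window = 0.44, config.adapt_interval

    xb = spec.include_fixed_ses and X is not None
    if spec.include_fixed_ses and X is None:
        raise ValueError("model includes a fixed SES effect but no ses_std")

    b_prior_var = spec.beta_prior_sd ** 2
    hn_var = spec.sigma_prior_sd ** 2

    S = config.n_retained
    out_b0 = np.empty(S)
    out_b1 = np.empty(S) if xb else None
    out_u = np.empty((S, n)) if spec.include_car else None
    out_v = np.empty((S, n)) if spec.include_iid else None
    out_su = np.empty(S) if spec.include_car else None
    out_sv = np.empty(S) if spec.include_iid else None
    out_dev = np.empty(S)
    keep = 0

    Xv = X if xb else np.zeros(n)
    b1_term = lambda: beta1 * Xv if xb else 0.0

    for it in range(config.iterations):
        base_re = u + v  # u, v are zero vectors when absent
        # ---- beta0
        eta = beta0 + b1_term() + base_re
        prop = beta0 + s_b0 * rng.standard_normal()
        d = (_binom_ll_terms(eta + (prop - beta0), R, N).sum()
             - _binom_ll_terms(eta, R, N).sum()
             + (beta0 ** 2 - prop ** 2) / (2 * b_prior_var))
        if np.log(rng.random()) < d:
            beta0 = prop
            acc["b0"] += 1
        # ---- beta1
        if xb:
            eta = beta0 + beta1 * Xv + base_re
            prop = beta1 + s_b1 * rng.standard_normal()
            d = (_binom_ll_terms(eta + (prop - beta1) * Xv, R, N).sum()
                 - _binom_ll_terms(eta, R, N).sum()
                 + (beta1 ** 2 - prop ** 2) / (2 * b_prior_var))
            if np.log(rng.random()) < d:
                beta1 = prop
                acc["b1"] += 1
        # ---- u, chromatic single-site updates
        if spec.include_car:
            base = beta0 + b1_term() + v
            for cls, nbr_idx, nbr_ptr, r_cls, n_cls, deg_cls in class_data:
                s_nb = np.add.reduceat(u[nbr_idx], nbr_ptr)
                cur = u[cls]
                prop = cur + s_u[cls] * rng.standard_normal(len(cls))
                dll = (_binom_ll_terms(base[cls] + prop, r_cls, n_cls)
                       - _binom_ll_terms(base[cls] + cur, r_cls, n_cls))
                dpr = -(deg_cls * (prop ** 2 - cur ** 2)
                        - 2.0 * (prop - cur) * s_nb) / (2 * sig_u ** 2)
                ok = np.log(rng.random(len(cls))) < dll + dpr
                u[cls[ok]] = prop[ok]
                acc_u[cls[ok]] += 1
            # sum-to-zero per component; absorb into beta0 when exact
            if single_full_component:
                m = u.mean()
                u -= m
                beta0 += m
            else:
                for ci in comp_idx:
                    u[ci] -= u[ci].mean()
        # ---- v, elementwise
        if spec.include_iid:
            base = beta0 + b1_term() + u
            prop = v + s_v * rng.standard_normal(n)
            dll = (_binom_ll_terms(base + prop, R, N)
                   - _binom_ll_terms(base + v, R, N))
            dpr = -(prop ** 2 - v ** 2) / (2 * sig_v ** 2)
            ok = np.log(rng.random(n)) < dll + dpr
            v[ok] = prop[ok]
            acc_v[ok] += 1
        # ---- scale parameters, log-scale random walks
        if spec.include_car:
            ss = lap_quad(u)
            prop = sig_u * np.exp(s_su * rng.standard_normal())
            d = (-(n_car - n_comp) * (np.log(prop) - np.log(sig_u))
                 - ss / 2 * (1 / prop ** 2 - 1 / sig_u ** 2)
                 - (prop ** 2 - sig_u ** 2) / (2 * hn_var)
                 + (np.log(prop) - np.log(sig_u)))
            if np.log(rng.random()) < d:
                sig_u = prop
                acc["su"] += 1
        if spec.include_iid:
            ssv = float(v @ v)
            prop = sig_v * np.exp(s_sv * rng.standard_normal())
            d = (-n * (np.log(prop) - np.log(sig_v))
                 - ssv / 2 * (1 / prop ** 2 - 1 / sig_v ** 2)
                 - (prop ** 2 - sig_v ** 2) / (2 * hn_var)
                 + (np.log(prop) - np.log(sig_v)))
            if np.log(rng.random()) < d:
                sig_v = prop
                acc["sv"] += 1
        # ---- adapt during burn-in only
        if it < config.burn_in and (it + 1) % window == 0:
            g = min(0.5, 2.0 / np.sqrt((it + 1) / window))
            s_b0 *= np.exp(g * (acc["b0"] / window - target))
            s_b1 *= np.exp(g * (acc["b1"] / window - target))
            s_su *= np.exp(g * (acc["su"] / window - target))
            s_sv *= np.exp(g * (acc["sv"] / window - target))
            s_u *= np.exp(g * (acc_u / window - target))
            s_v *= np.exp(g * (acc_v / window - target))
            acc = {k: 0 for k in acc}
            acc_u[:] = 0.0
            acc_v[:] = 0.0
        # ---- record
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            eta = beta0 + b1_term() + u + v
            out_b0[keep] = beta0
            if xb:
                out_b1[keep] = beta1
            if spec.include_car:
                out_u[keep] = u
                out_su[keep] = sig_u
            if spec.include_iid:
                out_v[keep] = v
                out_sv[keep] = sig_v
            out_dev[keep] = -2.0 * _binom_ll_terms(eta, R, N).sum()
            keep += 1

    return PosteriorDraws(ids=ids, beta0=out_b0[:keep], deviance=out_dev[:keep],
                          beta1=out_b1[:keep] if xb else None,
                          u=out_u[:keep] if spec.include_car else None,
                          v=out_v[:keep] if spec.include_iid else None,
                          sigma_u=out_su[:keep] if spec.include_car else None,
                          sigma_v=out_sv[:keep] if spec.include_iid else None)


# ---------------------------------------------------------------------------
# DIC and diagnostics
# ---------------------------------------------------------------------------

def _eta_samples(draws: PosteriorDraws, table: pd.DataFrame) -> np.ndarray:
    n = len(table)
    eta = np.tile(draws.beta0[:, None], (1, n))
    if draws.beta1 is not None:
        eta += draws.beta1[:, None] * table["ses_std"].to_numpy()[None, :]
    if draws.u is not None:
        eta += draws.u
    if draws.v is not None:
        eta += draws.v
    return eta


def dic(draws: PosteriorDraws, table: pd.DataFrame):
    """Deviance information criterion and effective parameter count.

    pD = mean deviance - deviance at the posterior means of each suburb's
    linear predictor (the "stochastic parents" plug-in); DIC = mean
    deviance + pD.
    """
    if draws.n_samples < 100:
        raise ValueError("need >= 100 retained draws for a stable DIC")
    table = table.set_index("suburb_id").loc[draws.ids].reset_index()
    d_bar = float(draws.deviance.mean())
    eta_bar = _eta_samples(draws, table).mean(axis=0)
    d_hat = -2.0 * log_likelihood(table, eta_bar)
    pd_ = d_bar - d_hat
    return d_bar + pd_, pd_


def _spectral0(x: np.ndarray) -> float:
    """Spectral density of the chain at frequency zero, via a Bartlett-
    windowed autocovariance sum (Newey-West)."""
    x = x - x.mean()
    m = len(x)
    lag = max(1, int(np.floor(np.sqrt(m))))
    gamma0 = float(x @ x) / m
    s = gamma0
    for k in range(1, lag + 1):
        gk = float(x[:-k] @ x[k:]) / m
        s += 2.0 * (1.0 - k / (lag + 1)) * gk
    return max(s, 0.0)


def geweke(chain, first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke convergence z: compares the means of the first ``first_frac``
    and last ``last_frac`` of the chain using spectral-density-at-zero
    variance estimates."""
    x = np.asarray(chain, float)
    if x.size < 200:
        raise ValueError("chain too short for the Geweke diagnostic")
    a = x[: int(x.size * first_frac)]
    b = x[-int(x.size * last_frac):]
    sa, sb = _spectral0(a), _spectral0(b)
    if sa == 0 or sb == 0:
        raise ValueError("zero spectral variance in a chain segment")
    return float((a.mean() - b.mean()) / np.sqrt(sa / a.size + sb / b.size))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class BYMModel:
    """Binomial-logit small-area model with optional SES fixed effect and
    BYM (ICAR + exchangeable) random effects.

    Parameters
    ----------
    table
        Suburb table with columns ``suburb_id``, ``births``, ``cases`` and,
        for models with a fixed effect, ``ses_std``.
    adjacency
        Neighbour structure over exactly the table's suburbs.
    spec
        A :class:`ModelSpec` or model name
        (``"null" | "random" | "fixed" | "full"``).
    """

    def __init__(self, table: pd.DataFrame, adjacency: Adjacency,
                 spec: ModelSpec | str = "full"):
        if isinstance(spec, str):
            spec = ModelSpec.from_name(spec)
        if set(table["suburb_id"]) != set(adjacency.ids):
            raise ValueError("table and adjacency cover different suburbs")
        self.table = table.set_index("suburb_id").loc[adjacency.ids].reset_index()
        self.adjacency = adjacency
        self.spec = spec

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, adjacency: Adjacency,
                       model: str = "full") -> "BYMModel":
        return cls(df, adjacency, ModelSpec.from_name(model))

    def fit(self, config: McmcConfig | None = None, **kwargs) -> "BYMResults":
        if config is None:
            config = McmcConfig(**kwargs)
        R = self.table["cases"].to_numpy(float)
        N = self.table["births"].to_numpy(float)
        X = (self.table["ses_std"].to_numpy(float)
             if "ses_std" in self.table.columns else None)
        draws = _run_mcmc(self.spec, R, N, X, self.adjacency, config)
        return BYMResults(self, draws, config)


class BYMResults:
    """Posterior draws plus derived summaries for a fitted BYM model."""

    def __init__(self, model: BYMModel, draws: PosteriorDraws,
                 config: McmcConfig):
        self.model = model
        self.draws = draws
        self.config = config
        self._dic: tuple | None = None
        self.geweke_z = self._geweke_table()
        bad = {k: z for k, z in self.geweke_z.items() if abs(z) > 3}
        if bad:
            warnings.warn(f"possible non-convergence; |Geweke z| > 3 for {bad}",
                          ConvergenceWarning)

    # -- diagnostics -------------------------------------------------------
    def _geweke_table(self) -> dict:
        out = {"beta0": geweke(self.draws.beta0),
               "deviance": geweke(self.draws.deviance)}
        if self.draws.beta1 is not None:
            out["beta1"] = geweke(self.draws.beta1)
        if self.draws.sigma_u is not None:
            out["sigma_u"] = geweke(self.draws.sigma_u)
        if self.draws.sigma_v is not None:
            out["sigma_v"] = geweke(self.draws.sigma_v)
        return out

    @property
    def dic(self) -> float:
        if self._dic is None:
            self._dic = dic(self.draws, self.model.table)
        return self._dic[0]

    @property
    def pd(self) -> float:
        if self._dic is None:
            self._dic = dic(self.draws, self.model.table)
        return self._dic[1]

    # -- estimates ---------------------------------------------------------
    @staticmethod
    def _ci(x):
        return tuple(np.quantile(x, [0.025, 0.975]))

    @property
    def mean_probability(self) -> dict:
        """Posterior summary of p at the mean-SES suburb, inverse-logit(b0)."""
        p = 1.0 / (1.0 + np.exp(-self.draws.beta0))
        return {"mean": float(p.mean()), "ci95": self._ci(p)}

    @property
    def beta1_summary(self) -> Optional[dict]:
        if self.draws.beta1 is None:
            return None
        b = self.draws.beta1
        return {"mean": float(b.mean()), "ci95": self._ci(b)}

    def posterior_mean(self, component: str) -> pd.Series:
        arr = getattr(self.draws, component, None)
        if arr is None:
            raise ValueError(f"model has no component {component!r}")
        return pd.Series(arr.mean(axis=0), index=self.draws.ids, name=component)

    def fitted_probabilities(self) -> pd.Series:
        """Posterior-mean per-suburb probability of poor fetal growth."""
        eta = _eta_samples(self.draws, self.model.table)
        p = (1.0 / (1.0 + np.exp(-eta))).mean(axis=0)
        return pd.Series(p, index=self.draws.ids, name="fitted_p")

    # -- effect summaries (delegated) ---------------------------------------
    def iqor(self, component: str) -> float:
        from . import summaries
        return summaries.iqor(summaries.component_effects(
            self.draws, self.model.table)[component])

    def variance_partition(self, use_hyperparameters: bool = False) -> float:
        from . import summaries
        return summaries.variance_partition(
            self.draws, use_hyperparameters=use_hyperparameters)

    def exceedance(self, threshold: float = 0.90):
        from . import summaries
        return summaries.exceedance(self.draws, threshold=threshold)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"BYM binomial-logit model ({spec.name}), "
            f"{len(self.model.table)} suburbs",
            f"  retained draws: {self.draws.n_samples} "
            f"(iterations {self.config.iterations}, burn-in "
            f"{self.config.burn_in}, thin {self.config.thin})",
            f"  DIC = {self.dic:.1f}   pD = {self.pd:.1f}",
        ]
        mp = self.mean_probability
        lines.append(f"  p    = {mp['mean']:.3f} "
                     f"({mp['ci95'][0]:.3f}, {mp['ci95'][1]:.3f})")
        if self.draws.beta1 is not None:
            b = self.beta1_summary
            lines.append(f"  b1   = {b['mean']:.2f} "
                         f"({b['ci95'][0]:.2f}, {b['ci95'][1]:.2f})")
        for s, arr in (("sigma_u", self.draws.sigma_u),
                       ("sigma_v", self.draws.sigma_v)):
            if arr is not None:
                lo, hi = self._ci(arr)
                lines.append(f"  {s} = {arr.mean():.3f} ({lo:.3f}, {hi:.3f})")
        gz = ", ".join(f"{k}: {z:+.2f}" for k, z in self.geweke_z.items())
        lines.append(f"  Geweke z: {gz}")
        return "\n".join(lines)

    def to_json_summary(self) -> dict:
        out = {"model": self.model.spec.name, "dic": self.dic, "pd": self.pd,
               "p": self.mean_probability, "geweke_z": self.geweke_z,
               "n_samples": self.draws.n_samples}
        if self.draws.beta1 is not None:
            out["beta1"] = self.beta1_summary
        if self.draws.sigma_u is not None:
            out["sigma_u_mean"] = float(self.draws.sigma_u.mean())
        if self.draws.sigma_v is not None:
            out["sigma_v_mean"] = float(self.draws.sigma_v.mean())
        return out
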