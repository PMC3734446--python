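"""Synthetic suburb registry: geography, SES surface, counts, birth records.

Everything downstream of the real (confidential) perinatal registry is
exercised against data from this module.  The generators reproduce the
statistical structure the analysis assumes:

* a contiguous lattice of areal units, optionally split by a river whose
  banks are reconnected with supplementary adjacencies;
* a spatially autocorrelated, standardised socioeconomic index;
* suburb-level binomial counts of poor fetal growth driven by a logit-linear
  model with an intrinsic-CAR spatial effect ``u`` and an exchangeable
  effect ``v``::

      logit(p_i) = beta0 + beta1 * X_i + u_i + v_i,   R_i ~ Bin(N_i, p_i)

* birth-level records carrying the eligibility fields (liveborn, plurality,
  gestation), a proportion-of-optimal-birthweight (POBW) ratio with
  configurable missingness, and a small-for-gestational-age (SGA) flag from
  a packaged synthetic centile table.

The true ``u`` and ``v`` are recorded alongside the counts so parameter
recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, box

from .geography import Adjacency, write_geojson_polygons

__all__ = [
    "SimulationParams",
    "SuburbGeography",
    "generate_geography",
    "generate_ses",
    "simulate_counts",
    "simulate_birth_records",
    "sample_icar",
    "sga_cutoff",
    "expected_birthweight",
]

RIVER_GAP = 0.3  # width of the river strip, in lattice cell units


@dataclass
class SimulationParams:
    """Generating values for the suburb-level count model and birth records.

    Defaults correspond to the study conditions the analysis emulates: a mean
    incidence of poor fetal growth near 5%, a socioeconomic log-odds slope of
    about -0.25 per SD, modest spatial and unstructured heterogeneity, and a
    low baseline POBW missingness.
    """

    beta0: float = -2.944  # logit(0.05)
    beta1: float = -0.25
    sigma_u: float = 0.3
    sigma_v: float = 0.2
    mean_births: float = 330.0
    pobw_missing_rate: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_u < 0 or self.sigma_v < 0:
            raise ValueError("sigma_u and sigma_v must be non-negative")
        if not (0 <= self.pobw_missing_rate < 1):
            raise ValueError("pobw_missing_rate must be in [0, 1)")
        if self.mean_births <= 0:
            raise ValueError("mean_births must be positive")


@dataclass
class SuburbGeography:
    """Regular-lattice stand-in for a set of suburb polygons."""

    ids: list
    polygons: list
    n_rows: int
    n_cols: int
    river: Optional[LineString] = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {i: k for k, i in enumerate(self.ids)}

    def footprint(self, unit_id) -> Polygon:
        return self.polygons[self._index[unit_id]]

    def centroid(self, unit_id):
        c = self.footprint(unit_id).centroid
        return (c.x, c.y)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_geojson(self, path, properties: pd.DataFrame | None = None) -> None:
        write_geojson_polygons(self.ids, self.polygons, path, properties)

    def grid_position(self, unit_id) -> tuple[int, int]:
        k = self._index[unit_id]
        return divmod(k, self.n_cols)


def generate_geography(n_rows: int, n_cols: int, river: bool = False,
                       seed: int = 0) -> SuburbGeography:
    """Unit-square lattice of ``n_rows x n_cols`` suburbs.

    With ``river=True`` a horizontal river strip of width 0.3 cells is
    inserted between the two middle rows: rows above it are shifted up, so
    the banks no longer touch and contiguity across the river is severed
    until supplementary edges restore it.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be >= 1")
    river_row = n_rows // 2 if river and n_rows >= 2 else None
    ids, polys = [], []
    for r in range(n_rows):
        y0 = float(r)
        if river_row is not None and r >= river_row:
            y0 += RIVER_GAP
        for c in range(n_cols):
            ids.append(f"S{r * n_cols + c:04d}")
            polys.append(box(float(c), y0, float(c) + 1.0, y0 + 1.0))
    river_line = None
    if river_row is not None:
        y = river_row + RIVER_GAP / 2.0
        river_line = LineString([(-1.0, y), (n_cols + 1.0, y)])
    return SuburbGeography(ids, polys, n_rows, n_cols, river_line)


# ---------------------------------------------------------------------------
# SES surface
# ---------------------------------------------------------------------------

def _lattice_w(n_rows: int, n_cols: int) -> np.ndarray:
    """Queen adjacency of the index lattice, ignoring any river gap.

    The SES field spans the river (a river does not interrupt the region's
    socioeconomic gradient), so smoothing uses the gapless lattice graph.
    """
    n = n_rows * n_cols
    w = np.zeros((n, n))
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n_rows and 0 <= cc < n_cols:
                        w[i, rr * n_cols + cc] = 1.0
    return w


def generate_ses(geography: SuburbGeography, spatial_smoothness: float = 0.8,
                 seed: int = 0) -> pd.Series:
    """Spatially correlated Gaussian SES surface on the lattice.

    Kernel-smoothed white noise: starting from an iid standard-normal field
    ``e``, the surface is ``y = (1 - s) e + s * M y`` iterated
    ``ceil(s / (1 - s))`` times, with ``M`` the row-normalised queen lattice
    adjacency.  ``s = 0`` returns the iid field unchanged; increasing ``s``
    monotonically increases the expected Moran's I of the draw.  Values are
    returned on a census-index-like scale (mean 1000, SD 100); the analysis
    standardises them within the study area anyway.
    """
    s = float(spatial_smoothness)
    if not (0 <= s < 1):
        raise ValueError("spatial_smoothness must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = geography.n
    if n < 2:
        return pd.Series(1000.0, index=pd.Index(geography.ids, name="suburb_id"),
                         name="ses_raw")
    e = rng.standard_normal(n)
    x = e
    if s > 0:
        w = _lattice_w(geography.n_rows, geography.n_cols)
        rowsum = w.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        m = w / rowsum
        for _ in range(int(np.ceil(s / (1.0 - s)))):
            x = (1.0 - s) * e + s * (m @ x)
    x = (x - x.mean()) / x.std()
    return pd.Series(1000.0 + 100.0 * x, index=pd.Index(geography.ids, name="suburb_id"),
                     name="ses_raw")


# ---------------------------------------------------------------------------
# ICAR field and counts
# ---------------------------------------------------------------------------

def sample_icar(adjacency: Adjacency, sigma_u: float, rng) -> np.ndarray:
    """Draw from the intrinsic CAR distribution with pairwise-difference
    precision ``(1/sigma_u^2) * (D - W)``, constrained to sum to zero per
    connected component; island units get exactly 0.

    Uses the spectral pseudo-inverse of the graph Laplacian per component.
    """
    ids = adjacency.ids
    index = {u: k for k, u in enumerate(ids)}
    u = np.zeros(len(ids))
    if sigma_u == 0:
        return u
    w = adjacency.to_sparse().toarray()
    for comp in adjacency.connected_components():
        if len(comp) < 2:
            continue  # island: u stays 0
        idx = np.array([index[i] for i in comp])
        wc = w[np.ix_(idx, idx)]
        lap = np.diag(wc.sum(axis=1)) - wc
        vals, vecs = np.linalg.eigh(lap)
        keep = vals > 1e-9
        z = rng.standard_normal(keep.sum())
        draw = vecs[:, keep] @ (z / np.sqrt(vals[keep]))
        draw -= draw.mean()  # numerical guard; null space already excluded
        u[idx] = sigma_u * draw
    return u


def simulate_counts(suburbs: pd.DataFrame, adjacency: Adjacency,
                    params: SimulationParams) -> pd.DataFrame:
    """Binomial suburb counts from the logit-linear convolution model.

    ``suburbs`` must carry ``suburb_id`` and standardised SES ``ses_std``;
    ``births`` is used if present, otherwise drawn Poisson(mean_births),
    floored at 1.  Returns the table with ``births``, ``cases``, ``p_true``,
    ``true_u`` and ``true_v`` appended.
    """
    tab = suburbs.copy().reset_index(drop=True)
    if set(tab["suburb_id"]) != set(adjacency.ids):
        raise ValueError("suburb ids do not match adjacency ids")
    # align to adjacency order
    tab = tab.set_index("suburb_id").loc[adjacency.ids].reset_index()
    rng = np.random.default_rng(params.seed)
    n = len(tab)
    if "births" in tab.columns:
        births = tab["births"].to_numpy(int)
    else:
        births = np.maximum(1, rng.poisson(params.mean_births, size=n))
    u = sample_icar(adjacency, params.sigma_u, rng)
    v = rng.standard_normal(n) * params.sigma_v
    eta = params.beta0 + params.beta1 * tab["ses_std"].to_numpy() + u + v
    p = 1.0 / (1.0 + np.exp(-eta))
    cases = rng.binomial(births, p)
    tab["births"] = births
    tab["cases"] = cases
    tab["p_true"] = p
    tab["true_u"] = u
    tab["true_v"] = v
    return tab


# ---------------------------------------------------------------------------
# Birth-level records
# ---------------------------------------------------------------------------

# Synthetic sex-by-gestation 10th-centile birthweight table (grams).  These
# are NOT published national centiles: they are generated from the smooth
# reference curve below and frozen here so the SGA classification mechanics
# are exercised against a packaged lookup table.
_GESTATIONS = tuple(range(33, 43))


def _median_birthweight(gestation) -> np.ndarray:
    # smooth synthetic growth curve, grams: 3450 g at 40 weeks, about 2000 g
    # at 33 weeks, about 990 g at 24 weeks
    g = np.asarray(gestation, dtype=float)
    return 3450.0 * np.exp(-0.078 * (40.0 - g))


def _sex_factor(male) -> np.ndarray:
    return np.where(np.asarray(male, bool), 1.03, 0.97)


# 10th centile placed 1.2816 growth-ratio SDs (0.125) below the sex-specific
# median, matching the spread of the simulated weight-for-gestation ratios
SGA_REFERENCE = {
    (sex, g): round(float(_median_birthweight(g) * (1.03 if sex == "M" else 0.97)
                          * (1.0 - 1.2816 * 0.125)), 1)
    for sex in ("M", "F") for g in _GESTATIONS
}


def sga_cutoff(sex: str, gestation: int) -> float:
    """Synthetic 10th-centile birthweight for (sex, completed weeks)."""
    try:
        return SGA_REFERENCE[(sex, int(gestation))]
    except KeyError:
        raise KeyError(
            f"no SGA reference entry for sex={sex!r}, gestation={gestation}")


def expected_birthweight(gestation, male, primiparous, maternal_height) -> np.ndarray:
    """Expected ("optimal") birthweight used as the POBW denominator.

    A simple documented function of gestation, sex, parity and maternal
    height; deliberately not the published regression coefficients.
    """
    base = _median_birthweight(np.asarray(gestation, float))
    parity = np.where(np.asarray(primiparous, bool), 0.965, 1.0)
    height = 1.0 + 0.0025 * (np.asarray(maternal_height, float) - 163.0)
    return base * _sex_factor(male) * parity * height


_GEST_PROBS = np.array([0.004, 0.005, 0.008, 0.015, 0.04, 0.11, 0.24, 0.33,
                        0.20, 0.048])
_GEST_PROBS = _GEST_PROBS / _GEST_PROBS.sum()


def simulate_birth_records(suburbs: pd.DataFrame, params: SimulationParams,
                           missing_bias: float = 0.0) -> pd.DataFrame:
    """Birth-level records consistent with the suburb-level probabilities.

    Per suburb ``i`` with poor-fetal-growth probability ``p_i`` (column
    ``p_true``, else derived from ``cases/births``), each birth draws a POBW
    ratio Normal(m_i, 0.125) with ``m_i`` chosen so P(POBW < 0.8) = p_i, and
    birthweight = POBW x expected weight.  A small share of records are
    stillborn, twins, or preterm (<33 weeks) so eligibility filtering has
    work to do.  POBW is set to null with probability ``pobw_missing_rate``;
    ``missing_bias`` > 0 tilts missingness toward smaller births (log-odds
    of missingness increase by ``missing_bias`` per unit drop in POBW).
    """
    rng = np.random.default_rng(params.seed + 1)
    sd = 0.125
    from scipy.stats import norm

    rows = []
    ses = suburbs.set_index("suburb_id")
    quintile = pd.qcut(ses["ses_std"], 5, labels=False) + 1
    for sid, row in ses.iterrows():
        n_births = int(row["births"])
        if "p_true" in row.index and not pd.isna(row["p_true"]):
            p_i = float(row["p_true"])
        else:
            p_i = max(1e-4, float(row["cases"]) / max(1, n_births))
        m_i = 0.8 - sd * norm.ppf(p_i)
        gest = rng.choice(np.arange(33, 43), size=n_births, p=_GEST_PROBS)
        # a sprinkle of very preterm births that eligibility must remove
        preterm = rng.random(n_births) < 0.012
        gest = np.where(preterm, rng.integers(24, 33, size=n_births), gest)
        male = rng.random(n_births) < 0.514
        primip = rng.random(n_births) < 0.40
        liveborn = rng.random(n_births) >= 0.007
        singleton = rng.random(n_births) >= 0.03
        height = rng.normal(163.0, 6.5, size=n_births)
        pobw = rng.normal(m_i, sd, size=n_births).clip(0.3, 1.8)
        ew = expected_birthweight(gest, male, primip, height)
        bw = pobw * ew
        sex = np.where(male, "M", "F")
        cut = np.array([sga_cutoff(s, g) if 33 <= g <= 42 else np.nan
                        for s, g in zip(sex, gest)])
        sga = bw < cut
        if params.pobw_missing_rate > 0:
            logit_rate = np.log(params.pobw_missing_rate
                                / (1 - params.pobw_missing_rate))
            miss_lp = logit_rate + missing_bias * (1.0 - pobw)
            missing = rng.random(n_births) < 1.0 / (1.0 + np.exp(-miss_lp))
        else:
            missing = np.zeros(n_births, dtype=bool)
        rows.append(pd.DataFrame({
            "suburb_id": sid,
            "birthweight": np.round(bw, 0),
            "gestation": gest,
            "sex": sex,
            "singleton": singleton,
            "liveborn": liveborn,
            "primiparous": primip,
            "maternal_height": np.round(height, 1),
            "pobw": np.where(missing, np.nan, pobw),
            "sga": sga,
            "ses_quintile": int(quintile.loc[sid]),
        }))
    return pd.concat(rows, ignore_index=True)
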