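"""End-to-end orchestration: simulate -> prepare -> fit (4 models x 2
periods) -> summarise -> spatial tests, as one reproducible, configured run.

A single global seed deterministically spawns per-stage seeds through
``numpy.random.SeedSequence(global_seed).spawn``, so any stage can be rerun
in isolation with the seed recorded in the manifest.  Every intermediate
artifact is persisted (CSV/GAL/GeoJSON/JSON) and hashed into a
machine-readable manifest; two runs with the same config produce identical
manifests apart from the timestamp.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geography as geo
from . import summaries as summ
from .bym import BYMModel, McmcConfig
from .simulate import (SimulationParams, generate_geography, generate_ses,
                       simulate_counts)
from .spatial import morans_i, oden_ipop

__all__ = ["RunConfig", "run_pipeline"]

MODELS = ("null", "random", "fixed", "full")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 1
    n_rows: int = 12
    n_cols: int = 12
    river: bool = True
    supplementary_max_distance: float = 0.5
    ses_smoothness: float = 0.8
    periods: tuple = ("1999-2001", "2004-2006")
    models: tuple = MODELS
    simulation: dict = field(default_factory=dict)   # SimulationParams overrides
    mcmc: dict = field(default_factory=dict)         # McmcConfig overrides
    exceedance_threshold: float = 0.90

    def __post_init__(self) -> None:
        if len(set(self.periods)) != len(self.periods):
            raise ValueError("period labels must be unique")
        bad = set(self.models) - set(MODELS)
        if bad:
            raise ValueError(f"unknown models: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _spawn_seeds(seed: int, n: int) -> list[int]:
    # keep spawned seeds below 2**31 so they remain portable integers
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def _log(fh, **fields) -> None:
    fh.write(json.dumps(fields) + "\n")
    fh.flush()


def run_pipeline(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logf = open(out / "run.log.jsonl", "w")
    artifacts: dict[str, str] = {}
    t0 = time.time()

    def persist(name: str, path: Path) -> None:
        artifacts[name] = _sha256(path)

    n_stage_seeds = 1 + 2 * len(config.periods)
    seeds = _spawn_seeds(config.seed, n_stage_seeds)
    seed_iter = iter(seeds)

    try:
        # ---- geography and adjacency (shared across periods) --------------
        _log(logf, stage="geography", status="start")
        geog = generate_geography(config.n_rows, config.n_cols,
                                  river=config.river, seed=next(seed_iter))
        adj = geo.contiguity_adjacency(geog)
        adj = geo.add_supplementary_edges(
            adj, geog, config.supplementary_max_distance)
        geog.to_geojson(out / "suburbs.geojson")
        geo.write_gal(adj, out / "adjacency.gal")
        persist("suburbs.geojson", out / "suburbs.geojson")
        persist("adjacency.gal", out / "adjacency.gal")
        _log(logf, stage="geography", status="done", n_units=geog.n,
             n_edges=len(adj.edges()))

        fits_manifest = []
        period_effects: dict[str, dict] = {}
        for period in config.periods:
            # ---- SES + counts ---------------------------------------------
            ses_seed, count_seed = next(seed_iter), next(seed_iter)
            _log(logf, stage="simulate", period=period, status="start")
            ses = generate_ses(geog, config.ses_smoothness, seed=ses_seed)
            tab = pd.DataFrame({"suburb_id": list(geog.ids),
                                "ses_raw": ses.to_numpy()})
            from .cohort import standardize_ses
            tab["ses_std"] = standardize_ses(tab["ses_raw"])
            params = SimulationParams(**{"seed": count_seed,
                                         **config.simulation})
            tab = simulate_counts(tab, adj, params)
            tab_path = out / f"suburbs_{period}.csv"
            tab.to_csv(tab_path, index=False)
            persist(tab_path.name, tab_path)
            _log(logf, stage="simulate", period=period, status="done",
                 births=int(tab["births"].sum()), cases=int(tab["cases"].sum()))

            # ---- spatial tests --------------------------------------------
            moran = morans_i(tab["ses_std"], adj, n_permutations=999,
                             seed=ses_seed)
            ipop = oden_ipop(tab["cases"], tab["births"], adj,
                             n_permutations=499, seed=count_seed)
            sp_path = out / f"spatial_tests_{period}.json"
            sp_path.write_text(json.dumps(
                {"morans_i_ses": moran.to_dict(),
                 "oden_ipop_cases": ipop.to_dict()}, indent=2))
            persist(sp_path.name, sp_path)

            # ---- fits ------------------------------------------------------
            fit_seeds = _spawn_seeds(count_seed, len(config.models))
            results = {}
            for model_name, fseed in zip(config.models, fit_seeds):
                _log(logf, stage="fit", period=period, model=model_name,
                     status="start")
                cfg = McmcConfig(**{"seed": fseed, **config.mcmc})
                res = BYMModel(tab, adj, model_name).fit(cfg)
                results[model_name] = res
                sj = res.to_json_summary()
                fit_path = out / f"fit_{period}_{model_name}.json"
                fit_path.write_text(json.dumps(sj, indent=2))
                persist(fit_path.name, fit_path)
                draws_path = out / f"draws_{period}_{model_name}.csv"
                res.draws.to_frame().to_csv(draws_path, index=False)
                persist(draws_path.name, draws_path)
                fits_manifest.append({"period": period, "model": model_name,
                                      "seed": fseed, "dic": sj["dic"],
                                      "pd": sj["pd"]})
                _log(logf, stage="fit", period=period, model=model_name,
                     status="done", dic=sj["dic"])

            # ---- summaries -------------------------------------------------
            table1_rows, effects_by_model = [], {}
            for model_name in config.models:
                res = results[model_name]
                eff = summ.component_effects(res.draws, res.model.table)
                effects_by_model[model_name] = eff
                for comp, series in eff.items():
                    table1_rows.append({"period": period, "model": model_name,
                                        "component": comp,
                                        "iqor": summ.iqor(series)})
            if table1_rows:
                t1 = pd.DataFrame(table1_rows)
                t1_path = out / f"table1_{period}.csv"
                t1.to_csv(t1_path, index=False)
                persist(t1_path.name, t1_path)
            t2 = pd.DataFrame([{
                "period": period, "model": m, "dic": results[m].dic,
                "pd": results[m].pd,
                "p_mean": results[m].mean_probability["mean"],
                "beta1_mean": (results[m].beta1_summary or {}).get("mean"),
            } for m in config.models])
            t2_path = out / f"table2_{period}.csv"
            t2.to_csv(t2_path, index=False)
            persist(t2_path.name, t2_path)
            for m in ("full", "random"):
                if m in results:
                    exc = results[m].exceedance(config.exceedance_threshold)
                    e_path = out / f"exceedance_{period}_{m}.csv"
                    exc.to_csv(e_path, index=False)
                    persist(e_path.name, e_path)
            ref = "full" if "full" in effects_by_model else config.models[-1]
            eff = dict(effects_by_model.get(ref, {}))
            eff["ses_raw"] = tab.set_index("suburb_id")["ses_raw"]
            period_effects[period] = eff

        # ---- between-period stability -------------------------------------
        if len(config.periods) == 2:
            a, b = config.periods
            stab = summ.period_stability(period_effects[a], period_effects[b])
            s_path = out / "period_stability.json"
            s_path.write_text(json.dumps(stab, indent=2))
            persist(s_path.name, s_path)

        manifest = {
            "config": asdict(config),
            "stage_seeds": seeds,
            "fits": fits_manifest,
            "artifacts": artifacts,
            "package": "growthmap 0.1.0",
            "elapsed_seconds": round(time.time() - t0, 2),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:  # persist what we have, then re-raise with stage
        _log(logf, stage="pipeline", status="failed", error=str(exc))
        logf.close()
        raise
    logf.close()
    return out
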