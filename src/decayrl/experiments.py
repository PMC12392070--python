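"""Configuration-driven reproduction of the figure-level simulation protocols.

Each experiment id (``fig1`` .. ``fig6``) bundles one published simulation
protocol with every parameter defaulting to its printed value; supplementary
variants (e.g. gamma = 0.9) are parameter overrides, not code paths.  Running
an experiment writes long-format CSV tables plus a JSON sidecar carrying the
resolved configuration and seed, so every output is reproducible and
diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distributional import (
    CODING_CONDITIONS,
    distribution_coding_score,
    mean_coding_score,
    run_distributional_batch,
)
from .feature_td import make_features, run_feature_td, run_navigation
from .hierarchical import HierarchicalParams, run_hierarchical
from .ovrnn import run_ovrnn
from .tabular_td import run_punctate
from .tasks import make_task

__all__ = [
    "ExperimentConfig",
    "DEFAULTS",
    "run_experiment",
    "summarize_trace",
    "run_many",
]

#: printed parameter values used as configuration defaults (audited by tests).
DEFAULTS = {
    "n_states": 5,
    "n_trials": 200,
    "a": 0.15,
    "kappa_values": (0.0, 0.01, 0.02),
    "gamma": 1.0,
    "gamma_discounting": 0.75,
    "w0": 0.5,
    "a_plus": 0.15,
    "a_minus": 0.075,
    "feature_dim": 100,
    "n_active": 10,
    "a_sr": 0.001,
    "navigation_trials": 360,
    "session_len": 40,
    "ovrnn": {
        "n_units": 40,
        "gamma": 0.8,
        "a_rnn": 0.1,
        "a_value": 0.03,
        "dr_values": (0.0, 0.001),
    },
    "hierarchical": {
        "a_M": 0.25,
        "a_M_alt": 0.125,
        "a_L": 0.025,
        "kappa_M": 0.01,
        "kappa_M_alt": 0.005,
        "kappa_L": 0.0,
        "kappa_L_alt": 0.001,
        "gamma": 1.0,
    },
    "distributional": {
        "rates": (0.15, 0.05, 0.05, 0.15),
        "kappa_values": (0.0, 0.01),
        "gamma": 1.0,
        "noise_sd_values": (0.05, 0.07),
        "n_coding_sims": 1000,
    },
    "fig6": {"rates": (0.15, 0.015, 0.005), "n_trials": 100,
             "reward_schedule": ((0.5, 0.5), (1.5, 0.5))},
    "n_repetitions": 100,
}

EXPERIMENTS = ("fig1", "fig2", "fig3", "fig4", "fig5", "fig6")


@dataclass
class ExperimentConfig:
    """Resolved configuration of one figure-experiment."""

    experiment: str
    seed: int = 0
    n_repetitions: int = 100
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment id: {self.experiment!r}")
        for k in ("kappa", "kappa_M", "kappa_L"):
            v = self.params.get(k)
            if v is not None and not 0.0 <= float(v) < 1.0:
                raise ValueError(f"{k} must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "seed": self.seed,
            "n_repetitions": self.n_repetitions,
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(
            experiment=d["experiment"],
            seed=int(d.get("seed", 0)),
            n_repetitions=int(d.get("n_repetitions", 100)),
            params=dict(d.get("params", {})),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def summarize_trace(
    trace: pd.DataFrame,
    stat: str = "mean_sd",
    value_col: str = "delta",
    by=("step",),
    group_reward: bool = False,
) -> pd.DataFrame:
    """Per-time-step aggregation of a long-format trace.

    ``stat`` is ``mean_sd`` or ``mean_sem``; with ``group_reward=True`` the
    aggregation is additionally split by the realized reward size of each
    trial (as in probabilistic-reward figures).
    """
    if stat not in ("mean_sd", "mean_sem"):
        raise ValueError("stat must be 'mean_sd' or 'mean_sem'")
    if trace.empty:
        raise ValueError("empty trace")
    keys = list(by)
    if group_reward:
        keys = ["reward"] + keys
    grp = trace.groupby(keys)[value_col]
    out = grp.agg(mean="mean", sd="std", n="count").reset_index()
    if stat == "mean_sem":
        out["sem"] = out["sd"] / np.sqrt(out["n"])
        out = out.drop(columns="sd")
    return out


def run_many(runner, n_repetitions: int, rng: np.random.Generator):
    """Run ``runner(rep_rng)`` ``n_repetitions`` times on child generators.

    Child generators are spawned from ``rng`` so repetitions are independent
    but fully reproducible.  Returns the list of results.
    """
    return [runner(np.random.default_rng(rng.integers(2**31))) for _ in range(n_repetitions)]


# ---------------------------------------------------------------------------
# figure protocols


def _steady_profile(trace: pd.DataFrame, last_k: int = 1) -> pd.DataFrame:
    last = trace["trial"].max()
    sel = trace[trace["trial"] > last - last_k]
    return sel.groupby("step")[["delta", "value"]].mean().reset_index()


def _fig1(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    p = cfg.params
    rng = np.random.default_rng(cfg.seed)
    n_trials = int(p.get("n_trials", DEFAULTS["n_trials"]))
    gamma = float(p.get("gamma", DEFAULTS["gamma"]))
    kappas = tuple(p.get("kappa_values", DEFAULTS["kappa_values"]))
    spec = make_task(DEFAULTS["n_states"], [(1.0, 1.0)], n_trials, gamma)
    out = {}

    # punctate kappa sweep + temporal-discounting contrast
    rows = []
    for kappa in kappas:
        tr = run_punctate(spec, a=DEFAULTS["a"], kappa=kappa,
                          rng=np.random.default_rng(rng.integers(2**31)))
        prof = _steady_profile(tr)
        prof.insert(0, "kappa", kappa)
        rows.append(prof)
    out["punctate_steady"] = pd.concat(rows, ignore_index=True)

    spec_disc = make_task(DEFAULTS["n_states"], [(1.0, 1.0)], n_trials,
                          float(p.get("gamma_discounting",
                                      DEFAULTS["gamma_discounting"])))
    tr = run_punctate(spec_disc, a=DEFAULTS["a"], kappa=0.0,
                      rng=np.random.default_rng(rng.integers(2**31)))
    out["punctate_discounting"] = _steady_profile(tr)

    # feature representations at each kappa
    rows = []
    for kind in ("sparse", "dense", "SR", "PR"):
        for kappa in kappas:
            if kind in ("sparse", "dense"):
                def one(r, kind=kind, kappa=kappa):
                    feats = make_features(kind, spec.n_states,
                                          DEFAULTS["feature_dim"],
                                          DEFAULTS["n_active"], rng=r)
                    return _steady_profile(
                        run_feature_td(spec, feats, DEFAULTS["a_plus"],
                                       DEFAULTS["a_minus"], kappa, rng=r)
                    )
                profs = run_many(one, cfg.n_repetitions, rng)
                prof = (
                    pd.concat(profs)
                    .groupby("step")
                    .agg(delta=("delta", "mean"), delta_sd=("delta", "std"),
                         value=("value", "mean"))
                    .reset_index()
                )
            else:
                feats = make_features(kind, spec.n_states, gamma=1.0)
                prof = _steady_profile(
                    run_feature_td(spec, feats, DEFAULTS["a_plus"],
                                   DEFAULTS["a_minus"], kappa,
                                   rng=np.random.default_rng(rng.integers(2**31)))
                )
                prof["delta_sd"] = 0.0
            prof.insert(0, "kappa", kappa)
            prof.insert(0, "kind", kind)
            rows.append(prof)
    out["feature_steady"] = pd.concat(rows, ignore_index=True)

    # navigation with online SR learning
    nav_rows = []
    for reward in (1.0, 0.5):
        nav = run_navigation(reward_size=reward,
                             rng=np.random.default_rng(rng.integers(2**31)))
        sm = nav.session_mean_delta().reset_index().melt(
            id_vars="session", var_name="state", value_name="mean_delta"
        )
        sm.insert(0, "reward", reward)
        nav_rows.append(sm)
    out["navigation_sessions"] = pd.concat(nav_rows, ignore_index=True)
    return out


def _fig2(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    p = cfg.params
    rng = np.random.default_rng(cfg.seed)
    n_trials = int(p.get("n_trials", 1000))
    last_k = int(p.get("last_k", 100))
    rows = []
    for dr in p.get("dr_values", DEFAULTS["ovrnn"]["dr_values"]):
        for cue_type in ("fixed", "dynamic"):
            for iti_kind in ("short", "long"):
                def one(r, dr=dr, cue_type=cue_type, iti_kind=iti_kind):
                    res = run_ovrnn(cue_type, iti_kind, dr=dr,
                                    n_trials=n_trials, rng=r)
                    return res.mean_profile(last_k).reset_index()
                profs = run_many(one, cfg.n_repetitions, rng)
                prof = summarize_trace(
                    pd.concat(profs), "mean_sem", "delta", by=("step",)
                )
                vprof = pd.concat(profs).groupby("step")["value"].mean()
                prof["value"] = prof["step"].map(vprof)
                prof.insert(0, "iti", iti_kind)
                prof.insert(0, "cue", cue_type)
                prof.insert(0, "dr", dr)
                rows.append(prof)
    return {"ovrnn_profiles": pd.concat(rows, ignore_index=True)}


def _fig3(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    p = cfg.params
    h = DEFAULTS["hierarchical"]
    out = {}
    phases = tuple(
        (name, int(n)) for name, n in p.get(
            "phases", (("learning", 200), ("rest", 200), ("extinction", 200))
        )
    )
    variants = {
        "original": HierarchicalParams(h["a_M"], h["a_L"], h["kappa_M"],
                                       h["kappa_L"], 1.0),
        "revised": HierarchicalParams(h["a_M"], h["a_L"], h["kappa_M"],
                                      h["kappa_L"], 0.5),
        "common_ratio": HierarchicalParams(h["a_M"], h["a_L"], h["kappa_M"],
                                           h["kappa_L_alt"], 0.5),
    }
    traces = []
    for name, params in variants.items():
        res = run_hierarchical(phases, params)
        tr = res.trace.copy()
        tr.insert(0, "variant", name)
        traces.append(tr)
    out["hierarchical_trace"] = pd.concat(traces, ignore_index=True)

    # learning/decay-ratio sweep on circuit M (halve a_M, kappa_M, or both)
    rows = []
    for label, (a_M, kappa_M) in {
        "original": (h["a_M"], h["kappa_M"]),
        "half_a": (h["a_M_alt"], h["kappa_M"]),
        "half_kappa": (h["a_M"], h["kappa_M_alt"]),
        "half_both": (h["a_M_alt"], h["kappa_M_alt"]),
    }.items():
        res = run_hierarchical(
            (("learning", 200),),
            HierarchicalParams(a_M, h["a_L"], kappa_M, h["kappa_L"], 1.0),
        )
        last = res.trace[res.trace["trial"] == 199]
        prof = last.groupby("step")["delta_M"].mean().reset_index()
        prof.insert(0, "variant", label)
        rows.append(prof)
    out["ratio_sweep"] = pd.concat(rows, ignore_index=True)
    return out


def _fig4(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    p = cfg.params
    d = DEFAULTS["distributional"]
    rng = np.random.default_rng(cfg.seed)
    n_sims = int(p.get("n_sims", cfg.n_repetitions))
    n_coding = int(p.get("n_coding_sims", d["n_coding_sims"]))
    out = {}

    spec13 = make_task(5, [(1.0, 0.5), (3.0, 0.5)], 2000)
    rows = []
    for algorithm, kappa in (
        ("integRPE", 0.0), ("integRPE", 0.01), ("segreRPE", 0.0)
    ):
        batch = run_distributional_batch(
            algorithm, spec13, n_sims, kappa=kappa, rates=d["rates"],
            rng=np.random.default_rng(rng.integers(2**31)),
            snapshot_trials=(200, 2000),
        )
        for trial, (V1, V2) in batch["snapshots"].items():
            for j, V in ((1, V1), (2, V2)):
                df = pd.DataFrame({
                    "algorithm": algorithm, "kappa": kappa, "trial": trial,
                    "pathway": j, "step": np.arange(1, 6),
                    "mean": V.mean(axis=0), "sd": V.std(axis=0),
                })
                rows.append(df)
    out["value_snapshots"] = pd.concat(rows, ignore_index=True)

    # coding-strength analysis
    spec200 = {name: make_task(5, sched, 200)
               for name, sched in CODING_CONDITIONS.items()}
    coding_rows, mean_rows = [], []
    for algorithm, kappa in (("integRPE", 0.01), ("segreRPE", 0.0)):
        batches = {
            name: run_distributional_batch(
                algorithm, spec, n_coding, kappa=kappa, rates=d["rates"],
                rng=np.random.default_rng(rng.integers(2**31)),
            )
            for name, spec in spec200.items()
        }
        for noise_sd in p.get("noise_sd_values", d["noise_sd_values"]):
            dc = distribution_coding_score(
                batches["always2"], batches["variable13"], noise_sd,
                np.random.default_rng(rng.integers(2**31)),
            )
            dc.insert(0, "noise_sd", noise_sd)
            dc.insert(0, "algorithm", algorithm)
            coding_rows.append(dc)
            mc = mean_coding_score(
                batches,
                {"always0": 0.0, "variable13": 2.0, "always2": 2.0},
                noise_sd,
                np.random.default_rng(rng.integers(2**31)),
            )
            mc.insert(0, "noise_sd", noise_sd)
            mc.insert(0, "algorithm", algorithm)
            mean_rows.append(mc)
    out["distribution_coding"] = pd.concat(coding_rows, ignore_index=True)
    out["mean_coding"] = pd.concat(mean_rows, ignore_index=True)
    return out


def _fig5(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Cue value (TD-RPE upon cue) as a function of the cue-reward delay."""
    p = cfg.params
    rng = np.random.default_rng(cfg.seed)
    kappas = tuple(p.get("kappa_values", (0.01, 0.02)))
    n_max = int(p.get("n_max", 10))
    n_reps = int(p.get("n_repetitions_features", cfg.n_repetitions))
    rows = []
    for kappa in kappas:
        for n in range(1, n_max + 1):
            spec = make_task(n, [(1.0, 1.0)], DEFAULTS["n_trials"], 1.0)
            tr = run_punctate(spec, DEFAULTS["a"], kappa,
                              np.random.default_rng(rng.integers(2**31)))
            cue = tr[(tr["trial"] == spec.n_trials - 1) & (tr["step"] == 0)]
            rows.append(("punctate", kappa, n, float(cue["delta"].iloc[0]), 0.0))
            for kind in ("sparse", "dense"):
                def one(r, kind=kind, kappa=kappa, spec=spec):
                    feats = make_features(kind, spec.n_states,
                                          DEFAULTS["feature_dim"],
                                          DEFAULTS["n_active"], rng=r)
                    tr = run_feature_td(spec, feats, DEFAULTS["a_plus"],
                                        DEFAULTS["a_minus"], kappa, rng=r)
                    cue = tr[(tr["trial"] == spec.n_trials - 1)
                             & (tr["step"] == 0)]
                    return float(cue["delta"].iloc[0])
                vals = np.array(run_many(one, n_reps, rng))
                rows.append((kind, kappa, n, float(vals.mean()),
                             float(vals.std())))
    return {
        "cue_value_vs_delay": pd.DataFrame(
            rows, columns=["kind", "kappa", "n_states", "cue_value", "sd"]
        )
    }


def _fig6(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Dense features, probabilistic reward, learning-rate sweep."""
    p = cfg.params
    f6 = DEFAULTS["fig6"]
    rng = np.random.default_rng(cfg.seed)
    spec = make_task(5, f6["reward_schedule"],
                     int(p.get("n_trials", f6["n_trials"])))
    rows = []
    for a in p.get("rates", f6["rates"]):
        def one(r, a=a):
            feats = make_features("dense", spec.n_states,
                                  DEFAULTS["feature_dim"], rng=r)
            tr = run_feature_td(spec, feats, a_plus=a, a_minus=a,
                                kappa=0.0, rng=r)
            return tr[tr["trial"] == spec.n_trials - 1]
        finals = pd.concat(run_many(one, cfg.n_repetitions, rng))
        prof = summarize_trace(finals, "mean_sd", "delta",
                               by=("step",), group_reward=True)
        prof.insert(0, "a", a)
        rows.append(prof)
    return {"final_trial_delta": pd.concat(rows, ignore_index=True)}


_RUNNERS = {
    "fig1": _fig1, "fig2": _fig2, "fig3": _fig3,
    "fig4": _fig4, "fig5": _fig5, "fig6": _fig6,
}


def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Run one figure-experiment and write its tables under ``out_dir``.

    Writes one CSV per output table plus ``config.json`` (resolved config,
    seed and package version).  Deterministic given (config, seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = _RUNNERS[config.experiment](config)
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    sidecar = config.to_dict()
    sidecar["package_version"] = __version__
    sidecar["tables"] = sorted(tables)
    (out_dir / "config.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir
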