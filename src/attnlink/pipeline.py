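"""End-to-end seeded pipeline: simulate -> fit -> decode -> link.

Every stage writes its outputs (and the resolved configuration plus a
provenance log) under the output directory, and later stages read only
those files, so stages can be rerun individually and the whole run is
reproducible bit-for-bit from the config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fitting, linking, neuro, structures as st, synth

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "fit", "decode", "link")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    experiment: str = "5_4"          # "5_4" (GCM) or "shj" (SUSTAIN)
    n_participants: int = 10
    seed: int = 0
    kappa: float = synth.DEFAULT_KAPPA
    sigma: float = 1.0
    n_units: int = 100
    runs: int = 5
    trials_per_run: int = 16
    dirichlet_alpha: float = 1.0
    ga_population: int = 24
    ga_generations: int = 30
    ga_starts: int = 1
    svc_c: float = 1.0
    n_perm: int = 500
    perm_engine: str = "mixed"
    n_boot: int = 0
    out_dir: str = "attnlink_out"

    def __post_init__(self):
        if self.experiment not in ("5_4", "shj"):
            raise ValueError("experiment must be '5_4' or 'shj'")
        if self.n_participants < 5:
            raise ValueError("need at least 5 participants for the linking model")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        self.model = "gcm" if self.experiment == "5_4" else "sustain"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def synth_config(self) -> synth.SynthConfig:
        return synth.SynthConfig(
            n_participants=self.n_participants, model=self.model,
            dirichlet_alpha=self.dirichlet_alpha, kappa=self.kappa,
            sigma=self.sigma, n_units=self.n_units, runs=self.runs,
            trials_per_run=self.trials_per_run, seed=self.seed,
        )

    def ga_config(self) -> fitting.GAConfig:
        return fitting.GAConfig(population=self.ga_population,
                                generations=self.ga_generations,
                                n_starts=self.ga_starts)


def _write_provenance(out: Path, config: PipelineConfig, stage: str) -> None:
    import sklearn
    import statsmodels
    prov = {
        "stage": stage,
        "seed": config.seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
    with (out / "provenance.jsonl").open("a") as fh:
        fh.write(json.dumps(prov) + "\n")
    (out / "config.yaml").write_text(
        yaml.safe_dump({k: v for k, v in dataclasses.asdict(config).items()})
    )


def _stage_simulate(config: PipelineConfig, out: Path):
    structure = st.load_structure(config.experiment)
    scfg = config.synth_config()
    cohort = synth.simulate_participants(structure, scfg)
    patterns = synth.simulate_patterns(cohort, structure, scfg)
    all_trials = []
    for pid in cohort.participants:
        tr = cohort.trials[pid]
        if isinstance(tr, dict):
            for problem_trials in tr.values():
                all_trials += problem_trials
        else:
            all_trials += tr
    st.write_trials_tsv(all_trials, out / "behavior.tsv")
    rows = []
    for pid, profs in cohort.profiles.items():
        for rule, w in profs.items():
            for k, v in enumerate(w):
                rows.append(dict(participant=pid, rule=rule, dimension=k, weight=float(v)))
    pd.DataFrame(rows).to_csv(out / "true_attention.tsv", sep="\t", index=False)
    pat_dir = out / "patterns"
    pat_dir.mkdir(exist_ok=True)
    for pid, by_rule in patterns.items():
        for rule, pm in by_rule.items():
            pm.save(pat_dir / f"{pid}__{rule}")
    mappings = {
        pid: {"permutation": list(m.permutation), "polarity": list(m.polarity),
              "feature_names": list(m.feature_names)}
        for pid, m in cohort.mappings.items()
    }
    (out / "mappings.json").write_text(json.dumps(mappings, indent=1))


def _stage_fit(config: PipelineConfig, out: Path):
    structure = st.load_structure(config.experiment)
    trials = st.read_trials_tsv(out / "behavior.tsv")
    by_pid = {}
    for t in trials:
        by_pid.setdefault(t.participant, []).append(t)
    ga = config.ga_config()
    rows, results = [], []
    for i, (pid, tr) in enumerate(sorted(by_pid.items())):
        fit_seed = config.seed * 1000 + i
        if config.model == "gcm":
            res = fitting.fit_gcm(tr, structure, ga_config=ga, seed=fit_seed)
        else:
            by_problem = {}
            for t in tr:  # trials are written in experienced order
                by_problem.setdefault(t.problem, []).append(t)
            res = fitting.fit_sustain_chain(by_problem, ga_config=ga, seed=fit_seed)
        results.append(res.to_dict())
        for rule, w in res.attention.items():
            for k, v in enumerate(w):
                rows.append(dict(participant=pid, rule=rule, dimension=k, weight=float(v)))
    pd.DataFrame(rows).to_csv(out / "fitted_attention.tsv", sep="\t", index=False)
    (out / "fits.json").write_text(json.dumps(results, indent=1))


def _stage_decode(config: PipelineConfig, out: Path):
    pat_dir = out / "patterns"
    rows = []
    for path in sorted(pat_dir.glob("*.json")):
        pid, rule = path.stem.split("__", 1)
        pm = neuro.TrialPatternMatrix.load(path.with_suffix(""))
        retain = None
        if config.experiment == "shj":
            runs = sorted(np.unique(pm.runs))
            retain = runs[-2:]  # late-learning folds only
        for k in range(pm.n_dims):
            res = neuro.decode_feature(pm, k, C=config.svc_c, retain_runs=retain)
            for run, acc in res.fold_accuracies.items():
                rows.append(dict(participant=pid, rule=rule, dimension=k,
                                 run=run, accuracy=acc))
    pd.DataFrame(rows).to_csv(out / "decoding.tsv", sep="\t", index=False)


def _stage_link(config: PipelineConfig, out: Path):
    att = pd.read_csv(out / "fitted_attention.tsv", sep="\t")
    dec = pd.read_csv(out / "decoding.tsv", sep="\t")
    merged = dec.merge(att, on=["participant", "rule", "dimension"], how="left")
    if merged["weight"].isna().any():
        raise ValueError("decoding rows without fitted attention weights")
    if config.experiment == "5_4":
        table = (merged.groupby(["participant", "rule", "dimension", "weight"],
                                as_index=False)["accuracy"].mean())
        table["run"] = None
    else:
        table = merged
    res = linking.attention_shuffle_test(
        table, config.experiment, n_perm=config.n_perm,
        seed=config.seed, engine=config.perm_engine,
    )
    if config.n_boot > 0:
        boot = linking.fit_link_model(table, config.experiment,
                                      n_boot=config.n_boot, seed=config.seed)
        res.ci = boot.ci

    mappings = json.loads((out / "mappings.json").read_text())
    wide = att.groupby(["participant", "dimension"], as_index=False)["weight"].mean()
    rows = []
    for pid, grp in wide.groupby("participant"):
        m = mappings[pid]
        w = grp.set_index("dimension")["weight"]
        for j, feat in enumerate(m["feature_names"]):
            rows.append(dict(participant=pid, feature=feat,
                             weight=float(w[m["permutation"][j]])))
    F, dfs, p_anova, bf_null = linking.salience_anova(pd.DataFrame(rows))

    report = {
        "link": res.to_dict(),
        "salience_anova": {"F": F, "df": list(dfs), "p": p_anova, "bf_null": bf_null},
    }
    (out / "link_result.json").write_text(json.dumps(report, indent=1))
    summary = res.summary() + (
        f"\nsalience rm-ANOVA: F({dfs[0]:.0f}, {dfs[1]:.0f}) = {F:.3f}, "
        f"p = {p_anova:.3f}, BF_null = {bf_null:.2f}"
    )
    (out / "summary.txt").write_text(summary + "\n")
    return report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "decode": _stage_decode,
    "link": _stage_link,
}


def run_pipeline(config: PipelineConfig, stage: str = "all", out=None):
    """Run one stage or the whole pipeline; returns the final report (link stage).

    Raises with a stage-tagged message on failure.
    """
    out = Path(out if out is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = STAGES if stage == "all" else (stage,)
    if any(s not in STAGES for s in stages):
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES + ('all',)}")
    report = None
    for s in stages:
        _write_provenance(out, config, s)
        try:
            report = _STAGE_FUNCS[s](config, out)
        except Exception as exc:
            raise RuntimeError(f"[stage {s}] {exc}") from exc
    return report
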