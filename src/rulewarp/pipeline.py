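"""End-to-end orchestration: simulate -> fit HMM -> belief profile ->
single-neuron metrics -> pseudopopulations -> RSA -> subspace -> report.

A :class:`RunConfig` (YAML- or dict-loadable, unknown keys rejected) drives
one reproducible run; every source of randomness derives from the single
root seed via named per-stage substreams, so identical configs produce
byte-identical outputs. Each stage writes its tables into the run directory
and can be re-run from the cached outputs of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import belief, hmm, metrics, pseudopop, rsa, subspace, synth, task
from .spikes import SpikeCountTable

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "fit_hmm", "belief", "metrics", "pseudopop",
               "rsa", "subspace", "report")
STAGE_DEPS = {
    "fit_hmm": ("simulate",),
    "belief": ("simulate", "fit_hmm"),
    "metrics": ("simulate", "fit_hmm"),
    "pseudopop": ("simulate", "fit_hmm"),
    "rsa": ("pseudopop",),
    "subspace": ("pseudopop",),
    "report": (),
}


class ConfigError(ValueError):
    pass


class StageDependencyError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Schema-validated configuration for one pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    # simulation
    n_blocks: int = 20
    criterion: int = 15
    agent: dict = field(default_factory=dict)
    tuning: dict = field(default_factory=dict)
    # HMM
    hmm_restarts: int = 100
    hmm_max_iter: int = 500
    hmm_tol: float = 1e-6
    # metrics
    n_perm: int = 1000
    mi_bins: int = 2
    mi_shuffles: int = 100
    # pseudopopulations / subspace
    n_per_condition: int = 20
    cv_folds: int = 20
    lambda_grid: list | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for s in STAGE_ORDER:
            self.stages.setdefault(s, True)
        synth.AgentSpec(**self.agent)      # validate eagerly
        synth.TuningSpec(**self.tuning)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        allowed = {f.name for f in fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _check_dependencies(cfg: RunConfig, out: Path) -> None:
    cached = {
        "simulate": (out / "trials.tsv").exists(),
        "fit_hmm": (out / "states.tsv").exists(),
        "pseudopop": (out / "pseudo_rule_vs_residual_meta.json").exists(),
    }
    for stage in STAGE_ORDER:
        if not cfg.stages.get(stage):
            continue
        for dep in STAGE_DEPS.get(stage, ()):
            if not cfg.stages.get(dep) and not cached.get(dep, False):
                raise StageDependencyError(
                    f"stage {stage!r} requires {dep!r}, which is disabled and "
                    f"has no cached output in {out}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in dependency order; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _check_dependencies(config, out)
    t0 = time.time()
    chash = config.config_hash()
    with open(out / "config.json", "w") as fh:
        json.dump({"config": config.resolved(), "hash": chash}, fh, indent=1)

    streams = {s: np.random.default_rng(ss) for s, ss in
               zip(STAGE_ORDER, np.random.SeedSequence(config.seed).spawn(len(STAGE_ORDER)))}
    log: dict = {"config_hash": chash, "stages": {}}
    report: dict = {"config_hash": chash}

    trials = spikes = states_df = None
    hmm_fit = None
    truth = None

    def stage_done(name):
        log["stages"][name] = round(time.time() - t0, 2)
        logger.info("stage %s done (%.1fs)", name, time.time() - t0)

    if config.stages["simulate"]:
        agent = synth.AgentSpec(**config.agent)
        schedule = task.BlockSchedule(criterion=config.criterion)
        trials, truth = synth.simulate_behavior(
            agent, schedule, n_blocks=config.n_blocks, seed=streams["simulate"])
        spikes, _ = synth.simulate_neurons(
            trials, truth, synth.TuningSpec(**config.tuning), seed=streams["simulate"])
        task.write_trials(trials, out / "trials.tsv")
        spikes.write(out / "spikes.tsv")
        if spikes.epoch_counts is not None:
            t_n, n_n, _ = spikes.epoch_counts.shape
            edf = pd.DataFrame({
                "neuron_id": np.repeat(spikes.neuron_ids, t_n * 3),
                "trial_index": np.tile(np.repeat(spikes.trial_index, 3), n_n),
                "epoch": np.tile([1, 2, 3], t_n * n_n),
                "spike_count": spikes.epoch_counts.transpose(1, 0, 2).ravel(),
            })
            edf.to_csv(out / "spikes_epochs.tsv", sep="\t", index=False)
        pd.DataFrame({"trial_index": trials["trial_index"],
                      "true_state": truth.states}).to_csv(
            out / "true_states.tsv", sep="\t", index=False)
        report["n_trials"] = len(trials)
        report["reward_rate"] = float(trials["reward"].mean())
        stage_done("simulate")

    def need_trials():
        nonlocal trials
        if trials is None:
            trials = task.read_trials(out / "trials.tsv")
        return trials

    def need_spikes():
        nonlocal spikes
        if spikes is None:
            spikes = SpikeCountTable.read(out / "spikes.tsv")
            epath = out / "spikes_epochs.tsv"
            if epath.exists():
                edf = pd.read_csv(epath, sep="\t")
                cube = (edf.pivot_table(index=["trial_index", "epoch"],
                                        columns="neuron_id", values="spike_count")
                        [list(spikes.neuron_ids)].to_numpy())
                spikes.epoch_counts = cube.reshape(spikes.n_trials, 3,
                                                   spikes.n_neurons).transpose(0, 2, 1)
        return spikes

    def need_states():
        nonlocal states_df
        if states_df is None:
            states_df = pd.read_csv(out / "states.tsv", sep="\t")
        return states_df["hmm_state"].to_numpy()

    if config.stages["fit_hmm"]:
        tr = need_trials()
        fitted, inf = hmm.fit_baum_welch(
            tr, n_restarts=config.hmm_restarts, max_iter=config.hmm_max_iter,
            tol=config.hmm_tol, seed=streams["fit_hmm"])
        hmm_fit = fitted
        states_df = pd.DataFrame({
            "trial_index": tr["trial_index"],
            "hmm_state": inf.viterbi_path,
            "state_posterior": inf.posteriors.max(axis=1),
        })
        states_df.to_csv(out / "states.tsv", sep="\t", index=False)
        with open(out / "hmm.json", "w") as fh:
            json.dump({"a_rr": fitted.a_rr, "a_oo": fitted.a_oo,
                       "log_likelihood": inf.log_likelihood,
                       "converged": bool(inf.converged),
                       "restart_index": int(inf.restart_index)}, fh, indent=1)
        report["hmm"] = {"a_rr": fitted.a_rr, "a_oo": fitted.a_oo,
                         "p_rule_trials": float(np.mean(inf.viterbi_path != "residual"))}
        stage_done("fit_hmm")

    if config.stages["belief"]:
        tr = need_trials()
        profile = belief.choice_class_profile(tr, need_states())
        profile.to_csv(out / "infogain.tsv", sep="\t", index=False)
        stage_done("belief")

    if config.stages["metrics"]:
        tr, sp, st = need_trials(), need_spikes(), need_states()
        mdir = out / "metrics"
        mdir.mkdir(exist_ok=True)
        per_neuron, summary = metrics.tuning_anova_suite(sp, tr, st)
        per_neuron.to_csv(mdir / "anova.tsv", sep="\t", index=False)
        summary.to_csv(mdir / "anova_summary.tsv", sep="\t", index=False)
        mi = metrics.mutual_information_table(
            sp, tr, st, n_bins=config.mi_bins,
            seed=int(streams["metrics"].integers(2**31)),
            n_shuffle=config.mi_shuffles)
        mi.to_csv(mdir / "mi.tsv", sep="\t", index=False)
        ic = metrics.identity_category_table(sp, tr, st)
        ic.to_csv(mdir / "icindex.tsv", sep="\t", index=False)
        if sp.epoch_counts is not None:
            glm = metrics.relevance_tuning_glm(sp, tr, st, target="choice")
            glm.contrasts.to_csv(mdir / "tuningglm_contrasts.tsv", sep="\t", index=False)
            pd.DataFrame({"param": glm.params.index, "estimate": glm.params.values,
                          "se": glm.bse.values, "p": glm.pvalues.values}).to_csv(
                mdir / "tuningglm.tsv", sep="\t", index=False)
        rsum = {}
        is_rule = st != "residual"
        centered = metrics.zscore_within_neuron(sp.counts, mode="center_only")
        for region in np.unique(sp.regions):
            m = sp.regions == region
            diff, p = metrics.rate_contrast_permutation(
                centered[:, m].mean(axis=1), is_rule, n_perm=config.n_perm,
                seed=int(streams["metrics"].integers(2**31)), exact=False)
            rsum[str(region)] = {
                "rate_diff_rule_minus_residual": diff, "rate_diff_p": p,
                "mi_rule_median": float(np.nanmedian(mi[mi["region"] == region]["mi_rule"])),
                "mi_residual_median": float(np.nanmedian(mi[mi["region"] == region]["mi_residual"])),
            }
        with open(mdir / "summary.json", "w") as fh:
            json.dump(rsum, fh, indent=1)
        report["metrics"] = rsum
        stage_done("metrics")

    pseudos: dict = {}
    if config.stages["pseudopop"]:
        tr, sp, st = need_trials(), need_spikes(), need_states()
        for scheme in pseudopop.SCHEMES:
            mat = pseudopop.build_pseudotrials(
                sp, tr, st, scheme, n_per_condition=config.n_per_condition,
                seed=streams["pseudopop"])
            pseudos[scheme] = mat
            pseudopop.write_pseudotrials(mat, out / f"pseudo_{scheme}")
        gini = metrics.gini_by_pseudotrial(pseudos["rule_vs_residual"].rates)
        ctx = pseudos["rule_vs_residual"].rows["context"].to_numpy()
        report["gini"] = {
            "rule_mean": float(np.nanmean(gini[ctx == "rule"])),
            "residual_mean": float(np.nanmean(gini[ctx == "residual"])),
        }
        stage_done("pseudopop")

    def need_pseudo(scheme):
        if scheme not in pseudos:
            pseudos[scheme] = pseudopop.read_pseudotrials(out / f"pseudo_{scheme}")
        return pseudos[scheme]

    if config.stages["rsa"]:
        rdir = out / "rsa"
        rdir.mkdir(exist_ok=True)
        for scheme in ("rule_vs_residual", "color_vs_shape_rule"):
            mat = need_pseudo(scheme)
            cents, labels = rsa.condition_centroids(mat)
            rmat = rsa.distance_matrix(cents, labels, scheme=scheme)
            rmat.pair_table().to_csv(rdir / f"distances_{scheme}.tsv",
                                     sep="\t", index=False)
            rsa.rsa_contrasts(rmat).to_csv(rdir / f"contrasts_{scheme}.tsv",
                                           sep="\t", index=False)
            rsa.rsa_anova(rmat).to_csv(rdir / f"anova_{scheme}.tsv",
                                       sep="\t", index=False)
        stage_done("rsa")

    if config.stages["subspace"]:
        sdir = out / "subspace"
        sdir.mkdir(exist_ok=True)
        mat = need_pseudo("per_rule")
        lam = None if config.lambda_grid is None else np.asarray(config.lambda_grid)
        dims = subspace.fit_choice_classifiers(
            mat, cv_folds=config.cv_folds, lambdas=lam,
            seed=int(streams["subspace"].integers(2**31)))
        rdims = subspace.fit_rule_classifiers(
            mat, cv_folds=config.cv_folds, lambdas=lam,
            seed=int(streams["subspace"].integers(2**31)))
        coefs = pd.DataFrame(dims.coefs.T, columns=list(dims.features))
        coefs.insert(0, "neuron_id", dims.neuron_ids)
        coefs.to_csv(sdir / "coefficients.tsv", sep="\t", index=False)
        table = subspace.project(mat, dims)
        table.to_csv(sdir / "projections.tsv", sep="\t", index=False)
        anova, contrasts = subspace.projection_anova(table)
        anova.to_csv(sdir / "anova.tsv", sep="\t", index=False)
        contrasts.to_csv(sdir / "contrasts.tsv", sep="\t", index=False)
        angles = pd.DataFrame([
            {"feature": f,
             "angle_rule_vs_choice": subspace.dimension_angle(dims.coef(f),
                                                              rdims.coef(f))}
            for f in dims.features])
        angles.to_csv(sdir / "angles.tsv", sep="\t", index=False)
        report["subspace"] = {
            "mean_rule_choice_angle_deg": float(angles["angle_rule_vs_choice"].mean()),
            "cv_accuracy": [float(a) for a in dims.cv_accuracy],
            "lambda": dims.lambda_ if np.isscalar(dims.lambda_) else list(dims.lambda_),
            "projection_means": {
                lev: float(table[table["chosen"]
                                 & (table["relevance"] == lev)]["projection"].mean())
                for lev in ("relevant", "irrelevant", "residual")},
        }
        stage_done("subspace")

    if config.stages["report"]:
        report["log"] = log
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
        stage_done("report")
    return out
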