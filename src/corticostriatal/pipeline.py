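"""End-to-end pipeline: configuration, seeding, staging and file I/O.

A single hierarchical configuration (YAML or JSON) drives the full chain

    simulate-behavior -> fit-qlearning -> build-dataset -> train ->
    run-autonomous -> analyze-latent -> analyze-potential -> compare-cca

writing each stage's artifacts into an output directory.  Stages are
resumable: a stage whose outputs already exist is skipped unless forced.
One global seed is expanded into independent per-stage child seeds so any
stage can be reproduced in isolation.  A manifest records the config, the
seeds and the package version.
"""

from __future__ import annotations

import json
import hashlib
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (autonomous, behavior_synth, dynamics_analysis, latent_analysis,
               model_comparison, rnn_model, signal_coding, task_env, trainer,
               value_model)

log = logging.getLogger("corticostriatal")

STAGES = ("simulate-behavior", "fit-qlearning", "build-dataset", "train",
          "run-autonomous", "analyze-latent", "analyze-potential", "compare-cca")

#: demo-scale defaults: every value with a published counterpart uses it;
#: sizes and iteration counts are the reduced desk-scale ones.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "behavior": {"n_blocks": 120, "augment_blocks": 80},
    "qlearning": {"alpha": value_model.FITTED_ALPHA,
                  "gamma": value_model.FITTED_GAMMA,
                  "beta": value_model.FITTED_BETA,
                  "tau_q": value_model.FITTED_TAU_Q,
                  "refit": False, "n_restarts": 3, "fit_blocks": 40},
    "coding": {"action_pulse_len": 10, "dt": 1.0},
    "network": {"n_s": rnn_model.N_STRIATAL_SCALED,
                "n_p": rnn_model.N_PREFRONTAL_SCALED,
                "g": 1.0, "tau": 10.0, "noise_sd": 0.01},
    "training": {"lr0": 0.001, "n_outer": 4, "iters_per_outer": 250,
                 "lr_decay": 2.0 / 3.0, "batch_k": 10, "striatal_weight": 2.0,
                 "optimizer": "adam"},
    "dataset": {"test_blocks": 25},
    "autonomous": {"n_blocks": 64, "balanced": True, "max_repeats": 1000},
    # distance_space "unit": distances in full unit space (appropriate for
    # small simulated populations); "dpc": in the d_sub-dim sequence subspace
    "analysis": {"n_components": 6, "grid": 30, "d_sub": 10,
                 "distance_space": "unit", "smoothing_sigma": 2.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(
            base.get(k), dict) else v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Reject invalid settings before any compute."""
    if cfg["training"]["lr0"] <= 0:
        raise ValueError("training.lr0 must be positive")
    if cfg["behavior"]["n_blocks"] <= cfg["dataset"]["test_blocks"]:
        raise ValueError("behavior.n_blocks must exceed dataset.test_blocks")
    if cfg["network"]["n_s"] < 2 or cfg["network"]["n_p"] < 2:
        raise ValueError("network sizes must be >= 2")
    value_model.QParams(**{k: cfg["qlearning"][k]
                           for k in ("alpha", "gamma", "beta", "tau_q")}).validate()


def stage_seeds(seed: int) -> dict[str, int]:
    """Expand the global seed into one independent child seed per stage."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {stage: int(c.generate_state(1)[0] % (2 ** 31))
            for stage, c in zip(STAGES, children)}


def _coding_config(cfg: dict) -> signal_coding.CodingConfig:
    return signal_coding.CodingConfig.scaled(
        action_pulse_len=cfg["coding"]["action_pulse_len"],
        dt=cfg["coding"]["dt"])


def run_pipeline(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "artifacts",
    force: bool = False,
    stages: list[str] | None = None,
) -> Path:
    """Execute the pipeline stages in order; returns the artifacts directory.

    ``config`` may be a path to a YAML/JSON file or an override dict.
    Existing stage outputs are reused unless ``force``.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = load_config(None, overrides=config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg["seed"])
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    manifest = {"config": cfg, "config_hash": digest, "seeds": seeds}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    run = stages or list(STAGES)
    ccfg = _coding_config(cfg)

    def need(*paths) -> bool:
        return force or not all((out / p).exists() for p in paths)

    def upstream(path, stage):
        if not (out / path).exists():
            raise FileNotFoundError(
                f"missing artifact {path}: rerun stage '{stage}'")
        return out / path

    if "simulate-behavior" in run and need("behavior_log.csv"):
        log.info("stage simulate-behavior")
        qp = value_model.QParams(**{k: cfg["qlearning"][k]
                                    for k in ("alpha", "gamma", "beta", "tau_q")})
        rng = np.random.default_rng(seeds["simulate-behavior"])
        blog = behavior_synth.simulate_session(cfg["behavior"]["n_blocks"], qp, rng)
        task_env.write_log(blog, out / "behavior_log.csv")
        aug = behavior_synth.simulate_session(
            cfg["behavior"]["augment_blocks"], qp, rng)
        aug["block_id"] += 10_000  # keep augmentation block ids disjoint
        task_env.write_log(aug, out / "augment_log.csv")
        prof, curve = behavior_synth.error_profile(blog)
        prof.to_json(out / "error_profile.json")
        curve.to_csv(out / "behavior_curve.csv", index=False)

    if "fit-qlearning" in run and need("qparams.json"):
        log.info("stage fit-qlearning")
        blog = task_env.read_log(upstream("behavior_log.csv", "simulate-behavior"))
        qp = value_model.QParams(**{k: cfg["qlearning"][k]
                                    for k in ("alpha", "gamma", "beta", "tau_q")})
        nll = None
        if cfg["qlearning"]["refit"]:
            sub = blog[blog["block_id"] < cfg["qlearning"]["fit_blocks"]]
            qp, nll, _ = value_model.fit_params(
                sub, init=qp, n_restarts=cfg["qlearning"]["n_restarts"],
                seed=seeds["fit-qlearning"])
        qp.to_json(out / "qparams.json", nll=nll)

    if "build-dataset" in run and need("train_set.h5", "test_set.h5"):
        log.info("stage build-dataset")
        blog = task_env.read_log(upstream("behavior_log.csv", "simulate-behavior"))
        qp = value_model.QParams.from_json(upstream("qparams.json", "fit-qlearning"))
        traces = value_model.generate_value_traces(blog, qp)
        aug = task_env.read_log(upstream("augment_log.csv", "simulate-behavior"))
        aug_traces = value_model.generate_value_traces(aug, qp)
        train, test = signal_coding.build_dataset(
            blog, traces, ccfg, test_blocks=cfg["dataset"]["test_blocks"],
            augment=(aug, aug_traces), rng=seeds["build-dataset"])
        value_model.save_traces(out / "value_traces.h5", traces,
                                alpha=qp.alpha, gamma=qp.gamma,
                                beta=qp.beta, tau_q=qp.tau_q)
        signal_coding.save_dataset(out / "train_set.h5", train)
        signal_coding.save_dataset(out / "test_set.h5", test)

    if "train" in run and need("trained_params.h5"):
        log.info("stage train")
        train_set = signal_coding.load_dataset(upstream("train_set.h5",
                                                        "build-dataset"))
        net = cfg["network"]
        params0 = rnn_model.init_params(
            n_s=net["n_s"], n_p=net["n_p"], g=net["g"], rng=seeds["train"],
            tau=net["tau"], noise_sd=net["noise_sd"])
        params0.save(out / "untrained_params.h5", seed=seeds["train"])
        tcfg = trainer.TrainConfig(seed=seeds["train"], dt=ccfg.dt,
                                   **cfg["training"])
        params, history = trainer.train(params0, train_set, tcfg)
        params.save(out / "trained_params.h5", seed=seeds["train"])
        history.to_csv(out / "training_log.csv", index=False)
        test_set = signal_coding.load_dataset(upstream("test_set.h5",
                                                       "build-dataset"))
        trainer.evaluate_mse_by_trial(params, test_set, dt=ccfg.dt).to_csv(
            out / "test_mse_by_trial.csv", index=False)

    results = None
    if "run-autonomous" in run and need("autonomous_log.csv"):
        log.info("stage run-autonomous")
        params = rnn_model.NetworkParams.load(upstream("trained_params.h5",
                                                       "train"))
        forced = (list(range(1, task_env.N_SEQUENCES + 1))
                  if cfg["autonomous"]["balanced"] else None)
        results = autonomous.run_session(
            params, ccfg, cfg["autonomous"]["n_blocks"],
            rng=seeds["run-autonomous"], forced_sequences=forced,
            record_states=True, dt=ccfg.dt,
            max_repeats=cfg["autonomous"]["max_repeats"])
        alog = autonomous.session_log(results)
        task_env.write_log(alog, out / "autonomous_log.csv")
        autonomous.behavioral_curve(results).to_csv(
            out / "autonomous_curve.csv", index=False)

    if {"analyze-latent", "analyze-potential", "compare-cca"} & set(run):
        if results is None:
            params = rnn_model.NetworkParams.load(upstream("trained_params.h5",
                                                           "train"))
            forced = (list(range(1, task_env.N_SEQUENCES + 1))
                      if cfg["autonomous"]["balanced"] else None)
            results = autonomous.run_session(
                params, ccfg, cfg["autonomous"]["n_blocks"],
                rng=seeds["run-autonomous"], forced_sequences=forced,
                record_states=True, dt=ccfg.dt)
        # certainty levels calibrated on the training behavior's curve
        curve = pd.read_csv(upstream("behavior_curve.csv", "simulate-behavior"))
        level_of_trial = behavior_synth.level_map_from_curve(curve)

    if "analyze-latent" in run and need("distance_curves.csv"):
        log.info("stage analyze-latent")
        an = cfg["analysis"]
        frames = []
        for region in ("prefrontal", "striatal"):
            pt = latent_analysis.population_tensor(
                results, region=region, level_of_trial=level_of_trial,
                n_per_cell="min", rng=seeds["analyze-latent"])
            model = latent_analysis.fit_dpca(pt, n_components=an["n_components"])
            sub = None if an["distance_space"] == "unit" else model
            clusters = (latent_analysis.hemifield_clusters(pt)
                        if region == "prefrontal" else None)
            d = latent_analysis.inter_sequence_distance(
                pt, clusters=clusters, subspace=sub, d_sub=an["d_sub"])
            d["region"], d["metric"] = region, "inter_sequence"
            c = latent_analysis.centroid_compactness(pt, subspace=sub,
                                                     d_sub=an["d_sub"])
            c = c.rename(columns={"sequence": "seq_a", "compactness": "distance"})
            c["seq_b"], c["region"], c["metric"] = -1, region, "centroid"
            frames.extend([d, c])
            if region == "prefrontal":
                sep = latent_analysis.hemifield_separation_test(
                    pt, subspace=sub, d_sub=an["d_sub"])
                sep.to_csv(out / "hemifield_separation.csv", index=False)
        pd.concat(frames, ignore_index=True).to_csv(
            out / "distance_curves.csv", index=False)

    if "analyze-potential" in run and need("path_lengths.csv"):
        log.info("stage analyze-potential")
        an = cfg["analysis"]
        params = rnn_model.NetworkParams.load(upstream("trained_params.h5",
                                                       "train"))
        frames = []
        for region in ("prefrontal", "striatal"):
            pt = latent_analysis.population_tensor(
                results, region=region, level_of_trial=level_of_trial,
                n_per_cell="min", rng=seeds["analyze-potential"])
            model = latent_analysis.fit_dpca(pt, n_components=an["n_components"])
            frozen = dynamics_analysis.frozen_inputs_from_results(
                results, region=region, level_of_trial=level_of_trial)
            pl = dynamics_analysis.path_length_by_certainty(
                params, region, pt, model, frozen, grid=an["grid"], dt=ccfg.dt)
            pl["region"] = region
            frames.append(pl)
        pd.concat(frames, ignore_index=True).to_csv(
            out / "path_lengths.csv", index=False)

    if "compare-cca" in run and need("cca_coefficients.csv"):
        log.info("stage compare-cca")
        trained = rnn_model.NetworkParams.load(upstream("trained_params.h5",
                                                        "train"))
        untrained = rnn_model.NetworkParams.load(upstream("untrained_params.h5",
                                                          "train"))
        test_set = signal_coding.load_dataset(upstream("test_set.h5",
                                                       "build-dataset"))
        seq_counts = pd.Series([b.sequence_id for b in test_set]).value_counts()
        seq = int(seq_counts.index[0])
        # surrogate reference population: trained-model activity plus noise
        rng = np.random.default_rng(seeds["compare-cca"])
        ref = model_comparison.trial_averaged_activity(
            trained, test_set, region="prefrontal", sequence_id=seq, dt=ccfg.dt)
        ref = ref + rng.standard_normal(ref.shape) * (0.1 * ref.std())
        table = model_comparison.trained_vs_untrained(
            trained, untrained, ref, test_set, region="prefrontal",
            sequence_id=seq, dt=ccfg.dt)
        table.to_csv(out / "cca_coefficients.csv", index=False)
        summary = {"mean_trained": table.attrs["mean_trained"],
                   "mean_untrained": table.attrs["mean_untrained"],
                   "reference": "synthetic surrogate (trained model + noise)",
                   "sequence_id": seq}
        (out / "cca_summary.json").write_text(json.dumps(summary, indent=2))

    return out


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
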