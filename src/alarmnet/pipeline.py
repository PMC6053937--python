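"""End-to-end pipeline: generate/load -> indices -> acoustics -> responses ->
models -> network, with CSV/YAML artefacts and a reproducibility manifest.

A run is configured by a PipelineConfig (YAML-loadable).  Exactly one of
the two input modes is active: a synthetic block (seed + sizes + optional
overrides) or paths to real input tables.  Every stage writes its outputs
under the run directory and records row counts in the manifest; a fixed
(config, seed) pair reproduces every CSV byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, acoustics, community, models, network
from .indices import (derive_indices, estimate_alarm_propensity,
                      estimate_call_profile, jacobs_transform, write_long)
from .responses import code_trials, pretrial_relaxation_filter

STAGES = ["generate", "indices", "acoustics", "responses", "models", "network"]

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Options for one pipeline run (see module docstring)."""

    output_dir: str
    seed: int = 0
    synthetic: dict | None = field(default_factory=dict)   # sizes, overrides...
    input_paths: dict | None = None                        # real-data mode
    normalized_consistency: bool = True
    similarity_scale: bool = True
    network_threshold: float = network.DEFAULT_THRESHOLD
    include_conspecific: bool = False
    n_per_combination: int | None = None
    n_per_pair: int | None = None

    def __post_init__(self):
        if (self.input_paths is None) == (self.synthetic is None):
            raise ValueError("PipelineConfig: exactly one of synthetic / "
                             "input_paths must be given")
        if not 0 <= self.network_threshold <= 1:
            raise ValueError("PipelineConfig: network_threshold outside [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        doc = {k: v for k, v in vars(self).items()}
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "alarmnet_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": config.digest(),
        "stages": {},
    }
    stage = "generate"
    try:
        # -- generate / load ------------------------------------------------
        if config.synthetic is not None:
            syn = dict(config.synthetic)
            overrides = syn.pop("overrides", None)
            cfg = community.generate_community(
                seed=config.seed, overrides=overrides, **syn)
            trials = community.simulate_predator_trials(
                cfg, config.n_per_combination, seed=config.seed + 1)
            call_table = community.simulate_call_table(cfg, seed=config.seed + 2)
            cfg.to_yaml(out / "community.yaml")
        else:
            cfg = None
            trials = pd.read_csv(config.input_paths["predator_trials"])
            call_table = _read_named(config.input_paths, "acoustic_features", stage)
        trials.to_csv(out / "predator_trials.csv", index=False)
        call_table.to_csv(out / "acoustic_features.csv", index=False)
        manifest["stages"][stage] = {"predator_trials": len(trials),
                                     "calls": len(call_table)}

        # -- indices --------------------------------------------------------
        stage = "indices"
        if cfg is not None:
            epsilon = cfg.epsilon
            pred_ab = cfg.predator_abundances
            masses = cfg.body_masses
            herb_ab = cfg.herbivore_abundances
        else:
            jacobs = pd.read_csv(config.input_paths["jacobs"], index_col=0)
            epsilon = jacobs_transform(jacobs)
            species_tab = pd.read_csv(config.input_paths["species"], index_col=0)
            masses = species_tab["body_mass_kg"]
            herb_ab = species_tab["abundance"]
            pred_ab = pd.read_csv(config.input_paths["predators"],
                                  index_col=0)["abundance"]
        I, n_cells = estimate_alarm_propensity(trials)
        C = estimate_call_profile(I)
        I.to_csv(out / "alarm_propensity.csv")
        C.to_csv(out / "call_profile.csv")
        manifest["stages"][stage] = {"propensity_cells": int(n_cells.to_numpy().sum())}

        # -- acoustics ------------------------------------------------------
        stage = "acoustics"
        S = acoustics.acoustic_similarity(call_table, scale=config.similarity_scale)
        S.to_csv(out / "acoustic_similarity.csv")
        manifest["stages"][stage] = {"vocal_species": len(S)}

        idx = derive_indices(I.fillna(0.0) if cfg is None else cfg.alarm_propensity,
                             epsilon, pred_ab, masses, herb_ab, similarity=S,
                             normalized=config.normalized_consistency)
        write_long(idx.L, out / "consistency.csv", "consistency")
        write_long(idx.V, out / "reliability.csv", "reliability")
        write_long(idx.size_ratio, out / "size_ratio.csv", "size_ratio")

        # -- responses ------------------------------------------------------
        stage = "responses"
        if cfg is not None:
            playbacks = community.simulate_playbacks(
                cfg, idx, config.n_per_pair, seed=config.seed + 3)
            logs = [community.event_log_for_trial(row)
                    for _, row in playbacks.iterrows()]
        else:
            raise NotImplementedError(
                "responses stage: real-data event-log ingestion requires an "
                "event table; use responses.logs_from_frame directly")
        relaxed = [pretrial_relaxation_filter(log) for log in logs]
        coded = code_trials([log for log, ok in zip(logs, relaxed) if ok])
        coded.to_csv(out / "coded_responses.csv", index=False)
        playbacks.to_csv(out / "playback_trials.csv", index=False)
        manifest["stages"][stage] = {"playbacks": len(playbacks),
                                     "coded": len(coded)}

        # -- models ---------------------------------------------------------
        stage = "models"
        prelim, filtered = models.preliminary_calltype_model(playbacks)
        fits = models.fit_response_models(
            filtered, idx, masses, include_conspecific=config.include_conspecific)
        m1 = models.fit_alarm_model_M1(trials, epsilon)
        coef_rows = []
        for name, fit in {"M1": m1, "prelim": prelim, **{
                f"M2.{i+1}": f for i, f in enumerate(fits.values())}}.items():
            tab = fit.coefficients.reset_index(names="term")
            tab.insert(0, "model", name)
            tab.insert(1, "response", fit.spec.response)
            coef_rows.append(tab)
        pd.concat(coef_rows).to_csv(out / "model_coefficients.csv", index=False)
        manifest["stages"][stage] = {
            "models_fitted": 2 + len(fits),
            "converged": int(m1.converged) + int(prelim.converged)
            + sum(f.converged for f in fits.values()),
        }

        # -- network --------------------------------------------------------
        stage = "network"
        P = network.response_probability_matrix(playbacks)
        P.to_csv(out / "response_probabilities.csv")
        G = network.build_network(P, config.network_threshold,
                                  include_conspecific=config.include_conspecific)
        network.write_graphml(G, out / "communication_network.graphml")
        network.write_edge_list(G, out / "communication_edges.csv")
        manifest["stages"][stage] = {"nodes": G.number_of_nodes(),
                                     "edges": G.number_of_edges()}
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _read_named(paths: dict, key: str, stage: str) -> pd.DataFrame:
    if key not in paths:
        raise FileNotFoundError(f"{stage} stage: input table {key!r} not configured")
    p = Path(paths[key])
    if not p.exists():
        raise FileNotFoundError(f"{stage} stage: missing input file {p}")
    return pd.read_csv(p)


def validate_inputs(tables: dict) -> pd.DataFrame:
    """Schema / invariant checks over input tables; returns a violation report.

    ``tables`` maps table names to DataFrames; recognised names are
    ``jacobs`` (values in [-1, 1]), ``species`` (positive masses, nonnegative
    abundances), ``predators`` (nonnegative abundances), ``propensity``
    (values in [0, 1]), ``call_profile`` (columns sum to 1) and
    ``acoustic_features`` (nonnegative, 7 features).  Data is never mutated;
    the report has one row per violation (empty means clean).
    """
    rows = []

    def flag(table, row, message):
        rows.append({"table": table, "row": str(row), "violation": message})

    if "jacobs" in tables:
        J = tables["jacobs"]
        for sp, r in J.iterrows():
            bad = r[(r < -1) | (r > 1)]
            for col in bad.index:
                flag("jacobs", sp, f"Jacobs index outside [-1, 1] for {col}")
    if "species" in tables:
        t = tables["species"]
        if "body_mass_kg" in t:
            for sp in t.index[t["body_mass_kg"] <= 0]:
                flag("species", sp, "non-positive body mass")
        if "abundance" in t:
            for sp in t.index[t["abundance"] < 0]:
                flag("species", sp, "negative abundance")
    if "predators" in tables:
        t = tables["predators"]
        if "abundance" in t:
            for p in t.index[t["abundance"] < 0]:
                flag("predators", p, "negative abundance")
            if not t["abundance"].sum() > 0:
                flag("predators", "(all)", "abundances sum to zero")
    if "propensity" in tables:
        I = tables["propensity"]
        for p, r in I.iterrows():
            bad = r[(r < 0) | (r > 1)]
            for col in bad.index:
                flag("propensity", p, f"propensity outside [0, 1] for {col}")
    if "call_profile" in tables:
        C = tables["call_profile"]
        sums = C.sum(axis=0, skipna=False)
        for caller, s in sums.items():
            if pd.notna(s) and abs(s - 1.0) > 1e-6:
                flag("call_profile", caller, f"column sums to {s:.6f}, not 1")
    if "acoustic_features" in tables:
        t = tables["acoustic_features"]
        missing = [f for f in acoustics.FEATURES if f not in t.columns]
        if missing:
            flag("acoustic_features", "(columns)", f"missing features {missing}")
        else:
            neg = t[acoustics.FEATURES] < 0
            for i in t.index[neg.any(axis=1)]:
                flag("acoustic_features", t.loc[i].get("species", i),
                     "negative feature value")
    return pd.DataFrame(rows, columns=["table", "row", "violation"])
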