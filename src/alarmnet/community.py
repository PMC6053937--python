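"""Synthetic savannah-herbivore communities and behavioural trial simulation.

Real multi-species alarm-call field data are not publicly deposited, so this
module generates communities and trial datasets with the statistical
structure the analysis assumes, making every downstream stage testable:

* a community of herbivore prey species (body masses, relative abundances,
  a vocal flag — typically one species, like the eland, never alarm-calls)
  and predator species (relative abundances, Jacobs preference indices);
* predator-model presentation trials: for each herbivore x (predator +
  control) combination a fixed number of Bernoulli alarm trials, the alarm
  probability given by the community's true propensity matrix I(x, j);
* playback trials: a balanced receiver x (vocal caller + control) design
  whose binary response follows a logistic model with a per-receiver random
  intercept, and whose continuous (latency, duration, head-lift speed;
  log-normal) and count (head-ups, scratches; negative-binomial) responses
  are generated conditional on a binary response occurring — latency is
  undefined when nothing happened;
* deterministic event-log rendering, so the response-coding stage can be
  checked for exact recovery of the generator's latent variables.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
(config, seed) pairs give identical trial tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import lognorm

from . import acoustics
from .design import DESIGN_TERMS, build_playback_design
from .indices import DerivedIndices, derive_indices, jacobs_transform
from .responses import EventLog

# Default true coefficients of the binary response process, on the logit
# scale with information covariates scaled to [0, 1].  Magnitudes for the
# terms with unambiguous published analogues (receiver size, size-ratio
# linear/quadratic, their interaction, caller consistency, acoustic
# similarity); zero where no defensible value exists.  "control" is the
# control-condition intercept, not an offset.
DEFAULT_TRUE_BETAS = {
    "intercept": -3.0,
    "control": -2.2,
    "conspecific": 0.96,
    "receiver_size": -0.45,
    "size_ratio": 6.48,
    "size_ratio_sq": -4.35,
    "rbs_x_ratio": 0.0,
    "rbs_x_ratio_sq": 0.44,
    "consistency": 1.74,
    "reliability": 0.0,
    "similarity": 0.37,
    "abundance": 0.0,
    "grass_height": 0.0,
    "cover_proximity": 0.0,
    "speaker_distance": 0.0,
    "wind_speed": 0.0,
    "group_size": 0.0,
}

# Conditional response processes (given a binary response): intercepts on the
# log scale, shared covariate coefficients default to zero, and a
# per-receiver random intercept (``re_sd``, log scale) — species differ in
# baseline response strength just as they do in response probability.
DEFAULT_PROCESSES = {
    "latency": {"intercept": np.log(2.0), "sigma": 0.5, "re_sd": 0.3, "betas": {}},
    "duration": {"intercept": np.log(25.0), "sigma": 0.6, "re_sd": 0.3, "betas": {}},
    "headlift_speed": {"intercept": np.log(30.0), "sigma": 0.3, "re_sd": 0.3, "betas": {}},
    "head_ups": {"intercept": np.log(2.0), "alpha": 0.5, "re_sd": 0.3, "betas": {}},
    "scratches": {"intercept": 0.0, "alpha": 0.5, "re_sd": 0.3, "betas": {}},
}

DEFAULT_COVARIATE_RANGES = {
    "distance_m": (20.0, 120.0),        # predator-model distance, uniform
    "grass_height_cm": (3.3, 0.4),      # lognormal (mu, sigma) of log cm
    "cover_proximity_m": 80.0,          # exponential scale
    "speaker_distance_m": (35.0, 5.0),  # normal (mean, sd), clipped at 15 m
    "wind_speed_ms": (0.0, 8.0),        # uniform
    "group_size_mean": 7.0,             # 1 + Poisson
    "young_present_p": 0.3,
}

__all__ = [
    "CommunityConfig",
    "generate_community",
    "simulate_predator_trials",
    "simulate_call_table",
    "simulate_playbacks",
    "event_log_for_trial",
    "true_indices",
    "DEFAULT_TRUE_BETAS",
]


@dataclass
class CommunityConfig:
    """Ground truth for one synthetic community (see module docstring)."""

    n_herbivores: int
    n_predators: int
    seed: int
    species: list
    predators: list
    body_masses: pd.Series
    herbivore_abundances: pd.Series
    predator_abundances: pd.Series
    jacobs_matrix: pd.DataFrame          # herbivores x predators, in [-1, 1]
    alarm_propensity: pd.DataFrame       # predators x callers, I(x, j)
    acoustic_features: pd.DataFrame      # vocal species x 7 features
    vocal_flags: pd.Series
    true_betas: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETAS))
    processes: dict = field(default_factory=lambda: {
        k: {**v, "betas": dict(v["betas"])} for k, v in DEFAULT_PROCESSES.items()})
    trial_counts: dict = field(default_factory=lambda: {"predator_sim": 9,
                                                        "playback": 17})
    control_rate: float = 0.05
    random_intercept_sd: float = 0.5
    censor_prob: float = 0.05
    covariate_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_RANGES))

    def validate(self) -> None:
        if self.n_herbivores < 2:
            raise ValueError("n_herbivores: need at least 2 species")
        if self.n_predators < 2:
            raise ValueError("n_predators: need at least 2 predators")
        if (self.body_masses <= 0).any():
            raise ValueError("body_masses: masses must be positive")
        if (self.herbivore_abundances < 0).any():
            raise ValueError("herbivore_abundances: must be nonnegative")
        if (self.predator_abundances < 0).any() or not self.predator_abundances.sum() > 0:
            raise ValueError("predator_abundances: must be nonnegative with positive sum")
        J = self.jacobs_matrix.to_numpy()
        if np.any(J < -1) or np.any(J > 1):
            raise ValueError("jacobs_matrix: entries must lie in [-1, 1]")
        I = self.alarm_propensity.to_numpy()
        if np.any(I < 0) or np.any(I > 1):
            raise ValueError("alarm_propensity: entries must lie in [0, 1]")
        if not self.vocal_flags.any():
            raise ValueError("vocal_flags: at least one herbivore must be vocal")
        nonvocal = self.vocal_flags.index[~self.vocal_flags]
        if len(nonvocal) and self.alarm_propensity[nonvocal].to_numpy().any():
            raise ValueError("alarm_propensity: non-vocal species must have I = 0")
        if set(self.acoustic_features.index) - set(self.vocal_flags.index[self.vocal_flags]):
            raise ValueError("acoustic_features: features given for a non-vocal species")
        if not 0 <= self.control_rate <= 1:
            raise ValueError("control_rate: must lie in [0, 1]")

    @property
    def vocal_species(self) -> list:
        return [s for s in self.species if self.vocal_flags[s]]

    @property
    def epsilon(self) -> pd.DataFrame:
        """Vulnerability matrix (receivers x predators) from the Jacobs table."""
        return jacobs_transform(self.jacobs_matrix)

    def to_yaml(self, path) -> None:
        doc = {
            "n_herbivores": self.n_herbivores,
            "n_predators": self.n_predators,
            "seed": self.seed,
            "species": list(self.species),
            "predators": list(self.predators),
            "body_masses": self.body_masses.to_dict(),
            "herbivore_abundances": self.herbivore_abundances.to_dict(),
            "predator_abundances": self.predator_abundances.to_dict(),
            "jacobs_matrix": {s: self.jacobs_matrix.loc[s].to_dict()
                              for s in self.species},
            "alarm_propensity": {p: self.alarm_propensity.loc[p].to_dict()
                                 for p in self.predators},
            "acoustic_features": {s: self.acoustic_features.loc[s].to_dict()
                                  for s in self.acoustic_features.index},
            "vocal_flags": {k: bool(v) for k, v in self.vocal_flags.items()},
            "true_betas": {k: float(v) for k, v in self.true_betas.items()},
            "trial_counts": dict(self.trial_counts),
            "control_rate": float(self.control_rate),
            "random_intercept_sd": float(self.random_intercept_sd),
            "censor_prob": float(self.censor_prob),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def generate_community(
    seed: int,
    n_herbivores: int = 12,
    n_predators: int = 5,
    overrides: dict | None = None,
    vulnerability_coupling: float = 0.0,
    mass_range: tuple = (15.0, 1200.0),
    n_nonvocal: int = 1,
) -> CommunityConfig:
    """Generate a fully populated community, deterministic for a fixed seed.

    ``vulnerability_coupling`` is the logit-scale slope linking a caller's
    alarm propensity to its own vulnerability: with coupling ``c``,
    I(x, j) = expit(-c/2 + c * epsilon(j, x)), so species alarm more readily
    to predators that prefer them (the adaptive-information hypothesis);
    with coupling 0 propensities are sampled uniformly on [0, 1].

    ``overrides`` is a partial config: matching CommunityConfig fields are
    replaced after generation and the invariants re-checked.
    """
    if n_herbivores < 2 or n_predators < 2:
        raise ValueError("generate_community: counts must be >= 2")
    rng = np.random.default_rng(seed)
    species = [f"sp{i+1:02d}" for i in range(n_herbivores)]
    predators = [f"pred{i+1}" for i in range(n_predators)]

    lo, hi = np.log(mass_range[0]), np.log(mass_range[1])
    masses = pd.Series(np.exp(rng.uniform(lo, hi, n_herbivores)), index=species,
                       name="body_mass_kg")
    herb_ab = pd.Series(rng.lognormal(3.0, 1.0, n_herbivores), index=species,
                        name="abundance")
    pred_ab = pd.Series(rng.gamma(2.0, 1.0, n_predators), index=predators,
                        name="abundance")
    jacobs = pd.DataFrame(rng.uniform(-1.0, 1.0, (n_herbivores, n_predators)),
                          index=species, columns=predators)
    vocal = pd.Series(True, index=species, name="vocal")
    if n_nonvocal:
        silent = rng.choice(species, size=n_nonvocal, replace=False)
        vocal[silent] = False

    eps = jacobs_transform(jacobs)                     # herbivores x predators
    if vulnerability_coupling != 0.0:
        c = vulnerability_coupling
        I = expit(-c / 2.0 + c * eps.T.to_numpy())     # predators x callers
    else:
        I = rng.uniform(0.0, 1.0, (n_predators, n_herbivores))
    I = pd.DataFrame(I, index=predators, columns=species)
    I.loc[:, ~vocal] = 0.0

    vocal_sp = [s for s in species if vocal[s]]
    feats = pd.DataFrame(index=vocal_sp, columns=acoustics.FEATURES, dtype=float)
    feats["duration_s"] = rng.uniform(0.1, 1.5, len(vocal_sp))
    feats["harmonics"] = rng.uniform(0.0, 5.0, len(vocal_sp))
    feats["n_components"] = rng.integers(1, 6, len(vocal_sp)).astype(float)
    feats["pulses"] = rng.integers(0, 2, len(vocal_sp)).astype(float)
    if not feats["pulses"].any():
        feats.iloc[0, feats.columns.get_loc("pulses")] = 1.0
    feats["q25_hz"] = rng.uniform(200.0, 3000.0, len(vocal_sp))
    feats["bandwidth_hz"] = rng.uniform(100.0, 2000.0, len(vocal_sp))
    feats["df3_hz"] = rng.uniform(500.0, 8000.0, len(vocal_sp))

    cfg = CommunityConfig(
        n_herbivores=n_herbivores, n_predators=n_predators, seed=seed,
        species=species, predators=predators, body_masses=masses,
        herbivore_abundances=herb_ab, predator_abundances=pred_ab,
        jacobs_matrix=jacobs, alarm_propensity=I, acoustic_features=feats,
        vocal_flags=vocal,
    )
    if overrides:
        for key, value in overrides.items():
            if not hasattr(cfg, key):
                raise ValueError(f"generate_community: unknown override field {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            elif isinstance(current, pd.Series) and not isinstance(value, pd.Series):
                updated = current.copy()
                for k, v in dict(value).items():
                    updated[k] = v
                setattr(cfg, key, updated)
            else:
                setattr(cfg, key, value)
        if "vocal_flags" in overrides:
            cfg.alarm_propensity.loc[:, ~cfg.vocal_flags] = 0.0
            cfg.acoustic_features = cfg.acoustic_features.loc[
                [s for s in cfg.acoustic_features.index if cfg.vocal_flags[s]]]
    cfg.validate()
    return cfg


def true_indices(cfg: CommunityConfig, similarity: pd.DataFrame | None = None,
                 normalized: bool = True) -> DerivedIndices:
    """Derived indices from the community's *true* propensities and Jacobs table."""
    if similarity is None:
        tab = cfg.acoustic_features.reset_index(names="species")
        similarity = acoustics.acoustic_similarity(tab)
    return derive_indices(
        cfg.alarm_propensity, cfg.epsilon, cfg.predator_abundances,
        cfg.body_masses, cfg.herbivore_abundances, similarity=similarity,
        normalized=normalized,
    )


def simulate_predator_trials(
    cfg: CommunityConfig,
    n_per_combination: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced predator-model presentation experiment.

    For every herbivore x (predator + control) combination,
    ``n_per_combination`` trials (default from ``cfg.trial_counts``); the
    alarm outcome is Bernoulli(I(x, j)) for predator models and
    Bernoulli(control_rate) for the neutral control model.
    """
    cfg.validate()
    n = n_per_combination or cfg.trial_counts["predator_sim"]
    if n < 1:
        raise ValueError("simulate_predator_trials: n_per_combination must be >= 1")
    rng = np.random.default_rng(seed)
    rmin, rmax = cfg.covariate_ranges["distance_m"]
    rows = []
    for sp in cfg.species:
        for model in cfg.predators + ["control"]:
            is_pred = model != "control"
            p = cfg.alarm_propensity.loc[model, sp] if is_pred else cfg.control_rate
            for _ in range(n):
                rows.append({
                    "focal_species": sp,
                    "model_kind": "predator" if is_pred else "control",
                    "predator_id": model if is_pred else None,
                    "distance_m": rng.uniform(rmin, rmax),
                    "group_size": 1 + rng.poisson(cfg.covariate_ranges["group_size_mean"] - 1),
                    "young_present": bool(rng.random() < cfg.covariate_ranges["young_present_p"]),
                    "alarm_given": bool(rng.random() < p),
                })
    out = pd.DataFrame(rows)
    out.insert(0, "trial_id", [f"P{i:05d}" for i in range(len(out))])
    return out


def simulate_call_table(cfg: CommunityConfig, n_calls: int = 10, seed: int = 0,
                        noise_sd: float = 0.15) -> pd.DataFrame:
    """Per-call acoustic feature table: species centroids with lognormal noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for sp in cfg.acoustic_features.index:
        base = cfg.acoustic_features.loc[sp].to_numpy()
        for c in range(n_calls):
            noise = np.exp(rng.normal(0.0, noise_sd, len(base)))
            rows.append({"species": sp, "call_id": f"{sp}_c{c:02d}",
                         **dict(zip(acoustics.FEATURES, base * noise))})
    return pd.DataFrame(rows)


def _sample_negbin(rng, mu, alpha):
    """NB2 draws: Poisson with gamma-distributed rate (var = mu + alpha mu^2)."""
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


def simulate_playbacks(
    cfg: CommunityConfig,
    indices: DerivedIndices,
    n_per_pair: int | None = None,
    seed: int = 0,
    response_window: float = 10.0,
) -> pd.DataFrame:
    """Balanced playback experiment over receiver x (vocal caller + control).

    The binary response follows logit(p) = x'beta + u_receiver with
    u ~ N(0, random_intercept_sd^2) and the covariates of
    ``design.build_playback_design`` dotted with ``cfg.true_betas``.
    Conditional on a response, latency (truncated below the response window's
    upper bound), duration (= latency + a log-normal resumption delay,
    censored with probability ``censor_prob``) and head-lift speed are
    log-normal, and head-up / scratch counts are negative-binomial, each with
    its own intercept and optional shared-covariate coefficients.
    """
    cfg.validate()
    if indices is None:
        raise ValueError("simulate_playbacks: derived indices are required")
    n = n_per_pair or cfg.trial_counts["playback"]
    if n < 1:
        raise ValueError("simulate_playbacks: n_per_pair must be >= 1")
    rng = np.random.default_rng(seed)

    callers = cfg.vocal_species + ["control"]
    rows = []
    cr = cfg.covariate_ranges
    for recv in cfg.species:
        for caller in callers:
            for _ in range(n):
                if caller == "control":
                    kind, csp = "control", None
                elif caller == recv:
                    kind, csp = "conspecific", caller
                else:
                    kind, csp = "heterospecific", caller
                mu, sg = cr["grass_height_cm"]
                dmu, dsd = cr["speaker_distance_m"]
                wlo, whi = cr["wind_speed_ms"]
                rows.append({
                    "receiver_species": recv,
                    "caller_species": csp,
                    "call_kind": kind,
                    "grass_height": rng.lognormal(mu, sg),
                    "cover_proximity": rng.exponential(cr["cover_proximity_m"]),
                    "speaker_distance": max(15.0, rng.normal(dmu, dsd)),
                    "wind_speed": rng.uniform(wlo, whi),
                    "group_size": 1 + rng.poisson(cr["group_size_mean"] - 1),
                })
    trials = pd.DataFrame(rows)
    trials.insert(0, "trial_id", [f"B{i:05d}" for i in range(len(trials))])

    X = build_playback_design(trials, indices, cfg.body_masses)
    beta = cfg.true_betas
    is_control = X["control"].to_numpy() > 0
    eta = np.where(is_control, beta["control"], beta["intercept"])
    eta = eta + beta["conspecific"] * X["conspecific"].to_numpy()
    for term in DESIGN_TERMS:
        b = beta.get(term, 0.0)
        if b:
            eta = eta + b * X[term].to_numpy()
    u = rng.normal(0.0, cfg.random_intercept_sd, cfg.n_herbivores)
    u = pd.Series(u, index=cfg.species)
    eta = eta + u.loc[trials["receiver_species"]].to_numpy()
    responded = rng.random(len(trials)) < expit(eta)

    recv_idx = pd.Index(cfg.species).get_indexer(trials["receiver_species"])

    def process_eta(name):
        proc = cfg.processes[name]
        e = np.full(len(trials), proc["intercept"], dtype=float)
        for term, b in proc["betas"].items():
            e += b * X[term].to_numpy()
        re_sd = proc.get("re_sd", 0.0)
        if re_sd:
            e += rng.normal(0.0, re_sd, cfg.n_herbivores)[recv_idx]
        return proc, e

    m = len(trials)
    lat = np.full(m, np.nan)
    dur = np.full(m, np.nan)
    censored = np.zeros(m, dtype=bool)
    speed = np.full(m, np.nan)
    head_ups = np.zeros(m, dtype=int)
    scratches = np.zeros(m, dtype=int)

    idx = np.where(responded)[0]
    proc, e = process_eta("latency")
    dist = lognorm(s=proc["sigma"], scale=np.exp(e[idx]))
    lat[idx] = dist.ppf(rng.random(len(idx)) * dist.cdf(response_window))
    proc, e = process_eta("duration")
    dur[idx] = lat[idx] + rng.lognormal(e[idx], proc["sigma"])
    censored[idx] = rng.random(len(idx)) < cfg.censor_prob
    dur[censored] = np.nan
    proc, e = process_eta("headlift_speed")
    speed[idx] = rng.lognormal(e[idx], proc["sigma"])
    proc, e = process_eta("head_ups")
    head_ups[idx] = _sample_negbin(rng, np.exp(e[idx]), proc["alpha"])
    proc, e = process_eta("scratches")
    scratches[idx] = _sample_negbin(rng, np.exp(e[idx]), proc["alpha"])

    trials["responded"] = responded
    trials["latency_s"] = lat
    trials["duration_s"] = dur
    trials["duration_censored"] = censored
    trials["headlift_speed"] = speed
    trials["n_head_ups"] = head_ups
    trials["n_scratches"] = scratches
    trials.attrs["random_intercepts"] = u.to_dict()
    trials.attrs["seed"] = seed
    return trials


def event_log_for_trial(row, onset: float = 30.0, log_end: float = 330.0) -> EventLog:
    """Deterministically render one playback trial as a behaviour event log.

    The animal forages from 25 s before the playback; if it responded, the
    foraging bout ends at onset + latency, head-up bouts and scratches are
    laid out between the first response and the resumption of foraging, and
    a >= 10 s foraging bout starts at onset + duration.  Censored trials get
    only a short (< 10 s) terminal foraging bout, so the coder flags them
    censored.  Coding this log recovers the generator's latent variables
    exactly.
    """
    events = [(onset - 25.0, "forage_start")]
    if not row["responded"]:
        events.append((log_end, "forage_end"))
        return EventLog(trial_id=row["trial_id"], onset=onset, events=events)
    lat = float(row["latency_s"])
    t_first = onset + lat
    if bool(row["duration_censored"]) or pd.isna(row["duration_s"]):
        t_resume = log_end - 5.0                 # < 10 s bout: stays censored
    else:
        t_resume = onset + float(row["duration_s"])
    events.append((t_first, "forage_end"))
    n_h = int(row["n_head_ups"])
    n_s = int(row["n_scratches"])
    span = max(t_resume - t_first, 1e-6)
    if n_h == 0:
        events.append((t_first, "other_behaviour_change"))
    for m in range(n_h):
        s = t_first + span * m / n_h
        events.append((s, "head_up_start"))
        events.append((s + 0.4 * span / n_h, "head_up_end"))
    for m in range(n_s):
        events.append((t_first + span * (m + 0.5) / (n_s + 1), "scratch"))
    events.append((t_resume, "forage_start"))
    if bool(row["duration_censored"]) or pd.isna(row["duration_s"]):
        events.append((t_resume + 5.0, "forage_end"))    # < 10 s: not resumed
    else:
        events.append((max(log_end, t_resume + 15.0), "forage_end"))
    events.sort(key=lambda e: e[0])
    hl = row.get("headlift_speed", np.nan)
    return EventLog(
        trial_id=row["trial_id"], onset=onset, events=events,
        headlift_speed=None if pd.isna(hl) else float(hl),
    )
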