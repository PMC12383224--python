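"""Synthetic cohorts with the statistical structure the analyses assume.

Generative model, per participant:

* latent chronic stress ~ N(0, 1); the Perceived Stress Scale total is
  ``round(clip(pss_mean + pss_sd · stress, 0, 40))``, decomposed
  deterministically into 10 item scores that sum exactly to the total (and
  stored with the reverse-keyed items inverted, so instrument scoring
  recovers the total).
* true decision parameters on the logit scale:
  ``theta_P = base_mean_P + coupling_P · stress + N(0, base_sd_P)`` for
  P in {C, N, I}, mapped through the inverse logit.  ``coupling = 0``
  (the default) encodes the null regime in which chronic stress has no
  effect on moral decision parameters.
* binary responses: accept ~ Bernoulli(p_cell) with p_cell from the CNI
  tree (:func:`moraldm.estimators.cni_predict`).
* 1-6 Likert responses: a probit-latent threshold model,
  ``latent = Phi^{-1}(p_cell) + N(0, likert_noise_sd)`` cut at five
  thresholds whose middle cutpoint is 0, so dichotomizing at 4 recovers an
  accept draw with probability Phi(Phi^{-1}(p)/sigma) — exactly p at the
  default sigma = 1.

Demographic defaults mirror the replication cohort (n = 208, PSS
12.15 ± 6.84, age 32.07 ± 12.35, 56.7% female); base parameter means echo
the reported cohort means (C 0.20, N 0.25, I 0.41).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit, ndtri

from .dilemma import CATEGORIES, PSS10_REVERSE_ITEMS, default_battery
from .estimators import cni_predict

__all__ = [
    "SimConfig",
    "draw_participants",
    "sample_binary_responses",
    "sample_likert_responses",
    "simulate_cohort",
    "decompose_pss_total",
]

_PARAMS = ("C", "N", "I")
_PROB_EPS = 1e-7


@dataclass
class SimConfig:
    """Simulation settings; defaults are the study conditions being emulated."""

    n_participants: int = 208
    items_per_category: int = 6
    coupling: dict = field(default_factory=lambda: {"C": 0.0, "N": 0.0, "I": 0.0})
    base_mean: dict = field(
        default_factory=lambda: {"C": float(logit(0.20)), "N": float(logit(0.25)), "I": float(logit(0.41))}
    )
    base_sd: dict = field(default_factory=lambda: {"C": 0.5, "N": 0.5, "I": 0.5})
    likert_noise_sd: float = 1.0
    likert_thresholds: tuple = (-1.8, -0.8, 0.0, 0.8, 1.8)
    pss_mean: float = 12.15
    pss_sd: float = 6.84
    pss_reverse_items: tuple = PSS10_REVERSE_ITEMS
    female_prop: float = 0.567
    age_mean: float = 32.07
    age_sd: float = 12.35
    age_min: int = 17
    age_max: int = 89
    mc_key: tuple = (1, 0, 1, 0, 1, 1, 0, 1, 0, 1, 1, 0, 1)
    mc_endorse: float = 0.5
    acute_stress_rate: float = 0.0
    attention_fail_rate: float = 0.0
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.items_per_category < 1:
            raise ValueError("items_per_category must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for m in (self.coupling, self.base_mean, self.base_sd):
            if set(m) != set(_PARAMS):
                raise ValueError(f"parameter maps need exactly keys {_PARAMS}, got {sorted(m)}")
        thr = np.asarray(self.likert_thresholds, dtype=float)
        if thr.shape != (5,) or np.any(np.diff(thr) <= 0):
            raise ValueError("likert_thresholds must be 5 strictly increasing cutpoints")
        if self.likert_noise_sd < 0:
            raise ValueError("likert_noise_sd must be >= 0")
        if len(self.mc_key) != 13 or any(v not in (0, 1) for v in self.mc_key):
            raise ValueError("mc_key must be 13 binary values")
        for name, p in (
            ("female_prop", self.female_prop),
            ("mc_endorse", self.mc_endorse),
            ("acute_stress_rate", self.acute_stress_rate),
            ("attention_fail_rate", self.attention_fail_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.pss_mean <= 40.0:
            raise ValueError("pss_mean must lie on the 0-40 scale")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        d = dict(d)
        for key in ("likert_thresholds", "pss_reverse_items", "mc_key"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("likert_thresholds", "pss_reverse_items", "mc_key"):
            d[key] = list(d[key])
        return d


def decompose_pss_total(total: int, n_items: int = 10) -> np.ndarray:
    """Spread a scale total evenly over items (remainder on early items).

    Deterministic and exactly summing; each item lands in 0..4 for any total
    in [0, 4·n_items].
    """
    if not 0 <= total <= 4 * n_items:
        raise ValueError(f"total {total} infeasible for {n_items} items")
    base, rem = divmod(int(total), n_items)
    items = np.full(n_items, base, dtype=int)
    items[:rem] += 1
    return items


def draw_participants(config: SimConfig, rng: np.random.Generator):
    """Draw participant records and the latent truth table.

    Returns
    -------
    (records, truth): ``records`` holds the covariate table (gender, age,
    stored PSS-10 items, social-desirability items, screening flags);
    ``truth`` the latent stress and true (C, N, I) per participant.
    """
    n = config.n_participants
    pids = [f"P{i + 1:04d}" for i in range(n)]
    stress = rng.standard_normal(n)
    pss_total = np.rint(np.clip(config.pss_mean + config.pss_sd * stress, 0, 40)).astype(int)

    # scored item decomposition, then invert reverse-keyed items for storage
    items = np.vstack([decompose_pss_total(t) for t in pss_total])
    stored = items.copy()
    rev = [p - 1 for p in config.pss_reverse_items]
    stored[:, rev] = 4 - stored[:, rev]

    true = {}
    for p in _PARAMS:
        eta = config.base_mean[p] + config.coupling[p] * stress + rng.normal(0.0, config.base_sd[p], n)
        true[p] = expit(eta)

    gender = np.where(rng.random(n) < config.female_prop, "female", "male")
    age = np.rint(np.clip(rng.normal(config.age_mean, config.age_sd, n), config.age_min, config.age_max)).astype(int)
    mc = (rng.random((n, 13)) < config.mc_endorse).astype(int)
    acute = (rng.random(n) < config.acute_stress_rate).astype(int)
    attention = (rng.random(n) >= config.attention_fail_rate).astype(int)

    records = pd.DataFrame({"participant_id": pids, "gender": gender, "age": age})
    for j in range(10):
        records[f"pss10_{j + 1}"] = stored[:, j]
    for j in range(13):
        records[f"mc_{j + 1}"] = mc[:, j]
    records["acute_stress"] = acute
    records["attention_pass"] = attention

    truth = pd.DataFrame(
        {
            "participant_id": pids,
            "stress_latent": stress,
            "pss_total": pss_total,
            "C_true": true["C"],
            "N_true": true["N"],
            "I_true": true["I"],
        }
    )
    return records, truth


def _cell_prob_matrix(truth: pd.DataFrame, battery: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-participant x per-item acceptance probabilities under the tree."""
    probs = cni_predict(
        truth["C_true"].to_numpy(), truth["N_true"].to_numpy(), truth["I_true"].to_numpy()
    )  # (n, 4)
    items = battery.sort_values("presentation_order").reset_index(drop=True)
    cat_idx = items["category"].map({c: i for i, c in enumerate(CATEGORIES)}).to_numpy()
    return probs[:, cat_idx], items


def _long_frame(truth: pd.DataFrame, items: pd.DataFrame, values: np.ndarray, col: str) -> pd.DataFrame:
    n, m = values.shape
    return pd.DataFrame(
        {
            "participant_id": np.repeat(truth["participant_id"].to_numpy(), m),
            "item_id": np.tile(items["item_id"].to_numpy(), n),
            "category": np.tile(items["category"].to_numpy(), n),
            col: values.ravel(),
        }
    )


def sample_binary_responses(
    truth: pd.DataFrame, battery: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Bernoulli accept/reject draws from each participant's tree probabilities."""
    p_items, items = _cell_prob_matrix(truth, battery)
    accept = (rng.random(p_items.shape) < p_items).astype(int)
    return _long_frame(truth, items, accept, "accept")


def sample_likert_responses(
    truth: pd.DataFrame,
    battery: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """1-6 ratings from the probit-latent threshold model."""
    p_items, items = _cell_prob_matrix(truth, battery)
    latent = ndtri(np.clip(p_items, _PROB_EPS, 1 - _PROB_EPS))
    if config.likert_noise_sd > 0:
        latent = latent + rng.normal(0.0, config.likert_noise_sd, p_items.shape)
    ratings = 1 + np.digitize(latent, np.asarray(config.likert_thresholds, dtype=float))
    return _long_frame(truth, items, ratings.astype(int), "rating")


def simulate_cohort(config: SimConfig, seed: int | None = None) -> dict:
    """Generate a full cohort: records, truth, battery, binary and Likert responses.

    The run seed (``config.seed`` unless overridden) is split into
    independent child streams for participants, binary draws, and Likert
    draws, so each stage is individually reproducible.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    rng_part, rng_bin, rng_lik = (np.random.default_rng(s) for s in root.spawn(3))
    battery = default_battery(config.items_per_category)
    records, truth = draw_participants(config, rng_part)
    responses_binary = sample_binary_responses(truth, battery, rng_bin)
    responses_likert = sample_likert_responses(truth, battery, config, rng_lik)
    return {
        "records": records,
        "truth": truth,
        "battery": battery,
        "responses_binary": responses_binary,
        "responses_likert": responses_likert,
    }
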