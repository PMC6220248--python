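"""Synthetic cohort generator with ground truth.

Emulates the statistical structure the downstream analysis assumes, for a
study whose imaging data are not redistributable: a cohort of weighted
connectomes sharing one sparse connected backbone, with per-subject
multiplicative edge noise and idiosyncratic weak "noise" edges; a standard
normal latent factor z_s per subject that (a) scales every edge incident to
designated effect nodes by exp(gamma * z_s) — which moves those nodes'
betweenness after top-K binarization — and (b) loads on a 12-item ordinal
questionnaire whose sum is the trait score. Covariates are age (uniform on
20–65) and sex (Bernoulli, 33/51 male). Everything is deterministic under
the config seed, and the full ground truth is returned for recovery checks.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import Cohort, RegionTable, WeightedConnectome, default_region_table

#: marginal category probabilities used to discretize item latents into 0..4
ITEM_CATEGORY_PROBS = (0.1, 0.2, 0.4, 0.2, 0.1)


@dataclass
class GeneratorConfig:
    """Cohort generator parameters.

    Weight distributions are log-normal; ``*_weight_mean`` is the median on
    the natural scale (exp of the log-scale location) and ``*_weight_sd`` the
    log-scale sigma. ``gamma`` may be a scalar applied to every effect node
    or a per-node mapping (signed: negative gamma plants a negative
    betweenness–trait effect).
    """

    n_subjects: int = 51
    n_nodes: int = 83
    backbone_edges: int = 343
    backbone_weight_mean: float = 100.0
    backbone_weight_sd: float = 0.6
    noise_weight_mean: float = 20.0
    noise_weight_sd: float = 0.6
    n_noise_edges: int = 60
    subject_noise_sd: float = 0.3
    effect_nodes: tuple[int, ...] = (10, 45)
    gamma: float | dict[int, float] = field(
        default_factory=lambda: {10: 0.8, 45: -0.8})
    beta_trait: float = 2.0
    trait_mean: float = 23.5
    trait_sd: float = 7.5
    n_items: int = 12
    interitem_corr: float = 0.262
    age_range: tuple[float, float] = (20.0, 65.0)
    sex_prob_male: float = 33 / 51
    seed: int = 0

    def __post_init__(self) -> None:
        n_pairs = self.n_nodes * (self.n_nodes - 1) // 2
        if not (0 < self.backbone_edges <= n_pairs):
            raise ValueError("backbone_edges must be in (0, n(n-1)/2]")
        targets = set(self.effect_nodes)
        if isinstance(self.gamma, dict):
            targets |= set(self.gamma)
        if any(not (0 <= v < self.n_nodes) for v in targets):
            raise ValueError("effect_nodes outside 0..n_nodes-1")
        for name in ("backbone_weight_sd", "noise_weight_sd",
                     "subject_noise_sd", "trait_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.interitem_corr < 1):
            raise ValueError("interitem_corr must be in (0, 1)")

    @property
    def gamma_map(self) -> dict[int, float]:
        if isinstance(self.gamma, dict):
            return {int(k): float(v) for k, v in self.gamma.items()}
        return {v: float(self.gamma) for v in self.effect_nodes}


@dataclass
class GroundTruth:
    """What was planted: per-subject latent factors and the effect structure."""

    subject_ids: list[str]
    z: list[float]
    effect_nodes: list[int]
    gamma: dict[int, float]
    beta_trait: float
    backbone_edges: list[tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "subject_ids": self.subject_ids,
            "z": self.z,
            "effect_nodes": self.effect_nodes,
            "gamma": {str(k): v for k, v in self.gamma.items()},
            "beta_trait": self.beta_trait,
            "backbone_edges": [list(e) for e in self.backbone_edges],
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _region_table(n_nodes: int) -> RegionTable:
    if n_nodes == 83:
        return default_region_table()
    return RegionTable.from_names([f"node_{i:03d}" for i in range(n_nodes)])


def _all_pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def _is_connected(n: int, edges: list[tuple[int, int]]) -> bool:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n


def generate_backbone(config: GeneratorConfig,
                      rng: np.random.Generator | int | None = None,
                      max_retries: int = 200) -> WeightedConnectome:
    """Draw the shared backbone: ``backbone_edges`` uniformly random node
    pairs carrying log-normal weights, resampled (bounded retries) until the
    backbone graph is connected."""
    if config.backbone_edges < config.n_nodes - 1:
        raise ValueError(
            f"backbone_edges={config.backbone_edges} cannot connect "
            f"{config.n_nodes} nodes (need >= n_nodes-1)")
    rng = np.random.default_rng(rng)
    pairs = _all_pairs(config.n_nodes)
    for _ in range(max_retries):
        pick = rng.choice(len(pairs), size=config.backbone_edges,
                          replace=False)
        chosen = [pairs[m] for m in pick]
        if _is_connected(config.n_nodes, chosen):
            break
    else:
        raise RuntimeError("could not draw a connected backbone "
                           f"in {max_retries} tries")
    w = np.zeros((config.n_nodes, config.n_nodes))
    mu = math.log(config.backbone_weight_mean)
    for i, j in chosen:
        w[i, j] = w[j, i] = rng.lognormal(mu, config.backbone_weight_sd)
    return WeightedConnectome(subject_id="backbone", weights=w,
                              regions=_region_table(config.n_nodes),
                              weight_unit="synthetic")


def generate_subject(backbone: WeightedConnectome, z_s: float,
                     config: GeneratorConfig,
                     rng: np.random.Generator | int | None = None,
                     subject_id: str = "subject",
                     ) -> WeightedConnectome:
    """One subject's connectome from the backbone and their latent z_s.

    Each backbone weight gets an independent log-normal noise factor
    (log-scale SD ``subject_noise_sd``); every edge incident to an effect
    node v is additionally scaled by exp(gamma_v * z_s); ``n_noise_edges``
    random non-backbone pairs receive weights from the noise distribution.
    """
    if not math.isfinite(z_s):
        raise ValueError("z_s must be finite")
    rng = np.random.default_rng(rng)
    n = backbone.n_nodes
    w = backbone.weights.copy()
    iu, ju = np.triu_indices(n, k=1)
    on_backbone = w[iu, ju] > 0
    noise = np.exp(rng.normal(0.0, config.subject_noise_sd,
                              size=on_backbone.sum()))
    vals = w[iu, ju]
    vals[on_backbone] *= noise
    gamma_map = config.gamma_map
    if gamma_map:
        scale = np.ones(len(iu))
        for v, g in gamma_map.items():
            incident = (iu == v) | (ju == v)
            scale[incident] *= math.exp(g * z_s)
        vals *= scale * (vals > 0)
    # idiosyncratic weak edges off the backbone
    off = np.flatnonzero(vals == 0)
    if config.n_noise_edges > 0 and len(off) > 0:
        k = min(config.n_noise_edges, len(off))
        pick = rng.choice(off, size=k, replace=False)
        vals[pick] = rng.lognormal(math.log(config.noise_weight_mean),
                                   config.noise_weight_sd, size=k)
    w = np.zeros_like(w)
    w[iu, ju] = vals
    w = w + w.T
    return WeightedConnectome(subject_id=subject_id, weights=w,
                              regions=backbone.regions,
                              weight_unit="synthetic")


def _item_thresholds() -> np.ndarray:
    cum = np.cumsum(ITEM_CATEGORY_PROBS)[:-1]
    return stats.norm.ppf(cum)


def generate_trait(z_s: float, age: float, sex: str,
                   config: GeneratorConfig,
                   rng: np.random.Generator | int | None = None,
                   ) -> tuple[np.ndarray, float]:
    """Item responses (0..4 each) and the raw trait score (item sum).

    Items discretize equicorrelated latent normals (pairwise correlation
    ``interitem_corr``) whose common component carries beta_trait * z_s;
    categories follow the fixed marginal probabilities (0.1, 0.2, 0.4, 0.2,
    0.1). The cohort-level linear rescale to (trait_mean, trait_sd) happens
    in :func:`generate_cohort`; ``age`` and ``sex`` are accepted for
    interface symmetry but carry no trait effect in this model.
    """
    rng = np.random.default_rng(rng)
    r = config.interitem_corr
    b = config.beta_trait
    common = (b * z_s + rng.normal()) / math.sqrt(1.0 + b * b)
    latents = (math.sqrt(r) * common
               + math.sqrt(1.0 - r) * rng.normal(size=config.n_items))
    items = np.searchsorted(_item_thresholds(), latents).astype(int)
    return items, float(items.sum())


def generate_cohort(config: GeneratorConfig,
                    ) -> tuple[Cohort, GroundTruth]:
    """Assemble the full synthetic cohort plus its ground truth.

    Per subject: z_s ~ N(0, 1), age ~ U(age_range), sex ~ Bernoulli
    (sex_prob_male). Trait scores are the item sums linearly rescaled so the
    cohort matches (trait_mean, trait_sd) exactly (sample moments).
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ids = [f"sub-{i + 1:03d}" for i in range(n)]
    z = rng.standard_normal(n)
    ages = rng.uniform(*config.age_range, size=n)
    sexes = np.where(rng.random(n) < config.sex_prob_male, "male", "female")
    backbone = generate_backbone(config, rng)
    connectomes = [
        generate_subject(backbone, float(z[s]), config, rng, subject_id=ids[s])
        for s in range(n)
    ]
    item_rows = np.empty((n, config.n_items), dtype=int)
    raw = np.empty(n)
    for s in range(n):
        items, score = generate_trait(float(z[s]), float(ages[s]),
                                      str(sexes[s]), config, rng)
        item_rows[s] = items
        raw[s] = score
    sd = raw.std(ddof=1)
    if sd > 0:
        scores = config.trait_mean + config.trait_sd * (raw - raw.mean()) / sd
    else:  # degenerate cohort (e.g. n_items tiny); keep the mean target
        scores = np.full(n, config.trait_mean)
    cov = pd.DataFrame({
        "age": ages,
        "sex": sexes,
        "trait_score": scores,
        **{f"item_{k + 1}": item_rows[:, k] for k in range(config.n_items)},
    }, index=pd.Index(ids, name="subject_id"))
    iu, ju = np.triu_indices(config.n_nodes, k=1)
    bb_edges = [(int(i), int(j)) for i, j in zip(iu, ju)
                if backbone.weights[i, j] > 0]
    truth = GroundTruth(subject_ids=ids, z=[float(v) for v in z],
                        effect_nodes=sorted(config.gamma_map),
                        gamma=config.gamma_map,
                        beta_trait=config.beta_trait,
                        backbone_edges=bb_edges)
    return Cohort(connectomes=connectomes, covariates=cov), truth


def config_from_dict(d: dict) -> GeneratorConfig:
    """Build a config from a plain mapping (e.g. a YAML block), rejecting
    unknown keys."""
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown generator keys: {sorted(unknown)}")
    d = dict(d)
    for tup_key in ("age_range", "effect_nodes"):
        if tup_key in d and isinstance(d[tup_key], list):
            d[tup_key] = tuple(d[tup_key])
    if "gamma" in d and isinstance(d["gamma"], dict):
        d["gamma"] = {int(k): float(v) for k, v in d["gamma"].items()}
    return GeneratorConfig(**d)
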