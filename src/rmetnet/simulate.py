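"""Synthetic cohort generator.

Produces study-shaped forced-choice data — two groups of participants, an
answer key with a configured valence partition, per-trial choices and
reaction times, and trait scores — so that every pipeline stage can be
exercised and validated without clinical data.

Choice model
------------
Per item and group, the correct word receives probability ``target_prob``.
The residual mass is spread over the three distractors and the no-response
category by a single draw from a symmetric Dirichlet whose concentration
is the group's ``diversity`` (optionally scaled per valence): a low
concentration piles the wrong-answer mass onto one alternative (a
consistent error), a high concentration spreads it evenly (diverse
errors).  Each participant's choice is then an independent categorical
draw from the item's probability vector.  ``diversity`` is thus the
generative analogue of low answer consensus, the quantity the in-degree
and density indices are meant to pick up.

Reaction times are log-normal: each participant gets a latent mean RT
drawn from a log-normal matched to the group's mean/SD, and each trial is
a log-normal draw around that participant mean (within-participant CV
``rt_within_cv``), truncated to the 8-second display window.

Trait scores (AQ "patterns" for both groups, ADI-R socio-emotional
reciprocity for group A only, as the instrument is administered to the
clinical group) are linear in participant accuracy plus Gaussian noise
scaled to hit the configured correlation in expectation.

All randomness flows from a single seeded generator; the same seed
reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_io import (
    DISPLAY_WINDOW_MS,
    NO_RESPONSE,
    VALENCES,
    AnswerKey,
    ItemSpec,
    ResponseRecord,
    TraitRecord,
    ValidationError,
)
from .metrics import in_degree_vector, network_density
from .network import build_response_network
from .stats import two_sample_t


@dataclass
class GroupParams:
    """Generative parameters for one participant group."""

    label: str
    n: int = 30
    target_prob: float = 0.7
    diversity: float = 1.0
    valence_diversity: dict[str, float] = field(default_factory=dict)
    rt_mean_ms: float = 3700.0
    rt_sd_ms: float = 550.0
    rt_within_cv: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.target_prob < 1.0 or self.target_prob == 1.0):
            raise ValidationError(
                f"group {self.label}: target_prob must be in (0, 1]"
            )
        if self.diversity < 0:
            raise ValidationError(f"group {self.label}: diversity must be >= 0")
        if self.n < 1:
            raise ValidationError(f"group {self.label}: n must be >= 1")
        for v in self.valence_diversity:
            if v not in VALENCES:
                raise ValidationError(
                    f"group {self.label}: unknown valence {v!r} in "
                    "valence_diversity"
                )

    def item_diversity(self, valence: str) -> float:
        return self.diversity * self.valence_diversity.get(valence, 1.0)


def _default_group_a() -> GroupParams:
    # clinical-like group: lower accuracy, slower, more diverse errors,
    # extra error diversity on negative items
    return GroupParams(
        label="A",
        n=30,
        target_prob=0.68,
        diversity=1.0,
        valence_diversity={"negative": 2.5},
        rt_mean_ms=4006.0,
        rt_sd_ms=438.0,
    )


def _default_group_b() -> GroupParams:
    # control-like group: higher accuracy, faster, more concentrated errors
    return GroupParams(
        label="B",
        n=30,
        target_prob=0.74,
        diversity=0.4,
        valence_diversity={},
        rt_mean_ms=3485.0,
        rt_sd_ms=671.0,
    )


@dataclass
class SimConfig:
    """Full generative configuration for a two-group synthetic cohort."""

    seed: int
    n_items: int = 43
    valence_counts: tuple[int, int, int] = (19, 15, 9)  # negative, neutral, positive
    group_a: GroupParams = field(default_factory=_default_group_a)
    group_b: GroupParams = field(default_factory=_default_group_b)
    #: Fixed no-response probability; ``None`` folds no-response into the
    #: Dirichlet residual as a fourth wrong-answer category.
    nr_rate: float | None = None
    #: Target Pearson correlation of accuracy with the AQ "patterns"
    #: subscale (both groups) and the ADI-R socio-emotional reciprocity
    #: subscale (group A only).
    r_aq: float = -0.441
    r_adir: float = -0.427
    #: SD of an optional per-item jitter on the logit of target_prob
    #: (difficulty heterogeneity); 0 disables it.
    item_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        self.valence_counts = tuple(int(c) for c in self.valence_counts)
        if len(self.valence_counts) != 3 or any(c < 0 for c in self.valence_counts):
            raise ValidationError("valence_counts must be 3 non-negative integers")
        if sum(self.valence_counts) != self.n_items:
            raise ValidationError(
                f"valence_counts {self.valence_counts} sum to "
                f"{sum(self.valence_counts)}, expected n_items={self.n_items}"
            )
        if self.nr_rate is not None:
            max_resid = 1.0 - max(
                self.group_a.target_prob, self.group_b.target_prob
            )
            if not (0.0 <= self.nr_rate <= max_resid):
                raise ValidationError(
                    f"nr_rate must be in [0, {max_resid:.3f}] given the "
                    "groups' target probabilities"
                )
        for r in (self.r_aq, self.r_adir):
            if not (-1.0 < r < 0.0):
                raise ValidationError(
                    "trait correlations must be negative and in (-1, 0)"
                )

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        data = dict(data)
        for g in ("group_a", "group_b"):
            if g in data and isinstance(data[g], Mapping):
                data[g] = GroupParams(**data[g])
        if "valence_counts" in data:
            data["valence_counts"] = tuple(data["valence_counts"])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Generation internals
# ---------------------------------------------------------------------------


def _residual_weights(rng: np.random.Generator, alpha: float, k: int) -> np.ndarray:
    """Symmetric Dirichlet draw over k categories; alpha -> 0 limit puts
    all mass on one uniformly chosen category."""
    if alpha <= 0.0:
        w = np.zeros(k)
        w[rng.integers(k)] = 1.0
        return w
    return rng.dirichlet(np.full(k, alpha))


def make_answer_key(cfg: SimConfig, rng: np.random.Generator) -> AnswerKey:
    """Synthetic answer key: unique target words, distractors sampled from
    a shared pool (so wrong answers can be shared across items, as in real
    word banks), valences assigned by shuffling the configured partition."""
    n = cfg.n_items
    pool_size = max(8, int(round(1.4 * n)))
    pool = [f"word_{j:03d}" for j in range(1, pool_size + 1)]
    valences = np.repeat(list(VALENCES), cfg.valence_counts)
    rng.shuffle(valences)
    items = []
    for i in range(1, n + 1):
        distractors = tuple(rng.choice(pool, size=3, replace=False))
        items.append(
            ItemSpec(
                item_id=i,
                target=f"target_{i:03d}",
                distractors=distractors,  # type: ignore[arg-type]
                valence=str(valences[i - 1]),
            )
        )
    return AnswerKey(items=tuple(items))


def _item_probs(
    rng: np.random.Generator,
    params: GroupParams,
    valence: str,
    nr_rate: float | None,
    jitter: float,
) -> np.ndarray:
    """Probability vector over (target, d1, d2, d3, NR) for one item/group."""
    p_t = params.target_prob
    if jitter != 0.0 and 0.0 < p_t < 1.0:
        logit = math.log(p_t / (1.0 - p_t)) + jitter
        p_t = 1.0 / (1.0 + math.exp(-logit))
    residual = 1.0 - p_t
    alpha = params.item_diversity(valence)
    if nr_rate is None:
        w = _residual_weights(rng, alpha, 4)  # d1, d2, d3, NR
        probs = np.concatenate([[p_t], residual * w])
    else:
        w = _residual_weights(rng, alpha, 3)  # distractors only
        probs = np.concatenate([[p_t], (residual - nr_rate) * w, [nr_rate]])
    return probs / probs.sum()


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_rt(rng: np.random.Generator, mean: float, cv: float) -> float:
    """One trial RT, log-normal, truncated to the display window by redraw."""
    mu, sigma = _lognormal_params(mean, cv * mean)
    for _ in range(20):
        rt = float(rng.lognormal(mu, sigma))
        if rt <= DISPLAY_WINDOW_MS:
            return rt
    return DISPLAY_WINDOW_MS  # pathological parameters: clamp at the window


def _correlated_scores(
    rng: np.random.Generator,
    x: np.ndarray,
    rho: float,
    loc: float,
    scale: float,
) -> np.ndarray:
    """Scores with Pearson correlation rho to x in expectation, rescaled to
    (loc, scale) and floored at zero."""
    x = np.asarray(x, float)
    z = x - x.mean()
    sx = z.std(ddof=1)
    eps = rng.standard_normal(len(x))
    if sx == 0.0 or len(x) < 3:
        t = eps
    else:
        noise_sd = sx * math.sqrt(1.0 / rho**2 - 1.0)
        t = math.copysign(1.0, rho) * z + noise_sd * eps
    st = t.std(ddof=1)
    if st == 0.0:
        return np.full(len(x), loc)
    return np.maximum(0.0, loc + scale * (t - t.mean()) / st)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[list[ResponseRecord], AnswerKey, list[TraitRecord]]:
    """Generate a complete synthetic cohort.

    Returns the full response table (every participant x item), the answer
    key, and the trait table.  Regenerating with the same config (seed
    included) is bit-identical.
    """
    rng = np.random.default_rng(cfg.seed)
    key = make_answer_key(cfg, rng)

    responses: list[ResponseRecord] = []
    traits: list[TraitRecord] = []
    for params in (cfg.group_a, cfg.group_b):
        pids = [f"{params.label}{k:03d}" for k in range(1, params.n + 1)]
        jitters = (
            rng.normal(0.0, cfg.item_jitter_sd, size=cfg.n_items)
            if cfg.item_jitter_sd > 0
            else np.zeros(cfg.n_items)
        )
        # per-item choice distributions for this group
        prob_rows = [
            _item_probs(rng, params, item.valence, cfg.nr_rate, jitters[i])
            for i, item in enumerate(key)
        ]
        # per-participant latent mean RT
        mu, sigma = _lognormal_params(params.rt_mean_ms, params.rt_sd_ms)
        subj_rt = rng.lognormal(mu, sigma, size=params.n)

        n_correct = np.zeros(params.n, dtype=int)
        for i, item in enumerate(key):
            cats = item.answer_categories
            choices = rng.choice(5, size=params.n, p=prob_rows[i])
            for p_idx, c in enumerate(choices):
                choice = cats[c]
                if choice == NO_RESPONSE:
                    rt = None
                else:
                    rt = _draw_rt(rng, subj_rt[p_idx], params.rt_within_cv)
                if c == 0:
                    n_correct[p_idx] += 1
                responses.append(
                    ResponseRecord(
                        participant_id=pids[p_idx],
                        group=params.label,
                        item_id=item.item_id,
                        choice=choice,
                        rt_ms=rt,
                    )
                )

        accuracy = 100.0 * n_correct / cfg.n_items
        aq = _correlated_scores(rng, accuracy, cfg.r_aq, loc=6.0, scale=2.0)
        if params is cfg.group_a:
            adir = _correlated_scores(rng, accuracy, cfg.r_adir, loc=14.0, scale=5.0)
        else:
            adir = None
        for p_idx, pid in enumerate(pids):
            traits.append(
                TraitRecord(
                    participant_id=pid,
                    group=params.label,
                    aq={"patterns": float(aq[p_idx])},
                    adir=(
                        {"socio_emotional_reciprocity": float(adir[p_idx])}
                        if adir is not None
                        else {}
                    ),
                )
            )

    return responses, key, traits


def recovery_experiment(
    cfg: SimConfig,
    n_replicates: int,
    delta_diversity: float,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Monte-Carlo check that the in-degree statistic recovers a known
    diversity difference.

    Both groups are given group A's generative parameters so that they are
    exchangeable at ``delta_diversity = 0``; group B's diversity is then
    shifted by ``delta_diversity``.  Each replicate simulates a cohort,
    builds both networks, and runs the pooled t-test on the in-degree
    vectors.  The summary reports how often the higher-diversity group has
    the higher mean in-degree and the t-test rejection rate at ``alpha``
    (the type-I error rate when ``delta_diversity = 0``).
    """
    if n_replicates < 2:
        raise ValidationError("recovery experiment needs n_replicates >= 2")
    base = cfg.group_a
    shifted = dataclasses.replace(
        base,
        label="B",
        diversity=base.diversity + delta_diversity,
        valence_diversity=dict(base.valence_diversity),
    )
    if shifted.diversity < 0:
        raise ValidationError("delta_diversity drives group B diversity below 0")

    children = np.random.SeedSequence(cfg.seed).spawn(n_replicates)
    rows = []
    for rep, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2**31))
        rep_cfg = dataclasses.replace(
            cfg,
            seed=seed,
            group_a=dataclasses.replace(
                base, label="A", valence_diversity=dict(base.valence_diversity)
            ),
            group_b=shifted,
        )
        responses, key, _ = simulate_cohort(rep_cfg)
        net_a = build_response_network(responses, key, "A")
        net_b = build_response_network(responses, key, "B")
        vec_a = in_degree_vector(net_a, key)
        vec_b = in_degree_vector(net_b, key)
        res = two_sample_t(vec_a, vec_b)
        rows.append(
            {
                "replicate": rep,
                "seed": seed,
                "mean_in_degree_a": float(np.mean(vec_a)),
                "mean_in_degree_b": float(np.mean(vec_b)),
                "density_a": network_density(net_a),
                "density_b": network_density(net_b),
                "t": res.value,
                "p_value": res.p_value,
            }
        )
    table = pd.DataFrame(rows)
    higher = table["mean_in_degree_b"] > table["mean_in_degree_a"]
    if delta_diversity < 0:
        higher = table["mean_in_degree_a"] > table["mean_in_degree_b"]
    summary = {
        "n_replicates": n_replicates,
        "delta_diversity": delta_diversity,
        "alpha": alpha,
        "frac_higher_diversity_higher_in_degree": float(higher.mean()),
        "rejection_rate": float((table["p_value"] < alpha).mean()),
    }
    return table, summary
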