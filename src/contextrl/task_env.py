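"""Three-phase instrumental learning task: schedules, rewards, stopping rule.

The task presents two fixed stimulus pairs ("contexts"): (A1, B) and (A2, C).
A1 and A2 pay from the same truncated normal N(64, 13); B and C pay from
N(54, 13) and N(44, 13). A learning phase of adaptive length (100-300 trials)
is followed by a 24-trial transfer phase over all six unordered stimulus
pairs and a 16-trial value-estimation phase over the four stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

LEARNING, TRANSFER, ESTIMATION = "learning", "transfer", "estimation"
PARTIAL, COMPLETE = "partial", "complete"

STIMULI = ("A1", "B", "A2", "C")
CONTEXTS = (("A1", "B"), ("A2", "C"))

__all__ = [
    "OptionSpec", "TaskConfig", "TrialSpec", "DegenerateHistoryError",
    "default_config", "draw_reward", "build_learning_schedule",
    "stopping_decision", "build_eval_schedules",
    "PARTIAL", "COMPLETE", "LEARNING", "TRANSFER", "ESTIMATION",
    "STIMULI", "CONTEXTS",
]


class DegenerateHistoryError(RuntimeError):
    """Raised when the stopping rule is asked to compare an empty reward history."""


@dataclass(frozen=True)
class OptionSpec:
    """One bandit arm: a stimulus paying from a truncated normal (points)."""

    label: str
    mu: float
    sigma: float
    # reward scale shown to participants; bounds are [mu-3*sigma, mu+3*sigma]
    # intersected with this display range
    scale_low: float = 0.0
    scale_high: float = 100.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def bounds(self) -> tuple[float, float]:
        lo = max(self.scale_low, self.mu - 3.0 * self.sigma)
        hi = min(self.scale_high, self.mu + 3.0 * self.sigma)
        if not lo < hi:
            raise ValueError(f"empty truncation interval for {self.label}")
        return lo, hi


@dataclass(frozen=True)
class TaskConfig:
    contexts: tuple[tuple[OptionSpec, OptionSpec], tuple[OptionSpec, OptionSpec]]
    min_trials: int = 100
    max_trials: int = 300
    stop_tolerance: float = 1.0
    transfer_repeats: int = 4
    estimation_repeats: int = 4
    feedback_regime: str = PARTIAL
    init_q: float = 0.0
    estimation_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.min_trials > self.max_trials:
            raise ValueError("min_trials must be <= max_trials")
        if self.stop_tolerance <= 0:
            raise ValueError("stop_tolerance must be > 0")
        if self.feedback_regime not in (PARTIAL, COMPLETE):
            raise ValueError(f"unknown feedback regime {self.feedback_regime!r}")
        labels = [o.label for pair in self.contexts for o in pair]
        if len(labels) != 4 or len(set(labels)) != 4:
            raise ValueError("task requires exactly 4 uniquely labelled stimuli")
        for pair in self.contexts:
            for o in pair:
                o.bounds  # validates truncation interval

    @property
    def options(self) -> dict[str, OptionSpec]:
        return {o.label: o for pair in self.contexts for o in pair}

    @property
    def stimuli(self) -> tuple[str, ...]:
        return tuple(o.label for pair in self.contexts for o in pair)

    def with_regime(self, regime: str) -> "TaskConfig":
        return replace(self, feedback_regime=regime)


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: phase, which stimuli appear, and on which side."""

    phase: str
    stimuli: tuple[str, ...]       # 2 labels (learning/transfer), 1 (estimation)
    left: str | None = None        # side assignment where applicable

    def __post_init__(self) -> None:
        n = 1 if self.phase == ESTIMATION else 2
        if len(self.stimuli) != n:
            raise ValueError(f"{self.phase} trial must show {n} stimulus/stimuli")

    @property
    def right(self) -> str | None:
        if self.left is None or len(self.stimuli) != 2:
            return None
        a, b = self.stimuli
        return b if self.left == a else a


def default_config(regime: str = PARTIAL, **overrides) -> TaskConfig:
    """The study's task configuration: pairs (A1,B) and (A2,C), N(64,13)/N(54,13)/N(44,13)."""
    contexts = (
        (OptionSpec("A1", 64.0, 13.0), OptionSpec("B", 54.0, 13.0)),
        (OptionSpec("A2", 64.0, 13.0), OptionSpec("C", 44.0, 13.0)),
    )
    return TaskConfig(contexts=contexts, feedback_regime=regime, **overrides)


def config_from_yaml(path) -> TaskConfig:
    """Flat key-value task description: means/sigmas per label plus schedule knobs."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    means = raw.get("means", {"A1": 64, "B": 54, "A2": 64, "C": 44})
    sigmas = raw.get("sigmas", {k: 13 for k in means})
    pairs = raw.get("contexts", [["A1", "B"], ["A2", "C"]])
    contexts = tuple(
        tuple(OptionSpec(lb, float(means[lb]), float(sigmas[lb])) for lb in pair)
        for pair in pairs
    )
    kw = {k: raw[k] for k in (
        "min_trials", "max_trials", "stop_tolerance", "transfer_repeats",
        "estimation_repeats", "feedback_regime", "init_q", "estimation_noise_sd",
    ) if k in raw}
    return TaskConfig(contexts=contexts, **kw)  # type: ignore[arg-type]


def draw_reward(option: OptionSpec, rng: np.random.Generator) -> float:
    """Sample one reward from N(mu, sigma) truncated to the option's bounds.

    Rejection sampling: exact, and cheap because at most the ~0.27% of mass
    outside mu±3sigma (plus any display-range clip) is rejected.
    """
    lo, hi = option.bounds
    while True:
        r = rng.normal(option.mu, option.sigma)
        if lo <= r <= hi:
            return float(r)


def _balanced_sides(pair: tuple[str, str], n: int, rng: np.random.Generator) -> list[str]:
    """Left-stimulus assignment for n trials of one pair, each side used n//2 times."""
    sides = [pair[0]] * (n // 2) + [pair[1]] * (n - n // 2)
    rng.shuffle(sides)
    return sides


def build_learning_schedule(config: TaskConfig, rng: np.random.Generator) -> list[TrialSpec]:
    """Pseudorandom interleaving of the two contexts over config.max_trials trials.

    Contexts are shuffled within consecutive blocks of two (one trial per
    context per block), so exposure is balanced at every even trial count.
    Within each context, each stimulus appears on the left in exactly half of
    that context's scheduled trials.
    """
    n = config.max_trials
    order: list[int] = []
    for _ in range((n + 1) // 2):
        blk = [0, 1]
        rng.shuffle(blk)
        order.extend(blk)
    order = order[:n]
    ctx_pairs = tuple((a.label, b.label) for a, b in config.contexts)
    sides = [_balanced_sides(ctx_pairs[c], order.count(c), rng) for c in range(2)]
    counters = [0, 0]
    schedule = []
    for c in order:
        schedule.append(TrialSpec(LEARNING, ctx_pairs[c], left=sides[c][counters[c]]))
        counters[c] += 1
    return schedule


def stopping_decision(
    experienced_rewards_a1: list[float],
    experienced_rewards_a2: list[float],
    trial_index: int,
    config: TaskConfig,
) -> str:
    """Adaptive learning-phase termination.

    After ``min_trials`` trials the phase stops as soon as the experienced
    mean rewards of the two equal-valued stimuli (A1, A2) differ by less than
    ``stop_tolerance``; runs still unmatched at ``max_trials`` are excluded.
    Returns one of ``"continue" | "stop" | "exclude"``.
    """
    if trial_index < 1:
        raise ValueError("trial_index must be >= 1")
    if trial_index < config.min_trials:
        return "continue"
    if not experienced_rewards_a1 or not experienced_rewards_a2:
        raise DegenerateHistoryError(
            "empty reward history for A1 or A2 at/after min_trials"
        )
    gap = abs(float(np.mean(experienced_rewards_a1)) - float(np.mean(experienced_rewards_a2)))
    if gap < config.stop_tolerance:
        return "stop"
    if trial_index >= config.max_trials:
        return "exclude"
    return "continue"


def build_eval_schedules(
    config: TaskConfig, rng: np.random.Generator
) -> tuple[list[TrialSpec], list[TrialSpec]]:
    """Transfer (all 6 unordered pairs x repeats, side-counterbalanced) and
    estimation (each stimulus x repeats) schedules, pseudorandom order."""
    labels = config.stimuli
    pairs = [(labels[i], labels[j]) for i in range(4) for j in range(i + 1, 4)]
    transfer: list[TrialSpec] = []
    for pair in pairs:
        for left in _balanced_sides(pair, config.transfer_repeats, rng):
            transfer.append(TrialSpec(TRANSFER, pair, left=left))
    rng.shuffle(transfer)

    estimation = [TrialSpec(ESTIMATION, (lb,)) for lb in labels
                  for _ in range(config.estimation_repeats)]
    rng.shuffle(estimation)
    return transfer, estimation
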