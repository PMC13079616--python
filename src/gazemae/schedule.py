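"""Experiment configuration and trial-schedule construction.

One session of the paradigm crosses seven signed motion-coherence levels
(-30 ... +30 % in 10 % steps, positive = toward the gazed-at object) with a
left/right placement of the adapting face, balanced within each coherence
level. The session is a single flat shuffle of the resulting trial
templates, sliced into contiguous blocks of equal size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError

#: Vertical probe positions (px) relative to the agent's line of sight.
PROBE_OFFSETS = (-460, -230, 0, 230, 460)

#: Signed coherence levels (%) used in every experiment.
COHERENCE_LEVELS = (-30, -20, -10, 0, 10, 20, 30)

AGENT_CONDITIONS = ("sighted", "blindfolded")

#: experiment id -> (agent condition, probe offset in px)
EXPERIMENT_PRESETS = {
    "1a": ("sighted", -460),
    "1b": ("sighted", -230),
    "1c": ("sighted", 0),
    "1d": ("sighted", 230),
    "1e": ("sighted", 460),
    "2a": ("blindfolded", -460),
    "2b": ("blindfolded", -230),
    "2c": ("blindfolded", 0),
    "2d": ("blindfolded", 230),
    "2e": ("blindfolded", 460),
}

SIGHTED_FAMILY = ("1a", "1b", "1c", "1d", "1e")
BLINDFOLDED_FAMILY = ("2a", "2b", "2c", "2d", "2e")


@dataclass(frozen=True)
class StimulusParams:
    """Kinematic parameters of the random-dot motion probe.

    Defaults are the study values: 400 dots of 2 px diameter in a
    230 x 230 px square, moving at 2 px/frame with a 12-frame lifetime
    (200 ms at 60 Hz), shown for 1.0 s.
    """

    n_dots: int = 400
    field_size: float = 230.0
    dot_diameter: float = 2.0
    speed: float = 2.0
    lifetime: int = 12
    duration: float = 1.0
    refresh: float = 60.0

    def __post_init__(self) -> None:
        for name in ("n_dots", "field_size", "dot_diameter", "speed",
                     "lifetime", "duration", "refresh"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"StimulusParams.{name} must be positive")
        if self.lifetime > self.duration * self.refresh:
            raise ConfigurationError(
                "dot lifetime exceeds the number of frames in one presentation"
            )

    @property
    def lifetime_ms(self) -> float:
        """Dot lifetime in milliseconds (200 ms at the defaults)."""
        return 1000.0 * self.lifetime / self.refresh

    @property
    def n_frames(self) -> int:
        """Frames in one probe presentation (duration x refresh)."""
        return int(round(self.duration * self.refresh))


@dataclass
class ExperimentConfig:
    """Full description of one experiment version.

    ``timing`` documents the fixation / adapting-image / inter-trial
    durations; it affects no computation.
    """

    experiment_id: str = "1c"
    agent_condition: str = "sighted"
    probe_offset: int = 0
    coherence_levels: tuple[int, ...] = COHERENCE_LEVELS
    trials_per_condition: int = 10
    blocks: int = 7
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    seed: int | None = None
    timing: dict = field(default_factory=lambda: {
        "fixation_s": 1.5, "image_s": 1.5, "iti_s": [1.0, 2.0]})

    def __post_init__(self) -> None:
        if self.agent_condition not in AGENT_CONDITIONS:
            raise ConfigurationError(
                f"agent_condition must be one of {AGENT_CONDITIONS}, "
                f"got {self.agent_condition!r}")
        if self.probe_offset not in PROBE_OFFSETS:
            raise ConfigurationError(
                f"probe_offset must be one of {PROBE_OFFSETS}, "
                f"got {self.probe_offset}")
        if self.trials_per_condition < 0 or self.blocks < 1:
            raise ConfigurationError("trials_per_condition >= 0 and blocks >= 1 required")
        total = self.trials_per_condition * len(self.coherence_levels)
        if total % self.blocks != 0:
            raise ConfigurationError(
                f"{total} trials cannot be split into {self.blocks} equal blocks")

    @property
    def n_trials(self) -> int:
        return self.trials_per_condition * len(self.coherence_levels)


def preset(experiment_id: str, **overrides) -> ExperimentConfig:
    """Configuration for one of the ten study experiments ("1a".."2e")."""
    try:
        agent, offset = EXPERIMENT_PRESETS[experiment_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown experiment id {experiment_id!r}; "
            f"expected one of {sorted(EXPERIMENT_PRESETS)}") from None
    return ExperimentConfig(experiment_id=experiment_id, agent_condition=agent,
                            probe_offset=offset, **overrides)


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an ExperimentConfig from a YAML or JSON file.

    Any omitted key falls back to the study default. An ``experiment_id``
    matching a preset fills agent_condition/probe_offset unless overridden.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} does not hold a mapping")
    stim = StimulusParams(**raw.pop("stimulus", {}))
    exp_id = raw.get("experiment_id")
    if exp_id in EXPERIMENT_PRESETS:
        agent, offset = EXPERIMENT_PRESETS[exp_id]
        raw.setdefault("agent_condition", agent)
        raw.setdefault("probe_offset", offset)
    if "coherence_levels" in raw:
        raw["coherence_levels"] = tuple(raw["coherence_levels"])
    return ExperimentConfig(stimulus=stim, **raw)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    data = asdict(config)
    data["coherence_levels"] = list(config.coherence_levels)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


class TrialTemplate(NamedTuple):
    """One planned trial: face placement, signed coherence, block index."""

    face_side: str
    coherence_signed: int
    block: int


def build_schedule(config: ExperimentConfig,
                   seed: int | np.random.Generator | None = None) -> list[TrialTemplate]:
    """Build the randomized trial list for one session.

    Per coherence level, ``trials_per_condition`` trials with face side
    balanced to within one trial (exactly half/half at even counts). The
    whole session is one flat shuffle, then cut into ``config.blocks``
    contiguous blocks of equal size. Reproducible given the seed.
    """
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t = config.trials_per_condition
    pairs: list[tuple[str, int]] = []
    for level in config.coherence_levels:
        n_left = t // 2
        if t % 2:  # odd count: the extra side is randomized per level
            n_left += int(rng.integers(2))
        sides = ["left"] * n_left + ["right"] * (t - n_left)
        pairs.extend((s, level) for s in sides)

    if not pairs:
        return []
    order = rng.permutation(len(pairs))
    block_size = len(pairs) // config.blocks
    return [
        TrialTemplate(face_side=pairs[j][0], coherence_signed=pairs[j][1],
                      block=i // block_size)
        for i, j in enumerate(order)
    ]
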