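"""Base-rate-controlled Monte-Carlo generation of contingency quadruples.

Each simulated trial draws two independent binary attributes with prescribed
base rates (marginal probabilities of a 1) over ``n`` observations and
reduces them to a quadruple ``(a, b, c, d)``.  The default study design is a
grid of 15 base-rate pairs spanning [.1, .1] to [.9, .9], with 100,000
trials per pair and ``n = 2000`` (large enough that zero cells essentially
never occur at these design cells).

Because the two attributes are independent, the quadruple of one trial is
exactly multinomial with cell probabilities (pi1*pi2, pi1*(1-pi2),
(1-pi1)*pi2, (1-pi1)*(1-pi2)); the default sampler draws it directly, which
is distributionally identical to materialising the two length-``n`` vectors
and roughly three orders of magnitude faster.  The explicit-vector sampler
is retained for fidelity checks.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import yaml

from .quadruples import ContingencyQuadruple, count_quadruple

__all__ = [
    "BaseRatePair",
    "SimulationConfig",
    "DEFAULT_BASE_RATE_PAIRS",
    "SAMPLER_MODES",
    "cell_probabilities",
    "sample_quadruple",
    "sample_quadruples",
    "generate_trials",
    "write_trials",
    "read_trials",
]

SAMPLER_MODES = ("multinomial", "explicit_vectors")

# Vectors in explicit mode are drawn in blocks of this many trials to bound
# memory at (2 * block * n) bytes of booleans.
_EXPLICIT_BLOCK = 1000


@dataclass(frozen=True, order=True)
class BaseRatePair:
    """A sorted pair of base rates ``0 < pi1 <= pi2 < 1``.

    The first attribute always carries the smaller rate; constructing the
    pair with the rates reversed stores them sorted.
    """

    pi1: float
    pi2: float

    def __post_init__(self) -> None:
        lo, hi = sorted((float(self.pi1), float(self.pi2)))
        if not (0.0 < lo and hi < 1.0):
            raise ValueError(f"base rates must lie strictly in (0, 1), got ({lo}, {hi})")
        object.__setattr__(self, "pi1", lo)
        object.__setattr__(self, "pi2", hi)

    @property
    def label(self) -> str:
        """Filename-safe label, e.g. ``p10_p30`` for (.1, .3)."""
        return f"p{round(self.pi1 * 100):02d}_p{round(self.pi2 * 100):02d}"

    def as_tuple(self) -> Tuple[float, float]:
        return (self.pi1, self.pi2)

    def __str__(self) -> str:
        return f"[{self.pi1:g}, {self.pi2:g}]"


#: The 15 design cells of the study, in the order they are conventionally
#: tabulated.
DEFAULT_BASE_RATE_PAIRS: Tuple[BaseRatePair, ...] = tuple(
    BaseRatePair(p1, p2)
    for (p1, p2) in [
        (0.1, 0.1), (0.1, 0.3), (0.1, 0.5), (0.1, 0.7), (0.1, 0.9),
        (0.3, 0.3), (0.3, 0.5), (0.3, 0.7), (0.3, 0.9),
        (0.5, 0.5), (0.5, 0.7), (0.5, 0.9),
        (0.7, 0.7), (0.7, 0.9), (0.9, 0.9),
    ]
)


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the Monte-Carlo trial generator."""

    base_rate_pairs: Tuple[BaseRatePair, ...] = DEFAULT_BASE_RATE_PAIRS
    trials: int = 100_000
    n: int = 2000
    seed: int = 0
    sampler_mode: str = "multinomial"

    def __post_init__(self) -> None:
        pairs = tuple(
            p if isinstance(p, BaseRatePair) else BaseRatePair(*p)
            for p in self.base_rate_pairs
        )
        object.__setattr__(self, "base_rate_pairs", pairs)
        if len(pairs) == 0:
            raise ValueError("at least one base-rate pair is required")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if self.sampler_mode not in SAMPLER_MODES:
            raise ValueError(f"sampler_mode must be one of {SAMPLER_MODES}")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_yaml(self, path=None) -> str:
        payload = {
            "base_rate_pairs": [list(p.as_tuple()) for p in self.base_rate_pairs],
            "trials": self.trials,
            "n": self.n,
            "seed": self.seed,
            "sampler_mode": self.sampler_mode,
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            text = Path(source).read_text()
        elif isinstance(source, io.IOBase):
            text = source.read()
        else:
            text = str(source)
        payload = yaml.safe_load(text) or {}
        kwargs = {}
        if "base_rate_pairs" in payload:
            kwargs["base_rate_pairs"] = tuple(
                BaseRatePair(*p) for p in payload["base_rate_pairs"]
            )
        for key in ("trials", "n", "seed", "sampler_mode"):
            if key in payload:
                kwargs[key] = payload[key]
        return cls(**kwargs)


def cell_probabilities(pair: BaseRatePair) -> np.ndarray:
    """Multinomial cell probabilities of (a, b, c, d) under independence."""
    p1, p2 = pair.pi1, pair.pi2
    return np.array([p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)])


def _pair_seed_sequence(seed: int, pair: BaseRatePair) -> np.random.SeedSequence:
    # Keyed by the pair itself (not its position), so that pairs can be
    # generated in any order, or individually, with identical streams.
    key = (round(pair.pi1 * 10_000), round(pair.pi2 * 10_000))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=key)


def sample_quadruples(
    pair: BaseRatePair,
    n: int,
    rng: np.random.Generator,
    mode: str = "multinomial",
    trials: int = 1,
) -> np.ndarray:
    """Draw ``trials`` quadruples as a ``(trials, 4)`` integer array."""
    if n < 4:
        raise ValueError("n must be >= 4")
    if mode == "multinomial":
        return rng.multinomial(n, cell_probabilities(pair), size=trials).astype(np.int64)
    if mode == "explicit_vectors":
        out = np.empty((trials, 4), dtype=np.int64)
        done = 0
        while done < trials:
            block = min(_EXPLICIT_BLOCK, trials - done)
            x1 = rng.random((block, n)) < pair.pi1
            x2 = rng.random((block, n)) < pair.pi2
            a = (x1 & x2).sum(axis=1)
            b = (x1 & ~x2).sum(axis=1)
            c = (~x1 & x2).sum(axis=1)
            out[done:done + block, 0] = a
            out[done:done + block, 1] = b
            out[done:done + block, 2] = c
            out[done:done + block, 3] = n - a - b - c
            done += block
        return out
    raise ValueError(f"unknown sampler mode {mode!r}")


def sample_quadruple(
    pair: BaseRatePair,
    n: int,
    rng: np.random.Generator,
    mode: str = "multinomial",
) -> ContingencyQuadruple:
    """Draw a single trial as a :class:`ContingencyQuadruple`."""
    a, b, c, d = sample_quadruples(pair, n, rng, mode=mode, trials=1)[0]
    return ContingencyQuadruple(int(a), int(b), int(c), int(d))


def generate_trials(config: SimulationConfig) -> Dict[BaseRatePair, np.ndarray]:
    """Generate the full trial set: one ``(trials, 4)`` array per design cell.

    Each base-rate pair uses an independent child stream derived from the
    master seed and the pair's identity, so the result does not depend on
    generation order.
    """
    out: Dict[BaseRatePair, np.ndarray] = {}
    for pair in config.base_rate_pairs:
        rng = np.random.default_rng(_pair_seed_sequence(config.seed, pair))
        out[pair] = sample_quadruples(
            pair, config.n, rng, mode=config.sampler_mode, trials=config.trials
        )
    return out


def write_trials(trials: Mapping[BaseRatePair, np.ndarray], out_dir) -> None:
    """Write one ``<label>.csv`` per pair with header ``a,b,c,d``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pair, quads in trials.items():
        path = out_dir / f"{pair.label}.csv"
        np.savetxt(path, quads, fmt="%d", delimiter=",", header="a,b,c,d", comments="")


def read_trials(in_dir, pairs: Iterable[BaseRatePair]) -> Dict[BaseRatePair, np.ndarray]:
    in_dir = Path(in_dir)
    out = {}
    for pair in pairs:
        path = in_dir / f"{pair.label}.csv"
        out[pair] = np.loadtxt(path, dtype=np.int64, delimiter=",", skiprows=1)
    return out
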