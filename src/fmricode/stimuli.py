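"""Prototype/distortion stimulus generation.

Stimuli follow the classic prototype-distortion design: a base item is a
vector of independent standard-normal feature activations, and graded
category members are produced by adding Gaussian noise of increasing
standard deviation to the prototype.  Every emitted item is re-normalized
to mean 0 and (population) standard deviation 1, so that the noise level
controls only the *similarity* of a distortion to its prototype, never its
overall scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Prototype",
    "StimulusSet",
    "znormalize",
    "generate_prototype",
    "generate_distortions",
]


class DegenerateInputError(ValueError):
    """Raised when an operation receives a constant (zero-variance) vector."""


def znormalize(v: np.ndarray, *, ddof: int = 0) -> np.ndarray:
    """Center and scale ``v`` to mean 0 and standard deviation 1.

    The population convention (``ddof=0``) is the default so that "sd = 1"
    holds literally for each item.  The map is affine-invariant:
    ``znormalize(a*v + b) == znormalize(v)`` for any ``a > 0``.

    Raises
    ------
    DegenerateInputError
        If ``v`` has fewer than 2 elements or zero variance.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise DegenerateInputError("need a 1-D vector of length >= 2")
    sd = v.std(ddof=ddof)
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateInputError("constant or non-finite vector cannot be z-normalized")
    return (v - v.mean()) / sd


@dataclass(frozen=True)
class Prototype:
    """A z-normalized category prototype and the seed that produced it."""

    values: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def dim(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class StimulusSet:
    """A prototype together with its ordered noise distortions.

    ``distortions`` is an ``(n_levels, dim)`` array; row ``i`` (0-based) is
    the distortion at noise level ``i + 1``.  ``noise_sds`` holds the noise
    standard deviation of each level and increases in constant steps.
    """

    prototype: Prototype
    distortions: np.ndarray
    noise_sds: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "distortions", np.asarray(self.distortions, dtype=float))
        object.__setattr__(self, "noise_sds", np.asarray(self.noise_sds, dtype=float))

    @property
    def n_levels(self) -> int:
        return self.distortions.shape[0]

    def items(self) -> np.ndarray:
        """Prototype plus distortions as a single ``(1 + n_levels, dim)`` array."""
        return np.vstack([self.prototype.values, self.distortions])

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: one row per stimulus, columns are dimensions.

        The index carries the level number (0 = prototype) and the noise
        standard deviation of that level.
        """
        idx = pd.MultiIndex.from_arrays(
            [np.arange(self.n_levels + 1), np.concatenate([[0.0], self.noise_sds])],
            names=["level", "noise_sd"],
        )
        return pd.DataFrame(self.items(), index=idx)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def generate_prototype(dim: int = 100, seed: int | np.random.Generator | None = None) -> Prototype:
    """Draw a prototype of ``dim`` independent N(0, 1) activations, z-normalized.

    Deterministic given an integer seed.  ``dim`` must be at least 2 because
    Pearson similarity is undefined for shorter vectors.
    """
    if dim < 2:
        raise ValueError(f"dim must be >= 2, got {dim}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = znormalize(rng.standard_normal(dim))
    return Prototype(values=values, seed=seed if isinstance(seed, int) else None)


def generate_distortions(
    prototype: Prototype,
    n_levels: int = 19,
    sd_step: float = 0.05,
    seed: int | np.random.Generator | None = None,
    *,
    cumulative: bool = False,
) -> StimulusSet:
    """Create graded noise distortions of ``prototype``.

    Level ``i`` (1-based) adds fresh Gaussian noise of standard deviation
    ``i * sd_step`` to the prototype, then z-normalizes, so each distortion
    is conditionally independent given the prototype.  With
    ``cumulative=True`` the level-``i`` noise (sd ``i * sd_step``) is
    instead added to the running level ``i - 1`` chain, producing a random
    walk away from the prototype.

    Defaults (``n_levels=19``, ``sd_step=0.05``) give noise sds
    0.05, 0.10, ..., 0.95.
    """
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    if sd_step <= 0:
        raise ValueError(f"sd_step must be positive, got {sd_step}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base = prototype.values
    dim = base.size
    rows = np.empty((n_levels, dim))
    chain = base
    for i in range(1, n_levels + 1):
        noise = rng.standard_normal(dim) * (i * sd_step)
        if cumulative:
            chain = chain + noise
            rows[i - 1] = znormalize(chain)
        else:
            rows[i - 1] = znormalize(base + noise)
    noise_sds = sd_step * np.arange(1, n_levels + 1)
    return StimulusSet(prototype=prototype, distortions=rows, noise_sds=noise_sds)
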