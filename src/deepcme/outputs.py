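"""Output functions g_i(x) whose terminal expectations E[g_i(X(T))] are estimated."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["OutputFunction", "SpeciesMoment", "OutputSpec", "default_outputs"]


@dataclass(frozen=True)
class OutputFunction:
    """A named map from state vectors to reals, vectorised over leading axes."""

    name: str
    fn: Callable

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.asarray(self.fn(X), dtype=float)


def SpeciesMoment(species: int, power: int, n_species: int | None = None) -> OutputFunction:
    """g(x) = x_i^m for species index ``species`` (0-based) and moment order ``power``."""
    name = f"X{species + 1}^{power}" if power != 1 else f"X{species + 1}"
    return OutputFunction(name, lambda X, i=species, m=power: X[..., i] ** m)


@dataclass(frozen=True)
class OutputSpec:
    """Ordered collection of R output functions."""

    outputs: tuple

    def __post_init__(self):
        if len(self.outputs) < 1:
            raise ValueError("need at least one output function")

    @property
    def R(self) -> int:
        return len(self.outputs)

    @property
    def names(self) -> list:
        return [o.name for o in self.outputs]

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Evaluate all outputs at states ``X`` (..., n) -> (..., R)."""
        X = np.asarray(X, dtype=float)
        return np.stack([o(X) for o in self.outputs], axis=-1)


def default_outputs(n: int) -> OutputSpec:
    """First two moments of the terminal species: g1 = x_n, g2 = x_n^2."""
    return OutputSpec((SpeciesMoment(n - 1, 1), SpeciesMoment(n - 1, 2)))
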