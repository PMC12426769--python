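"""Discretization schemes for temperature and equivalence ratios.

Three default schemes are provided:

* temperature — 30 uniform 10 °C bins covering −100 to 200 °C;
* reactant amount — 15 custom bins over the equivalence ratio, with
  narrow dedicated bins around the empirically dominant values 1.0,
  1.5, 2.0 and 2.5;
* agent amount — 27 custom bins spanning catalytic (≤10⁻⁴ eq) through
  solvent-scale (≥10³ eq) regimes, so substoichiometric, stoichiometric
  and superstoichiometric usage land in distinct bins.

All bins are half-open ``[lo, hi)``. Values outside the covered range
clip to the first/last bin rather than erroring, since extreme solvent
ratios do occur. Each bin carries a representative value (for the
temperature scheme, the midpoint: the 0–10 °C bin is reported as 5 °C)
used when presenting predictions to a user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import yaml


@dataclass(frozen=True)
class BinScheme:
    """Ordered half-open bins with one representative value per bin."""

    edges: tuple[float, ...]
    representatives: tuple[float, ...]
    name: str = ""

    def __post_init__(self):
        edges = self.edges
        if len(edges) < 2:
            raise ValueError("need at least two edges")
        if any(edges[i] >= edges[i + 1] for i in range(len(edges) - 1)):
            raise ValueError("edges must be strictly increasing")
        if len(self.representatives) != self.n_bins:
            raise ValueError("one representative per bin required")
        for i, rep in enumerate(self.representatives):
            if not (edges[i] <= rep < edges[i + 1]):
                raise ValueError(
                    f"representative {rep} outside bin [{edges[i]}, {edges[i + 1]})"
                )

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, x: float) -> int:
        return assign_bin(x, self)

    def interval(self, i: int) -> tuple[float, float]:
        return (self.edges[i], self.edges[i + 1])

    def content_hash(self) -> str:
        import hashlib

        payload = repr((self.edges, self.representatives)).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "edges": [e if math.isfinite(e) else (".inf" if e > 0 else "-.inf") for e in self.edges],
            "representatives": list(self.representatives),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinScheme":
        def _edge(e):
            if e == ".inf":
                return math.inf
            if e == "-.inf":
                return -math.inf
            return float(e)

        return cls(
            edges=tuple(_edge(e) for e in d["edges"]),
            representatives=tuple(float(r) for r in d["representatives"]),
            name=d.get("name", ""),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "BinScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def assign_bin(x: float, s: BinScheme) -> int:
    """Index of the half-open bin containing ``x``, clipping out-of-range values."""
    if not math.isfinite(x):
        raise ValueError(f"cannot bin non-finite value {x}")
    if x < s.edges[0]:
        return 0
    for i in range(s.n_bins):
        if s.edges[i] <= x < s.edges[i + 1]:
            return i
    return s.n_bins - 1


def bin_distance(i: int, j: int) -> int:
    """Absolute distance between two bin indices."""
    if i < 0 or j < 0:
        raise ValueError("bin indices must be non-negative")
    return abs(i - j)


def temperature_bins() -> BinScheme:
    """30 uniform bins of 10 °C from −100 to 200 °C; 25 °C falls in [20, 30)."""
    edges = tuple(float(-100 + 10 * i) for i in range(31))
    reps = tuple(float(-95 + 10 * i) for i in range(30))
    return BinScheme(edges=edges, representatives=reps, name="temperature")


_REACTANT_EDGES = (
    0.0, 0.5, 0.95, 1.05, 1.15, 1.35, 1.55, 1.95, 2.05,
    2.45, 2.55, 3.5, 5.0, 7.5, 15.0, math.inf,
)
_REACTANT_REPS = (
    0.25, 0.75, 1.0, 1.1, 1.25, 1.5, 1.75, 2.0,
    2.25, 2.5, 3.0, 4.0, 6.0, 10.0, 20.0,
)


def reactant_amount_bins() -> BinScheme:
    """15 bins over the reactant equivalence ratio.

    1.0, 1.5, 2.0 and 2.5 eq each sit inside a narrow dedicated bin,
    matching the sharp peaks of observed stoichiometries.
    """
    return BinScheme(edges=_REACTANT_EDGES, representatives=_REACTANT_REPS, name="reactant_amount")


_AGENT_EDGES = (
    0.0, 1e-4, 3e-4, 1e-3, 3e-3, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5,
    0.8, 0.95, 1.05, 1.25, 1.55, 2.05, 2.55, 3.5, 5.0, 7.5, 10.0,
    20.0, 50.0, 100.0, 300.0, 1000.0, math.inf,
)
_AGENT_REPS = (
    5e-5, 2e-4, 5e-4, 2e-3, 5e-3, 0.015, 0.03, 0.075, 0.15, 0.3,
    0.65, 0.9, 1.0, 1.15, 1.4, 1.8, 2.3, 3.0, 4.0, 6.0, 8.5,
    15.0, 30.0, 75.0, 200.0, 500.0, 1500.0,
)


def agent_amount_bins() -> BinScheme:
    """27 bins over the agent equivalence ratio, ≤1e−4 through ≥1e3.

    Fine resolution in the substoichiometric (catalyst-loading) region,
    dedicated near-1 bins for stoichiometric reagents, and broad
    log-spaced bins for solvent-scale excess.
    """
    return BinScheme(edges=_AGENT_EDGES, representatives=_AGENT_REPS, name="agent_amount")


@dataclass(frozen=True)
class BinSchemes:
    """The three schemes used together throughout the pipeline."""

    temperature: BinScheme
    reactant: BinScheme
    agent: BinScheme

    @classmethod
    def default(cls) -> "BinSchemes":
        return cls(temperature_bins(), reactant_amount_bins(), agent_amount_bins())

    def content_hash(self) -> str:
        import hashlib

        payload = (
            self.temperature.content_hash()
            + self.reactant.content_hash()
            + self.agent.content_hash()
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
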