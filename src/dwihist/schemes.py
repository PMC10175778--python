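"""Diffusion-weighting (b-value) schemes and the FSL-dialect bval sidecar.

The acquisition protocol this package models samples eight b-values,
0-2000 s/mm². Each signal model is fitted on its own subset of that
scheme: the mono-exponential ADC on {0, 800}, the IVIM bi-exponential on
the low-b portion {0, 50, 100, 200, 400} where perfusion still
contributes, and diffusion kurtosis on all eight values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BValueScheme",
    "FULL_SCHEME",
    "MONO_SCHEME",
    "IVIM_SCHEME",
    "DKI_SCHEME",
    "read_bval",
    "write_bval",
]


@dataclass(frozen=True)
class BValueScheme:
    """An ordered set of diffusion weightings, in s/mm².

    Values must be strictly increasing and start at 0 (the unweighted
    reference volume every model normalizes against).
    """

    values: tuple[float, ...] = field(default=(0, 50, 100, 200, 400, 800, 1000, 2000))

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2:
            raise ValueError("a b-value scheme needs at least two values")
        if vals[0] != 0.0:
            raise ValueError("b-value scheme must start at b=0")
        if any(v < 0 for v in vals):
            raise ValueError("b-values must be non-negative")
        if any(b >= a for b, a in zip(vals, vals[1:])):
            raise ValueError("b-values must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def subset(self, keep: tuple[float, ...]) -> "BValueScheme":
        """Restrict to the listed b-values (all must be present)."""
        missing = [b for b in keep if float(b) not in self.values]
        if missing:
            raise ValueError(f"b-values not in scheme: {missing}")
        return BValueScheme(tuple(sorted(float(b) for b in keep)))

    def indices_of(self, other: "BValueScheme") -> np.ndarray:
        """Positions of ``other``'s b-values inside this scheme."""
        pos = {b: i for i, b in enumerate(self.values)}
        try:
            return np.array([pos[b] for b in other.values], dtype=int)
        except KeyError as exc:
            raise ValueError(f"b-value {exc.args[0]} not in scheme") from None


#: Full acquisition scheme (diffusion kurtosis uses all of it).
FULL_SCHEME = BValueScheme((0, 50, 100, 200, 400, 800, 1000, 2000))
#: Mono-exponential ADC subset.
MONO_SCHEME = BValueScheme((0, 800))
#: IVIM low-b subset where pseudo-diffusion is visible.
IVIM_SCHEME = BValueScheme((0, 50, 100, 200, 400))
#: Alias; kurtosis fitting uses every acquired shell.
DKI_SCHEME = FULL_SCHEME


def read_bval(path: str | os.PathLike) -> BValueScheme:
    """Read an FSL-dialect bval sidecar (whitespace-separated, one row)."""
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValueError(f"empty bval file: {path}")
    return BValueScheme(tuple(float(t) for t in tokens))


def write_bval(path: str | os.PathLike, scheme: BValueScheme) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in scheme.values) + "\n")
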