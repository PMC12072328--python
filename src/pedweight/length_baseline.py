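"""Length-zone weight estimation: the tape-style comparison baseline.

A length-based tape maps a child's supine head-to-heel length to the weight
printed on the color zone the length falls in.  The algorithmic contract is
an interval lookup over an ordered, contiguous, non-overlapping partition of
the tape's valid range [45.9, 146.5] cm with non-decreasing zone weights;
lengths outside that range are an error, mirroring the clinical exclusion
rule for children off the tape.

The packaged default table (``data/length_zones_synthetic.csv``) is
synthetic: zone weights are read off this package's synthetic growth curves
at each zone's midpoint length, so the baseline is internally consistent
with the simulated population.  A real tape's printed values can be
substituted via the same CSV schema (lower_cm, upper_cm, label, weight_kg).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "TAPE_MIN_CM",
    "TAPE_MAX_CM",
    "LengthZoneTable",
    "LengthOutOfRangeError",
    "default_zone_table",
    "bt_estimate",
]

TAPE_MIN_CM = 45.9
TAPE_MAX_CM = 146.5


class LengthOutOfRangeError(ValueError):
    """Length falls outside the tape's valid range."""


@dataclass
class LengthZoneTable:
    """Ordered zones (lower inclusive, upper exclusive; final zone closed)."""

    lowers: np.ndarray
    uppers: np.ndarray
    labels: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.lowers = np.asarray(self.lowers, dtype=float)
        self.uppers = np.asarray(self.uppers, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.lowers)
        if not (len(self.uppers) == len(self.labels) == len(self.weights) == n and n > 0):
            raise ValueError("zone arrays must be non-empty and equal length")
        if np.any(self.uppers <= self.lowers):
            raise ValueError("each zone needs upper > lower")
        if not np.allclose(self.lowers[1:], self.uppers[:-1]):
            raise ValueError("zones must be contiguous and sorted")
        if np.any(np.diff(self.weights) < 0):
            raise ValueError("zone weights must be non-decreasing with length")
        if not (
            abs(self.lowers[0] - TAPE_MIN_CM) < 1e-9
            and abs(self.uppers[-1] - TAPE_MAX_CM) < 1e-9
        ):
            raise ValueError(
                f"table must span [{TAPE_MIN_CM}, {TAPE_MAX_CM}] cm exactly"
            )

    @classmethod
    def from_csv(cls, path) -> "LengthZoneTable":
        df = pd.read_csv(path)
        return cls(
            df["lower_cm"].to_numpy(),
            df["upper_cm"].to_numpy(),
            df["label"].astype(str).tolist(),
            df["weight_kg"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "lower_cm": self.lowers,
                "upper_cm": self.uppers,
                "label": self.labels,
                "weight_kg": self.weights,
            }
        ).to_csv(path, index=False)


def default_zone_table() -> LengthZoneTable:
    """The packaged synthetic zone table."""
    ref = resources.files("pedweight.data").joinpath("length_zones_synthetic.csv")
    with resources.as_file(ref) as path:
        return LengthZoneTable.from_csv(path)


def bt_estimate(table: LengthZoneTable, length_cm: float) -> float:
    """Zone weight for a supine length; final zone is upper-inclusive.

    Binary search over zone lower bounds; raises
    :class:`LengthOutOfRangeError` for lengths off the tape.
    """
    if not TAPE_MIN_CM <= length_cm <= TAPE_MAX_CM:
        raise LengthOutOfRangeError(
            f"length {length_cm:.1f} cm outside tape range "
            f"[{TAPE_MIN_CM}, {TAPE_MAX_CM}]"
        )
    i = int(np.searchsorted(table.lowers, length_cm, side="right") - 1)
    i = min(i, len(table.lowers) - 1)  # length == TAPE_MAX_CM lands in last zone
    return float(table.weights[i])
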