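"""Stress-strain curve container with CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StressStrainCurve:
    """Sampled uniaxial response: dimensionless strain vs stress in MPa.

    Invariants: strain strictly increasing, stress(0) ~ 0.
    """

    strain: np.ndarray
    stress: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape:
            raise ValueError("strain/stress length mismatch")
        if self.strain.size >= 2 and not np.all(np.diff(self.strain) > 0):
            raise ValueError("strain samples must be strictly increasing")
        if not (np.isfinite(self.strain).all() and np.isfinite(self.stress).all()):
            raise ValueError("non-finite curve samples")

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.stress))

    def prepeak(self) -> "StressStrainCurve":
        """Samples up to and including the stress maximum."""
        k = self.peak_index
        return StressStrainCurve(self.strain[: k + 1], self.stress[: k + 1],
                                 dict(self.meta))

    def interp(self, strain) -> np.ndarray:
        return np.interp(strain, self.strain, self.stress)

    def to_csv(self, path) -> None:
        pd.DataFrame({"strain": self.strain, "stress_MPa": self.stress}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StressStrainCurve":
        df = pd.read_csv(path)
        return cls(df["strain"].to_numpy(), df["stress_MPa"].to_numpy())
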