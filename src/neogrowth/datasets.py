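"""Observation fixtures and pseudo-data generation.

``load_observations`` returns the packaged day-10/day-21 channel-filling
percentages for the three calcium-phosphate materials (hydroxyapatite HAp,
tricalcium phosphate TCP and their 60/40 blend BCP), pooled across the four
cross-section shapes at each channel size.  ``generate_pseudo_observations``
produces synthetic tables from a known growth coefficient for
parameter-recovery experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .geometry import ChannelSpec

MATERIALS = ("HAp", "TCP", "BCP")

OBS_COLUMNS = ["material", "shape", "d_mm", "day", "filling_pct"]


@dataclass
class ObservationTable:
    """Observed (or synthetic) filling percentages per geometry and day.

    Rows: material, shape (a cross-section name or ``"pooled"`` for the
    mean over shapes), channel size d in mm, day, filling in percent.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(OBS_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")
        self.df = self.df[OBS_COLUMNS].reset_index(drop=True)
        pct = self.df["filling_pct"]
        if (pct < 0).any() or (pct > 100).any():
            raise ValueError("filling_pct must lie in [0, 100]")
        # late observations should not fall below early ones for the same
        # geometry; measurement noise can break this, so warn rather than fail
        for key, grp in self.df.groupby(["material", "shape", "d_mm"]):
            g = grp.sort_values("day")
            if (np.diff(g["filling_pct"].to_numpy()) < 0).any():
                warnings.warn(
                    f"non-monotone filling over days for {key}", stacklevel=2
                )

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservationTable":
        return cls(pd.read_csv(path))


def load_observations(material: str) -> ObservationTable:
    """Packaged filling table for one material (HAp, TCP or BCP)."""
    if material not in MATERIALS:
        raise ValueError(
            f"unknown material {material!r}; expected one of {MATERIALS}"
        )
    src = resources.files("neogrowth.data").joinpath("observations.csv")
    with src.open() as fh:
        df = pd.read_csv(fh)
    return ObservationTable(df[df["material"] == material])


@dataclass
class PseudoDataSpec:
    """Recipe for a synthetic observation table from a known coefficient."""

    A_true: float
    geometries: list[ChannelSpec]
    days: list[float] = field(default_factory=lambda: [10.0, 21.0])
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.geometries:
            raise ValueError("need at least one geometry")


def generate_pseudo_observations(
    spec: PseudoDataSpec, sim_config=None
) -> ObservationTable:
    """Simulate each geometry at ``A_true``, sample the filling at the
    requested days, add seeded Gaussian noise (percentage points) and clip
    to [0, 100].  Deterministic per seed."""
    from .calibrate import SimConfig, simulate_channel_filling

    config = sim_config or SimConfig()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for geom in spec.geometries:
        pct = simulate_channel_filling(
            geom.shape, geom.d, spec.A_true, config, spec.days
        )
        for day in spec.days:
            val = pct[day] + rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else pct[day]
            rows.append(
                {
                    "material": "pseudo",
                    "shape": geom.shape,
                    "d_mm": geom.d,
                    "day": day,
                    "filling_pct": float(np.clip(val, 0.0, 100.0)),
                }
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # noise may break day-monotonicity
        return ObservationTable(pd.DataFrame(rows))
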