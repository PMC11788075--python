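"""Per-gene diel peak timing and per-taxon peak-time profiles.

Each gene's peak is the clock time of its maximum expression over the series
(argmax; invariant to any monotone per-gene transform). Sample times are
classified into day/night with dawn/dusk overlays from the sunrise/sunset
geometry of the series design, and per-taxon profiles summarize what percent
of a taxon's highly expressed genes peak at each time point, whether the
majority peaks in daylight, and whether a sizable fraction peaks during the
dawn or dusk transitions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import circular_distance
from .synthetic import SampleDesign


@dataclass
class PhaseWindows:
    """Day/night partition of sample times with dawn/dusk overlays."""

    sunrise: float
    sunset: float
    dawn_halfwidth: float = 1.5
    dusk_halfwidth: float = 1.5

    @classmethod
    def from_design(cls, design: SampleDesign) -> "PhaseWindows":
        return cls(
            sunrise=design.sunrise,
            sunset=design.sunset,
            dawn_halfwidth=design.dawn_halfwidth,
            dusk_halfwidth=design.dusk_halfwidth,
        )

    def is_day(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t > self.sunrise) & (t < self.sunset)

    def is_dawn(self, t) -> np.ndarray:
        return circular_distance(t, self.sunrise) <= self.dawn_halfwidth

    def is_dusk(self, t) -> np.ndarray:
        return circular_distance(t, self.sunset) <= self.dusk_halfwidth

    def classify(self, t) -> np.ndarray:
        """Map clock times to one of dawn / dusk / morning-day / evening-night.

        The transition overlays take precedence over the plain day/night
        split, dawn before dusk.
        """
        t = np.asarray(t, dtype=float)
        out = np.where(self.is_day(t), "morning/day", "evening/night").astype(object)
        out[self.is_dusk(t)] = "dusk"
        out[self.is_dawn(t)] = "dawn"
        return out


@dataclass
class PeakProfile:
    """Peak-time distribution of one taxon's highly expressed genes."""

    taxon: str
    percents: pd.Series  # time -> percent of genes peaking there (sums to 100)
    majority_phase: str  # day / night / mixed
    dawn_flag: bool
    dusk_flag: bool
    n_genes: int
    n_constant: int = 0

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "percents": {f"{t:04.1f}": float(p) for t, p in self.percents.items()},
            "majority_phase": self.majority_phase,
            "dawn_flag": bool(self.dawn_flag),
            "dusk_flag": bool(self.dusk_flag),
            "n_genes": int(self.n_genes),
            "n_constant": int(self.n_constant),
        }


def zscale_log2(row, pseudocount: float = 1.0) -> tuple[np.ndarray, bool]:
    """log2(x + pseudocount) then z-scale to mean 0, sd 1 (population sd).

    Constant rows are flagged and returned as zeros. Scaling the input by a
    positive constant shifts the log, which the z-scale removes.
    """
    x = np.log2(np.asarray(row, dtype=float) + pseudocount)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def zscale_log2_frame(values: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    x = np.log2(values.to_numpy(dtype=float) + pseudocount)
    sd = x.std(axis=1, keepdims=True)
    centered = x - x.mean(axis=1, keepdims=True)
    out = np.divide(centered, sd, out=np.zeros_like(x), where=sd > 0)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def peak_time(row, design: SampleDesign) -> tuple[float, bool]:
    """Clock time of the maximum value; ties break to the earliest tied time.

    Returns (time, constant_flag); constant rows report the earliest time.
    """
    x = np.asarray(row, dtype=float)
    if x.size == 0:
        raise ValueError("empty expression row")
    if x.size != len(design.sample_times):
        raise ValueError("row length must match the design's sample times")
    if x.size < 2:
        raise ValueError("need at least two timepoints")
    constant = bool(np.all(x == x[0]))
    return float(design.sample_times[int(np.argmax(x))]), constant


def peak_times(values: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Per-gene peak times for a genes x samples matrix."""
    arr = values.to_numpy(dtype=float)
    idx = arr.argmax(axis=1)
    constant = (arr == arr[:, :1]).all(axis=1)
    return pd.DataFrame(
        {
            "peak_time": design.sample_times[idx],
            "constant": constant,
        },
        index=values.index,
    )


def peak_profile(
    taxon: str,
    values: pd.DataFrame,
    design: SampleDesign,
    windows: PhaseWindows | None = None,
    majority_threshold: float = 50.0,
    transition_threshold: float = 20.0,
) -> PeakProfile:
    """Summarize at which times a taxon's genes reach maximum expression.

    majority_phase is "day" ("night") when more than ``majority_threshold``
    percent of genes peak at daylight (night) times, else "mixed"; the dawn
    and dusk flags fire when at least ``transition_threshold`` percent of
    genes peak inside the respective transition window.
    """
    if values.shape[0] < 1:
        raise ValueError("taxon must have at least one gene")
    windows = windows or PhaseWindows.from_design(design)
    peaks = peak_times(values, design)
    counts = peaks["peak_time"].value_counts()
    percents = pd.Series(0.0, index=design.sample_times)
    for t, c in counts.items():
        percents.loc[t] = 100.0 * c / len(peaks)

    t = design.sample_times
    day_pct = float(percents[windows.is_day(t)].sum())
    night_pct = float(percents[~windows.is_day(t)].sum())
    if day_pct > majority_threshold:
        majority = "day"
    elif night_pct > majority_threshold:
        majority = "night"
    else:
        majority = "mixed"
    return PeakProfile(
        taxon=taxon,
        percents=percents,
        majority_phase=majority,
        dawn_flag=float(percents[windows.is_dawn(t)].sum()) >= transition_threshold,
        dusk_flag=float(percents[windows.is_dusk(t)].sum()) >= transition_threshold,
        n_genes=int(values.shape[0]),
        n_constant=int(peaks["constant"].sum()),
    )


def taxon_profiles(
    values: pd.DataFrame,
    catalog: pd.DataFrame,
    design: SampleDesign,
    windows: PhaseWindows | None = None,
) -> dict[str, PeakProfile]:
    """Peak profiles for every taxon with at least one gene in ``values``."""
    taxa = catalog.loc[catalog.index.intersection(values.index), "taxon"]
    out = {}
    for taxon, genes in taxa.groupby(taxa).groups.items():
        out[str(taxon)] = peak_profile(
            str(taxon), values.loc[genes], design, windows=windows
        )
    return out
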