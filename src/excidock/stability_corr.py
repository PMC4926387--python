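"""Per-excipient mean binding affinity vs melting temperature.

The conformational-stability readout of an excipient screen is the melting
temperature Tm of the protein co-formulated with each excipient.  This
module averages the per-pose docking energies that feed each excipient's
consolidated hotspot entries and fits Tm = a + b * <E_bind> by ordinary
least squares, optionally excluding named records (arginine acts as a
negative control in the bundled screen: it binds well but destabilises the
protein through a detergent-like mechanism, so it is excluded from the fit
by default policy rather than hard-coding).

A reference dataset from a published Fab excipient screen (eight common
excipients: two amino acids, two disaccharides, two polyol isomers, two
polysorbate surfactants, with measured Tm and per-pose docking energies)
ships with the package; see :func:`load_reference_dataset`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), used for reported means."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def mean_binding(e_values: Sequence[float], ndigits: int = 2) -> float:
    """Arithmetic mean of per-pose binding energies, reported at 2 decimals
    (half-up)."""
    vals = list(e_values)
    if not vals:
        raise ValueError("need at least one energy value")
    return round_half_up(float(np.mean(vals)), ndigits)


@dataclass
class StabilityRecord:
    excipient: str
    concentration: str
    t_m: float  # degrees C
    e_values: list[float] = field(default_factory=list)
    excluded: bool = False

    @property
    def mean_e(self) -> float:
        return mean_binding(self.e_values)


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    n_used: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "n_used": self.n_used,
        }


def fit_linear(records: Iterable[StabilityRecord]) -> CorrelationResult:
    """OLS fit of Tm on mean binding energy over non-excluded records."""
    used = [r for r in records if not r.excluded]
    if len(used) < 2:
        raise ValueError("need at least 2 non-excluded records")
    x = np.array([r.mean_e for r in used])
    y = np.array([r.t_m for r in used])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in mean binding energies")
    res = stats.linregress(x, y)
    return CorrelationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        n_used=len(used),
    )


def apply_exclusions(records: list[StabilityRecord],
                     exclude: Iterable[str] = ("arginine",)) -> list[StabilityRecord]:
    """Flag named excipients as excluded (case-insensitive); returns records."""
    names = {e.lower() for e in exclude}
    for r in records:
        r.excluded = r.excipient.lower() in names
    return records


def records_from_frame(df: pd.DataFrame) -> list[StabilityRecord]:
    """Build records from a frame with columns excipient, concentration,
    tm_c and either e_values (';'-separated) or mean_e."""
    out = []
    for _, row in df.iterrows():
        if "e_values" in df.columns and isinstance(row["e_values"], str):
            evals = [float(v) for v in row["e_values"].split(";") if v]
        elif "mean_e" in df.columns:
            evals = [float(row["mean_e"])]
        else:
            raise ValueError("frame needs an e_values or mean_e column")
        out.append(StabilityRecord(
            excipient=str(row["excipient"]),
            concentration=str(row.get("concentration", "")),
            t_m=float(row["tm_c"]),
            e_values=evals,
        ))
    return out


def load_reference_dataset() -> list[StabilityRecord]:
    """The bundled Fab excipient screen: Tm and per-pose docking energies."""
    with importlib.resources.files("excidock.data").joinpath(
        "fab_excipient_tm.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    return records_from_frame(df)
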