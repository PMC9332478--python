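"""Internal-standard calibration: detector responses -> concentrations (µg/L).

Quantification follows the usual semi-quantitative GC-MS workflow: each
compound with an authentic standard has a linear calibration
``response = slope * concentration + intercept``; compounds without their own
standard borrow the curve of a structurally similar compound (same chemical
class, nearest retention index).  Cells below the detection limit are flagged
rather than dropped, and "trace" observations carry no numeric value at all.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .catalog_io import CompoundCatalog, MISSING_TOKENS

__all__ = [
    "CalibrationCurve",
    "Measurement",
    "ConcentrationMatrix",
    "QuantificationError",
    "load_curves",
    "internal_standard_concentration",
    "invert_calibration",
    "assign_surrogates",
    "quantify",
]

# censoring flags for concentration cells
OK = "OK"
TRACE = "TRACE"
BELOW_LOD = "BELOW_LOD"
BELOW_LOQ = "BELOW_LOQ"


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear standard curve of one compound, response = slope*conc + intercept."""

    compound_id: int
    slope: float
    intercept: float = 0.0
    r_squared: float | None = None
    loq: float | None = None
    lod: float | None = None
    is_surrogate_for: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise QuantificationError(f"curve {self.compound_id}: zero slope")
        if (
            self.lod is not None
            and self.loq is not None
            and self.lod > self.loq
        ):
            raise QuantificationError(
                f"curve {self.compound_id}: LOD {self.lod} exceeds LOQ {self.loq}"
            )

    def forward(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class Measurement:
    """Replicate detector responses (or a summary) for one sample x compound."""

    sample_id: str
    compound_id: int
    replicate_responses: tuple[float, ...] = ()
    mean: float | None = None
    sd: float | None = None
    n: int | None = None
    trace_flag: bool = False

    def __post_init__(self) -> None:
        if self.trace_flag and (self.replicate_responses or self.mean is not None):
            raise QuantificationError(
                "trace-flagged measurement cannot carry numeric responses"
            )
        if not self.trace_flag:
            if self.replicate_responses:
                if len(self.replicate_responses) < 1:
                    raise QuantificationError("need at least one replicate")
            elif self.mean is None:
                raise QuantificationError("measurement has neither replicates nor summary")
            else:
                if self.n is None or self.n < 1:
                    raise QuantificationError("summary measurement needs n >= 1")
                if self.sd is not None and self.sd < 0:
                    raise QuantificationError("negative sd")


@dataclass
class ConcentrationMatrix:
    """Sample x compound concentration table with censoring flags.

    ``mean``/``sd`` are DataFrames indexed by sample with compound_id columns;
    ``censored`` holds string flags (OK / TRACE / BELOW_LOD / BELOW_LOQ).
    TRACE cells have NaN mean and sd.
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    censored: pd.DataFrame

    def __post_init__(self) -> None:
        for other in (self.sd, self.censored):
            if other.shape != self.mean.shape:
                raise QuantificationError("inconsistent matrix shapes")
            if not (
                other.index.equals(self.mean.index)
                and other.columns.equals(self.mean.columns)
            ):
                raise QuantificationError("inconsistent matrix labels")
        ok = self.censored.isin([OK, BELOW_LOQ])
        bad = self.mean.where(ok) < 0
        if bool(bad.any().any()):
            raise QuantificationError("negative concentration in an OK cell")

    @property
    def samples(self) -> list[str]:
        return list(self.mean.index)

    @property
    def compounds(self) -> list[int]:
        return list(self.mean.columns)

    def numeric(self) -> pd.DataFrame:
        """Means with non-OK cells (TRACE, BELOW_LOD) masked to NaN."""
        return self.mean.where(self.censored.isin([OK, BELOW_LOQ]))

    @classmethod
    def from_summary(
        cls,
        mean: pd.DataFrame,
        sd: pd.DataFrame | None = None,
        censored: pd.DataFrame | None = None,
    ) -> "ConcentrationMatrix":
        if sd is None:
            sd = pd.DataFrame(0.0, index=mean.index, columns=mean.columns)
        if censored is None:
            censored = pd.DataFrame(OK, index=mean.index, columns=mean.columns)
            censored = censored.mask(mean.isna(), TRACE)
        return cls(mean=mean, sd=sd, censored=censored)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (sample, compound, mean, sd, flag)."""
        rows = []
        for s in self.samples:
            for c in self.compounds:
                rows.append(
                    {
                        "sample": s,
                        "compound_id": c,
                        "mean": self.mean.at[s, c],
                        "sd": self.sd.at[s, c],
                        "flag": self.censored.at[s, c],
                    }
                )
        return pd.DataFrame(rows)


def load_curves(path: str | Path) -> list[CalibrationCurve]:
    """Read calibration curves from a CSV with columns compound_id, slope,
    intercept, r_squared, loq, lod (numbers may carry thousands separators)."""

    def num(cell: str | None) -> float | None:
        if cell is None or cell.strip().lower() in MISSING_TOKENS:
            return None
        return float(cell.replace(",", ""))

    curves = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            curves.append(
                CalibrationCurve(
                    compound_id=int(row["compound_id"]),
                    slope=num(row["slope"]),  # type: ignore[arg-type]
                    intercept=num(row.get("intercept")) or 0.0,
                    r_squared=num(row.get("r_squared")),
                    loq=num(row.get("loq")),
                    lod=num(row.get("lod")),
                )
            )
    if not curves:
        raise QuantificationError("no calibration curves in file")
    return curves


def internal_standard_concentration(
    spike_volume_ul: float, spike_strength_ug_per_ul: float, sample_volume_ml: float
) -> float:
    """Concentration (µg/L) of the internal standard in the spiked sample.

    E.g. 1 µL of 0.816 µg/µL 2-methyl-3-heptanone in 5 mL of sample
    -> 0.816 µg / 0.005 L = 163.2 µg/L.
    """
    for v, label in (
        (spike_volume_ul, "spike volume"),
        (spike_strength_ug_per_ul, "spike strength"),
        (sample_volume_ml, "sample volume"),
    ):
        if v <= 0:
            raise QuantificationError(f"nonpositive {label}: {v}")
    return spike_volume_ul * spike_strength_ug_per_ul / (sample_volume_ml / 1000.0)


def invert_calibration(
    curve: CalibrationCurve, response: float
) -> tuple[float, bool]:
    """Solve the calibration line for concentration.

    Returns ``(concentration, clamped)``; negative solutions (responses below
    the intercept crossing) clamp to 0 with ``clamped=True`` so that batch
    runs never produce negative concentrations.
    """
    conc = (response - curve.intercept) / curve.slope
    if conc < 0:
        return 0.0, True
    return conc, False


def assign_surrogates(
    catalog: CompoundCatalog,
    curves: Sequence[CalibrationCurve],
    fallback: Literal["nearest_ri", None] = "nearest_ri",
) -> dict[int, CalibrationCurve]:
    """Map every catalog compound to a calibration curve.

    A compound with its own curve maps to it.  Otherwise it borrows the curve
    of the same chemical class whose owner has the nearest retention index
    (ties broken by lowest curve compound_id).  If its class has no curve,
    ``fallback='nearest_ri'`` borrows the globally RI-nearest curve; with
    ``fallback=None`` such orphans raise an error.
    """
    if not curves:
        raise QuantificationError("need at least one calibration curve")
    by_id = {c.compound_id: c for c in curves}
    cat_by_id = catalog.by_id()

    def ri_of(cid: int) -> float:
        rec = cat_by_id.get(cid)
        if rec is None or rec.retention_index is None:
            return math.inf
        return float(rec.retention_index)

    mapping: dict[int, CalibrationCurve] = {}
    orphans: list[str] = []
    for rec in catalog:
        if rec.compound_id in by_id:
            mapping[rec.compound_id] = by_id[rec.compound_id]
            continue
        candidates = [
            c
            for c in curves
            if c.compound_id in cat_by_id
            and cat_by_id[c.compound_id].compound_class == rec.compound_class
        ]
        if not candidates and fallback == "nearest_ri":
            candidates = list(curves)
        if not candidates:
            orphans.append(rec.name)
            continue
        target_ri = ri_of(rec.compound_id)
        mapping[rec.compound_id] = min(
            candidates,
            key=lambda c: (abs(ri_of(c.compound_id) - target_ri), c.compound_id),
        )
    if orphans:
        raise QuantificationError(
            "no calibration curve available for: " + ", ".join(sorted(orphans))
        )
    return mapping


def quantify(
    measurements: Iterable[Measurement],
    curve_map: dict[int, CalibrationCurve],
    loq_policy: Literal["keep-flag", "censor"] = "keep-flag",
) -> ConcentrationMatrix:
    """Invert replicate responses through each compound's curve and assemble
    the concentration matrix.

    Replicates are inverted individually, then averaged (sample sd, ddof=1).
    Cells whose mean falls below the curve's LOD are flagged BELOW_LOD; cells
    between LOD and LOQ are flagged BELOW_LOQ and, under ``loq_policy=
    'censor'``, have their value suppressed.
    """
    cells: dict[tuple[str, int], tuple[float | None, float | None, str]] = {}
    samples: list[str] = []
    compounds: list[int] = []
    for m in measurements:
        if m.sample_id not in samples:
            samples.append(m.sample_id)
        if m.compound_id not in compounds:
            compounds.append(m.compound_id)
        if m.trace_flag:
            cells[(m.sample_id, m.compound_id)] = (None, None, TRACE)
            continue
        try:
            curve = curve_map[m.compound_id]
        except KeyError:
            raise QuantificationError(
                f"no calibration curve mapped for compound {m.compound_id}"
            ) from None
        if m.replicate_responses:
            concs = np.array(
                [invert_calibration(curve, r)[0] for r in m.replicate_responses]
            )
            mean = float(concs.mean())
            sd = float(concs.std(ddof=1)) if len(concs) > 1 else 0.0
        else:
            mean, _ = invert_calibration(curve, float(m.mean))  # type: ignore[arg-type]
            sd = abs(m.sd / curve.slope) if m.sd is not None else 0.0
        flag = OK
        if curve.lod is not None and mean < curve.lod:
            flag = BELOW_LOD
        elif curve.loq is not None and mean < curve.loq:
            flag = BELOW_LOQ
            if loq_policy == "censor":
                mean, sd = None, None
        if flag == BELOW_LOD:
            mean, sd = None, None
        cells[(m.sample_id, m.compound_id)] = (mean, sd, flag)

    mean_df = pd.DataFrame(np.nan, index=samples, columns=compounds)
    sd_df = pd.DataFrame(np.nan, index=samples, columns=compounds)
    flag_df = pd.DataFrame(TRACE, index=samples, columns=compounds)
    for (s, c), (mean, sd, flag) in cells.items():
        if mean is not None:
            mean_df.at[s, c] = mean
            sd_df.at[s, c] = sd
        flag_df.at[s, c] = flag
    return ConcentrationMatrix(mean=mean_df, sd=sd_df, censored=flag_df)
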