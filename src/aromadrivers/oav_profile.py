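"""Odor activity values (OAV) and aroma-category profiles.

The OAV of a volatile is its concentration divided by its odor detection
threshold; compounds with OAV above 1 are considered aroma-active and are the
only ones that enter a sample's aroma profile.  A profile aggregates the OAVs
of active compounds into descriptor-derived aroma categories (fruity, floral,
sour, ...) via a configurable descriptor -> category map.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .catalog_io import CompoundCatalog
from .quantification import ConcentrationMatrix

__all__ = [
    "OAVMatrix",
    "compute_oav",
    "aroma_active",
    "load_category_map",
    "aggregate_profile",
]


@dataclass
class OAVMatrix:
    """Sample x compound odor activity values; NaN marks an undefined OAV
    (absent threshold, or a trace / below-detection concentration cell)."""

    oav: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.oav.index)

    @property
    def compounds(self) -> list[int]:
        return list(self.oav.columns)


def compute_oav(conc: ConcentrationMatrix, catalog: CompoundCatalog) -> OAVMatrix:
    """OAV[s, c] = concentration mean / odor threshold.

    Undefined (NaN) wherever the catalog records no threshold or the
    concentration cell is not a plain numeric observation.
    """
    thresholds = catalog.thresholds()
    missing = [c for c in conc.compounds if c not in thresholds]
    if missing:
        raise KeyError(f"compounds absent from catalog: {missing}")
    numeric = conc.numeric()
    denom = pd.Series(
        {c: thresholds[c] if thresholds[c] is not None else np.nan
         for c in conc.compounds},
        dtype=float,
    )
    oav = numeric.div(denom, axis=1)
    return OAVMatrix(oav=oav)


def aroma_active(oav: OAVMatrix, cutoff: float = 1.0) -> dict[str, set[int]]:
    """Per-sample set of aroma-active compounds (OAV strictly above cutoff)."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    active = {}
    for s in oav.samples:
        row = oav.oav.loc[s]
        active[s] = set(row.index[(row > cutoff).fillna(False)])
    return active


def load_category_map(path: str | Path | None = None) -> dict[str, set[str]]:
    """Load a descriptor -> aroma-category map (default: packaged YAML).

    Maps category name to the set of catalog descriptor terms that count
    toward it; a descriptor may serve several categories.
    """
    if path is None:
        text = (
            resources.files("aromadrivers.data")
            .joinpath("category_map.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or not raw:
        raise ValueError("category map must be a non-empty mapping")
    cmap: dict[str, set[str]] = {}
    for category, terms in raw.items():
        if not terms:
            raise ValueError(f"category {category!r} has no descriptor terms")
        cmap[str(category)] = {str(t).strip().lower() for t in terms}
    return cmap


def aggregate_profile(
    oav: OAVMatrix,
    catalog: CompoundCatalog,
    category_map: dict[str, set[str]] | None = None,
    cutoff: float = 1.0,
    agg: Literal["sum", "mean", "max"] = "sum",
) -> pd.DataFrame:
    """Sample x category aroma-intensity table.

    A compound contributes its OAV to every category whose descriptor set
    intersects the compound's descriptors, provided the compound is
    aroma-active in that sample.  The per-category aggregator is the sum of
    contributing OAVs by default (mean and max are available).
    """
    if category_map is None:
        category_map = load_category_map()
    by_id = catalog.by_id()
    active = aroma_active(oav, cutoff=cutoff)
    categories = list(category_map)
    out = pd.DataFrame(0.0, index=oav.samples, columns=categories)
    for s in oav.samples:
        for category, terms in category_map.items():
            contrib = [
                float(oav.oav.at[s, c])
                for c in active[s]
                if set(by_id[c].descriptors) & terms
            ]
            if not contrib:
                out.at[s, category] = 0.0
            elif agg == "sum":
                out.at[s, category] = float(np.sum(contrib))
            elif agg == "mean":
                out.at[s, category] = float(np.mean(contrib))
            elif agg == "max":
                out.at[s, category] = float(np.max(contrib))
            else:
                raise ValueError(f"unknown aggregator {agg!r}")
    return out
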