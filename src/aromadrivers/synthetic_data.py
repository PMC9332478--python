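"""Synthetic study generators and packaged reference tables.

Two generators emulate the statistical structure of the study so the whole
pipeline is testable without any external data:

* a hedonic panel of 86 consumers (76 completers) rating 6 products on the
  1-7 scale, with three latent preference clusters of sizes 30/18/28 whose
  archetype mean-liking rows encode the reported qualitative pattern
  (cluster 1 scores low overall but favors B4/B6, cluster 2 favors B2/B3,
  cluster 3 favors B1/B3/B6);
* triplicate GC-MS measurements with per-class log-normal true
  concentrations, responses produced through the forward calibration lines
  with multiplicative CV noise, and random trace cells.

``paper_fixtures`` returns parse-validated copies of the packaged tables
(sample metadata, compound catalog, calibration curves, concentration matrix
with trace flags, and the printed OAV table used for cross-checking).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .catalog_io import CompoundCatalog, load_catalog
from .consumer_panel import ConsumerPanel, load_vocabulary
from .quantification import (
    CalibrationCurve,
    ConcentrationMatrix,
    Measurement,
    load_curves,
)

__all__ = [
    "PanelSpec",
    "gen_liking_panel",
    "gen_comments",
    "ConcSpec",
    "gen_concentrations",
    "FixtureBundle",
    "paper_fixtures",
]

PRODUCTS = ("B1", "B2", "B3", "B4", "B5", "B6")

#: archetype mean liking per cluster, encoding the reported preference
#: pattern with enough separation for reliable recovery at noise sd 1
DEFAULT_ARCHETYPES = np.array(
    [
        [2.2, 2.4, 2.2, 3.8, 2.0, 3.9],   # cluster 1: low overall, favors B4/B6
        [2.6, 5.8, 5.2, 2.6, 2.4, 3.0],   # cluster 2: favors B2/B3
        [5.0, 2.8, 4.8, 2.8, 2.6, 5.2],   # cluster 3: favors B1/B3/B6
    ]
)

#: permanent-residence frequencies (Beijing dominates at ~48%)
DEFAULT_REGIONS = {
    "Beijing": 0.48,
    "Hebei": 0.08,
    "Shanxi": 0.06,
    "Sichuan": 0.06,
    "Chongqing": 0.04,
    "Hunan": 0.04,
    "Heilongjiang": 0.04,
    "Henan": 0.05,
    "Shaanxi": 0.04,
    "Inner Mongolia": 0.03,
    "Hubei": 0.03,
    "Anhui": 0.03,
    "Zhejiang": 0.02,
}


@dataclass
class PanelSpec:
    n_consumers: int = 86
    n_products: int = 6
    cluster_sizes: tuple[int, ...] = (30, 18, 28)
    archetypes: np.ndarray = field(
        default_factory=lambda: DEFAULT_ARCHETYPES.copy()
    )
    noise_sd: float = 1.0
    n_attitude_items: int = 20
    regions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    seed: int = 0

    def __post_init__(self) -> None:
        self.archetypes = np.asarray(self.archetypes, dtype=float)
        if self.archetypes.shape != (len(self.cluster_sizes), self.n_products):
            raise ValueError("archetype matrix shape must be clusters x products")
        if np.any(self.archetypes < 1) or np.any(self.archetypes > 7):
            raise ValueError("archetype means must lie on the 1..7 scale")
        if sum(self.cluster_sizes) > self.n_consumers:
            raise ValueError("cluster sizes exceed the panel size")
        if self.noise_sd < 0:
            raise ValueError("negative noise sd")

    @property
    def n_completers(self) -> int:
        return int(sum(self.cluster_sizes))


def _round_clip(x: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(x), 1, 7).astype(int)


def gen_liking_panel(spec: PanelSpec) -> tuple[ConsumerPanel, pd.Series]:
    """Generate a hedonic panel plus ground-truth cluster labels.

    Each completer's score row is their cluster archetype plus iid Gaussian
    noise, rounded and clipped to 1..7.  Non-completers (panel size minus the
    cluster-size total) additionally get one product score removed at random.
    Fully reproducible from ``spec.seed``; truth labels cover completers only
    (NaN-rated consumers carry label 0).
    """
    rng = np.random.default_rng(spec.seed)
    products = (
        list(PRODUCTS)
        if spec.n_products == len(PRODUCTS)
        else [f"P{i + 1}" for i in range(spec.n_products)]
    )
    n = spec.n_consumers
    n_complete = spec.n_completers

    truth = np.zeros(n, dtype=int)
    rows = np.empty((n, spec.n_products))
    start = 0
    for cl, size in enumerate(spec.cluster_sizes, start=1):
        idx = slice(start, start + size)
        truth[idx] = cl
        rows[idx] = spec.archetypes[cl - 1][None, :] + rng.normal(
            0.0, spec.noise_sd, size=(size, spec.n_products)
        )
        start += size
    # incomplete consumers: draw scores from a random archetype, then drop one
    for i in range(n_complete, n):
        cl = rng.integers(len(spec.cluster_sizes))
        rows[i] = spec.archetypes[cl] + rng.normal(
            0.0, spec.noise_sd, size=spec.n_products
        )
    scores = _round_clip(rows).astype(float)
    for i in range(n_complete, n):
        scores[i, rng.integers(spec.n_products)] = np.nan

    # shuffle consumer order so cluster membership is not positional
    perm = rng.permutation(n)
    scores, truth = scores[perm], truth[perm]

    ids = [f"C{i + 1:03d}" for i in range(n)]
    region_names = list(spec.regions)
    region_p = np.asarray(list(spec.regions.values()), dtype=float)
    region_p = region_p / region_p.sum()
    consumers = pd.DataFrame(
        {
            "gender": rng.choice(["F", "M"], size=n, p=[0.67, 0.33]),
            "age": rng.integers(18, 41, size=n),
            "region": rng.choice(region_names, size=n, p=region_p),
        },
        index=pd.Index(ids, name="consumer_id"),
    )
    # attitude items: 1-7 agreement, mildly cluster-shifted so cluster
    # profiles have structure to summarize
    shift = {0: 0.0, 1: -0.5, 2: 0.5, 3: 0.5}
    att = rng.normal(4.0, 1.2, size=(n, spec.n_attitude_items))
    att += np.array([shift.get(t, 0.0) for t in truth])[:, None]
    for j in range(spec.n_attitude_items):
        consumers[f"att_{j + 1:02d}"] = _round_clip(att[:, j])

    liking = pd.DataFrame(scores, index=consumers.index, columns=products)
    panel = ConsumerPanel(consumers=consumers, liking=liking)
    return panel, pd.Series(truth, index=consumers.index, name="true_cluster")


def gen_comments(
    panel: ConsumerPanel,
    mention_prob: float = 0.4,
    seed: int = 0,
    vocabulary: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Multinomial open-comment table: each consumer x product pair mentions
    one liked and/or one disliked vocabulary term with probability
    ``mention_prob`` per polarity, the liked (disliked) polarity being more
    probable for scores above (below) the scale midpoint."""
    if vocabulary is None:
        vocabulary = load_vocabulary()
    rng = np.random.default_rng(seed)
    records = []
    for cid in panel.liking.index:
        for product in panel.products:
            score = panel.liking.at[cid, product]
            if np.isnan(score):
                continue
            p_like = (score - 1) / 6.0
            for polarity, gate in (("liked", p_like), ("disliked", 1 - p_like)):
                if rng.random() < mention_prob * gate:
                    records.append(
                        {
                            "consumer_id": cid,
                            "product": product,
                            "polarity": polarity,
                            "term": str(rng.choice(vocabulary[polarity])),
                        }
                    )
    return pd.DataFrame(records, columns=["consumer_id", "product", "polarity", "term"])


#: natural-log mean/sd of true concentrations per chemical class, spanning
#: the observed magnitudes (major esters/acids ~1e5-1e7 µg/L, minor
#: compounds ~1e1-1e3 µg/L)
DEFAULT_CLASS_LOGNORM = {
    "ester": (8.5, 1.8),
    "aldehyde": (8.0, 1.5),
    "acid": (9.5, 2.0),
    "alcohol": (10.5, 1.2),
    "ketone": (6.8, 1.0),
    "phenol": (7.0, 1.2),
    "furan": (7.0, 1.3),
    "pyrazine": (7.0, 1.5),
    "other": (6.5, 1.5),
}


@dataclass
class ConcSpec:
    catalog: CompoundCatalog
    n_samples: int = 6
    n_replicates: int = 3
    class_lognorm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_LOGNORM)
    )
    replicate_cv: float = 0.05
    trace_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_cv < 0:
            raise ValueError("negative replicate CV")
        if not 0 <= self.trace_prob <= 1:
            raise ValueError("trace probability outside [0, 1]")


def gen_concentrations(
    spec: ConcSpec, curve_map: dict[int, CalibrationCurve] | None = None
) -> tuple[list[Measurement], pd.DataFrame]:
    """Generate raw replicate responses plus the true mean matrix.

    True sample x compound means are log-normal per chemical class; each
    replicate concentration is the true mean times ``(1 + cv * z)`` pushed
    through the compound's forward calibration line.  Trace cells are
    injected with probability ``trace_prob``.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"B{i + 1}" for i in range(spec.n_samples)]
    if curve_map is None:
        curve_map = {
            rec.compound_id: CalibrationCurve(rec.compound_id, slope=1.0)
            for rec in spec.catalog
        }
    measurements: list[Measurement] = []
    truth = pd.DataFrame(
        np.nan, index=samples, columns=spec.catalog.compound_ids()
    )
    for rec in spec.catalog:
        mu, sigma = spec.class_lognorm[rec.compound_class.value]
        curve = curve_map[rec.compound_id]
        for s in samples:
            if rng.random() < spec.trace_prob:
                measurements.append(
                    Measurement(sample_id=s, compound_id=rec.compound_id, trace_flag=True)
                )
                continue
            true_mean = float(rng.lognormal(mu, sigma))
            truth.at[s, rec.compound_id] = true_mean
            factors = 1.0 + spec.replicate_cv * rng.standard_normal(spec.n_replicates)
            factors = np.clip(factors, 0.0, None)
            responses = tuple(curve.forward(true_mean * f) for f in factors)
            measurements.append(
                Measurement(
                    sample_id=s,
                    compound_id=rec.compound_id,
                    replicate_responses=responses,
                )
            )
    return measurements, truth


@dataclass
class FixtureBundle:
    """Packaged copies of the study's printed tables."""

    samples: pd.DataFrame
    catalog: CompoundCatalog            # printed odor thresholds
    catalog_implied: CompoundCatalog    # thresholds implied by the OAV table
    curves: list[CalibrationCurve]
    concentrations: ConcentrationMatrix
    printed_oav: pd.DataFrame           # compound x product, NaN where unprinted
    concentration_letters: pd.DataFrame


def _data_path(name: str):
    return resources.files("aromadrivers.data").joinpath(name)


def _verify_checksums() -> None:
    checks = json.loads(_data_path("checksums.json").read_text(encoding="utf-8"))
    for name, expected in checks.items():
        digest = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
        if digest != expected:
            raise RuntimeError(f"fixture checksum mismatch for {name}")


def paper_fixtures() -> FixtureBundle:
    """Load and validate the packaged reference tables."""
    _verify_checksums()
    with resources.as_file(_data_path("sample_metadata.csv")) as p:
        samples = pd.read_csv(p, index_col="code")
    with resources.as_file(_data_path("compound_catalog.csv")) as p:
        catalog = load_catalog(p, provenance="packaged compound catalog")
        catalog_implied = load_catalog(
            p,
            provenance="packaged compound catalog (implied thresholds)",
            threshold_column="odor_threshold_implied",
        )
    with resources.as_file(_data_path("calibration_curves.csv")) as p:
        curves = load_curves(p)
    with resources.as_file(_data_path("concentration_matrix.csv")) as p:
        long = pd.read_csv(p)
    mean = long.pivot(index="sample", columns="compound_id", values="mean")
    sd = long.pivot(index="sample", columns="compound_id", values="sd")
    flags = long.pivot(index="sample", columns="compound_id", values="flag")
    letters = long.pivot(index="sample", columns="compound_id", values="letters")
    conc = ConcentrationMatrix(mean=mean, sd=sd, censored=flags)
    with resources.as_file(_data_path("printed_oav.csv")) as p:
        printed = pd.read_csv(p, index_col="compound_id")
    return FixtureBundle(
        samples=samples,
        catalog=catalog,
        catalog_implied=catalog_implied,
        curves=curves,
        concentrations=conc,
        printed_oav=printed,
        concentration_letters=letters,
    )
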