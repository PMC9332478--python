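"""Hedonic consumer panel: completer filtering, liking summaries, region
means, and open-comment elicitation rates.

A panel bundles three tables: one row per consumer (demographics plus 20
attitude items on a 1-7 agreement scale), a consumers x products liking
matrix on the 7-point hedonic scale, and a long table of open-comment terms
(consumer, product, liked/disliked polarity, term from a controlled
vocabulary).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConsumerPanel",
    "filter_completers",
    "liking_summary",
    "region_liking_matrix",
    "elicitation_rates",
    "load_vocabulary",
    "normalize_comments",
]

POLARITIES = ("liked", "disliked")


@dataclass
class ConsumerPanel:
    """Consumer table + liking matrix + optional comment table.

    ``consumers`` is indexed by consumer_id; ``liking`` shares that index and
    has one column per product (NaN = not rated); ``comments`` has columns
    (consumer_id, product, polarity, term).
    """

    consumers: pd.DataFrame
    liking: pd.DataFrame
    comments: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.liking.index.equals(self.consumers.index):
            raise ValueError("liking matrix and consumer table indexes differ")
        vals = self.liking.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 1) & (vals <= 7))
        if not ok.all():
            raise ValueError("liking scores must lie in 1..7")
        if self.comments is not None:
            bad = set(self.comments["polarity"]) - set(POLARITIES)
            if bad:
                raise ValueError(f"unknown comment polarity: {sorted(bad)}")

    @property
    def products(self) -> list[str]:
        return list(self.liking.columns)

    @property
    def n_consumers(self) -> int:
        return len(self.consumers)

    def attitude_items(self) -> pd.DataFrame:
        cols = [c for c in self.consumers.columns if c.startswith("att_")]
        return self.consumers[cols]


def filter_completers(panel: ConsumerPanel) -> ConsumerPanel:
    """Keep only consumers with a liking score for every product."""
    complete = panel.liking.notna().all(axis=1)
    if int(complete.sum()) == 0:
        raise ValueError("no consumer completed all products")
    keep = panel.liking.index[complete]
    comments = panel.comments
    if comments is not None:
        comments = comments[comments["consumer_id"].isin(keep)].reset_index(drop=True)
    return ConsumerPanel(
        consumers=panel.consumers.loc[keep].copy(),
        liking=panel.liking.loc[keep].copy(),
        comments=comments,
    )


def liking_summary(liking: pd.DataFrame) -> pd.DataFrame:
    """Per-product mean, sd, n and rank (1 = best liked); the spread of the
    product means (max - min) is stored under ``.attrs['mean_range']``."""
    if len(liking) < 1:
        raise ValueError("empty liking matrix")
    out = pd.DataFrame(
        {
            "mean": liking.mean(axis=0),
            "sd": liking.std(axis=0, ddof=1),
            "n": liking.notna().sum(axis=0),
        }
    )
    out["rank"] = out["mean"].rank(ascending=False, method="min").astype(int)
    out.attrs["mean_range"] = float(out["mean"].max() - out["mean"].min())
    return out


def region_liking_matrix(
    panel: ConsumerPanel, min_n: int = 1
) -> pd.DataFrame:
    """Region x product mean liking; ``.attrs['n']`` holds per-region counts
    and regions with fewer than ``min_n`` consumers are listed under
    ``.attrs['flagged']``."""
    if "region" not in panel.consumers.columns:
        raise ValueError("panel has no region column")
    regions = panel.consumers["region"]
    mat = panel.liking.groupby(regions).mean()
    counts = panel.liking.groupby(regions).size()
    mat.attrs["n"] = counts.to_dict()
    mat.attrs["flagged"] = sorted(counts.index[counts < min_n])
    return mat


def elicitation_rates(comments: pd.DataFrame, n_panel: int) -> pd.DataFrame:
    """Distinct-consumer mention counts and rates per (term, product,
    polarity).

    A consumer mentioning the same term twice for a product counts once; the
    rate divides by the full panel size, so rates lie in [0, 1].
    """
    if n_panel < 1:
        raise ValueError("panel size must be at least 1")
    if comments.empty:
        return pd.DataFrame(
            columns=["term", "product", "polarity", "count", "rate"]
        )
    counts = (
        comments.drop_duplicates(["consumer_id", "product", "polarity", "term"])
        .groupby(["term", "product", "polarity"])
        .size()
        .rename("count")
        .reset_index()
    )
    counts["rate"] = counts["count"] / n_panel
    return counts


def load_vocabulary(path: str | Path | None = None) -> dict[str, list[str]]:
    """Controlled comment vocabulary: {'liked': [...], 'disliked': [...]}."""
    if path is None:
        text = (
            resources.files("aromadrivers.data")
            .joinpath("comment_vocabulary.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    vocab = yaml.safe_load(text)
    for pol in POLARITIES:
        if pol not in vocab or not vocab[pol]:
            raise ValueError(f"vocabulary lacks {pol!r} terms")
        vocab[pol] = [str(t).strip().lower() for t in vocab[pol]]
    return vocab


def normalize_comments(
    comments: pd.DataFrame, vocabulary: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Map free-text terms onto the controlled vocabulary; out-of-vocabulary
    terms are kept in an 'other' bucket rather than dropped."""
    if vocabulary is None:
        vocabulary = load_vocabulary()
    known = {pol: set(terms) for pol, terms in vocabulary.items()}
    out = comments.copy()
    out["term"] = out["term"].astype(str).str.strip().str.lower()
    in_vocab = [
        term in known.get(pol, set())
        for term, pol in zip(out["term"], out["polarity"])
    ]
    out.loc[~np.asarray(in_vocab), "term"] = "other"
    return out
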