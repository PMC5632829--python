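"""Controlled vocabularies for coded wearable-camera image streams.

Every image record carries a *setting* (where the child was), and — when the
image contains food marketing — a *marketing medium* (the channel carrying
the message) and a *product category*. Product categories are classified as
``core`` (recommended to be marketed to children) or ``non_core`` (not
recommended, under a nutrient-profiling classification in which all fast food
counts as non-core). Detailed settings roll up to aggregate setting groups;
marketing observed in convenience stores and supermarkets is too dense to
code item-by-item and is excluded from analysis, so those two settings map to
the ``excluded`` group.

The vocabulary ships as package data (``data/vocabulary.json``) and is
config-extensible: analyses with extra detailed settings or categories can
load their own mapping with :func:`load_vocabulary`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "Vocabulary",
    "VocabularyError",
    "load_vocabulary",
    "classify_core_status",
    "validate_and_filter",
    "CODED_IMAGE_COLUMNS",
]

#: Required columns of the coded-image table. One row per (image, marketing
#: code); marketing-free images appear once with empty medium/product.
CODED_IMAGE_COLUMNS = ["child_id", "timestamp", "setting", "medium", "product"]

AGGREGATE_GROUPS = frozenset(
    {
        "home",
        "school",
        "food_venues",
        "recreation_venues",
        "other_public_spaces",
        "excluded",
        "unknown",
    }
)


class VocabularyError(ValueError):
    """An input code is outside the closed vocabulary, or a row is malformed."""


@dataclass(frozen=True)
class Vocabulary:
    """Closed code vocabulary: settings, media, product categories.

    Attributes
    ----------
    setting_groups
        Detailed setting label -> aggregate group (one of
        ``home, school, food_venues, recreation_venues, other_public_spaces,
        excluded, unknown``).
    media
        Allowed marketing-medium labels.
    core_status
        Product-category label -> ``core`` or ``non_core``.
    """

    setting_groups: Mapping[str, str]
    media: frozenset = field(default_factory=frozenset)
    core_status: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.setting_groups.values()) - AGGREGATE_GROUPS
        if bad:
            raise VocabularyError(f"unknown aggregate setting group(s): {sorted(bad)}")
        bad = set(self.core_status.values()) - {"core", "non_core"}
        if bad:
            raise VocabularyError(f"core status must be core/non_core, got {sorted(bad)}")

    @property
    def settings(self) -> frozenset:
        return frozenset(self.setting_groups)

    @property
    def products(self) -> frozenset:
        return frozenset(self.core_status)

    def aggregate_setting(self, setting: str) -> str:
        try:
            return self.setting_groups[setting]
        except KeyError:
            raise VocabularyError(f"unknown setting label: {setting!r}") from None

    def marketing_settings(self) -> list[str]:
        """Detailed settings that may carry marketing codes (not excluded/unknown)."""
        return [
            s
            for s, g in self.setting_groups.items()
            if g not in ("excluded", "unknown")
        ]


def load_vocabulary(path: str | None = None) -> Vocabulary:
    """Load the packaged default vocabulary, or a user JSON file.

    The JSON layout is ``{"settings": {label: group}, "media": [...],
    "products": {label: "core"|"non_core"}}``.
    """
    if path is None:
        text = (
            resources.files("camexposure").joinpath("data/vocabulary.json").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    return Vocabulary(
        setting_groups=dict(raw["settings"]),
        media=frozenset(raw["media"]),
        core_status=dict(raw["products"]),
    )


def classify_core_status(category: str, vocab: Vocabulary | None = None) -> str:
    """Return ``core`` or ``non_core`` for a product-category label.

    A total, deterministic lookup on the closed vocabulary: the ten
    non-recommended categories (sugary drinks, fast food, confectionery,
    snack foods, ice cream, diet soft drinks, cookies/cakes/pastries,
    unhealthy milk products, unhealthy cereals, other non-core) map to
    ``non_core``; everything else recognised maps to ``core``.
    """
    vocab = vocab or load_vocabulary()
    try:
        return vocab.core_status[category]
    except KeyError:
        raise VocabularyError(f"unknown product category: {category!r}") from None


def _normalise_labels(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip().str.lower()


def validate_and_filter(
    records: pd.DataFrame,
    vocab: Vocabulary | None = None,
    strict: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Validate a coded-image table and drop excluded-setting rows.

    Parameters
    ----------
    records
        Coded-image table with columns ``child_id, timestamp, setting,
        medium, product``. ``medium``/``product`` are empty (NaN or "") on
        marketing-free images and must be empty/non-empty together.
    vocab
        Vocabulary; packaged default if omitted.
    strict
        In strict mode any vocabulary violation or malformed timestamp raises
        :class:`VocabularyError` naming the offending row. In permissive mode
        labels are lower-cased and whitespace-trimmed first, and rows that
        still fail are rejected and counted rather than raising.

    Returns
    -------
    (retained, report)
        ``retained`` — valid rows whose setting is not in the excluded group,
        sorted by ``(child_id, timestamp)``;
        ``report`` — counts ``{"input": n, "retained": k,
        "excluded_setting": e, "rejected": r}`` with ``k + e + r == n``.

    Notes
    -----
    Rows with an ``unknown`` setting are retained for the exposure-time
    denominator but may not carry marketing codes.
    """
    vocab = vocab or load_vocabulary()
    missing = [c for c in CODED_IMAGE_COLUMNS if c not in records.columns]
    if missing:
        raise VocabularyError(f"coded-image table missing column(s): {missing}")

    df = records.loc[:, CODED_IMAGE_COLUMNS].copy()
    n_input = len(df)
    if n_input == 0:
        empty = df.assign(timestamp=pd.to_datetime(df["timestamp"]))
        return empty, {"input": 0, "retained": 0, "excluded_setting": 0, "rejected": 0}

    if not strict:
        for col in ("setting", "medium", "product"):
            df[col] = _normalise_labels(df[col])
    else:
        for col in ("setting", "medium", "product"):
            df[col] = df[col].fillna("").astype(str)

    if pd.api.types.is_datetime64_any_dtype(df["timestamp"]):
        ts = pd.to_datetime(df["timestamp"])
    else:
        ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad_ts = ts.isna()
    bad_setting = ~df["setting"].isin(vocab.settings)
    has_medium = df["medium"] != ""
    has_product = df["product"] != ""
    bad_medium = has_medium & ~df["medium"].isin(vocab.media)
    bad_product = has_product & ~df["product"].isin(vocab.products)
    bad_pairing = has_medium != has_product
    # unknown setting is a denominator-only placeholder: no marketing allowed
    unknown_marketing = (df["setting"] == "unknown") & has_medium

    bad = bad_ts | bad_setting | bad_medium | bad_product | bad_pairing | unknown_marketing
    if strict and bad.any():
        idx = int(df.index[bad][0])
        row = records.loc[idx]
        if bool(bad_ts.loc[idx]):
            reason = f"malformed timestamp {row['timestamp']!r}"
        elif bool(bad_setting.loc[idx]):
            reason = f"unknown setting {row['setting']!r}"
        elif bool(bad_medium.loc[idx]):
            reason = f"unknown medium {row['medium']!r}"
        elif bool(bad_product.loc[idx]):
            reason = f"unknown product {row['product']!r}"
        elif bool(bad_pairing.loc[idx]):
            reason = "medium and product must be empty or non-empty together"
        else:
            reason = "marketing code on an unknown-setting image"
        raise VocabularyError(f"row {idx}: {reason}")

    df["timestamp"] = ts
    n_rejected = int(bad.sum())
    df = df.loc[~bad]

    groups = df["setting"].map(vocab.setting_groups)
    excluded = groups == "excluded"
    n_excluded = int(excluded.sum())
    retained = (
        df.loc[~excluded]
        .sort_values(["child_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )
    report = {
        "input": n_input,
        "retained": len(retained),
        "excluded_setting": n_excluded,
        "rejected": n_rejected,
    }
    return retained, report
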