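"""Collapse per-image marketing codes into exposure episodes.

An *exposure episode* starts on the first image bearing a particular
(setting, medium, product) code, is extended by every subsequent same-coded
image arriving within the timeout (30 s by default) of the previous one, and
ends once more than the timeout elapses since the last same-coded image. A
later same-coded image then starts a new episode. Episodes for different
code triples are tracked independently, so one image carrying k distinct
codes contributes to k episodes. Overnight gaps and wear gaps longer than
the timeout terminate episodes automatically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .vocab import Vocabulary, load_vocabulary

__all__ = ["segment", "summarise", "SegmentationError"]

CODE_COLS = ["setting", "medium", "product"]

AGG_SETTING_GROUPS = (
    "home",
    "school",
    "food_venues",
    "recreation_venues",
    "other_public_spaces",
)


class SegmentationError(ValueError):
    pass


def segment(
    records: pd.DataFrame,
    timeout: float = 30.0,
    boundary: str = "continue",
    permissive: bool = False,
) -> pd.DataFrame:
    """Segment coded image rows into exposure episodes.

    Parameters
    ----------
    records
        Coded-image rows (possibly several children). Marketing-free rows
        (empty medium) are ignored. Must be sorted by timestamp within child
        unless ``permissive`` (which sorts).
    timeout
        Maximum gap (seconds) between successive same-coded images inside one
        episode.
    boundary
        Whether a gap of exactly ``timeout`` continues the episode
        (``"continue"``, the default reading of "ended when 30 s had
        elapsed") or closes it (``"close"``).
    permissive
        Auto-sort unsorted input instead of raising.

    Returns
    -------
    DataFrame with one row per episode: ``child_id, setting, medium,
    product, start, end, n_images``, ordered by (child, code, start).

    Notes
    -----
    Duplicate identical rows (same child, timestamp and code) are collapsed
    first: one image is one instant of exposure. The gap clock runs from the
    *last* same-coded image, not the episode start.
    """
    if timeout < 0:
        raise SegmentationError("timeout must be non-negative")
    if boundary not in ("continue", "close"):
        raise SegmentationError("boundary must be 'continue' or 'close'")

    df = records.loc[records["medium"].fillna("") != ""].copy()
    if df.empty:
        return pd.DataFrame(
            columns=["child_id", *CODE_COLS, "start", "end", "n_images"]
        )
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if not df.groupby("child_id", observed=True)["timestamp"].apply(
        lambda s: s.is_monotonic_increasing
    ).all():
        if not permissive:
            raise SegmentationError(
                "records not sorted by timestamp within child (use permissive=True to auto-sort)"
            )
    df = df.drop_duplicates(["child_id", "timestamp", *CODE_COLS])
    df = df.sort_values(["child_id", *CODE_COLS, "timestamp"], kind="mergesort")

    t = df["timestamp"].to_numpy("datetime64[ns]").astype("int64") / 1e9
    keys = df[["child_id", *CODE_COLS]]
    new_key = (keys != keys.shift()).any(axis=1).to_numpy()
    gap = np.diff(t, prepend=t[0] if len(t) else 0.0)
    over = gap > timeout if boundary == "continue" else gap >= timeout
    new_episode = new_key | over
    new_episode[0] = True
    ep_id = np.cumsum(new_episode)

    out = (
        df.assign(_ep=ep_id)
        .groupby("_ep", sort=True)
        .agg(
            child_id=("child_id", "first"),
            setting=("setting", "first"),
            medium=("medium", "first"),
            product=("product", "first"),
            start=("timestamp", "first"),
            end=("timestamp", "last"),
            n_images=("timestamp", "size"),
        )
        .reset_index(drop=True)
    )
    return out


def summarise(
    episodes: pd.DataFrame,
    child_record: pd.Series | dict,
    vocab: Vocabulary | None = None,
    seconds_per_photo: float = 7.0,
) -> dict:
    """Roll one child's episodes up to core/non-core margin counts.

    Returns a flat dict with ``child_id``, ``n_photos``, ``exposure_time``
    (= n_photos x seconds_per_photo), totals ``core_total`` /
    ``noncore_total``, and margin counts ``{core|noncore}_setting_<group>``,
    ``..._medium_<label>`` and ``noncore_product_<label>`` (core exposures
    all share the single core product label, so no core product margin is
    emitted). Each margin sums to the matching total.
    """
    vocab = vocab or load_vocabulary()
    rec = dict(child_record)
    child_id = rec["child_id"]
    n_photos = int(rec["n_photos"])
    out: dict = {
        "child_id": child_id,
        "n_photos": n_photos,
        "exposure_time": n_photos * seconds_per_photo,
        "core_total": 0,
        "noncore_total": 0,
    }
    for group in AGG_SETTING_GROUPS:
        out[f"core_setting_{group}"] = 0
        out[f"noncore_setting_{group}"] = 0
    for m in sorted(vocab.media):
        out[f"core_medium_{m}"] = 0
        out[f"noncore_medium_{m}"] = 0
    for p in sorted(vocab.products):
        if vocab.core_status[p] == "non_core":
            out[f"noncore_product_{p}"] = 0

    if len(episodes) == 0:
        return out
    eps = episodes.loc[episodes["child_id"] == child_id]
    for _, ep in eps.iterrows():
        try:
            status = vocab.core_status[ep["product"]]
            group = vocab.aggregate_setting(ep["setting"])
            if ep["medium"] not in vocab.media:
                raise KeyError(ep["medium"])
        except KeyError as err:
            raise SegmentationError(f"episode with unknown code: {err}") from None
        pref = "core" if status == "core" else "noncore"
        out[f"{pref}_total"] += 1
        out[f"{pref}_setting_{group}"] += 1
        out[f"{pref}_medium_{ep['medium']}"] += 1
        if status == "non_core":
            out[f"noncore_product_{ep['product']}"] += 1
    return out


def summarise_children(
    episodes: pd.DataFrame,
    children: pd.DataFrame,
    vocab: Vocabulary | None = None,
    seconds_per_photo: float = 7.0,
) -> pd.DataFrame:
    """Per-child exposure summary table for a whole cohort (vectorised).

    Same margins as :func:`summarise`, one row per child in ``children``
    (children with no episodes get all-zero counts).
    """
    vocab = vocab or load_vocabulary()
    base = children[["child_id", "n_photos"]].copy()
    base["exposure_time"] = base["n_photos"] * seconds_per_photo

    cols: dict[str, pd.Series] = {}
    if len(episodes):
        eps = episodes.copy()
        eps["core_status"] = eps["product"].map(vocab.core_status)
        if eps["core_status"].isna().any():
            bad = eps.loc[eps["core_status"].isna(), "product"].iloc[0]
            raise SegmentationError(f"episode with unknown product: {bad!r}")
        eps["agg_setting"] = eps["setting"].map(vocab.setting_groups)
        pref = eps["core_status"].map({"core": "core", "non_core": "noncore"})
        eps["k_total"] = pref + "_total"
        eps["k_setting"] = pref + "_setting_" + eps["agg_setting"]
        eps["k_medium"] = pref + "_medium_" + eps["medium"]
        eps["k_product"] = np.where(
            eps["core_status"] == "non_core", "noncore_product_" + eps["product"], None
        )
        for key in ("k_total", "k_setting", "k_medium", "k_product"):
            sub = eps.dropna(subset=[key])
            piv = sub.groupby(["child_id", key], observed=True).size().unstack(
                fill_value=0
            )
            for c in piv.columns:
                cols[c] = piv[c]

    names = ["core_total", "noncore_total"]
    names += [f"{p}_setting_{g}" for p in ("core", "noncore") for g in AGG_SETTING_GROUPS]
    names += [f"{p}_medium_{m}" for p in ("core", "noncore") for m in sorted(vocab.media)]
    names += [
        f"noncore_product_{p}"
        for p in sorted(vocab.products)
        if vocab.core_status[p] == "non_core"
    ]
    for name in names:
        s = cols.get(name)
        base[name] = (
            base["child_id"].map(s).fillna(0).astype(int) if s is not None else 0
        )
    return base
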