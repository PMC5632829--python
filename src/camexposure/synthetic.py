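"""Synthetic wearable-camera study generator with known ground truth.

The original field data (privacy-protected images of children's days) cannot
be shared, so this module generates a complete synthetic study with the same
design, to drive recovery and calibration testing against known truth:

* a sampling frame of schools in 9 strata (3 ethnicity groups x 3
  school-decile groups), each school with a Year-8 roll;
* probability-proportional-to-size (PPS) stratified sampling of schools and
  equal-size child samples per school, with inverse-probability sampling
  weights rescaled so weighted stratum shares match population shares;
* per child, four 10-hour wear days photographed every 7 seconds;
* food-marketing exposures arising as a marked episode process: for every
  (detailed setting, marketing medium, product category) triple, episode
  starts follow a Poisson process at a configured per-day intensity, each
  episode lasting a drawn duration; every image whose timestamp falls inside
  an episode emits one coded row for that triple.

Default intensities are calibrated so the aggregate-setting margins equal
observed per-day exposure rates from children's everyday environments
(non-core total 27.3 and core total 12.3 episodes per 10-h day), split
across media and product categories proportional to their observed shares.
The generator returns the true episode log alongside the coded stream, so
segmentation and estimation can be checked against truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .vocab import Vocabulary, load_vocabulary

__all__ = [
    "GeneratorConfig",
    "CohortData",
    "default_intensity_table",
    "build_frame",
    "sample_pps",
    "compute_weights",
    "generate_children",
    "simulate_streams",
    "simulate_cohort",
    "NONCORE_SETTING_RATES",
    "CORE_SETTING_RATES",
]

ETHNICITIES = ("NZE", "Maori", "Pacific")
DECILES = ("low", "medium", "high")

# Calibration targets: observed mean exposure rates (episodes per 10-h day)
# by aggregate setting, and percentage shares by medium / product category.
NONCORE_SETTING_RATES = {
    "home": 8.9,
    "school": 5.3,
    "food_venues": 2.7,
    "recreation_venues": 2.1,
    "other_public_spaces": 8.3,
}
CORE_SETTING_RATES = {
    "home": 5.5,
    "school": 5.3,
    "food_venues": 0.2,
    "recreation_venues": 0.4,
    "other_public_spaces": 0.9,
}
NONCORE_MEDIUM_SHARES = {
    "product_packaging": 63.9,
    "sign": 27.9,
    "instore_marketing": 3.6,
    "print_media": 2.2,
    "screen": 0.6,
    "merchandise": 1.9,
}
CORE_MEDIUM_SHARES = {
    "product_packaging": 73.5,
    "sign": 21.2,
    "instore_marketing": 0.6,
    "print_media": 0.2,
    "screen": 0.5,
    "merchandise": 3.9,
}
NONCORE_PRODUCT_SHARES = {
    "sugary_drinks": 33.4,
    "fast_food": 22.1,
    "confectionery": 11.1,
    "snack_foods": 10.5,
    "ice_cream": 7.0,
    "diet_soft_drinks": 4.9,
    "cookies_cakes_pastries": 4.8,
    "milk_product_unhealthy": 2.8,
    "cereal_unhealthy": 2.5,
    "other_noncore": 0.9,
}

#: First wear day (a Thursday); children wear Thursday through Sunday.
DAY0 = np.datetime64("2014-07-17T08:00:00")

DAY_SECONDS = 36_000  # reporting day: 10 hours


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Study-design and process parameters for the synthetic generator.

    The defaults reproduce the study conditions: 9 ethnicity x decile strata,
    28 sampled schools (3 per stratum plus one extra) of 6 children each
    (n = 168), 4 consecutive 10-hour wear days, one image every 7 seconds,
    and episode intensities calibrated to the observed per-day rates.
    """

    seed: int = 0
    #: candidate schools per stratum in the frame (total ~93 in the region)
    frame_schools_per_stratum: Mapping[tuple, int] | int = 10
    #: schools sampled per stratum; int applies to all strata
    schools_per_stratum: Mapping[tuple, int] | int | None = None
    children_per_school: int = 6
    wear_days: int = 4
    image_interval: float = 7.0  # seconds between images
    wear_seconds: float = 36_000.0  # wear window per day (10 h)
    #: fraction of the wear window randomly removed per day (camera off for
    #: sport/swimming etc.); 0 disables removals
    wear_removal_frac: float = 0.0
    #: per-triple episode intensities (episodes per 10-h day); None -> default
    intensity_table: pd.DataFrame | None = None
    #: episode duration: lognormal with this median (s) and log-sd, floored
    duration_median: float = 45.0
    duration_sigma: float = 0.4
    duration_min: float = 10.0
    #: multiplicative effects on NON-CORE intensities, for recovery and
    #: interaction experiments; keys are labels / (ethnicity, decile) pairs
    ethnicity_multipliers: Mapping[str, float] = field(default_factory=dict)
    decile_multipliers: Mapping[str, float] = field(default_factory=dict)
    interaction_multipliers: Mapping[tuple, float] = field(default_factory=dict)
    #: emit one row per marketing-free image (True) or only marketing rows,
    #: with photo counts still derived from the wear windows (False)
    include_marketing_free: bool = True

    def schools_sampled(self) -> dict:
        """Sampled-school counts per (ethnicity, decile) stratum."""
        if self.schools_per_stratum is None:
            out = {(e, d): 3 for e in ETHNICITIES for d in DECILES}
            out[("NZE", "medium")] = 4  # 28 school slots -> 168 children
            return out
        if isinstance(self.schools_per_stratum, int):
            return {
                (e, d): self.schools_per_stratum
                for e in ETHNICITIES
                for d in DECILES
            }
        return dict(self.schools_per_stratum)

    def frame_counts(self) -> dict:
        if isinstance(self.frame_schools_per_stratum, int):
            return {
                (e, d): self.frame_schools_per_stratum
                for e in ETHNICITIES
                for d in DECILES
            }
        return dict(self.frame_schools_per_stratum)

    def validate(self) -> None:
        if self.image_interval <= 0:
            raise ConfigError("image_interval must be positive")
        if self.wear_seconds <= 0 or self.wear_days <= 0:
            raise ConfigError("wear window and wear days must be positive")
        if not 0 <= self.wear_removal_frac < 1:
            raise ConfigError("wear_removal_frac must be in [0, 1)")
        if self.children_per_school <= 0:
            raise ConfigError("children_per_school must be positive")
        for cell, n in self.frame_counts().items():
            if n <= 0:
                raise ConfigError(f"empty frame stratum {cell}")
        if self.intensity_table is not None:
            if (self.intensity_table["rate_per_day"] < 0).any():
                raise ConfigError("episode intensities must be non-negative")


@dataclass
class CohortData:
    """Everything one synthetic study produces."""

    frame: pd.DataFrame
    schools: pd.DataFrame
    children: pd.DataFrame
    coded: pd.DataFrame
    truth: pd.DataFrame


def _share_weights(shares: Mapping[str, float]) -> dict:
    total = sum(shares.values())
    return {k: v / total for k, v in shares.items()}


def default_intensity_table(vocab: Vocabulary | None = None) -> pd.DataFrame:
    """Per-triple episode intensities calibrated to the observed margins.

    Each aggregate setting's per-day rate is split evenly across its detailed
    settings, then across media and product categories proportional to the
    observed shares (independence across the three axes). Core exposures all
    carry the ``core_food`` product label. Columns: ``setting, medium,
    product, core_status, rate_per_day``.
    """
    vocab = vocab or load_vocabulary()
    groups: dict[str, list] = {}
    for s in vocab.marketing_settings():
        groups.setdefault(vocab.aggregate_setting(s), []).append(s)

    rows = []
    for core_status, setting_rates, medium_shares, product_shares in (
        ("non_core", NONCORE_SETTING_RATES, NONCORE_MEDIUM_SHARES, NONCORE_PRODUCT_SHARES),
        ("core", CORE_SETTING_RATES, CORE_MEDIUM_SHARES, {"core_food": 100.0}),
    ):
        med = _share_weights(medium_shares)
        prod = _share_weights(product_shares)
        for group, group_rate in setting_rates.items():
            for setting in groups[group]:
                s_rate = group_rate / len(groups[group])
                for m, mw in med.items():
                    for p, pw in prod.items():
                        rows.append((setting, m, p, core_status, s_rate * mw * pw))
    return pd.DataFrame(
        rows, columns=["setting", "medium", "product", "core_status", "rate_per_day"]
    )


def build_frame(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the school sampling frame: 9 strata with Year-8 rolls.

    Deterministic given ``config.seed``. Rolls are lognormal (median ~55),
    so PPS selection probabilities vary several-fold within a stratum.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    rows = []
    sid = 0
    for e in ETHNICITIES:
        for d in DECILES:
            n = config.frame_counts()[(e, d)]
            rolls = np.maximum(
                10, np.round(rng.lognormal(np.log(55.0), 0.55, size=n))
            ).astype(int)
            for roll in rolls:
                rows.append((f"S{sid:03d}", e, d, int(roll)))
                sid += 1
    return pd.DataFrame(
        rows, columns=["school_id", "ethnicity_stratum", "decile_group", "year8_roll"]
    )


def sample_pps(
    frame: pd.DataFrame,
    schools_per_stratum: Mapping[tuple, int] | int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Systematic PPS sampling of schools within each stratum.

    Within each (ethnicity, decile) stratum the frame is randomly ordered,
    roll sizes are cumulated, and ``n_h`` systematic points with a random
    start select schools. Each selected school carries its inclusion
    probability ``pi = n_h * roll / sum(rolls in stratum)``. Schools so
    large that ``n_h * roll > sum(rolls)`` are certainty units: they enter
    the sample with probability 1 and the remainder of the stratum is
    sampled systematically.
    """
    out = []
    for (e, d), grp in frame.groupby(
        ["ethnicity_stratum", "decile_group"], sort=True, observed=True
    ):
        n_h = (
            schools_per_stratum
            if isinstance(schools_per_stratum, int)
            else schools_per_stratum[(e, d)]
        )
        if n_h > len(grp):
            raise ConfigError(
                f"stratum ({e},{d}): requested {n_h} schools from frame of {len(grp)}"
            )
        if grp["year8_roll"].sum() <= 0:
            raise ConfigError(f"stratum ({e},{d}): zero total roll")

        # peel off certainty units (n * roll exceeds the remaining total)
        remaining = grp
        certain = []
        while True:
            n_rem = n_h - len(certain)
            total = remaining["year8_roll"].sum()
            big = n_rem * remaining["year8_roll"] > total
            if n_rem == 0 or not big.any():
                break
            certain.extend(remaining.index[big].tolist())
            remaining = remaining.loc[~big]
        sel_parts = []
        if certain:
            c = grp.loc[certain].copy()
            c["inclusion_prob"] = 1.0
            sel_parts.append(c)
        n_rem = n_h - len(certain)
        if n_rem > 0:
            total = remaining["year8_roll"].sum()
            order = rng.permutation(len(remaining))
            shuffled = remaining.iloc[order]
            cum = np.cumsum(shuffled["year8_roll"].to_numpy(float))
            step = total / n_rem
            points = rng.uniform(0, step) + step * np.arange(n_rem)
            pos = np.searchsorted(cum, points, side="right")
            sel = shuffled.iloc[pos].copy()
            sel["inclusion_prob"] = n_rem * sel["year8_roll"].to_numpy(float) / total
            sel_parts.append(sel)
        out.append(pd.concat(sel_parts))
    return pd.concat(out, ignore_index=True)


def compute_weights(
    children: pd.DataFrame, population_shares: Mapping[tuple, float]
) -> pd.Series:
    """Post-stratified sampling weights, normalised to sum to the sample size.

    ``weight_i`` is proportional to (population share of child *i*'s
    ethnicity x decile stratum) / (sample share of that stratum), so weighted
    stratum shares reproduce the population shares by construction.
    """
    n = len(children)
    key = list(zip(children["ethnicity"], children["decile_group"]))
    counts = pd.Series(key).value_counts()
    missing = [c for c in population_shares if counts.get(c, 0) == 0]
    if missing:
        raise ConfigError(f"stratum with zero sampled children: {missing}")
    pop = np.array([population_shares[k] for k in key], float)
    samp = np.array([counts[k] / n for k in key], float)
    w = pop / samp
    return pd.Series(w * n / w.sum(), index=children.index, name="sampling_weight")


def population_shares_from_frame(frame: pd.DataFrame) -> dict:
    """Year-8 population share of each (ethnicity, decile) stratum."""
    totals = frame.groupby(["ethnicity_stratum", "decile_group"], observed=True)[
        "year8_roll"
    ].sum()
    return (totals / totals.sum()).to_dict()


def generate_children(
    schools: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw ``children_per_school`` children per sampled school.

    Children take their school's stratum (recruitment was stratified by
    ethnicity); gender is ~53% female and ages concentrate at 12 years,
    matching the cohort's observed age/gender structure.
    """
    ages = np.array([11, 12, 13, 14])
    age_p = np.array([0.080, 0.753, 0.161, 0.006])
    rows = []
    cid = 0
    for _, s in schools.iterrows():
        for _ in range(config.children_per_school):
            rows.append(
                (
                    f"C{cid:04d}",
                    s["school_id"],
                    s["ethnicity_stratum"],
                    s["decile_group"],
                    "female" if rng.random() < 0.527 else "male",
                    int(rng.choice(ages, p=age_p / age_p.sum())),
                )
            )
            cid += 1
    return pd.DataFrame(
        rows, columns=["child_id", "school_id", "ethnicity", "decile_group", "gender", "age"]
    )


def _noncore_multiplier(config: GeneratorConfig, eth: str, dec: str) -> float:
    m = config.ethnicity_multipliers.get(eth, 1.0)
    m *= config.decile_multipliers.get(dec, 1.0)
    m *= config.interaction_multipliers.get((eth, dec), 1.0)
    return m


def simulate_streams(
    children: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
    vocab: Vocabulary | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate coded image streams and the true episode log.

    For each child-day a wear window is drawn (default the full 10 hours;
    with ``wear_removal_frac > 0`` the window is shortened, emulating
    camera-off periods). Images tick every ``image_interval`` seconds inside
    the window. For every intensity-table triple, episode starts are Poisson
    at ``rate * window/36000`` per day (non-core rates scaled by any stratum
    multipliers), durations are lognormal, and same-triple episodes are made
    sequential (they cannot overlap, since overlapping same-code episodes are
    indistinguishable in coded data). Every image tick inside an episode
    emits a coded row for that triple; a tick inside episodes of k distinct
    triples emits k rows.

    Returns ``(coded, truth, children)`` where ``children`` gains
    ``n_photos`` and ``exposure_time`` (= n_photos x image_interval) columns.
    Marketing-free rows (empty medium/product) are included when
    ``config.include_marketing_free`` and carry a baseline setting drawn per
    child-day.
    """
    config.validate()
    vocab = vocab or load_vocabulary()
    itab = (
        config.intensity_table
        if config.intensity_table is not None
        else default_intensity_table(vocab)
    )
    dt = config.image_interval
    n_children = len(children)
    n_days = config.wear_days
    n_cd = n_children * n_days

    # wear window length per child-day
    win = np.full(n_cd, config.wear_seconds, float)
    if config.wear_removal_frac > 0:
        win *= 1.0 - rng.uniform(0, config.wear_removal_frac, size=n_cd)
    n_img_cd = (np.floor((win - 1e-9) / dt) + 1).astype(int)  # ticks 0, dt, 2dt, ...

    # per child-day x triple intensity matrix
    rates = itab["rate_per_day"].to_numpy(float)
    noncore = (itab["core_status"] == "non_core").to_numpy()
    mult_child = np.array(
        [
            _noncore_multiplier(config, e, d)
            for e, d in zip(children["ethnicity"], children["decile_group"])
        ]
    )
    mult_cd = np.repeat(mult_child, n_days)
    lam = np.outer(win / DAY_SECONDS, rates)
    lam[:, noncore] *= mult_cd[:, None]
    counts = rng.poisson(lam)  # (n_cd, T)

    cd_idx, tr_idx = np.nonzero(counts)
    reps = counts[cd_idx, tr_idx]
    ep_cd = np.repeat(cd_idx, reps)
    ep_tr = np.repeat(tr_idx, reps)
    k = len(ep_cd)

    starts = rng.uniform(0, win[ep_cd])
    durs = np.maximum(
        config.duration_min,
        rng.lognormal(np.log(config.duration_median), config.duration_sigma, size=k),
    )
    # sequential same-triple episodes: sort within (child-day, triple), push
    # each start past the previous episode's end
    order = np.lexsort((starts, ep_tr, ep_cd))
    ep_cd, ep_tr = ep_cd[order], ep_tr[order]
    starts, durs = starts[order], durs[order]
    ends = np.empty(k)
    prev_end = -np.inf
    for i in range(k):
        if i > 0 and ep_cd[i] == ep_cd[i - 1] and ep_tr[i] == ep_tr[i - 1]:
            if starts[i] <= prev_end:
                starts[i] = prev_end + 1e-6
        else:
            prev_end = -np.inf
        ends[i] = starts[i] + durs[i]
        prev_end = ends[i]

    # emit image ticks falling inside each episode (clipped to wear window)
    last_tick = (n_img_cd[ep_cd] - 1) * dt
    k0 = np.ceil(starts / dt).astype(int)
    k1 = np.floor(np.minimum(ends, last_tick) / dt).astype(int)
    n_rows = np.maximum(0, k1 - k0 + 1)
    total = int(n_rows.sum())
    ep_of_row = np.repeat(np.arange(k), n_rows)
    if k:
        row_in_ep = np.arange(total) - np.repeat(
            np.concatenate(([0], np.cumsum(n_rows)[:-1])), n_rows
        )
    else:
        row_in_ep = np.zeros(0, int)
    tick = k0[ep_of_row] + row_in_ep  # image index within the child-day

    child_ids = children["child_id"].to_numpy()
    day_of_cd = np.tile(np.arange(n_days), n_children)
    child_of_cd = np.repeat(np.arange(n_children), n_days)
    base_cd = DAY0 + (day_of_cd * 86_400).astype("timedelta64[s]")

    def _stamp(cd: np.ndarray, seconds: np.ndarray) -> np.ndarray:
        return base_cd[cd] + np.round(seconds).astype("timedelta64[s]")

    settings = itab["setting"].to_numpy()
    media = itab["medium"].to_numpy()
    products = itab["product"].to_numpy()

    coded_mkt = pd.DataFrame(
        {
            "child_id": child_ids[child_of_cd[ep_cd[ep_of_row]]],
            "timestamp": _stamp(ep_cd[ep_of_row], tick * dt),
            "setting": settings[ep_tr[ep_of_row]],
            "medium": media[ep_tr[ep_of_row]],
            "product": products[ep_tr[ep_of_row]],
        }
    )

    truth = pd.DataFrame(
        {
            "child_id": child_ids[child_of_cd[ep_cd]],
            "setting": settings[ep_tr],
            "medium": media[ep_tr],
            "product": products[ep_tr],
            "start": _stamp(ep_cd, starts),
            "end": _stamp(ep_cd, ends),
            "n_images": n_rows,
        }
    )

    if config.include_marketing_free:
        # every tick not covered by a marketing row appears once, uncoded
        all_cd = np.repeat(np.arange(n_cd), n_img_cd)
        all_tick = np.arange(int(n_img_cd.sum())) - np.repeat(
            np.concatenate(([0], np.cumsum(n_img_cd)[:-1])), n_img_cd
        )
        key_all = all_cd.astype(np.int64) * 10_000_000 + all_tick
        key_mkt = ep_cd[ep_of_row].astype(np.int64) * 10_000_000 + tick
        free = ~np.isin(key_all, key_mkt)
        base_setting = rng.choice(
            ["home", "school", "street"], p=[0.5, 0.3, 0.2], size=n_cd
        )
        coded_free = pd.DataFrame(
            {
                "child_id": child_ids[child_of_cd[all_cd[free]]],
                "timestamp": _stamp(all_cd[free], all_tick[free] * dt),
                "setting": base_setting[all_cd[free]],
                "medium": "",
                "product": "",
            }
        )
        coded = pd.concat([coded_mkt, coded_free], ignore_index=True)
    else:
        coded = coded_mkt
    coded = coded.sort_values(["child_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )

    children = children.copy()
    n_photos = np.bincount(child_of_cd, weights=n_img_cd, minlength=n_children)
    children["n_photos"] = n_photos.astype(int)
    children["exposure_time"] = children["n_photos"] * dt
    return coded, truth, children


def simulate_cohort(config: GeneratorConfig) -> CohortData:
    """One-call synthetic study: frame -> PPS schools -> children -> streams."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_frame, r_sample, r_children, r_stream = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    frame = build_frame(config, r_frame)
    schools = sample_pps(frame, config.schools_sampled(), r_sample)
    children = generate_children(schools, config, r_children)
    children["sampling_weight"] = compute_weights(
        children, population_shares_from_frame(frame)
    )
    coded, truth, children = simulate_streams(children, config, r_stream)
    return CohortData(frame, schools, children, coded, truth)
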