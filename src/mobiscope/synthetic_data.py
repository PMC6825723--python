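"""Seeded synthetic-study generator with known ground truth.

Generates a full cohort — multi-domain covariates with a specified
correlation structure, home-anchored daily GPS tracks, classified activity
bouts, injected missingness and outliers — whose latent mobility outcomes
follow a linear model on the square-root scale:

    sqrt(outcome) = intercept + Σ_k beta_k · z(covariate_k) + N(0, noise_sd)

so the downstream association chain is exactly well-specified and
parameter-recovery tests have a known truth.

Construction guarantees (used by the round-trip tests):

* the farthest track waypoint sits exactly at the action-range target;
* the daily convex hull is built in the home-centred planar frame that the
  metric code itself uses, so the computed hull area equals its target to
  float precision (tracks are unprojected/re-projected losslessly);
* daily AGT hours and step counts are laid out so that the 12-h-scaled
  values equal their targets exactly for any registration length.

No attempt is made at realistic human-mobility modelling (road networks,
transport modes); fidelity is to the statistical structure only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime, time, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .activity_metrics import ActivityInterval
from .gps_metrics import DailyTrack, GpsFix, HomeLocation, unproject_local

OUTCOME_COLUMNS = (
    "agt_h",
    "steps",
    "life_space_area_km2",
    "path_distance_km",
    "action_range_km",
)

AR_CAP_KM = 15.0
#: hull-area targets are capped below the area achievable by a fan of
#: waypoints at the action-range radius
AREA_CAP_FRACTION = 0.90

DEFAULT_COVARIATES = [
    # (name, domain, mean, sd) — scales loosely follow a community-dwelling
    # older-adult cohort; gender/education are numeric codes.
    ("age", "demographic", 71.0, 5.5),
    ("gender", "demographic", 0.62, 0.49),
    ("education", "demographic", 14.0, 3.0),
    ("grip_strength", "physical", 282.0, 113.0),
    ("leg_strength", "physical", 1.45, 0.45),
    ("gait_speed", "physical", 1.38, 0.15),
    ("hotap_a", "cognitive", 11.8, 4.5),
    ("attention_window", "cognitive", 50.0, 17.0),
    ("fes", "psychological", 19.3, 4.2),
    ("mpte3", "social", 2.5, 2.0),
    ("isel_tss", "social", 20.7, 3.6),
    ("max_temperature", "environmental", 18.0, 6.0),
]

DEFAULT_CORRELATIONS = {
    ("grip_strength", "leg_strength"): 0.40,
    ("grip_strength", "gait_speed"): 0.30,
    ("leg_strength", "gait_speed"): 0.30,
    ("age", "grip_strength"): -0.30,
    ("age", "gait_speed"): -0.25,
    ("hotap_a", "attention_window"): 0.25,
    ("fes", "gait_speed"): -0.20,
}

DEFAULT_EFFECTS = {
    "agt_h": [("gait_speed", 0.30), ("age", -0.25), ("grip_strength", 0.20)],
    "steps": [("gait_speed", 0.30), ("leg_strength", 0.20)],
    "life_space_area_km2": [("grip_strength", 0.25), ("gender", 0.20)],
    "path_distance_km": [("leg_strength", 0.25), ("education", 0.20)],
    "action_range_km": [("gender", 0.25), ("leg_strength", 0.20)],
}

DEFAULT_INTERCEPTS = {
    "agt_h": 1.05,
    "steps": 98.0,
    "life_space_area_km2": 3.0,
    "path_distance_km": 5.5,
    "action_range_km": 2.9,
}


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimulationConfig:
    n_participants: int = 150
    days_per_participant: Union[int, tuple[int, int]] = 7
    home_center: tuple[float, float] = (50.94, 6.96)  # urban mid-latitude
    home_radius_km: float = 5.0
    covariate_spec: list[tuple[str, str, float, float]] = field(
        default_factory=lambda: list(DEFAULT_COVARIATES))
    correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    effect_spec: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_EFFECTS.items()})
    intercepts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    noise_sd: float = 0.30
    missing_rate: float = 0.03
    missing_mechanism: str = "mcar"
    outlier_rate: float = 0.0
    exceptional_trip_rate: float = 0.0   # plants >15 km fixes to exercise the filter
    day_variability_sd: float = 0.0      # lognormal day-level multiplier (free choice)
    vary_registration: bool = True
    start_date: _date = _date(2020, 6, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not (0 <= self.outlier_rate < 1):
            raise ConfigurationError("outlier_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        lo, hi = self.days_range
        if not (6 <= lo <= hi <= 9):
            raise ConfigurationError("days_per_participant must lie in {6..9}")
        for name, _dom, _mean, sd in self.covariate_spec:
            if sd <= 0:
                raise ConfigurationError(f"sd of covariate {name!r} must be > 0")
        for out, effects in self.effect_spec.items():
            if out not in OUTCOME_COLUMNS:
                raise ConfigurationError(f"unknown outcome {out!r} in effect_spec")
            known = {name for name, *_ in self.covariate_spec}
            for cov, _beta in effects:
                if cov not in known:
                    raise ConfigurationError(
                        f"effect_spec for {out!r} references unknown covariate {cov!r}")
        # correlation matrix must be positive definite
        np.linalg.cholesky(self.correlation_matrix())

    @property
    def days_range(self) -> tuple[int, int]:
        d = self.days_per_participant
        return (d, d) if isinstance(d, int) else (int(d[0]), int(d[1]))

    @property
    def covariate_names(self) -> list[str]:
        return [name for name, *_ in self.covariate_spec]

    def correlation_matrix(self) -> np.ndarray:
        names = self.covariate_names
        idx = {n: i for i, n in enumerate(names)}
        r = np.eye(len(names))
        for (a, b), rho in self.correlations.items():
            if a not in idx or b not in idx:
                raise ConfigurationError(f"correlation names unknown: {(a, b)}")
            r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho
        try:
            np.linalg.cholesky(r)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError("correlation matrix not positive definite") from exc
        return r


@dataclass
class GroundTruth:
    """Latent per-participant targets plus the generating coefficients."""

    targets: pd.DataFrame                       # index: participant id
    betas: dict[str, dict[str, float]]          # generative coefs on z-scores
    std_betas: dict[str, dict[str, float]]      # implied standardized betas
    outcome_sd: dict[str, float]                # model sd of sqrt(outcome)
    mechanism: str = "mcar"

    def to_json_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "betas": self.betas,
            "std_betas": self.std_betas,
            "outcome_sd": self.outcome_sd,
            "targets": {
                str(pid): {c: float(v) for c, v in row.items()}
                for pid, row in self.targets.iterrows()
            },
        }


# ---------------------------------------------------------------------------
# covariates and latent outcome targets
# ---------------------------------------------------------------------------

def simulate_covariates(config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw the participant × covariate table (multivariate normal)."""
    rng = rng or np.random.default_rng(config.seed)
    names = config.covariate_names
    n = config.n_participants
    ids = [f"P{i:04d}" for i in range(n)]
    if n == 0:
        return pd.DataFrame(columns=names, index=pd.Index(ids, name="participant_id"))
    r = config.correlation_matrix()
    z = rng.standard_normal((n, len(names))) @ np.linalg.cholesky(r).T
    means = np.array([c[2] for c in config.covariate_spec])
    sds = np.array([c[3] for c in config.covariate_spec])
    data = means + z * sds
    return pd.DataFrame(data, columns=names,
                        index=pd.Index(ids, name="participant_id"))


def implied_standardized_betas(config: SimulationConfig) -> GroundTruth:
    """Betas and model sds implied by the effect spec (no sampling).

    The standardized beta of covariate k for outcome o is
    beta_k / sd(sqrt o), with sd(sqrt o)² = b'Rb + noise_sd².
    """
    names = config.covariate_names
    idx = {n: i for i, n in enumerate(names)}
    r = config.correlation_matrix()
    betas, std_betas, outcome_sd = {}, {}, {}
    for out in OUTCOME_COLUMNS:
        effects = config.effect_spec.get(out, [])
        b = np.zeros(len(names))
        for cov, beta in effects:
            b[idx[cov]] = beta
        var = float(b @ r @ b) + config.noise_sd ** 2
        sd = math.sqrt(var) if var > 0 else 1.0
        betas[out] = {cov: float(beta) for cov, beta in effects}
        std_betas[out] = {cov: float(beta / sd) for cov, beta in effects}
        outcome_sd[out] = sd
    return GroundTruth(pd.DataFrame(), betas, std_betas, outcome_sd,
                       config.missing_mechanism)


def simulate_mobility_targets(covariates: pd.DataFrame, config: SimulationConfig,
                              rng: Optional[np.random.Generator] = None
                              ) -> GroundTruth:
    """Latent outcome targets: linear on the sqrt scale, squared, clipped.

    Negative linear predictors clip to zero before squaring; action-range
    targets cap at 15 km and hull-area targets at 90% of the disc-sector
    area reachable at that range (so the track constructor can realise them).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    truth = implied_standardized_betas(config)
    n = len(covariates)
    cols = {}
    z = {}
    for name, _dom, mean, sd in config.covariate_spec:
        z[name] = (covariates[name].to_numpy(dtype=float) - mean) / sd
    for out in OUTCOME_COLUMNS:
        lp = np.full(n, config.intercepts[out], dtype=float)
        for cov, beta in config.effect_spec.get(out, []):
            lp = lp + beta * z[cov]
        lp = lp + rng.standard_normal(n) * config.noise_sd
        cols[out] = np.clip(lp, 0.0, None) ** 2
    cols["action_range_km"] = np.clip(cols["action_range_km"], 0.0, AR_CAP_KM)
    area_cap = AREA_CAP_FRACTION * math.pi * cols["action_range_km"] ** 2
    cols["life_space_area_km2"] = np.minimum(cols["life_space_area_km2"], area_cap)
    truth.targets = pd.DataFrame(cols, index=covariates.index)
    return truth


# ---------------------------------------------------------------------------
# track construction
# ---------------------------------------------------------------------------

def _fan_waypoints(ar_km: float, area_km2: float, rng: np.random.Generator,
                   n_arc: int = 24) -> np.ndarray:
    """Planar waypoints (km) whose convex hull with the origin has the given
    area while the farthest point sits exactly at ``ar_km``."""
    theta0 = rng.uniform(0.0, 2 * math.pi)
    if ar_km <= 0:
        return np.zeros((1, 2))
    if area_km2 <= 0:
        # straight out-and-back: collinear, zero-area hull
        return np.array([[0.0, 0.0],
                         [ar_km * math.sin(theta0), ar_km * math.cos(theta0)]])

    def fan(phi: float) -> np.ndarray:
        angles = theta0 + np.linspace(0.0, phi, n_arc)
        return np.column_stack([ar_km * np.sin(angles), ar_km * np.cos(angles)])

    def hull_area(phi: float) -> float:
        from shapely.geometry import MultiPoint
        pts = np.vstack([[0.0, 0.0], fan(phi)])
        return MultiPoint(pts).convex_hull.area

    phi_max = 2 * math.pi * (n_arc - 1) / n_arc
    target = min(area_km2, hull_area(phi_max))
    lo, hi = 1e-9, phi_max
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if hull_area(mid) < target:
            lo = mid
        else:
            hi = mid
    return np.vstack([[0.0, 0.0], fan(0.5 * (lo + hi))])


def _densify(waypoints: np.ndarray, step_km: float) -> np.ndarray:
    """Insert points along each segment so consecutive fixes are ~step apart."""
    pts = [waypoints[0]]
    for a, b in zip(waypoints[:-1], waypoints[1:]):
        seg = float(np.hypot(*(b - a)))
        k = max(1, int(math.ceil(seg / step_km)))
        for j in range(1, k + 1):
            pts.append(a + (b - a) * (j / k))
    return np.array(pts)


def simulate_day_track(
    home: HomeLocation,
    participant_id: str,
    day: _date,
    ar_km: float,
    area_km2: float,
    distance_km: float,
    rng: np.random.Generator,
    exceptional_trip: bool = False,
) -> DailyTrack:
    """Construct one day's GPS track realising the given targets.

    The route is home → fan of arc waypoints at the action-range radius →
    home, densified to ~1-minute fixes, padded with short out-and-back
    pacing legs until the cumulative path length reaches ``distance_km``
    (when the geometry alone falls short).  ``exceptional_trip`` appends a
    single fix beyond the 15-km filter radius.
    """
    if not (0.0 <= ar_km <= AR_CAP_KM):
        raise ConfigurationError("action-range target must be in [0, 15] km")
    if ar_km <= 0:
        xy = np.zeros((20, 2))
    else:
        way = _fan_waypoints(ar_km, area_km2, rng)
        route = np.vstack([way, [[0.0, 0.0]]])
        seglen = np.hypot(*np.diff(route, axis=0).T)
        base_len = float(seglen.sum())
        extra = max(0.0, distance_km - base_len)
        if extra > 0:
            # pacing: shuttle between home and a point on the first ray
            u = way[1] / np.hypot(*way[1])
            leg = min(0.5, ar_km / 2)
            q = u * leg
            n_full, rem = divmod(extra, 2 * leg)
            pacing = []
            for _ in range(int(n_full)):
                pacing += [q, [0.0, 0.0]]
            if rem > 0:
                pacing += [u * (rem / 2), [0.0, 0.0]]
            route = np.vstack([route, np.array(pacing)])
        total = float(np.hypot(*np.diff(route, axis=0).T).sum())
        xy = _densify(route, step_km=max(total / 600.0, 0.02))
    if exceptional_trip:
        bearing = rng.uniform(0, 2 * math.pi)
        xy = np.vstack([xy, 20.0 * np.array([math.sin(bearing), math.cos(bearing)])])

    lats, lons = unproject_local(xy[:, 0], xy[:, 1], home)
    t0 = datetime.combine(day, time(9, 0), tzinfo=timezone.utc)
    fixes = [
        GpsFix(t0 + timedelta(minutes=i), float(la), float(lo))
        for i, (la, lo) in enumerate(zip(np.atleast_1d(lats), np.atleast_1d(lons)))
    ]
    return DailyTrack(participant_id, day, fixes)


# ---------------------------------------------------------------------------
# activity construction
# ---------------------------------------------------------------------------

#: registration lengths whose ratio to 12 h is exactly representable in binary,
#: keeping the scale/unscale round trip loss-free
_REGISTRATION_CHOICES = (9.0, 10.5, 12.0, 13.5)


def simulate_activity_day(
    participant_id: str,
    day: _date,
    agt_scaled_h: float,
    steps_scaled: float,
    rng: np.random.Generator,
    vary_registration: bool = True,
) -> list[ActivityInterval]:
    """Construct one day of bouts whose 12-h-scaled AGT/steps equal the targets.

    Raw values are pre-divided by the 12/registration factor so that the
    scaling step recovers the targets exactly.  Above-threshold time goes
    into a single 4.5-MET gait bout; steps with no qualifying AGT go into a
    2.5-MET active bout; the rest of the registration window is ≤3-MET
    filler.  All bouts lie inside 07:00–21:00.
    """
    if agt_scaled_h < 0 or steps_scaled < 0:
        raise ConfigurationError("activity targets must be >= 0")
    reg = float(rng.choice(_REGISTRATION_CHOICES)) if vary_registration else 12.0
    agt_raw = agt_scaled_h * reg / 12.0
    steps_raw = steps_scaled * reg / 12.0
    if agt_raw > reg - 1.0:
        raise ConfigurationError(
            f"AGT target {agt_scaled_h} h cannot fit a {reg} h registration day")

    tz = timezone.utc
    t = datetime.combine(day, time(7, 0), tzinfo=tz)
    intervals: list[ActivityInterval] = []

    def add(hours: float, cls: str, met: float, steps: float = 0.0) -> None:
        nonlocal t
        if hours <= 0:
            return
        end = t + timedelta(hours=hours)
        intervals.append(ActivityInterval(t, end, cls, met, steps))
        t = end

    add(0.5, "other", 1.3)
    if agt_raw > 0:
        add(agt_raw, "gait", 4.5, steps_raw)
    elif steps_raw > 0:
        add(min(1.0, reg - 0.5), "active", 2.5, steps_raw)
    used = sum(iv.hours for iv in intervals)
    add(reg - used, "other", 1.5)
    return intervals


# ---------------------------------------------------------------------------
# missingness and outliers
# ---------------------------------------------------------------------------

def inject_missingness(
    table: pd.DataFrame,
    rate: float,
    mechanism: str = "mcar",
    rng: Optional[np.random.Generator] = None,
    protect: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask cells of ``table`` and return ``(masked table, boolean mask)``.

    Mechanisms: ``mcar`` masks every cell independently with probability
    ``rate``; ``mar`` masks cells of each column with probability
    ``min(1, 5·rate)`` for rows in the top decile of the *first* column
    (which itself stays observed); ``mnar`` masks each cell in the top
    decile of its *own* column with probability 0.5.  Columns listed in
    ``protect`` are never masked.
    """
    if not (0 <= rate < 1):
        raise ConfigurationError("missing rate must be in [0, 1)")
    rng = rng or np.random.default_rng()
    out = table.copy()
    maskable = [c for c in table.columns if c not in protect]
    mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    if not maskable or len(table) == 0:
        return out, mask

    if mechanism == "mcar":
        m = rng.random((len(table), len(maskable))) < rate
    elif mechanism == "mar":
        driver = table[maskable[0]].to_numpy(dtype=float)
        hi = driver >= np.quantile(driver, 0.9)
        p = np.where(hi, min(1.0, 5 * rate), 0.0)[:, None]
        m = rng.random((len(table), len(maskable))) < p
        m[:, 0] = False  # the driver stays observed
    elif mechanism == "mnar":
        vals = table[maskable].to_numpy(dtype=float)
        hi = vals >= np.quantile(vals, 0.9, axis=0)
        m = (rng.random(vals.shape) < 0.5) & hi
    else:
        raise ConfigurationError(f"unknown missingness mechanism {mechanism!r}")

    for j, col in enumerate(maskable):
        out.loc[m[:, j], col] = np.nan
        mask[col] = m[:, j]
    return out, mask


def inject_outliers(
    table: pd.DataFrame,
    rate: float,
    rng: Optional[np.random.Generator] = None,
    factor: float = 8.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace a random ``rate`` fraction of cells with far-fence values."""
    if not (0 <= rate < 1):
        raise ConfigurationError("outlier rate must be in [0, 1)")
    rng = rng or np.random.default_rng()
    out = table.copy()
    where = pd.DataFrame(False, index=table.index, columns=table.columns)
    for col in table.columns:
        vals = table[col].to_numpy(dtype=float)
        hit = rng.random(len(vals)) < rate
        if not hit.any():
            continue
        sd = np.nanstd(vals) or 1.0
        sign = rng.choice([-1.0, 1.0], size=int(hit.sum()))
        out.loc[hit, col] = np.nanmean(vals) + sign * factor * sd
        where[col] = hit
    return out, where


# ---------------------------------------------------------------------------
# full study bundle
# ---------------------------------------------------------------------------

def simulate_homes(config: SimulationConfig, rng: np.random.Generator
                   ) -> pd.DataFrame:
    """Home locations uniform in a disc around the configured centre."""
    n = config.n_participants
    clat, clon = config.home_center
    center = HomeLocation(clat, clon)
    r = config.home_radius_km * np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * math.pi, n)
    lat, lon = unproject_local(r * np.sin(th), r * np.cos(th), center)
    return pd.DataFrame({"home_lat": np.atleast_1d(lat), "home_lon": np.atleast_1d(lon)},
                        index=pd.Index([f"P{i:04d}" for i in range(n)],
                                       name="participant_id"))


def generate_study(config: SimulationConfig, out_dir: Union[str, Path]) -> Path:
    """Write a complete on-disk study bundle; deterministic in the seed.

    Layout::

        out_dir/
          participants.csv          # id, home, covariates (blank = missing)
          gps/<id>_<date>.csv
          activity/<id>_<date>.csv
          truth.json

    Returns ``out_dir`` as a :class:`~pathlib.Path`.
    """
    from . import cli_io

    out = Path(out_dir)
    (out / "gps").mkdir(parents=True, exist_ok=True)
    (out / "activity").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    covariates = simulate_covariates(config, rng)
    truth = simulate_mobility_targets(covariates, config, rng)
    homes = simulate_homes(config, rng)

    masked, mask = inject_missingness(
        covariates, config.missing_rate, config.missing_mechanism, rng)
    if config.outlier_rate > 0:
        masked, _ = inject_outliers(masked, config.outlier_rate, rng)

    participants = homes.join(masked)
    participants.to_csv(out / "participants.csv", float_format="%.10g")

    lo, hi = config.days_range
    day_counts = rng.integers(lo, hi + 1, size=config.n_participants)
    for i, pid in enumerate(covariates.index):
        home = HomeLocation(float(homes.loc[pid, "home_lat"]),
                            float(homes.loc[pid, "home_lon"]))
        tg = truth.targets.loc[pid]
        for d in range(int(day_counts[i])):
            day = config.start_date + timedelta(days=d)
            mult = (float(np.exp(rng.normal(0.0, config.day_variability_sd)))
                    if config.day_variability_sd > 0 else 1.0)
            exceptional = (config.exceptional_trip_rate > 0
                           and rng.random() < config.exceptional_trip_rate)
            # AR-max is a period maximum: realise it exactly on day 0 and
            # never exceed it on later days
            ar = tg["action_range_km"] if d == 0 else tg["action_range_km"] * min(1.0, mult)
            area = min(tg["life_space_area_km2"] * mult,
                       AREA_CAP_FRACTION * math.pi * ar ** 2)
            track = simulate_day_track(
                home, pid, day, float(ar), float(area),
                float(tg["path_distance_km"] * mult), rng,
                exceptional_trip=exceptional)
            cli_io.write_gps_csv(track, out / "gps" / f"{pid}_{day.isoformat()}.csv")
            intervals = simulate_activity_day(
                pid, day, float(tg["agt_h"] * mult), float(tg["steps"] * mult),
                rng, config.vary_registration)
            cli_io.write_activity_csv(
                pid, intervals, out / "activity" / f"{pid}_{day.isoformat()}.csv")

    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    return out
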