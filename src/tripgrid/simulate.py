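"""Synthetic labeled telemetry cohorts.

Generates per-second GPS fixes for a cohort of normal and abnormal
(MCI-like) drivers on an axis-aligned lattice of streets, emulating the
signal content of an in-vehicle telematics logger: coordinates, device
speed over ground (SOG) with sensor noise, and GPS position jitter.

Normal drivers hold a smooth cruise speed (an Ornstein-Uhlenbeck profile)
and make clean 90-degree turns at intersections. Abnormal drivers run the
same machinery but, in episode windows of 10-60 s, probabilistically
exhibit the anomaly motifs associated with cognitive impairment: erratic
speed oscillation, unexplained mid-block near-stops (hesitation), and
loop/backtrack detours (wandering). Every second inside such an episode is
marked in an ``anomalous`` column so that tests can verify the weak-label
structure: *all* segments of an abnormal driver are labeled 1 even though
only a fraction contain an injected episode.

The lattice geometry is a deliberate stand-in that keeps occupancy-grid
shapes (straight runs, L and U turns, loops) interpretable; it makes no
claim about real road networks or clinically validated MCI kinematics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gridding import KM_PER_DEG

__all__ = [
    "PhenotypeParams",
    "SimulationConfig",
    "NORMAL_PHENOTYPE",
    "ABNORMAL_PHENOTYPE",
    "simulate_trip",
    "simulate_cohort",
]

_BLOCK_M = 125.0  # lattice street spacing
_TURN_SPEED_KPH = 12.0
_HEADINGS = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, -1.0], [-1.0, 0.0]])  # N, E, S, W


@dataclass(frozen=True)
class PhenotypeParams:
    """Kinematic profile of one driver class.

    Episode probabilities apply per 10-60 s window and are zero for the
    normal phenotype; ``turn_rate`` is the expected number of turns per km.
    """

    label: int
    base_speed_kph: float = 35.0
    speed_jitter_kph: float = 2.0
    turn_rate_per_km: float = 5.0
    erratic_prob: float = 0.0
    hesitation_prob: float = 0.0
    wander_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.base_speed_kph <= 0:
            raise ValueError("base_speed_kph must be positive")
        for name in ("erratic_prob", "hesitation_prob", "wander_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.erratic_prob + self.hesitation_prob + self.wander_prob > 1.0:
            raise ValueError("episode probabilities must sum to <= 1")


NORMAL_PHENOTYPE = PhenotypeParams(label=0)
# Episode rates chosen so roughly half of an abnormal driver's minutes are
# clean driving, matching the premise that abnormal drivers exhibit both
# normal and anomalous behavior.
ABNORMAL_PHENOTYPE = PhenotypeParams(
    label=1,
    base_speed_kph=35.0,
    speed_jitter_kph=4.0,
    turn_rate_per_km=5.0,
    erratic_prob=0.30,
    hesitation_prob=0.20,
    wander_prob=0.20,
)


@dataclass(frozen=True)
class SimulationConfig:
    n_drivers: int = 20
    abnormal_fraction: float = 0.5
    trips_per_driver: int = 2
    trip_duration_s: int = 300
    sample_hz: int = 1
    origin_lat: float = 26.37
    origin_lon: float = -80.10
    gps_noise_m: float = 12.0
    sog_noise_kph: float = 1.0
    stop_prob: float = 0.15  # chance of a signal/stop-sign halt per intersection
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drivers < 2 and 0.0 < self.abnormal_fraction < 1.0:
            raise ValueError("need >= 2 drivers to represent both labels")
        if not 0.0 <= self.abnormal_fraction <= 1.0:
            raise ValueError("abnormal_fraction must be in [0, 1]")
        if self.sample_hz != 1:
            raise ValueError("only 1 Hz sampling is supported")


def _draw_episode(rng: np.random.Generator, ph: PhenotypeParams) -> str:
    u = rng.random()
    if u < ph.erratic_prob:
        return "erratic"
    if u < ph.erratic_prob + ph.hesitation_prob:
        return "hesitation"
    if u < ph.erratic_prob + ph.hesitation_prob + ph.wander_prob:
        return "wander"
    return "clean"


def simulate_trip(
    phenotype: PhenotypeParams,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One trip of per-second fixes on the street lattice.

    Returns columns ``timestamp, lat, lon, sog_kph, anomalous``; the
    ``anomalous`` flag marks seconds inside an injected episode (always
    False for the normal phenotype) and is a simulator side-channel, not
    part of the telemetry CSV schema.
    """
    n = int(cfg.trip_duration_s)
    if n < 3:
        raise ValueError(f"trip duration {n} s too short (need >= 3 s)")

    p_turn = min(phenotype.turn_rate_per_km * _BLOCK_M / 1000.0, 0.9)
    x = y = 0.0  # meters east / north of the trip origin
    heading = int(rng.integers(4))
    v = phenotype.base_speed_kph / 3.6  # m/s
    target = phenotype.base_speed_kph / 3.6
    sigma = phenotype.speed_jitter_kph / 3.6
    wander_dir = 1
    last_turn = 1 if rng.random() < 0.5 else -1
    straight_left = 0  # blocks to commit straight after a route turn

    xs = np.empty(n)
    ys = np.empty(n)
    speeds = np.empty(n)
    anom = np.zeros(n, dtype=bool)

    episode = "clean"
    ep_left = 0
    hesit_at = -1
    hesit_len = 0
    stop_left = 0  # seconds remaining at a traffic control

    for t in range(n):
        if ep_left == 0:
            ep_left = int(rng.integers(10, 61))
            episode = _draw_episode(rng, phenotype)
            if episode == "hesitation":
                hesit_at = t + int(rng.integers(2, max(3, ep_left - 8)))
                hesit_len = int(rng.integers(8, 21))
            elif episode == "wander":
                # sustained circling/backtracking: turn the same way at every
                # intersection for the whole episode
                wander_dir = 1 if rng.random() < 0.5 else -1
        ep_left -= 1
        anom[t] = episode != "clean"

        # target speed for this second
        if episode == "erratic":
            target = (
                phenotype.base_speed_kph / 3.6
                + (15.0 / 3.6) * math.sin(2.0 * math.pi * t / 8.0)
                + rng.normal(0.0, 2.0 * sigma)
            )
        elif episode == "hesitation" and hesit_at <= t < hesit_at + hesit_len:
            target = 4.0 / 3.6  # sustained mid-block crawl, longer than a light
        else:
            target = phenotype.base_speed_kph / 3.6

        # traffic controls halt everyone, normal and abnormal alike
        if stop_left > 0:
            stop_left -= 1
            target = 0.0

        # Ornstein-Uhlenbeck relaxation toward the target
        v += 0.4 * (target - v) + rng.normal(0.0, sigma)
        v = max(v, 0.0)

        # advance along the lattice, turning only at intersections
        d = v  # 1 s step
        while d > 0:
            hx, hy = _HEADINGS[heading]
            along = x * hx + y * hy
            next_node = math.floor(along / _BLOCK_M + 1e-9) * _BLOCK_M + _BLOCK_M
            gap = next_node - along
            if d < gap:
                x += hx * d
                y += hy * d
                d = 0.0
            else:
                x += hx * gap
                y += hy * gap
                d -= gap
                # snap to the intersection to avoid drift off the lattice
                x = round(x / _BLOCK_M) * _BLOCK_M if hx else x
                y = round(y / _BLOCK_M) * _BLOCK_M if hy else y
                if rng.random() < cfg.stop_prob:
                    stop_left = int(rng.integers(3, 13))  # red light / stop sign
                if episode == "wander":
                    # lost-driver circling: turn the same way at every
                    # intersection, so the route curls into tight loops
                    # around single blocks instead of making progress
                    heading = (heading + wander_dir) % 4
                    v = min(v, _TURN_SPEED_KPH / 3.6)
                elif straight_left > 0:
                    straight_left -= 1
                elif rng.random() < p_turn:
                    # purposeful route turn, staircase-biased: alternating
                    # with the previous turn direction keeps routes making
                    # progress, so routes never curl into tight loops
                    turn = -last_turn if rng.random() < 0.75 else last_turn
                    heading = (heading + turn) % 4
                    last_turn = turn
                    v = min(v, _TURN_SPEED_KPH / 3.6)
                    straight_left = 1
        xs[t] = x
        ys[t] = y
        speeds[t] = v

    gps = rng.normal(0.0, cfg.gps_noise_m, size=(n, 2))
    lat = cfg.origin_lat + (ys + gps[:, 1]) / 1000.0 / KM_PER_DEG
    lon = cfg.origin_lon + (xs + gps[:, 0]) / 1000.0 / (
        KM_PER_DEG * math.cos(math.radians(cfg.origin_lat))
    )
    sog = np.maximum(speeds * 3.6 + rng.normal(0.0, cfg.sog_noise_kph, size=n), 0.0)
    return pd.DataFrame(
        {
            "timestamp": np.arange(n, dtype=np.int64),
            "lat": lat,
            "lon": lon,
            "sog_kph": sog,
            "anomalous": anom,
        }
    )


def simulate_cohort(
    cfg: SimulationConfig = SimulationConfig(),
    normal: PhenotypeParams = NORMAL_PHENOTYPE,
    abnormal: PhenotypeParams = ABNORMAL_PHENOTYPE,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a labeled cohort.

    Returns ``(telemetry, labels, manifest)``: telemetry has one row per
    second with columns ``driver_id, trip_id, timestamp, lat, lon, sog_kph,
    anomalous``; labels has one row per driver (``driver_id, label``) —
    constant per driver, so every segment of an abnormal driver inherits
    label 1 regardless of episode content. The manifest records every
    parameter and the seed.
    """
    if normal.label != 0 or abnormal.label != 1:
        raise ValueError("phenotype labels must be 0 (normal) and 1 (abnormal)")
    rng = np.random.default_rng(cfg.seed)
    n_abn = round(cfg.n_drivers * cfg.abnormal_fraction)
    frames = []
    labels = []
    for i in range(cfg.n_drivers):
        label = 1 if i < n_abn else 0
        ph = abnormal if label else normal
        driver_id = f"d{i:03d}"
        labels.append({"driver_id": driver_id, "label": label})
        for k in range(cfg.trips_per_driver):
            trip = simulate_trip(ph, cfg, rng)
            trip.insert(0, "trip_id", f"{driver_id}_t{k:02d}")
            trip.insert(0, "driver_id", driver_id)
            frames.append(trip)
    telemetry = pd.concat(frames, ignore_index=True)
    manifest = {
        "config": asdict(cfg),
        "normal_phenotype": asdict(normal),
        "abnormal_phenotype": asdict(abnormal),
    }
    return telemetry, pd.DataFrame(labels), manifest
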