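"""Survey design description and station layout.

The survey design emulated here is a nearshore detailed grid: two lines of
planned stations running parallel to the coast along the 9 m and 13 m
isobaths (52 planned stations each, ~2 km spacing), split into North, Middle
and South zones, revisited in three seasonal periods with three replicate
grabs per station.  Feeding hotspots are small targeted areas sampled once
with 12 individual grabs treated as replicates.

Zone sizes along each line are not dictated by the printed per-period
sampled counts alone; the defaults split each 52-station line so zone totals
(North 43, Middle 42, South 19) can accommodate the largest per-period
demand (42/41/18 in the mid-season period).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd

__all__ = ["ZONES", "PERIODS", "LINES", "DesignSpec", "StationLayout", "make_design"]

ZONES: tuple[str, ...] = ("North", "Middle", "South")
PERIODS: tuple[str, ...] = ("1", "2", "3")
#: isobath line label -> nominal depth (m)
LINES: dict[str, float] = {"9m": 9.0, "13m": 13.0}

#: stations sampled per (period, zone) in the detailed grid
DEFAULT_STATIONS_SAMPLED: dict[tuple[str, str], int] = {
    ("1", "North"): 22, ("1", "Middle"): 32, ("1", "South"): 14,
    ("2", "North"): 42, ("2", "Middle"): 41, ("2", "South"): 18,
    ("3", "North"): 21, ("3", "Middle"): 21, ("3", "South"): 12,
}

#: per-line split of planned stations across zones (sums to 52 per line)
DEFAULT_ZONE_SPLIT: dict[str, dict[str, int]] = {
    "9m": {"North": 22, "Middle": 21, "South": 9},
    "13m": {"North": 21, "Middle": 21, "South": 10},
}

DEFAULT_HOTSPOTS: dict[str, int] = {"North": 6, "Middle": 2, "South": 3}


class DesignConfigError(ValueError):
    """Raised when a survey design configuration is internally inconsistent."""


@dataclass
class DesignSpec:
    """Configuration of the grid + hotspot survey design."""

    zones: tuple[str, ...] = ZONES
    periods: tuple[str, ...] = PERIODS
    lines: dict[str, float] = field(default_factory=lambda: dict(LINES))
    planned_stations_per_line: int = 52
    station_spacing_km: float = 2.0
    zone_split_per_line: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ZONE_SPLIT.items()}
    )
    stations_sampled: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_STATIONS_SAMPLED)
    )
    replicates_per_grid_station: int = 3
    hotspots_per_zone: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_HOTSPOTS)
    )
    grabs_per_hotspot: int = 12

    def zone_totals(self) -> dict[str, int]:
        """Planned stations per zone, summed over the isobath lines."""
        totals = {z: 0 for z in self.zones}
        for line in self.lines:
            for z, n in self.zone_split_per_line[line].items():
                totals[z] += n
        return totals

    def validate(self) -> None:
        if self.replicates_per_grid_station < 0 or self.grabs_per_hotspot < 0:
            raise DesignConfigError("replicate/grab counts must be >= 0")
        for line, split in self.zone_split_per_line.items():
            if line not in self.lines:
                raise DesignConfigError(f"zone split refers to unknown line {line!r}")
            if any(n < 0 for n in split.values()):
                raise DesignConfigError("zone splits must be >= 0")
            if sum(split.values()) != self.planned_stations_per_line:
                raise DesignConfigError(
                    f"zone split for line {line} sums to {sum(split.values())}, "
                    f"expected {self.planned_stations_per_line}"
                )
        totals = self.zone_totals()
        for (period, zone), n in self.stations_sampled.items():
            if n < 0:
                raise DesignConfigError("sampled station counts must be >= 0")
            if zone not in self.zones or period not in self.periods:
                raise DesignConfigError(
                    f"stations_sampled key ({period!r}, {zone!r}) outside design"
                )
            if n > totals[zone]:
                raise DesignConfigError(
                    f"period {period} zone {zone}: {n} stations sampled but only "
                    f"{totals[zone]} planned"
                )
        for n in self.hotspots_per_zone.values():
            if n < 0:
                raise DesignConfigError("hotspot counts must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        # tuple keys are not YAML/JSON friendly
        d["stations_sampled"] = {
            f"{p}:{z}": n for (p, z), n in self.stations_sampled.items()
        }
        d["zones"] = list(self.zones)
        d["periods"] = list(self.periods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        d = dict(d)
        d["zones"] = tuple(d.get("zones", ZONES))
        d["periods"] = tuple(d.get("periods", PERIODS))
        if "stations_sampled" in d:
            d["stations_sampled"] = {
                tuple(k.split(":", 1)): int(v)
                for k, v in d["stations_sampled"].items()
            }
        return cls(**d)

    @classmethod
    def balanced(
        cls,
        stations_per_line: int = 52,
        replicates: int = 3,
        periods: tuple[str, ...] = PERIODS,
        hotspots: bool = False,
    ) -> "DesignSpec":
        """Fully sampled balanced variant used by calibration studies.

        Splits each line as evenly as possible across the three zones and
        samples every station in every period.
        """
        base, extra = divmod(stations_per_line, len(ZONES))
        split = {
            z: base + (1 if i < extra else 0) for i, z in enumerate(ZONES)
        }
        zone_split = {line: dict(split) for line in LINES}
        totals = {z: 2 * n for z, n in split.items()}
        sampled = {(p, z): totals[z] for p in periods for z in ZONES}
        return cls(
            periods=periods,
            planned_stations_per_line=stations_per_line,
            zone_split_per_line=zone_split,
            stations_sampled=sampled,
            replicates_per_grid_station=replicates,
            hotspots_per_zone=dict(DEFAULT_HOTSPOTS) if hotspots else
            {z: 0 for z in ZONES},
        )


@dataclass
class StationLayout:
    """Planned grid stations plus the per-period sampling quota."""

    stations: pd.DataFrame  # station_id, zone, line, depth_nominal_m, position_km
    sampled_counts: dict[tuple[str, str], int]
    spec: DesignSpec

    def zone_period_count(self, period: str, zone: str) -> int:
        return self.sampled_counts.get((period, zone), 0)


def make_design(config: DesignSpec) -> StationLayout:
    """Lay out the planned grid stations for a design configuration.

    Stations are placed at the configured spacing along each isobath line,
    assigned contiguously to zones from north to south, and labelled
    ``G<depth>-<zone initial><index>``.
    """
    config.validate()
    rows = []
    for line, depth in config.lines.items():
        split = config.zone_split_per_line[line]
        pos = 0
        for zone in config.zones:
            for i in range(split.get(zone, 0)):
                rows.append(
                    {
                        "station_id": f"G{line}-{zone[0]}{i + 1:02d}",
                        "zone": zone,
                        "line": line,
                        "depth_nominal_m": float(depth),
                        "position_km": pos * config.station_spacing_km,
                    }
                )
                pos += 1
    stations = pd.DataFrame(
        rows, columns=["station_id", "zone", "line", "depth_nominal_m", "position_km"]
    )
    return StationLayout(
        stations=stations,
        sampled_counts=dict(config.stations_sampled),
        spec=config,
    )
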