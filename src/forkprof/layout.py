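"""Genome layout: the fixed annotation a profiling run needs.

A :class:`GenomeLayout` describes one circular bacterial chromosome: its
length, the *dif* chromosome-dimer resolution site (where the circle is
computationally opened for linear presentation), *oriC*, the polar *ter*
replication-trap sites, the ribosomal RNA operons, and named reference
regions used for normalization (e.g. the *rrnG* reporter segment or the
*terE–terD* interval).

Coordinate conventions
----------------------
Genomic positions in layouts, YAML configs and region tables are 1-based
inclusive, as printed in genome annotation. All internal bin arithmetic is
0-based half-open; the conversion happens here, at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigError

#: The two polar directions on the circle. CW means increasing coordinate.
CW = "CW"
CCW = "CCW"
DIRECTIONS = (CW, CCW)


@dataclass(frozen=True)
class TerSite:
    """A polar replication-termination site.

    ``blocked_direction`` names the travel direction of forks that the site
    arrests: a ``CW``-blocking site stops forks moving toward increasing
    coordinates.
    """

    name: str
    position: int
    blocked_direction: str
    efficiency: float = 1.0

    def __post_init__(self):
        if self.blocked_direction not in DIRECTIONS:
            raise ConfigError(
                f"ter site {self.name!r}: blocked_direction must be one of "
                f"{DIRECTIONS}, got {self.blocked_direction!r}"
            )
        if not 0.0 <= self.efficiency <= 1.0:
            raise ConfigError(f"ter site {self.name!r}: efficiency not in [0, 1]")


@dataclass(frozen=True)
class RrnOperon:
    """A ribosomal RNA operon (start/end 1-based inclusive)."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ConfigError(f"rrn operon {self.name!r}: start > end")


@dataclass
class GenomeLayout:
    """Annotation of one circular chromosome.

    Parameters
    ----------
    name : str
        Genome or strain name.
    length_bp : int
        Chromosome length in bp.
    dif_pos, oric_pos : int
        1-based positions of *dif* and *oriC*.
    ter_sites : list of TerSite
    rrn_operons : list of RrnOperon
    regions : dict
        Named reference regions, ``name -> (start, end)`` 1-based inclusive.
    """

    name: str
    length_bp: int
    dif_pos: int
    oric_pos: int
    ter_sites: list = field(default_factory=list)
    rrn_operons: list = field(default_factory=list)
    regions: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ConfigError("length_bp must be positive")
        for label, pos in (("dif_pos", self.dif_pos), ("oric_pos", self.oric_pos)):
            if not 1 <= pos <= self.length_bp:
                raise ConfigError(f"{label}={pos} outside [1, {self.length_bp}]")
        self.ter_sites = [
            t if isinstance(t, TerSite) else TerSite(*t) for t in self.ter_sites
        ]
        self.rrn_operons = [
            r if isinstance(r, RrnOperon) else RrnOperon(*r) for r in self.rrn_operons
        ]
        for t in self.ter_sites:
            if not 1 <= t.position <= self.length_bp:
                raise ConfigError(f"ter site {t.name!r} outside chromosome")
        for r in self.rrn_operons:
            if not (1 <= r.start <= self.length_bp and 1 <= r.end <= self.length_bp):
                raise ConfigError(f"rrn operon {r.name!r} outside chromosome")
        for rname, (s, e) in self.regions.items():
            if s > e:
                raise ConfigError(f"region {rname!r}: start > end")
            if not (1 <= s and e <= self.length_bp):
                raise ConfigError(f"region {rname!r} outside chromosome")

    # -- bin arithmetic -------------------------------------------------

    def n_bins(self, bin_size: int) -> int:
        return math.ceil(self.length_bp / bin_size)

    def region(self, region) -> tuple[int, int]:
        """Resolve a region name or ``(start, end)`` pair (1-based incl.)."""
        if isinstance(region, str):
            try:
                return tuple(self.regions[region])
            except KeyError:
                raise ConfigError(
                    f"unknown region {region!r}; known: {sorted(self.regions)}"
                ) from None
        s, e = region
        return int(s), int(e)

    def region_bins(self, region, bin_size: int) -> tuple[int, int]:
        """Half-open bin-index range of bins lying *fully inside* a region.

        Edge bins that only partially overlap the region are excluded, so a
        region mean never depends on sequence outside the region.
        """
        start, end = self.region(region)
        lo = math.ceil((start - 1) / bin_size)
        hi = end // bin_size  # bins [lo, hi) satisfy (i+1)*bin_size <= end
        if hi <= lo:
            raise ConfigError(
                f"region {region!r} contains no complete {bin_size}-bp bin"
            )
        return lo, hi

    def circular_distance(self, a: int, b: int) -> int:
        """Shortest distance between two positions on the circle (bp)."""
        d = abs(a - b) % self.length_bp
        return min(d, self.length_bp - d)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regions"] = {k: list(v) for k, v in self.regions.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeLayout":
        d = dict(d)
        d["ter_sites"] = [
            TerSite(**t) if isinstance(t, dict) else TerSite(*t)
            for t in d.get("ter_sites", [])
        ]
        d["rrn_operons"] = [
            RrnOperon(**r) if isinstance(r, dict) else RrnOperon(*r)
            for r in d.get("rrn_operons", [])
        ]
        d["regions"] = {k: tuple(v) for k, v in d.get("regions", {}).items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GenomeLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def mg1655_layout() -> GenomeLayout:
    """The E. coli K-12 MG1655 chromosome (U00096.3), approximate annotation.

    Lengths and the named normalization regions are exact; individual
    ter/rrn coordinates are rounded public values adequate for window
    arithmetic and trough association, not for base-pair genetics.
    """
    return GenomeLayout(
        name="MG1655",
        length_bp=4_641_652,
        dif_pos=1_588_774,
        oric_pos=3_925_860,
        ter_sites=[
            TerSite("terA", 1_343_429, CCW),
            TerSite("terB", 1_682_327, CW),
            TerSite("terC", 1_609_157, CW),
            TerSite("terD", 1_279_162, CCW),
            TerSite("terE", 1_083_560, CCW),
            TerSite("terF", 2_318_101, CW),
            TerSite("terG", 2_376_412, CW),
            TerSite("terH", 601_025, CCW),
            TerSite("terI", 656_360, CCW),
            TerSite("terJ", 3_191_355, CW),
        ],
        rrn_operons=[
            RrnOperon("rrnA", 4_035_531, 4_040_906, "+"),
            RrnOperon("rrnB", 4_166_659, 4_172_057, "+"),
            RrnOperon("rrnC", 3_941_808, 3_946_875, "+"),
            RrnOperon("rrnD", 3_423_194, 3_429_236, "-"),
            RrnOperon("rrnE", 4_208_147, 4_213_596, "+"),
            RrnOperon("rrnG", 2_729_616, 2_735_541, "-"),
            RrnOperon("rrnH", 223_771, 229_271, "+"),
        ],
        regions={
            "rrnG_reporter": (2_700_000, 2_748_600),
            "terED": (1_082_000, 1_282_000),
        },
    )
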