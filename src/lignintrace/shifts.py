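"""Chemical-shift assignments and named spectral regions for grass lignin.

This module is the single source of truth for where each lignin carbon
resonates, which carbons can carry precursor-derived :sup:`13`\\ C, and which
2D cross-peaks are diagnostic for each monolignol unit.  Every downstream
stage (spectrum synthesis, 1D integration, 2D volumetrics) looks shifts up
here rather than hard-coding ppm values.

Units follow the standard monolignol nomenclature:

* ``G`` -- guaiacyl, ``S`` -- syringyl, ``H`` -- *p*-hydroxyphenyl
* ``FA`` -- ferulate, ``pCA`` -- *p*-coumarate (wall-bound hydroxycinnamates)
* ``OMe`` -- methoxy carbons (introduced by SAM-dependent O-methylation,
  hence never labeled by ring-derived precursors)
* ``CARB`` -- the carbohydrate background (cellulose/hemicellulose carbons)

Carbons with locally symmetric or spectrally merged positions (e.g. S C2/6,
G C3/4) are stored as one site with ``n_carbons`` reflecting the number of
equivalent carbons, so integrated areas convert directly to per-unit molar
quantities.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

LIGNIN_UNITS = ("G", "S", "H", "FA", "pCA")
ALL_UNITS = LIGNIN_UNITS + ("OMe", "CARB")


@dataclass(frozen=True)
class CarbonSite:
    """One resolved carbon environment of a lignin unit or the background."""

    unit: str
    carbon: str
    shift_ppm: float
    n_carbons: int = 1
    labelable: bool = True

    def __post_init__(self) -> None:
        if not -20.0 <= self.shift_ppm <= 220.0:
            raise ValueError(f"shift {self.shift_ppm} ppm outside -20..220")
        if self.n_carbons < 1:
            raise ValueError("n_carbons must be >= 1")
        if self.unit == "OMe" and self.labelable:
            raise ValueError("methoxy carbons are never labelable")


@dataclass(frozen=True)
class CrossPeakDef:
    """A 2D cross-peak between two carbons of the same unit.

    ``name`` is the field-standard composite label (e.g. ``S2/6-3/5``); the
    same name may cover several concrete site pairs (e.g. ``FA2/5/8-9``
    expands to C2-C9, C5-C9 and C8-C9).
    """

    unit: str
    site_a: str
    site_b: str
    f1_ppm: float
    f2_ppm: float
    name: str

    @property
    def mirrored(self) -> "CrossPeakDef":
        return CrossPeakDef(
            self.unit, self.site_b, self.site_a, self.f2_ppm, self.f1_ppm, self.name
        )


@dataclass(frozen=True)
class SpectralRegion:
    name: str
    lo_ppm: float
    hi_ppm: float

    def __post_init__(self) -> None:
        if not self.lo_ppm < self.hi_ppm:
            raise ValueError(f"region {self.name}: need lo < hi")

    def __contains__(self, ppm: float) -> bool:
        return self.lo_ppm <= ppm <= self.hi_ppm

    @property
    def width(self) -> float:
        return self.hi_ppm - self.lo_ppm


@dataclass
class ShiftTable:
    """Lookup table of :class:`CarbonSite` entries keyed by (unit, carbon)."""

    sites: dict[tuple[str, str], CarbonSite] = field(default_factory=dict)

    def add(self, site: CarbonSite) -> None:
        self.sites[(site.unit, site.carbon)] = site

    def lookup(self, unit: str, carbon: str) -> CarbonSite:
        try:
            return self.sites[(unit, carbon)]
        except KeyError:
            raise KeyError(f"no site {carbon!r} for unit {unit!r}") from None

    def sites_for(self, unit: str) -> list[CarbonSite]:
        return [s for (u, _), s in self.sites.items() if u == unit]

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (s.unit, s.carbon, s.shift_ppm, s.n_carbons, s.labelable) for s in self
        ]
        return pd.DataFrame(
            rows, columns=["unit", "carbon", "shift_ppm", "n_carbons", "labelable"]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ShiftTable":
        table = cls()
        for row in df.itertuples(index=False):
            table.add(
                CarbonSite(
                    unit=str(row.unit),
                    carbon=str(row.carbon),
                    shift_ppm=float(row.shift_ppm),
                    n_carbons=int(row.n_carbons),
                    labelable=bool(row.labelable),
                )
            )
        return table

    @classmethod
    def from_csv(cls, path) -> "ShiftTable":
        return cls.from_dataframe(pd.read_csv(path))


# (unit, carbon, shift/ppm, n_carbons, labelable)
# Aromatic anchor shifts: G/FA C3,C4 147/148-149, S C3/5 153, S C2/6 104,
# H C4 160, FA C9 168 (carbonyl), pCA C4/C9 160/168.  Remaining positions are
# standard lignin assignments and may be overridden from a CSV.
_DEFAULT_SITES: list[tuple[str, str, float, int, bool]] = [
    ("G", "C1", 135.0, 1, True),
    ("G", "C2", 111.0, 1, True),
    ("G", "C3/4", 147.0, 2, True),
    ("G", "C5", 115.0, 1, True),
    ("G", "C6", 119.0, 1, True),
    ("S", "C1", 134.0, 1, True),
    ("S", "C2/6", 104.0, 2, True),
    ("S", "C3/5", 153.0, 2, True),
    ("S", "C4", 138.0, 1, True),
    ("H", "C1", 130.0, 1, True),
    ("H", "C2/6", 128.0, 2, True),
    ("H", "C3/5", 116.0, 2, True),
    ("H", "C4", 160.0, 1, True),
    ("FA", "C1", 126.0, 1, True),
    ("FA", "C2", 111.0, 1, True),
    ("FA", "C3", 148.0, 1, True),
    ("FA", "C4", 149.0, 1, True),
    ("FA", "C5", 116.0, 1, True),
    ("FA", "C6", 123.0, 1, True),
    ("FA", "C7", 145.0, 1, True),
    ("FA", "C8", 117.0, 1, True),
    ("FA", "C9", 168.0, 1, True),
    ("pCA", "C4", 160.0, 1, True),
    ("pCA", "C9", 168.0, 1, True),
    ("OMe", "CH3", 56.0, 1, False),
    # Cellulose/hemicellulose: C1 105; C4 crystalline 89 / amorphous 84;
    # the dominant C2/C3/C5 envelope at 73; C6 crystalline 65 / amorphous 62.
    ("CARB", "C1", 105.0, 1, False),
    ("CARB", "C4cr", 89.0, 1, False),
    ("CARB", "C4am", 84.0, 1, False),
    ("CARB", "C2/3/5", 73.0, 3, False),
    ("CARB", "C6cr", 65.0, 1, False),
    ("CARB", "C6am", 62.0, 1, False),
]


def default_shift_table() -> ShiftTable:
    """Return the built-in shift table covering all units and the background."""
    table = ShiftTable()
    for unit, carbon, shift, n, lab in _DEFAULT_SITES:
        table.add(CarbonSite(unit, carbon, shift, n, lab))
    return table


def load_shift_table(path=None) -> ShiftTable:
    """Load a shift table from CSV; with no path, the packaged default CSV."""
    if path is not None:
        return ShiftTable.from_csv(path)
    ref = importlib.resources.files("lignintrace.data").joinpath("shifts.csv")
    with importlib.resources.as_file(ref) as p:
        return ShiftTable.from_csv(p)


# Composite cross-peak labels -> concrete (site_a, site_b) pairs.
_CATALOG_SPEC: list[tuple[str, str, list[tuple[str, str]]]] = [
    ("G", "G2/5-1", [("C2", "C1"), ("C5", "C1")]),
    ("G", "G2/5-3/4", [("C2", "C3/4"), ("C5", "C3/4")]),
    ("S", "S2/6-3/5", [("C2/6", "C3/5")]),
    ("S", "S2/6-1", [("C2/6", "C1")]),
    ("S", "S2/6-4", [("C2/6", "C4")]),
    ("H", "H3/5-4", [("C3/5", "C4")]),
    ("H", "H2/6-4", [("C2/6", "C4")]),
    ("FA", "FA2/5/8-9", [("C2", "C9"), ("C5", "C9"), ("C8", "C9")]),
    ("FA", "FA1/6-9", [("C1", "C9"), ("C6", "C9")]),
    ("FA", "FA3/4/7-9", [("C3", "C9"), ("C4", "C9"), ("C7", "C9")]),
    ("pCA", "pCA4-9", [("C4", "C9")]),
]


def crosspeak_catalog(table: ShiftTable | None = None) -> list[CrossPeakDef]:
    """The diagnostic 2D cross-peak catalogue (one orientation per peak).

    Coordinates are taken verbatim from the shift table; a missing site
    raises ``KeyError``.  Use :func:`expand_symmetric` to add the mirrored
    (f2, f1) twins implied by homonuclear symmetry.
    """
    if table is None:
        table = default_shift_table()
    defs: list[CrossPeakDef] = []
    for unit, name, pairs in _CATALOG_SPEC:
        for site_a, site_b in pairs:
            a = table.lookup(unit, site_a)
            b = table.lookup(unit, site_b)
            defs.append(CrossPeakDef(unit, site_a, site_b, a.shift_ppm, b.shift_ppm, name))
    return defs


def expand_symmetric(catalog: list[CrossPeakDef]) -> list[CrossPeakDef]:
    """Append the (f2, f1) mirror of every cross-peak."""
    return list(catalog) + [p.mirrored for p in catalog]


def quantification_probes(table: ShiftTable | None = None) -> dict[str, list[CrossPeakDef]]:
    """Per-unit probe cross-peaks used for molar-composition estimation.

    One or two well-isolated cross-peaks per unit, chosen so that each
    integration box (+/- 1.5 ppm) has >= 5 ppm clearance from every peak of a
    *different* unit in at least one dimension; box integrals are then
    unit-pure and composition follows from multiplicity-weighted volumes.
    """
    if table is None:
        table = default_shift_table()
    by_name = {}
    for p in crosspeak_catalog(table):
        by_name.setdefault(p.name, []).append(p)

    def pick(name: str, site_a: str) -> CrossPeakDef:
        for p in by_name[name]:
            if p.site_a == site_a:
                return p
        raise KeyError(f"{name}/{site_a}")

    # G uses C2-C1 alone: the C5-C1 box (115, 135) sits 4 ppm from *both*
    # C2-C1 and C6-C1 and would collect their tails from two sides.
    return {
        "G": [pick("G2/5-1", "C2")],
        "S": [pick("S2/6-3/5", "C2/6")],
        "H": [pick("H3/5-4", "C3/5")],
        "FA": [pick("FA2/5/8-9", "C2")],
    }


def pair_multiplicity(table: ShiftTable, peak: CrossPeakDef) -> int:
    """Number of equivalent carbon pairs contributing to a cross-peak."""
    return (
        table.lookup(peak.unit, peak.site_a).n_carbons
        * table.lookup(peak.unit, peak.site_b).n_carbons
    )


def catalog_to_csv(catalog: list[CrossPeakDef], path) -> None:
    pd.DataFrame(
        [(p.unit, p.site_a, p.site_b, p.f1_ppm, p.f2_ppm, p.name) for p in catalog],
        columns=["unit", "site_a", "site_b", "f1_ppm", "f2_ppm", "name"],
    ).to_csv(path, index=False)


def catalog_from_csv(path) -> list[CrossPeakDef]:
    df = pd.read_csv(path)
    return [
        CrossPeakDef(
            str(r.unit), str(r.site_a), str(r.site_b),
            float(r.f1_ppm), float(r.f2_ppm), str(r.name),
        )
        for r in df.itertuples(index=False)
    ]


#: Integration bounds for the 1D pipeline.  ``aromatic`` is the lignin
#: quantification window (excludes the FA/pCA carbonyl near 168 ppm);
#: ``carbohydrate_ref`` is the search window for the normalization peak.
def named_regions() -> dict[str, SpectralRegion]:
    return {
        "aromatic": SpectralRegion("aromatic", 108.0, 165.0),
        "carbohydrate_ref": SpectralRegion("carbohydrate_ref", 70.0, 75.0),
        "deconv_window": SpectralRegion("deconv_window", 140.0, 158.0),
        "carbonyl": SpectralRegion("carbonyl", 165.0, 175.0),
    }
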