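"""Quantitative structural features from OCT sector thickness tables.

The ANN branch of the concatenated classifier consumes two scalars per eye:

* ``WA_MT`` — area-weighted average macular thickness over the four
  quadrant sectors (upper/lower x outer/inner) of the concentric macular
  rings.  The weights are the quadrant areas (in units of pi) of the
  annuli bounded by circles of radius 0.5, 1.5 and 3 (disc diameters):
  inner sectors weigh (1.5^2 - 0.5^2)/4 = 0.5, outer sectors
  (3^2 - 1.5^2)/4 = 1.6875.
* ``WA_RNFL`` — area-weighted average peripapillary retinal nerve fiber
  layer thickness over the six directional sectors.  Relative sector
  areas are T=N=4 and TS=TI=NS=NI=2 (the global sector G has area 1 and
  does not enter the weighted average); the normalizer is 2*(8/17) with
  weights expressed on the 17-part total area.

Both features carry µm units and thin under glaucomatous damage, which
is what makes them informative inputs for early-stage detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MACULAR_SECTOR_NAMES = ("UO", "UI", "LO", "LI")
RNFL_SECTOR_NAMES = ("G", "T", "TS", "TI", "N", "NS", "NI")

#: Relative areas of the seven RNFL sectors (G, T, TS, TI, N, NS, NI).
RNFL_SECTOR_AREAS = {"G": 1, "T": 4, "TS": 2, "TI": 2, "N": 4, "NS": 2, "NI": 2}

#: Radii of the three concentric macular circles (inner, middle, outer).
MACULAR_RING_RADII = (0.5, 1.5, 3.0)

COHORT_COLUMNS = ("subject_id", "label", "vmd") + MACULAR_SECTOR_NAMES + RNFL_SECTOR_NAMES


class SchemaError(ValueError):
    """A thickness table is missing a required column."""


def quarter_annulus_weight(r_inner: float, r_outer: float) -> float:
    """Area of one quadrant of an annulus, in units of pi.

    Parameters
    ----------
    r_inner, r_outer : float
        Radii bounding the annulus, ``0 <= r_inner < r_outer``.

    Returns
    -------
    float
        ``(r_outer**2 - r_inner**2) / 4``, the quadrant area divided by
        pi.  For the macular rings this yields the sector weights 0.5
        (inner, radii 0.5–1.5) and 1.6875 (outer, radii 1.5–3).
    """
    if r_inner < 0:
        raise ValueError(f"r_inner must be non-negative, got {r_inner}")
    if r_inner >= r_outer:
        raise ValueError(f"need r_inner < r_outer, got {r_inner} >= {r_outer}")
    return (r_outer**2 - r_inner**2) / 4.0


# Macular sector weights derived from the ring radii.
_W_INNER = quarter_annulus_weight(MACULAR_RING_RADII[0], MACULAR_RING_RADII[1])
_W_OUTER = quarter_annulus_weight(MACULAR_RING_RADII[1], MACULAR_RING_RADII[2])


@dataclass(frozen=True)
class MacularSectors:
    """Macular thickness (µm) in the four quadrant sectors."""

    UO: float
    UI: float
    LO: float
    LI: float

    def __post_init__(self) -> None:
        for name in MACULAR_SECTOR_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"macular sector {name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class RnflSectors:
    """Peripapillary RNFL thickness (µm) in the seven sectors."""

    G: float
    T: float
    TS: float
    TI: float
    N: float
    NS: float
    NI: float

    def __post_init__(self) -> None:
        for name in RNFL_SECTOR_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"RNFL sector {name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class FeatureVector:
    """The two structural features fed to the ANN branch (µm)."""

    wa_mt: float
    wa_rnfl: float


def wa_mt(m: MacularSectors) -> float:
    """Weighted average macular thickness.

    ``[0.5*(UI+LI) + 1.6875*(UO+LO)] / [2*(0.5+1.6875)]`` with the
    weights being the quadrant-annulus areas of the macular rings.
    """
    num = _W_INNER * (m.UI + m.LI) + _W_OUTER * (m.UO + m.LO)
    den = 2.0 * (_W_INNER + _W_OUTER)
    return num / den


def wa_rnfl(r: RnflSectors) -> float:
    """Weighted average RNFL thickness.

    ``[(4/17)*(T+N) + (2/17)*(TS+NS+TI+NI)] / (2*(8/17))``.  The global
    sector G does not enter the value; only the six directional sectors
    are averaged, normalized by their own total weight 16/17.
    """
    num = (4.0 / 17.0) * (r.T + r.N) + (2.0 / 17.0) * (r.TS + r.NS + r.TI + r.NI)
    den = 2.0 * (8.0 / 17.0)
    return num / den


def featurize(table: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Compute (wa_mt, wa_rnfl) for every row of a cohort table.

    Parameters
    ----------
    table : DataFrame or path to CSV
        Must carry the 14-column cohort schema (``subject_id``,
        ``label``, ``vmd`` and the 11 sector columns).

    Returns
    -------
    DataFrame
        Columns ``subject_id, label, wa_mt, wa_rnfl``, row order
        preserved.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    for col in COHORT_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"cohort table is missing required column {col!r}")
    out = pd.DataFrame(
        {
            "subject_id": table["subject_id"].to_numpy(),
            "label": table["label"].to_numpy(),
            "wa_mt": [
                wa_mt(MacularSectors(*(float(row[n]) for n in MACULAR_SECTOR_NAMES)))
                for _, row in table.iterrows()
            ],
            "wa_rnfl": [
                wa_rnfl(RnflSectors(*(float(row[n]) for n in RNFL_SECTOR_NAMES)))
                for _, row in table.iterrows()
            ],
        }
    )
    return out


def candidate_inputs(table: pd.DataFrame) -> pd.DataFrame:
    """All 17 candidate scalar inputs considered for the ANN branch.

    Nine macular quantities (the four sectors, four region averages and
    WA_MT) plus eight RNFL quantities (the seven sectors and WA_RNFL).
    Provided as a screening utility; the classifier itself uses only
    WA_MT and WA_RNFL.
    """
    for col in COHORT_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"cohort table is missing required column {col!r}")
    out = table[["subject_id", "label"]].copy()
    for name in MACULAR_SECTOR_NAMES + RNFL_SECTOR_NAMES:
        out[name] = table[name].astype(float)
    out["MT_upper"] = (out["UO"] + out["UI"]) / 2.0
    out["MT_lower"] = (out["LO"] + out["LI"]) / 2.0
    out["MT_inner"] = (out["UI"] + out["LI"]) / 2.0
    out["MT_outer"] = (out["UO"] + out["LO"]) / 2.0
    feats = featurize(table)
    out["WA_MT"] = feats["wa_mt"].to_numpy()
    out["WA_RNFL"] = feats["wa_rnfl"].to_numpy()
    return out
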