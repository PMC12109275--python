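"""Synthetic fundus-image + OCT-thickness cohorts.

No public dataset with paired fundus photographs, macular/RNFL sector
thicknesses and glaucoma staging exists, so this module generates
phantom cohorts carrying the statistical structure the classifier
assumes:

* per-eye sector thicknesses drawn from Gaussians with healthy means in
  physiological ranges (macular sectors ~280-310 µm, RNFL sectors
  ~70-140 µm), thinned multiplicatively in glaucomatous eyes with a
  class-dependent fraction, truncated at 0;
* a staging score (vision mean defect, dB) consistent with the clinical
  bands: early (-6, 0], moderate (-12, -6], severe below -12;
* fundus phantoms with a bright optic disc and cup (cup-to-disc ratio
  enlarged in glaucoma), a darker macula, dark vessel arcs, a smooth
  multiplicative illumination gradient, and a burned-in text band at a
  known top-left position — each the target of one preprocessing step.

Identical spec + seed yields a bit-identical cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .features import (
    COHORT_COLUMNS,
    MACULAR_SECTOR_NAMES,
    RNFL_SECTOR_NAMES,
    MacularSectors,
    RnflSectors,
)

LABELS = ("healthy", "early", "moderate", "severe")

#: Healthy mean sector thicknesses (µm); inner macular sectors are
#: thicker than outer, and the RNFL follows the ISNT-like profile with
#: thick superior/inferior and thin temporal/nasal sectors.
HEALTHY_MACULAR_MEANS = {"UO": 285.0, "UI": 310.0, "LO": 283.0, "LI": 308.0}
HEALTHY_RNFL_MEANS = {
    "G": 97.0,
    "T": 70.0,
    "TS": 135.0,
    "TI": 140.0,
    "N": 75.0,
    "NS": 105.0,
    "NI": 110.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic cohort."""

    n_healthy: int = 204
    n_early: int = 130
    n_moderate: int = 51
    n_severe: int = 31
    image_rows: int = 500
    image_cols: int = 750
    thinning_fraction_early: float = 0.15
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_healthy", "n_early", "n_moderate", "n_severe"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.image_rows <= 0 or self.image_cols <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.0 < self.thinning_fraction_early < 1.0:
            raise ValueError(
                f"thinning_fraction_early must be in (0,1), got {self.thinning_fraction_early}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def thinning_fraction(self, label: str) -> float:
        """Mean fractional thickness loss for a severity class.

        Moderate and severe eyes thin 1.75x and 2.5x the early
        fraction, capped below total loss.
        """
        f = self.thinning_fraction_early
        return {
            "healthy": 0.0,
            "early": f,
            "moderate": min(1.75 * f, 0.85),
            "severe": min(2.5 * f, 0.9),
        }[label]

    def counts(self) -> dict[str, int]:
        return {
            "healthy": self.n_healthy,
            "early": self.n_early,
            "moderate": self.n_moderate,
            "severe": self.n_severe,
        }


@dataclass(frozen=True)
class ThicknessRecord:
    """One eye's macular and RNFL sector thicknesses (µm)."""

    macular: MacularSectors
    rnfl: RnflSectors


@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic eye: label, staging score, thickness, render recipe."""

    subject_id: str
    label: str
    vmd: float
    thickness: ThicknessRecord
    geometry: dict = field(compare=False, default_factory=dict)
    render_seed: int = field(compare=False, default=0)
    image_path: Path | None = field(compare=False, default=None)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def y(self) -> int:
        """Binary target: 1 for any glaucoma stage, 0 for healthy."""
        return 0 if self.label == "healthy" else 1


_VMD_BANDS = {  # dB; healthy by convention non-negative
    "healthy": (0.0, 2.0),
    "early": (-6.0, 0.0),
    "moderate": (-12.0, -6.0),
    "severe": (-20.0, -12.0),
}


def _draw_geometry(rng: np.random.Generator, label: str, spec: PhantomSpec) -> dict:
    h, w = spec.image_rows, spec.image_cols
    if label == "healthy":
        cdr = rng.normal(0.35, 0.05)
    else:
        cdr = rng.normal(0.60, 0.05)
    cdr = float(np.clip(cdr, 0.1, 0.9))
    return {
        "disc_center": (
            float(h * (0.50 + rng.uniform(-0.03, 0.03))),
            float(w * (0.68 + rng.uniform(-0.02, 0.02))),
        ),
        "disc_radius": float(min(h, w) * rng.uniform(0.085, 0.105)),
        "cup_to_disc": cdr,
        "macula_center": (
            float(h * (0.52 + rng.uniform(-0.02, 0.02))),
            float(w * (0.38 + rng.uniform(-0.02, 0.02))),
        ),
        "macula_radius": float(min(h, w) * rng.uniform(0.13, 0.16)),
        "illum_slope": float(rng.uniform(-0.25, 0.25)),
        "illum_bump": float(rng.uniform(0.1, 0.3)),
        "illum_bump_center": (float(rng.uniform(0.2, 0.8)), float(rng.uniform(0.2, 0.8))),
        "n_vessels": int(rng.integers(4, 7)),
    }


def generate_cohort(spec: PhantomSpec) -> list[SubjectRecord]:
    """Draw a full cohort; reproducible from (spec, spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    idx = 0
    for label in LABELS:
        thin = spec.thinning_fraction(label)
        lo, hi = _VMD_BANDS[label]
        for _ in range(spec.counts()[label]):
            mac = {
                k: max(0.0, rng.normal(v * (1.0 - thin), spec.noise_sd))
                for k, v in HEALTHY_MACULAR_MEANS.items()
            }
            rn = {
                k: max(0.0, rng.normal(v * (1.0 - thin), spec.noise_sd))
                for k, v in HEALTHY_RNFL_MEANS.items()
            }
            vmd = float(rng.uniform(lo, hi))
            geometry = _draw_geometry(rng, label, spec)
            records.append(
                SubjectRecord(
                    subject_id=f"S{idx:04d}",
                    label=label,
                    vmd=vmd,
                    thickness=ThicknessRecord(
                        macular=MacularSectors(**{k: mac[k] for k in MACULAR_SECTOR_NAMES}),
                        rnfl=RnflSectors(**{k: rn[k] for k in RNFL_SECTOR_NAMES}),
                    ),
                    geometry=geometry,
                    render_seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
            idx += 1
    return records


def text_band(spec: PhantomSpec) -> tuple[int, int, int, int]:
    """The burned-in text region as (row0, row1, col0, col1), exclusive ends."""
    h, w = spec.image_rows, spec.image_cols
    return (max(0, int(0.02 * h)), max(1, int(0.10 * h)), max(0, int(0.02 * w)), max(1, int(0.35 * w)))


def render_fundus_phantom(record: SubjectRecord, spec: PhantomSpec) -> np.ndarray:
    """Render one phantom fundus photograph.

    Returns a uint8 array of shape (image_rows, image_cols, 3), RGB.
    Deterministic given the record's stored geometry and render seed.
    """
    if not record.geometry:
        raise ValueError("record carries no render geometry")
    h, w = spec.image_rows, spec.image_cols
    g = record.geometry
    rng = np.random.default_rng(record.render_seed)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)

    # fundus background with gentle radial falloff toward the periphery
    r2 = ((rr - h / 2) / (h / 2)) ** 2 + ((cc - w / 2) / (w / 2)) ** 2
    falloff = 1.0 - 0.35 * np.clip(r2, 0, 1)
    img = np.stack(
        [180.0 * falloff, 90.0 * falloff, 40.0 * falloff], axis=-1
    )

    # darker macular region (smooth Gaussian dip)
    mr, mc = g["macula_center"]
    d2 = ((rr - mr) ** 2 + (cc - mc) ** 2) / g["macula_radius"] ** 2
    img *= (1.0 - 0.35 * np.exp(-d2))[..., None]

    # bright optic disc and even brighter cup
    dr, dc = g["disc_center"]
    disc = ((rr - dr) ** 2 + (cc - dc) ** 2) <= g["disc_radius"] ** 2
    cup = ((rr - dr) ** 2 + (cc - dc) ** 2) <= (g["cup_to_disc"] * g["disc_radius"]) ** 2
    img[disc] = np.array([235.0, 190.0, 120.0])
    img[cup] = np.array([252.0, 235.0, 185.0])

    # dark vessel arcs: parabolas emanating from the disc
    for _ in range(g["n_vessels"]):
        a = rng.uniform(-4e-4, 4e-4)
        slope = rng.uniform(-0.7, 0.7)
        width = rng.uniform(2.0, 5.0) * h / 500.0
        curve = dr + slope * (cc - dc) + a * (cc - dc) ** 2
        vessel = np.abs(rr - curve) < width
        img[vessel] = np.array([70.0, 25.0, 15.0])

    # smooth multiplicative illumination field (flash artifact)
    br, bc = g["illum_bump_center"]
    bump = np.exp(-(((rr / h - br) ** 2 + (cc / w - bc) ** 2) / 0.18))
    illum = 1.0 + g["illum_slope"] * (cc / w - 0.5) + g["illum_bump"] * bump
    img *= illum[..., None]

    # burned-in text band: bright glyph blobs at a fixed corner
    r0, r1, c0, c1 = text_band(spec)
    band_rng = np.random.default_rng(record.render_seed + 1)
    glyphs = band_rng.random((r1 - r0, c1 - c0)) < 0.55
    for ch in range(3):
        sub = img[r0:r1, c0:c1, ch]
        sub[glyphs] = 255.0
        img[r0:r1, c0:c1, ch] = sub

    return np.clip(img, 0, 255).astype(np.uint8)


def write_dataset(records: list[SubjectRecord], directory: str | Path, spec: PhantomSpec) -> Path:
    """Write PNGs, the 14-column cohort CSV, and a JSON manifest.

    Returns the manifest path.  The CSV round-trips thicknesses at full
    float precision.
    """
    directory = Path(directory)
    img_dir = directory / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        png = img_dir / f"{rec.subject_id}.png"
        Image.fromarray(render_fundus_phantom(rec, spec)).save(png)
        row = {"subject_id": rec.subject_id, "label": rec.label, "vmd": rec.vmd}
        for n in MACULAR_SECTOR_NAMES:
            row[n] = getattr(rec.thickness.macular, n)
        for n in RNFL_SECTOR_NAMES:
            row[n] = getattr(rec.thickness.rnfl, n)
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    csv_path = directory / "cohort.csv"
    table.to_csv(csv_path, index=False, float_format="%.17g")

    counts: dict[str, int] = {lab: 0 for lab in LABELS}
    for rec in records:
        counts[rec.label] += 1
    manifest = {
        "n": len(records),
        "counts": counts,
        "image_rows": spec.image_rows,
        "image_cols": spec.image_cols,
        "seed": spec.seed,
        "cohort_csv": csv_path.name,
        "images": {rec.subject_id: f"images/{rec.subject_id}.png" for rec in records},
        "spec": dataclasses.asdict(spec),
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_dataset(directory: str | Path) -> list[SubjectRecord]:
    """Read back a written dataset; inverse of :func:`write_dataset`.

    Render geometry is not persisted, so returned records compare equal
    to the originals on identity, label, staging score and thickness.
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    table = pd.read_csv(directory / manifest["cohort_csv"], float_precision="round_trip")
    records = []
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        records.append(
            SubjectRecord(
                subject_id=sid,
                label=str(row["label"]),
                vmd=float(row["vmd"]),
                thickness=ThicknessRecord(
                    macular=MacularSectors(*(float(row[n]) for n in MACULAR_SECTOR_NAMES)),
                    rnfl=RnflSectors(*(float(row[n]) for n in RNFL_SECTOR_NAMES)),
                ),
                image_path=directory / manifest["images"][sid],
            )
        )
    return records
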