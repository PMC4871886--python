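"""Carbon biomass from cell counts and biovolumes.

Protist per-cell carbon quotas follow the standard allometric
volume-to-carbon regressions for marine protists:

    diatoms:      pg C cell⁻¹ = 0.288 · V^0.811
    non-diatoms:  pg C cell⁻¹ = 0.216 · V^0.939

with V the cell biovolume in μm³.  Nanoplankton are approximated as
spheres at the midpoint diameter of their size class and converted at
183 fg C μm⁻³; prokaryotes use fixed per-cell factors (20 fg C for
heterotrophs, 200 fg C for *Synechococcus*).

Internal carbon arithmetic is in pg; conversion to μg happens only at
reporting (1 μg = 10⁶ pg), which avoids repeated scale slips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CountMatrix, TaxonRecord, ValidationError, logger

# (coefficient, exponent) of pg C = a · V^b
DIATOM_QUOTA = (0.288, 0.811)
NON_DIATOM_QUOTA = (0.216, 0.939)

# fg C cell⁻¹ conversion factors for prokaryotes
PROKARYOTE_FG_C = {"heterotroph": 20.0, "synechococcus": 200.0}

# fg C μm⁻³ for nanoplankton spheres
NANO_FG_C_PER_UM3 = 183.0

# arithmetic midpoints of the printed nanoplankton size classes (μm)
NANO_CLASS_DIAMETERS = {"2-3": 2.5, "3-5": 4.0, "5-10": 7.5}

PG_PER_UG = 1e6
FG_PER_UG = 1e9


def protist_carbon_quota(biovolume, model: str):
    """Per-cell carbon quota (pg C cell⁻¹) from biovolume (μm³).

    ``model`` is ``"diatom"`` or ``"non_diatom"``.  Accepts scalars or
    arrays; strictly increasing in biovolume.
    """
    v = np.asarray(biovolume, dtype=float)
    if np.any(v <= 0):
        raise ValidationError("biovolume must be > 0")
    if model == "diatom":
        a, b = DIATOM_QUOTA
    elif model == "non_diatom":
        a, b = NON_DIATOM_QUOTA
    else:
        raise ValidationError(f"unknown carbon model {model!r}")
    out = a * v ** b
    return float(out) if np.isscalar(biovolume) else out


def sphere_biovolume(diameter: float) -> float:
    """Volume (μm³) of a sphere of the given diameter (μm): π·d³/6."""
    if not diameter > 0:
        raise ValidationError("diameter must be > 0")
    return np.pi * diameter ** 3 / 6.0


@dataclass(frozen=True)
class NanoSizeClassCounts:
    """Nanoplankton abundance (cells L⁻¹) per size class."""

    small: float = 0.0    # 2–3 μm
    medium: float = 0.0   # 3–5 μm
    large: float = 0.0    # 5–10 μm

    def __post_init__(self) -> None:
        if min(self.small, self.medium, self.large) < 0:
            raise ValidationError("nanoplankton abundances must be >= 0")


def nanoplankton_biomass(counts: NanoSizeClassCounts,
                         fg_c_per_um3: float = NANO_FG_C_PER_UM3) -> float:
    """Nanoplankton carbon (μg C L⁻¹): Σ abundance × sphere volume × 183 fg μm⁻³."""
    per_class = {
        "2-3": counts.small, "3-5": counts.medium, "5-10": counts.large,
    }
    total_fg = sum(ab * sphere_biovolume(NANO_CLASS_DIAMETERS[cls]) * fg_c_per_um3
                   for cls, ab in per_class.items())
    return total_fg / FG_PER_UG


def prokaryote_biomass(abundance: float, kind: str) -> float:
    """Prokaryote carbon (μg C L⁻¹) from abundance (cells L⁻¹) and a fixed
    per-cell factor (``heterotroph`` 20 fg, ``synechococcus`` 200 fg)."""
    if abundance < 0:
        raise ValidationError("abundance must be >= 0")
    try:
        fg = PROKARYOTE_FG_C[kind]
    except KeyError:
        raise ValidationError(f"unknown prokaryote kind {kind!r}") from None
    return abundance * fg / FG_PER_UG


def taxon_quota(rec: TaxonRecord) -> float:
    """Per-cell quota (pg C) for a taxon record, honouring fixed quotas."""
    if rec.carbon_model == "fixed":
        return float(rec.fixed_quota)
    return protist_carbon_quota(rec.biovolume, rec.carbon_model)


def community_biomass(counts: CountMatrix,
                      taxa: dict[str, TaxonRecord]) -> pd.DataFrame:
    """Biomass matrix (μg C L⁻¹ per taxon × sample) = abundance × quota.

    Linear in abundance; raises listing any taxa that cannot be resolved
    against the taxon table.
    """
    missing = [t for t in counts.taxa if t not in taxa]
    if missing:
        raise ValidationError(f"taxa without carbon model: {missing}")
    quotas = pd.Series({t: taxon_quota(taxa[t]) for t in counts.taxa})
    out = counts.data.mul(quotas, axis=0) / PG_PER_UG
    logger.info("community_biomass: %d taxa x %d samples", *out.shape)
    return out
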