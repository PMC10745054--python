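"""Bundled reference data from the sublingual-mucosa surrogate study.

The study this package models compared a track-etched polycarbonate
membrane ("Nuclepore", 0.05 µm pores) with porcine sublingual mucosa and
porcine skin, mounted in Franz diffusion cells:

* a transmembranal water-loss (TMWL) panel — 16 waterproofing
  formulations (5 hydrophobic, 5 hydrophilic, 6 liposomal) applied to
  the synthetic membrane and to the mucosa, plus untreated controls;
* steady-state permeability coefficients Kp (10⁻³ cm/h) for seven
  actives (four drugs, three biocides) through each of the three
  membranes;
* HPLC assay limits of detection / quantification per analyte.

These values serve as worked-example anchors and as calibration targets
for the synthetic generator; they are not re-measured by this package.
"""

from __future__ import annotations

from importlib import resources

from .study_data import AnalyteSpec, TMWLRecord, read_tmwl_table

#: Canonical membrane labels used throughout.
NUCLEPORE = "nuclepore"
MUCOSA = "mucosa"
SKIN = "skin"

#: Formulation class by panel index (F01–F16).
FORMULATION_CLASSES = {
    **{f"F{i:02d}": "hydrophobic" for i in range(1, 6)},
    **{f"F{i:02d}": "hydrophilic" for i in range(6, 11)},
    **{f"F{i:02d}": "liposomal" for i in range(11, 17)},
}

#: The seven study analytes: lipophilicity (log Ko/w at pH 7.4),
#: molecular weight (Da) and HPLC LoD/LoQ (µg/mL).
ANALYTES: dict[str, AnalyteSpec] = {
    a.name: a
    for a in (
        AnalyteSpec("caffeine", log_kow=-0.1, molecular_weight=194.2,
                    lod_ug_ml=0.82, loq_ug_ml=2.49),
        AnalyteSpec("ketorolac", log_kow=2.3, molecular_weight=376.4,
                    lod_ug_ml=0.10, loq_ug_ml=0.28),
        AnalyteSpec("dexamethasone", log_kow=1.8, molecular_weight=392.5,
                    lod_ug_ml=0.23, loq_ug_ml=0.70),
        AnalyteSpec("ivermectin", log_kow=5.8, molecular_weight=875.1,
                    lod_ug_ml=0.55, loq_ug_ml=1.66),
        AnalyteSpec("fungitrol", log_kow=2.4, molecular_weight=281.1,
                    lod_ug_ml=1.09, loq_ug_ml=3.31),
        AnalyteSpec("propiconazole", log_kow=3.5, molecular_weight=342.2,
                    lod_ug_ml=0.37, loq_ug_ml=1.11),
        AnalyteSpec("permethrin", log_kow=6.5, molecular_weight=391.3,
                    lod_ug_ml=0.49, loq_ug_ml=1.49),
    )
}

#: Measured permeability coefficients, Kp in 10⁻³ cm/h (means over n = 4
#: cells), per membrane and analyte. Used by the synthetic generator to
#: place its membranes in the observed permeability range.
KP_1E3_CM_H: dict[str, dict[str, float]] = {
    SKIN: {
        "caffeine": 5.1, "ketorolac": 2.2, "dexamethasone": 0.5,
        "ivermectin": 0.3, "fungitrol": 0.7, "propiconazole": 0.2,
        "permethrin": 0.2,
    },
    MUCOSA: {
        "caffeine": 39.2, "ketorolac": 59.4, "dexamethasone": 25.7,
        "ivermectin": 5.7, "fungitrol": 4.0, "propiconazole": 4.5,
        "permethrin": 2.7,
    },
    NUCLEPORE: {
        "caffeine": 54.7, "ketorolac": 67.5, "dexamethasone": 44.3,
        "ivermectin": 41.1, "fungitrol": 44.4, "propiconazole": 40.8,
        "permethrin": 36.8,
    },
}

#: Untreated-membrane TMWL baselines, g/(m²·h).
TMWL_BASELINES = {NUCLEPORE: 80.8, MUCOSA: 72.4}

#: Receptor caffeine Cmax (µg/mL) through unmodified membranes — the
#: worked-example anchor for percent-of-dose computations.
CAFFEINE_CMAX_UG_ML = {SKIN: 107.2, MUCOSA: 514.5, NUCLEPORE: 507.0}


def load_tmwl_panel() -> list[TMWLRecord]:
    """Load the bundled two-membrane TMWL panel (34 records).

    16 formulations on each of the synthetic membrane and the sublingual
    mucosa, plus one untreated control per membrane. Values are
    formulation means, g/(m²·h).
    """
    source = resources.files("franzperm").joinpath("data/tmwl_panel.csv")
    with resources.as_file(source) as path:
        return read_tmwl_table(path)


def formulation_class(formulation: str) -> str | None:
    """Map a panel formulation label (prefix F01–F16) to its class."""
    prefix = formulation.split()[0] if formulation else ""
    return FORMULATION_CLASSES.get(prefix)
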