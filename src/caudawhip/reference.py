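"""Published reference values shipped as fixtures for the audit stage.

These are the printed numbers from the source study's two result tables
for the Vienna *Plateosaurus trossingensis* specimen (Frick Field no.
15.5) and the comparative taxa, plus the stated model constants.  They
are *inputs* to the audit (which recomputes their internal arithmetic and
flags inconsistencies) and presets for the comparative pipeline; nothing
in the estimation code reads them.

The four Vienna mass/energy variants are indexed by column key:

======================  ==============================================
``bone``                preserved bones only
``bone_imputed``        with the four missing caudals interpolated
``soft``                bones + estimated soft tissue
``soft_imputed``        imputed caudals + soft tissue
======================  ==============================================
"""

from __future__ import annotations

# --- model constants as stated in the source -------------------------------

DENSITY_KG_PER_LITRE = 0.8          # bulk density, kg per 1000 cm³
MUSCLE_FRACTION = 0.359             # muscle volume fraction added as soft tissue
SKIN_FRACTION = 0.057               # skin volume fraction added as soft tissue
ROUNDED_SCALING_FACTOR = 1.7        # 1/(1-0.359-0.057) at 2 significant figures
STATED_STRIKE_VELOCITY_M_S = 2.0    # stated upper-bound lateral strike velocity
TRANSFER_EFFICIENCY = 0.85          # implied by every transferred/total ratio; unstated

# Vienna specimen bookkeeping
VIENNA_SPECIMEN_ID = "Frick-15.5"
VIENNA_PRESERVED_CAUDALS = 43
VIENNA_EXPECTED_CAUDALS = 45
VIENNA_MISSING_POSITIONS = (4, 9, 27, 37)
VIENNA_TP_POSITION = 25             # whiplash computed "from Ca25"

# --- Vienna energy/mass grid (first result table) --------------------------

TABLE1_COLUMNS = ("bone", "bone_imputed", "soft", "soft_imputed")

TABLE1 = {
    "tail_mass_kg": (26.5, 28.4, 76.5, 82.0),
    "tail_length_m": (1.958, 2.1, 1.958, 2.1),
    "whiplash_mass_kg": (0.3, 0.3, 0.7, 0.8),
    "whiplash_length_m": (0.597, 0.622, 0.597, 0.622),
    "whole_tail_energy_kJ": (56.136, 60.207, 162.234, 173.999),
    "transferred_energy_kJ": (47.716, 51.176, 137.899, 147.899),
    "quick_whiplash_energy_kJ": (0.537, 0.559, 1.553, 1.616),
}


def table1_value(row: str, column: str) -> float:
    """Look up one printed Vienna grid value by row name and column key."""
    return TABLE1[row][TABLE1_COLUMNS.index(column)]


# --- comparative table (second result table) -------------------------------
# fields: taxon, specimen, n caudals, total tail length (m), whip length (m),
#         printed whip percentage, bone-only whole-tail-whip energy (kJ)

TABLE2 = (
    {
        "taxon": "Varanus salvator",
        "specimen_id": "IPUW 3480",
        "n_caudals": 110.0,
        "total_length_m": 1.03,
        "whip_length_m": 0.34,
        "whip_pct": 32.80,
        "energy_kJ": 0.03,
    },
    {
        "taxon": "Diplodocus carnegii",
        "specimen_id": "NHMW 1904/0004/0003",
        "n_caudals": 70.0,
        "total_length_m": 13.26,
        "whip_length_m": 7.28,
        "whip_pct": 54.90,
        "energy_kJ": 179.54,
    },
    {
        "taxon": "Plateosaurus trossingensis (Huene)",
        "specimen_id": "Huene-1926",
        "n_caudals": 42.0,
        "total_length_m": 2.55,
        "whip_length_m": 0.48,
        "whip_pct": 18.70,
        "energy_kJ": 82.51,
    },
    {
        "taxon": "Plateosaurus trossingensis (Vienna)",
        "specimen_id": VIENNA_SPECIMEN_ID,
        "n_caudals": 42.0,
        "total_length_m": 1.90,
        "whip_length_m": 0.60,
        "whip_pct": 31.50,
        "energy_kJ": 56.14,
    },
    {
        "taxon": "Iguana iguana",
        "specimen_id": "NHMW-ZOO-HS-1680",
        "n_caudals": 39.0,
        "total_length_m": 0.64,
        "whip_length_m": 0.41,
        "whip_pct": 37.10,
        "energy_kJ": 0.01,
    },
)

# --- comparative-taxon strike parameters -----------------------------------
# Diplodocus mass and velocity follow published biomechanical modelling of
# diplodocid tail whips; extant-taxon velocities are the upper bounds of
# published ranges (monitor ~13-20 m/s, iguana 5-10 m/s).

DIPLODOCUS_TAIL_MASS_KG = 33.2
DIPLODOCUS_STRIKE_VELOCITY_M_S = 104.0
VARANUS_STRIKE_VELOCITY_M_S = 20.0
IGUANA_STRIKE_VELOCITY_M_S = 10.0
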