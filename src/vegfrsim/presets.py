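"""Reference parameter sets for HUVEC and RAW 264.7 simulations.

These are *synthetic stand-ins* for the supplementary parameter tables the
model was originally seeded from.  The structural facts stated in the main
literature are encoded directly: five VEGFR1 carboxy-terminal tyrosine
sites (Tyr794, Tyr1169, Tyr1213, Tyr1242, Tyr1333) at 0.171 Å/amino acid,
PLCγ and PI3K as the only Tyr794 binders, Src docking at Tyr1169/Tyr1213,
a global adapter phosphorylation rate of 0.01/s, a 1 pL cell volume, and a
50 ng/mL VEGF-A164 dose.  Everything else — adapter crystal-structure
extents, SH2 binding kinetics, copy numbers per cell, and response
weights — is set once to field-typical values (SH2 Kd's in the
0.1-1 µM range, qFlow-scale receptor counts, adapter pools of 1e3-1e4
copies/cell) and flagged ``provenance: fixture``.

Adapter sizes (~50-60 Å) combined with the site spacing make exactly the
documented steric outcome emerge: at most two adapters bind VEGFR1
simultaneously and every feasible pair includes Tyr794, because the
distal-site cluster (Tyr1169...Tyr1333, gaps of 5-28 Å) cannot fit two
adapter half-footprints while Tyr794 sits >= 64 Å away from the cluster.
"""

from __future__ import annotations

from .errors import ConfigurationError
from .params import (
    AdapterSpec,
    LigandSpec,
    ModelParameters,
    PhosphataseSpec,
    ReceptorSpec,
    per_molar_rate_to_per_molecule as _k2,
)

VEGFR1_SITES = (("Y794", 794), ("Y1169", 1169), ("Y1213", 1213),
                ("Y1242", 1242), ("Y1333", 1333))
VEGFR2_SITES = (("Y951", 951), ("Y1059", 1059), ("Y1175", 1175), ("Y1214", 1214))

#: receptor surface densities, molecules/cell (qFlow-scale; fixture)
_RECEPTOR_CONC = {
    "HUVEC": {"VEGFR1": 1800.0, "VEGFR2": 4900.0},
    "RAW": {"VEGFR1": 10300.0, "VEGFR2": 2200.0},
}

#: adapter pools, molecules/cell (fixture)
_ADAPTER_CONC = {
    "HUVEC": {"PLCg": 1.2e4, "PI3K": 8.0e3, "Src": 5.0e3, "Abl": 2.0e3, "cCbl": 3.0e3},
    "RAW": {"PLCg": 9.0e3, "PI3K": 1.2e4, "Src": 6.0e3, "Abl": 3.0e3, "cCbl": 4.0e3},
}

#: SH2-domain binding kinetics (kon in 1/(M s), koff in 1/s) and
#: crystal-structure extent along the tail axis (Å); all fixture
_ADAPTER_KINETICS = {
    #        kon_M    koff   size_y
    "PLCg": (1.0e6, 0.30, 56.0),
    "PI3K": (8.0e5, 0.20, 60.0),
    "Src": (5.0e5, 0.50, 48.0),
    "Abl": (5.0e5, 0.50, 52.0),
    "cCbl": (6.0e5, 0.40, 58.0),
}

#: receptor tyrosine-site docking maps
_SITE_MAP = {
    "VEGFR1": {
        "PLCg": ("Y794", "Y1169"),
        "PI3K": ("Y794", "Y1213"),
        "Src": ("Y1169", "Y1213"),
        "Abl": ("Y1213",),
        "cCbl": ("Y1333",),
    },
    "VEGFR2": {
        "PLCg": ("Y1175",),
        "PI3K": ("Y1175",),
        "Src": ("Y951", "Y1214"),
        "Abl": ("Y1214",),
        "cCbl": ("Y1059",),
    },
}

#: response weights (unitless, fixture): migration led by PLCγ then PI3K,
#: proliferation dominated by PLCγ; c-Cbl feeds only the degradation channel
_WEIGHTS = {
    "PLCg": {"migration": 0.45, "proliferation": 0.50},
    "PI3K": {"migration": 0.30, "proliferation": 0.10},
    "Src": {"migration": 0.15, "proliferation": 0.25},
    "Abl": {"migration": 0.05, "proliferation": 0.10},
    "cCbl": {"migration": 0.0, "proliferation": 0.0},
}

#: VEGF capture kinetics (kon in 1/(M s), koff in 1/s); VEGFR1 binds VEGF
#: roughly an order of magnitude tighter than VEGFR2
_VEGF_KINETICS = {"VEGFR1": (3.0e7, 1.0e-3), "VEGFR2": (1.0e7, 1.0e-3)}


def reference_parameters(cell: str = "HUVEC") -> ModelParameters:
    """Build the reference VEGFR1+VEGFR2 parameter set for one cell type."""
    if cell not in _RECEPTOR_CONC:
        raise ConfigurationError(f"unknown cell type {cell!r}; use HUVEC or RAW")
    receptors = []
    for rname, sites in (("VEGFR1", VEGFR1_SITES), ("VEGFR2", VEGFR2_SITES)):
        kon_m, koff = _VEGF_KINETICS[rname]
        receptors.append(
            ReceptorSpec(
                name=rname,
                concentration=_RECEPTOR_CONC[cell][rname],
                kon_vegf=_k2(kon_m),
                koff_vegf=koff,
                sites=sites,
                aa_spacing=0.171,
                provenance="fixture",
            )
        )
    adapters = []
    for aname, (kon_m, koff, size_y) in _ADAPTER_KINETICS.items():
        adapters.append(
            AdapterSpec(
                name=aname,
                concentration=_ADAPTER_CONC[cell][aname],
                kon=_k2(kon_m),
                koff=koff,
                size_y=size_y,
                site_names={r: _SITE_MAP[r][aname] for r in _SITE_MAP},
                weights=dict(_WEIGHTS[aname]),
                provenance="fixture",
            )
        )
    params = ModelParameters(
        receptors=receptors,
        adapters=adapters,
        phosphatase=PhosphataseSpec(),
        ligand=LigandSpec(concentration_mass=50.0),
    )
    return params.validate()
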