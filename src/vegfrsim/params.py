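"""Parameter data model, unit conversions, file I/O, and fixture generation.

The model works in molecules/cell and seconds.  Bimolecular rate constants
are stored in 1/(molecule*s), i.e. already divided by ``N_A * V_cell`` so
that mass-action propensities can be formed directly from copy numbers.
Concentrations quoted in the literature in molar units are converted through
the cell volume (default 1 pL).

Parameter sets are stored on disk as a directory of four CSV tables
(``receptors.csv``, ``sites.csv``, ``adapters.csv``, ``weights.csv``) plus a
``config.yaml`` holding the scalar parameters (global phosphorylation rate,
cell volume, ligand dose, phosphatase kinetics).  Column layouts are
documented in :func:`save_parameters`.
"""

from __future__ import annotations

import copy
import csv
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import (
    ParameterParseError,
    ParameterValidationError,
    UnknownEntityError,
)

AVOGADRO = 6.02214076e23  # 1/mol

#: default global adapter phosphorylation rate, 1/s
DEFAULT_KP = 0.01
#: default cell volume used for molar <-> molecules/cell conversion, L
DEFAULT_CELL_VOLUME = 1e-12
#: default VEGF-A164 homodimer molecular weight, g/mol
DEFAULT_VEGF_MW = 38200.0

RESPONSES = ("migration", "proliferation", "degradation")
#: the adapter whose phosphorylation *is* the degradation response
DEGRADATION_ADAPTER = "cCbl"


def molar_to_molecules(concentration: float, volume: float = DEFAULT_CELL_VOLUME) -> float:
    """Convert mol/L to molecules per cell of the given volume (L)."""
    if concentration < 0:
        raise ParameterValidationError(f"negative concentration: {concentration}")
    if volume <= 0:
        raise ParameterValidationError(f"non-positive volume: {volume}")
    return concentration * AVOGADRO * volume


def molecules_to_molar(count: float, volume: float = DEFAULT_CELL_VOLUME) -> float:
    """Inverse of :func:`molar_to_molecules`."""
    if count < 0:
        raise ParameterValidationError(f"negative count: {count}")
    if volume <= 0:
        raise ParameterValidationError(f"non-positive volume: {volume}")
    return count / (AVOGADRO * volume)


def per_molar_rate_to_per_molecule(kon: float, volume: float = DEFAULT_CELL_VOLUME) -> float:
    """Convert a bimolecular rate from 1/(M*s) to 1/(molecule*s)."""
    if kon < 0:
        raise ParameterValidationError(f"negative rate: {kon}")
    return kon / (AVOGADRO * volume)


@dataclass
class AdapterSpec:
    """One intracellular adapter protein (PLCγ, PI3K, Src, Abl, c-Cbl, ...).

    ``kon``/``koff`` apply to every receptor and every tyrosine site the
    adapter can occupy (a single SH2-domain interaction is assumed).
    ``size_y`` is the maximal extent of the adapter along the receptor
    carboxy-terminal axis, in Å; half of it is the one-sided footprint used
    by the steric feasibility rule.  ``kp_scale`` multiplies the global
    phosphorylation rate; inhibitors set it to 0.
    """

    name: str
    concentration: float  # molecules/cell
    kon: float  # 1/(molecule*s)
    koff: float  # 1/s
    size_y: float  # Å
    site_names: dict[str, tuple[str, ...]] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    kp_scale: float = 1.0
    provenance: str = "fixture"

    def validate(self) -> None:
        if self.concentration < 0:
            raise ParameterValidationError(
                f"adapter {self.name}: concentration must be >= 0, got {self.concentration}"
            )
        for attr in ("kon", "koff", "size_y"):
            if getattr(self, attr) <= 0:
                raise ParameterValidationError(
                    f"adapter {self.name}: {attr} must be > 0, got {getattr(self, attr)}"
                )
        if self.kp_scale < 0:
            raise ParameterValidationError(f"adapter {self.name}: kp_scale must be >= 0")
        for resp, w in self.weights.items():
            if w < 0:
                raise ParameterValidationError(
                    f"adapter {self.name}: weight for {resp} must be >= 0, got {w}"
                )

    @property
    def kd_molecules(self) -> float:
        """Dissociation constant in molecules/cell units."""
        return self.koff / self.kon

    def weight(self, response: str) -> float:
        return self.weights.get(response, 0.0)


@dataclass
class ReceptorSpec:
    """A VEGF receptor with its carboxy-terminal tyrosine docking sites.

    ``sites`` is ordered by residue index; ``aa_spacing`` converts residue
    separation to physical distance along the tail (Å per amino acid).
    """

    name: str
    concentration: float  # molecules/cell
    kon_vegf: float  # 1/(molecule*s)
    koff_vegf: float  # 1/s
    sites: tuple[tuple[str, int], ...] = ()
    aa_spacing: float = 0.171  # Å / amino acid
    provenance: str = "fixture"

    def validate(self) -> None:
        if self.concentration < 0:
            raise ParameterValidationError(
                f"receptor {self.name}: concentration must be >= 0, got {self.concentration}"
            )
        for attr in ("kon_vegf", "koff_vegf", "aa_spacing"):
            if getattr(self, attr) <= 0:
                raise ParameterValidationError(
                    f"receptor {self.name}: {attr} must be > 0, got {getattr(self, attr)}"
                )
        residues = [r for _, r in self.sites]
        if any(b <= a for a, b in zip(residues, residues[1:])):
            raise ParameterValidationError(
                f"receptor {self.name}: site residue indices must be strictly increasing"
            )
        names = [s for s, _ in self.sites]
        if len(set(names)) != len(names):
            raise ParameterValidationError(f"receptor {self.name}: duplicate site names")

    @property
    def site_names(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.sites)

    def residue(self, site: str) -> int:
        for s, r in self.sites:
            if s == site:
                return r
        raise UnknownEntityError(f"receptor {self.name} has no site {site!r}")


@dataclass
class PhosphataseSpec:
    """Generalized phosphatase (PTPN) treated as an inexhaustible reservoir."""

    kon: float = per_molar_rate_to_per_molecule(1e6)  # 1/(molecule*s)
    koff: float = 0.1  # 1/s
    kd_cat: float = 0.1  # catalytic dephosphorylation rate, 1/s
    reservoir_concentration: float = 1e5  # molecules/cell, held constant

    def validate(self) -> None:
        for attr in ("kon", "koff", "kd_cat", "reservoir_concentration"):
            if getattr(self, attr) <= 0:
                raise ParameterValidationError(
                    f"phosphatase: {attr} must be > 0, got {getattr(self, attr)}"
                )


@dataclass
class LigandSpec:
    """VEGF dose.  Mass concentration in ng/mL; converted via the homodimer MW."""

    concentration_mass: float = 50.0  # ng/mL
    molecular_weight: float = DEFAULT_VEGF_MW  # g/mol
    depletion_mode: bool = False  # False: bath ligand held constant

    def validate(self) -> None:
        if self.concentration_mass < 0:
            raise ParameterValidationError(
                f"ligand: concentration_mass must be >= 0, got {self.concentration_mass}"
            )
        if self.molecular_weight <= 0:
            raise ParameterValidationError(
                f"ligand: molecular_weight must be > 0, got {self.molecular_weight}"
            )


def ligand_molar(ligand: LigandSpec) -> float:
    """VEGF dose in mol/L: (ng/mL == ug/L == 1e-6 g/L) over g/mol."""
    ligand.validate()
    return ligand.concentration_mass * 1e-6 / ligand.molecular_weight


@dataclass
class ModelParameters:
    """The complete parameterization of a VEGFR-adapter signaling model."""

    receptors: list[ReceptorSpec] = field(default_factory=list)
    adapters: list[AdapterSpec] = field(default_factory=list)
    phosphatase: PhosphataseSpec = field(default_factory=PhosphataseSpec)
    ligand: LigandSpec = field(default_factory=LigandSpec)
    kp: float = DEFAULT_KP  # 1/s
    cell_volume: float = DEFAULT_CELL_VOLUME  # L
    degradation_adapter: str = DEGRADATION_ADAPTER

    def validate(self) -> "ModelParameters":
        if self.kp <= 0:
            raise ParameterValidationError(f"kp must be > 0, got {self.kp}")
        if self.cell_volume <= 0:
            raise ParameterValidationError(f"cell_volume must be > 0, got {self.cell_volume}")
        names = [a.name for a in self.adapters]
        if len(set(names)) != len(names):
            raise ParameterValidationError("adapter names must be unique")
        rnames = [r.name for r in self.receptors]
        if len(set(rnames)) != len(rnames):
            raise ParameterValidationError("receptor names must be unique")
        self.phosphatase.validate()
        self.ligand.validate()
        for r in self.receptors:
            r.validate()
        for a in self.adapters:
            a.validate()
            for rname, sites in a.site_names.items():
                rec = self.receptor(rname)
                for s in sites:
                    if s not in rec.site_names:
                        raise ParameterValidationError(
                            f"adapter {a.name}: site {s!r} not on receptor {rname}"
                        )
                # canonical order: by residue along the tail
                a.site_names[rname] = tuple(
                    s for s in rec.site_names if s in set(sites)
                )
        return self

    def receptor(self, name: str) -> ReceptorSpec:
        for r in self.receptors:
            if r.name == name:
                return r
        raise UnknownEntityError(f"unknown receptor {name!r}")

    def adapter(self, name: str) -> AdapterSpec:
        for a in self.adapters:
            if a.name == name:
                return a
        raise UnknownEntityError(f"unknown adapter {name!r}")

    def vegf_molecules(self) -> float:
        """Ligand copy number in the reaction volume (molecules/cell-volume)."""
        return molar_to_molecules(ligand_molar(self.ligand), self.cell_volume)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def digest(self) -> str:
        """Stable content hash identifying this parameterization."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_RECEPTOR_COLS = ["name", "concentration", "kon_vegf", "koff_vegf", "aa_spacing", "provenance"]
_SITE_COLS = ["receptor", "site", "residue", "adapters"]
_ADAPTER_COLS = ["name", "concentration", "kon", "koff", "size_y", "kp_scale", "provenance"]
_WEIGHT_COLS = ["adapter", "response", "weight"]


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter directory.

    Layout::

        receptors.csv  name, concentration, kon_vegf, koff_vegf, aa_spacing, provenance
        sites.csv      receptor, site, residue, adapters   (';'-joined adapter names)
        adapters.csv   name, concentration, kon, koff, size_y, kp_scale, provenance
        weights.csv    adapter, response, weight
        config.yaml    kp, cell_volume, degradation_adapter, ligand{...}, phosphatase{...}
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    def _write(fname: str, cols: list[str], rows: list[list]) -> None:
        with open(path / fname, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            w.writerows(rows)

    _write(
        "receptors.csv",
        _RECEPTOR_COLS,
        [
            [r.name, repr(r.concentration), repr(r.kon_vegf), repr(r.koff_vegf),
             repr(r.aa_spacing), r.provenance]
            for r in params.receptors
        ],
    )
    site_rows = []
    for r in params.receptors:
        for site, residue in r.sites:
            binders = [a.name for a in params.adapters
                       if site in a.site_names.get(r.name, ())]
            site_rows.append([r.name, site, residue, ";".join(binders)])
    _write("sites.csv", _SITE_COLS, site_rows)
    _write(
        "adapters.csv",
        _ADAPTER_COLS,
        [
            [a.name, repr(a.concentration), repr(a.kon), repr(a.koff),
             repr(a.size_y), repr(a.kp_scale), a.provenance]
            for a in params.adapters
        ],
    )
    weight_rows = [
        [a.name, resp, repr(w)]
        for a in params.adapters
        for resp, w in sorted(a.weights.items())
    ]
    _write("weights.csv", _WEIGHT_COLS, weight_rows)

    config = {
        "kp": params.kp,
        "cell_volume": params.cell_volume,
        "degradation_adapter": params.degradation_adapter,
        "ligand": {
            "concentration_mass": params.ligand.concentration_mass,
            "molecular_weight": params.ligand.molecular_weight,
            "depletion_mode": params.ligand.depletion_mode,
        },
        "phosphatase": {
            "kon": params.phosphatase.kon,
            "koff": params.phosphatase.koff,
            "kd_cat": params.phosphatase.kd_cat,
            "reservoir_concentration": params.phosphatase.reservoir_concentration,
        },
    }
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _read_table(path: Path, required: list[str]) -> list[dict[str, str]]:
    if not path.exists():
        raise ParameterParseError(f"missing parameter table: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParameterParseError(f"{path}: empty file")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ParameterParseError(f"{path}: missing columns {missing}")
        rows = []
        for i, row in enumerate(reader, start=2):
            row["_line"] = str(i)
            rows.append(row)
    return rows


def _to_float(row: dict, key: str, path: Path) -> float:
    try:
        return float(row[key])
    except (TypeError, ValueError) as exc:
        raise ParameterParseError(
            f"{path} line {row['_line']}: field {key!r} = {row.get(key)!r} is not numeric"
        ) from exc


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a parameter directory written by :func:`save_parameters`.

    Missing optional scalars fall back to the documented defaults
    (kp = 0.01/s, cell volume = 1 pL).
    """
    path = Path(path)
    if not path.is_dir():
        raise ParameterParseError(f"parameter path is not a directory: {path}")

    config: dict = {}
    cfg_path = path / "config.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            try:
                config = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ParameterParseError(f"{cfg_path}: invalid YAML: {exc}") from exc

    receptors: list[ReceptorSpec] = []
    for row in _read_table(path / "receptors.csv", _RECEPTOR_COLS[:-1]):
        receptors.append(
            ReceptorSpec(
                name=row["name"],
                concentration=_to_float(row, "concentration", path),
                kon_vegf=_to_float(row, "kon_vegf", path),
                koff_vegf=_to_float(row, "koff_vegf", path),
                aa_spacing=_to_float(row, "aa_spacing", path),
                provenance=row.get("provenance", "fixture") or "fixture",
            )
        )
    rec_by_name = {r.name: r for r in receptors}

    site_map: dict[str, list[tuple[str, int]]] = {r.name: [] for r in receptors}
    binders: dict[tuple[str, str], list[str]] = {}
    for row in _read_table(path / "sites.csv", _SITE_COLS):
        rname = row["receptor"]
        if rname not in rec_by_name:
            raise ParameterParseError(
                f"{path}/sites.csv line {row['_line']}: unknown receptor {rname!r}"
            )
        site = row["site"]
        site_map[rname].append((site, int(_to_float(row, "residue", path))))
        names = [s for s in (row.get("adapters") or "").split(";") if s]
        binders[(rname, site)] = names
    for r in receptors:
        r.sites = tuple(sorted(site_map[r.name], key=lambda t: t[1]))

    adapters: list[AdapterSpec] = []
    for row in _read_table(path / "adapters.csv", _ADAPTER_COLS[:-2]):
        name = row["name"]
        site_names: dict[str, tuple[str, ...]] = {}
        for (rname, site), ads in binders.items():
            if name in ads:
                site_names.setdefault(rname, ())
                site_names[rname] = site_names[rname] + (site,)
        adapters.append(
            AdapterSpec(
                name=name,
                concentration=_to_float(row, "concentration", path),
                kon=_to_float(row, "kon", path),
                koff=_to_float(row, "koff", path),
                size_y=_to_float(row, "size_y", path),
                site_names=site_names,
                kp_scale=float(row["kp_scale"]) if row.get("kp_scale") else 1.0,
                provenance=row.get("provenance", "fixture") or "fixture",
            )
        )
    ad_by_name = {a.name: a for a in adapters}

    wpath = path / "weights.csv"
    if wpath.exists():
        for row in _read_table(wpath, _WEIGHT_COLS):
            aname = row["adapter"]
            if aname not in ad_by_name:
                raise ParameterParseError(
                    f"{wpath} line {row['_line']}: unknown adapter {aname!r}"
                )
            ad_by_name[aname].weights[row["response"]] = _to_float(row, "weight", path)

    lig_cfg = config.get("ligand", {})
    ptp_cfg = config.get("phosphatase", {})
    params = ModelParameters(
        receptors=receptors,
        adapters=adapters,
        phosphatase=PhosphataseSpec(**ptp_cfg) if ptp_cfg else PhosphataseSpec(),
        ligand=LigandSpec(**lig_cfg) if lig_cfg else LigandSpec(),
        kp=float(config.get("kp", DEFAULT_KP)),
        cell_volume=float(config.get("cell_volume", DEFAULT_CELL_VOLUME)),
        degradation_adapter=config.get("degradation_adapter", DEGRADATION_ADAPTER),
    )
    return params.validate()


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def generate_fixture_parameters(
    seed: int,
    n_adapters: int,
    n_receptors: int = 2,
    n_sites: int = 3,
) -> ModelParameters:
    """Generate a random but structurally faithful parameter set.

    Adapter concentrations are log-uniform on [1e2, 1e5] molecules/cell (the
    concentration-sweep range), dissociation constants log-uniform on
    1-1000 nM, and adapter sizes are drawn (then inflated if necessary) so
    that at least one steric co-occupancy constraint is active on the first
    receptor.  Deterministic for a fixed seed.
    """
    if n_adapters < 1:
        raise ParameterValidationError("n_adapters must be >= 1")
    rng = np.random.default_rng(seed)

    receptors: list[ReceptorSpec] = []
    for i in range(n_receptors):
        base = int(rng.integers(700, 900))
        gaps = rng.integers(40, 400, size=n_sites)
        residues = base + np.cumsum(gaps)
        sites = tuple((f"Y{r}", int(r)) for r in residues)
        receptors.append(
            ReceptorSpec(
                name=f"R{i + 1}",
                concentration=float(rng.uniform(1e3, 2e4)),
                kon_vegf=per_molar_rate_to_per_molecule(float(rng.uniform(1e6, 1e7))),
                koff_vegf=float(rng.uniform(1e-4, 1e-2)),
                sites=sites,
                aa_spacing=0.171,
            )
        )

    adapters: list[AdapterSpec] = []
    for j in range(n_adapters):
        kd_nm = 10 ** rng.uniform(0, 3)  # 1-1000 nM
        koff = float(10 ** rng.uniform(-2, 0))
        kon = per_molar_rate_to_per_molecule(koff / (kd_nm * 1e-9))
        site_names: dict[str, tuple[str, ...]] = {}
        for rec in receptors:
            k = int(rng.integers(1, len(rec.site_names) + 1))
            idx = rng.choice(len(rec.site_names), size=k, replace=False)
            site_names[rec.name] = tuple(rec.site_names[i] for i in sorted(idx))
        adapters.append(
            AdapterSpec(
                name=f"A{j + 1}",
                concentration=float(10 ** rng.uniform(2, 5)),
                kon=kon,
                koff=koff,
                size_y=float(rng.uniform(20, 80)),
                site_names=site_names,
                weights={
                    "migration": float(rng.uniform(0, 1)),
                    "proliferation": float(rng.uniform(0, 1)),
                },
            )
        )

    # guarantee an active steric constraint: some adapter pair must not fit
    # between the closest pair of sites either of them can flank
    rec = receptors[0]
    residues = [r for _, r in rec.sites]
    min_gap = min(
        abs(b - a) * rec.aa_spacing for a, b in zip(residues, residues[1:])
    ) if len(residues) > 1 else 0.0
    if len(residues) > 1:
        largest = max(adapters, key=lambda a: a.size_y)
        if largest.size_y / 2 + min(a.size_y for a in adapters) / 2 <= min_gap:
            largest.size_y = 2 * min_gap + 1.0

    params = ModelParameters(receptors=receptors, adapters=adapters)
    return params.validate()
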