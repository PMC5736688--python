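"""Rule-based generation of mass-action reaction networks.

Two model variants are produced from the same parameterization:

* **nonspecific** — every adapter competes for a single generic
  phospho-tyrosine site; at most one adapter is bound per receptor at a
  time.  Reactions follow the five-step scheme per receptor R and
  adapter A::

      VEGF + R        <-> pR                    (kon_VEGF / koff_VEGF)
      pR + A          <-> [pR:A]                (kon_A / koff_A)
      [pR:A]           -> [pR:pA]               (kp)
      [pR:pA] + PTPN  <-> [pR:pA:PTPN]          (kon_PTPN / koff_PTPN)
      [pR:pA:PTPN]     -> pR + [A:PTPN]         (kd_PTPN)
      [A:PTPN]         -> A + PTPN              (koff_PTPN)

  The final release step closes the adapter cycle (the adapter moiety is
  conserved).

* **specific** — receptor species are phospho-receptors annotated with a
  sterically feasible occupancy state: each bound adapter sits at a named
  tyrosine site and is unphosphorylated (``u``), phosphorylated (``p``), or
  phosphorylated with phosphatase attached (``pP``).  Binding connects a
  state to each feasible superstate; phosphorylation, phosphatase
  association and catalysis act per bound adapter with the same rate
  constants as above.

The ligand is a boundary species held constant by default (bath dosing);
the phosphatase reservoir is always held constant.  Receptor
phosphorylation is lumped into ligand binding (VEGF + R directly yields
pR); ligand dissociation occurs only from the unoccupied phospho-receptor.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, UnknownEntityError
from .params import ModelParameters
from .steric import BindingConfiguration, enumerate_configurations

VEGF_ID = "VEGF"
PTPN_ID = "PTPN"

#: per-adapter flag values: unphosphorylated, phospho, phospho with PTPN bound
FLAGS = ("u", "p", "pP")


@dataclass(frozen=True)
class Species:
    """One chemical species, with enough composition metadata to form
    moiety-conservation vectors and phospho-adapter readouts.

    ``adapter_content`` counts copies of each adapter in the species (bound
    or complexed), ``phospho_content`` counts only chemically phosphorylated
    copies (flags ``p`` and ``pP``; the post-catalysis [A:PTPN] complex is
    dephosphorylated and does not count).
    """

    id: str
    kind: str  # ligand | free_receptor | phospho_receptor_complex |
    #            free_adapter | adapter_phosphatase_complex | phosphatase
    receptor: str | None = None
    occupancy: tuple[tuple[str, str, str], ...] = ()  # (site, adapter, flag)
    adapter: str | None = None
    constant: bool = False

    @property
    def adapter_content(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        if self.adapter is not None:
            counts[self.adapter] = counts.get(self.adapter, 0) + 1
        for _, a, _ in self.occupancy:
            counts[a] = counts.get(a, 0) + 1
        return counts

    @property
    def phospho_content(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, a, flag in self.occupancy:
            if flag in ("p", "pP"):
                counts[a] = counts.get(a, 0) + 1
        return counts


@dataclass(frozen=True)
class Reaction:
    """An irreversible elementary mass-action reaction.

    Reversible scheme steps are emitted as two reactions sharing a ``label``
    (suffixed ``+``/``-``); :func:`n_scheme_steps` counts label groups.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float  # 1/s (unimolecular) or 1/(molecule*s) (bimolecular)
    label: str

    def __post_init__(self):
        left = sorted(self.reactants)
        if len(left) > 2:
            raise ConfigurationError(f"reaction {self.label}: order > 2 unsupported")


@dataclass
class ReactionNetwork:
    """Enumerated species and reactions plus the initial state."""

    variant: str
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    initial_state: dict[str, float] = field(default_factory=dict)
    params_digest: str = ""

    def __post_init__(self):
        self._index = {s.id: i for i, s in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise ConfigurationError("duplicate species ids")

    def species_by_id(self, sid: str) -> Species:
        try:
            return self.species[self._index[sid]]
        except KeyError:
            raise UnknownEntityError(f"unknown species {sid!r}") from None

    def index(self, sid: str) -> int:
        try:
            return self._index[sid]
        except KeyError:
            raise UnknownEntityError(f"unknown species {sid!r}") from None

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def validate(self) -> "ReactionNetwork":
        for r in self.reactions:
            for sid in r.reactants + r.products:
                self.species_by_id(sid)
        for sid, x0 in self.initial_state.items():
            self.species_by_id(sid)
            if x0 < 0:
                raise ConfigurationError(f"negative initial amount for {sid}")
        return self


def n_scheme_steps(network: ReactionNetwork) -> int:
    """Number of scheme steps (reversible pairs counted once)."""
    return len({r.label.rstrip("+-") for r in network.reactions})


# ---------------------------------------------------------------------------
# species id construction
# ---------------------------------------------------------------------------

def _occupancy_id(receptor: str, occupancy: tuple[tuple[str, str, str], ...]) -> str:
    if not occupancy:
        return f"p{receptor}"
    inner = "|".join(f"{site}:{a}~{flag}" for site, a, flag in occupancy)
    return f"p{receptor}[{inner}]"


def _sort_occupancy(
    rec_site_order: dict[str, int], occupancy: dict[str, tuple[str, str]]
) -> tuple[tuple[str, str, str], ...]:
    return tuple(
        (site, a, flag)
        for site, (a, flag) in sorted(occupancy.items(), key=lambda kv: rec_site_order[kv[0]])
    )


# ---------------------------------------------------------------------------
# shared species (ligand, phosphatase, adapters)
# ---------------------------------------------------------------------------

def _base_species(params: ModelParameters) -> tuple[list[Species], dict[str, float]]:
    species = [
        Species(VEGF_ID, "ligand", constant=not params.ligand.depletion_mode),
        Species(PTPN_ID, "phosphatase", constant=True),
    ]
    init = {
        VEGF_ID: params.vegf_molecules(),
        PTPN_ID: params.phosphatase.reservoir_concentration,
    }
    for a in params.adapters:
        species.append(Species(a.name, "free_adapter", adapter=a.name))
        species.append(
            Species(f"{a.name}:PTPN", "adapter_phosphatase_complex", adapter=a.name)
        )
        init[a.name] = a.concentration
        init[f"{a.name}:PTPN"] = 0.0
    return species, init


def _release_reactions(params: ModelParameters) -> list[Reaction]:
    ptp = params.phosphatase
    return [
        Reaction((f"{a.name}:PTPN",), (a.name, PTPN_ID), ptp.koff, f"release:{a.name}")
        for a in params.adapters
    ]


# ---------------------------------------------------------------------------
# nonspecific model
# ---------------------------------------------------------------------------

def build_nonspecific_network(params: ModelParameters) -> ReactionNetwork:
    """Single generic phospho-tyrosine site per receptor, one adapter at a time."""
    params.validate()
    ptp = params.phosphatase
    species, init = _base_species(params)
    reactions: list[Reaction] = []

    for rec in params.receptors:
        rid, prid = rec.name, f"p{rec.name}"
        species.append(Species(rid, "free_receptor", receptor=rec.name))
        species.append(Species(prid, "phospho_receptor_complex", receptor=rec.name))
        init[rid] = rec.concentration
        init[prid] = 0.0
        reactions.append(
            Reaction((VEGF_ID, rid), (prid,), rec.kon_vegf, f"ligand:{rec.name}+")
        )
        reactions.append(
            Reaction((prid,), (VEGF_ID, rid), rec.koff_vegf, f"ligand:{rec.name}-")
        )
        for a in params.adapters:
            if not a.site_names.get(rec.name):
                continue
            bound = f"{prid}:{a.name}"
            phospho = f"{prid}:p{a.name}"
            ternary = f"{prid}:p{a.name}:PTPN"
            species.append(
                Species(bound, "phospho_receptor_complex", receptor=rec.name,
                        occupancy=(("pY", a.name, "u"),))
            )
            species.append(
                Species(phospho, "phospho_receptor_complex", receptor=rec.name,
                        occupancy=(("pY", a.name, "p"),))
            )
            species.append(
                Species(ternary, "phospho_receptor_complex", receptor=rec.name,
                        occupancy=(("pY", a.name, "pP"),))
            )
            init[bound] = init[phospho] = init[ternary] = 0.0
            tag = f"{rec.name}:{a.name}"
            reactions.append(Reaction((prid, a.name), (bound,), a.kon, f"bind:{tag}+"))
            reactions.append(Reaction((bound,), (prid, a.name), a.koff, f"bind:{tag}-"))
            reactions.append(
                Reaction((bound,), (phospho,), params.kp * a.kp_scale, f"phos:{tag}")
            )
            reactions.append(
                Reaction((phospho, PTPN_ID), (ternary,), ptp.kon, f"ptpn:{tag}+")
            )
            reactions.append(
                Reaction((ternary,), (phospho, PTPN_ID), ptp.koff, f"ptpn:{tag}-")
            )
            reactions.append(
                Reaction((ternary,), (prid, f"{a.name}:PTPN"), ptp.kd_cat, f"cat:{tag}")
            )
    reactions.extend(_release_reactions(params))
    net = ReactionNetwork(
        "nonspecific", species, reactions, init, params_digest=params.digest()
    )
    return net.validate()


# ---------------------------------------------------------------------------
# specific model
# ---------------------------------------------------------------------------

def build_specific_network(
    params: ModelParameters,
    configs: dict[str, set[BindingConfiguration]] | None = None,
) -> ReactionNetwork:
    """Tyrosine-site-specific model over the sterically feasible state space.

    ``configs`` maps receptor name to its feasible configuration set; when
    omitted it is computed with :func:`~vegfrsim.steric.enumerate_configurations`.
    All sites of a phospho-receptor are simultaneously competent; binding
    transitions exist only between feasible occupancy states.
    """
    params.validate()
    ptp = params.phosphatase
    species, init = _base_species(params)
    reactions: list[Reaction] = []

    for rec in params.receptors:
        rec_configs = (
            configs[rec.name] if configs is not None else enumerate_configurations(rec, params)
        )
        feasible_occ = {c.occupancy for c in rec_configs}
        if () not in feasible_occ:
            raise ConfigurationError(
                f"feasible set for {rec.name} lacks the empty configuration"
            )
        site_order = {s: i for i, s in enumerate(rec.site_names)}

        rid = rec.name
        species.append(Species(rid, "free_receptor", receptor=rec.name))
        init[rid] = rec.concentration

        # enumerate states: feasible occupancy x per-adapter flags
        state_ids: set[str] = set()
        for cfg in rec_configs:
            occ = cfg.as_dict()
            sites = sorted(occ, key=site_order.__getitem__)
            for flags in itertools.product(FLAGS, repeat=len(sites)):
                occupancy = _sort_occupancy(
                    site_order, {s: (occ[s], f) for s, f in zip(sites, flags)}
                )
                sid = _occupancy_id(rec.name, occupancy)
                if sid in state_ids:
                    continue
                state_ids.add(sid)
                species.append(
                    Species(sid, "phospho_receptor_complex", receptor=rec.name,
                            occupancy=occupancy)
                )
                init[sid] = 0.0

        empty_id = _occupancy_id(rec.name, ())
        reactions.append(
            Reaction((VEGF_ID, rid), (empty_id,), rec.kon_vegf, f"ligand:{rec.name}+")
        )
        reactions.append(
            Reaction((empty_id,), (VEGF_ID, rid), rec.koff_vegf, f"ligand:{rec.name}-")
        )

        # transitions from every state
        for sid in sorted(state_ids):
            sp = next(s for s in species if s.id == sid)
            occ = {site: (a, flag) for site, a, flag in sp.occupancy}
            bare = frozenset((site, a) for site, (a, _) in occ.items())

            # adapter association onto any free, allowed site (feasible target)
            for a in params.adapters:
                for site in a.site_names.get(rec.name, ()):
                    if site in occ:
                        continue
                    target_bare = tuple(sorted(dict(bare | {(site, a.name)}).items()))
                    if target_bare not in feasible_occ:
                        continue
                    new_occ = dict(occ)
                    new_occ[site] = (a.name, "u")
                    tid = _occupancy_id(rec.name, _sort_occupancy(site_order, new_occ))
                    if tid not in state_ids:
                        raise ConfigurationError(
                            f"target state {tid} missing from feasible state set"
                        )
                    tag = f"{rec.name}:{a.name}@{site}:{sid}"
                    reactions.append(
                        Reaction((sid, a.name), (tid,), a.kon, f"bind:{tag}+")
                    )
                    reactions.append(
                        Reaction((tid,), (sid, a.name), a.koff, f"bind:{tag}-")
                    )

            # per-bound-adapter events
            for site, (aname, flag) in occ.items():
                adapter = params.adapter(aname)
                tag = f"{rec.name}:{aname}@{site}:{sid}"
                if flag == "u":
                    new_occ = dict(occ)
                    new_occ[site] = (aname, "p")
                    tid = _occupancy_id(rec.name, _sort_occupancy(site_order, new_occ))
                    reactions.append(
                        Reaction((sid,), (tid,), params.kp * adapter.kp_scale, f"phos:{tag}")
                    )
                elif flag == "p":
                    new_occ = dict(occ)
                    new_occ[site] = (aname, "pP")
                    tid = _occupancy_id(rec.name, _sort_occupancy(site_order, new_occ))
                    reactions.append(
                        Reaction((sid, PTPN_ID), (tid,), ptp.kon, f"ptpn:{tag}+")
                    )
                    reactions.append(
                        Reaction((tid,), (sid, PTPN_ID), ptp.koff, f"ptpn:{tag}-")
                    )
                else:  # pP: catalysis releases the dephosphorylated adapter-PTPN complex
                    new_occ = dict(occ)
                    del new_occ[site]
                    tid = _occupancy_id(rec.name, _sort_occupancy(site_order, new_occ))
                    reactions.append(
                        Reaction((sid,), (tid, f"{aname}:PTPN"), ptp.kd_cat, f"cat:{tag}")
                    )

    reactions.extend(_release_reactions(params))
    # drop duplicate reactions that arise when the same transition is reachable
    # from several enumeration paths (labels make them distinct otherwise)
    seen: set[tuple] = set()
    unique: list[Reaction] = []
    for r in reactions:
        key = (r.reactants, r.products, r.rate_constant, r.label)
        if key not in seen:
            seen.add(key)
            unique.append(r)
    net = ReactionNetwork(
        "specific", species, unique, init, params_digest=params.digest()
    )
    return net.validate()


# ---------------------------------------------------------------------------
# stoichiometry and conservation
# ---------------------------------------------------------------------------

def stoichiometry_matrix(network: ReactionNetwork) -> np.ndarray:
    """Integer stoichiometry matrix S (n_species x n_reactions)."""
    S = np.zeros((network.n_species, network.n_reactions), dtype=np.int64)
    for j, r in enumerate(network.reactions):
        for sid in r.reactants:
            S[network.index(sid), j] -= 1
        for sid in r.products:
            S[network.index(sid), j] += 1
    return S


def moiety_vector(network: ReactionNetwork, kind: str, name: str) -> np.ndarray:
    """Conservation vector counting copies of an adapter or receptor moiety.

    For ``kind='adapter'`` the vector counts free, receptor-bound (any
    flag) and phosphatase-complexed copies; for ``kind='receptor'`` it
    marks the free receptor and every phospho-receptor state.  Both lie in
    the left null space of the stoichiometry matrix.
    """
    v = np.zeros(network.n_species)
    for i, sp in enumerate(network.species):
        if kind == "adapter":
            v[i] = sp.adapter_content.get(name, 0)
        elif kind == "receptor":
            v[i] = 1.0 if sp.receptor == name else 0.0
        else:
            raise ConfigurationError(f"unknown moiety kind {kind!r}")
    return v


def export_network_csv(network: ReactionNetwork, outdir: str | Path) -> None:
    """Write species and reaction tables for inspection."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "species.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "kind", "receptor", "adapter", "constant", "initial"])
        for sp in network.species:
            w.writerow([sp.id, sp.kind, sp.receptor or "", sp.adapter or "",
                        int(sp.constant), repr(network.initial_state.get(sp.id, 0.0))])
    with open(outdir / "reactions.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "reactants", "products", "rate_constant"])
        for r in network.reactions:
            w.writerow([r.label, " + ".join(r.reactants), " + ".join(r.products),
                        repr(r.rate_constant)])
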