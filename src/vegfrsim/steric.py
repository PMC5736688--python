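"""Steric geometry of adapter binding along the receptor carboxy terminus.

The receptor tail is treated as a one-dimensional axis.  The distance
between two tyrosine docking sites is the residue separation times the
per-amino-acid spacing measured from the kinase-domain crystal structure
(0.171 Å/aa for VEGFR1).  An adapter docks by its center, so it occupies
half its total size toward each neighboring site.  Two adapters may occupy
two sites simultaneously only if the sum of their one-sided footprints is
strictly smaller than the inter-site distance; feasibility of a multi-site
configuration is checked pairwise over all occupied sites.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass
from pathlib import Path

from .errors import UnknownEntityError
from .params import AdapterSpec, ModelParameters, ReceptorSpec


@dataclass(frozen=True)
class BindingConfiguration:
    """A sterically allowed assignment of adapters to receptor tyrosine sites.

    ``occupancy`` maps site name -> adapter name; unoccupied sites are
    absent.  Hashable so configuration sets can be compared directly.
    """

    receptor: str
    occupancy: tuple[tuple[str, str], ...] = ()  # sorted (site, adapter) pairs

    @staticmethod
    def from_dict(receptor: str, occupancy: dict[str, str]) -> "BindingConfiguration":
        return BindingConfiguration(receptor, tuple(sorted(occupancy.items())))

    def as_dict(self) -> dict[str, str]:
        return dict(self.occupancy)

    def __len__(self) -> int:
        return len(self.occupancy)


def site_distance(receptor: ReceptorSpec, site_a: str, site_b: str) -> float:
    """Distance in Å between two tyrosine sites along the receptor tail."""
    ra = receptor.residue(site_a)
    rb = receptor.residue(site_b)
    return abs(ra - rb) * receptor.aa_spacing


def adapter_footprint(adapter: AdapterSpec) -> float:
    """One-sided occupancy toward a neighboring site: half the adapter size, Å."""
    return adapter.size_y / 2.0


def is_feasible(config: BindingConfiguration, params: ModelParameters) -> bool:
    """True iff every occupied-site pair has room for both adapter footprints.

    Also enforces that each adapter is assigned only to sites it can bind.
    Ties (combined footprint exactly equal to the distance) are infeasible.
    """
    receptor = params.receptor(config.receptor)
    occ = config.as_dict()
    for site, aname in occ.items():
        adapter = params.adapter(aname)
        if site not in receptor.site_names:
            raise UnknownEntityError(f"receptor {receptor.name} has no site {site!r}")
        if site not in adapter.site_names.get(receptor.name, ()):
            return False
    for (sa, aa), (sb, ab) in itertools.combinations(occ.items(), 2):
        gap = site_distance(receptor, sa, sb)
        footprint = adapter_footprint(params.adapter(aa)) + adapter_footprint(params.adapter(ab))
        if not footprint < gap:
            return False
    return True


def enumerate_configurations(
    receptor: ReceptorSpec, params: ModelParameters
) -> set[BindingConfiguration]:
    """All sterically feasible adapter-to-site assignments on one receptor.

    Grows configurations site by site, pruning with the pairwise feasibility
    test (feasibility is anti-monotone in occupancy, so pruning is exact:
    any superset of an infeasible assignment is infeasible).  The result
    always contains the empty configuration.
    """
    binders: dict[str, list[str]] = {
        site: [a.name for a in params.adapters if site in a.site_names.get(receptor.name, ())]
        for site in receptor.site_names
    }
    sites = list(receptor.site_names)
    found: set[BindingConfiguration] = set()

    def extend(i: int, occ: dict[str, str]) -> None:
        if i == len(sites):
            found.add(BindingConfiguration.from_dict(receptor.name, occ))
            return
        extend(i + 1, occ)  # leave site empty
        site = sites[i]
        for aname in binders[site]:
            trial = dict(occ)
            trial[site] = aname
            if is_feasible(BindingConfiguration.from_dict(receptor.name, trial), params):
                extend(i + 1, trial)

    extend(0, {})
    return found


def max_occupancy(configs: set[BindingConfiguration]) -> int:
    """Largest number of simultaneously bound adapters over the feasible set."""
    return max((len(c) for c in configs), default=0)


def export_configurations_csv(
    configs: set[BindingConfiguration], path: str | Path
) -> None:
    """Write the feasible-configuration table (receptor, sites, adapters)."""
    rows = sorted(
        (c.receptor, ";".join(s for s, _ in c.occupancy), ";".join(a for _, a in c.occupancy))
        for c in configs
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["receptor", "sites", "adapters"])
        w.writerows(rows)
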