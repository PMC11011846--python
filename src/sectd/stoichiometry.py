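"""Valence-constrained enumeration and assignment of antibody-antigen complexes.

A complex is physically realisable when there exists a connected bipartite
bond graph between antibody and antigen subunits in which each antibody
uses at most its paratope valence (2 Fab arms for IgG), each antigen offers
at most one bond per epitope domain (HER2: domain II for pertuzumab, domain
IV for trastuzumab), and every bond joins an antibody to its cognate
domain.  Realisability is decided by an exhaustive spanning-tree search
over bond assignments, so non-IgG valences work unchanged; complexes are
capped at 12 subunits to bound the search.

Labels follow the study's naming: C1 (1 antibody + 1 antigen heterodimer),
C2 (1 antibody + 2 antigens heterotrimer), C3 (two distinct antibodies
bridged by one antigen with a second antigen on the free Fab), and HO(n)
for catenary chains of n repeat units (alternating bivalent antibodies and
two-epitope antigens).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

from .species import (
    ComplexComposition,
    Registry,
    composition_mass,
)

__all__ = [
    "BindingRules",
    "AssignmentResult",
    "is_connected_valid",
    "enumerate_compositions",
    "assign_stoichiometry",
    "label_complex",
    "format_assignment_report",
]


@dataclass(frozen=True)
class BindingRules:
    """Structural constraints on complex formation.

    Valences and cognate domains live on the species themselves; the rules
    carry the global caps.  ``max_subunits`` bounds the exhaustive bond
    search (12 admits catenary chains up to three repeat units, covering
    the largest species observed at ~1400 kDa).
    """

    max_subunits: int = 12


DEFAULT_RULES = BindingRules()


def _structure_key(comp: ComplexComposition, registry: Registry):
    """Canonical key of the binding-relevant structure (species-name free)."""
    items = []
    for name, count in comp.counts:
        sp = registry[name]
        if sp.role == "antibody":
            items.append(("ab", sp.paratope_valence, sp.cognate_domain, count))
        else:
            items.append(("ag", tuple(sorted(sp.epitope_domains)), count))
    return tuple(sorted(items))


@lru_cache(maxsize=65536)
def _connected_valid_cached(key) -> bool:
    antibodies: list[tuple[int, str]] = []   # (valence, domain) per subunit
    antigens: list[tuple[str, ...]] = []     # exposed domains per subunit
    for item in key:
        if item[0] == "ab":
            _, valence, domain, count = item
            antibodies.extend([(valence, domain)] * count)
        else:
            _, domains, count = item
            antigens.extend([domains] * count)

    n_ab, n_ag = len(antibodies), len(antigens)
    total = n_ab + n_ag
    if total == 1:
        return True
    if n_ab == 0 or n_ag == 0:
        return False  # no antibody-antibody or antigen-antigen bonds exist

    # Candidate bonds: antibody i -- antigen j through the antibody's
    # cognate domain, when the antigen exposes that domain.
    candidate = [(i, j) for i in range(n_ab) for j in range(n_ag)
                 if antibodies[i][1] in antigens[j]]
    if len(candidate) < total - 1:
        return False

    ab_capacity = [v for v, _ in antibodies]
    # one bond per (antigen copy, domain): since each antibody binds a
    # single domain, track per-antigen per-domain occupancy
    ag_slot_free = [dict.fromkeys(doms, True) for doms in antigens]

    visited_ab = [False] * n_ab
    visited_ag = [False] * n_ag

    def frontier_edges():
        for i, j in candidate:
            if visited_ab[i] != visited_ag[j]:  # exactly one endpoint visited
                if ab_capacity[i] > 0 and ag_slot_free[j][antibodies[i][1]]:
                    yield i, j

    def grow(n_visited: int) -> bool:
        if n_visited == total:
            return True
        tried: set = set()
        for i, j in list(frontier_edges()):
            # symmetry pruning: endpoints with identical class, visited
            # state and remaining capacity are interchangeable
            sig = (antibodies[i], visited_ab[i], ab_capacity[i],
                   antigens[j], visited_ag[j],
                   tuple(sorted(ag_slot_free[j].items())))
            if sig in tried:
                continue
            tried.add(sig)
            newly_ab = not visited_ab[i]
            newly_ag = not visited_ag[j]
            visited_ab[i] = visited_ag[j] = True
            ab_capacity[i] -= 1
            ag_slot_free[j][antibodies[i][1]] = False
            if grow(n_visited + 1):
                return True
            ab_capacity[i] += 1
            ag_slot_free[j][antibodies[i][1]] = True
            if newly_ab:
                visited_ab[i] = False
            if newly_ag:
                visited_ag[j] = False
        return False

    # root the search at the first antibody (every connected complex with
    # >= 2 subunits contains one)
    visited_ab[0] = True
    return grow(1)


def is_connected_valid(comp: ComplexComposition, registry: Registry,
                       rules: BindingRules = DEFAULT_RULES) -> bool:
    """True iff the composition admits a connected, valence-respecting bond graph."""
    if comp.total_subunits > rules.max_subunits:
        return False
    return _connected_valid_cached(_structure_key(comp, registry))


def enumerate_compositions(max_mass_kda: float, registry: Registry,
                           rules: BindingRules = DEFAULT_RULES
                           ) -> list[ComplexComposition]:
    """All realisable compositions with total mass <= ``max_mass_kda``.

    Deterministic order: ascending mass, then lexicographic counts.
    Includes free monomers.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    names = sorted(registry)
    masses = [registry[n].mw_kda for n in names]
    if max_mass_kda < min(masses):
        return []

    results: list[ComplexComposition] = []

    def recurse(idx: int, current: dict[str, int], mass: float, subunits: int) -> None:
        if idx == len(names):
            if current:
                comp = ComplexComposition.from_dict(current)
                if is_connected_valid(comp, registry, rules):
                    results.append(comp)
            return
        name, m = names[idx], masses[idx]
        max_count = min(int((max_mass_kda - mass) / m + 1e-9),
                        rules.max_subunits - subunits)
        for count in range(max_count + 1):
            if count:
                current[name] = count
            recurse(idx + 1, current, mass + count * m, subunits + count)
        current.pop(name, None)

    recurse(0, {}, 0.0, 0)
    results.sort(key=lambda c: (composition_mass(c, registry), c.counts))
    return results


def label_complex(comp: ComplexComposition, registry: Registry) -> str:
    """Classify a composition as free / C1 / C2 / C3 / HO(n) / other."""
    ab = {n: c for n, c in comp.counts if registry[n].role == "antibody"}
    n_ab = sum(ab.values())
    n_ag = sum(c for n, c in comp.counts if registry[n].role == "antigen")
    if comp.total_subunits == 1:
        return "free"
    if n_ab == 1 and n_ag == 1:
        return "C1"
    if n_ab == 1 and n_ag == 2:
        return "C2"
    if n_ab == 2 and len(ab) == 2 and n_ag == 2:
        return "C3"
    if len(ab) == 2 and len(set(ab.values())) == 1:
        n = next(iter(ab.values()))
        if n >= 2 and n_ag == 2 * n:
            return f"HO({n})"
    return "other"


@dataclass
class AssignmentResult:
    """Outcome of matching a measured mass to the nearest realisable complex."""

    measured_mw: float
    composition: Optional[ComplexComposition]
    label: str
    theoretical_mw: Optional[float]
    delta_kda: Optional[float]
    relative_error: Optional[float]
    assigned: bool
    tolerance: float
    alternatives: list[tuple[ComplexComposition, float]] = field(default_factory=list)

    def __str__(self) -> str:
        if not self.assigned:
            return f"{self.measured_mw:.1f} kDa -> unassigned (tolerance {self.tolerance:.0%})"
        return (f"{self.measured_mw:.1f} kDa -> {self.label} [{self.composition}] "
                f"theoretical {self.theoretical_mw:.1f} kDa "
                f"(rel. error {self.relative_error:.2%})")


def assign_stoichiometry(measured_mw: float, registry: Registry,
                         rules: BindingRules = DEFAULT_RULES,
                         tolerance: float = 0.05,
                         n_alternatives: int = 5) -> AssignmentResult:
    """Assign the realisable composition with minimal |mass - measured|.

    Ties are broken by fewer total subunits, then fewer distinct species,
    then lexicographic counts.  If the best candidate exceeds the relative
    ``tolerance`` an unassigned result is returned (never an exception).
    The default 5% tolerance covers the largest deviation observed between
    measured and theoretical complex masses (~3.4%).
    """
    if measured_mw <= 0:
        raise ValueError("measured_mw must be positive")
    if not 0 < tolerance <= 0.2:
        raise ValueError("tolerance must be in (0, 0.2]")
    candidates = enumerate_compositions(measured_mw * (1 + tolerance) + 1.0,
                                        registry, rules)
    if not candidates:
        return AssignmentResult(measured_mw, None, "unassigned", None, None,
                                None, False, tolerance)

    def sort_key(comp: ComplexComposition):
        mass = composition_mass(comp, registry)
        return (abs(mass - measured_mw), comp.total_subunits,
                len(comp.counts), comp.counts)

    ranked = sorted(candidates, key=sort_key)
    best = ranked[0]
    best_mass = composition_mass(best, registry)
    delta = abs(best_mass - measured_mw)
    rel = delta / measured_mw
    alternatives = [(c, composition_mass(c, registry)) for c in ranked[1:1 + n_alternatives]]
    if rel > tolerance:
        return AssignmentResult(measured_mw, None, "unassigned", None, delta,
                                rel, False, tolerance, alternatives)
    return AssignmentResult(measured_mw, best, label_complex(best, registry),
                            best_mass, delta, rel, True, tolerance, alternatives)


def format_assignment_report(results: list[AssignmentResult],
                             registry: Registry) -> str:
    """Delimited-text report of assignments (one row per measured mass)."""
    lines = ["measured_kda\tlabel\tcomposition\ttheoretical_kda\trel_error\talternatives"]
    for r in results:
        if r.assigned:
            alts = ";".join(f"{c}({m:.1f})" for c, m in r.alternatives[:3])
            lines.append(f"{r.measured_mw:.1f}\t{r.label}\t{r.composition}\t"
                         f"{r.theoretical_mw:.1f}\t{r.relative_error:.4f}\t{alts}")
        else:
            lines.append(f"{r.measured_mw:.1f}\tunassigned\t-\t-\t-\t-")
    return "\n".join(lines) + "\n"
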