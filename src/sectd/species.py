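"""Protein species registry, extinction coefficients and complex compositions.

A :class:`ProteinSpecies` holds the measured physical parameters of one
monomeric protein (an IgG antibody or the HER2 extracellular domain):
molecular weight, refractive-index increment dn/dc, specific absorbance
increment dA/dc at 280 nm, intrinsic viscosity and binding valence
information.  A :class:`ComplexComposition` is an integer multiset of
species; its mass and mass-weighted dA/dc are derived from the registry.

Sequence-based molar extinction coefficients at 280 nm are computed by the
aromatic-residue additivity method (Trp/Tyr/cystine contributions); two
published coefficient sets are shipped and the 1989 set is the default.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from Bio import SeqIO

__all__ = [
    "ProteinSpecies",
    "Registry",
    "AminoAcidComposition",
    "ExtinctionCoefficientSet",
    "ComplexComposition",
    "COEFFICIENT_SETS",
    "GILL_VON_HIPPEL_1989",
    "PACE_1995",
    "DEFAULT_ANALYSIS_SPECIES",
    "CATENARY_REPEAT_UNIT",
    "default_registry",
    "read_fasta",
    "epsilon_280",
    "dadc_from_epsilon",
    "composition_mass",
    "composition_dadc",
    "catenary_mass",
    "synthetic_standards_path",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinSpecies:
    """One monomeric protein and its solution-state parameters.

    Parameters are in package units (kDa, mL/g, mL g^-1 cm^-1, nm).  For
    antibodies ``paratope_valence`` is the number of Fab arms (2 for IgG)
    and ``cognate_domain`` names the single antigen domain bound; for
    antigens ``epitope_domains`` lists the domains exposed (one bond each).
    """

    name: str
    role: str  # "antibody" | "antigen"
    mw_kda: float
    dn_dc: float = 0.185
    da_dc: float = 0.0
    intrinsic_viscosity: float = 1.0
    rh_nm: Optional[float] = None
    sequence: Optional[str] = None
    paratope_valence: int = 0
    epitope_domains: frozenset[str] = frozenset()
    cognate_domain: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ("antibody", "antigen"):
            raise ValueError(f"role must be 'antibody' or 'antigen', got {self.role!r}")
        if self.mw_kda <= 0 or self.dn_dc <= 0 or self.intrinsic_viscosity <= 0:
            raise ValueError(f"{self.name}: mw_kda, dn_dc and intrinsic_viscosity must be positive")
        if self.da_dc < 0:
            raise ValueError(f"{self.name}: da_dc must be non-negative")
        if self.role == "antibody":
            if self.paratope_valence < 1:
                raise ValueError(f"antibody {self.name} needs paratope_valence >= 1")
            if self.epitope_domains:
                raise ValueError(f"antibody {self.name} must not expose epitope domains")
            if self.cognate_domain is None:
                raise ValueError(f"antibody {self.name} needs a cognate_domain")
        else:
            if self.paratope_valence != 0:
                raise ValueError(f"antigen {self.name} must have paratope_valence 0")
            if not self.epitope_domains:
                raise ValueError(f"antigen {self.name} needs at least one epitope domain")


class Registry(Mapping):
    """Immutable name -> :class:`ProteinSpecies` mapping."""

    def __init__(self, species: list[ProteinSpecies] | dict[str, ProteinSpecies]):
        if isinstance(species, dict):
            species = list(species.values())
        self._species: dict[str, ProteinSpecies] = {}
        for sp in species:
            if sp.name in self._species:
                raise ValueError(f"duplicate species name {sp.name!r}")
            self._species[sp.name] = sp

    def __getitem__(self, name: str) -> ProteinSpecies:
        try:
            return self._species[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}; registered: {sorted(self._species)}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._species)

    def __len__(self) -> int:
        return len(self._species)

    def subset(self, names) -> "Registry":
        return Registry([self[n] for n in names])

    @property
    def antibodies(self) -> list[ProteinSpecies]:
        return [s for s in self._species.values() if s.role == "antibody"]

    @property
    def antigens(self) -> list[ProteinSpecies]:
        return [s for s in self._species.values() if s.role == "antigen"]


def default_registry() -> Registry:
    """The five species characterised in this study.

    Antibody parameters are the SEC-TD measured values of the branded
    products; ``trastuzumab`` carries the Herceptin values and
    ``pertuzumab`` the Perjeta values.  ``her2`` is the glycosylated HER2
    extracellular domain; its measured mass includes glycosylation.
    Trastuzumab binds HER2 domain IV, pertuzumab domain II.
    """
    dom = frozenset({"II", "IV"})
    return Registry([
        ProteinSpecies("trastuzumab", "antibody", 147.0, 0.185, 1.38, 6.5, 5.5,
                       paratope_valence=2, cognate_domain="IV"),
        ProteinSpecies("pertuzumab", "antibody", 147.1, 0.185, 1.33, 6.4, 5.5,
                       paratope_valence=2, cognate_domain="II"),
        ProteinSpecies("ontruzant", "antibody", 147.7, 0.185, 1.37, 6.4, 5.5,
                       paratope_valence=2, cognate_domain="IV"),
        ProteinSpecies("herzuma", "antibody", 147.9, 0.185, 1.38, 6.3, 5.5,
                       paratope_valence=2, cognate_domain="IV"),
        ProteinSpecies("her2", "antigen", 86.3, 0.185, 0.90, 6.5, 4.4,
                       epitope_domains=dom),
    ])


#: Species used for stoichiometry assignment unless the caller narrows the
#: registry: the biosimilars are analytically indistinguishable from the
#: reference trastuzumab by mass, so assignment is reported on this trio.
DEFAULT_ANALYSIS_SPECIES = ("trastuzumab", "pertuzumab", "her2")


# ---------------------------------------------------------------------------
# Extinction coefficients


@dataclass(frozen=True)
class ExtinctionCoefficientSet:
    """Molar residue contributions to epsilon(280 nm), M^-1 cm^-1."""

    name: str
    eps_trp: float
    eps_tyr: float
    eps_cystine: float

    def __post_init__(self) -> None:
        if min(self.eps_trp, self.eps_tyr, self.eps_cystine) < 0:
            raise ValueError("extinction coefficients must be non-negative")


GILL_VON_HIPPEL_1989 = ExtinctionCoefficientSet("gill-vonhippel-1989", 5540.0, 1480.0, 134.0)
PACE_1995 = ExtinctionCoefficientSet("pace-1995", 5500.0, 1490.0, 125.0)
COEFFICIENT_SETS = {s.name: s for s in (GILL_VON_HIPPEL_1989, PACE_1995)}


@dataclass
class AminoAcidComposition:
    """Residue counts of a protein, with derived chromophore counts.

    ``n_cystine`` defaults to the fully oxidised reading (all cysteines
    disulfide-paired, appropriate for secreted proteins such as IgGs and
    serum albumins) and can be overridden.
    """

    counts: Counter = field(default_factory=Counter)
    n_cystine: Optional[int] = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("residue counts must be non-negative")
        max_cystine = self.counts.get("C", 0) // 2
        if self.n_cystine is None:
            self.n_cystine = max_cystine
        elif not 0 <= self.n_cystine <= max_cystine:
            raise ValueError(f"n_cystine must be in [0, {max_cystine}]")

    @property
    def n_trp(self) -> int:
        return self.counts.get("W", 0)

    @property
    def n_tyr(self) -> int:
        return self.counts.get("Y", 0)

    def __add__(self, other: "AminoAcidComposition") -> "AminoAcidComposition":
        return AminoAcidComposition(self.counts + other.counts,
                                    n_cystine=self.n_cystine + other.n_cystine)


def read_fasta(path, record: Optional[str] = None,
               all_cys_paired: bool = True) -> AminoAcidComposition:
    """Read FASTA record(s) into an :class:`AminoAcidComposition`.

    All records are concatenated (multi-chain proteins are stored as one
    record per chain); pass ``record`` to select a single record by the
    first token of its header.  Letters outside the 20 standard residues
    are tallied under ``'X'`` and excluded from coefficient math.
    """
    path = Path(path)
    counts: Counter = Counter()
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if record is not None and rec.id != record:
            continue
        n_records += 1
        for letter in str(rec.seq).upper():
            counts[letter if letter in STANDARD_AA else "X"] += 1
    if n_records == 0:
        which = f"record {record!r}" if record else "records"
        raise ValueError(f"no FASTA {which} with sequence data in {path}")
    n_cystine = counts.get("C", 0) // 2 if all_cys_paired else 0
    return AminoAcidComposition(counts, n_cystine=n_cystine)


def epsilon_280(comp: AminoAcidComposition,
                coefficients: ExtinctionCoefficientSet = GILL_VON_HIPPEL_1989) -> float:
    """Molar extinction coefficient at 280 nm, M^-1 cm^-1 (additive model)."""
    return (comp.n_trp * coefficients.eps_trp
            + comp.n_tyr * coefficients.eps_tyr
            + comp.n_cystine * coefficients.eps_cystine)


def dadc_from_epsilon(eps: float, mw_kda: float) -> float:
    """Convert molar epsilon to the specific increment dA/dc (mL g^-1 cm^-1).

    dA/dc = eps / M for a 1 cm path, with M = mw_kda * 1000 g/mol.
    """
    if mw_kda <= 0:
        raise ValueError("mw_kda must be positive")
    return eps / (mw_kda * 1000.0)


# ---------------------------------------------------------------------------
# Complex compositions


@dataclass(frozen=True)
class ComplexComposition:
    """Integer counts of each species in a complex (order-free, hashable)."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("a composition must contain at least one subunit")
        if any(c < 1 for _, c in self.counts):
            raise ValueError("all counts must be >= 1")
        object.__setattr__(self, "counts", tuple(sorted(self.counts)))

    @classmethod
    def from_dict(cls, counts: Mapping) -> "ComplexComposition":
        return cls(tuple((name, int(c)) for name, c in counts.items() if c > 0))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def total_subunits(self) -> int:
        return sum(c for _, c in self.counts)

    def mass_kda(self, registry: Registry) -> float:
        return composition_mass(self, registry)

    def da_dc(self, registry: Registry) -> float:
        return composition_dadc(self, registry)

    def antigen_mass_fraction(self, registry: Registry) -> float:
        """Fraction of the complex mass contributed by antigen subunits."""
        total = self.mass_kda(registry)
        antigen = sum(c * registry[n].mw_kda for n, c in self.counts
                      if registry[n].role == "antigen")
        return antigen / total

    def __str__(self) -> str:
        return "+".join(f"{n}:{c}" for n, c in self.counts)

    @classmethod
    def parse(cls, text: str) -> "ComplexComposition":
        counts: dict[str, int] = {}
        for part in text.split("+"):
            name, _, num = part.partition(":")
            counts[name.strip()] = counts.get(name.strip(), 0) + (int(num) if num else 1)
        return cls.from_dict(counts)


def composition_mass(comp: ComplexComposition, registry: Registry) -> float:
    """Exact count-weighted total mass of a composition, kDa."""
    return sum(c * registry[name].mw_kda for name, c in comp.counts)


def composition_dadc(comp: ComplexComposition, registry: Registry) -> float:
    """Mass-weighted mean dA/dc of the members, mL g^-1 cm^-1."""
    total = composition_mass(comp, registry)
    if total <= 0:
        raise ValueError("composition has non-positive total mass")
    weighted = sum(c * registry[name].mw_kda * registry[name].da_dc
                   for name, c in comp.counts)
    return weighted / total


#: Repeat unit of the antigen-antibody catenary chain: one trastuzumab and
#: one pertuzumab bridged by HER2 copies, two antigens per repeat.
CATENARY_REPEAT_UNIT = ComplexComposition.from_dict(
    {"trastuzumab": 1, "pertuzumab": 1, "her2": 2})


def catenary_mass(n: int, registry: Registry,
                  repeat_unit: ComplexComposition = CATENARY_REPEAT_UNIT) -> float:
    """Mass of an n-repeat catenary chain, kDa (exactly linear in n)."""
    if n < 1:
        raise ValueError("chain length n must be >= 1")
    return n * composition_mass(repeat_unit, registry)


def catenary_composition(n: int,
                         repeat_unit: ComplexComposition = CATENARY_REPEAT_UNIT
                         ) -> ComplexComposition:
    """Composition of an n-repeat catenary chain."""
    if n < 1:
        raise ValueError("chain length n must be >= 1")
    return ComplexComposition.from_dict(
        {name: n * c for name, c in repeat_unit.counts})


def synthetic_standards_path() -> Path:
    """Path to the shipped synthetic standard-protein FASTA fixtures.

    The records are synthetic stand-in sequences whose Trp/Tyr/Cys counts
    match literature compositions of the named proteins (the exact lot
    sequences are unavailable); filler residues are alanine.
    """
    return Path(__file__).parent / "data" / "synthetic_standards.fasta"


#: Literature monomer masses (kDa) of the standard proteins matching the
#: synthetic fixture records; used to convert sequence epsilon to dA/dc.
STANDARD_PROTEIN_MW = {
    "bsa": 66.4,
    "ovalbumin": 42.75,
    "conalbumin": 75.8,
    "trastuzumab": 145.4,
    "pertuzumab": 145.2,
}
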