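"""Domain model for two-locus fruiting-body colour genetics.

The organism is a bipolar heterothallic basidiomycete: haploid monokaryons
carry one allele at each of two colour loci (A and B) plus a mating-type
idiomorph, and only monokaryons with *different* idiomorphs can mate into a
fruiting dikaryon.  The colour of the fruiting body is a property of the
dikaryon, i.e. of the *union* of the two haploid genotypes.

Under duplicate-recessive epistasis the dikaryon is purple only when a
dominant allele is present at locus A *and* at locus B across the pair; a
dihybrid random union of gametes therefore segregates 9 purple : 7 white.
Alternative colour rules (single-locus, dominant-at-either) are expressible
as :class:`GeneticModel` instances so that competing hypotheses can be
scored against observed phenotype counts.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "Allele",
    "Color",
    "MatingType",
    "HaplotypeClass",
    "StrainType",
    "Haplotype",
    "GeneticModel",
    "IncompleteGenotypeError",
    "DUPLICATE_RECESSIVE",
    "SINGLE_LOCUS_A",
    "SINGLE_LOCUS_B",
    "DOMINANT_EITHER",
    "DEFAULT_CANDIDATE_MODELS",
    "fb_color",
    "haplotype_class",
    "compatible",
    "mating_grid",
    "MatingGrid",
    "gamete_class_frequencies",
    "expected_phenotype_ratio",
]


class Color(str, enum.Enum):
    """Binary fruiting-body colour phenotype."""

    PURPLE = "purple"
    WHITE = "white"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Allele(str, enum.Enum):
    """Allele state at a colour locus."""

    DOMINANT = "dominant"
    RECESSIVE = "recessive"


class MatingType(str, enum.Enum):
    """Bipolar mating-type idiomorphs.

    MAT1 corresponds to the white parent's idiomorph and MAT2 to the purple
    parent's; only MAT1 x MAT2 pairings can fruit.
    """

    MAT1 = "MAT1"
    MAT2 = "MAT2"


class HaplotypeClass(str, enum.Enum):
    """The four gamete classes at the two colour loci.

    Upper case = dominant allele, lower case = recessive allele; first
    character is locus A, second is locus B.
    """

    AB = "AB"
    Ab = "Ab"
    aB = "aB"
    ab = "ab"

    @property
    def dominant_a(self) -> bool:
        return self.value[0] == "A"

    @property
    def dominant_b(self) -> bool:
        return self.value[1] == "B"

    @classmethod
    def from_flags(cls, dominant_a: bool, dominant_b: bool) -> "HaplotypeClass":
        return cls(("A" if dominant_a else "a") + ("B" if dominant_b else "b"))


class StrainType(str, enum.Enum):
    """Four-way typing of mapping-population monokaryons.

    P/W records the colour produced against the primary (single-dominant)
    tester; the d/r suffix records whether the strain behaved as a parental
    (non-recombinant) or recombinant gamete against the recombinant testers.
    """

    PD = "Pd"
    PR = "Pr"
    WD = "Wd"
    WR = "Wr"
    AMBIGUOUS = "ambiguous"
    INCONSISTENT = "inconsistent"


class IncompleteGenotypeError(ValueError):
    """Raised when a colour call is requested for an unspecified genotype."""


@dataclass(frozen=True)
class Haplotype:
    """A haploid genotype: colour-locus alleles, mating idiomorph, markers.

    ``marker_alleles`` is an optional ordered tuple of parental-origin codes
    ('A' = white-parent band, 'B' = purple-parent band, None = missing),
    aligned to a marker map held elsewhere.
    """

    allele_a: Optional[Allele]
    allele_b: Optional[Allele]
    mating: Optional[MatingType] = None
    marker_alleles: Optional[Tuple[Optional[str], ...]] = None

    @classmethod
    def from_class(
        cls,
        hclass: HaplotypeClass | str,
        mating: Optional[MatingType] = None,
        marker_alleles: Optional[Tuple[Optional[str], ...]] = None,
    ) -> "Haplotype":
        hclass = HaplotypeClass(hclass)
        return cls(
            allele_a=Allele.DOMINANT if hclass.dominant_a else Allele.RECESSIVE,
            allele_b=Allele.DOMINANT if hclass.dominant_b else Allele.RECESSIVE,
            mating=mating,
            marker_alleles=marker_alleles,
        )

    @property
    def haplotype_class(self) -> HaplotypeClass:
        if self.allele_a is None or self.allele_b is None:
            raise IncompleteGenotypeError(
                "haplotype has unspecified colour-locus alleles"
            )
        return HaplotypeClass.from_flags(
            self.allele_a is Allele.DOMINANT, self.allele_b is Allele.DOMINANT
        )


@dataclass(frozen=True)
class GeneticModel:
    """A colour rule: dominance presence at (A, B) in the dikaryon -> colour.

    ``expected_f2_ratio`` is the purple:white ratio of a dihybrid random
    union of unlinked gametes, carried as a label; all quantitative
    expectations are recomputed from ``color_rule``.
    """

    name: str
    color_rule: Callable[[bool, bool], Color]
    expected_f2_ratio: Tuple[int, int]

    def __post_init__(self) -> None:
        for a, b in itertools.product((False, True), repeat=2):
            c = self.color_rule(a, b)
            if not isinstance(c, Color):
                raise ValueError(
                    f"model {self.name!r}: color_rule must return a Color "
                    f"for ({a}, {b}), got {c!r}"
                )

    def color_of_union(self, dominant_a: bool, dominant_b: bool) -> Color:
        return self.color_rule(dominant_a, dominant_b)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p, w = self.expected_f2_ratio
        return f"GeneticModel({self.name!r}, F2 {p}:{w})"


DUPLICATE_RECESSIVE = GeneticModel(
    name="duplicate_recessive",
    color_rule=lambda a, b: Color.PURPLE if (a and b) else Color.WHITE,
    expected_f2_ratio=(9, 7),
)

SINGLE_LOCUS_A = GeneticModel(
    name="single_locus_A",
    color_rule=lambda a, b: Color.PURPLE if a else Color.WHITE,
    expected_f2_ratio=(3, 1),
)

SINGLE_LOCUS_B = GeneticModel(
    name="single_locus_B",
    color_rule=lambda a, b: Color.PURPLE if b else Color.WHITE,
    expected_f2_ratio=(3, 1),
)

DOMINANT_EITHER = GeneticModel(
    name="dominant_either",
    color_rule=lambda a, b: Color.PURPLE if (a or b) else Color.WHITE,
    expected_f2_ratio=(15, 1),
)

DEFAULT_CANDIDATE_MODELS: Tuple[GeneticModel, ...] = (
    DUPLICATE_RECESSIVE,
    SINGLE_LOCUS_A,
    SINGLE_LOCUS_B,
    DOMINANT_EITHER,
)


def haplotype_class(h: Haplotype) -> HaplotypeClass:
    """Classify a haplotype into one of AB / Ab / aB / ab."""
    return h.haplotype_class


def fb_color(h1: Haplotype, h2: Haplotype, model: GeneticModel) -> Color:
    """Fruiting-body colour of the dikaryon formed by two monokaryons.

    Symmetric in its haplotype arguments: the colour depends only on whether
    a dominant allele is present at each locus across the pair.
    """
    for h in (h1, h2):
        if h.allele_a is None or h.allele_b is None:
            raise IncompleteGenotypeError(
                "both haplotypes must be fully specified at loci A and B"
            )
    dominant_a = Allele.DOMINANT in (h1.allele_a, h2.allele_a)
    dominant_b = Allele.DOMINANT in (h1.allele_b, h2.allele_b)
    return model.color_of_union(dominant_a, dominant_b)


def compatible(m1: MatingType, m2: MatingType) -> bool:
    """Bipolar mating compatibility: fruiting requires different idiomorphs."""
    return MatingType(m1) is not MatingType(m2)


@dataclass(frozen=True)
class MatingGrid:
    """Result of enumerating a strain-type x strain-type mating grid."""

    table: pd.DataFrame
    n_purple: int
    n_white: int


_GRID_ORDER = (StrainType.PD, StrainType.PR, StrainType.WD, StrainType.WR)


def mating_grid(
    model: GeneticModel,
    type_haplotypes: Mapping[StrainType, HaplotypeClass | str],
) -> MatingGrid:
    """Enumerate the 4x4 grid of fruiting-body colours among strain types.

    ``type_haplotypes`` maps each of Pd / Pr / Wd / Wr to a haplotype class;
    every ordered pairing is coloured by ``model`` and the purple / white
    cell counts over the 16 cells are returned alongside the table.
    """
    missing = [t for t in _GRID_ORDER if t not in type_haplotypes]
    if missing:
        raise ValueError(
            "type_haplotypes must cover Pd, Pr, Wd, Wr; missing "
            + ", ".join(t.value for t in missing)
        )
    haps = {
        t: Haplotype.from_class(type_haplotypes[t]) for t in _GRID_ORDER
    }
    labels = [t.value for t in _GRID_ORDER]
    cells = [
        [fb_color(haps[row], haps[col], model).value for col in _GRID_ORDER]
        for row in _GRID_ORDER
    ]
    table = pd.DataFrame(cells, index=labels, columns=labels)
    flat = [c for row in cells for c in row]
    return MatingGrid(
        table=table,
        n_purple=flat.count(Color.PURPLE.value),
        n_white=flat.count(Color.WHITE.value),
    )


# ---------------------------------------------------------------------------
# Gamete-frequency algebra
# ---------------------------------------------------------------------------

Distortion = Mapping[str, Tuple[float, float]]
_F1_PHASE = (HaplotypeClass.AB, HaplotypeClass.ab)


def _recombinant_classes(
    phase: Tuple[HaplotypeClass, HaplotypeClass],
) -> Tuple[HaplotypeClass, HaplotypeClass]:
    p1, p2 = phase
    if {p1, p2} not in ({HaplotypeClass.AB, HaplotypeClass.ab},
                        {HaplotypeClass.Ab, HaplotypeClass.aB}):
        raise ValueError(
            "phase must pair complementary classes (AB/ab or Ab/aB), got "
            f"{p1.value}/{p2.value}"
        )
    return (
        HaplotypeClass.from_flags(p1.dominant_a, p2.dominant_b),
        HaplotypeClass.from_flags(p2.dominant_a, p1.dominant_b),
    )


def gamete_class_frequencies(
    r: float,
    phase: Tuple[HaplotypeClass, HaplotypeClass] = _F1_PHASE,
    distortion: Optional[Distortion] = None,
) -> dict[HaplotypeClass, float]:
    """Gamete class frequencies from one meiosis of a known-phase dikaryon.

    Parental classes each occur at (1-r)/2 and recombinant classes at r/2,
    where r is the recombination fraction between loci A and B.  Optional
    ``distortion`` gives per-locus transmission weights as
    ``{"A": (w_dominant, w_recessive), "B": (...)}``; weights multiply the
    Mendelian frequencies and the distribution is renormalised, modelling
    gamete-level viability selection.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must lie in [0, 0.5], got {r}")
    freqs = {hc: 0.0 for hc in HaplotypeClass}
    for hc in phase:
        freqs[HaplotypeClass(hc)] += (1.0 - r) / 2.0
    for hc in _recombinant_classes(tuple(HaplotypeClass(p) for p in phase)):
        freqs[hc] += r / 2.0
    if distortion:
        for locus, (w_dom, w_rec) in distortion.items():
            if locus not in ("A", "B"):
                raise ValueError(f"unknown locus in distortion weights: {locus!r}")
            if w_dom <= 0 or w_rec <= 0:
                raise ValueError("transmission weights must be strictly positive")
            for hc in HaplotypeClass:
                dom = hc.dominant_a if locus == "A" else hc.dominant_b
                freqs[hc] *= w_dom if dom else w_rec
        total = sum(freqs.values())
        freqs = {hc: f / total for hc, f in freqs.items()}
    return freqs


def expected_phenotype_ratio(
    model: GeneticModel,
    design: str,
    tester: Optional[HaplotypeClass | str] = None,
    r: float = 0.5,
    distortion: Optional[Distortion] = None,
    phase: Tuple[HaplotypeClass, HaplotypeClass] = _F1_PHASE,
) -> dict[Color, float]:
    """Expected phenotype probabilities for a population design.

    Probabilities are derived from the gamete-class frequencies of the F1
    meiosis and the model's colour rule, never from a stored ratio:

    - ``test_cross`` / ``back_cross``: each gamete is united with the fixed
      ``tester`` haplotype class (the two designs differ only in which
      tester is biologically available);
    - ``f2_random_union``: two gametes drawn independently are united.
    """
    if design not in ("test_cross", "back_cross", "f2_random_union"):
        raise ValueError(f"unknown design {design!r}")
    freqs = gamete_class_frequencies(r, phase=phase, distortion=distortion)
    out = {Color.PURPLE: 0.0, Color.WHITE: 0.0}
    if design in ("test_cross", "back_cross"):
        if tester is None:
            raise ValueError(f"{design} design requires a tester haplotype class")
        t = HaplotypeClass(tester)
        for hc, f in freqs.items():
            c = model.color_of_union(
                hc.dominant_a or t.dominant_a, hc.dominant_b or t.dominant_b
            )
            out[c] += f
    else:
        for (h1, f1), (h2, f2) in itertools.product(freqs.items(), repeat=2):
            c = model.color_of_union(
                h1.dominant_a or h2.dominant_a, h1.dominant_b or h2.dominant_b
            )
            out[c] += f1 * f2
    return out
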