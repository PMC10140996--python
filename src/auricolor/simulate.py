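"""Seeded stochastic simulation of meiosis, crosses and population designs.

Models one F1 dikaryon undergoing meiosis: gametes fall into the four
haplotype classes with frequencies (1-r)/2 (parental) and r/2 (recombinant),
optionally skewed by per-locus transmission weights (gamete-level viability
selection, the simplest mechanism producing segregation distortion).  The
mating-type locus segregates 1:1 unless weighted and is assumed unlinked to
the colour loci.

Marker inheritance along contigs follows the Haldane (no-interference)
model: the switch probability between adjacent positions is
r = (1 - exp(-2 d_Morgan)) / 2 with physical distance converted at a
configurable bp-per-cM scale.  A contig carrying a trait locus anchors its
marker chain on the trait allele's parental origin, so nearby markers
co-segregate with the trait; contigs without a trait locus assort
independently of everything else.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    Allele,
    Color,
    GeneticModel,
    Haplotype,
    HaplotypeClass,
    MatingType,
    compatible,
    fb_color,
    gamete_class_frequencies,
)

__all__ = [
    "MarkerLocus",
    "MeiosisParams",
    "Monokaryon",
    "CrossResult",
    "Population",
    "gamete_frequencies",
    "draw_gametes",
    "simulate_meiosis",
    "perform_cross",
    "build_population",
    "haldane_r_from_bp",
]

DEFAULT_BP_PER_CM = 400_000.0


@dataclass(frozen=True)
class MarkerLocus:
    """One SSR-style marker: contig label, physical position, name."""

    contig: str
    position_bp: int
    name: str


@dataclass(frozen=True)
class MeiosisParams:
    """Parameters of one meiosis of the F1 dikaryon.

    transmission_weights maps "A" / "B" to (w_dominant, w_recessive) and
    "mating" to (w_MAT1, w_MAT2); weights are relative and renormalised.
    """

    r: float = 0.5
    transmission_weights: Optional[Mapping[str, Tuple[float, float]]] = None
    marker_map: Optional[Tuple[MarkerLocus, ...]] = None
    bp_per_cm: float = DEFAULT_BP_PER_CM

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 0.5:
            raise ValueError(f"r must lie in [0, 0.5], got {self.r}")
        if self.bp_per_cm <= 0:
            raise ValueError("bp_per_cm must be positive")
        if self.transmission_weights:
            for locus, (w1, w2) in self.transmission_weights.items():
                if locus not in ("A", "B", "mating"):
                    raise ValueError(f"unknown transmission-weight key {locus!r}")
                if w1 <= 0 or w2 <= 0:
                    raise ValueError(
                        f"transmission weights for {locus!r} must be positive"
                    )
        if self.marker_map is not None:
            by_contig: dict[str, list[int]] = {}
            seen = set()
            for m in self.marker_map:
                if m.position_bp < 0:
                    raise ValueError(f"marker {m.name}: negative position")
                if m.name in seen:
                    raise ValueError(f"duplicate marker name {m.name!r}")
                seen.add(m.name)
                by_contig.setdefault(m.contig, []).append(m.position_bp)
            for contig, pos in by_contig.items():
                if pos != sorted(pos):
                    raise ValueError(
                        f"marker positions on {contig} must be sorted"
                    )

    @property
    def locus_distortion(self) -> Optional[dict[str, Tuple[float, float]]]:
        """Colour-locus subset of the weights, for the class-frequency algebra."""
        if not self.transmission_weights:
            return None
        d = {k: v for k, v in self.transmission_weights.items() if k in ("A", "B")}
        return d or None

    @property
    def mating_weights(self) -> Tuple[float, float]:
        if self.transmission_weights and "mating" in self.transmission_weights:
            return tuple(self.transmission_weights["mating"])  # type: ignore[return-value]
        return (1.0, 1.0)


@dataclass(frozen=True)
class Monokaryon:
    """A named haploid strain (one meiotic product)."""

    id: str
    haplotype: Haplotype

    @property
    def mating(self) -> Optional[MatingType]:
        return self.haplotype.mating


@dataclass(frozen=True)
class CrossResult:
    """Outcome of one mono-mono cross attempt."""

    id: str
    parent1: str
    parent2: str
    design: str
    fruited: bool
    color: Optional[Color]
    replicate: int = 1


@dataclass
class Population:
    """A designed population: monokaryons and/or cross results."""

    design: str
    monokaryons: list[Monokaryon] = field(default_factory=list)
    crosses: list[CrossResult] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def haldane_r_from_bp(distance_bp: float, bp_per_cm: float = DEFAULT_BP_PER_CM) -> float:
    """Recombination fraction between two positions on the same contig."""
    d_morgan = distance_bp / bp_per_cm / 100.0
    return 0.5 * (1.0 - math.exp(-2.0 * d_morgan))


def gamete_frequencies(
    parent: Tuple[Haplotype, Haplotype],
    params: MeiosisParams,
) -> pd.Series:
    """Analytic gamete frequencies over (haplotype class, mating idiomorph).

    The parent's phase (which alleles are coupled) is read off its two
    haplotypes.  Returns a Series indexed by (class, mating) summing to 1.
    """
    h1, h2 = parent
    if h1.mating is None or h2.mating is None or h1.mating is h2.mating:
        raise ValueError("parent dikaryon must carry two different idiomorphs")
    phase = (h1.haplotype_class, h2.haplotype_class)
    class_freqs = gamete_class_frequencies(
        params.r, phase=phase, distortion=params.locus_distortion
    )
    w1, w2 = params.mating_weights
    mating_freqs = {MatingType.MAT1: w1 / (w1 + w2), MatingType.MAT2: w2 / (w1 + w2)}
    index = pd.MultiIndex.from_product(
        [[hc.value for hc in HaplotypeClass], [m.value for m in MatingType]],
        names=["class", "mating"],
    )
    values = [
        class_freqs[HaplotypeClass(hc)] * mating_freqs[MatingType(m)]
        for hc, m in index
    ]
    return pd.Series(values, index=index, name="frequency")


def draw_gametes(
    freqs: pd.Series,
    n: int,
    seed: int | np.random.Generator,
) -> list[Monokaryon]:
    """Draw ``n`` monokaryon gametes from a (class, mating) frequency table."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.choice(len(freqs), size=n, p=freqs.to_numpy())
    out = []
    for i, k in enumerate(idx, start=1):
        hc, m = freqs.index[k]
        out.append(
            Monokaryon(
                id=f"MK{i:03d}",
                haplotype=Haplotype.from_class(HaplotypeClass(hc), MatingType(m)),
            )
        )
    return out


def _marker_chain(
    positions: Sequence[float],
    anchor_index: Optional[int],
    anchor_origin: Optional[str],
    bp_per_cm: float,
    rng: np.random.Generator,
) -> list[str]:
    """Parental origins along one contig under Haldane switching.

    With an anchor (a trait locus at ``positions[anchor_index]`` whose origin
    is known) the chain is generated outward from the anchor; otherwise the
    leftmost position starts at a fair coin flip.
    """
    n = len(positions)
    origins: list[Optional[str]] = [None] * n
    if anchor_index is None:
        start, origins[0] = 0, "A" if rng.random() < 0.5 else "B"
    else:
        start, origins[anchor_index] = anchor_index, anchor_origin
    other = {"A": "B", "B": "A"}
    for i in range(start + 1, n):
        r = haldane_r_from_bp(positions[i] - positions[i - 1], bp_per_cm)
        origins[i] = other[origins[i - 1]] if rng.random() < r else origins[i - 1]
    for i in range(start - 1, -1, -1):
        r = haldane_r_from_bp(positions[i + 1] - positions[i], bp_per_cm)
        origins[i] = other[origins[i + 1]] if rng.random() < r else origins[i + 1]
    return origins  # type: ignore[return-value]


def simulate_meiosis(
    parent: Tuple[Haplotype, Haplotype],
    params: MeiosisParams,
    n: int,
    seed: int | np.random.Generator,
    trait_positions: Optional[Mapping[str, Tuple[str, int]]] = None,
    id_prefix: str = "MK",
) -> list[Monokaryon]:
    """Draw ``n`` gametes with colour loci, mating type and marker vectors.

    ``trait_positions`` maps colour locus "A" / "B" to (contig, position_bp);
    a contig carrying a trait locus anchors its marker chain on that locus's
    parental origin (recessive allele = white-parent origin 'A', dominant =
    purple-parent origin 'B').  At most one trait locus per contig.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freqs = gamete_frequencies(parent, params)
    idx = rng.choice(len(freqs), size=n, p=freqs.to_numpy())

    marker_map = params.marker_map or ()
    contigs: dict[str, list[MarkerLocus]] = {}
    for m in marker_map:
        contigs.setdefault(m.contig, []).append(m)
    trait_by_contig: dict[str, Tuple[str, int]] = {}
    if trait_positions:
        for locus, (contig, pos) in trait_positions.items():
            if locus not in ("A", "B"):
                raise ValueError(f"unknown trait locus {locus!r}")
            if contig in trait_by_contig:
                raise ValueError(f"contig {contig} carries more than one trait locus")
            trait_by_contig[contig] = (locus, pos)

    out = []
    for i, k in enumerate(idx, start=1):
        hc_s, m_s = freqs.index[k]
        hc = HaplotypeClass(hc_s)
        marker_alleles: Optional[Tuple[Optional[str], ...]] = None
        if marker_map:
            calls: dict[str, str] = {}
            for contig, loci in contigs.items():
                positions = [float(l.position_bp) for l in loci]
                anchor_index = anchor_origin = None
                if contig in trait_by_contig:
                    locus, tpos = trait_by_contig[contig]
                    dom = hc.dominant_a if locus == "A" else hc.dominant_b
                    anchor_origin = "B" if dom else "A"
                    combined = sorted(positions + [float(tpos)])
                    anchor_index = combined.index(float(tpos))
                    origins = _marker_chain(
                        combined, anchor_index, anchor_origin, params.bp_per_cm, rng
                    )
                    del origins[anchor_index]
                else:
                    origins = _marker_chain(
                        positions, None, None, params.bp_per_cm, rng
                    )
                for locus_obj, origin in zip(loci, origins):
                    calls[locus_obj.name] = origin
            marker_alleles = tuple(calls[m.name] for m in marker_map)
        out.append(
            Monokaryon(
                id=f"{id_prefix}{i:03d}",
                haplotype=Haplotype.from_class(
                    hc, MatingType(m_s), marker_alleles=marker_alleles
                ),
            )
        )
    return out


def perform_cross(
    mk1: Monokaryon,
    mk2: Monokaryon,
    fruiting_rate: float,
    model: GeneticModel,
    seed: int | np.random.Generator,
    design: str = "cross",
    cross_id: Optional[str] = None,
    replicate: int = 1,
) -> CrossResult:
    """Attempt one mono-mono cross.

    Incompatible pairs (same idiomorph) never fruit; compatible pairs fruit
    with probability ``fruiting_rate`` independent of genotype.  A tester
    with ``mating=None`` is treated as unconstrained (always compatible).
    Fruited crosses carry the fruiting-body colour under ``model``.
    """
    if not 0.0 <= fruiting_rate <= 1.0:
        raise ValueError("fruiting_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cid = cross_id or f"{mk1.id}x{mk2.id}"
    ok = (
        mk1.mating is None
        or mk2.mating is None
        or compatible(mk1.mating, mk2.mating)
    )
    fruited = bool(ok and rng.random() < fruiting_rate)
    color = fb_color(mk1.haplotype, mk2.haplotype, model) if fruited else None
    return CrossResult(
        id=cid, parent1=mk1.id, parent2=mk2.id, design=design,
        fruited=fruited, color=color, replicate=replicate,
    )


def _is_compatible(a: Monokaryon, b: Monokaryon) -> bool:
    return a.mating is None or b.mating is None or compatible(a.mating, b.mating)


def build_population(
    design: str,
    *,
    seed: int | np.random.Generator,
    model: GeneticModel,
    parent: Optional[Tuple[Haplotype, Haplotype]] = None,
    params: Optional[MeiosisParams] = None,
    n: Optional[int] = None,
    strains: Optional[Sequence[Monokaryon]] = None,
    tester: Optional[Monokaryon] = None,
    testers: Optional[Sequence[Monokaryon]] = None,
    fruiting_rate: float = 1.0,
    replicates: int = 1,
    trait_positions: Optional[Mapping[str, Tuple[str, int]]] = None,
) -> Population:
    """Construct one population of the study's design repertoire.

    - ``mapping``: n monokaryon gametes of the F1 ``parent``;
    - ``test_cross`` / ``back_cross``: one cross per strain against
      ``tester``, skipping incompatible pairs when the tester carries a
      mating type;
    - ``inbred``: every compatible unordered pair among ``strains``;
    - ``recombinant_inbred``: every compatible (strain, tester) pair over
      the ``testers`` list.

    Deterministic given (arguments, seed).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pop = Population(design=design, provenance={"design": design})

    if design == "mapping":
        if parent is None or params is None or n is None:
            raise ValueError("mapping design requires parent, params and n")
        pop.monokaryons = simulate_meiosis(
            parent, params, n, rng, trait_positions=trait_positions
        )
        return pop

    if strains is None or len(strains) == 0:
        raise ValueError(f"{design} design requires a non-empty strain list")

    def attempt(a: Monokaryon, b: Monokaryon, k: int) -> None:
        for rep in range(1, replicates + 1):
            pop.crosses.append(
                perform_cross(
                    a, b, fruiting_rate, model, rng,
                    design=design, cross_id=f"{design}-{k:04d}r{rep}",
                    replicate=rep,
                )
            )

    if design in ("test_cross", "back_cross"):
        if tester is None:
            raise ValueError(f"{design} design requires a tester")
        k = 0
        for s in strains:
            if not _is_compatible(s, tester):
                continue
            k += 1
            attempt(s, tester, k)
    elif design == "inbred":
        k = 0
        for a, b in itertools.combinations(strains, 2):
            if not _is_compatible(a, b):
                continue
            k += 1
            attempt(a, b, k)
    elif design == "recombinant_inbred":
        if not testers:
            raise ValueError("recombinant_inbred design requires testers")
        k = 0
        for s in strains:
            for t in testers:
                if not _is_compatible(s, t):
                    continue
                k += 1
                attempt(s, t, k)
    else:
        raise ValueError(f"unknown design {design!r}")
    return pop
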