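"""Synthetic study generator.

Builds a complete in-silico breeding study with the statistical structure
of the real one: a white double-recessive parent (class ab) crossed with a
purple double-dominant parent (class AB); a mapping population of haploid
F1 gametes; a single-dominant test-cross tester (class Ab); two
recombinant-class testers (aB, one per idiomorph); back-cross, inbred and
recombinant-inbred designs; per-locus transmission distortion; and
SSR-style marker matrices on named contigs with the two trait loci placed
among the markers.

Default parameters reproduce the study conditions: 87 mapping strains,
A-B recombinant gamete proportion 0.377, mating-type weights giving a
54:33 expected idiomorph ratio, B-locus weights giving a 30:57 expected
B:b ratio, and 67.1% fruiting success in the inbred designs (the
expected counts match the observed ratios; individual draws are random).
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    Color,
    DUPLICATE_RECESSIVE,
    GeneticModel,
    Haplotype,
    HaplotypeClass,
    MatingType,
)
from .simulate import (
    DEFAULT_BP_PER_CM,
    MarkerLocus,
    MeiosisParams,
    Monokaryon,
    Population,
    build_population,
)

__all__ = [
    "ContigPlan",
    "StudyConfig",
    "StudyBundle",
    "generate_study",
    "truth_report",
    "DEFAULT_MARKER_PLAN",
    "DEFAULT_TRAIT_POSITIONS",
]


@dataclass(frozen=True)
class ContigPlan:
    """Evenly spaced SSR-style markers along one contig."""

    name: str
    n_markers: int
    spacing_bp: int = 2_000_000
    start_bp: int = 0
    first_marker_number: int = 2501

    def loci(self) -> Tuple[MarkerLocus, ...]:
        return tuple(
            MarkerLocus(
                contig=self.name,
                position_bp=self.start_bp + i * self.spacing_bp,
                name=f"SSR{self.first_marker_number + i}",
            )
            for i in range(self.n_markers)
        )


# Trait locus A sits on Contig9 between the 5th and 6th markers, locus B on
# Contig19 mid-run; Contig2 carries trait-free background markers.
DEFAULT_MARKER_PLAN: Tuple[ContigPlan, ...] = (
    ContigPlan(name="Contig9", n_markers=10, first_marker_number=2501),
    ContigPlan(name="Contig19", n_markers=8, first_marker_number=2601),
    ContigPlan(name="Contig2", n_markers=5, first_marker_number=2701),
)

DEFAULT_TRAIT_POSITIONS: dict[str, Tuple[str, int]] = {
    "A": ("Contig9", 9_000_000),
    "B": ("Contig19", 7_000_000),
}


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one synthetic study.

    Defaults are the study conditions; weights are expectation-matched to
    the printed ratios (mating 54:33 of 87; B:b 30:57 of 87).
    """

    n_mapping: int = 87
    r_ab: float = 0.377
    mating_weights: Tuple[float, float] = (54.0, 33.0)  # MAT1 : MAT2
    a_weights: Tuple[float, float] = (1.0, 1.0)         # A : a
    b_weights: Tuple[float, float] = (30.0, 57.0)       # B : b
    fruiting_rate: float = 0.671
    n_inbred_mat1: int = 15
    n_inbred_mat2: int = 14
    marker_plan: Tuple[ContigPlan, ...] = DEFAULT_MARKER_PLAN
    trait_positions: Mapping[str, Tuple[str, int]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_POSITIONS)
    )
    bp_per_cm: float = DEFAULT_BP_PER_CM
    missing_rate: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mapping < 1:
            raise ValueError("n_mapping must be >= 1")
        if not 0.0 <= self.r_ab <= 0.5:
            raise ValueError("r_ab must lie in [0, 0.5]")
        if not 0.0 <= self.fruiting_rate <= 1.0:
            raise ValueError("fruiting_rate must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for nm, w in (("mating", self.mating_weights),
                      ("a", self.a_weights), ("b", self.b_weights)):
            if w[0] <= 0 or w[1] <= 0:
                raise ValueError(f"{nm}_weights must be strictly positive")
        names = [c.name for c in self.marker_plan]
        if len(names) != len(set(names)):
            raise ValueError("marker_plan contig names must be unique")
        contig_names = set(names)
        for locus, (contig, _) in self.trait_positions.items():
            if locus not in ("A", "B"):
                raise ValueError(f"unknown trait locus {locus!r}")
            if contig not in contig_names:
                raise ValueError(
                    f"trait locus {locus} placed on unknown contig {contig!r}"
                )

    def meiosis_params(self) -> MeiosisParams:
        loci = tuple(l for plan in self.marker_plan for l in plan.loci())
        return MeiosisParams(
            r=self.r_ab,
            transmission_weights={
                "A": self.a_weights,
                "B": self.b_weights,
                "mating": self.mating_weights,
            },
            marker_map=loci,
            bp_per_cm=self.bp_per_cm,
        )


@dataclass
class StudyBundle:
    """A generated study: strains, populations, markers and ground truth."""

    config: StudyConfig
    parents: dict[str, Monokaryon]
    testers: dict[str, Monokaryon]
    populations: dict[str, Population]
    marker_matrix: pd.DataFrame
    truth: pd.DataFrame

    recurrent_parent_id: str = "ACW001-33"
    dominant_parent_id: str = "ACP004-33"
    primary_tester_id: str = "ACW001-9"
    recombinant_tester_ids: Tuple[str, str] = ("REC-23", "REC-51")

    @property
    def mapping_strains(self) -> list[Monokaryon]:
        return self.populations["mapping"].monokaryons

    def to_dir(self, path) -> None:
        """Write the bundle as CSV/YAML files (see the io module schemas)."""
        from . import io as aio

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        aio.write_strain_table(aio.strains_to_frame(self), path / "strains.csv")
        for design, pop in self.populations.items():
            if pop.crosses:
                aio.write_cross_table(
                    aio.crosses_to_frame(pop.crosses),
                    path / f"crosses_{design}.csv",
                )
        aio.write_marker_matrix(self.marker_matrix, path / "markers.csv")
        self.truth.to_csv(path / "truth.csv", index=False)
        aio.write_config(self.config, path / "config.yaml")


def generate_study(cfg: StudyConfig) -> StudyBundle:
    """Generate a complete synthetic study from a config.

    Regeneration with the same config (including seed) is deterministic.
    The mapping population, its marker matrix and every cross design are
    produced, together with a per-strain ground-truth table for recovery
    tests.
    """
    rng = np.random.default_rng(cfg.seed)
    model = DUPLICATE_RECESSIVE
    params = cfg.meiosis_params()

    parents = {
        "ACW001-33": Monokaryon(
            "ACW001-33", Haplotype.from_class(HaplotypeClass.ab, MatingType.MAT1)
        ),
        "ACP004-33": Monokaryon(
            "ACP004-33", Haplotype.from_class(HaplotypeClass.AB, MatingType.MAT2)
        ),
    }
    testers = {
        # the test-cross tester mates successfully with the whole mapping
        # population, so its idiomorph is modelled as unconstrained
        "ACW001-9": Monokaryon(
            "ACW001-9", Haplotype.from_class(HaplotypeClass.Ab, None)
        ),
        "REC-23": Monokaryon(
            "REC-23", Haplotype.from_class(HaplotypeClass.aB, MatingType.MAT2)
        ),
        "REC-51": Monokaryon(
            "REC-51", Haplotype.from_class(HaplotypeClass.aB, MatingType.MAT1)
        ),
    }
    parent_dikaryon = (
        parents["ACW001-33"].haplotype,
        parents["ACP004-33"].haplotype,
    )

    populations: dict[str, Population] = {}
    populations["mapping"] = build_population(
        "mapping",
        seed=rng,
        model=model,
        parent=parent_dikaryon,
        params=params,
        n=cfg.n_mapping,
        trait_positions=cfg.trait_positions,
    )
    mapping = populations["mapping"].monokaryons

    populations["test_cross"] = build_population(
        "test_cross",
        seed=rng, model=model, strains=mapping,
        tester=testers["ACW001-9"], fruiting_rate=1.0,
        replicates=cfg.replicates,
    )
    populations["back_cross"] = build_population(
        "back_cross",
        seed=rng, model=model, strains=mapping,
        tester=parents["ACW001-33"], fruiting_rate=1.0,
        replicates=cfg.replicates,
    )

    mat1 = [s for s in mapping if s.mating is MatingType.MAT1]
    mat2 = [s for s in mapping if s.mating is MatingType.MAT2]
    inbred_subset = mat1[: cfg.n_inbred_mat1] + mat2[: cfg.n_inbred_mat2]
    populations["inbred"] = build_population(
        "inbred",
        seed=rng, model=model, strains=inbred_subset,
        fruiting_rate=cfg.fruiting_rate, replicates=cfg.replicates,
    )
    populations["recombinant_inbred"] = build_population(
        "recombinant_inbred",
        seed=rng, model=model, strains=mapping,
        testers=[testers["REC-23"], testers["REC-51"]],
        fruiting_rate=cfg.fruiting_rate, replicates=cfg.replicates,
    )

    marker_names = [l.name for l in params.marker_map or ()]
    calls = pd.DataFrame(
        [list(s.haplotype.marker_alleles or ()) for s in mapping],
        index=[s.id for s in mapping],
        columns=marker_names,
    )
    calls.index.name = "strain_id"
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = calls.mask(mask)

    truth = pd.DataFrame(
        [
            {
                "strain_id": s.id,
                "mating_type": s.mating.value if s.mating else "",
                "haplotype_class": s.haplotype.haplotype_class.value,
                "in_inbred_subset": s in inbred_subset,
            }
            for s in mapping
        ]
    )

    return StudyBundle(
        config=cfg,
        parents=parents,
        testers=testers,
        populations=populations,
        marker_matrix=calls,
        truth=truth,
    )


def truth_report(
    bundle: StudyBundle,
    inferred: pd.DataFrame,
) -> Tuple[pd.DataFrame, dict]:
    """Compare pipeline-inferred haplotype classes with the ground truth.

    ``inferred`` is the strain table of
    :class:`~auricolor.inference.ColorInheritanceResults` (columns
    ``strain_id`` and ``haplotype_class``).  Returns a per-strain comparison
    table and aggregate accuracy statistics; strains the pipeline left
    unclassified are counted separately, never as errors.
    """
    truth = bundle.truth[["strain_id", "haplotype_class"]].rename(
        columns={"haplotype_class": "true_class"}
    )
    inf = inferred[["strain_id", "haplotype_class"]].rename(
        columns={"haplotype_class": "inferred_class"}
    )
    unknown = set(inf["strain_id"]) - set(truth["strain_id"])
    if unknown:
        raise ValueError(
            f"inferred table contains unknown strain ids: {sorted(unknown)[:5]}"
        )
    table = truth.merge(inf, on="strain_id", how="left")
    table["classified"] = table["inferred_class"].notna()
    table["match"] = table["classified"] & (
        table["true_class"] == table["inferred_class"]
    )
    n_classified = int(table["classified"].sum())
    stats = {
        "n_strains": int(len(table)),
        "n_classified": n_classified,
        "n_correct": int(table["match"].sum()),
        "accuracy_among_classified": (
            float(table.loc[table["classified"], "match"].mean())
            if n_classified
            else float("nan")
        ),
        "misclassified": table.loc[
            table["classified"] & ~table["match"], "strain_id"
        ].tolist(),
    }
    return table, stats
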