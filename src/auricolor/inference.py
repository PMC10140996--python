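"""Inference pipeline: strain typing, haplotype deduction, segregation tests,
recombination-fraction estimation and genetic-model selection.

The pipeline reconstructs, from observed cross phenotypes alone, what each
haploid mapping strain carries at the two colour loci:

1. the test-cross against a single-dominant tester splits strains into
   purple-type (P) and white-type (W);
2. crosses against recombinant-class testers refine P/W into four types
   (Pd, Pr, Wd, Wr);
3. each type is solved back to a haplotype class by finding the unique
   class consistent with every observed cross colour under the colour rule
   (no lookup table);
4. counts of recombinant classes estimate the A-B recombination fraction
   with an exact binomial confidence interval;
5. chi-square goodness-of-fit tests flag distorted segregation, and
   candidate colour models are ranked by summed chi-square across designs.

`ColorInheritance` wraps the whole pipeline in a model object whose
``fit()`` returns a results object with a ``summary()`` table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    Color,
    DEFAULT_CANDIDATE_MODELS,
    DUPLICATE_RECESSIVE,
    GeneticModel,
    Haplotype,
    HaplotypeClass,
    StrainType,
    expected_phenotype_ratio,
    fb_color,
)

__all__ = [
    "ClassificationRecord",
    "SegTestResult",
    "RecombEstimate",
    "ModelFit",
    "PopulationCounts",
    "UnclassifiableError",
    "AmbiguousHaplotypeError",
    "InconsistentObservationsError",
    "classify_color_type",
    "classify_strain_type",
    "solve_haplotype_class",
    "infer_haplotype_class",
    "deduce_tester_haplotype",
    "estimate_recombination",
    "chi_square_segregation",
    "select_model",
    "ColorInheritance",
    "ColorInheritanceResults",
    "DEFAULT_TESTER_CLASSES",
]

DEFAULT_TESTER_CLASSES: dict[str, HaplotypeClass] = {
    "primary": HaplotypeClass.Ab,
    "recombinant": HaplotypeClass.aB,
    "recurrent": HaplotypeClass.ab,
}


class UnclassifiableError(ValueError):
    """No observation available to classify a strain."""


class AmbiguousHaplotypeError(ValueError):
    """More than one haplotype class is consistent with the observations."""

    def __init__(self, candidates: Iterable[HaplotypeClass]):
        self.candidates = frozenset(candidates)
        names = sorted(c.value for c in self.candidates)
        super().__init__(f"ambiguous: consistent classes {{{', '.join(names)}}}")


class InconsistentObservationsError(ValueError):
    """No haplotype class is consistent with the observations."""


@dataclass
class ClassificationRecord:
    """Per-strain cross phenotypes feeding the typing pipeline."""

    strain_id: str
    testcross_color: Optional[Color] = None
    recomb_tester_colors: dict[str, Optional[Color]] = field(default_factory=dict)
    backcross_color: Optional[Color] = None

    def __post_init__(self) -> None:
        if (
            self.testcross_color is None
            and self.backcross_color is None
            and not any(c is not None for c in self.recomb_tester_colors.values())
        ):
            raise ValueError(
                f"strain {self.strain_id}: at least one observation required"
            )


@dataclass(frozen=True)
class SegTestResult:
    """Chi-square goodness-of-fit verdict for a segregation-ratio hypothesis."""

    chi2: float
    df: int
    p: float
    hypothesis: str
    alpha: float
    verdict: str  # "consistent" | "distorted"

    @property
    def distorted(self) -> bool:
        return self.verdict == "distorted"


@dataclass(frozen=True)
class RecombEstimate:
    """Recombination-fraction estimate from haploid class counts."""

    n_recombinant: int
    n_total: int
    r_hat: float
    ci: Tuple[float, float]
    p_value_unlinked: float
    linked: bool  # True iff r = 0.5 rejected

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.ci
        return (
            f"r_hat = {self.n_recombinant}/{self.n_total} = {self.r_hat:.4f} "
            f"(95% CI {lo:.3f}-{hi:.3f}); "
            + ("linkage supported" if self.linked else "r=0.5 not rejected")
        )


def classify_color_type(record: ClassificationRecord) -> str:
    """P/W split from the test-cross phenotype (P iff purple)."""
    if record.testcross_color is None:
        raise UnclassifiableError(
            f"strain {record.strain_id}: no test-cross observation"
        )
    return "P" if record.testcross_color is Color.PURPLE else "W"


def classify_strain_type(
    pw: str,
    recomb_tester_colors: Mapping[str, Optional[Color]],
) -> StrainType:
    """Refine a P/W call into Pd / Pr / Wd / Wr using recombinant testers.

    Both recombinant testers carry the same haplotype class, so a fruited
    observation from either suffices; a disagreement between them is flagged
    ``inconsistent``, and no observation at all yields ``ambiguous``.
    """
    colors = {c for c in recomb_tester_colors.values() if c is not None}
    if not colors:
        return StrainType.AMBIGUOUS
    if len(colors) > 1:
        return StrainType.INCONSISTENT
    purple = colors.pop() is Color.PURPLE
    if pw == "P":
        return StrainType.PD if purple else StrainType.PR
    return StrainType.WR if purple else StrainType.WD


def solve_haplotype_class(
    observations: Iterable[Tuple[HaplotypeClass | str, Color]],
    model: GeneticModel = DUPLICATE_RECESSIVE,
) -> frozenset[HaplotypeClass]:
    """All haplotype classes consistent with (tester class, colour) pairs."""
    obs = [(HaplotypeClass(t), Color(c)) for t, c in obs_list(observations)]
    out = set()
    for hc in HaplotypeClass:
        h = Haplotype.from_class(hc)
        if all(
            fb_color(h, Haplotype.from_class(t), model) is c for t, c in obs
        ):
            out.add(hc)
    return frozenset(out)


def obs_list(observations) -> list:
    obs = list(observations)
    if not obs:
        raise ValueError("at least one observation required")
    return obs


_TYPE_OBSERVATIONS = {
    StrainType.PD: (("primary", Color.PURPLE), ("recombinant", Color.PURPLE)),
    StrainType.PR: (("primary", Color.PURPLE), ("recombinant", Color.WHITE)),
    StrainType.WD: (("primary", Color.WHITE), ("recombinant", Color.WHITE)),
    StrainType.WR: (("primary", Color.WHITE), ("recombinant", Color.PURPLE)),
}


def infer_haplotype_class(
    st: StrainType,
    tester_classes: Mapping[str, HaplotypeClass] = DEFAULT_TESTER_CLASSES,
    model: GeneticModel = DUPLICATE_RECESSIVE,
) -> HaplotypeClass:
    """Haplotype class implied by a strain type, solved from the colour rule.

    The strain type encodes two cross colours (against the primary and the
    recombinant tester); the unique class consistent with both under
    ``model`` is returned.  With the study's tester assignment
    (primary=Ab, recombinant=aB) this yields Pd->AB, Pr->aB, Wd->ab, Wr->Ab.
    """
    if st not in _TYPE_OBSERVATIONS:
        raise ValueError(f"strain type {st.value} does not map to a haplotype class")
    obs = [
        (tester_classes[role], color) for role, color in _TYPE_OBSERVATIONS[st]
    ]
    classes = solve_haplotype_class(obs, model)
    if len(classes) == 1:
        return next(iter(classes))
    if not classes:
        raise InconsistentObservationsError(
            f"no haplotype class consistent with type {st.value} under "
            f"model {model.name}"
        )
    raise AmbiguousHaplotypeError(classes)


def deduce_tester_haplotype(
    observations: Iterable[Tuple[HaplotypeClass | str, Color]],
    model: GeneticModel = DUPLICATE_RECESSIVE,
    known: Optional[Iterable[HaplotypeClass]] = None,
) -> HaplotypeClass:
    """Solve an unknown tester's haplotype class from its cross colours.

    ``observations`` pairs the *known* class of each crossed strain with the
    observed colour.  ``known`` optionally restricts the candidate set.
    Raises :class:`AmbiguousHaplotypeError` (carrying the candidate set) if
    more than one class fits, :class:`InconsistentObservationsError` if none.
    """
    candidates = solve_haplotype_class(observations, model)
    if known is not None:
        candidates = candidates & frozenset(HaplotypeClass(k) for k in known)
    if len(candidates) == 1:
        return next(iter(candidates))
    if not candidates:
        raise InconsistentObservationsError(
            "no tester haplotype class is consistent with the observations"
        )
    raise AmbiguousHaplotypeError(candidates)


def estimate_recombination(
    class_counts: Mapping[HaplotypeClass | str, int],
    parental_phase: Tuple[HaplotypeClass | str, HaplotypeClass | str] = (
        HaplotypeClass.AB,
        HaplotypeClass.ab,
    ),
    alpha: float = 0.05,
) -> RecombEstimate:
    """Estimate r from haploid class counts.

    r_hat = (non-parental count) / total, with a Clopper-Pearson
    (exact binomial) confidence interval and an exact two-sided binomial
    test of r = 0.5 (the no-linkage null).
    """
    counts = {HaplotypeClass(k): int(v) for k, v in class_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("class counts must be non-negative")
    total = sum(counts.values())
    if total < 1:
        raise ValueError("total class count must be >= 1")
    parental = {HaplotypeClass(p) for p in parental_phase}
    n_rec = sum(v for k, v in counts.items() if k not in parental)
    test = stats.binomtest(n_rec, total, 0.5)
    ci = test.proportion_ci(confidence_level=1 - alpha, method="exact")
    return RecombEstimate(
        n_recombinant=n_rec,
        n_total=total,
        r_hat=n_rec / total,
        ci=(float(ci.low), float(ci.high)),
        p_value_unlinked=float(test.pvalue),
        linked=bool(test.pvalue < alpha),
    )


def chi_square_segregation(
    observed: Sequence[int] | Mapping[str, int],
    expected_ratio: Sequence[float],
    alpha: float = 0.05,
    hypothesis: Optional[str] = None,
    yates: bool = False,
) -> SegTestResult:
    """Pearson chi-square goodness of fit against a small-integer ratio.

    No continuity correction by default; ``yates=True`` applies the Yates
    correction (only meaningful for two categories).  Verdict is
    "distorted" iff p < alpha.
    """
    if isinstance(observed, Mapping):
        labels = list(observed.keys())
        obs = np.asarray([observed[k] for k in labels], dtype=float)
    else:
        labels = None
        obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least two categories")
    if obs.size != ratio.size:
        raise ValueError(
            f"observed has {obs.size} categories but ratio has {ratio.size}"
        )
    if np.any(ratio <= 0):
        raise ValueError("expected ratio terms must be positive")
    expected = obs.sum() * ratio / ratio.sum()
    if yates:
        chi2 = float(np.sum((np.abs(obs - expected) - 0.5) ** 2 / expected))
    else:
        chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))
    label = hypothesis or ":".join(f"{x:g}" for x in ratio)
    return SegTestResult(
        chi2=chi2, df=df, p=p, hypothesis=label, alpha=alpha,
        verdict="distorted" if p < alpha else "consistent",
    )


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationCounts:
    """Observed phenotype counts for one designed population."""

    design: str  # test_cross | back_cross | f2_random_union
    counts: Mapping[Color, int]
    tester: Optional[HaplotypeClass] = None
    label: Optional[str] = None


@dataclass(frozen=True)
class ModelFit:
    """Summed chi-square fit of one candidate colour model."""

    model: GeneticModel
    chi2: float
    df: int
    p: float
    per_population: Tuple[SegTestResult, ...]

    @property
    def adequate(self) -> bool:
        return self.p >= 0.05 and math.isfinite(self.chi2)


def select_model(
    populations: Sequence[PopulationCounts],
    candidates: Sequence[GeneticModel] = DEFAULT_CANDIDATE_MODELS,
    r: float = 0.5,
    alpha: float = 0.05,
) -> list[ModelFit]:
    """Rank candidate colour models by summed chi-square across populations.

    Expected phenotype probabilities per design come from
    :func:`expected_phenotype_ratio` (never a hard-coded ratio).  A model
    predicting probability 0 for an observed phenotype receives infinite
    chi-square.  Results are sorted ascending by chi2 (ties keep candidate
    order); a fit is ``adequate`` when its overall p >= 0.05.
    """
    if not populations:
        raise ValueError("at least one population required")
    if not candidates:
        raise ValueError("at least one candidate model required")
    fits = []
    for model in candidates:
        parts = []
        total_chi2, total_df = 0.0, 0
        for pop in populations:
            probs = expected_phenotype_ratio(
                model, pop.design, tester=pop.tester, r=r
            )
            obs = np.array(
                [pop.counts.get(Color.PURPLE, 0), pop.counts.get(Color.WHITE, 0)],
                dtype=float,
            )
            exp_p = np.array([probs[Color.PURPLE], probs[Color.WHITE]])
            n = obs.sum()
            if n == 0:
                raise ValueError(f"population {pop.label or pop.design}: no counts")
            if np.any((exp_p == 0) & (obs > 0)):
                chi2, p = math.inf, 0.0
            else:
                keep = exp_p > 0
                chi2 = float(
                    np.sum((obs[keep] - n * exp_p[keep]) ** 2 / (n * exp_p[keep]))
                )
                p = float(stats.chi2.sf(chi2, 1))
            parts.append(
                SegTestResult(
                    chi2=chi2, df=1, p=p, alpha=alpha,
                    hypothesis=f"{model.name}|{pop.label or pop.design}",
                    verdict="distorted" if p < alpha else "consistent",
                )
            )
            total_chi2 += chi2
            total_df += 1
        total_p = float(stats.chi2.sf(total_chi2, total_df)) if math.isfinite(total_chi2) else 0.0
        fits.append(
            ModelFit(
                model=model, chi2=total_chi2, df=total_df, p=total_p,
                per_population=tuple(parts),
            )
        )
    return sorted(fits, key=lambda f: f.chi2)


# ---------------------------------------------------------------------------
# Model-object facade
# ---------------------------------------------------------------------------


class ColorInheritance:
    """Colour-inheritance model fitted to strain and cross tables.

    Parameters
    ----------
    strains : DataFrame with columns ``strain_id``, ``mating_type`` (and an
        optional ``role`` column marking parents/testers).
    crosses : DataFrame with columns ``cross_id, parent1, parent2, design,
        fruited, color, replicate`` covering the test-cross, back-cross and
        recombinant-inbred designs.
    primary_tester, recombinant_testers, recurrent_parent : strain ids of
        the single-dominant tester, the recombinant-class testers and the
        double-recessive recurrent parent.
    tester_classes : haplotype classes of the tester roles (defaults to the
        study assignment primary=Ab, recombinant=aB, recurrent=ab).
    """

    def __init__(
        self,
        strains: pd.DataFrame,
        crosses: pd.DataFrame,
        *,
        primary_tester: str,
        recombinant_testers: Sequence[str] = (),
        recurrent_parent: Optional[str] = None,
        tester_classes: Mapping[str, HaplotypeClass] = DEFAULT_TESTER_CLASSES,
        candidates: Sequence[GeneticModel] = DEFAULT_CANDIDATE_MODELS,
    ) -> None:
        self.strains = strains.reset_index(drop=True)
        self.crosses = crosses.reset_index(drop=True)
        self.primary_tester = primary_tester
        self.recombinant_testers = tuple(recombinant_testers)
        self.recurrent_parent = recurrent_parent
        self.tester_classes = dict(tester_classes)
        self.candidates = tuple(candidates)
        special = {primary_tester, recurrent_parent, *recombinant_testers}
        role = strains["role"] if "role" in strains.columns else None
        ids = []
        for i, sid in enumerate(self.strains["strain_id"]):
            if sid in special:
                continue
            if role is not None and role.iloc[i] not in ("mapping", "", None) \
                    and not (isinstance(role.iloc[i], float) and math.isnan(role.iloc[i])):
                continue
            ids.append(sid)
        self.mapping_ids: list[str] = ids

    @classmethod
    def from_bundle(cls, bundle, **kwargs) -> "ColorInheritance":
        """Build from a synthetic :class:`~auricolor.synth.StudyBundle`."""
        from .io import crosses_to_frame, strains_to_frame

        frames = [
            crosses_to_frame(bundle.populations[d].crosses)
            for d in ("test_cross", "back_cross", "recombinant_inbred")
            if d in bundle.populations
        ]
        return cls(
            strains_to_frame(bundle),
            pd.concat(frames, ignore_index=True),
            primary_tester=bundle.primary_tester_id,
            recombinant_testers=bundle.recombinant_tester_ids,
            recurrent_parent=bundle.recurrent_parent_id,
            **kwargs,
        )

    # -- record assembly ---------------------------------------------------

    def _consensus_color(self, rows: pd.DataFrame) -> Optional[Color]:
        """Colour agreed by fruited replicates; None if none fruited.

        Returns the string "conflict" sentinel via exception-free path:
        conflicting replicate colours are treated as missing and counted in
        ``n_conflicts``.
        """
        colors = {
            Color(c) for c, f in zip(rows["color"], rows["fruited"])
            if f and isinstance(c, str) and c
        }
        if len(colors) == 1:
            return colors.pop()
        if len(colors) > 1:
            self._n_conflicts += 1
        return None

    def _records(self) -> list[ClassificationRecord]:
        self._n_conflicts = 0
        cr = self.crosses
        recs = []
        for sid in self.mapping_ids:
            mine = cr[(cr["parent1"] == sid) | (cr["parent2"] == sid)]
            other = mine["parent1"].where(mine["parent2"] == sid, mine["parent2"])
            tc = mine[(mine["design"] == "test_cross") & (other == self.primary_tester)]
            bc = mine[(mine["design"] == "back_cross") & (other == self.recurrent_parent)]
            recomb: dict[str, Optional[Color]] = {}
            for t in self.recombinant_testers:
                rows = mine[(mine["design"] == "recombinant_inbred") & (other == t)]
                if len(rows):
                    recomb[t] = self._consensus_color(rows)
            try:
                recs.append(
                    ClassificationRecord(
                        strain_id=sid,
                        testcross_color=self._consensus_color(tc) if len(tc) else None,
                        recomb_tester_colors=recomb,
                        backcross_color=self._consensus_color(bc) if len(bc) else None,
                    )
                )
            except ValueError:
                # strain with no usable observation at all: keep as ambiguous
                recs.append(
                    ClassificationRecord.__new__(ClassificationRecord)
                )
                recs[-1].strain_id = sid
                recs[-1].testcross_color = None
                recs[-1].recomb_tester_colors = {}
                recs[-1].backcross_color = None
        return recs

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        alpha: float = 0.05,
        model: GeneticModel = DUPLICATE_RECESSIVE,
    ) -> "ColorInheritanceResults":
        """Run the full inference pipeline and return a results object."""
        records = self._records()
        rows = []
        class_counts: dict[HaplotypeClass, int] = {hc: 0 for hc in HaplotypeClass}
        for rec in records:
            pw = hclass = None
            try:
                pw = classify_color_type(rec)
                st = classify_strain_type(pw, rec.recomb_tester_colors)
            except UnclassifiableError:
                st = StrainType.AMBIGUOUS
            if st in _TYPE_OBSERVATIONS:
                hclass = infer_haplotype_class(st, self.tester_classes, model)
                class_counts[hclass] += 1
            rows.append(
                {
                    "strain_id": rec.strain_id,
                    "color_type": pw,
                    "strain_type": st.value,
                    "haplotype_class": hclass.value if hclass else None,
                    "backcross_color": (
                        rec.backcross_color.value if rec.backcross_color else None
                    ),
                }
            )
        strain_table = pd.DataFrame(rows)

        typed = strain_table["haplotype_class"].notna()
        recomb = (
            estimate_recombination(class_counts, alpha=alpha)
            if typed.any()
            else None
        )

        seg_tests: dict[str, SegTestResult] = {}
        mt = self.strains[
            self.strains["strain_id"].isin(self.mapping_ids)
        ]["mating_type"].value_counts()
        if len(mt) == 2:
            seg_tests["mating_type 1:1"] = chi_square_segregation(
                [int(mt.get("MAT1", 0)), int(mt.get("MAT2", 0))],
                (1, 1), alpha=alpha, hypothesis="mating type 1:1",
            )
        tc_counts = strain_table["color_type"].value_counts()
        n_p, n_w = int(tc_counts.get("P", 0)), int(tc_counts.get("W", 0))
        populations: list[PopulationCounts] = []
        if n_p + n_w > 0:
            seg_tests["test_cross 1:1"] = chi_square_segregation(
                [n_p, n_w], (1, 1), alpha=alpha, hypothesis="test-cross P:W 1:1",
            )
            # in the test-cross the tester supplies A, so colour reveals B
            seg_tests["locus_B 1:1"] = chi_square_segregation(
                [n_p, n_w], (1, 1), alpha=alpha, hypothesis="B:b 1:1",
            )
            populations.append(
                PopulationCounts(
                    design="test_cross",
                    counts={Color.PURPLE: n_p, Color.WHITE: n_w},
                    tester=self.tester_classes["primary"],
                    label="test_cross",
                )
            )
        bc = strain_table["backcross_color"].value_counts()
        bc_p, bc_w = int(bc.get("purple", 0)), int(bc.get("white", 0))
        if bc_p + bc_w > 0:
            probs = expected_phenotype_ratio(
                model, "back_cross", tester=self.tester_classes["recurrent"], r=0.5
            )
            seg_tests["back_cross model ratio"] = chi_square_segregation(
                [bc_p, bc_w],
                (probs[Color.PURPLE], probs[Color.WHITE]),
                alpha=alpha,
                hypothesis=f"back-cross P:W under {model.name} (r=0.5)",
            )
            populations.append(
                PopulationCounts(
                    design="back_cross",
                    counts={Color.PURPLE: bc_p, Color.WHITE: bc_w},
                    tester=self.tester_classes["recurrent"],
                    label="back_cross",
                )
            )

        model_fits = (
            select_model(populations, self.candidates, alpha=alpha)
            if populations
            else []
        )
        return ColorInheritanceResults(
            model=self,
            strain_table=strain_table,
            class_counts={k.value: v for k, v in class_counts.items()},
            recomb=recomb,
            seg_tests=seg_tests,
            model_fits=model_fits,
            alpha=alpha,
            n_replicate_conflicts=self._n_conflicts,
        )


@dataclass
class ColorInheritanceResults:
    """Fitted colour-inheritance results.

    Carries the per-strain typing table, haplotype-class counts, the
    recombination-fraction estimate with its exact CI, all segregation-test
    verdicts and the ranked candidate-model fits.
    """

    model: ColorInheritance
    strain_table: pd.DataFrame
    class_counts: dict[str, int]
    recomb: Optional[RecombEstimate]
    seg_tests: dict[str, SegTestResult]
    model_fits: list[ModelFit]
    alpha: float
    n_replicate_conflicts: int = 0

    @property
    def best_model(self) -> Optional[GeneticModel]:
        return self.model_fits[0].model if self.model_fits else None

    def to_dict(self) -> dict:
        d = {
            "strains": self.strain_table.where(
                self.strain_table.notna(), None
            ).to_dict(orient="records"),
            "class_counts": self.class_counts,
            "alpha": self.alpha,
            "replicate_conflicts": self.n_replicate_conflicts,
            "segregation_tests": {
                k: {
                    "chi2": t.chi2, "df": t.df, "p": t.p,
                    "hypothesis": t.hypothesis, "verdict": t.verdict,
                }
                for k, t in self.seg_tests.items()
            },
            "model_ranking": [
                {
                    "model": f.model.name,
                    "chi2": f.chi2 if math.isfinite(f.chi2) else None,
                    "df": f.df,
                    "p": f.p,
                    "adequate": f.adequate,
                }
                for f in self.model_fits
            ],
        }
        if self.recomb:
            d["recombination"] = {
                "n_recombinant": self.recomb.n_recombinant,
                "n_total": self.recomb.n_total,
                "r_hat": self.recomb.r_hat,
                "ci95": list(self.recomb.ci),
                "p_value_unlinked": self.recomb.p_value_unlinked,
                "linked": self.recomb.linked,
            }
        return d

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        """Human-readable fitting summary."""
        lines = ["Colour-inheritance analysis", "=" * 60]
        counts = self.strain_table["strain_type"].value_counts()
        lines.append("Strain types: " + ", ".join(
            f"{t}={int(counts.get(t, 0))}"
            for t in ("Pd", "Pr", "Wd", "Wr", "ambiguous", "inconsistent")
            if counts.get(t, 0)
        ))
        lines.append("Haplotype classes: " + ", ".join(
            f"{k}={v}" for k, v in self.class_counts.items()
        ))
        if self.recomb:
            lines.append(f"Recombination: {self.recomb}")
        lines.append("-" * 60)
        lines.append(f"{'segregation test':<32}{'chi2':>8}{'p':>10}  verdict")
        for name, t in self.seg_tests.items():
            lines.append(
                f"{t.hypothesis:<32}{t.chi2:>8.3f}{t.p:>10.4f}  {t.verdict}"
            )
        if self.model_fits:
            lines.append("-" * 60)
            lines.append(f"{'candidate model':<24}{'chi2':>10}{'p':>10}  fit")
            for f in self.model_fits:
                chi = f"{f.chi2:.3f}" if math.isfinite(f.chi2) else "inf"
                lines.append(
                    f"{f.model.name:<24}{chi:>10}{f.p:>10.4f}  "
                    + ("adequate" if f.adequate else "poor")
                )
            lines.append(f"Best-fitting model: {self.model_fits[0].model.name}")
        return "\n".join(lines)
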