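"""Two-point linkage analysis for haploid progeny.

Markers are scored by parental origin ('A' = one parent's band, 'B' = the
other's), so for any marker pair the recombination-fraction estimate is
simply the mismatch fraction over strains informative for both markers.
The two-point LOD is the log10 likelihood ratio of linkage at the estimate
versus independence:

    LOD = n_rec * log10(2 r) + n_par * log10(2 (1 - r))

which is 0 at r = 0.5 and n * log10(2) for perfectly co-segregating
markers.  Markers are grouped as connected components of the LOD >=
threshold graph, ordered within groups by minimising total adjacent rf
(exhaustive for small groups, greedy chain + 2-opt otherwise), and a binary
trait can be placed as a pseudo-marker between its flanking markers.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .core import Color

__all__ = [
    "MarkerMatrix",
    "LinkageGroup",
    "TraitPlacement",
    "GeneticMap",
    "MapGapError",
    "pairwise_rf_lod",
    "group_markers",
    "order_markers",
    "map_distance",
    "place_trait",
    "TwoPointLinkage",
    "LinkageMapResults",
    "trait_vector_from_colors",
]

logger = logging.getLogger(__name__)

VALID_CODES = {"A", "B"}
EXHAUSTIVE_ORDER_MAX = 7


class MapGapError(ValueError):
    """A linkage group contains marker pairs with no informative strains."""


class MarkerMatrix:
    """Strains x markers matrix of parental-origin codes.

    ``calls`` is a DataFrame indexed by strain id with marker-name columns;
    entries are 'A', 'B' or NaN (missing).
    """

    def __init__(self, calls: pd.DataFrame):
        bad = set(calls.stack().unique()) - VALID_CODES
        if bad:
            raise ValueError(
                f"invalid marker codes {sorted(map(str, bad))}; allowed: A, B, missing"
            )
        if calls.index.has_duplicates:
            raise ValueError("duplicate strain ids in marker matrix")
        if calls.columns.has_duplicates:
            raise ValueError("duplicate marker names in marker matrix")
        self.calls = calls

    @property
    def strains(self) -> list[str]:
        return list(self.calls.index)

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def missing_fraction(self) -> pd.Series:
        """Per-marker fraction of missing calls."""
        return self.calls.isna().mean()

    def numeric(self) -> np.ndarray:
        """Encode A=0, B=1, missing=NaN."""
        arr = self.calls.to_numpy(dtype=object)
        return np.where(arr == "B", 1.0, np.where(arr == "A", 0.0, np.nan))


def pairwise_rf_lod(
    m: MarkerMatrix,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise recombination fractions, LOD scores and informative counts.

    rf = mismatches / informative strains, computed pairwise over strains
    non-missing for both markers.  In the LOD sum a term with a zero count
    contributes nothing (the 0*log(0) = 0 likelihood convention), so
    perfectly co-segregating markers score n*log10(2); the reported rf is
    never adjusted.  Pairs with zero informative strains get NaN and are
    logged.
    """
    if len(m.markers) < 2:
        raise ValueError("need at least two markers")
    x = m.numeric()
    valid = ~np.isnan(x)
    p = np.where(valid, x, 0.0)          # indicator of B
    q = np.where(valid, 1.0 - x, 0.0)    # indicator of A
    n_inf = valid.astype(float).T @ valid.astype(float)
    mism = p.T @ q + q.T @ p
    n_par = n_inf - mism
    with np.errstate(invalid="ignore", divide="ignore"):
        rf = np.where(n_inf > 0, mism / np.maximum(n_inf, 1), np.nan)
        term_rec = np.where(
            mism > 0, mism * np.log10(2.0 * np.where(mism > 0, rf, 1.0)), 0.0
        )
        term_par = np.where(
            n_par > 0,
            n_par * np.log10(2.0 * np.where(n_par > 0, 1.0 - rf, 1.0)),
            0.0,
        )
        lod = np.where(n_inf > 0, term_rec + term_par, np.nan)
    if np.any((n_inf == 0) & ~np.eye(len(m.markers), dtype=bool)):
        ii, jj = np.where((n_inf == 0) & ~np.eye(len(m.markers), dtype=bool))
        for i, j in zip(ii, jj):
            if i < j:
                logger.warning(
                    "no informative strains for pair (%s, %s)",
                    m.markers[i], m.markers[j],
                )
    names = m.markers
    mk = lambda a: pd.DataFrame(a, index=names, columns=names)
    np.fill_diagonal(rf, 0.0)
    return mk(rf), mk(lod), mk(n_inf.astype(int))


def group_markers(lod: pd.DataFrame, threshold: float = 3.0) -> list[list[str]]:
    """Linkage groups: connected components of the LOD >= threshold graph.

    Groups are sorted by decreasing size then by first marker name; markers
    within a group are returned in name order (ordering along the map is a
    separate step).  Result is invariant to marker input order.
    """
    g = nx.Graph()
    g.add_nodes_from(lod.index)
    names = list(lod.index)
    arr = lod.to_numpy()
    for i, j in itertools.combinations(range(len(names)), 2):
        v = arr[i, j]
        if not math.isnan(v) and v >= threshold:
            g.add_edge(names[i], names[j])
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), c[0]))


def map_distance(r: float, fn: str = "kosambi") -> float:
    """Map distance in centimorgans for a recombination fraction.

    Haldane: d = -50 ln(1 - 2r); Kosambi: d = 25 ln((1+2r)/(1-2r)).
    """
    if not 0.0 <= r < 0.5:
        raise ValueError(f"map distance undefined for r={r}; need 0 <= r < 0.5")
    if fn == "haldane":
        return -50.0 * math.log(1.0 - 2.0 * r)
    if fn == "kosambi":
        return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    raise ValueError(f"unknown map function {fn!r}")


def _chain_length(order: Sequence[int], d: np.ndarray) -> float:
    return sum(d[order[i], order[i + 1]] for i in range(len(order) - 1))


def _two_opt(order: list[int], d: np.ndarray) -> list[int]:
    best = _chain_length(order, d)
    improved = True
    while improved:
        improved = False
        for i in range(len(order) - 1):
            for j in range(i + 2, len(order) + 1):
                new = order[:i] + order[i:j][::-1] + order[j:]
                length = _chain_length(new, d)
                if length < best - 1e-12:
                    order, best, improved = new, length, True
    return order


def order_markers(
    group: Sequence[str],
    rf: pd.DataFrame,
    map_function: str = "kosambi",
) -> Tuple[list[str], list[float]]:
    """Order a linkage group and return cumulative map positions (cM).

    Minimises total adjacent rf: exhaustively for groups of up to seven
    markers, otherwise by greedy chain extension
    refined with 2-opt.  The order and its reverse are equivalent; the
    orientation with the lexicographically smaller first marker is
    returned.  Adjacent rf >= 0.5 is capped just below 0.5 for the distance
    transform (and logged).
    """
    group = list(group)
    if len(group) < 2:
        return group, [0.0] * len(group)
    sub = rf.loc[group, group].to_numpy()
    nan_pairs = [
        (group[i], group[j])
        for i, j in itertools.combinations(range(len(group)), 2)
        if math.isnan(sub[i, j])
    ]
    if nan_pairs:
        raise MapGapError(
            "no pairwise rf within group for pairs: "
            + ", ".join(f"{a}-{b}" for a, b in nan_pairs)
        )
    n = len(group)
    if n <= EXHAUSTIVE_ORDER_MAX:
        best = min(
            itertools.permutations(range(n)),
            key=lambda o: (_chain_length(o, sub), o),
        )
        order = list(best)
    else:
        # greedy: start from the tightest pair, extend the nearer end
        i0, j0 = min(
            itertools.combinations(range(n), 2), key=lambda p: sub[p[0], p[1]]
        )
        order, remaining = [i0, j0], set(range(n)) - {i0, j0}
        while remaining:
            head, tail = order[0], order[-1]
            kh = min(remaining, key=lambda k: sub[head, k])
            kt = min(remaining, key=lambda k: sub[tail, k])
            if sub[head, kh] < sub[tail, kt]:
                order.insert(0, kh)
                remaining.remove(kh)
            else:
                order.append(kt)
                remaining.remove(kt)
        order = _two_opt(order, sub)
    names = [group[i] for i in order]
    if names[-1] < names[0]:
        names.reverse()
        order.reverse()
    cum = [0.0]
    for a, b in zip(order, order[1:]):
        r = sub[a, b]
        if r >= 0.5:
            logger.warning(
                "adjacent rf %.3f >= 0.5 between %s and %s; capping for distance",
                r, group[a], group[b],
            )
            r = 0.4999
        cum.append(cum[-1] + map_distance(r, map_function))
    return names, cum


@dataclass(frozen=True)
class LinkageGroup:
    """An ordered linkage group with cumulative cM positions."""

    markers: Tuple[str, ...]
    positions_cm: Tuple[float, ...]


@dataclass(frozen=True)
class TraitPlacement:
    """Placement of a binary trait pseudo-marker on the map."""

    trait: str
    placed: bool
    group_index: Optional[int] = None
    flanking: Tuple[Tuple[str, float, float], ...] = ()  # (marker, rf, lod)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if not self.placed:
            return f"{self.trait}: unplaced"
        fl = "; ".join(f"{m} (rf={r:.3f}, LOD={l:.2f})" for m, r, l in self.flanking)
        return f"{self.trait}: group {self.group_index}, flanked by {fl}"


@dataclass
class GeneticMap:
    """Ordered linkage groups plus pairwise provenance and trait placements."""

    groups: list[LinkageGroup]
    rf: pd.DataFrame
    lod: pd.DataFrame
    n_informative: pd.DataFrame
    map_function: str
    lod_threshold: float
    placements: list[TraitPlacement] = field(default_factory=list)


def trait_vector_from_colors(
    colors: pd.Series,
    purple_origin: str = "B",
) -> pd.Series:
    """Encode a colour phenotype vector as parental-origin pseudo-marker codes.

    By default purple maps to the purple parent's band 'B' and white to 'A';
    missing phenotypes stay missing.
    """
    other = "A" if purple_origin == "B" else "B"
    mapping = {Color.PURPLE.value: purple_origin, Color.WHITE.value: other,
               Color.PURPLE: purple_origin, Color.WHITE: other}
    return colors.map(lambda c: mapping.get(c, np.nan))


def place_trait(
    trait: pd.Series,
    m: MarkerMatrix,
    gmap: GeneticMap,
    trait_name: str = "trait",
) -> TraitPlacement:
    """Place a binary trait pseudo-marker relative to an existing map.

    The trait vector (codes 'A'/'B'/missing aligned to strains) is scored
    against every marker; if its best LOD reaches the map's threshold it is
    assigned to that marker's group and the two group markers with the
    smallest rf to the trait are reported as flanking.
    """
    vec = trait.reindex(m.calls.index)
    aug = MarkerMatrix(
        pd.concat([m.calls, vec.rename("__trait__")], axis=1)
    )
    rf, lod, _ = pairwise_rf_lod(aug)
    t_rf = rf["__trait__"].drop("__trait__")
    t_lod = lod["__trait__"].drop("__trait__")
    best = t_lod.idxmax()
    if pd.isna(best) or t_lod[best] < gmap.lod_threshold:
        return TraitPlacement(trait=trait_name, placed=False)
    group_index = next(
        i for i, g in enumerate(gmap.groups) if best in g.markers
    )
    members = list(gmap.groups[group_index].markers)
    ranked = t_rf[members].sort_values(kind="stable")
    flank = tuple(
        (name, float(t_rf[name]), float(t_lod[name]))
        for name in ranked.index[: min(2, len(ranked))]
    )
    return TraitPlacement(
        trait=trait_name, placed=True, group_index=group_index, flanking=flank
    )


# ---------------------------------------------------------------------------
# Model-object facade
# ---------------------------------------------------------------------------


class TwoPointLinkage:
    """Two-point linkage model over a haploid marker matrix.

    Parameters
    ----------
    markers : :class:`MarkerMatrix` or a strains x markers DataFrame of
        'A'/'B'/missing codes.
    traits : optional mapping of trait name -> per-strain code Series
        ('A'/'B'/missing; use :func:`trait_vector_from_colors` to encode a
        colour phenotype).
    """

    def __init__(
        self,
        markers: MarkerMatrix | pd.DataFrame,
        traits: Optional[Mapping[str, pd.Series]] = None,
    ) -> None:
        self.matrix = (
            markers if isinstance(markers, MarkerMatrix) else MarkerMatrix(markers)
        )
        self.traits = dict(traits or {})

    def fit(
        self,
        lod_threshold: float = 3.0,
        map_function: str = "kosambi",
    ) -> "LinkageMapResults":
        """Compute rf/LOD, group, order, and place any traits."""
        rf, lod, n_inf = pairwise_rf_lod(self.matrix)
        groups = []
        for g in group_markers(lod, threshold=lod_threshold):
            names, cum = order_markers(g, rf, map_function=map_function)
            groups.append(
                LinkageGroup(markers=tuple(names), positions_cm=tuple(cum))
            )
        gmap = GeneticMap(
            groups=groups, rf=rf, lod=lod, n_informative=n_inf,
            map_function=map_function, lod_threshold=lod_threshold,
        )
        for name, vec in self.traits.items():
            gmap.placements.append(
                place_trait(vec, self.matrix, gmap, trait_name=name)
            )
        return LinkageMapResults(model=self, genetic_map=gmap)


@dataclass
class LinkageMapResults:
    """Fitted linkage map: groups, distances, provenance, trait placements."""

    model: TwoPointLinkage
    genetic_map: GeneticMap

    @property
    def groups(self) -> list[LinkageGroup]:
        return self.genetic_map.groups

    @property
    def placements(self) -> list[TraitPlacement]:
        return self.genetic_map.placements

    def map_frame(self) -> pd.DataFrame:
        """Long-format map table: group, marker, position (cM)."""
        rows = [
            {"group": gi + 1, "marker": mk, "position_cm": round(cm, 4)}
            for gi, g in enumerate(self.genetic_map.groups)
            for mk, cm in zip(g.markers, g.positions_cm)
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, map_path, pairwise_path=None) -> None:
        """Write the map (and optionally the pairwise rf/LOD table) as TSV."""
        self.map_frame().to_csv(map_path, sep="\t", index=False)
        if pairwise_path is not None:
            gm = self.genetic_map
            rows = []
            names = list(gm.rf.index)
            for i, j in itertools.combinations(range(len(names)), 2):
                rows.append(
                    {
                        "marker1": names[i],
                        "marker2": names[j],
                        "rf": round(float(gm.rf.iat[i, j]), 6),
                        "lod": round(float(gm.lod.iat[i, j]), 4),
                        "n_informative": int(gm.n_informative.iat[i, j]),
                    }
                )
            pd.DataFrame(rows).to_csv(pairwise_path, sep="\t", index=False)

    def to_loc(self, path, population_name: str = "mapping") -> None:
        """Export the marker matrix in a JoinMap-style .loc text layout."""
        m = self.model.matrix
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"name = {population_name}\n")
            fh.write("popt = HAP\n")
            fh.write(f"nloc = {len(m.markers)}\n")
            fh.write(f"nind = {len(m.strains)}\n\n")
            for mk in m.markers:
                calls = "".join(
                    c if isinstance(c, str) else "-" for c in m.calls[mk]
                )
                fh.write(f"{mk}\t{calls}\n")

    def summary(self) -> str:
        lines = ["Two-point linkage map", "=" * 60]
        lines.append(
            f"{len(self.genetic_map.rf)} markers, "
            f"{len(self.groups)} linkage group(s), "
            f"LOD threshold {self.genetic_map.lod_threshold:g}, "
            f"{self.genetic_map.map_function} map function"
        )
        for gi, g in enumerate(self.groups, start=1):
            lines.append("-" * 60)
            lines.append(f"Group {gi} ({len(g.markers)} markers)")
            for mk, cm in zip(g.markers, g.positions_cm):
                lines.append(f"  {mk:<16}{cm:8.2f} cM")
        for p in self.placements:
            lines.append("-" * 60)
            lines.append(str(p))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Draw linkage groups as vertical bars with marker ticks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.5 * max(1, len(self.groups)), 6))
        for gi, g in enumerate(self.groups):
            x = gi
            ax.plot([x, x], [0, max(g.positions_cm or [0])], color="k", lw=2)
            for mk, cm in zip(g.markers, g.positions_cm):
                ax.plot([x - 0.05, x + 0.05], [cm, cm], color="k", lw=1)
                ax.annotate(
                    mk, (x + 0.07, cm), fontsize=7, va="center"
                )
        ax.set_xticks(range(len(self.groups)))
        ax.set_xticklabels([f"G{i+1}" for i in range(len(self.groups))])
        ax.set_ylabel("position (cM)")
        ax.invert_yaxis()
        return ax
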