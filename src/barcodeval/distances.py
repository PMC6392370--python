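"""Kimura 2-parameter distances and barcoding-gap analysis.

The K2P distance between two aligned rows is computed from the transition
proportion P (A<->G, C<->T) and transversion proportion Q over *compared*
sites: positions where either row carries a gap, N or another ambiguity
code are excluded pair by pair (pairwise deletion), which preserves
information in length-variable regions such as ITS.

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Saturated pairs for which the logarithm is undefined are recorded as
undefined rather than clamped to an arbitrary ceiling, and are excluded
from all summaries with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from barcodeval.seqio import Alignment, TaxonMap

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class UndefinedDistanceError(ValueError):
    """The K2P estimate does not exist (saturation: log argument <= 0)."""


class NoOverlapError(ValueError):
    """Two rows share no compared (unambiguous) sites."""


@dataclass(frozen=True)
class PairCounts:
    """Sufficient statistics of the K2P estimate for one pair of rows."""

    n_compared: int
    P: float  # transition proportion
    Q: float  # transversion proportion

    def __post_init__(self):
        if self.n_compared < 1:
            raise ValueError("n_compared must be >= 1")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError("require P >= 0, Q >= 0, P + Q <= 1")


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Rows as int8 codes: A,C,G,T -> 0..3; gap/N/ambiguity -> -1."""
    mat = np.full((len(aln), aln.length), -1, dtype=np.int8)
    for i, rec in enumerate(aln):
        for j, c in enumerate(rec.sequence):
            mat[i, j] = _CODE.get(c, -1)
    return mat


def pair_counts(a: str, b: str) -> PairCounts:
    """Transition/transversion proportions for two aligned sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        cx, cy = _CODE.get(x, -1), _CODE.get(y, -1)
        if cx < 0 or cy < 0:
            continue
        n += 1
        if cx != cy:
            # purines are codes {0, 2}; a difference within a purine or
            # pyrimidine class is a transition, across classes a transversion
            if (cx % 2) == (cy % 2):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise NoOverlapError("no unambiguous sites shared by the two rows")
    return PairCounts(n_compared=n, P=ts / n, Q=tv / n)


def k2p(counts: PairCounts) -> float:
    """K2P distance in substitutions/site; exactly 0 for identical rows."""
    P, Q = counts.P, counts.Q
    if P == 0.0 and Q == 0.0:
        return 0.0
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise UndefinedDistanceError(
            f"saturated pair: P={P:.4g}, Q={Q:.4g} leaves log argument <= 0"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise K2P distances.

    Undefined (saturated or non-overlapping) entries hold NaN and are listed
    in ``undefined_pairs``.
    """

    labels: list[str]
    d: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self._index[lab] for lab in keep]
        sub = self.d[np.ix_(idx, idx)]
        undef = [
            (a, b) for a, b in self.undefined_pairs
            if a in set(keep) and b in set(keep)
        ]
        return DistanceMatrix(list(keep), sub, undef)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.10g")


def distance_matrix(aln: Alignment) -> DistanceMatrix:
    """All pairwise K2P distances of an alignment (pairwise deletion)."""
    codes = encode_alignment(aln)
    n = len(aln)
    valid = codes >= 0
    purine_parity = codes % 2  # 0 for A/G, 1 for C/T (junk where invalid)
    d = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    labels = aln.ids
    for i in range(n):
        for j in range(i + 1, n):
            mask = valid[i] & valid[j]
            m = int(mask.sum())
            if m == 0:
                d[i, j] = d[j, i] = np.nan
                undefined.append((labels[i], labels[j]))
                continue
            diff = mask & (codes[i] != codes[j])
            ts = int((diff & (purine_parity[i] == purine_parity[j])).sum())
            tv = int(diff.sum()) - ts
            try:
                val = k2p(PairCounts(m, ts / m, tv / m))
            except UndefinedDistanceError:
                val = np.nan
                undefined.append((labels[i], labels[j]))
            d[i, j] = d[j, i] = val
    return DistanceMatrix(labels, d, undefined)


@dataclass
class SpeciesGap:
    """Per-species extremes used by the distance-gap criterion."""

    species: str
    max_intra: float | None  # None: no defined intraspecific pair
    min_inter: float | None  # None: no defined interspecific pair


@dataclass
class GapSummary:
    """Intra/interspecific distance partition and its relative histogram."""

    per_species: list[SpeciesGap]
    intra: np.ndarray
    inter: np.ndarray
    bin_width: float
    bin_left_edges: np.ndarray
    intra_freq: np.ndarray  # relative frequency of intraspecific pairs per bin
    inter_freq: np.ndarray
    n_undefined_excluded: int = 0

    @property
    def intra_mean(self) -> float | None:
        return float(np.mean(self.intra)) if self.intra.size else None

    @property
    def inter_mean(self) -> float | None:
        return float(np.mean(self.inter)) if self.inter.size else None

    @property
    def intra_range(self) -> tuple[float, float] | None:
        if not self.intra.size:
            return None
        return float(self.intra.min()), float(self.intra.max())

    @property
    def inter_range(self) -> tuple[float, float] | None:
        if not self.inter.size:
            return None
        return float(self.inter.min()), float(self.inter.max())

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_left_edges,
                "intra_rel_freq": self.intra_freq,
                "inter_rel_freq": self.inter_freq,
            }
        )

    def to_dict(self) -> dict:
        return {
            "intra_mean": self.intra_mean,
            "intra_range": self.intra_range,
            "inter_mean": self.inter_mean,
            "inter_range": self.inter_range,
            "n_intra_pairs": int(self.intra.size),
            "n_inter_pairs": int(self.inter.size),
            "n_undefined_excluded": self.n_undefined_excluded,
            "per_species": [
                {
                    "species": s.species,
                    "max_intra": s.max_intra,
                    "min_inter": s.min_inter,
                }
                for s in self.per_species
            ],
        }


def partition_distances(
    m: DistanceMatrix,
    taxa: TaxonMap,
    exclude: bool = True,
    bin_width: float = 0.005,
) -> GapSummary:
    """Split pairwise distances into intra- and interspecific classes.

    Outgroups never contribute; with ``exclude=True`` single-individual
    species are removed as well (the standard study filter). Undefined
    distances are dropped from every summary and counted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    members = taxa.species_members(include_outgroups=False)
    members = {sp: [s for s in ids if s in m._index] for sp, ids in members.items()}
    members = {sp: ids for sp, ids in members.items() if ids}
    if exclude:
        members = {sp: ids for sp, ids in members.items() if len(ids) >= 2}
    if not any(len(ids) >= 2 for ids in members.values()):
        raise ValueError("no species with >= 2 individuals after exclusion")

    species_of = {sid: sp for sp, ids in members.items() for sid in ids}
    kept = [lab for lab in m.labels if lab in species_of]
    idx = {lab: m._index[lab] for lab in kept}

    intra: list[float] = []
    inter: list[float] = []
    n_undef = 0
    per_intra: dict[str, list[float]] = {sp: [] for sp in members}
    per_inter: dict[str, list[float]] = {sp: [] for sp in members}
    for a_pos, a in enumerate(kept):
        for b in kept[a_pos + 1:]:
            val = m.d[idx[a], idx[b]]
            if np.isnan(val):
                n_undef += 1
                continue
            sa, sb = species_of[a], species_of[b]
            if sa == sb:
                intra.append(val)
                per_intra[sa].append(val)
            else:
                inter.append(val)
                per_inter[sa].append(val)
                per_inter[sb].append(val)
    if n_undef:
        logger.warning(
            "%d undefined pairwise distances excluded from gap summary", n_undef
        )

    intra_arr = np.asarray(intra, dtype=float)
    inter_arr = np.asarray(inter, dtype=float)
    top = float(max(intra_arr.max(initial=0.0), inter_arr.max(initial=0.0)))
    n_bins = max(1, int(math.floor(top / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width  # left-closed, right-open
    left = edges[:-1]

    def rel_freq(values: np.ndarray) -> np.ndarray:
        if not values.size:
            return np.zeros(n_bins)
        counts, _ = np.histogram(values, bins=edges)
        # np.histogram closes the last bin on the right, matching our top edge
        return counts / values.size

    per_species = [
        SpeciesGap(
            species=sp,
            max_intra=max(per_intra[sp]) if per_intra[sp] else None,
            min_inter=min(per_inter[sp]) if per_inter[sp] else None,
        )
        for sp in sorted(members)
    ]
    return GapSummary(
        per_species=per_species,
        intra=intra_arr,
        inter=inter_arr,
        bin_width=bin_width,
        bin_left_edges=left,
        intra_freq=rel_freq(intra_arr),
        inter_freq=rel_freq(inter_arr),
        n_undefined_excluded=n_undef,
    )


def gap_criterion(g: GapSummary) -> pd.DataFrame:
    """Per-species distance-gap outcome.

    A species passes when its minimum interspecific distance strictly
    exceeds its maximum intraspecific distance; ties fail. Species without
    any defined intraspecific pair are not evaluable and are excluded from
    the resolution denominator.
    """
    rows = []
    for s in g.per_species:
        evaluable = s.max_intra is not None and s.min_inter is not None
        passes = bool(evaluable and s.min_inter > s.max_intra)
        rows.append(
            {
                "species": s.species,
                "max_intra": s.max_intra,
                "min_inter": s.min_inter,
                "evaluable": evaluable,
                "passes": passes,
            }
        )
    return pd.DataFrame(rows)
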